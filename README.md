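# tpp-triage

A prioritization engine for drug-development pipeline registries. It takes a
candidate-medicine registry and produces:

1. **Eligibility screening** — six exclusion criteria applied to
   clinical-phase candidates, with flowchart-style attrition accounting
   (`eligibility_screen`).
2. **Profile matching** — nine-parameter target-product-profile ratings per
   candidate, rated independently by two raters and merged with third-rater
   adjudication (`tpp_matching`).
3. **Scoring and tiers** — level codes and parameter weights (efficacy and
   safety weighted above the rest) turn a consensus sheet into a weighted
   score; phase-specific thresholds on the score fraction yield
   high / medium / low potential tiers (`scoring_rank`). The whole scheme is
   YAML-configurable; `default_scheme()` documents the defaults
   (codes 3/2/1/0, unknown = 0, double weight on efficacy/safety, cuts at
   0.70 / 0.40 of the maximum achievable score).
4. **Landscape summaries** — marginal counts with one-decimal (half-up)
   percentages, per-scope medicine-subclass frequency tables and
   dual-indication detection (`landscape_summary`).
5. **Traffic-light matrices** — candidate × parameter color grids with a
   final-rank column, exported as CSV, SVG or HTML (`traffic_light`).
6. **Synthetic data** — seeded generators for registries and paired rating
   sheets with a configurable inter-rater agreement probability, plus three
   bundled deterministic fixtures (`flow`, `preclinical_tables`,
   `clinical_ranks`) that reproduce published pipeline-landscape marginals
   for offline testing (`synthetic_data`).

## CLI

```bash
tpp-triage validate registry.csv
tpp-triage screen registry.csv --phases phase1,phase2,phase3,phase4 --out flow.json
tpp-triage rank registry.csv sheets.csv --scheme scheme.yaml --out ranks.csv
tpp-triage summarize registry.csv --out summary.json
tpp-triage subclasses registry.csv --scope prevention --out table.csv
tpp-triage matrix ranks.csv sheets.csv --format svg --out matrix.svg
tpp-triage fixtures --name flow --out flow.csv
```

Registries are CSV (UTF-8, header row, quoted fields) or JSON
(`{"snapshot_year": ..., "candidates": [...]}`); unknown columns are kept as
opaque annotations and round-trip. Rating sheets are wide CSV
(`candidate_id, rater_id`, one column per parameter) or long-format JSON.

## Layout

```
src/tpp_triage/
  candidate_registry.py   data model, validation, CSV/JSON I/O
  eligibility_screen.py   six-criterion screen + FlowReport
  tpp_matching.py         rating scales, sheets, adjudication
  scoring_rank.py         scoring scheme, tiers, rank tables
  landscape_summary.py    percent(), summaries, subclass tables
  traffic_light.py        color mapping, matrix build/export
  synthetic_data/         generators + bundled fixtures (data/*.csv)
  cli.py                  tpp-triage entry point
```
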