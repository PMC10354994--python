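name,indication,phase,tier
Aspirin,prevention,phase3,high
Vaginal progesterone,prevention,phase3,high
Omega-3 fatty acid,prevention,phase3,high
Pravastatin,prevention,phase3,medium
Oral progesterone,prevention,phase2,high
L-arginine,prevention,phase2,high
Selenium,prevention,phase2,high
Lactoferrin,prevention,phase1,medium
Prevention low-rank candidate 01,prevention,phase3,low
Prevention low-rank candidate 02,prevention,phase3,low
Prevention low-rank candidate 03,prevention,phase3,low
Prevention low-rank candidate 04,prevention,phase3,low
Prevention low-rank candidate 05,prevention,phase2,low
Prevention low-rank candidate 06,prevention,phase2,low
Prevention low-rank candidate 07,prevention,phase2,low
Prevention low-rank candidate 08,prevention,phase2,low
Prevention low-rank candidate 09,prevention,phase2,low
Prevention low-rank candidate 10,prevention,phase2,low
Prevention low-rank candidate 11,prevention,phase2,low
Prevention low-rank candidate 12,prevention,phase1,low
Prevention low-rank candidate 13,prevention,phase1,low
Retosiban,management,phase3,medium
Glyceryl trinitrate,management,phase3,medium
Nicardipine,management,phase2,high
Nicorandil,management,phase2,high
Isosorbide dinitrate,management,phase2,high
Celecoxib,management,phase2,high
Human chorionic gonadotropin,management,phase2,medium
Relcovaptan,management,phase2,medium
Bryophyllum pinnatum extract,management,phase1,medium
Management low-rank candidate 01,management,phase3,low
Management low-rank candidate 02,management,phase3,low
Management low-rank candidate 03,management,phase2,low
Management low-rank candidate 04,management,phase2,low
Management low-rank candidate 05,management,phase2,low
Management low-rank candidate 06,management,phase2,low
Management low-rank candidate 07,management,phase2,low
Management low-rank candidate 08,management,phase2,low
Management low-rank candidate 09,management,phase2,low
Management low-rank candidate 10,management,phase2,low
Management low-rank candidate 11,management,phase1,low
Management low-rank candidate 12,management,phase1,low
Management low-rank candidate 13,management,phase1,low
Management low-rank candidate 14,management,phase1,low
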