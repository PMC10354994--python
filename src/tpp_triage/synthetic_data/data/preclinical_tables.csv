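scope,subclass,name,archetype,route
prevention,Amino acid-peptide,AG126,new_entity,Unspecified
prevention,Amino acid-peptide,AG1288,new_entity,Unspecified
prevention,Amino acid-peptide,Anti-Toll-like receptor 4 (TLR4) monoclonal antibody,new_entity,Intravenous
prevention,Amino acid-peptide,Etanercept,repurposed,Unspecified
prevention,Amino acid-peptide,Histone deacetylase inhibitors (nanosuspension),new_entity,Vaginal
prevention,Amino acid-peptide,IMD-0560,new_entity,Vaginal
prevention,Amino acid-peptide,Melatonin,repurposed,Oral
prevention,Amino acid-peptide,NS-398,new_entity,Intravenous
prevention,Amino acid-peptide,Rytvela,new_entity,Unspecified
prevention,Amino acid-peptide,SB 202190,new_entity,Unspecified
prevention,Amino acid-peptide,SB 239063,new_entity,Unspecified
prevention,Amino acid-peptide,Super-repressor (SR) IkB-alpha (exosome delivery),new_entity,Injection
prevention,Amino acid-peptide,Synthetic TLR4,new_entity,Intravenous
prevention,Amino acid-peptide,Vaginal progesterone (nanosuspension),new_entity,"Vaginal, rectal, topical"
prevention,Antibiotics,Sirolimus,repurposed,Oral
prevention,Anti-depressant,Rolipram,new_entity,"Oral, injectable"
prevention,Cell therapy,Exosome-based protein therapeutics,new_entity,Injectable
prevention,Cell therapy,Pen-NBD (cell-penetrating peptide delivery),new_entity,Intravenous
prevention,Disease-modifying anti-rheumatic drugs,Sulfasalazine,repurposed,Oral
prevention,Enzyme inhibitors (statins),Simvastatin,repurposed,Oral
prevention,Herbal,Abeliophyllum distichum Nakai leaf extract,new_entity,Oral
prevention,Herbal,Astragali radix extract,repurposed,Oral
prevention,Herbal,Cucurbita moschata extract,repurposed,Oral
prevention,Herbal,Parthenolide,new_entity,"Oral, intravenous"
prevention,Immunosuppressant,Tocilizumab,repurposed,"Intravenous, subcutaneous"
prevention,Opioid receptor antagonist,(+)-Naloxone,new_entity,"Intravenous, intramuscular, intraperitoneal, oral"
prevention,Opioid receptor antagonist,(+)-Naltrexone,new_entity,"Intravenous, intramuscular, intraperitoneal, oral"
prevention,Organic compound,U-0126,new_entity,Subcutaneous
prevention,Polyphenol,Gallic acid,repurposed,Oral
prevention,Polyphenol,Honokial,repurposed,Oral
prevention,Polyphenol,Nobiletin,repurposed,Oral
prevention,Polyphenol,Resveratrol,repurposed,Oral
prevention,Probiotics,Microbiome therapeutics,new_entity,Unspecified
prevention,Small molecule,Sc514,new_entity,Unspecified
prevention,Small molecule,TPCA-1,new_entity,Unspecified
prevention,Unclassified,Replens gel,repurposed,Vaginal
management,Amino acid-peptide,15d-PGJ2,new_entity,Intravenous
management,Amino acid-peptide,Azapeptide analogues,new_entity,Subcutaneous
management,Amino acid-peptide,BRL 37344,new_entity,Unspecified
management,Amino acid-peptide,Butaprost,new_entity,Unspecified
management,Amino acid-peptide,CyPPA,new_entity,Injectable
management,Amino acid-peptide,Exedine-4,repurposed,"Subcutaneous, intravenous"
management,Amino acid-peptide,Leptin,repurposed,"Oral, subcutaneous"
management,Amino acid-peptide,N-acetylcysteine (nanoparticle delivery),new_entity,Intravenous
management,Amino acid-peptide,PDC113.824,new_entity,Injectable
management,Amino acid-peptide,SCH-772984,new_entity,Unspecified
management,Amino acid-peptide,SKF-86002,new_entity,Unspecified
management,Amino acid-peptide,Surfactant protein A,new_entity,Injection
management,Anti-depressant,Rolipram,new_entity,"Oral, injectable"
management,Anti-convulsant,Retigabine,repurposed,Oral
management,Anti-malarial,Chloroquine/hydroxychloroquine,repurposed,"Intravenous, oral"
management,Herbal,Carvacrol,new_entity,Unspecified
management,Herbal,"Ananas comosus, ethyl acetate fraction",repurposed,Oral
management,Herbal,Curcuma aeruginosa rhizome,repurposed,Unspecified
management,Herbal,Pimpinella anisum extract,repurposed,Oral
management,Herbal,Paeoniflorin,new_entity,Intravenous
management,Hydrogen sulfide donors,GYY4137,new_entity,Intravenous
management,Muscle relaxant,Botulinum toxin A,repurposed,"Intramuscular, intravenous"
management,Organic compound,"1,10-Phenatroline",new_entity,Unspecified
management,Organic compound,Alpha-bisabolol,repurposed,Unspecified
management,Organic compound,Citral,repurposed,"Oral, intravenous"
management,Organic compound,OXznl,new_entity,Injectable
management,Polyphenol,"Galetin 3,6-dimethyl ether",repurposed,"Intravenous, oral"
management,Polyphenol,Resveratrol,new_entity,Unspecified
management,Polyphenol,Scutellaria baicalensis root extract,repurposed,Oral
management,Polyphenol,Tannic acid,repurposed,"Oral, vaginal, topical"
management,Proton-pump inhibitors,Esomeprazole,repurposed,"Oral, intravenous"
management,Proton-pump inhibitors,Lansoprazole,repurposed,"Oral, intravenous"
management,Proton-pump inhibitors,Omeprazole,repurposed,"Oral, intravenous"
management,Proton-pump inhibitors,Pantoprazole,repurposed,"Oral, intravenous"
management,Proton-pump inhibitors,Rabeprazole,repurposed,"Oral, intravenous"
management,Thalidomide analogue,4APDPMe,new_entity,"Intravenous, intramuscular"
management,Thalidomide analogue,4NO2DPDMe,new_entity,"Intravenous, intramuscular"
management,Tocolytic,AS603831,new_entity,"Oral, intravenous"
management,Tocolytic,AS604872,new_entity,Oral
management,Tocolytic,HC067047,new_entity,Intraperitoneal
management,Tocolytic,Hydrozone sulfanilide oxytocin antagonists,new_entity,Intravenous
management,Tocolytic,Indomethacin (nanoparticle delivery),new_entity,Oral
management,Tocolytic,PGN-1473,new_entity,Intrauterine
management,Tocolytic,PGN-9856,new_entity,Injectable
management,Tocolytic,Salbutamol (nanoparticle delivery),repurposed,Unspecified
management,Tocolytic,SAR-150640,new_entity,Parenteral
management,Tocolytic,THG113.31,new_entity,"Intravenous, topical"
management,Uricosuric agent,Benzbromarone,repurposed,Oral
management,Vascular agents,Amiloride,repurposed,"Oral, intraperitoneal"
management,Vascular agents,Isradipine,repurposed,Oral
management,Vascular agents,LDD175,new_entity,Injectable
management,Vascular agents,Levosimendan,repurposed,"Intravenous, oral"
management,Vascular agents,MONNA,new_entity,Unspecified
management,Vascular agents,Nebivolol,repurposed,Oral
management,Vascular agents,Nifedipine (nanoparticle delivery),new_entity,"Intravenous, oral, rectal"
management,Vascular agents,Pinacidil,repurposed,Oral
management,Vascular agents,S-Nitrocysteine,new_entity,Injectable
management,Vascular agents,ZD-7288,new_entity,Unspecified
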