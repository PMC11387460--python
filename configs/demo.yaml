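# Demo scenario: a synthetic 20,000-report database with two antihistamine
# target drugs and three planted drug-event associations.  Runs the full
# pipeline in well under a minute on one CPU.
simulate:
  n_reports: 20000
  n_drugs: 8
  n_pts: 24
  seed: 7
  duplicate_rate: 0.10
  alias_noise_rate: 0.15
  drug_names: [cetirizine, loratadine, ibuprofen, metformin, amoxicillin,
               omeprazole, lisinopril, atorvastatin]
  # baseline reporting probabilities follow a Zipf law over this order, so
  # nonspecific terms lead and the planted PTs sit at moderate baselines
  pt_names: [DRUG INEFFECTIVE, HEADACHE, NAUSEA, FATIGUE, RASH, DIZZINESS,
             VOMITING, SOMNOLENCE, DIARRHOEA, PRURITUS, URTICARIA, SNEEZING,
             RHINORRHOEA, NASAL CONGESTION, COUGH, DYSPNOEA, INSOMNIA,
             NERVOUSNESS, ANXIETY, PALPITATIONS, OVERDOSE,
             LACRIMATION INCREASED, VISION BLURRED, PERICARDITIS]
  planted_signals:
    - {drug: cetirizine, pt: SOMNOLENCE, lambda: 8.0}
    - {drug: cetirizine, pt: PERICARDITIS, lambda: 6.0}
    - {drug: loratadine, pt: SNEEZING, lambda: 10.0}
targets: [cetirizine, loratadine]
exclusions: [levocetirizine, pseudoephedrine]
roles: [PS, SS]
levels: [PT, SOC]
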