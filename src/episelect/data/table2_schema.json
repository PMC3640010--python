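[
  {"name": "Gender", "categories": ["Male", "Female"], "ordinal": false},
  {"name": "Side", "categories": ["Left", "Right"], "ordinal": false},
  {"name": "SurgeryAge", "categories": ["17-32", "33-54"], "ordinal": true},
  {"name": "OnsetAge", "categories": ["0-1", "2-10", "11-20"], "ordinal": true},
  {"name": "ElapsedTime", "categories": ["7-13", "14-19", "20-39"], "ordinal": true},
  {"name": "SeizureType", "categories": ["Generalized", "Partial Complex", "Both"], "ordinal": false},
  {"name": "SeizureFreq", "categories": ["Daily", "Weekly", "2-Weekly", "3-Weekly", "4-Weekly", "Other"], "ordinal": false},
  {"name": "Febrile", "categories": ["Negative", "Positive"], "ordinal": false},
  {"name": "VIQ", "categories": ["Low", "Normal-Low", "Normal", "Normal-High", "High"], "ordinal": true},
  {"name": "PIQ", "categories": ["Low", "Normal-Low", "Normal", "Normal-High", "High"], "ordinal": true},
  {"name": "FSIQ", "categories": ["Low", "Normal-Low", "Normal", "Normal-High", "High"], "ordinal": true},
  {"name": "MlogI", "categories": ["Low", "Normal-Low", "Normal", "Normal-High", "High"], "ordinal": true},
  {"name": "MlogII", "categories": ["Low", "Normal-Low", "Normal", "Normal-High", "High"], "ordinal": true},
  {"name": "MvisI", "categories": ["Low", "Normal-Low", "Normal", "Normal-High", "High"], "ordinal": true},
  {"name": "MvisII", "categories": ["Low", "Normal-Low", "Normal", "Normal-High", "High"], "ordinal": true},
  {"name": "Sczi", "categories": ["Negative", "Positive"], "ordinal": false},
  {"name": "Cdi", "categories": ["Negative", "Positive"], "ordinal": false},
  {"name": "Depi", "categories": ["Negative", "Positive"], "ordinal": false},
  {"name": "P.Style", "categories": ["EB1", "EB2", "EB3"], "ordinal": false}
]
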