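{
  "index_factor": "CKD",
  "factors": [
    {"name": "Cerebrovascular Disease", "abbreviation": "CVD", "codes": "430-438", "kind": "diagnosis"},
    {"name": "Chronic Kidney Disease", "abbreviation": "CKD", "codes": "585, 586", "kind": "diagnosis"},
    {"name": "Congestive Heart Failure", "abbreviation": "CHF", "codes": "398.91, 402, 404, 425.4-425.9, 428", "kind": "diagnosis"},
    {"name": "Coronary Artery Disease", "abbreviation": "CAD", "codes": "410-414", "kind": "diagnosis"},
    {"name": "Diabetes mellitus", "abbreviation": "DM", "codes": "250", "kind": "diagnosis"},
    {"name": "Glomerulonephritis", "abbreviation": "GN", "codes": "582", "kind": "diagnosis"},
    {"name": "Hemodialysis", "abbreviation": "HD", "codes": "58001C,58019C,58020C,58021C,58022C,58023C,58024C,58025C,58027C,58029C,58030B", "kind": "procedure"},
    {"name": "Hyperlipidemia", "abbreviation": "Hyperlipidemia", "codes": "272", "kind": "diagnosis"},
    {"name": "Hypertension", "abbreviation": "HTN", "codes": "401", "kind": "diagnosis"},
    {"name": "Peritoneal Dialysis", "abbreviation": "PD", "codes": "58002C,58009B,58010B,58011C,58012B,58017C,58028C", "kind": "procedure"},
    {"name": "Polycystic Kidney Disease", "abbreviation": "PKD", "codes": "75312", "kind": "diagnosis"},
    {"name": "Proteinuria", "abbreviation": "Proteinuria", "codes": "791", "kind": "diagnosis"},
    {"name": "Renal stone", "abbreviation": "Renal stone", "codes": "592", "kind": "diagnosis"},
    {"name": "Renal transplantation", "abbreviation": "RTPL", "codes": "V420", "kind": "diagnosis"},
    {"name": "Systemic Lupus Erythematosus", "abbreviation": "SLE", "codes": "7100", "kind": "diagnosis"}
  ]
}
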