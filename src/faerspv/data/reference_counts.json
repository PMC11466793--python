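{
  "comment": "Published marginal counts from a FAERS analysis (2011Q1-2023Q2) of interstitial lung disease among ALK tyrosine-kinase-inhibitor reports; used for arithmetic-consistency checks of the reporting conventions.",
  "database": {
    "total_reports": 15656531,
    "duplicates_removed": 2126495,
    "under18_removed": 439205,
    "retained": 13090831
  },
  "alk_reports": {
    "total": 20064,
    "crizotinib": 9130,
    "ceritinib": 1929,
    "alectinib": 4673,
    "brigatinib": 2138,
    "lorlatinib": 2492
  },
  "ild_cases": {
    "total": 640,
    "crizotinib": 294,
    "ceritinib": 51,
    "alectinib": 157,
    "brigatinib": 94,
    "lorlatinib": 44
  },
  "ild_outcome_records": {
    "crizotinib": {"hospitalization": 166, "disability": 10, "life_threatening": 51, "death": 98, "other": 149},
    "ceritinib": {"hospitalization": 24, "disability": 1, "life_threatening": 6, "death": 11, "other": 17},
    "alectinib": {"hospitalization": 71, "disability": 1, "life_threatening": 13, "death": 18, "other": 31},
    "brigatinib": {"hospitalization": 56, "disability": 1, "life_threatening": 7, "death": 15, "other": 22},
    "lorlatinib": {"hospitalization": 20, "disability": 0, "life_threatening": 6, "death": 14, "other": 20}
  },
  "ild_sex": {
    "crizotinib": {"male": 131, "female": 140, "unknown": 23},
    "ceritinib": {"male": 21, "female": 23, "unknown": 7},
    "alectinib": {"male": 80, "female": 62, "unknown": 15},
    "brigatinib": {"male": 30, "female": 48, "unknown": 16},
    "lorlatinib": {"male": 25, "female": 16, "unknown": 3}
  }
}
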