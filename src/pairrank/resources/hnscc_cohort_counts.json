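{
  "cohort": "TCGA HNSCC",
  "description": "Published per-group clinical counts for the head-and-neck squamous cell carcinoma training cohort, stratified by gene-pair risk group. Counts only; percentages are recomputed by cohort_table.",
  "groups": {
    "low": {
      "n": 286,
      "gender": {"Female": 72, "Male": 214},
      "t_stage": {"T1-2": 126, "T3-4": 157, "Missing": 3},
      "n_stage": {"N-": 133, "N+": 148, "Missing": 5},
      "m_stage": {"M0": 274, "M1": 2, "Missing": 10},
      "grade": {"I-II": 70, "III-IV": 216}
    },
    "high": {
      "n": 186,
      "gender": {"Female": 53, "Male": 133},
      "t_stage": {"T1-2": 57, "T3-4": 129, "Missing": 0},
      "n_stage": {"N-": 66, "N+": 119, "Missing": 1},
      "m_stage": {"M0": 181, "M1": 2, "Missing": 3},
      "grade": {"I-II": 27, "III-IV": 159}
    }
  }
}
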