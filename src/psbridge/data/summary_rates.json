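{
  "group_sizes": {
    "PALI_6_12": 179,
    "RIS_2_4": 113,
    "RIS_4_6": 129,
    "PLACEBO_PALI": 95,
    "PLACEBO_RIS": 122
  },
  "completion_pct": {
    "PALI_6_12": 64.8,
    "RIS_2_4": 54.0,
    "RIS_4_6": 66.7,
    "PLACEBO_PALI": 36.8,
    "PLACEBO_RIS": 51.6
  },
  "printed_adjusted_completion_pct": {
    "PALI_6_12": 28.0,
    "RIS_2_4": 2.4,
    "RIS_4_6": 15.1
  },
  "response_pct": {
    "PALI_6_12": 55.1,
    "RIS_2_4": 40.7,
    "RIS_4_6": 51.6,
    "POOLED_PLACEBO": 28.1
  },
  "printed_response_diff_pct": {
    "PALI_6_12_vs_RIS_2_4": 14.4,
    "PALI_6_12_vs_RIS_4_6": 3.5
  }
}
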