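{
  "description": "Published cross-classification of the five liver metastasis subtypes (rows) against the translated CMS and the CRIS frameworks, as printed: per row one undelimited digit run covering the 4 CMS cells followed by the 5 CRIS cells, plus the marginal facts printed alongside (count/denominator pairs, confident-classification totals, subtype prevalence percentages and Pearson chi-squared statistics) used to validate the parse.",
  "row_labels": ["LMS1", "LMS2", "LMS3", "LMS4", "LMS5"],
  "cms_columns": ["CMS1", "CMS2", "CMS3", "CMS4"],
  "cris_columns": ["CRIS-A", "CRIS-B", "CRIS-C", "CRIS-D", "CRIS-E"],
  "digit_runs": [
    "104171312103",
    "080141612",
    "015010334105",
    "03202433125",
    "1003893482"
  ],
  "constraints": {
    "known_cells_cms": {"LMS1,CMS1": 10, "LMS5,CMS4": 38},
    "known_cells_cris": {"LMS4,CRIS-C": 31},
    "cms_column_sums": {"CMS1": 11, "CMS4": 58},
    "cms_row_sums": {"LMS1": 22},
    "cris_row_sums": {"LMS4": 45},
    "cris_total": 139,
    "cohort_size": 169,
    "lms_prevalence_percent": [18, 10, 19, 30, 24],
    "chi2_cms": 151.9,
    "chi2_cris": 82.9
  }
}
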