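{
  "comment": "Published group-level summary of the reference study: per-group mean (SD) number of different emotion words and Spearman similarity of the group's production matrix to the adult matrix over the 20 x 66 = 1320 flattened cells.",
  "age_groups": ["4-5", "6-7", "8-9", "10-11", "adult"],
  "mean_words": {"4-5": 4.4, "6-7": 5.4, "8-9": 7.0, "10-11": 9.7, "adult": 14.7},
  "sd_words": {"4-5": 1.4, "6-7": 1.1, "8-9": 1.8, "10-11": 2.3, "adult": 2.4},
  "similarity_to_adult": {"4-5": 0.329, "6-7": 0.405, "8-9": 0.443, "10-11": 0.551},
  "n_cells": 1320,
  "n_words_total": 66,
  "anova": {"F": 139.9, "df1": 4, "df2": 145, "eta_squared": 0.79}
}
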