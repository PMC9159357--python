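{
  "condition_lineA": {
    "blue_red_ratio": null,
    "median_RE_4sU": -0.568131,
    "median_RE_FT": -0.599415,
    "median_RE_total": -0.626858,
    "median_SS_by_gene_type": {
      "lncRNA": -2.75337,
      "mRNA": -1.455444,
      "pseudogene": -1.237696
    },
    "median_dSS_ipa_minus_tpa": -0.480755,
    "n_blue": 1,
    "n_red": 0
  },
  "condition_lineB": {
    "blue_red_ratio": null,
    "median_RE_4sU": -0.602581,
    "median_RE_FT": -0.689334,
    "median_RE_total": -0.24038,
    "median_SS_by_gene_type": {
      "lncRNA": -2.438776,
      "mRNA": -1.347737,
      "pseudogene": -1.679277
    },
    "median_dSS_ipa_minus_tpa": -0.826027,
    "n_blue": 3,
    "n_red": 0
  },
  "condition_lineC": {
    "blue_red_ratio": null,
    "median_RE_4sU": -0.388239,
    "median_RE_FT": -0.805173,
    "median_RE_total": -0.865846,
    "median_SS_by_gene_type": {
      "lncRNA": -2.650578,
      "mRNA": -1.246139,
      "pseudogene": -1.395561
    },
    "median_dSS_ipa_minus_tpa": -1.188826,
    "n_blue": 4,
    "n_red": 0
  },
  "n_genes_detected": 20,
  "n_genes_with_apa_pair": 15,
  "n_ipa_events": 7,
  "n_pas_clusters": 47,
  "n_pas_expressed": 47,
  "region_class_counts": {
    "IPA": 7,
    "TPA": 40
  },
  "thresholds": {
    "alpha": 0.05,
    "cluster_window": 24,
    "fdr": 0.05,
    "min_clip_t": 2,
    "min_mapq": 10,
    "min_reads": 5,
    "pseudocount": 1.0,
    "rel_abund": 0.05,
    "seed": 7,
    "strict_gt5": false
  }
}
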