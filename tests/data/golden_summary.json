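{
  "cms_threshold": 5.405049,
  "n_genes_assigned": 0,
  "n_selected_snvs": 1,
  "qc": {
    "n_samples_in": 75,
    "n_samples_out": 73,
    "n_variants_in": 1343,
    "n_variants_out": 1289,
    "removed": {
      "het_outlier": 2,
      "hwe": 5,
      "ibd": 0,
      "sample_missing": 0,
      "singleton": 43,
      "variant_missing": 6
    },
    "thresholds": {
      "het_sd": 3.0,
      "hwe_p": 1e-06,
      "ibd_pi_hat": null,
      "sample_miss": 0.03,
      "var_miss": 0.05
    }
  },
  "regions": {
    "n_gene_overlapping": 0,
    "n_regions": 1,
    "n_unannotated": 1
  }
}
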