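{
  "comment": "Published M. incognita LGT survey counts used as worked-example inputs: copy-number distributions of laterally acquired genes, duplication-cohort counts from the supported trees, and in-paralog group counts.",
  "proteome_size_minc": 20359,
  "proteome_size_mhap": 14421,
  "orthomcl_blast_distribution": {
    "singletons": 202,
    "rows": [
      [1, 65, 65],
      [2, 59, 118],
      [3, 23, 69],
      [4, 16, 64],
      [5, 6, 30],
      [6, 2, 12],
      [7, 5, 35],
      [8, 2, 16],
      [">8", 5, 69]
    ]
  },
  "phylogenetic_distribution": {
    "singletons": 0,
    "rows": [
      [1, 34, 34],
      [2, 27, 54],
      [3, 10, 30],
      [4, 9, 36],
      [5, 7, 35],
      [6, 2, 12],
      [7, 3, 21],
      [8, 2, 16],
      [">8", 28, 275]
    ]
  },
  "duplication_cohort": {
    "n_both_species": 92,
    "n_duplicated": 76,
    "n_before": 60,
    "n_after_given_before": 43
  },
  "inparalogs": {
    "n_lgt_genes_in_groups": 206,
    "n_lgt_genes_duplicated": 123,
    "n_genome_groups": 7647,
    "n_genome_groups_duplicated": 2137
  },
  "mobile_elements": {
    "n_loose": 146,
    "element_counts": {"plasmid": 117, "prophage": 19, "virus": 10},
    "n_strict": 32
  }
}
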