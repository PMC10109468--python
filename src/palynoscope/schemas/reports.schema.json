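{
  "flow_report.json": {
    "required": [
      "master_seed",
      "n_images",
      "n_agreement",
      "n_agreement_no_fossil",
      "n_agreement_fossil",
      "n_fossil_pollen_spore",
      "n_fossil_unknown",
      "n_disputed",
      "n_no_agreement",
      "n_review_queue",
      "n_pending"
    ],
    "types": {"*": "number"}
  },
  "review_queue.json": {
    "required": ["master_seed", "queue", "workload"],
    "types": {"master_seed": "number", "queue": "array", "workload": "object"}
  },
  "census.json": {
    "required": [
      "master_seed",
      "rows",
      "n_unique",
      "n_identifiable",
      "n_indeterminable",
      "total_area_cm2"
    ],
    "types": {"rows": "array", "*": "number"}
  },
  "performance.json": {
    "required": [
      "master_seed",
      "recall",
      "n_truth",
      "n_matched",
      "missed_specimen_ids",
      "n_false_clusters"
    ],
    "types": {"missed_specimen_ids": "array", "*": "number"}
  }
}
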