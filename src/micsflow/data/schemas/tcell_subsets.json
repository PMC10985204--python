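{
  "name": "tcell_subsets",
  "unassigned_label": "other T",
  "populations": [
    {"label": "Treg", "priority": 3, "gate": {"all": [{"marker": "CD3", "positive": true}, {"marker": "CD4", "positive": true}, {"marker": "FoxP3", "positive": true}, {"marker": "CD25", "positive": true}]}},
    {"label": "Th", "priority": 2, "gate": {"all": [{"marker": "CD3", "positive": true}, {"marker": "CD4", "positive": true}, {"marker": "CD8", "positive": false}]}},
    {"label": "Tc", "priority": 1, "gate": {"all": [{"marker": "CD3", "positive": true}, {"marker": "CD8", "positive": true}, {"marker": "CD4", "positive": false}]}}
  ]
}
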