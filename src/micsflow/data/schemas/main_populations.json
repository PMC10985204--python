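{
  "name": "main_populations",
  "unassigned_label": "unassigned",
  "populations": [
    {"label": "Plasma cells", "priority": 16, "gate": {"all": [{"marker": "CD38", "positive": true}, {"marker": "CD138", "positive": true}]}},
    {"label": "Mast cells", "priority": 15, "gate": {"marker": "CD117", "positive": true}},
    {"label": "pDC", "priority": 14, "gate": {"marker": "CD123", "positive": true}},
    {"label": "Granulocytes", "priority": 13, "gate": {"marker": "CD66b", "positive": true}},
    {"label": "Macrophages", "priority": 12, "gate": {"marker": "CD163", "positive": true}},
    {"label": "MDSC", "priority": 11, "gate": {"all": [{"marker": "CD11b", "positive": true}, {"marker": "S100A8", "positive": true}, {"marker": "HLA-DR", "positive": false}]}},
    {"label": "Monocytes", "priority": 10, "gate": {"all": [{"marker": "CD64", "positive": true}, {"marker": "CD11b", "positive": true}, {"marker": "CD163", "positive": false}]}},
    {"label": "mDC", "priority": 9, "gate": {"all": [{"marker": "CD11c", "positive": true}, {"marker": "CD64", "positive": false}, {"marker": "CD163", "positive": false}]}},
    {"label": "NK cells", "priority": 8, "gate": {"all": [{"marker": "CD56", "positive": true}, {"marker": "CD3", "positive": false}]}},
    {"label": "T cells", "priority": 7, "gate": {"all": [{"marker": "CD45", "positive": true}, {"marker": "CD3", "positive": true}]}},
    {"label": "B cells", "priority": 6, "gate": {"all": [{"marker": "CD19", "positive": true}, {"marker": "CD3", "positive": false}]}},
    {"label": "Endothelial", "priority": 5, "gate": {"all": [{"marker": "CD31", "positive": true}, {"marker": "CD45", "positive": false}]}},
    {"label": "Epithelial", "priority": 4, "gate": {"all": [{"marker": "PanCK", "positive": true}, {"marker": "CD45", "positive": false}]}},
    {"label": "Platelets", "priority": 3, "gate": {"all": [{"marker": "CD61", "positive": true}, {"marker": "CD45", "positive": false}]}},
    {"label": "Erythrocytes", "priority": 2, "gate": {"all": [{"marker": "CD36", "positive": true}, {"marker": "CD45", "positive": false}, {"marker": "CD61", "positive": false}, {"marker": "CD31", "positive": false}]}},
    {"label": "Fibroblasts", "priority": 1, "gate": {"all": [{"marker": "FSP1", "positive": true}, {"marker": "CD45", "positive": false}, {"marker": "PanCK", "positive": false}]}}
  ]
}
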