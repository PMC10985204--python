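{
  "name": "tonsil",
  "unassigned_label": "unassigned",
  "populations": [
    {"label": "Plasma cells", "priority": 13, "gate": {"all": [{"marker": "CD38", "positive": true}, {"marker": "CD138", "positive": true}]}},
    {"label": "Mast cells", "priority": 12, "gate": {"marker": "CD117", "positive": true}},
    {"label": "pDC", "priority": 11, "gate": {"marker": "CD123", "positive": true}},
    {"label": "Granulocytes", "priority": 10, "gate": {"marker": "CD66b", "positive": true}},
    {"label": "Macrophages", "priority": 9, "gate": {"marker": "CD163", "positive": true}},
    {"label": "mDC", "priority": 8, "gate": {"all": [{"marker": "CD11c", "positive": true}, {"marker": "CD163", "positive": false}]}},
    {"label": "NK cells", "priority": 7, "gate": {"all": [{"marker": "CD56", "positive": true}, {"marker": "CD3", "positive": false}]}},
    {"label": "T cells", "priority": 6, "gate": {"all": [{"marker": "CD45", "positive": true}, {"marker": "CD3", "positive": true}]}},
    {"label": "B cells", "priority": 5, "gate": {"all": [{"marker": "CD19", "positive": true}, {"marker": "CD3", "positive": false}]}},
    {"label": "Lymphatic vessels", "priority": 4, "gate": {"all": [{"marker": "Podoplanin", "positive": true}, {"marker": "CD45", "positive": false}]}},
    {"label": "Blood vessels", "priority": 3, "gate": {"all": [{"marker": "CD31", "positive": true}, {"marker": "CD45", "positive": false}, {"marker": "Podoplanin", "positive": false}]}},
    {"label": "Squamous epithelium", "priority": 2, "gate": {"all": [{"marker": "PanCK", "positive": true}, {"marker": "CD45", "positive": false}]}},
    {"label": "Fibroblasts", "priority": 1, "gate": {"all": [{"marker": "FSP1", "positive": true}, {"marker": "CD45", "positive": false}, {"marker": "PanCK", "positive": false}]}}
  ]
}
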