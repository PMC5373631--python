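[
 {"id": "t7", "value": 36, "cmp": "eq", "tolerance": 0,
  "units": "branches",
  "claim": "whole-cell count of major-process branch paths"},
 {"id": "t8", "value": 39.0, "cmp": "eq", "tolerance": 0.78,
  "units": "um",
  "claim": "mean centroid distance of the three furthest endpoints"},
 {"id": "t11", "value": 90.0, "cmp": "ge", "tolerance": 0.0,
  "units": "%",
  "claim": "minimum relative steady concentration over cell-body cells in the stratification model"}
]
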