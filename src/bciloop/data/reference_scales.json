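{
  "note": "Serial clinical-scale totals recorded for the single trial participant. Stored as reference data only: the item-level inputs needed to recompute them are not available.",
  "fugl_meyer_upper_extremity": {
    "timepoints": ["1 month pre-implant", "1 month post-implant", "7 weeks post-implant"],
    "scores": [30, 36, 38],
    "maximum": 66
  },
  "motricity_index": {
    "timepoints": ["1 month pre-implant", "2 months post-implant", "3 months post-implant"],
    "scores": [48, 61.5, 75.5]
  },
  "stroke_impact_scale": {
    "timepoints": ["1 month pre-implant", "6 months post-implant"],
    "scores": [232, 269],
    "range": [64, 320]
  },
  "jebsen_taylor_variant_move5_seconds": {
    "myoelectric": 146,
    "bci": 95
  },
  "modified_ashworth": {
    "note": "Serial measurements declined gradually over the implantation phase (0 = normal tone, 4 = most spastic)."
  }
}
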