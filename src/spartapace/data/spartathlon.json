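{
  "name": "Spartathlon",
  "time_limit_hours": 36.0,
  "total_km": 246.8,
  "checkpoints": [
    {"index": 1, "label": "Athens-Corinth", "segment_km": 19.5},
    {"index": 2, "label": "Athens-Corinth", "segment_km": 22.7},
    {"index": 3, "label": "Athens-Corinth", "segment_km": 37.8},
    {"index": 4, "label": "Corinth-Nemea", "segment_km": 20.1},
    {"index": 5, "label": "Corinth-Nemea", "segment_km": 23.2},
    {"index": 6, "label": "Nemea-Nestani", "segment_km": 36.2},
    {"index": 7, "label": "Nemea-Nestani", "segment_km": 12.0},
    {"index": 8, "label": "Nestani-Tegea", "segment_km": 23.8},
    {"index": 9, "label": "Tegea-Sparta", "segment_km": 31.4},
    {"index": 10, "label": "Tegea-Sparta", "segment_km": 20.1}
  ]
}
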