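{
  "mabc": {
    "n_items": 16,
    "answer_grid": [0, 25, 50, 75, 100],
    "scale": [0, 100],
    "higher_is_better": true
  },
  "dhi": {
    "n_items": 25,
    "answers": ["yes", "sometimes", "no"],
    "weights": {"yes": 4, "sometimes": 2, "no": 0},
    "scale": [0, 100],
    "mdc": 18,
    "higher_is_better": false
  },
  "drs": {
    "scale": [0, 5],
    "categories": [
      {"label": "None", "min": 0, "max": 1},
      {"label": "Mild", "min": 2, "max": 2},
      {"label": "Moderate", "min": 3, "max": 3},
      {"label": "Severe", "min": 4, "max": 5}
    ],
    "mdc": 1,
    "higher_is_better": false
  },
  "vas": {
    "scale": [0, 10],
    "mdc_by_variant": {"vas_dizziness": 4.3},
    "higher_is_better": false
  },
  "mmst": {
    "n_movements": 10,
    "intensity_scale": [0, 10],
    "duration_points": [
      {"min_s": 0, "max_s": 5, "points": 0, "max_exclusive": true},
      {"min_s": 5, "max_s": 10, "points": 1, "max_exclusive": false},
      {"min_s": 10, "max_s": 30, "points": 2, "min_exclusive": true, "max_exclusive": false},
      {"min_s": 30, "max_s": null, "points": 3, "min_exclusive": true}
    ],
    "quotient_divisor": 20.48,
    "higher_is_better": false
  },
  "sus": {
    "n_items": 10,
    "item_scale": [1, 5],
    "scale": [0, 100],
    "curved_grades": [
      {"grade": "A+", "min": 84.1},
      {"grade": "A", "min": 80.8},
      {"grade": "A-", "min": 78.9},
      {"grade": "B+", "min": 77.2},
      {"grade": "B", "min": 74.1},
      {"grade": "B-", "min": 72.6},
      {"grade": "C+", "min": 71.1},
      {"grade": "C", "min": 65.0},
      {"grade": "C-", "min": 62.7},
      {"grade": "D", "min": 51.7},
      {"grade": "F", "min": 0.0}
    ],
    "higher_is_better": true
  }
}
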