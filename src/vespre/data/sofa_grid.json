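{
  "description": "Standard Sepsis-3 SOFA scoring grid, one organ system per entry. Each organ lists score bands over the worst in-window value. Direction 'low' means lower values are worse (band matches when value < upper using strict/non-strict rule per band); 'high' means higher values are worse. Respiration sub-scores 3-4 conventionally also require ventilatory support, which this event model does not carry, so the grid scores on the P/F ratio alone. Cardiovascular sub-scores above 2 require vasopressor dose rates; any vasopressor administration scores a floor of 2.",
  "organs": {
    "respiration": {
      "variable": "pf_ratio",
      "direction": "low",
      "bands": [
        {"score": 4, "below": 100},
        {"score": 3, "below": 200},
        {"score": 2, "below": 300},
        {"score": 1, "below": 400}
      ]
    },
    "coagulation": {
      "variable": "platelets",
      "direction": "low",
      "bands": [
        {"score": 4, "below": 20},
        {"score": 3, "below": 50},
        {"score": 2, "below": 100},
        {"score": 1, "below": 150}
      ]
    },
    "liver": {
      "variable": "bilirubin",
      "direction": "high",
      "bands": [
        {"score": 4, "at_least": 12.0},
        {"score": 3, "at_least": 6.0},
        {"score": 2, "at_least": 2.0},
        {"score": 1, "at_least": 1.2}
      ]
    },
    "cardiovascular": {
      "variable": "map",
      "direction": "low",
      "bands": [
        {"score": 1, "below": 70}
      ],
      "vasopressor_floor": 2
    },
    "cns": {
      "variable": "gcs",
      "direction": "low",
      "bands": [
        {"score": 4, "below": 6},
        {"score": 3, "below": 10},
        {"score": 2, "below": 13},
        {"score": 1, "below": 15}
      ]
    },
    "renal": {
      "variable": "creatinine",
      "direction": "high",
      "bands": [
        {"score": 4, "at_least": 5.0},
        {"score": 3, "at_least": 3.5},
        {"score": 2, "at_least": 2.0},
        {"score": 1, "at_least": 1.2}
      ]
    }
  }
}
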