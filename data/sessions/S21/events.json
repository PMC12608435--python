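{
  "recording_start": 1600000000.0,
  "pss": 12,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000224.9885235,
      "points": 3,
      "errors": 3
    },
    {
      "level": 2,
      "start_unix": 1600000224.9885235,
      "stop_unix": 1600000251.8770812,
      "points": 6,
      "errors": 2
    },
    {
      "level": 3,
      "start_unix": 1600000251.8770812,
      "stop_unix": 1600000277.680471,
      "points": 6,
      "errors": 4
    },
    {
      "level": 4,
      "start_unix": 1600000277.680471,
      "stop_unix": 1600000313.6477165,
      "points": 8,
      "errors": 2
    }
  ]
}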