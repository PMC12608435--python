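{
  "recording_start": 1600000000.0,
  "pss": 11,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000228.236562,
      "points": 6,
      "errors": 0
    },
    {
      "level": 2,
      "start_unix": 1600000228.236562,
      "stop_unix": 1600000256.8284805,
      "points": 6,
      "errors": 2
    },
    {
      "level": 3,
      "start_unix": 1600000256.8284805,
      "stop_unix": 1600000288.9595418,
      "points": 10,
      "errors": 0
    },
    {
      "level": 4,
      "start_unix": 1600000288.9595418,
      "stop_unix": 1600000313.0601425,
      "points": 7,
      "errors": 3
    }
  ]
}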