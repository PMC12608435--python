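{
  "recording_start": 1600000000.0,
  "pss": 13,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000225.8229616,
      "points": 2,
      "errors": 4
    },
    {
      "level": 2,
      "start_unix": 1600000225.8229616,
      "stop_unix": 1600000251.21817,
      "points": 5,
      "errors": 3
    },
    {
      "level": 3,
      "start_unix": 1600000251.21817,
      "stop_unix": 1600000284.6483774,
      "points": 5,
      "errors": 5
    },
    {
      "level": 4,
      "start_unix": 1600000284.6483774,
      "stop_unix": 1600000319.9637432,
      "points": 6,
      "errors": 4
    }
  ]
}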