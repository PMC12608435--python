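{
  "recording_start": 1600000000.0,
  "pss": 22,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000223.8533015,
      "points": 4,
      "errors": 2
    },
    {
      "level": 2,
      "start_unix": 1600000223.8533015,
      "stop_unix": 1600000258.3656125,
      "points": 8,
      "errors": 0
    },
    {
      "level": 3,
      "start_unix": 1600000258.3656125,
      "stop_unix": 1600000284.2480643,
      "points": 9,
      "errors": 1
    },
    {
      "level": 4,
      "start_unix": 1600000284.2480643,
      "stop_unix": 1600000317.0897574,
      "points": 9,
      "errors": 1
    }
  ]
}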