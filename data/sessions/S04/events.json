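{
  "recording_start": 1600000000.0,
  "pss": 9,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000228.4427993,
      "points": 5,
      "errors": 1
    },
    {
      "level": 2,
      "start_unix": 1600000228.4427993,
      "stop_unix": 1600000258.9492362,
      "points": 8,
      "errors": 0
    },
    {
      "level": 3,
      "start_unix": 1600000258.9492362,
      "stop_unix": 1600000294.1338036,
      "points": 10,
      "errors": 0
    },
    {
      "level": 4,
      "start_unix": 1600000294.1338036,
      "stop_unix": 1600000324.127745,
      "points": 9,
      "errors": 1
    }
  ]
}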