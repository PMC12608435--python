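{
  "recording_start": 1600000000.0,
  "pss": 26,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000228.425423,
      "points": 6,
      "errors": 0
    },
    {
      "level": 2,
      "start_unix": 1600000228.425423,
      "stop_unix": 1600000255.847476,
      "points": 8,
      "errors": 0
    },
    {
      "level": 3,
      "start_unix": 1600000255.847476,
      "stop_unix": 1600000289.4749916,
      "points": 7,
      "errors": 3
    },
    {
      "level": 4,
      "start_unix": 1600000289.4749916,
      "stop_unix": 1600000318.4601402,
      "points": 9,
      "errors": 1
    }
  ]
}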