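{
  "recording_start": 1600000000.0,
  "pss": 25,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000226.2869248,
      "points": 4,
      "errors": 2
    },
    {
      "level": 2,
      "start_unix": 1600000226.2869248,
      "stop_unix": 1600000250.7497985,
      "points": 6,
      "errors": 2
    },
    {
      "level": 3,
      "start_unix": 1600000250.7497985,
      "stop_unix": 1600000274.936933,
      "points": 7,
      "errors": 3
    },
    {
      "level": 4,
      "start_unix": 1600000274.936933,
      "stop_unix": 1600000304.7824898,
      "points": 5,
      "errors": 5
    }
  ]
}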