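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
      "stop_unix": 1600000228.4047265,
      "points": 5,
      "errors": 1
    },
    {
      "level": 2,
      "start_unix": 1600000228.4047265,
      "stop_unix": 1600000262.3618681,
      "points": 8,
      "errors": 0
    },
    {
      "level": 3,
      "start_unix": 1600000262.3618681,
      "stop_unix": 1600000286.765631,
      "points": 8,
      "errors": 2
    },
    {
      "level": 4,
      "start_unix": 1600000286.765631,
      "stop_unix": 1600000311.1839786,
      "points": 10,
      "errors": 0
    }
  ]
}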