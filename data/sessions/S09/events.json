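{
  "recording_start": 1600000000.0,
  "pss": 21,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000227.0863454,
      "points": 6,
      "errors": 0
    },
    {
      "level": 2,
      "start_unix": 1600000227.0863454,
      "stop_unix": 1600000257.6128833,
      "points": 8,
      "errors": 0
    },
    {
      "level": 3,
      "start_unix": 1600000257.6128833,
      "stop_unix": 1600000288.784663,
      "points": 9,
      "errors": 1
    },
    {
      "level": 4,
      "start_unix": 1600000288.784663,
      "stop_unix": 1600000318.8217814,
      "points": 9,
      "errors": 1
    }
  ]
}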