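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
      "stop_unix": 1600000227.6630142,
      "points": 5,
      "errors": 1
    },
    {
      "level": 2,
      "start_unix": 1600000227.6630142,
      "stop_unix": 1600000252.5660844,
      "points": 8,
      "errors": 0
    },
    {
      "level": 3,
      "start_unix": 1600000252.5660844,
      "stop_unix": 1600000280.8477771,
      "points": 9,
      "errors": 1
    },
    {
      "level": 4,
      "start_unix": 1600000280.8477771,
      "stop_unix": 1600000310.6168633,
      "points": 8,
      "errors": 2
    }
  ]
}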