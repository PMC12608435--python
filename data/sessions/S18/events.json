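{
  "recording_start": 1600000000.0,
  "pss": 6,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000225.5464027,
      "points": 6,
      "errors": 0
    },
    {
      "level": 2,
      "start_unix": 1600000225.5464027,
      "stop_unix": 1600000252.6582398,
      "points": 8,
      "errors": 0
    },
    {
      "level": 3,
      "start_unix": 1600000252.6582398,
      "stop_unix": 1600000280.2816546,
      "points": 8,
      "errors": 2
    },
    {
      "level": 4,
      "start_unix": 1600000280.2816546,
      "stop_unix": 1600000309.6187313,
      "points": 10,
      "errors": 0
    }
  ]
}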