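{
  "recording_start": 1600000000.0,
  "pss": 8,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000226.0346556,
      "points": 6,
      "errors": 0
    },
    {
      "level": 2,
      "start_unix": 1600000226.0346556,
      "stop_unix": 1600000260.3283513,
      "points": 7,
      "errors": 1
    },
    {
      "level": 3,
      "start_unix": 1600000260.3283513,
      "stop_unix": 1600000294.7549653,
      "points": 8,
      "errors": 2
    },
    {
      "level": 4,
      "start_unix": 1600000294.7549653,
      "stop_unix": 1600000328.8853421,
      "points": 9,
      "errors": 1
    }
  ]
}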