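{
  "recording_start": 1600000000.0,
  "pss": 16,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000224.6393747,
      "points": 5,
      "errors": 1
    },
    {
      "level": 2,
      "start_unix": 1600000224.6393747,
      "stop_unix": 1600000249.2460988,
      "points": 6,
      "errors": 2
    },
    {
      "level": 3,
      "start_unix": 1600000249.2460988,
      "stop_unix": 1600000279.4189239,
      "points": 10,
      "errors": 0
    },
    {
      "level": 4,
      "start_unix": 1600000279.4189239,
      "stop_unix": 1600000313.754424,
      "points": 10,
      "errors": 0
    }
  ]
}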