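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
      "stop_unix": 1600000221.4970548,
      "points": 5,
      "errors": 1
    },
    {
      "level": 2,
      "start_unix": 1600000221.4970548,
      "stop_unix": 1600000247.4783828,
      "points": 4,
      "errors": 4
    },
    {
      "level": 3,
      "start_unix": 1600000247.4783828,
      "stop_unix": 1600000279.5631635,
      "points": 7,
      "errors": 3
    },
    {
      "level": 4,
      "start_unix": 1600000279.5631635,
      "stop_unix": 1600000315.3517532,
      "points": 8,
      "errors": 2
    }
  ]
}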