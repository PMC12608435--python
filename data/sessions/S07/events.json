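{
  "recording_start": 1600000000.0,
  "pss": 18,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000221.072669,
      "points": 5,
      "errors": 1
    },
    {
      "level": 2,
      "start_unix": 1600000221.072669,
      "stop_unix": 1600000245.729963,
      "points": 6,
      "errors": 2
    },
    {
      "level": 3,
      "start_unix": 1600000245.729963,
      "stop_unix": 1600000279.3639722,
      "points": 9,
      "errors": 1
    },
    {
      "level": 4,
      "start_unix": 1600000279.3639722,
      "stop_unix": 1600000312.048275,
      "points": 9,
      "errors": 1
    }
  ]
}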