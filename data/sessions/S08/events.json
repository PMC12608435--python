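{
  "recording_start": 1600000000.0,
  "pss": 7,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000223.7355688,
      "points": 5,
      "errors": 1
    },
    {
      "level": 2,
      "start_unix": 1600000223.7355688,
      "stop_unix": 1600000256.8954973,
      "points": 6,
      "errors": 2
    },
    {
      "level": 3,
      "start_unix": 1600000256.8954973,
      "stop_unix": 1600000290.0535014,
      "points": 9,
      "errors": 1
    },
    {
      "level": 4,
      "start_unix": 1600000290.0535014,
      "stop_unix": 1600000322.7326567,
      "points": 6,
      "errors": 4
    }
  ]
}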