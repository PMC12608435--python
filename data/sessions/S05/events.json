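{
  "recording_start": 1600000000.0,
  "pss": 10,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000230.1003106,
      "points": 3,
      "errors": 3
    },
    {
      "level": 2,
      "start_unix": 1600000230.1003106,
      "stop_unix": 1600000257.2614613,
      "points": 7,
      "errors": 1
    },
    {
      "level": 3,
      "start_unix": 1600000257.2614613,
      "stop_unix": 1600000281.3699183,
      "points": 6,
      "errors": 4
    },
    {
      "level": 4,
      "start_unix": 1600000281.3699183,
      "stop_unix": 1600000305.9216936,
      "points": 8,
      "errors": 2
    }
  ]
}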