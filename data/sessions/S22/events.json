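{
  "recording_start": 1600000000.0,
  "pss": 13,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000223.6799402,
      "points": 4,
      "errors": 2
    },
    {
      "level": 2,
      "start_unix": 1600000223.6799402,
      "stop_unix": 1600000253.6804602,
      "points": 8,
      "errors": 0
    },
    {
      "level": 3,
      "start_unix": 1600000253.6804602,
      "stop_unix": 1600000287.293201,
      "points": 10,
      "errors": 0
    },
    {
      "level": 4,
      "start_unix": 1600000287.293201,
      "stop_unix": 1600000317.4747348,
      "points": 8,
      "errors": 2
    }
  ]
}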