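{
  "recording_start": 1600000000.0,
  "pss": 23,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000230.522404,
      "points": 6,
      "errors": 0
    },
    {
      "level": 2,
      "start_unix": 1600000230.522404,
      "stop_unix": 1600000255.7373219,
      "points": 8,
      "errors": 0
    },
    {
      "level": 3,
      "start_unix": 1600000255.7373219,
      "stop_unix": 1600000283.5720642,
      "points": 10,
      "errors": 0
    },
    {
      "level": 4,
      "start_unix": 1600000283.5720642,
      "stop_unix": 1600000314.7745543,
      "points": 10,
      "errors": 0
    }
  ]
}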