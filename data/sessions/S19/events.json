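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
      "stop_unix": 1600000223.7974682,
      "points": 6,
      "errors": 0
    },
    {
      "level": 2,
      "start_unix": 1600000223.7974682,
      "stop_unix": 1600000252.0166142,
      "points": 7,
      "errors": 1
    },
    {
      "level": 3,
      "start_unix": 1600000252.0166142,
      "stop_unix": 1600000283.4711483,
      "points": 10,
      "errors": 0
    },
    {
      "level": 4,
      "start_unix": 1600000283.4711483,
      "stop_unix": 1600000313.433647,
      "points": 9,
      "errors": 1
    }
  ]
}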