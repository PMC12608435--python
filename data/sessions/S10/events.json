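{
  "recording_start": 1600000000.0,
  "pss": 9,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000229.1629765,
      "points": 4,
      "errors": 2
    },
    {
      "level": 2,
      "start_unix": 1600000229.1629765,
      "stop_unix": 1600000264.226612,
      "points": 7,
      "errors": 1
    },
    {
      "level": 3,
      "start_unix": 1600000264.226612,
      "stop_unix": 1600000296.0716882,
      "points": 7,
      "errors": 3
    },
    {
      "level": 4,
      "start_unix": 1600000296.0716882,
      "stop_unix": 1600000327.7665863,
      "points": 9,
      "errors": 1
    }
  ]
}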