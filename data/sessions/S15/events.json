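{
  "recording_start": 1600000000.0,
  "pss": 17,
  "rest": {
    "start_unix": 1600000000.0,
    "stop_unix": 1600000180.0
  },
  "levels": [
    {
      "level": 1,
      "start_unix": 1600000195.0,
      "stop_unix": 1600000222.1649306,
      "points": 5,
      "errors": 1
    },
    {
      "level": 2,
      "start_unix": 1600000222.1649306,
      "stop_unix": 1600000250.3692012,
      "points": 7,
      "errors": 1
    },
    {
      "level": 3,
      "start_unix": 1600000250.3692012,
      "stop_unix": 1600000276.3355446,
      "points": 9,
      "errors": 1
    },
    {
      "level": 4,
      "start_unix": 1600000276.3355446,
      "stop_unix": 1600000310.1485264,
      "points": 5,
      "errors": 5
    }
  ]
}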