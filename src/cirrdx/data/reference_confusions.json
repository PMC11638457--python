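{
  "internal_test_1": {
    "combined": {"tp": 60, "fp": 5, "fn": 7, "tn": 22},
    "cnn": {"tp": 58, "fp": 7, "fn": 9, "tn": 20},
    "fib4": {"tp": 46, "fp": 9, "fn": 21, "tn": 18},
    "apri": {"tp": 48, "fp": 10, "fn": 19, "tn": 17},
    "reader1": {"tp": 55, "fp": 9, "fn": 12, "tn": 18},
    "reader2": {"tp": 48, "fp": 4, "fn": 19, "tn": 23}
  },
  "internal_test_2": {
    "combined": {"tp": 156, "fp": 25, "fn": 24, "tn": 61},
    "cnn": {"tp": 146, "fp": 18, "fn": 34, "tn": 68},
    "fib4": {"tp": 115, "fp": 31, "fn": 65, "tn": 55},
    "apri": {"tp": 107, "fp": 33, "fn": 73, "tn": 53},
    "reader1": {"tp": 134, "fp": 23, "fn": 46, "tn": 63},
    "reader2": {"tp": 128, "fp": 8, "fn": 52, "tn": 78}
  },
  "external_test": {
    "combined": {"tp": 62, "fp": 11, "fn": 12, "tn": 30},
    "cnn": {"tp": 57, "fp": 13, "fn": 17, "tn": 28},
    "fib4": {"tp": 46, "fp": 14, "fn": 28, "tn": 27},
    "apri": {"tp": 48, "fp": 19, "fn": 26, "tn": 22},
    "reader1": {"tp": 54, "fp": 11, "fn": 20, "tn": 30},
    "reader2": {"tp": 52, "fp": 12, "fn": 22, "tn": 29}
  }
}
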