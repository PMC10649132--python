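{
  "comment": "Fickett TESTCODE lookup tables: probability that a sequence with the given position/content parameter value is coding, and the weight (predictive ability) of each of the eight parameters.",
  "position_thresholds": [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0],
  "position_prob": {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.52, 0.41, 0.31, 0.17],
    "T": [0.51, 0.60, 0.69, 0.64, 0.53, 0.54, 0.44, 0.40, 0.31, 0.33]
  },
  "position_weight": {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33},
  "content_thresholds": [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0],
  "content_prob": {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19],
    "C": [0.50, 0.58, 0.58, 0.53, 0.48, 0.53, 0.48, 0.38, 0.25, 0.11],
    "G": [0.21, 0.44, 0.50, 0.49, 0.52, 0.61, 0.64, 0.62, 0.56, 0.32],
    "T": [0.30, 0.49, 0.56, 0.56, 0.52, 0.51, 0.47, 0.40, 0.29, 0.13]
  },
  "content_weight": {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
}
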