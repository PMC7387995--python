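{
  "1": {
    "scheme": "plain",
    "intercept": -7.124,
    "coefficients": {
      "gender": 0.705,
      "age": 0.108,
      "shoulder_height_diff": 0.705,
      "scapular_tilt": 0.618,
      "lumbar_concave": 0.790,
      "pelvic_tilt": -0.042,
      "flat_back": -0.965,
      "thoracic_kyphosis": 0.093,
      "lumbar_kyphosis": -2.235,
      "atr_thoracic": 0.916,
      "atr_thoracolumbar": 1.406,
      "atr_lumbar": 1.471
    }
  },
  "2": {
    "scheme": "aor_weighted",
    "intercept": -3.648,
    "coefficients": {
      "gender": 0.367,
      "age": 0.091,
      "shoulder_height_diff": 0.316,
      "scapular_tilt": 0.376,
      "lumbar_concave": 0.435,
      "pelvic_tilt": 0.105,
      "flat_back": -0.984,
      "thoracic_kyphosis": -0.037,
      "lumbar_kyphosis": -2.122,
      "atr_thoracic": 0.267,
      "atr_thoracolumbar": 0.275,
      "atr_lumbar": 0.273
    }
  },
  "3": {
    "scheme": "auc_weighted",
    "intercept": -3.787,
    "coefficients": {
      "gender": 0.448,
      "age": 0.069,
      "shoulder_height_diff": 0.650,
      "scapular_tilt": 0.495,
      "lumbar_concave": 0.756,
      "pelvic_tilt": -0.275,
      "flat_back": -0.827,
      "thoracic_kyphosis": -0.241,
      "lumbar_kyphosis": -1.955,
      "atr_thoracic": 1.001,
      "atr_thoracolumbar": 1.420,
      "atr_lumbar": 1.201
    }
  },
  "4": {
    "scheme": "aor_auc_weighted",
    "intercept": -3.648,
    "coefficients": {
      "gender": 0.222,
      "age": 0.058,
      "shoulder_height_diff": 0.186,
      "scapular_tilt": 0.213,
      "lumbar_concave": 0.2546,
      "pelvic_tilt": 0.066,
      "flat_back": -0.984,
      "thoracic_kyphosis": -0.037,
      "lumbar_kyphosis": -2.122,
      "atr_thoracic": 0.713,
      "atr_thoracolumbar": 0.166,
      "atr_lumbar": 0.163
    }
  }
}
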