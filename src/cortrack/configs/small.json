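{
  "master_seed": 7,
  "paradigm": {
    "syllable_dur_s": 0.32,
    "words_per_sentence": 4,
    "sentences_per_trial": 12,
    "n_trials": 6,
    "drop_first_sentence": true,
    "fs_hz": 500
  },
  "montage": {
    "name": "standard-64",
    "channels": ["F3", "Fz", "F4", "FC3", "FCz", "FC4", "C3", "Cz", "C4",
                 "CP3", "CPz", "CP4", "P3", "Pz", "P4", "Oz", "M1", "M2"],
    "exclude": [],
    "frontal_exclude": [],
    "mastoids": ["M1", "M2"]
  },
  "entrainment": {
    "band_hz": [0.1, 25.0],
    "neighbor_k": 2,
    "alpha": 0.05,
    "gap_s": 0.5
  },
  "n400": {
    "band_hz": [0.1, 30.0],
    "n_sentences_per_condition": 10,
    "isi_s": 2.5,
    "epoch_s": [-0.1, 0.7],
    "baseline_s": [-0.1, 0.0],
    "reject_uv": 75.0,
    "windows_ms": [[300, 500], [500, 700]],
    "roi": ["C3", "Cz", "C4", "CP3", "CPz", "CP4"],
    "fdr_q": 0.05
  },
  "cohorts": {
    "NL": {
      "n_subjects": 4,
      "coupling_rho": 0.6,
      "behavior_coupling_rho": 0.45,
      "n400_latency_ms": 400,
      "artifact_rate": 0.123,
      "distributions": {
        "amp_sentential": [0.8, 0.3],
        "amp_phrasal": [1.0, 0.35],
        "amp_syllabic": [1.5, 0.5],
        "n400_magnitude": [1.2, 0.8],
        "noise_scale": [10.0, 2.0],
        "comprehension_rating": [3.68, 0.5],
        "question_accuracy": [0.95, 0.04],
        "listening_score": [0.97, 0.02]
      }
    },
    "SL": {
      "n_subjects": 4,
      "coupling_rho": 0.6,
      "behavior_coupling_rho": 0.45,
      "n400_latency_ms": 450,
      "artifact_rate": 0.123,
      "distributions": {
        "amp_sentential": [0.03, 0.025],
        "amp_phrasal": [0.7, 0.3],
        "amp_syllabic": [1.4, 0.5],
        "n400_magnitude": [0.9, 0.7],
        "noise_scale": [10.0, 2.0],
        "comprehension_rating": [2.95, 0.72],
        "question_accuracy": [0.9, 0.05],
        "listening_score": [0.86, 0.07]
      }
    }
  },
  "correlation": {
    "pairs": [
      ["sentential_db", "listening_score"],
      ["sentential_db", "n400_500_700_uv"],
      ["sentential_db", "comprehension_rating"]
    ]
  }
}
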