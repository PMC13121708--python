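{
  "schema_version": "1",
  "seed": 20260,
  "stages": {
    "digitize": {
      "whole": {
        "P_L": 0.398504130124,
        "ci": [
          0.39173899488,
          0.405308247102
        ],
        "means": [
          5.00267848867,
          6.9983368157,
          7.99614818552
        ],
        "n_components": 3,
        "n_droplets": 20000,
        "sds": [
          0.151705031657,
          0.14985425987,
          0.147473255862
        ],
        "silhouette": null,
        "weights": [
          0.601495869876,
          0.306758536994,
          0.0917455931307
        ]
      }
    },
    "estimate": {
      "titer": {
        "P_L": 0.398504130124,
        "alpha": 0.5,
        "c_p": 20333424.3986,
        "ci": [
          19886048.1758,
          20788482.8013
        ],
        "lambda_b": 40.0,
        "lambda_p": 0.508335609966,
        "volume_pl": 50.0
      }
    },
    "simulate": {
      "alpha_mode": "fixed",
      "c_b_effective": 1600000000.0,
      "c_b_nominal": 1600000000.0,
      "c_p_true": 20000000.0,
      "n_droplets": 20000
    }
  }
}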