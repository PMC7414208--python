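{
  "baseline": {},
  "overall": {
    "bootstrap_auc": {
      "lower": {
        "rounded": 0.44,
        "value": 0.4352517985611511
      },
      "n_boot": 10000,
      "n_redraws": 0,
      "point_estimate": {
        "rounded": 0.49,
        "value": 0.48561151079136694
      },
      "scheme": "within_arm",
      "seed": 88277363,
      "upper": {
        "rounded": 0.54,
        "value": 0.5359712230215827
      }
    },
    "counts": {
      "a": 106,
      "b": 33,
      "c": 110,
      "d": 29,
      "n": 278,
      "n1": 139,
      "n2": 139
    },
    "estimate": {
      "auc": {
        "rounded": 0.49,
        "value": 0.48561151079136694
      },
      "correction_applied": false,
      "log_or_se": {
        "rounded": 0.2886,
        "value": 0.28863586104082767
      },
      "odds_ratio": {
        "rounded": 0.85,
        "value": 0.846831955922865
      },
      "se": {
        "rounded": 0.76,
        "value": 0.762589928057554
      },
      "sp": {
        "rounded": 0.21,
        "value": 0.20863309352517986
      }
    },
    "five_region": {
      "alpha": 0.05,
      "ci_lower": {
        "rounded": 0.5,
        "value": 0.5
      },
      "ci_upper": {
        "rounded": 1.49,
        "value": 1.4910236375229322
      },
      "conclusion": "statistically equivalent within [0.5, 2]",
      "p_lower": {
        "rounded": 0.03,
        "value": 0.03396557070118843
      },
      "p_upper": {
        "rounded": 0.0,
        "value": 0.0014532632494782926
      },
      "p_upper_lenient": {
        "rounded": 0.02,
        "value": 0.02380914718874553
      },
      "region_verdicts": {
        "negligible_ability": "retained",
        "no_ability": "retained",
        "recognizable_ability": "rejected",
        "recognizable_ability_lenient": "rejected",
        "strong_incorrect_tendency": "rejected",
        "weak_incorrect_tendency": "retained"
      }
    },
    "percent_replying_tap": {
      "filtered_arm": {
        "rounded": 79.1,
        "value": 79.13669064748201
      },
      "tap_arm": {
        "rounded": 76.3,
        "value": 76.2589928057554
      },
      "total": {
        "rounded": 77.7,
        "value": 77.6978417266187
      },
      "total_count": 216
    },
    "wald_ci": {
      "lower": {
        "rounded": 0.48,
        "value": 0.4809610951329506
      },
      "upper": {
        "rounded": 1.49,
        "value": 1.4910236375229322
      }
    }
  },
  "provenance": "aggregated table",
  "settings": {
    "alpha": 0.05,
    "baseline_method": "chisq_yates",
    "correction": "haldane",
    "lenient_upper": true,
    "level": 0.95,
    "n_boot": 10000,
    "scheme": "within_arm",
    "seed": 2018
  },
  "strata": {}
}
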