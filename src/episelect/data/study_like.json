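{
  "class_prior": 0.7368421052631579,
  "missing_rates": {
    "Cdi": 0.3684210526315789,
    "Depi": 0.3684210526315789,
    "FSIQ": 0.10526315789473684,
    "MlogI": 0.05263157894736842,
    "MlogII": 0.05263157894736842,
    "MvisI": 0.05263157894736842,
    "MvisII": 0.05263157894736842,
    "P.Style": 0.3684210526315789,
    "PIQ": 0.10526315789473684,
    "Sczi": 0.3684210526315789,
    "VIQ": 0.10526315789473684
  },
  "n": 19,
  "noise": {
    "Cdi": {
      "Negative": 0.4166666666666667,
      "Positive": 0.5833333333333334
    },
    "Depi": {
      "Negative": 0.3333333333333333,
      "Positive": 0.6666666666666666
    },
    "ElapsedTime": {
      "14-19": 0.21052631578947367,
      "20-39": 0.631578947368421,
      "7-13": 0.15789473684210525
    },
    "FSIQ": {
      "High": 0.058823529411764705,
      "Low": 0.0,
      "Normal": 0.5294117647058824,
      "Normal-High": 0.17647058823529413,
      "Normal-Low": 0.23529411764705882
    },
    "Febrile": {
      "Negative": 0.5263157894736842,
      "Positive": 0.47368421052631576
    },
    "Gender": {
      "Female": 0.47368421052631576,
      "Male": 0.5263157894736842
    },
    "MlogI": {
      "High": 0.0,
      "Low": 0.1111111111111111,
      "Normal": 0.6111111111111112,
      "Normal-High": 0.0,
      "Normal-Low": 0.2777777777777778
    },
    "MlogII": {
      "High": 0.0,
      "Low": 0.1111111111111111,
      "Normal": 0.7222222222222222,
      "Normal-High": 0.0,
      "Normal-Low": 0.16666666666666666
    },
    "MvisI": {
      "High": 0.1111111111111111,
      "Low": 0.0,
      "Normal": 0.7222222222222222,
      "Normal-High": 0.05555555555555555,
      "Normal-Low": 0.1111111111111111
    },
    "MvisII": {
      "High": 0.1111111111111111,
      "Low": 0.0,
      "Normal": 0.5,
      "Normal-High": 0.05555555555555555,
      "Normal-Low": 0.3333333333333333
    },
    "OnsetAge": {
      "0-1": 0.21052631578947367,
      "11-20": 0.42105263157894735,
      "2-10": 0.3684210526315789
    },
    "Sczi": {
      "Negative": 0.75,
      "Positive": 0.25
    },
    "SeizureFreq": {
      "2-Weekly": 0.10526315789473684,
      "3-Weekly": 0.15789473684210525,
      "4-Weekly": 0.15789473684210525,
      "Daily": 0.10526315789473684,
      "Other": 0.05263157894736842,
      "Weekly": 0.42105263157894735
    },
    "SeizureType": {
      "Both": 0.21052631578947367,
      "Generalized": 0.42105263157894735,
      "Partial Complex": 0.3684210526315789
    },
    "SurgeryAge": {
      "17-32": 0.5263157894736842,
      "33-54": 0.47368421052631576
    },
    "VIQ": {
      "High": 0.058823529411764705,
      "Low": 0.058823529411764705,
      "Normal": 0.47058823529411764,
      "Normal-High": 0.17647058823529413,
      "Normal-Low": 0.23529411764705882
    }
  },
  "planted": {
    "P.Style": {
      "improvement_only": {
        "EB1": 0.0,
        "EB2": 0.4,
        "EB3": 0.6
      },
      "seizure_free": {
        "EB1": 0.21428571428571427,
        "EB2": 0.7857142857142857,
        "EB3": 0.0
      }
    },
    "PIQ": {
      "improvement_only": {
        "High": 0.0,
        "Low": 0.2,
        "Normal": 0.6,
        "Normal-High": 0.0,
        "Normal-Low": 0.2
      },
      "seizure_free": {
        "High": 0.07142857142857142,
        "Low": 0.0,
        "Normal": 0.7142857142857143,
        "Normal-High": 0.21428571428571427,
        "Normal-Low": 0.0
      }
    },
    "Side": {
      "improvement_only": {
        "Left": 1.0,
        "Right": 0.0
      },
      "seizure_free": {
        "Left": 0.35714285714285715,
        "Right": 0.6428571428571429
      }
    }
  },
  "seed": 0
}
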