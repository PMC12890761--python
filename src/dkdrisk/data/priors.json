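{
  "scale": 1.0,
  "entries": {
    "family_history_ckd": {
      "kind": "binary",
      "prevalence": 0.218,
      "hr": 2.04,
      "se": 0.1,
      "prevalence_se": 0.01,
      "source": "REGARDS cohort (incident ESRD)",
      "conditioning": {}
    },
    "nsaid_chronic": {
      "kind": "binary",
      "prevalence": 0.30,
      "hr": 1.32,
      "se": 0.1,
      "prevalence_se": 0.01,
      "source": "Taiwan NHIRD, chronic exposure >=90 days/year",
      "conditioning": {
        "age": {"coef": 0.10, "center": 58.8, "scale": 11.4}
      }
    },
    "dr_severity": {
      "kind": "ordinal",
      "prevalence": [0.50, 0.20, 0.15, 0.10, 0.05],
      "hr": [2.9, 5.8, 10.2, 16.6],
      "se": [0.1, 0.1, 0.1, 0.1],
      "prevalence_se": 0.01,
      "source": "Meta-analysis of biopsy-proven nephropathy cohorts; Taiwan grade distribution",
      "conditioning": {
        "hba1c": {"coef": 0.12, "center": 8.1, "scale": 1.6},
        "diabetes_duration": {"coef": 0.12, "center": 11.2, "scale": 7.8}
      }
    },
    "imd_quintile": {
      "kind": "quintile",
      "prevalence": [0.20, 0.20, 0.20, 0.20, 0.20],
      "hr": [1.05, 1.10, 1.16, 1.22],
      "se": [0.1, 0.1, 0.1, 0.1],
      "prevalence_se": 0.01,
      "source": "UK CPRD deprivation quintiles (uniform by construction); modest assumed risk gradient",
      "conditioning": {}
    },
    "sglt2i": {
      "kind": "binary",
      "prevalence": 0.30,
      "hr": 0.61,
      "ci": [0.55, 0.67],
      "prevalence_se": 0.01,
      "source": "CREDENCE/DAPA-CKD pooled",
      "conditioning": {
        "hba1c": {"coef": 0.10, "center": 8.1, "scale": 1.6}
      }
    },
    "ace_arb": {
      "kind": "binary",
      "prevalence": 0.50,
      "hr": 0.77,
      "ci": [0.71, 0.83],
      "prevalence_se": 0.01,
      "source": "RENAAL/IDNT",
      "conditioning": {}
    },
    "glp1_ra": {
      "kind": "binary",
      "prevalence": 0.15,
      "hr": 0.79,
      "ci": [0.73, 0.85],
      "prevalence_se": 0.01,
      "source": "FLOW trial",
      "conditioning": {}
    },
    "finerenone": {
      "kind": "binary",
      "prevalence": 0.05,
      "hr": 0.82,
      "ci": [0.76, 0.88],
      "prevalence_se": 0.01,
      "source": "FIDELIO-DKD trial",
      "conditioning": {}
    },
    "statin": {
      "kind": "binary",
      "prevalence": 0.60,
      "hr": 0.88,
      "ci": [0.84, 0.92],
      "prevalence_se": 0.01,
      "source": "Chinese T2D cohort",
      "conditioning": {}
    }
  }
}
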