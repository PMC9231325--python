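{
  "description": "Reference values from the Korean prediabetes/T2DM case-control study this package models: the nine-SNP candidate panel with group risk-allele frequencies and published association results, the fixed oxidative-stress tertile cutpoints, and the group-level cohort parameters used by the default simulation config.",
  "n_case": 549,
  "n_control": 1036,
  "panel": [
    {"snp_id": "rs1260326",  "gene": "GCKR",     "risk_allele": "C", "raf_case": 0.471, "raf_control": 0.420,
     "p_unadjusted": 0.006, "or_unadjusted": 1.236, "p_adjusted": 0.002,   "or_adjusted": 1.291},
    {"snp_id": "rs2191349",  "gene": "DGKB",     "risk_allele": "T", "raf_case": 0.696, "raf_control": 0.674,
     "p_unadjusted": 0.208, "or_unadjusted": 1.106, "p_adjusted": 0.158,   "or_adjusted": 1.127},
    {"snp_id": "rs1799884",  "gene": "GCK",      "risk_allele": "T", "raf_case": 0.201, "raf_control": 0.176,
     "p_unadjusted": 0.075, "or_unadjusted": 1.189, "p_adjusted": 0.163,   "or_adjusted": 1.154},
    {"snp_id": "rs4607517",  "gene": "GCK",      "risk_allele": "A", "raf_case": 0.239, "raf_control": 0.219,
     "p_unadjusted": 0.206, "or_unadjusted": 1.121, "p_adjusted": 0.332,   "or_adjusted": 1.097},
    {"snp_id": "rs11558471", "gene": "SLC30A8",  "risk_allele": "A", "raf_case": 0.627, "raf_control": 0.580,
     "p_unadjusted": 0.011, "or_unadjusted": 1.215, "p_adjusted": 0.019,   "or_adjusted": 1.212},
    {"snp_id": "rs10811661", "gene": "CDKN2A/B", "risk_allele": "T", "raf_case": 0.595, "raf_control": 0.537,
     "p_unadjusted": 0.001, "or_unadjusted": 1.282, "p_adjusted": 0.00037, "or_adjusted": 1.346},
    {"snp_id": "rs1387153",  "gene": "MTNR1B",   "risk_allele": "T", "raf_case": 0.463, "raf_control": 0.417,
     "p_unadjusted": 0.012, "or_unadjusted": 1.211, "p_adjusted": 0.001,   "or_adjusted": 1.301},
    {"snp_id": "rs2166706",  "gene": "MTNR1B",   "risk_allele": "C", "raf_case": 0.472, "raf_control": 0.422,
     "p_unadjusted": 0.007, "or_unadjusted": 1.230, "p_adjusted": 0.001,   "or_adjusted": 1.321},
    {"snp_id": "rs10830963", "gene": "MTNR1B",   "risk_allele": "G", "raf_case": 0.485, "raf_control": 0.440,
     "p_unadjusted": 0.015, "or_unadjusted": 1.198, "p_adjusted": 0.001,   "or_adjusted": 1.307}
  ],
  "oss_cutoffs": {
    "ox_ldl":    {"c1": 36.34,   "c2": 51.76,   "units": "U/L"},
    "mda":       {"c1": 7.44,    "c2": 9.41,    "units": "nmol/mL"},
    "epi_pgf2a": {"c1": 1117.49, "c2": 1615.6,  "units": "pg/mg creatinine"}
  },
  "biomarker_specs": {
    "mda":       {"mean_control": 8.28,   "se_control": 0.07, "mean_case": 10.4,   "se_case": 0.23},
    "ox_ldl":    {"mean_control": 45.2,   "se_control": 0.63, "mean_case": 51.0,   "se_case": 0.87},
    "epi_pgf2a": {"mean_control": 1559.7, "se_control": 21.3, "mean_case": 1597.3, "se_case": 35.1}
  },
  "covariate_specs": {
    "age": {"mean_control": 47.0, "se_control": 0.33, "mean_case": 52.9, "se_case": 0.39},
    "bmi": {"mean_control": 23.8, "se_control": 0.09, "mean_case": 24.7, "se_case": 0.13},
    "sex": {"prop_male_control": 0.354, "prop_male_case": 0.495}
  }
}
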