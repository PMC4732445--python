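{
 "description": "Published per-cutoff performance of the refined indices MPI4-MPI6 in the index-development cohort of cold-stunned Kemp's ridley sea turtles (143 enrolled; 25 died within 7 days, 118 survived). SE/SP are percentages at two decimals, PPV/NPV percentages at one decimal (shown with a trailing zero), likelihood ratios at two decimals. The bolded published optimum (Youden) cut-offs were >=10, >=6 and >=8. The per-animal cohort itself was never released; these summary rows are inputs to the reconstruction and cutoff-recovery checks.",
 "n_died": 25,
 "n_survived": 118,
 "n_enrolled": 143,
 "mortality_percent": 17.5,
 "errata": [
  {
   "index": "MPI6",
   "cutoff": 4,
   "field": "lr_minus",
   "published": 0.07,
   "consistent_value": 0.08,
   "note": "The published 0.07 is inconsistent with the row's own SE (96.00) and SP (52.54): (1-0.96)/(62/118) = 0.0761, which rounds to 0.08 under the half-up rounding that reproduces every other cell of the three tables. Apparent truncation slip in the published table."
  }
 ],
 "tables": {
  "MPI4": {
   "analytes": ["pH", "pCO2", "potassium"],
   "source_table": "MPI1",
   "optimal_cutoff": 10,
   "rows": [
    {"cutoff": 4, "se": 80.00, "sp": 59.32, "ppv": 29.40, "npv": 93.30, "lr_plus": 1.97, "lr_minus": 0.34},
    {"cutoff": 6, "se": 76.00, "sp": 75.42, "ppv": 39.60, "npv": 93.70, "lr_plus": 3.09, "lr_minus": 0.32},
    {"cutoff": 8, "se": 72.00, "sp": 82.20, "ppv": 46.20, "npv": 93.30, "lr_plus": 4.05, "lr_minus": 0.34},
    {"cutoff": 10, "se": 68.00, "sp": 87.29, "ppv": 53.10, "npv": 92.80, "lr_plus": 5.35, "lr_minus": 0.37},
    {"cutoff": 12, "se": 56.00, "sp": 90.68, "ppv": 56.00, "npv": 90.70, "lr_plus": 6.01, "lr_minus": 0.49},
    {"cutoff": 14, "se": 52.00, "sp": 94.92, "ppv": 68.40, "npv": 90.30, "lr_plus": 10.23, "lr_minus": 0.51},
    {"cutoff": 16, "se": 48.00, "sp": 95.76, "ppv": 70.60, "npv": 89.70, "lr_plus": 11.33, "lr_minus": 0.54},
    {"cutoff": 18, "se": 48.00, "sp": 97.46, "ppv": 80.00, "npv": 89.80, "lr_plus": 18.88, "lr_minus": 0.53},
    {"cutoff": 20, "se": 32.00, "sp": 98.31, "ppv": 80.00, "npv": 87.20, "lr_plus": 18.88, "lr_minus": 0.69},
    {"cutoff": 22, "se": 16.00, "sp": 99.15, "ppv": 80.00, "npv": 84.80, "lr_plus": 18.88, "lr_minus": 0.85}
   ]
  },
  "MPI5": {
   "analytes": ["pH", "pCO2", "pO2", "potassium"],
   "source_table": "MPI2",
   "optimal_cutoff": 6,
   "rows": [
    {"cutoff": 3, "se": 96.00, "sp": 42.37, "ppv": 26.10, "npv": 98.00, "lr_plus": 1.67, "lr_minus": 0.09},
    {"cutoff": 4, "se": 92.00, "sp": 61.86, "ppv": 33.80, "npv": 97.30, "lr_plus": 2.41, "lr_minus": 0.13},
    {"cutoff": 5, "se": 80.00, "sp": 71.19, "ppv": 37.00, "npv": 94.40, "lr_plus": 2.78, "lr_minus": 0.28},
    {"cutoff": 6, "se": 80.00, "sp": 78.81, "ppv": 44.40, "npv": 94.90, "lr_plus": 3.78, "lr_minus": 0.25},
    {"cutoff": 7, "se": 72.00, "sp": 80.51, "ppv": 43.90, "npv": 93.10, "lr_plus": 3.69, "lr_minus": 0.35},
    {"cutoff": 8, "se": 72.00, "sp": 83.90, "ppv": 48.60, "npv": 93.40, "lr_plus": 4.47, "lr_minus": 0.33},
    {"cutoff": 9, "se": 64.00, "sp": 85.59, "ppv": 48.50, "npv": 91.80, "lr_plus": 4.44, "lr_minus": 0.42},
    {"cutoff": 10, "se": 56.00, "sp": 90.68, "ppv": 56.00, "npv": 90.70, "lr_plus": 6.01, "lr_minus": 0.49},
    {"cutoff": 11, "se": 44.00, "sp": 94.07, "ppv": 61.10, "npv": 88.80, "lr_plus": 7.42, "lr_minus": 0.60},
    {"cutoff": 12, "se": 36.00, "sp": 95.76, "ppv": 64.30, "npv": 87.60, "lr_plus": 8.50, "lr_minus": 0.67},
    {"cutoff": 13, "se": 36.00, "sp": 97.46, "ppv": 75.00, "npv": 87.80, "lr_plus": 14.16, "lr_minus": 0.66},
    {"cutoff": 14, "se": 36.00, "sp": 99.15, "ppv": 90.00, "npv": 88.00, "lr_plus": 42.48, "lr_minus": 0.65}
   ]
  },
  "MPI6": {
   "analytes": ["pH", "pO2", "potassium"],
   "source_table": "MPI3",
   "optimal_cutoff": 8,
   "rows": [
    {"cutoff": 4, "se": 96.00, "sp": 52.54, "ppv": 30.00, "npv": 98.40, "lr_plus": 2.02, "lr_minus": 0.07},
    {"cutoff": 6, "se": 92.00, "sp": 70.34, "ppv": 39.70, "npv": 97.60, "lr_plus": 3.10, "lr_minus": 0.11},
    {"cutoff": 8, "se": 88.00, "sp": 80.51, "ppv": 48.90, "npv": 96.90, "lr_plus": 4.51, "lr_minus": 0.15},
    {"cutoff": 10, "se": 72.00, "sp": 83.05, "ppv": 47.40, "npv": 93.30, "lr_plus": 4.25, "lr_minus": 0.34},
    {"cutoff": 12, "se": 72.00, "sp": 86.44, "ppv": 52.90, "npv": 93.60, "lr_plus": 5.31, "lr_minus": 0.32},
    {"cutoff": 14, "se": 64.00, "sp": 88.98, "ppv": 55.20, "npv": 92.10, "lr_plus": 5.81, "lr_minus": 0.40}
   ]
  }
 }
}
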