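[
 {
  "season": "spring",
  "intercept": 62.45,
  "terms": [
   {"covariate": "DTS", "radius_m": 2190, "coefficient": -0.20},
   {"covariate": "NDVI", "radius_m": 60, "coefficient": -22.96},
   {"covariate": "YearlyAOD", "radius_m": 1500, "coefficient": 60.67}
  ],
  "diagnostics": {"adj_r2": 0.86, "cv_r2": 0.83, "mean": 80.60,
                  "mae": 2.52, "rmse": 3.15, "cv_mae": 2.84, "cv_rmse": 3.55}
 },
 {
  "season": "summer",
  "intercept": 70.30,
  "terms": [
   {"covariate": "DTS", "radius_m": 4020, "coefficient": -0.22},
   {"covariate": "Road", "radius_m": 5010, "coefficient": 49.25}
  ],
  "diagnostics": {"adj_r2": 0.77, "cv_r2": 0.74, "mean": 67.03,
                  "mae": 2.87, "rmse": 3.63, "cv_mae": 3.13, "cv_rmse": 3.97}
 },
 {
  "season": "autumn",
  "intercept": 115.71,
  "terms": [
   {"covariate": "DTS", "radius_m": 1890, "coefficient": -0.50},
   {"covariate": "Slope", "radius_m": 3840, "coefficient": -1.26}
  ],
  "diagnostics": {"adj_r2": 0.85, "cv_r2": 0.84, "mean": 85.74,
                  "mae": 4.25, "rmse": 5.25, "cv_mae": 4.65, "cv_rmse": 5.67}
 },
 {
  "season": "winter",
  "intercept": 22.90,
  "terms": [
   {"covariate": "WinterAOD", "radius_m": 990, "coefficient": 323.41},
   {"covariate": "DTS", "radius_m": 2370, "coefficient": -0.410}
  ],
  "diagnostics": {"adj_r2": 0.89, "cv_r2": 0.86, "mean": 117.31,
                  "mae": 6.30, "rmse": 8.30, "cv_mae": 7.03, "cv_rmse": 9.63}
 },
 {
  "season": "yearly",
  "intercept": 115.83,
  "terms": [
   {"covariate": "DTS", "radius_m": 2400, "coefficient": -0.48},
   {"covariate": "Slope", "radius_m": 4620, "coefficient": -1.15}
  ],
  "diagnostics": {"adj_r2": 0.89, "cv_r2": 0.87, "mean": 87.42,
                  "mae": 3.37, "rmse": 4.33, "cv_mae": 3.72, "cv_rmse": 4.75}
 }
]
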