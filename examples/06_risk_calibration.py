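"""Map a raw risk score to absolute risk and check its calibration.

A dense linear risk score is trained on biomarkers, its training-set
outputs are cut into equal-count bins, and the per-bin disease prevalence
(rolling-averaged, linearly interpolated) becomes the absolute-risk map.
On held-out data the predicted percentages are compared with the realized
prevalence per bin (with 100-fold bootstrap CIs), crossed against a second
predictor in a 2-D heatmap, and combined with a synthetic external risk
estimator in one dense regression.
"""

import numpy as np
import pandas as pd

from gbmrs import (
    DiseaseSpec,
    SimulationConfig,
    apply_calibration,
    calibration_curve,
    fit_calibration,
    fit_combined,
    risk_heatmap,
    simulate_cohort,
)
from gbmrs.calibrate import toy_external_estimator
from gbmrs.preprocess import preprocess_biomarkers
from gbmrs.sparse_model import make_splits, ols_fit

config = SimulationConfig(
    n_samples=20_000, n_snps=100, n_biomarkers=10, n_causal_per_biomarker=8,
    heritability_h2=0.5, shared_env_var=0.1, n_sibling_pairs=500,
    disease_specs=[
        DiseaseSpec("dz", {"bm01": 1.0, "bm02": 0.8, "bm03": 0.5}, 0.0, 0.4, 0.12)
    ],
    seed=13,
)
genotypes, phenotypes = simulate_cohort(config)
splits = make_splits(phenotypes.sample_ids, phenotypes.sibling_pairs(),
                     n_validation=1000, seed=13)
features, _ = preprocess_biomarkers(phenotypes, splits.training[0], mode="first")
status = phenotypes.status("dz")
train_ids, eval_ids = splits.training[0], splits.evaluation

model = ols_fit(features.loc[train_ids].to_numpy(), status.reindex(train_ids).to_numpy(float),
                feature_ids=list(features.columns))
cal = fit_calibration(model.predict(features.loc[train_ids].to_numpy()),
                      status.reindex(train_ids).to_numpy(float), n_bins=40, window=5)
risks = apply_calibration(cal, model.predict(features.loc[eval_ids].to_numpy()))
y_eval = status.reindex(eval_ids).to_numpy(float)

curve = calibration_curve(risks, y_eval, n_bins=8, n_boot=100, seed=13)
print("predicted vs actual risk per bin (held-out siblings):")
for _, row in curve.iterrows():
    marker = "o" if not row["small_bin"] else "."  # hollow = small bin
    print(f"  {marker} predicted {row['mean_predicted_risk']:5.1f}%  actual "
          f"{row['actual_prevalence_pct']:5.1f}%  "
          f"[{row['ci_low_pct']:5.1f}, {row['ci_high_pct']:5.1f}]  n={row['count']}")

# cross the calibrated risk with a synthetic external estimator
external = toy_external_estimator(features, {"bm01": 1.2, "bm02": 0.8}, intercept=-2.2)
heat = risk_heatmap(risks, external.reindex(eval_ids).to_numpy(), y_eval, grid=4)
print("\n2-D prevalence heatmap (rows: our risk quartiles, cols: external):")
print(np.array2string(heat["prevalence"], precision=2, floatmode="fixed"))
print("counts per cell sum to", heat["counts"].sum())

ext_inputs = pd.DataFrame({"age_band": (features["bm04"] > 0).astype(float)}, index=features.index)
fit = fit_combined(features.loc[train_ids], ext_inputs.loc[train_ids],
                   status.reindex(train_ids), include_external_output=True,
                   external_risk=external.loc[train_ids])
print("\ncombined-regression top coefficients (external output included):")
print(fit.coefficients.head(5).to_string(index=False))
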