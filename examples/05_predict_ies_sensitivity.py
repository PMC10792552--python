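"""Predict IES sensitivity from event delays with cross-validated logistic
regression.

A recording is IES-sensitive when its cumulative iso-electric-suppression
time exceeds 30 s.  Event delays are transformed to
tau* = ln(1 + 100/(delay + 0.1)) and fed to an l2-regularized logistic
model (C = 1), evaluated with stratified group 4-fold cross-validation so
no subject spans folds.  Demonstrated on a synthetic cohort whose first-IES
delay separates the classes.
"""

import numpy as np

from anesmap import fit_evaluate, normalize_feature, synthetic_cohort

cohort = synthetic_cohort(n_subjects=12, recordings_per_subject=2, seed=0)
print(f"cohort: {len(cohort)} recordings, "
      f"{(cohort['delta_ies_s'] > 30).sum()} IES-sensitive")
print(f"feature example: a 60 s delay maps to tau* = {normalize_feature(60.0):.3f}")

for features in (["tau_ies1_s"], ["tau_ies1_s", "tau_delta_disp_s"],
                 ["tau_theta_decay_s"]):
    res = fit_evaluate(cohort, features, k=4, seed=0)
    fold_aucs = ", ".join("nan" if np.isnan(a) else f"{a:.2f}" for a in res.auc_per_fold)
    print(f"features {features}: pooled AUC {res.auc_pooled:.2f} "
          f"(per fold: {fold_aucs})")

print("\nThe first-IES delay carries the class signal, so models using it")
print("reach AUC 1.0 on this separable cohort, while the theta-decay delay")
print("alone performs at chance - mirroring how early-suppression timing,")
print("not theta dynamics, predicts sensitivity to deep anesthesia.")
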