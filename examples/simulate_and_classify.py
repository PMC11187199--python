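"""Virtual-removal framework on a synthetic SEEG cohort.

Generates 8 well-sampled and 8 poorly sampled patients, computes the
spatial-coupling correlations before (BR) / after (AR) removal of the
marked seizure-onset zone plus the random-removal control (RR), and
classifies implantation quality from the perturbation strength
rho_hat = log(nu + |BR/AR|).
"""

import numpy as np

from seegsp import (
    CohortConfig,
    FrameworkConfig,
    choose_threshold,
    generate_cohort,
    patient_perturbation,
)

seed = 0
cfg = FrameworkConfig(rng_seed=seed)
cohort = generate_cohort(8, 8, CohortConfig(), np.random.default_rng(seed))

strengths, labels = {}, {}
print(f"{'patient':8s} {'scenario':26s} {'rho_BR':>7s} {'rho_AR':>7s} "
      f"{'rho_RR':>7s} {'rho_hat':>8s}")
for sp in cohort:
    r = patient_perturbation(sp.data, cfg, np.random.default_rng(seed))
    pid = sp.data.patient_id
    strengths[pid] = r.strength
    labels[pid] = sp.data.outcome_label == "seizure_free"
    print(f"{pid:8s} {sp.scenario.kind:26s} {r.rho_br:7.2f} {r.rho_ar:7.2f} "
          f"{r.rho_rr:7.2f} {r.strength:8.2f}")

report = choose_threshold(strengths, labels, rng=np.random.default_rng(seed))
print(f"\nthreshold rho_hat* = {report.threshold:.2f}  "
      f"sensitivity = {report.sensitivity:.2f}  "
      f"specificity = {report.specificity:.2f}  AUC = {report.auc:.2f}")
print("Well-sampled patients lose their spatial coupling when the SOZ is "
      "removed (|AR| << |BR|, large rho_hat); poorly sampled patients do "
      "not, and random removal (RR ~ BR) shows the effect is not a "
      "sample-size artifact.")
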