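"""Ranked perturbation map (SP map) for a focal vs a multifocal patient.

Every channel in turn anchors its own spatial system; the change in the
power-law goodness of fit gives a per-channel perturbation strength.
Ranking channels by strength (rows) against distance to the perturbation
centroid (columns) yields an image whose diagonal structure indicates a
well-sampled focus.
"""

from pathlib import Path

import numpy as np

from seegsp import CohortConfig, FrameworkConfig, generate_cohort, quadrant_features
from seegsp.io import render_sp_map
from seegsp.ranked import ranked_perturbation

seed = 11
cfg = FrameworkConfig(rng_seed=seed)
cohort = generate_cohort(1, 2, CohortConfig(), np.random.default_rng(seed))
out_dir = Path("scratch")
out_dir.mkdir(exist_ok=True)

for sp in cohort:
    if sp.scenario.kind == "poorly_sampled_missed":
        continue
    ranked, sp_map = ranked_perturbation(sp.data, cfg)
    f = quadrant_features(sp_map, sp.data.patient_id)
    img = sp_map.image
    rm, cm = img.shape[0] // 2, img.shape[1] // 2
    mass = {
        "Q1": img[:rm, :cm][img[:rm, :cm] > 0].sum(),
        "Q2": img[:rm, cm:][img[:rm, cm:] > 0].sum(),
        "Q3": img[rm:, cm:][img[rm:, cm:] > 0].sum(),
        "Q4": img[rm:, :cm][img[rm:, :cm] > 0].sum(),
    }
    total = sum(mass.values())
    err = np.linalg.norm(ranked.centroid - sp.scenario.source)
    png = out_dir / f"{sp.data.patient_id}_map.png"
    render_sp_map(sp_map, png, title=f"{sp.data.patient_id} ({sp.scenario.kind})")
    print(f"{sp.data.patient_id} ({sp.scenario.kind}):")
    print(f"  diagonal (Q1+Q3) mass fraction = {(mass['Q1'] + mass['Q3']) / total:.2f}")
    print(f"  centroid error vs true source  = {err:.1f} mm")
    print(f"  quadrant features (q1,q2,q4)   = "
          f"({f.q1:.2f}, {f.q2:.2f}, {f.q4:.2f})  -> {png}")

print("\nA focal (well-sampled) patient concentrates intensity along the "
      "Q1->Q3 diagonal and its centroid lands near the true source; the "
      "two propagation islands break the diagonal and displace mass into "
      "Q2/Q4.")
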