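"""Virtual-removal perturbation of the spatial system.

The measured seizure-onset zone (SOZ) is deleted from the implantation and
the power-law goodness of fit ``rho`` is compared before (BR) and after (AR)
the deletion.  If the implantation truly sampled the focus, removal destroys
the spatial coupling and |rho| drops sharply; if the focus was missed, the
coupling was weak to begin with and removal changes little.  A random-removal
control (RR) deletes the same number of non-SOZ channels to show the effect
is not a sample-size artifact.  The per-patient summary statistic is the
perturbation strength ``rho_hat = log(nu + |rho_BR / rho_AR|)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    FrameworkConfig,
    PatientData,
    SegmentRates,
    build_spatial_system,
    select_spatial_reference,
)

__all__ = [
    "PerturbationResult",
    "ClassificationReport",
    "segment_is_valid",
    "rho_before_removal",
    "rho_after_removal",
    "rho_random_removal",
    "perturbation_strength",
    "patient_perturbation",
    "choose_threshold",
    "cliffs_delta",
    "MissingSOZError",
    "NoValidSegmentsError",
]

#: cap on |rho_BR / rho_AR| when rho_AR is exactly zero (1/epsilon, eps=1e-6)
RATIO_CAP = 1e6


class MissingSOZError(ValueError):
    """Patient has no (included) SOZ channel."""


class NoValidSegmentsError(ValueError):
    """No segment passes the event-rate validity criterion."""


@dataclass(frozen=True)
class PerturbationResult:
    """Per-patient virtual-removal summary."""

    patient_id: str
    rho_br_per_segment: tuple[float, ...]
    rho_ar_per_segment: tuple[float, ...]
    rho_rr_per_segment: tuple[float, ...]
    rho_br: float
    rho_ar: float
    rho_rr: float
    strength: float
    n_valid_segments: int


@dataclass(frozen=True)
class ClassificationReport:
    threshold: float
    sensitivity: float
    specificity: float
    auc: float
    auc_ci: tuple[float, float]
    per_patient_calls: Mapping[str, str]  # patient_id -> well_sampled / poorly_sampled


def segment_is_valid(segment: SegmentRates, cfg: FrameworkConfig) -> bool:
    """A segment is analyzable iff its busiest channel exceeds the rate bar.

    "More than one event per minute" is read strictly: a maximum channel
    rate of exactly ``cfg.min_events_per_min`` does not qualify.
    """
    if not segment.rates:
        return False
    return max(segment.rates.values()) > cfg.min_events_per_min


def _included_rates(patient: PatientData, segment: SegmentRates) -> dict[str, float]:
    inc = {c.channel_id for c in patient.included_channels}
    return {cid: r for cid, r in segment.rates.items() if cid in inc}


def rho_before_removal(
    patient: PatientData, segment: SegmentRates, cfg: FrameworkConfig
) -> Optional[float]:
    """rho of the system referenced at the maximum-rate SOZ channel."""
    soz = patient.soz_ids
    if not soz:
        raise MissingSOZError(f"patient {patient.patient_id!r} has no SOZ channel")
    rates = _included_rates(patient, segment)
    ref = select_spatial_reference(rates, mask=soz)
    return build_spatial_system(patient, segment, ref, cfg).rho


def rho_after_removal(
    patient: PatientData, segment: SegmentRates, cfg: FrameworkConfig
) -> Optional[float]:
    """rho after deleting the SOZ and re-anchoring at the remaining maximum.

    When every surviving channel's rate falls below ``cfg.min_events_per_min``
    the correlation is set to exactly 0: below that rate the fit is noise and
    produces spurious correlations.  With an empty SOZ this degenerates to an
    unconstrained before-removal system.
    """
    soz = patient.soz_ids
    rates = _included_rates(patient, segment)
    remaining = {cid: r for cid, r in rates.items() if cid not in soz}
    non_soz_channels = [c for c in patient.included_channels if c.channel_id not in soz]
    if len(non_soz_channels) < 3:
        return None
    if remaining and max(remaining.values()) < cfg.min_events_per_min:
        return 0.0
    ref = select_spatial_reference(remaining)
    return build_spatial_system(
        patient, segment, ref, cfg, channel_subset=remaining.keys()
    ).rho


def rho_random_removal(
    patient: PatientData,
    segment: SegmentRates,
    cfg: FrameworkConfig,
    rng: np.random.Generator,
) -> Optional[float]:
    """Median rho over random deletions of non-SOZ channels.

    Each iteration removes ``round(rr_fraction * N_SOZ)`` (at least 1)
    uniformly chosen non-SOZ channels without replacement and recomputes the
    SOZ-referenced system.  The median over ``cfg.rr_iterations`` iterations
    controls for the pure sample-size effect of deleting channels.
    """
    soz = patient.soz_ids
    if not soz:
        raise MissingSOZError(f"patient {patient.patient_id!r} has no SOZ channel")
    rates = _included_rates(patient, segment)
    non_soz = sorted(cid for cid in rates if cid not in soz)
    if not non_soz:
        return None
    n_remove = max(1, round(cfg.rr_fraction * len(soz)))
    n_remove = min(n_remove, len(non_soz))
    ref = select_spatial_reference(rates, mask=soz)

    rhos: list[float] = []
    for _ in range(cfg.rr_iterations):
        removed = set(rng.choice(non_soz, size=n_remove, replace=False))
        keep = [cid for cid in rates if cid not in removed]
        rho = build_spatial_system(
            patient, segment, ref, cfg, channel_subset=keep
        ).rho
        rhos.append(0.0 if rho is None else rho)
    return float(np.median(rhos))


def perturbation_strength(
    rho_br: float, rho_ar: float, cfg: FrameworkConfig
) -> float:
    """``log(nu + |rho_BR / rho_AR|)``, the virtual-removal statistic.

    ``nu > 0`` keeps the logarithm defined when the ratio is 0; being a
    monotone reparametrization it changes values but never patient ranking.
    A zero after-removal correlation with nonzero before-removal correlation
    is capped at ``|rho_BR| * RATIO_CAP``; both zero gives ``log(nu)``.
    """
    if rho_ar == 0.0:
        ratio = 0.0 if rho_br == 0.0 else abs(rho_br) * RATIO_CAP
    else:
        ratio = abs(rho_br / rho_ar)
    return float(np.log(cfg.nu + ratio))


def patient_perturbation(
    patient: PatientData,
    cfg: FrameworkConfig,
    rng: Optional[np.random.Generator] = None,
) -> PerturbationResult:
    """BR/AR/RR correlations per valid segment, their medians, and rho_hat.

    Undefined per-segment correlations (too few channels, zero variance)
    are zero-substituted before the median, consistent with the zero rule
    for quiescent after-removal systems.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    valid = [s for s in patient.segments if segment_is_valid(s, cfg)]
    if not valid:
        raise NoValidSegmentsError(f"patient {patient.patient_id!r} has no valid segment")

    def _sub(v: Optional[float]) -> float:
        return 0.0 if v is None else v

    br = [_sub(rho_before_removal(patient, s, cfg)) for s in valid]
    ar = [_sub(rho_after_removal(patient, s, cfg)) for s in valid]
    rr = [_sub(rho_random_removal(patient, s, cfg, rng)) for s in valid]

    rho_br = float(np.median(br))
    rho_ar = float(np.median(ar))
    rho_rr = float(np.median(rr))
    return PerturbationResult(
        patient_id=patient.patient_id,
        rho_br_per_segment=tuple(br),
        rho_ar_per_segment=tuple(ar),
        rho_rr_per_segment=tuple(rr),
        rho_br=rho_br,
        rho_ar=rho_ar,
        rho_rr=rho_rr,
        strength=perturbation_strength(rho_br, rho_ar, cfg),
        n_valid_segments=len(valid),
    )


def choose_threshold(
    strengths: Mapping[str, float],
    labels: Mapping[str, bool],
    n_bootstrap: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> ClassificationReport:
    """Operating point on the ROC of rho_hat against outcome labels.

    ``labels`` maps patient id to True for the positive (seizure-free /
    well-sampled) class.  The threshold maximizes Youden's J
    (sensitivity + specificity - 1); ties break toward higher sensitivity,
    i.e. the lowest qualifying threshold.  Patients with
    ``rho_hat >= threshold`` are called well-sampled.  The AUC confidence
    interval is a percentile bootstrap over patients.
    """
    from sklearn.metrics import roc_auc_score

    if rng is None:
        rng = np.random.default_rng(0)
    ids = sorted(strengths)
    y = np.array([bool(labels[i]) for i in ids])
    s = np.array([strengths[i] for i in ids], dtype=float)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")

    best_j, best_thr, best_sens, best_spec = -np.inf, np.nan, np.nan, np.nan
    for thr in np.unique(s):
        calls = s >= thr
        tp = int(np.sum(calls & y))
        fn = int(np.sum(~calls & y))
        tn = int(np.sum(~calls & ~y))
        fp = int(np.sum(calls & ~y))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        # strict > keeps the lowest threshold among ties -> higher sensitivity
        if j > best_j:
            best_j, best_thr, best_sens, best_spec = j, float(thr), sens, spec

    auc = float(roc_auc_score(y, s))
    boot = []
    n = len(ids)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        yb, sb = y[idx], s[idx]
        if yb.all() or not yb.any():
            continue
        boot.append(roc_auc_score(yb, sb))
    ci = (
        (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
        if boot
        else (np.nan, np.nan)
    )
    calls = {
        pid: ("well_sampled" if strengths[pid] >= best_thr else "poorly_sampled")
        for pid in ids
    }
    return ClassificationReport(
        threshold=best_thr,
        sensitivity=best_sens,
        specificity=best_spec,
        auc=auc,
        auc_ci=ci,
        per_patient_calls=calls,
    )


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta effect size: P(x > y) - P(x < y) over all pairs."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = xa[:, None] - ya[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (xa.size * ya.size))
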