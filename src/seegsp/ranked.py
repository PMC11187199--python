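"""Ranked perturbation framework and the SP map.

Instead of deleting the SOZ (which requires recorded seizures), the spatial
reference is permuted: every channel in turn anchors its own spatial system
and the change in goodness of fit relative to the unconstrained reference
system gives a per-channel perturbation strength ``P_hat = 1 - (rho_i -
rho_ref)``.  Channels that support the power-law coupling as well as the
global maximum-rate channel score near 1; channels that destroy it score
low.  The per-channel medians over segments are rendered as the SP map: an
image whose rows are channels ranked by strength (descending) and whose
columns bin each channel's distance to the perturbation centroid — a
well-sampled focal implantation produces a bright top-left/diagonal
structure, a poorly sampled one an ill-defined morphology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from skimage.morphology import closing, footprint_rectangle

from .core import (
    FrameworkConfig,
    PatientData,
    SegmentRates,
    build_spatial_system,
    select_spatial_reference,
)
from .removal import segment_is_valid, NoValidSegmentsError

__all__ = [
    "RankedPerturbation",
    "SPMap",
    "channel_perturbation_strengths",
    "median_strengths",
    "perturbation_centroid",
    "build_sp_map",
    "ranked_perturbation",
    "UndefinedReferenceError",
]


class UndefinedReferenceError(ValueError):
    """The unconstrained reference system has no defined correlation."""


@dataclass(frozen=True)
class RankedPerturbation:
    patient_id: str
    per_channel_strength: Mapping[str, float]  # P_bar, median over segments
    reference_id: str
    rho_ref: float
    centroid: np.ndarray  # (3,) mm
    high_set: frozenset[str]


@dataclass(frozen=True)
class SPMap:
    """Binned, ranked, morphologically smoothed perturbation image."""

    image: np.ndarray       # (n_channels, map_bins) after grayscale closing
    raw_image: np.ndarray   # pre-morphology: <= 1 nonzero entry per row
    bin_edges: np.ndarray   # (map_bins + 1,) mm
    row_order: tuple[str, ...]  # channel ids, strength descending
    degenerate: bool = False    # all distances zero -> single-bin map


def channel_perturbation_strengths(
    patient: PatientData, segment: SegmentRates, cfg: FrameworkConfig
) -> dict[str, float]:
    """Per-channel ``P_hat = 1 - (rho_i - rho_ref)`` for one segment.

    ``rho_ref`` anchors at the unconstrained maximum-rate channel.  Each
    permuted system excludes the global reference channel from its point
    set (on top of excluding its own acting reference, as always), so that
    the permutation measures the spatial role of ``c_i`` and not the
    leverage of the dominant channel.  When ``c_i`` *is* the global
    reference the two systems coincide and ``P_hat = 1`` by construction.
    Undefined permuted correlations count as 0 before differencing.
    """
    inc = {c.channel_id for c in patient.included_channels}
    rates = {cid: r for cid, r in segment.rates.items() if cid in inc}
    ref = select_spatial_reference(rates)
    rho_ref = build_spatial_system(patient, segment, ref, cfg).rho
    if rho_ref is None:
        raise UndefinedReferenceError(
            f"patient {patient.patient_id!r}: reference system correlation undefined"
        )
    strengths: dict[str, float] = {}
    for cid in rates:
        if cid == ref:
            strengths[cid] = 1.0
            continue
        rho_i = build_spatial_system(
            patient, segment, cid, cfg, drop_ids={ref}
        ).rho
        if rho_i is None:
            rho_i = 0.0
        strengths[cid] = 1.0 - (rho_i - rho_ref)
    return strengths


def median_strengths(per_segment: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Channel-wise median of P_hat maps over segments."""
    if not per_segment:
        raise ValueError("need at least one segment of strengths")
    keys = set().union(*(m.keys() for m in per_segment))
    return {
        cid: float(np.median([m[cid] for m in per_segment if cid in m]))
        for cid in sorted(keys)
    }


def perturbation_centroid(
    patient: PatientData, p_bar: Mapping[str, float], cfg: FrameworkConfig
) -> tuple[np.ndarray, frozenset[str]]:
    """Mean coordinate of the high-perturbation region.

    The region is every channel with strength at or above the
    ``cfg.centroid_percentile`` percentile (linear interpolation); the
    inclusive comparison guarantees a non-empty set even under ties.
    Returns the centroid and the high-set channel ids.
    """
    if not p_bar:
        raise ValueError("empty strength map")
    vals = np.array(list(p_bar.values()), dtype=float)
    thr = np.percentile(vals, cfg.centroid_percentile)
    high = frozenset(cid for cid, v in p_bar.items() if v >= thr)
    coords = np.array([patient.channel(cid).coordinate for cid in sorted(high)])
    return coords.mean(axis=0), high


def build_sp_map(
    patient: PatientData,
    p_bar: Mapping[str, float],
    centroid: np.ndarray,
    cfg: FrameworkConfig,
) -> SPMap:
    """Rank channels by strength and bin their centroid distances.

    Rows: channels sorted by P_bar descending (ties lexicographic).
    Columns: ``cfg.map_bins`` equal-width distance bins on [0, max
    distance]; bins are half-open with the last bin closed.  Each channel
    lights a single pixel of intensity P_bar in ``raw_image``; ``image``
    is its grayscale morphological closing with a 3x3 square element,
    which connects nearby activations into an interpretable shape.
    """
    if len(p_bar) < 2:
        raise ValueError("need at least 2 channels to build a map")
    order = sorted(p_bar, key=lambda cid: (-p_bar[cid], cid))
    dists = np.array(
        [np.linalg.norm(patient.channel(cid).coordinate - centroid) for cid in order]
    )
    dmax = float(dists.max())
    degenerate = dmax == 0.0
    n_bins = 1 if degenerate else cfg.map_bins
    edges = np.linspace(0.0, max(dmax, np.finfo(float).eps), n_bins + 1)
    width = edges[1] - edges[0]
    cols = np.minimum((dists / width).astype(int), n_bins - 1)

    raw = np.zeros((len(order), n_bins))
    for r, cid in enumerate(order):
        raw[r, cols[r]] = p_bar[cid]
    img = closing(raw, footprint_rectangle((3, 3))) if not degenerate else raw.copy()
    return SPMap(
        image=img,
        raw_image=raw,
        bin_edges=edges,
        row_order=tuple(order),
        degenerate=degenerate,
    )


def ranked_perturbation(
    patient: PatientData, cfg: FrameworkConfig
) -> tuple[RankedPerturbation, SPMap]:
    """Full ranked pipeline for one patient: strengths, centroid, map."""
    valid = [s for s in patient.segments if segment_is_valid(s, cfg)]
    if not valid:
        raise NoValidSegmentsError(f"patient {patient.patient_id!r} has no valid segment")
    per_segment = [channel_perturbation_strengths(patient, s, cfg) for s in valid]
    p_bar = median_strengths(per_segment)

    inc = {c.channel_id for c in patient.included_channels}
    ref_rates = {cid: r for cid, r in valid[0].rates.items() if cid in inc}
    ref = select_spatial_reference(ref_rates)
    rho_ref = build_spatial_system(patient, valid[0], ref, cfg).rho

    centroid, high = perturbation_centroid(patient, p_bar, cfg)
    sp_map = build_sp_map(patient, p_bar, centroid, cfg)
    ranked = RankedPerturbation(
        patient_id=patient.patient_id,
        per_channel_strength=p_bar,
        reference_id=ref,
        rho_ref=float(rho_ref) if rho_ref is not None else np.nan,
        centroid=centroid,
        high_set=high,
    )
    return ranked, sp_map
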