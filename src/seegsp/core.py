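"""Domain types and the power-law spatial system.

A stereo-EEG implantation is reduced to a set of bipolar channels, each
carrying a 3-D coordinate (mm, normalized template space) and a per-segment
interictal event rate (events/min).  The central object is the *spatial
system*: the pairing of log event rate with log Euclidean distance to a
chosen spatial reference channel.  Under the working hypothesis that rates
decay as a power law ``f = alpha * d**kappa`` away from a well-sampled
epileptic focus, the spatial system is linear in log-log space and its
Pearson correlation ``rho`` measures the goodness of fit of that hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ChannelRecord",
    "SegmentRates",
    "PatientData",
    "SpatialSystem",
    "FrameworkConfig",
    "bipolar_midpoint",
    "select_spatial_reference",
    "build_spatial_system",
    "loglog_pearson_fit",
    "InvalidCoordinateError",
    "EmptyReferenceError",
    "SchemaError",
]


class InvalidCoordinateError(ValueError):
    """A coordinate is non-finite or has the wrong dimensionality."""


class EmptyReferenceError(ValueError):
    """No eligible channel remains to serve as spatial reference."""


class SchemaError(ValueError):
    """An input table violates the on-disk schema."""


@dataclass(frozen=True)
class ChannelRecord:
    """One bipolar channel.

    Parameters
    ----------
    channel_id : str
        Unique label within a patient.
    coordinate : ndarray of shape (3,)
        Midpoint of the two contacts, mm, normalized template space.
    is_soz : bool
        Channel belongs to the clinically marked seizure-onset zone.
    is_resected : bool
        Channel lies within the resection cavity.
    excluded : bool
        White-matter / extra-cerebral / artifact channel; kept in the
        record but never enters any spatial system.
    """

    channel_id: str
    coordinate: np.ndarray
    is_soz: bool = False
    is_resected: bool = False
    excluded: bool = False

    def __post_init__(self) -> None:
        coord = np.asarray(self.coordinate, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise InvalidCoordinateError(
                f"channel {self.channel_id!r}: coordinate must be 3 finite components"
            )
        object.__setattr__(self, "coordinate", coord)


@dataclass(frozen=True)
class SegmentRates:
    """Event rates (events/min) per channel for one recording segment."""

    segment_id: str
    rates: Mapping[str, float]
    n_minutes: float = 10.0

    def __post_init__(self) -> None:
        if self.n_minutes <= 0:
            raise ValueError("n_minutes must be positive")
        for cid, r in self.rates.items():
            if not np.isfinite(r) or r < 0:
                raise ValueError(f"rate for {cid!r} must be finite and >= 0, got {r}")


@dataclass(frozen=True)
class PatientData:
    """All channels and rate segments for one patient."""

    patient_id: str
    channels: Sequence[ChannelRecord]
    segments: Sequence[SegmentRates]
    outcome_label: Optional[str] = None  # seizure_free / non_seizure_free / None

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate channel ids: {dup}")
        included = [c for c in self.channels if not c.excluded]
        if len(included) < 2:
            raise SchemaError("patient needs >= 2 non-excluded channels")
        known = set(ids)
        for seg in self.segments:
            unknown = set(seg.rates) - known
            if unknown:
                raise SchemaError(
                    f"segment {seg.segment_id!r} rates reference unknown channels: "
                    f"{sorted(unknown)}"
                )
        if self.outcome_label not in (None, "seizure_free", "non_seizure_free", "unknown"):
            raise ValueError(f"bad outcome_label {self.outcome_label!r}")

    # -- convenience accessors -------------------------------------------
    @property
    def included_channels(self) -> list[ChannelRecord]:
        return [c for c in self.channels if not c.excluded]

    @property
    def soz_ids(self) -> set[str]:
        return {c.channel_id for c in self.channels if c.is_soz and not c.excluded}

    def channel(self, channel_id: str) -> ChannelRecord:
        for c in self.channels:
            if c.channel_id == channel_id:
                return c
        raise KeyError(channel_id)


@dataclass(frozen=True)
class SpatialSystem:
    """A (log-distance, log-rate) point cloud around one reference channel.

    ``rho`` is the Pearson correlation of the points (goodness of fit of the
    power law); it is ``None`` when undefined (fewer than 3 points, or zero
    variance in either axis).  ``kappa`` and ``alpha_tilde`` are the
    least-squares slope and intercept of the log-log line; logarithms are
    natural throughout (``rho`` and ``kappa`` are base-invariant,
    ``alpha_tilde`` is not).
    """

    reference_id: str
    point_ids: tuple[str, ...]
    points: np.ndarray  # shape (n, 2): columns log_distance, log_rate
    rho: Optional[float]
    alpha_tilde: Optional[float]
    kappa: Optional[float]

    @property
    def defined(self) -> bool:
        return self.rho is not None


@dataclass(frozen=True)
class FrameworkConfig:
    """Tunable parameters of the whole framework.

    Defaults follow the reference protocol: a 0.1 events/min floor for
    zero-rate channels, segment validity at >1 event/min on the busiest
    channel, random removal of 20% of the SOZ size over 100 iterations,
    a 70th-percentile perturbation centroid, a 200-bin map, 1000x/75%
    k-means bootstrap, and 5 mm channel spheres counted on a 0.5 mm grid.
    """

    rate_floor: float = 0.1
    nu: float = 1.0
    min_events_per_min: float = 1.0
    rr_fraction: float = 0.20
    rr_iterations: int = 100
    centroid_percentile: float = 70.0
    map_bins: int = 200
    kmeans_bootstrap: int = 1000
    kmeans_subsample: float = 0.75
    sphere_radius_mm: float = 5.0
    grid_resolution_mm: float = 0.5
    incomplete_resection_percentile: float = 75.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.rr_fraction <= 1):
            raise ValueError("rr_fraction must lie in (0, 1]")
        for name in ("rate_floor", "nu", "min_events_per_min", "rr_iterations",
                     "map_bins", "kmeans_bootstrap", "kmeans_subsample",
                     "sphere_radius_mm", "grid_resolution_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("centroid_percentile", "incomplete_resection_percentile"):
            v = getattr(self, name)
            if not (0 < v < 100):
                raise ValueError(f"{name} must lie in (0, 100)")

    def with_(self, **kwargs) -> "FrameworkConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def bipolar_midpoint(contact_a: Iterable[float], contact_b: Iterable[float]) -> np.ndarray:
    """Midpoint between two contact coordinates (the bipolar channel position)."""
    a = np.asarray(contact_a, dtype=float)
    b = np.asarray(contact_b, dtype=float)
    if a.shape != (3,) or b.shape != (3,) or not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidCoordinateError("contacts must be 3-vectors with finite components")
    return (a + b) / 2.0


def select_spatial_reference(
    rates: Mapping[str, float],
    mask: Optional[Iterable[str]] = None,
) -> str:
    """Channel with the maximum rate, optionally restricted to ``mask``.

    The mask implements the reference constraint: the SOZ for the
    before-removal system, its complement after removal, or no constraint
    for the ranked framework.  Ties break lexicographically on channel id
    so the choice is deterministic.
    """
    if mask is not None:
        candidates = {cid: rates[cid] for cid in mask if cid in rates}
    else:
        candidates = dict(rates)
    candidates = {cid: r for cid, r in candidates.items() if np.isfinite(r)}
    if not candidates:
        raise EmptyReferenceError("no eligible channel to serve as spatial reference")
    best = max(candidates.values())
    return min(cid for cid, r in candidates.items() if r == best)


def loglog_pearson_fit(
    points: np.ndarray,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Pearson correlation and least-squares line for (x, y) pairs.

    Returns ``(rho, alpha_tilde, kappa)`` where ``y ~ alpha_tilde + kappa*x``.
    All three are ``None`` when fewer than 3 points are supplied; ``rho`` is
    additionally ``None`` when either axis has zero variance (the line
    parameters are then also withheld, because the fit is degenerate).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if pts.shape[0] < 3:
        return None, None, None
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    x, y = pts[:, 0], pts[:, 1]
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return None, None, None
    rho = float(np.corrcoef(x, y)[0, 1])
    kappa, alpha_tilde = np.polyfit(x, y, 1)
    return rho, float(alpha_tilde), float(kappa)


def build_spatial_system(
    patient: PatientData,
    segment: SegmentRates,
    reference_id: str,
    cfg: FrameworkConfig,
    channel_subset: Optional[Iterable[str]] = None,
    drop_ids: Optional[Iterable[str]] = None,
) -> SpatialSystem:
    """Construct the spatial system around ``reference_id``.

    For each included non-reference channel the point is
    ``(log d, log rate)`` with ``d`` the Euclidean distance (mm) to the
    reference coordinate.  ``cfg.rate_floor`` is added to channels whose
    rate is exactly 0 so the logarithm is defined; nonzero rates are left
    untouched to preserve their ordering.  The reference channel never
    appears in the point set.  ``channel_subset`` restricts the system to a
    subset of channel ids (used by the removal perturbations) and
    ``drop_ids`` removes individual channels from the point set (used by
    the ranked framework).
    """
    ref = patient.channel(reference_id)
    if ref.excluded:
        raise ValueError(f"reference channel {reference_id!r} is excluded")
    subset = set(channel_subset) if channel_subset is not None else None
    drop = set(drop_ids) if drop_ids is not None else set()

    ids: list[str] = []
    log_d: list[float] = []
    log_r: list[float] = []
    for ch in patient.included_channels:
        cid = ch.channel_id
        if cid == reference_id or cid in drop:
            continue
        if subset is not None and cid not in subset:
            continue
        if cid not in segment.rates:
            continue
        rate = segment.rates[cid]
        if rate == 0.0:
            rate = cfg.rate_floor
        d = float(np.linalg.norm(ch.coordinate - ref.coordinate))
        if d <= 0.0:
            # coincident channel: no defined log-distance; skip the point
            continue
        ids.append(cid)
        log_d.append(np.log(d))
        log_r.append(np.log(rate))

    pts = np.column_stack([log_d, log_r]) if ids else np.empty((0, 2))
    rho, alpha_tilde, kappa = loglog_pearson_fit(pts) if len(ids) >= 3 else (None, None, None)
    return SpatialSystem(
        reference_id=reference_id,
        point_ids=tuple(ids),
        points=pts,
        rho=rho,
        alpha_tilde=alpha_tilde,
        kappa=kappa,
    )
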