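"""Seeded generator of SEEG-like cohorts with known sampling quality.

The generator realizes the statistical structure the perturbation framework
assumes: a focal generator whose event rate decays as a power law of
distance, ``lambda(d) = alpha * max(d, 1 mm)**kappa``, sampled by
electrode-like linear contact arrays, with

* a shared per-channel multiplicative log-normal factor (tissue/electrode
  heterogeneity that is stable across segments, so segment medians estimate
  a stable spatial field),
* Poisson count variability within each 10-minute segment, and
* a weak spatially unstructured background rate emulating the irritative
  zone activity every SEEG implantation records (median 0.1 events/min,
  matching the typical non-SOZ channel rate).

Three scenarios are produced.  ``well_sampled``: the source sits amid the
electrodes and channels within ``soz_radius_mm`` form the (correctly)
measured SOZ.  In both poorly sampled scenarios every channel is at least
an exclusion distance from the true source, so the implantation records
propagated activity instead: spatially extended secondary generators
(short ridges of sub-sources along a well-sampled structure, firing at a
fraction of the source rate) that emulate the propagation / irritative
zone.  ``poorly_sampled_missed`` records one such region, which clinical
marking mistakes for a unifocal onset; ``poorly_sampled_propagation``
records two distinct islands.  For the poorly sampled kinds the
"measured SOZ" is the contiguous ``soz_radius_mm`` neighborhood of the
highest-rate channel, mimicking how an onset region is marked from the
recording alone.  Because the propagated regions are extended, deleting
the marked neighborhood leaves structured activity behind — the signature
that separates them from a genuinely well-sampled focus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .core import ChannelRecord, PatientData, SegmentRates, bipolar_midpoint

__all__ = [
    "SyntheticScenario",
    "SyntheticPatient",
    "CohortConfig",
    "generate_implantation",
    "expected_rates",
    "generate_rates",
    "generate_patient",
    "generate_cohort",
]

WELL = "well_sampled"
MISSED = "poorly_sampled_missed"
PROPAGATION = "poorly_sampled_propagation"


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth generative parameters for one patient."""

    kind: str
    source: np.ndarray                      # (3,) mm
    secondary_sources: tuple = ()           # propagated generators, (3,) each
    secondary_alphas: tuple = ()            # events/min at 1 mm, per generator
    alpha: float = 30.0                     # events/min at 1 mm from the source
    kappa: float = -1.5                     # power-law decay exponent (< 0)
    noise_sigma: float = 0.3                # per-channel log-normal sigma
    soz_radius_mm: float = 12.0             # ground-truth SOZ membership radius
    background_median: float = 0.1          # events/min, unstructured activity
    background_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa >= 0:
            raise ValueError("kappa must be negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        object.__setattr__(self, "source", np.asarray(self.source, dtype=float))


@dataclass(frozen=True)
class SyntheticPatient:
    """A PatientData plus its generative ground truth."""

    data: PatientData
    scenario: SyntheticScenario
    true_soz: frozenset[str]  # channels within soz_radius_mm of the true source


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation settings (geometry and recording protocol)."""

    n_electrodes: int = 12
    contacts_per_electrode: int = 12
    spacing_mm: float = 3.5
    scalp_radius_mm: float = 70.0
    target_radius_mm: float = 25.0
    n_segments: int = 5
    segment_minutes: float = 10.0
    exclusion_radius_mm: float = 20.0   # poor scenarios: min source-channel gap
    alpha: float = 30.0
    kappa: float = -1.5
    noise_sigma: float = 0.3
    soz_radius_mm: float = 12.0


def generate_implantation(
    n_electrodes: int,
    contacts_per_electrode: int,
    spacing_mm: float,
    rng: np.random.Generator,
    scalp_radius_mm: float = 70.0,
    target_radius_mm: float = 25.0,
) -> dict[str, np.ndarray]:
    """Bipolar channel coordinates for straight-line depth electrodes.

    Each electrode runs from a random entry point on a scalp-like sphere
    toward a random interior target; contacts are equally spaced starting
    at the target (deepest contact) and moving outward.  Bipolar channels
    sit at midpoints of consecutive contacts.  Returns an ordered mapping
    channel_id -> (3,) coordinate.
    """
    if n_electrodes <= 0 or contacts_per_electrode < 2 or spacing_mm <= 0:
        raise ValueError("counts must be positive and >= 2 contacts per electrode")
    channels: dict[str, np.ndarray] = {}
    for e in range(n_electrodes):
        u = rng.normal(size=3)
        entry = scalp_radius_mm * u / np.linalg.norm(u)
        while True:
            target = rng.uniform(-target_radius_mm, target_radius_mm, size=3)
            if np.linalg.norm(target) <= target_radius_mm:
                break
        direction = entry - target
        direction /= np.linalg.norm(direction)
        contacts = [target + k * spacing_mm * direction for k in range(contacts_per_electrode)]
        for k in range(contacts_per_electrode - 1):
            cid = f"E{e + 1:02d}C{k + 1:02d}-{k + 2:02d}"
            channels[cid] = bipolar_midpoint(contacts[k], contacts[k + 1])
    return channels


def expected_rates(
    coords: Mapping[str, np.ndarray], scenario: SyntheticScenario
) -> dict[str, float]:
    """Noise-free expected rate (events/min) per channel.

    The channel rate is ``alpha * max(d, 1)**kappa`` from the strongest
    applicable generator: the primary source or any propagated secondary
    sub-source with its own (smaller) alpha.  The 1 mm floor keeps the law
    finite at the source.
    """
    sources = [(scenario.source, scenario.alpha)]
    sources += list(zip(scenario.secondary_sources, scenario.secondary_alphas))
    out: dict[str, float] = {}
    for cid, xyz in coords.items():
        lam = 0.0
        for src, alpha in sources:
            d = max(float(np.linalg.norm(np.asarray(xyz) - np.asarray(src))), 1.0)
            lam = max(lam, alpha * d ** scenario.kappa)
        out[cid] = lam
    return out


def generate_rates(
    coords: Mapping[str, np.ndarray],
    scenario: SyntheticScenario,
    n_segments: int,
    segment_minutes: float,
    rng: np.random.Generator,
) -> list[SegmentRates]:
    """Observed per-segment rates: Poisson counts of a noisy power-law field.

    Per channel, the expected rate is scaled by a log-normal factor shared
    across segments and augmented by an unstructured background; each
    segment then draws an independent Poisson count over
    ``segment_minutes`` and reports count/minutes.
    """
    ids = list(coords)
    lam = np.array([expected_rates(coords, scenario)[cid] for cid in ids])
    factor = np.exp(scenario.noise_sigma * rng.normal(size=len(ids)))
    if scenario.background_median > 0:
        bg = scenario.background_median * np.exp(
            scenario.background_sigma * rng.normal(size=len(ids))
        )
    else:
        bg = np.zeros(len(ids))
    mean_rate = lam * factor + bg
    segments = []
    for j in range(n_segments):
        counts = rng.poisson(mean_rate * segment_minutes)
        rates = counts / segment_minutes
        segments.append(
            SegmentRates(
                segment_id=f"S{j + 1:02d}",
                rates=dict(zip(ids, rates.tolist())),
                n_minutes=segment_minutes,
            )
        )
    return segments


def _far_source(
    coords_arr: np.ndarray, min_gap: float, rng: np.random.Generator
) -> np.ndarray:
    """A source position at least ``min_gap`` mm from every channel."""
    center = coords_arr.mean(axis=0)
    for radius in np.arange(30.0, 120.0, 5.0):
        for _ in range(20):
            u = rng.normal(size=3)
            cand = center + radius * u / np.linalg.norm(u)
            if np.linalg.norm(coords_arr - cand, axis=1).min() >= min_gap:
                return cand
    raise RuntimeError("could not place a missed source")  # pragma: no cover


def generate_patient(
    patient_id: str,
    kind: str,
    cohort: CohortConfig,
    rng: np.random.Generator,
    outcome_label: Optional[str] = None,
) -> SyntheticPatient:
    """One synthetic patient of the requested scenario kind."""
    coords = generate_implantation(
        cohort.n_electrodes,
        cohort.contacts_per_electrode,
        cohort.spacing_mm,
        rng,
        cohort.scalp_radius_mm,
        cohort.target_radius_mm,
    )
    ids = list(coords)
    arr = np.array([coords[c] for c in ids])

    if kind == WELL:
        # a well-sampled implantation is one designed around the correct
        # hypothesis: the source sits centrally among the electrode
        # targets, near some channel, with >= 3 channels inside the SOZ
        center = arr.mean(axis=0)
        central = arr[np.linalg.norm(arr - center, axis=1) <= 15.0]
        if len(central) == 0:
            central = arr[np.argsort(np.linalg.norm(arr - center, axis=1))[:10]]
        while True:
            anchor = central[rng.integers(len(central))]
            source = anchor + rng.normal(scale=2.0, size=3)
            within = np.linalg.norm(arr - source, axis=1) <= cohort.soz_radius_mm
            if within.sum() >= 3:
                break
        scenario = SyntheticScenario(
            kind=kind, source=source, alpha=cohort.alpha, kappa=cohort.kappa,
            noise_sigma=cohort.noise_sigma, soz_radius_mm=cohort.soz_radius_mm,
        )
    elif kind in (MISSED, PROPAGATION):
        source = _far_source(arr, cohort.exclusion_radius_mm, rng)
        n_regions = 1 if kind == MISSED else 2
        n_sub = 5 if kind == MISSED else 3
        electrodes = sorted({cid.split("C")[0] for cid in ids})
        sub_sources: list[np.ndarray] = []
        alphas: list[float] = []
        chosen: list[np.ndarray] = []
        attempts = 0
        # islands of comparable strength: seizure spread engages each
        # region with similar intensity
        frac = rng.uniform(0.4, 0.7)
        while len(chosen) < n_regions and attempts < 500:
            attempts += 1
            # separate islands widely (different lobes) when the geometry
            # allows, relaxing for unusually compact implantations
            min_gap = 40.0 if attempts <= 200 else (30.0 if attempts <= 400 else 15.0)
            elec = electrodes[rng.integers(len(electrodes))]
            elec_xyz = np.array([coords[c] for c in ids if c.startswith(elec + "C")])
            center = elec_xyz.mean(axis=0)
            if chosen and min(np.linalg.norm(center - c) for c in chosen) < min_gap:
                continue
            chosen.append(center)
            # sub-sources spread along the electrode: the propagated
            # region is extended, not a point
            picks = np.linspace(0, len(elec_xyz) - 1, n_sub).astype(int)
            for k in picks:
                sub_sources.append(elec_xyz[k] + rng.normal(scale=1.5, size=3))
                alphas.append(cohort.alpha * frac * rng.uniform(0.9, 1.1))
        if len(chosen) < n_regions:  # pragma: no cover - geometry fallback
            raise RuntimeError("could not place propagated regions")
        scenario = SyntheticScenario(
            kind=kind, source=source,
            secondary_sources=tuple(sub_sources), secondary_alphas=tuple(alphas),
            alpha=cohort.alpha, kappa=cohort.kappa,
            noise_sigma=cohort.noise_sigma, soz_radius_mm=cohort.soz_radius_mm,
        )
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")

    segments = generate_rates(
        coords, scenario, cohort.n_segments, cohort.segment_minutes, rng
    )

    true_soz = frozenset(
        cid for cid in ids
        if np.linalg.norm(coords[cid] - scenario.source) <= cohort.soz_radius_mm
    )
    if kind == WELL:
        measured_soz = set(true_soz)
    else:
        # clinical marking from the recording alone: the contiguous
        # neighborhood of the channel with the strongest observed activity
        mean_obs = {
            cid: float(np.mean([s.rates[cid] for s in segments])) for cid in ids
        }
        top = min(ids, key=lambda c: (-mean_obs[c], c))
        measured_soz = {
            cid for cid in ids
            if np.linalg.norm(coords[cid] - coords[top]) <= cohort.soz_radius_mm
        }

    channels = [
        ChannelRecord(
            channel_id=cid,
            coordinate=coords[cid],
            is_soz=cid in measured_soz,
            is_resected=cid in measured_soz,
        )
        for cid in ids
    ]
    data = PatientData(
        patient_id=patient_id,
        channels=channels,
        segments=segments,
        outcome_label=outcome_label,
    )
    return SyntheticPatient(data=data, scenario=scenario, true_soz=true_soz)


def generate_cohort(
    n_well: int,
    n_poor: int,
    cohort: Optional[CohortConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[SyntheticPatient]:
    """A labeled cohort: well-sampled patients then alternating poor scenarios.

    Well-sampled patients carry the ``seizure_free`` outcome label and
    poorly sampled ones ``non_seizure_free``, mirroring the outcome-based
    validation the framework is scored against.
    """
    if cohort is None:
        cohort = CohortConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    patients: list[SyntheticPatient] = []
    for i in range(n_well):
        patients.append(
            generate_patient(f"W{i + 1:03d}", WELL, cohort, rng, "seizure_free")
        )
    for i in range(n_poor):
        kind = MISSED if i % 2 == 0 else PROPAGATION
        patients.append(
            generate_patient(f"P{i + 1:03d}", kind, cohort, rng, "non_seizure_free")
        )
    return patients
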