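"""Tabular I/O, configuration loading, pipeline orchestration, figures.

One on-disk schema serves real and synthetic data:

* channel table — CSV with columns ``channel_id, x_mm, y_mm, z_mm, is_soz,
  is_resected, excluded`` (0/1 flags);
* rates table — CSV with a ``channel_id`` column and one column per
  segment, values in events/min.

Everything downstream consumes the validated :class:`~seegsp.core.PatientData`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    ChannelRecord,
    FrameworkConfig,
    PatientData,
    SchemaError,
    SegmentRates,
)
from .removal import (
    MissingSOZError,
    NoValidSegmentsError,
    PerturbationResult,
    patient_perturbation,
    segment_is_valid,
)
from .ranked import RankedPerturbation, SPMap, ranked_perturbation
from .model import (
    ClusterModel,
    MapFeatures,
    classify_by_cluster,
    fit_cluster_model,
    probability_adequate,
    quadrant_features,
)
from .volumes import VolumeEstimate, percent_soz_resected, sphere_union_volume

logger = logging.getLogger("seegsp")

CHANNEL_COLUMNS = ["channel_id", "x_mm", "y_mm", "z_mm", "is_soz", "is_resected", "excluded"]


def write_patient(patient: PatientData, channel_path, rates_path) -> None:
    """Write the channel and rates tables for one patient."""
    rows = [
        {
            "channel_id": c.channel_id,
            "x_mm": repr(float(c.coordinate[0])),
            "y_mm": repr(float(c.coordinate[1])),
            "z_mm": repr(float(c.coordinate[2])),
            "is_soz": int(c.is_soz),
            "is_resected": int(c.is_resected),
            "excluded": int(c.excluded),
        }
        for c in patient.channels
    ]
    pd.DataFrame(rows, columns=CHANNEL_COLUMNS).to_csv(channel_path, index=False)

    ids = [c.channel_id for c in patient.channels]
    data = {"channel_id": ids}
    for seg in patient.segments:
        data[seg.segment_id] = [repr(float(seg.rates.get(cid, 0.0))) for cid in ids]
    pd.DataFrame(data).to_csv(rates_path, index=False)


def read_patient(
    channel_path,
    rates_path,
    patient_id: Optional[str] = None,
    outcome_label: Optional[str] = None,
    n_minutes: float = 10.0,
) -> PatientData:
    """Read and validate one patient from the two-table schema."""
    ch = pd.read_csv(channel_path, dtype={"channel_id": str},
                     float_precision="round_trip")
    missing = set(CHANNEL_COLUMNS) - set(ch.columns)
    if missing:
        raise SchemaError(f"channel table missing columns: {sorted(missing)}")
    if ch["channel_id"].duplicated().any():
        dup = ch.loc[ch["channel_id"].duplicated(), "channel_id"].tolist()
        raise SchemaError(f"duplicate channel_id rows: {dup}")
    for col in ("x_mm", "y_mm", "z_mm"):
        bad = pd.to_numeric(ch[col], errors="coerce").isna()
        if bad.any():
            row = ch.index[bad][0]
            raise SchemaError(f"non-numeric {col} at row {row} ({ch.loc[row, 'channel_id']!r})")

    channels = [
        ChannelRecord(
            channel_id=row.channel_id,
            coordinate=np.array([row.x_mm, row.y_mm, row.z_mm], dtype=float),
            is_soz=bool(int(row.is_soz)),
            is_resected=bool(int(row.is_resected)),
            excluded=bool(int(row.excluded)),
        )
        for row in ch.itertuples()
    ]
    known = {c.channel_id for c in channels}

    rt = pd.read_csv(rates_path, dtype={"channel_id": str},
                     float_precision="round_trip")
    if "channel_id" not in rt.columns:
        raise SchemaError("rates table missing channel_id column")
    unknown = set(rt["channel_id"]) - known
    if unknown:
        raise SchemaError(f"rates table references unknown channels: {sorted(unknown)}")
    segments = []
    for seg_col in [c for c in rt.columns if c != "channel_id"]:
        vals = pd.to_numeric(rt[seg_col], errors="coerce")
        if vals.isna().any():
            row = rt.index[vals.isna()][0]
            raise SchemaError(f"non-numeric rate in segment {seg_col!r} at row {row}")
        segments.append(
            SegmentRates(
                segment_id=seg_col,
                rates=dict(zip(rt["channel_id"], vals.astype(float))),
                n_minutes=n_minutes,
            )
        )
    pid = patient_id or Path(channel_path).stem.replace("_channels", "")
    return PatientData(
        patient_id=pid, channels=channels, segments=segments, outcome_label=outcome_label
    )


def load_config(path=None, **overrides) -> FrameworkConfig:
    """FrameworkConfig from an optional YAML file plus keyword overrides."""
    params: dict = {}
    if path is not None:
        with open(path) as fh:
            params.update(yaml.safe_load(fh) or {})
    params.update(overrides)
    valid = {f.name for f in dataclasses.fields(FrameworkConfig)}
    unknown = set(params) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return FrameworkConfig(**params)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineResult:
    manifest: dict
    perturbation: dict[str, PerturbationResult]
    ranked: dict[str, RankedPerturbation]
    maps: dict[str, SPMap]
    features: dict[str, MapFeatures]
    cluster_model: Optional[ClusterModel]
    probabilities: dict[str, float]
    calls: dict[str, str]
    volumes: dict[str, VolumeEstimate]
    errors: dict[str, list[str]]


def run_pipeline(
    patients: Sequence[PatientData],
    cfg: FrameworkConfig,
    region_maps: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> PipelineResult:
    """Execute the full analysis over a cohort.

    Per patient: virtual-removal perturbation (skipped with a logged reason
    when SOZ flags are absent), ranked perturbation and SP map, quadrant
    features, and channel-sphere volumetrics.  Across the cohort: the
    bootstrapped cluster model and per-patient adequacy probabilities.
    Stage errors are collected per patient and the run continues.
    All randomness derives from ``cfg.rng_seed`` through named substreams.
    """
    if not patients:
        raise ValueError("need at least one patient")
    cluster_rng = np.random.default_rng(
        np.random.SeedSequence((cfg.rng_seed, _stable_hash("cluster")))
    )

    result = PipelineResult(
        manifest={
            "rng_seed": cfg.rng_seed,
            "config": dataclasses.asdict(cfg),
            "n_patients": len(patients),
        },
        perturbation={}, ranked={}, maps={}, features={},
        cluster_model=None, probabilities={}, calls={}, volumes={}, errors={},
    )
    for patient in patients:
        pid = patient.patient_id
        errs: list[str] = []
        n_valid = sum(segment_is_valid(s, cfg) for s in patient.segments)
        logger.info(
            "%s: %d/%d valid segments, %d excluded channels",
            pid, n_valid, len(patient.segments),
            sum(c.excluded for c in patient.channels),
        )
        # deterministic per-patient stream, independent of cohort order
        prng = np.random.default_rng(
            np.random.SeedSequence((cfg.rng_seed, _stable_hash(pid)))
        )
        if patient.soz_ids:
            try:
                result.perturbation[pid] = patient_perturbation(patient, cfg, prng)
            except (MissingSOZError, NoValidSegmentsError) as exc:
                errs.append(f"virtual_removal: {exc}")
        else:
            logger.info("%s: no SOZ flags, virtual removal skipped", pid)
        try:
            ranked, sp_map = ranked_perturbation(patient, cfg)
            result.ranked[pid] = ranked
            result.maps[pid] = sp_map
            if not sp_map.degenerate:
                result.features[pid] = quadrant_features(sp_map, pid)
        except Exception as exc:  # noqa: BLE001 - collected, run continues
            errs.append(f"ranked_map: {exc}")
        soz_xyz = [c.coordinate for c in patient.included_channels if c.is_soz]
        res_xyz = [c.coordinate for c in patient.included_channels if c.is_resected]
        both_xyz = [
            c.coordinate for c in patient.included_channels if c.is_soz and c.is_resected
        ]
        regions = (region_maps or {}).get(pid)
        pct = None
        if regions:
            soz_regions = {regions[c.channel_id] for c in patient.channels
                           if c.is_soz and c.channel_id in regions}
            res_regions = {regions[c.channel_id] for c in patient.channels
                           if c.is_resected and c.channel_id in regions}
            pct = percent_soz_resected(soz_regions, res_regions)
        result.volumes[pid] = VolumeEstimate(
            soz_cm3=sphere_union_volume(soz_xyz, cfg),
            resected_cm3=sphere_union_volume(res_xyz, cfg),
            resected_soz_cm3=sphere_union_volume(both_xyz, cfg),
            soz_pct_resected=pct,
        )
        if errs:
            result.errors[pid] = errs

    feats = [result.features[p.patient_id] for p in patients
             if p.patient_id in result.features]
    if len(feats) >= 6:
        labels = {
            p.patient_id: p.outcome_label
            for p in patients if p.outcome_label in ("seizure_free", "non_seizure_free")
        }
        model = fit_cluster_model(
            feats, cfg, rng=cluster_rng, outcome_labels=labels or None
        )
        result.cluster_model = model
        for f in feats:
            result.probabilities[f.patient_id] = probability_adequate(f, model)
            result.calls[f.patient_id] = classify_by_cluster(f, model)
    if result.errors:
        logger.warning("pipeline finished with stage errors: %s", result.errors)
    return result


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "little")


def perturbation_table(results: Mapping[str, PerturbationResult],
                       calls: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    rows = []
    for pid in sorted(results):
        r = results[pid]
        rows.append({
            "patient_id": pid,
            "rho_br": r.rho_br,
            "rho_ar": r.rho_ar,
            "rho_rr": r.rho_rr,
            "strength": r.strength,
            "n_valid_segments": r.n_valid_segments,
            "call": (calls or {}).get(pid, ""),
        })
    return pd.DataFrame(rows)


def save_model(model: ClusterModel, path) -> None:
    payload = {
        "c1_hat": model.c1_hat.tolist(),
        "c2_hat": model.c2_hat.tolist(),
        "t1": list(model.t1),
        "t2": list(model.t2),
        "selected_features": list(model.selected_features),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> ClusterModel:
    with open(path) as fh:
        payload = json.load(fh)
    return ClusterModel(
        c1_hat=np.array(payload["c1_hat"]),
        c2_hat=np.array(payload["c2_hat"]),
        t1=tuple(payload["t1"]),
        t2=tuple(payload["t2"]),
        selected_features=tuple(payload["selected_features"]),
    )


# ---------------------------------------------------------------------------
# figures (presentation only, never consumed downstream)
# ---------------------------------------------------------------------------

def render_sp_map(sp_map: SPMap, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(sp_map.image, aspect="auto", cmap="hot",
                   extent=(sp_map.bin_edges[0], sp_map.bin_edges[-1],
                           sp_map.image.shape[0], 0))
    ax.set_xlabel("distance to perturbation centroid (mm)")
    ax.set_ylabel("channel rank (strength descending)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="perturbation strength")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_feature_space(
    features: Sequence[MapFeatures], model: ClusterModel, path
) -> None:
    """3-D scatter of (Q1, Q2, Q4) features with the fitted centroids."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = np.array([f.vector(model.selected_features) for f in features])
    calls = [classify_by_cluster(f, model) for f in features]
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    for call, color in (("well_sampled", "tab:green"), ("poorly_sampled", "tab:red")):
        pts = X[[c == call for c in calls]]
        if len(pts):
            ax.scatter(*pts.T, color=color, label=call, alpha=0.7)
    ax.scatter(*model.c1_hat, marker="*", s=200, color="black", label="c1 (adequate)")
    ax.scatter(*model.c2_hat, marker="X", s=150, color="gray", label="c2")
    labels = [q.upper() for q in model.selected_features]
    ax.set_xlabel(labels[0]); ax.set_ylabel(labels[1]); ax.set_zlabel(labels[2])
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
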