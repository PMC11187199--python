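"""Test utilities: toy-patient construction and independent oracles."""

import numpy as np

from seegsp.core import ChannelRecord, PatientData, SegmentRates


def build_patient(
    coords: dict,
    rates: dict,
    soz=(),
    excluded=(),
    patient_id: str = "T1",
    n_minutes: float = 10.0,
    outcome=None,
) -> PatientData:
    """Patient with a single rate segment from plain dicts."""
    channels = [
        ChannelRecord(
            channel_id=cid,
            coordinate=np.asarray(xyz, dtype=float),
            is_soz=cid in set(soz),
            excluded=cid in set(excluded),
        )
        for cid, xyz in coords.items()
    ]
    seg = SegmentRates(segment_id="S01", rates=dict(rates), n_minutes=n_minutes)
    return PatientData(patient_id=patient_id, channels=channels, segments=[seg],
                       outcome_label=outcome)


def pearson_bruteforce(x, y):
    """Term-by-term evaluation of the correlation sum (independent oracle)."""
    mx, my = np.mean(x), np.mean(y)
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    sx = np.sqrt(sum((xi - mx) ** 2 for xi in x))
    sy = np.sqrt(sum((yi - my) ** 2 for yi in y))
    return num / (sx * sy)
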