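"""Ranked perturbation strengths, the centroid, and SP-map construction."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from seegsp.core import build_spatial_system
from seegsp.ranked import (
    build_sp_map,
    channel_perturbation_strengths,
    median_strengths,
    perturbation_centroid,
    ranked_perturbation,
)
from helpers import build_patient, pearson_bruteforce


@pytest.fixture()
def toy_patient():
    rng = np.random.default_rng(12)
    coords = {f"c{i}": rng.uniform(-15, 15, 3) for i in range(6)}
    rates = {f"c{i}": float(rng.uniform(0.3, 7.0)) for i in range(6)}
    return build_patient(coords, rates)


class TestChannelStrengths:
    def test_reference_channel_scores_one(self, toy_patient, cfg):
        strengths = channel_perturbation_strengths(
            toy_patient, toy_patient.segments[0], cfg
        )
        ref = max(
            toy_patient.segments[0].rates,
            key=lambda c: (toy_patient.segments[0].rates[c], c),
        )
        assert strengths[ref] == 1.0

    def test_full_vector_matches_independent_recompute(self, toy_patient, cfg):
        """P_hat per channel equals a from-scratch evaluation of the
        permuted systems (global reference excluded from each point set)."""
        segment = toy_patient.segments[0]
        rates = dict(segment.rates)
        coords = {c.channel_id: c.coordinate for c in toy_patient.channels}
        ref = max(rates, key=lambda c: (rates[c], c))

        def rho_at(anchor, drop):
            xs, ys = [], []
            for cid, rate in rates.items():
                if cid == anchor or cid in drop:
                    continue
                d = np.linalg.norm(coords[cid] - coords[anchor])
                xs.append(np.log(d))
                ys.append(np.log(rate))
            return pearson_bruteforce(xs, ys)

        rho_ref = rho_at(ref, set())
        expected = {}
        for cid in rates:
            if cid == ref:
                expected[cid] = 1.0
            else:
                expected[cid] = 1.0 - (rho_at(cid, {ref}) - rho_ref)

        strengths = channel_perturbation_strengths(toy_patient, segment, cfg)
        for cid in rates:
            assert strengths[cid] == pytest.approx(expected[cid], abs=1e-12)

    def test_strength_shift_by_rho_difference(self, toy_patient, cfg):
        # P_hat = 1 - (rho_i - rho_ref) exactly
        segment = toy_patient.segments[0]
        strengths = channel_perturbation_strengths(toy_patient, segment, cfg)
        rates = segment.rates
        ref = max(rates, key=lambda c: (rates[c], c))
        rho_ref = build_spatial_system(toy_patient, segment, ref, cfg).rho
        other = sorted(c for c in rates if c != ref)[0]
        rho_i = build_spatial_system(
            toy_patient, segment, other, cfg, drop_ids={ref}
        ).rho
        assert strengths[other] == pytest.approx(1.0 - (rho_i - rho_ref))

    def test_rate_rescaling_invariance(self, toy_patient, cfg):
        scaled = build_patient(
            {c.channel_id: c.coordinate for c in toy_patient.channels},
            {cid: 7.3 * r for cid, r in toy_patient.segments[0].rates.items()},
        )
        s0 = channel_perturbation_strengths(toy_patient, toy_patient.segments[0], cfg)
        s1 = channel_perturbation_strengths(scaled, scaled.segments[0], cfg)
        for cid in s0:
            assert s1[cid] == pytest.approx(s0[cid], abs=1e-12)


class TestMedianStrengths:
    def test_single_segment_identity(self):
        assert median_strengths([{"a": 0.4, "b": 1.0}]) == {"a": 0.4, "b": 1.0}

    def test_median_of_three(self):
        maps = [{"a": 1.0}, {"a": 0.2}, {"a": 0.9}]
        assert median_strengths(maps)["a"] == 0.9

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        maps = [{f"c{i}": float(rng.uniform()) for i in range(8)} for _ in range(5)]
        out = median_strengths(maps)
        for cid in maps[0]:
            vals = sorted(m[cid] for m in maps)
            assert out[cid] == vals[2]


class TestPerturbationCentroid:
    def test_singleton_high_set(self, cfg):
        coords = {"a": (1, 2, 3), "b": (0, 0, 0), "c": (5, 5, 5), "d": (9, 0, 0)}
        patient = build_patient(coords, {k: 1.0 for k in coords})
        centroid, high = perturbation_centroid(
            patient, {"a": 1.0, "b": 0.0, "c": 0.0, "d": 0.0}, cfg
        )
        assert high == {"a"}
        np.testing.assert_allclose(centroid, [1, 2, 3])

    def test_all_equal_uses_every_channel(self, cfg):
        coords = {"a": (0, 0, 0), "b": (2, 0, 0), "c": (4, 0, 0)}
        patient = build_patient(coords, {k: 1.0 for k in coords})
        centroid, high = perturbation_centroid(
            patient, {"a": 0.5, "b": 0.5, "c": 0.5}, cfg
        )
        assert high == {"a", "b", "c"}
        np.testing.assert_allclose(centroid, [2, 0, 0])

    def test_ten_channel_top_thirty_percent(self, cfg):
        rng = np.random.default_rng(4)
        coords = {f"c{i}": rng.uniform(-10, 10, 3) for i in range(10)}
        patient = build_patient(coords, {k: 1.0 for k in coords})
        p_bar = {f"c{i}": i / 10.0 for i in range(10)}
        thr = np.percentile(list(p_bar.values()), cfg.centroid_percentile)
        expected_ids = [cid for cid, v in p_bar.items() if v >= thr]
        centroid, high = perturbation_centroid(patient, p_bar, cfg)
        assert high == set(expected_ids)
        np.testing.assert_allclose(
            centroid, np.mean([coords[c] for c in sorted(expected_ids)], axis=0)
        )


class TestSPMap:
    def test_rows_sorted_descending(self, cfg):
        rng = np.random.default_rng(5)
        coords = {f"c{i}": rng.uniform(-20, 20, 3) for i in range(12)}
        patient = build_patient(coords, {k: 1.0 for k in coords})
        p_bar = {cid: float(rng.uniform()) for cid in coords}
        sp_map = build_sp_map(patient, p_bar, np.zeros(3), cfg)
        values = [p_bar[cid] for cid in sp_map.row_order]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert sp_map.image.shape[1] == cfg.map_bins

    def test_raw_has_one_activation_per_row(self, cfg):
        rng = np.random.default_rng(6)
        coords = {f"c{i}": rng.uniform(-20, 20, 3) for i in range(9)}
        patient = build_patient(coords, {k: 1.0 for k in coords})
        p_bar = {cid: float(rng.uniform(0.1, 1.0)) for cid in coords}
        sp_map = build_sp_map(patient, p_bar, np.zeros(3), cfg)
        assert ((sp_map.raw_image > 0).sum(axis=1) <= 1).all()

    def test_closing_never_decreases_and_keeps_max(self, cfg):
        rng = np.random.default_rng(7)
        coords = {f"c{i}": rng.uniform(-20, 20, 3) for i in range(15)}
        patient = build_patient(coords, {k: 1.0 for k in coords})
        p_bar = {cid: float(rng.uniform(0.0, 1.0)) for cid in coords}
        sp_map = build_sp_map(patient, p_bar, np.zeros(3), cfg)
        assert (sp_map.image >= sp_map.raw_image - 1e-12).all()
        assert sp_map.image.max() == pytest.approx(sp_map.raw_image.max())

    def test_focal_set_lands_in_left_columns(self, cfg):
        rng = np.random.default_rng(8)
        coords, p_bar = {}, {}
        for i in range(5):  # tight focal set within 4 mm of the centroid
            u = rng.normal(size=3)
            coords[f"f{i}"] = rng.uniform(1.0, 4.0) * u / np.linalg.norm(u)
            p_bar[f"f{i}"] = 0.8 + 0.04 * i
        for i in range(20):  # distant background channels
            u = rng.normal(size=3)
            coords[f"b{i:02d}"] = 45.0 * u / np.linalg.norm(u) + rng.normal(size=3)
            p_bar[f"b{i:02d}"] = float(rng.uniform(0.0, 0.2))
        patient = build_patient(coords, {k: 1.0 for k in coords})
        sp_map = build_sp_map(patient, p_bar, np.zeros(3), cfg)
        top5 = sp_map.raw_image[:5]
        cols = np.argwhere(top5 > 0)[:, 1]
        assert (cols < 0.1 * cfg.map_bins).all()

    def test_all_distances_zero_is_degenerate(self, cfg):
        coords = {"a": (1, 1, 1), "b": (1, 1, 1)}
        patient = build_patient(coords, {"a": 1.0, "b": 1.0})
        sp_map = build_sp_map(patient, {"a": 1.0, "b": 0.5}, np.ones(3), cfg)
        assert sp_map.degenerate

    def test_deterministic(self, cfg):
        rng = np.random.default_rng(9)
        coords = {f"c{i}": rng.uniform(-20, 20, 3) for i in range(10)}
        patient = build_patient(coords, {k: 1.0 for k in coords})
        p_bar = {cid: float(rng.uniform()) for cid in coords}
        m1 = build_sp_map(patient, p_bar, np.zeros(3), cfg)
        m2 = build_sp_map(patient, p_bar, np.zeros(3), cfg)
        np.testing.assert_array_equal(m1.image, m2.image)
        assert m1.row_order == m2.row_order


class TestOnSyntheticCohort:
    def test_soz_channels_have_larger_strengths(self, small_cohort, cfg):
        """Within well-sampled patients the SOZ carries the perturbation."""
        soz_vals, other_vals = [], []
        for sp in small_cohort[:4]:
            if sp.scenario.kind != "well_sampled":
                continue
            ranked, _ = ranked_perturbation(sp.data, cfg)
            for cid, v in ranked.per_channel_strength.items():
                (soz_vals if cid in sp.data.soz_ids else other_vals).append(v)
        assert np.mean(soz_vals) > np.mean(other_vals)
        assert mannwhitneyu(soz_vals, other_vals, alternative="greater").pvalue < 0.01

    def test_centroid_close_to_true_source(self, small_cohort, cfg):
        """Centroid error stays below the implantation's spatial scale
        (median pairwise inter-channel distance) for most patients."""
        hits = []
        for sp in small_cohort:
            if sp.scenario.kind != "well_sampled":
                continue
            ranked, _ = ranked_perturbation(sp.data, cfg)
            coords = np.array([c.coordinate for c in sp.data.channels])
            pair = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
            spacing = np.median(pair[np.triu_indices(len(coords), 1)])
            err = np.linalg.norm(ranked.centroid - sp.scenario.source)
            hits.append(err < spacing)
        assert np.mean(hits) >= 0.8
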