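from collections import deque

import numpy as np
import pandas as pd
import pytest

import neurocompress as nc
from neurocompress import groupstats as gs


def make_meta(n_participants=8, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for c in (1, 2, 3):
            for b in (1, 2, 3, 4):
                rows.append(
                    {
                        "participant": f"s{p:02d}",
                        "complexity": c,
                        "block": b,
                        "accuracy": rng.uniform(0.5, 1.0),
                    }
                )
    return pd.DataFrame(rows)


def flood_fill_sizes(binary, connectivity=2):
    """Independent connected-components oracle (BFS over faces+edges)."""
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) <= connectivity
    ]
    seen = np.zeros_like(binary, dtype=bool)
    sizes = []
    for start in np.argwhere(binary):
        start = tuple(start)
        if seen[start]:
            continue
        size = 0
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            size += 1
            for d in offsets:
                w = tuple(np.add(v, d))
                if any(x < 0 or x >= s for x, s in zip(w, binary.shape)):
                    continue
                if binary[w] and not seen[w]:
                    seen[w] = True
                    q.append(w)
        sizes.append(size)
    return sorted(sizes, reverse=True)


class TestMixedInteraction:
    def test_recovers_planted_negative_interaction(self):
        meta = make_meta(seed=1)
        rng = np.random.default_rng(2)
        y = (
            0.5
            + 0.05 * meta["block"]
            + 0.02 * meta["complexity"]
            - 0.02 * meta["block"] * meta["complexity"]
            + rng.normal(0, 0.02, len(meta))
        )
        df = meta.assign(y=y)
        tab = gs.fit_mixed_interaction(df, "y")
        assert tab.loc["block:complexity", "coef"] < 0
        assert tab.loc["block:complexity", "p"] < 0.001
        assert tab.loc["block", "coef"] > 0


class TestVoxelwiseMap:
    def test_sign_recovery_and_participant_permutation_invariance(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        meta = make_meta(n_participants=6, seed=3)
        rng = np.random.default_rng(4)
        eff = -(0.03 * meta["block"] * meta["complexity"]).to_numpy()
        maps = rng.normal(0, 0.02, (len(meta), 5, 5, 5)) + eff[:, None, None, None]
        smap = gs.voxelwise_interaction_map(maps, meta, mask)
        assert np.all(smap.t[mask] < 0)
        # relabeling participants jointly leaves the fit unchanged
        meta2 = meta.copy()
        relabel = {f"s{p:02d}": f"z{p:02d}" for p in range(6)}
        meta2["participant"] = meta2["participant"].map(relabel)
        smap2 = gs.voxelwise_interaction_map(maps, meta2, mask)
        assert np.allclose(smap.t[mask], smap2.t[mask], atol=1e-8)

    def test_too_few_participants_rejected(self):
        meta = make_meta(n_participants=3)
        mask = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError):
            gs.voxelwise_interaction_map(
                np.zeros((len(meta), 2, 2, 2)), meta, mask
            )

    def test_null_interaction_rarely_crosses_the_voxel_threshold(self):
        mask = np.zeros((7, 7, 4), bool)
        mask[1:6, 1:6, 1:3] = True  # 50 voxels
        meta = make_meta(n_participants=10, seed=5)
        rng = np.random.default_rng(6)
        intercepts = rng.normal(0, 0.05, 10)
        u = np.repeat(intercepts, 12)
        maps = (
            rng.normal(0, 0.05, (len(meta), 7, 7, 4))
            + (0.02 * meta["block"]).to_numpy()[:, None, None, None]
            + u[:, None, None, None]
        )
        smap = gs.voxelwise_interaction_map(maps, meta, mask)
        from scipy import stats as sps

        t_crit = sps.t.ppf(1 - 0.001 / 2, smap.df_resid)
        rate = float(np.mean(np.abs(smap.t[mask]) > t_crit))
        assert rate <= 0.05


class TestClusterExtract:
    def test_planted_block_forms_single_cluster(self):
        t = np.zeros((10, 10, 10))
        t[2:7, 2:7, 2:7] = 10.0
        tab = gs.cluster_extract(t, voxel_p=0.001, extent=10, df_resid=100)
        assert len(tab) == 1
        assert tab.loc[0, "size"] == 125
        assert tab.loc[0, "sign"] == 1

    def test_extent_above_largest_cluster_gives_empty_table(self):
        t = np.zeros((6, 6, 6))
        t[1:3, 1:3, 1:3] = 8.0
        tab = gs.cluster_extract(t, voxel_p=0.001, extent=1000, df_resid=100)
        assert len(tab) == 0

    def test_sizes_match_flood_fill_oracle_on_random_maps(self):
        rng = np.random.default_rng(7)
        from scipy import stats as sps

        t_crit = sps.t.ppf(1 - 0.001 / 2, 200)
        for _ in range(20):
            t = rng.normal(0, 3.0, (12, 12, 12))
            tab = gs.cluster_extract(t, voxel_p=0.001, extent=1, df_resid=200)
            expect = flood_fill_sizes(t > t_crit) + flood_fill_sizes(-t > t_crit)
            assert sorted(tab["size"], reverse=True) == sorted(expect, reverse=True)

    def test_negative_clusters_detected_two_sided(self):
        t = np.zeros((6, 6, 6))
        t[1:4, 1:4, 1:4] = -9.0
        tab = gs.cluster_extract(t, voxel_p=0.001, extent=5, df_resid=50)
        assert tab.loc[0, "sign"] == -1 and tab.loc[0, "peak_t"] < 0


class TestBehavioralRegression:
    def test_learning_produces_large_repetition_effect(self, group_trials):
        tab = gs.behavioral_learning_regression(group_trials).set_index("effect")
        assert tab.loc["repetition", "chi2"] > 50
        assert tab.loc["repetition", "p"] < 0.001

    def test_shuffled_accuracy_kills_the_repetition_effect(self, group_trials):
        rng = np.random.default_rng(8)
        sh = group_trials.copy()
        correct = rng.permutation(sh["correct"].to_numpy())
        sh["correct"] = pd.array(correct, dtype="boolean")
        sh["response"] = pd.array(
            np.where(
                correct.astype(bool),
                sh["true_class"],
                np.where(sh["true_class"] == "A", "B", "A"),
            ),
            dtype="string",
        )
        tab = gs.behavioral_learning_regression(sh).set_index("effect")
        assert tab.loc["repetition", "chi2"] < 10


class TestLearningCurves:
    def test_all_correct_curve_is_one(self, schedule):
        trials = schedule.copy()
        trials["correct"] = pd.array([True] * len(trials), dtype="boolean")
        curves = gs.learning_curves(trials)
        assert np.allclose(curves["accuracy"], 1.0)

    def test_128_trials_give_8_blocks(self, sim_trials):
        curves = gs.learning_curves(sim_trials)
        assert (curves.groupby("problem")["block"].count() == 8).all()

    def test_alternating_accuracy_gives_half(self, schedule):
        trials = schedule.copy()
        trials["correct"] = pd.array([True, False] * (len(trials) // 2), dtype="boolean")
        curves = gs.learning_curves(trials)
        assert np.allclose(curves["accuracy"], 0.5)

    def test_indivisible_block_size_rejected(self, sim_trials):
        with pytest.raises(ValueError):
            gs.learning_curves(sim_trials, block_size=15)


def make_joined_tables(seed, slope=0.2, n_participants=10, null=False):
    rng = np.random.default_rng(seed)
    meta = make_meta(n_participants, seed=seed + 1000)
    meta["problem"] = meta["complexity"].map({1: "low", 2: "medium", 3: "high"})
    meta["order"] = np.tile(
        np.repeat(rng.integers(0, 2, n_participants), 12), 1
    ).astype(float)
    neural = meta.copy()
    neural["neural_compression"] = 0.5 + 0.1 * rng.standard_normal(len(meta))
    att = meta.copy()
    noise = 0.05 * rng.standard_normal(len(meta))
    u = np.repeat(rng.normal(0, 0.05, n_participants), 12)
    base = 0.1 + 0.02 * meta["block"].to_numpy() + u + noise
    if null:
        att["attention_compression"] = base
    else:
        att["attention_compression"] = (
            base + slope * neural["neural_compression"].to_numpy()
        )
    keys = ["participant", "problem", "block"]
    return (
        neural[keys + ["neural_compression"]],
        att[keys + ["attention_compression", "accuracy", "order"]],
    )


class TestCompressionAttentionRegression:
    def test_recovers_planted_slope_within_interval(self):
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            neural, att = make_joined_tables(seed=rep, slope=0.2)
            res = gs.compression_attention_regression(neural, att)
            lo, hi = res["ci"]
            hits += int(lo <= 0.2 <= hi)
        assert hits >= 0.85 * n_rep

    def test_null_slope_interval_covers_zero_at_nominal_rate(self):
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            neural, att = make_joined_tables(seed=1000 + rep, null=True)
            res = gs.compression_attention_regression(neural, att)
            lo, hi = res["ci"]
            hits += int(lo <= 0.0 <= hi)
        assert hits >= 0.8 * n_rep

    def test_duplicating_rows_keeps_point_estimate(self):
        neural, att = make_joined_tables(seed=5)
        res1 = gs.compression_attention_regression(neural, att)
        # duplicated keys break the 1:1 join contract, so duplicate via a
        # participant relabel that preserves the per-row structure instead
        big_n2 = neural.copy()
        big_n2["participant"] = big_n2["participant"] + "_b"
        big_a2 = att.copy()
        big_a2["participant"] = big_a2["participant"] + "_b"
        res2 = gs.compression_attention_regression(
            pd.concat([neural, big_n2], ignore_index=True),
            pd.concat([att, big_a2], ignore_index=True),
        )
        # REML variance components shift slightly with the doubled sample,
        # so the GLS point estimate is stable only to ~1e-2
        assert res2["coef"] == pytest.approx(res1["coef"], abs=0.01)

    def test_mismatched_tables_rejected(self):
        neural, att = make_joined_tables(seed=6)
        with pytest.raises(ValueError):
            gs.compression_attention_regression(neural.iloc[:50], att)

    def test_partial_residuals_align_with_slope(self):
        neural, att = make_joined_tables(seed=7, slope=0.3)
        res = gs.compression_attention_regression(neural, att)
        pr = res["partial_residuals"]
        r = np.corrcoef(pr["neural_partial"], pr["attention_partial"])[0, 1]
        assert r > 0.2
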