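"""Radius hierarchy metric, classification features, group statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from hypconn.connectivity import SUBNETWORKS, synthetic_node_meta
from hypconn.hierarchy import (
    build_features,
    classify_groups,
    group_difference,
    node_radius,
    radius_table,
    subnetwork_radii,
)
from hypconn.models import EmbeddingResult
from hypconn.synthdata import make_radius_table


def _emb(coords, K=-1.0, sid="s0", session="pre", group="HC", meta=None):
    coords = np.asarray(coords, dtype=float)
    if meta is None:
        meta = synthetic_node_meta(coords.shape[0])
    return EmbeddingResult(coords=coords, curvature=K, node_meta=meta,
                           subject_id=sid, session=session, group=group)


class TestNodeRadius:
    def test_origin_and_closed_form(self):
        emb = _emb([[0.0, 0.0], [0.5, 0.0]])
        r = node_radius(emb)
        assert np.isclose(r[0], 0.0)
        assert np.isclose(r[1], np.log(3.0))

    def test_rotation_invariance(self, rng):
        coords = rng.uniform(-0.5, 0.5, size=(10, 2))
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        r1 = node_radius(_emb(coords))
        r2 = node_radius(_emb(coords @ R.T))
        assert np.allclose(r1, r2, atol=1e-10)

    def test_curvature_scales_radius(self):
        emb1 = _emb([[0.3, 0.0]], K=-1.0)
        emb4 = _emb([[0.15, 0.0]], K=-4.0)
        # same relative position in each ball -> radius scales by 1/sqrt|K|
        assert np.isclose(node_radius(emb4)[0], node_radius(emb1)[0] / 2.0)


class TestSubnetworkRadii:
    def test_constant_radii(self):
        meta = synthetic_node_meta(16)  # two nodes per subnetwork
        out = subnetwork_radii(np.full(16, 0.7), meta)
        assert np.allclose(out.to_numpy(), 0.7)

    def test_hand_computed_means(self):
        meta = synthetic_node_meta(16)
        radii = np.arange(16, dtype=float)
        out = subnetwork_radii(radii, meta)
        # round-robin labels: subnetwork j has nodes {j, j+8}
        for j, net in enumerate(SUBNETWORKS):
            assert np.isclose(out[net], (j + (j + 8)) / 2.0)

    def test_zero_one_pattern(self):
        meta = synthetic_node_meta(16)
        radii = np.ones(16)
        radii[[0, 8]] = 0.0  # first subnetwork at the center
        out = subnetwork_radii(radii, meta)
        assert out[SUBNETWORKS[0]] == 0.0
        assert np.allclose(out[list(SUBNETWORKS[1:])], 1.0)

    def test_empty_subnetwork_rejected(self):
        meta = synthetic_node_meta(6)  # only 6 of 8 subnetworks present
        with pytest.raises(ValueError, match="no member"):
            subnetwork_radii(np.ones(6), meta)


class TestBuildFeatures:
    @pytest.fixture(scope="class")
    def cohort(self):
        from hypconn.synthdata import SynthCohortSpec, make_two_group_cohort

        spec = SynthCohortSpec(n_per_group=3, R=90, two_sessions=True, seed=5)
        graphs, _ = make_two_group_cohort(spec)
        embs = [
            _emb(np.random.default_rng(i).uniform(-0.4, 0.4, size=(90, 3)),
                 sid=g.subject_id, session=g.session, group=g.group,
                 meta=g.node_meta)
            for i, g in enumerate(graphs)
        ]
        return graphs, embs

    def test_feature_lengths(self, cohort):
        graphs, embs = cohort
        Xp, yp, _ = build_features(graphs, embs, feature_set="plv")
        Xr, _, _ = build_features(graphs, embs, feature_set="radius")
        Xc, _, _ = build_features(graphs, embs, feature_set="combined")
        assert Xp.shape[1] == 90 * 89 // 2 == 4005
        assert Xr.shape[1] == 90
        assert Xc.shape[1] == 4005 + 90

    def test_session_filter_keeps_pre_only(self, cohort):
        graphs, embs = cohort
        X, y, sids = build_features(graphs, embs, feature_set="radius")
        assert len(sids) == 6  # 3 per group, pre sessions only
        assert len(set(sids)) == 6

    def test_missing_embeddings_rejected(self, cohort):
        graphs, _ = cohort
        with pytest.raises(ValueError, match="embedding"):
            build_features(graphs, [], feature_set="radius")


class TestClassification:
    def test_perfectly_separable_features(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(20, 5)),
                       rng.normal(5, 0.1, size=(20, 5))])
        y = np.array(["HC"] * 20 + ["SCD"] * 20)
        rep = classify_groups(X, y, seed=0)
        assert rep.macro_f1 == 1.0
        assert rep.auc_roc == 1.0

    def test_permuted_labels_give_chance_auc(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(25, 4)),
                       rng.normal(1.5, 1, size=(25, 4))])
        y = np.array(["HC"] * 25 + ["SCD"] * 25)
        aucs = []
        for p in range(20):
            yp = np.random.default_rng(p).permutation(y)
            aucs.append(classify_groups(X, yp, seed=p).auc_roc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="two classes"):
            classify_groups(X, np.array(["HC"] * 10))

    def test_linear_kernel_auc_invariant_to_affine_feature_scaling(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.array(["A", "B"] * 20)
        a = classify_groups(X, y, kernel="linear", seed=1)
        b = classify_groups(X * 7.0 + 3.0, y, kernel="linear", seed=1)
        assert np.isclose(a.auc_roc, b.auc_roc, atol=1e-9)


class TestGroupDifference:
    def test_null_is_calibrated(self):
        flags = 0
        pvals = []
        for rep in range(40):
            table = make_radius_table(n_per_group=12, shift=0.0, seed=rep)
            out = group_difference(table, method="linear_adjusted")
            flags += int(out["significant"].sum())
            pvals.extend(out["p_value"])
        assert flags / (40 * 8) < 0.05  # FDR keeps the null nearly clean
        # raw p-values roughly uniform
        assert abs(np.mean(pvals) - 0.5) < 0.08

    def test_implanted_shift_detected_with_high_power(self):
        detected = 0
        n_rep = 60
        for rep in range(n_rep):
            table = make_radius_table(n_per_group=20, shift=0.15, noise_sd=0.05,
                                      seed=100 + rep)
            out = group_difference(table, method="linear_adjusted")
            sig = set(out[out.significant].subnetwork)
            detected += {"DAN", "FPN", "VAN"} <= sig
        assert detected / n_rep >= 0.9

    def test_effect_direction_matches_implant(self):
        table = make_radius_table(n_per_group=20, shift=0.2, noise_sd=0.05, seed=0)
        out = group_difference(table)
        groups = out.attrs["groups"]  # effect = groups[1] - groups[0]
        dan = out.set_index("subnetwork").loc["DAN", "effect"]
        # G2 radii are lowered; sign depends on group order
        assert (dan > 0) == (groups[1] == "HC")

    def test_permutation_matches_exact_enumeration(self):
        table = make_radius_table(n_per_group=4, shift=0.25, noise_sd=0.1,
                                  seed=7, two_sessions=False)
        out = group_difference(table, subnetworks=("DAN",), method="permutation",
                               n_perm=4000, seed=0)
        p_mc = float(out["p_value"].iloc[0])

        # exact null: all 70 balanced assignments of 8 subjects to groups
        df = table.groupby("subject_id").agg(
            {"radius_DAN": "mean", "age": "first", "group": "first"}
        ).reset_index()
        y = df["radius_DAN"].to_numpy()
        age = df["age"].to_numpy()
        obs_labels = (df["group"] == sorted(df["group"].unique())[1]).to_numpy()

        def contrast(lab):
            X = np.column_stack([np.ones(8), lab.astype(float), age])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            return beta[1]

        obs = abs(contrast(obs_labels))
        stats = [
            abs(contrast(np.isin(np.arange(8), combo)))
            for combo in itertools.combinations(range(8), 4)
        ]
        p_exact = np.mean([s >= obs - 1e-12 for s in stats])
        assert abs(p_mc - p_exact) < 0.05

    def test_degenerate_covariate_rejected(self):
        table = make_radius_table(n_per_group=5, seed=1)
        table["age"] = 70.0
        with pytest.raises(ValueError, match="constant"):
            group_difference(table)

    def test_single_group_rejected(self):
        table = make_radius_table(n_per_group=5, seed=1)
        table = table[table.group == "HC"]
        with pytest.raises(ValueError, match="two groups"):
            group_difference(table)


def test_fdr_monotonicity():
    # raising p-values elementwise never increases the rejection count
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.uniform(0, 0.3, size=8)
        q = np.minimum(p + rng.uniform(0, 0.3, size=8), 1.0)
        rej_p = multipletests(p, alpha=0.05, method="fdr_bh")[0].sum()
        rej_q = multipletests(q, alpha=0.05, method="fdr_bh")[0].sum()
        assert rej_q <= rej_p


def test_radius_table_layout():
    embs = [
        _emb(np.full((16, 2), 0.1 * (i + 1)), sid=f"s{i}", group="HC")
        for i in range(3)
    ]
    rt = radius_table(embs)
    assert len(rt) == 3
    assert all(f"radius_{n}" in rt.columns for n in SUBNETWORKS)
    assert rt["radius_pDMN"].is_monotonic_increasing
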