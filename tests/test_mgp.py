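"""Marker-gene-profile scores against an SVD oracle, orientation and
rescaling invariances, and the region x donor interaction model."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from hypometa.datatypes import AnnotatedExpression
from hypometa.enrichment import GeneRanking
from hypometa.mgp import (
    estimate_mgp,
    interaction_test,
    marker_auc_check,
    validate_markers,
)
from hypometa.simulate import SimulationConfig, gen_markers


def _expr_from_matrix(values, gene_names, donors=None):
    n_samples = values.shape[1]
    sample_ids = [f"s{i}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": donors if donors is not None else ["d0"] * n_samples,
            "structure_name": "ctx",
            "is_cerebral_cortex": True,
            "is_allocortex": False,
            "mni_x": 0.0, "mni_y": 0.0, "mni_z": 0.0,
        }
    )
    return AnnotatedExpression(
        pd.DataFrame(values, index=gene_names, columns=sample_ids), samples
    )


class TestEstimateMgp:
    def test_score_matches_svd_oracle_up_to_orientation(self, rng):
        n_markers, n_samples = 12, 40
        values = rng.normal(size=(n_markers, n_samples))
        genes = [f"M{i}" for i in range(n_markers)]
        expr = _expr_from_matrix(values, genes)
        est = estimate_mgp(expr, {"ct": genes}, scope="pooled")
        got = (
            est["scores"].set_index("sample_id")["score"]
            .loc[[f"s{i}" for i in range(n_samples)]]
            .to_numpy()
        )
        # independent oracle: leading left singular vector of the centered,
        # z-scored samples x markers matrix
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, keepdims=True
        )
        u, s, vt = np.linalg.svd(z.T - z.T.mean(axis=0), full_matrices=False)
        oracle = u[:, 0] * s[0]
        if np.corrcoef(oracle, z.T.mean(axis=1))[0, 1] < 0:
            oracle = -oracle
        oracle = (oracle - oracle.mean()) / oracle.std()
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_invariant_to_per_gene_affine_rescaling(self, rng):
        n_markers, n_samples = 8, 30
        values = rng.normal(size=(n_markers, n_samples))
        genes = [f"M{i}" for i in range(n_markers)]
        scale = rng.uniform(0.5, 10.0, size=(n_markers, 1))
        shift = rng.normal(scale=5.0, size=(n_markers, 1))
        a = estimate_mgp(_expr_from_matrix(values, genes), {"ct": genes}, scope="pooled")
        b = estimate_mgp(
            _expr_from_matrix(values * scale + shift, genes), {"ct": genes},
            scope="pooled",
        )
        np.testing.assert_allclose(
            a["scores"]["score"].to_numpy(), b["scores"]["score"].to_numpy(), atol=1e-8
        )

    def test_sign_flip_of_all_markers_leaves_score_invariant(self, rng):
        # the orientation rule re-anchors the score to the mean marker z
        n_markers, n_samples = 6, 25
        values = rng.normal(size=(n_markers, n_samples))
        genes = [f"M{i}" for i in range(n_markers)]
        a = estimate_mgp(_expr_from_matrix(values, genes), {"ct": genes}, scope="pooled")
        b = estimate_mgp(_expr_from_matrix(-values, genes), {"ct": genes}, scope="pooled")
        np.testing.assert_allclose(
            a["scores"]["score"].to_numpy(), -b["scores"]["score"].to_numpy(),
            atol=1e-8,
        )

    def test_constant_marker_dropped_all_constant_errors(self, rng):
        values = rng.normal(size=(4, 20))
        values[0] = 3.0
        genes = [f"M{i}" for i in range(4)]
        est = estimate_mgp(_expr_from_matrix(values, genes), {"ct": genes}, scope="pooled")
        assert est["summary"].loc[0, "n_markers_used"] == 3
        with pytest.raises(ValueError, match="non-constant"):
            estimate_mgp(
                _expr_from_matrix(np.ones((3, 20)), genes[:3]), {"ct": genes[:3]},
                scope="pooled",
            )

    def test_overlapping_markers_dropped_from_both_types(self):
        cleaned = validate_markers({"a": ["G1", "G2"], "b": ["G2", "G3"]})
        assert cleaned == {"a": ["G1"], "b": ["G3"]}

    def test_per_donor_scope_standardizes_within_donor(self, rng):
        config = SimulationConfig(n_marker_samples=120, n_donors=3, seed=15)
        markers, expr, _ = gen_markers(config)
        est = estimate_mgp(expr, markers, scope="per-donor")
        for (donor, ct), grp in est["scores"].groupby(["donor", "cell_type"]):
            assert grp["score"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["score"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)


class TestMarkerAuc:
    def test_markers_at_bottom_give_low_auc(self):
        genes = tuple(f"g{i:03d}" for i in range(200))
        ranking = GeneRanking(genes, tuple(float(200 - i) for i in range(200)))
        markers = {"mic": list(genes[-21:])}
        out = marker_auc_check(ranking, markers)
        assert out.loc[0, "AUC"] < 0.1
        assert out.loc[0, "direction"] == "down"

    def test_random_markers_near_half(self, rng):
        genes = tuple(f"g{i:03d}" for i in range(500))
        ranking = GeneRanking(genes, tuple(float(500 - i) for i in range(500)))
        aucs = []
        for _ in range(200):
            members = rng.choice(500, size=21, replace=False)
            out = marker_auc_check(ranking, {"ct": [genes[j] for j in members]})
            aucs.append(out.loc[0, "AUC"])
        aucs = np.array(aucs)
        se = aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 3 * se

    def test_pair_counting_oracle_on_21_marker_set(self, rng):
        genes = tuple(f"g{i:03d}" for i in range(300))
        ranking = GeneRanking(genes, tuple(float(300 - i) for i in range(300)))
        members = [genes[j] for j in rng.choice(300, size=21, replace=False)]
        out = marker_auc_check(ranking, {"ct": members})
        pos = ranking.positions()
        in_pos = {pos[g] for g in members}
        wins = sum(
            1 for a in in_pos for b in range(300) if b not in in_pos and a < b
        )
        assert out.loc[0, "AUC"] == pytest.approx(wins / (21 * 279), abs=1e-12)


class TestInteraction:
    def test_planted_interaction_detected(self):
        config = SimulationConfig(
            n_marker_samples=200, interaction_effect=1.5, seed=23
        )
        markers, expr, truth = gen_markers(config)
        est = estimate_mgp(expr, markers, scope="per-donor")
        target = list(markers)[-1]
        sub = est["scores"].query("cell_type == @target").set_index("sample_id")
        sub = sub.loc[list(expr.samples.index)]
        aberrant = config.donor_ids[config.aberrant_donor_index]
        res = interaction_test(
            sub["score"].to_numpy(),
            expr.samples["inside"].to_numpy(dtype=bool),
            (expr.samples["donor_id"] == aberrant).to_numpy(),
        )
        assert res["t"] > 0 and res["p"] < 0.05

    def test_null_p_uniform(self):
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(200):
            n = 60
            score = rng.normal(size=n)
            inside = rng.random(n) < 0.4
            donor = rng.random(n) < 0.3
            if inside.all() or (~inside).all() or donor.all() or (~donor).all():
                continue
            if not ((inside & donor).any() and (inside & ~donor).any()):
                continue
            ps.append(interaction_test(score, inside, donor)["p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_permuted_donor_flag_destroys_effect(self):
        config = SimulationConfig(
            n_marker_samples=200, interaction_effect=1.5, seed=24
        )
        markers, expr, _ = gen_markers(config)
        est = estimate_mgp(expr, markers, scope="per-donor")
        target = list(markers)[-1]
        sub = est["scores"].query("cell_type == @target").set_index("sample_id")
        sub = sub.loc[list(expr.samples.index)]
        rng = np.random.default_rng(0)
        aberrant = config.donor_ids[config.aberrant_donor_index]
        donor_flag = (expr.samples["donor_id"] == aberrant).to_numpy()
        ts = []
        for _ in range(11):
            ts.append(
                interaction_test(
                    sub["score"].to_numpy(),
                    expr.samples["inside"].to_numpy(dtype=bool),
                    rng.permutation(donor_flag),
                )["t"]
            )
        assert np.median(np.abs(ts)) < 1.0

    def test_collinear_design_names_term(self):
        score = np.arange(10.0)
        inside = np.array([True] * 5 + [False] * 5)
        with pytest.raises(ValueError, match="degenerate|collinear"):
            interaction_test(score, inside, inside.copy())

    def test_constant_flag_rejected(self):
        with pytest.raises(ValueError, match="does not vary"):
            interaction_test(
                np.arange(10.0),
                np.ones(10, dtype=bool),
                np.array([True, False] * 5),
            )

    def test_sign_recovery_rate(self):
        # planted positive interaction of 1 latent sd: sign recovered >= 95%
        rng = np.random.default_rng(77)
        hits = 0
        n_reps = 100
        for _ in range(n_reps):
            n = 120
            inside = rng.random(n) < 0.4
            donor = rng.random(n) < 0.3
            score = rng.normal(size=n) + 1.0 * (inside & donor)
            res = interaction_test(score, inside, donor)
            hits += res["sign"] > 0
        assert hits >= 95
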