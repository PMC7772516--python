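"""AUC set enrichment against pair-counting oracles, monotone-progression
flags under exchangeable nulls, and hypergeometric tails against full
enumeration — including the two worked examples reported for the human
pathology-stage and mouse microglia-state analyses."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from hypometa.datatypes import GeneSetCollection, HomologMap
from hypometa.enrichment import (
    GeneRanking,
    auc_enrichment,
    hypergeom_enrichment,
    monotone_flags,
    pairwise_stage_enrichment,
    progression_scan,
    rank_genes,
)


def _ranking(n, prefix="G"):
    genes = [f"{prefix}{i:04d}" for i in range(n)]
    return GeneRanking(tuple(genes), tuple(float(n - i) for i in range(n)))


def _auc_oracle(ranking: GeneRanking, members: set) -> float:
    """Brute-force pair counting on rank positions (top = best)."""
    pos = ranking.positions()
    in_pos = [pos[g] for g in members if g in pos]
    out_pos = [pos[g] for g in ranking.genes if g not in members]
    wins = sum(1 for a in in_pos for b in out_pos if a < b)
    return wins / (len(in_pos) * len(out_pos))


class TestAucEnrichment:
    def test_top_block_gives_auc_one(self):
        ranking = _ranking(1000)
        sets = GeneSetCollection({"TOP": list(ranking.genes[:50])})
        out = auc_enrichment(ranking, sets)
        assert out.loc[0, "AUC"] == 1.0
        assert out.loc[0, "direction"] == "up"

    def test_random_sets_mean_auc_half(self):
        ranking = _ranking(500)
        rng = np.random.default_rng(0)
        aucs = []
        sets = {}
        for i in range(2000):
            members = rng.choice(500, size=20, replace=False)
            sets[f"S{i}"] = [ranking.genes[j] for j in members]
        out = auc_enrichment(ranking, GeneSetCollection(sets))
        aucs = out["AUC"].to_numpy()
        se = aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 3 * se

    def test_matches_pair_counting_oracle_exactly(self):
        ranking = _ranking(100)
        rng = np.random.default_rng(1)
        sets = {
            f"S{i}": [ranking.genes[j] for j in rng.choice(100, 20, replace=False)]
            for i in range(10)
        }
        out = auc_enrichment(ranking, GeneSetCollection(sets)).set_index("set_id")
        for sid, members in sets.items():
            assert out.loc[sid, "AUC"] == pytest.approx(
                _auc_oracle(ranking, set(members)), abs=1e-12
            )

    def test_size_filter_is_applied_after_universe_intersection(self):
        ranking = _ranking(1000)
        sets = GeneSetCollection(
            {
                "TOO_SMALL": list(ranking.genes[:9]),
                "OK_LOW": list(ranking.genes[:10]),
                "OK_HIGH": list(ranking.genes[:200]),
                "TOO_BIG": list(ranking.genes[:201]),
                "BIG_BUT_SPARSE": list(ranking.genes[:150]) + [f"ABSENT{i}" for i in range(100)],
            }
        )
        out = auc_enrichment(ranking, sets)
        assert set(out["set_id"]) == {"OK_LOW", "OK_HIGH", "BIG_BUT_SPARSE"}

    def test_reversed_ranking_flips_auc(self):
        ranking = _ranking(200)
        members = list(ranking.genes[:30])
        sets = GeneSetCollection({"S": members})
        a = auc_enrichment(ranking, sets).loc[0, "AUC"]
        b = auc_enrichment(ranking.reversed(), sets).loc[0, "AUC"]
        assert a == pytest.approx(1.0 - b, abs=1e-12)

    def test_rank_genes_breaks_ties_lexicographically(self):
        stats = pd.Series({"B": 1.0, "A": 1.0, "C": 2.0})
        ranking = rank_genes(stats)
        assert ranking.genes == ("C", "A", "B")


class TestMonotoneFlags:
    def test_strictly_increasing_flagged(self):
        states = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        flags, frac = monotone_flags(states)
        assert flags.loc["g"] and frac == 1.0

    def test_tie_breaks_monotonicity(self):
        states = pd.DataFrame([[1.0, 1.0, 2.0]], index=["g"], columns=list("abc"))
        flags, _ = monotone_flags(states)
        assert not flags.loc["g"]

    def test_missing_value_excluded_from_both_counts(self):
        states = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, np.nan, 3.0]],
            index=["g1", "g2"], columns=list("abc"),
        )
        flags, frac = monotone_flags(states)
        assert "g2" not in flags.index
        assert frac == 1.0

    def test_exchangeable_null_fraction_one_over_k_factorial(self, rng):
        for k, expected in ((2, 1 / 2), (3, 1 / 6)):
            states = pd.DataFrame(
                rng.normal(size=(10_000, k)),
                index=[f"g{i}" for i in range(10_000)],
            )
            _, frac = monotone_flags(states)
            se = np.sqrt(expected * (1 - expected) / 10_000)
            assert abs(frac - expected) < 3 * se


class TestHypergeom:
    def test_human_pathology_worked_example(self):
        # universe 7319 genes, 17.9% increasing; 43 of 77 in the set
        p = hypergeom_enrichment(7319, round(0.179 * 7319), 77, 43)
        assert p < 1e-13

    def test_mouse_microglia_worked_example_needs_log_space(self):
        # universe 12712 genes, 6.5% increasing; 60 of 80 in the set
        p = hypergeom_enrichment(12712, round(0.065 * 12712), 80, 60)
        assert 0.0 < p < 1e-52

    def test_zero_hits_gives_one(self):
        assert hypergeom_enrichment(100, 30, 10, 0) == 1.0

    def test_tiny_enumeration_oracle(self):
        assert hypergeom_enrichment(5, 2, 2, 2) == pytest.approx(1 / comb(5, 2))

    def test_matches_full_enumeration_for_small_universes(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(5, 31))
            hits = int(rng.integers(0, n + 1))
            k = int(rng.integers(1, n + 1))
            obs = int(rng.integers(0, min(k, hits) + 1))
            # enumeration: P(X >= obs) = sum_j C(hits, j) C(n-hits, k-j) / C(n, k)
            total = sum(
                comb(hits, j) * comb(n - hits, k - j)
                for j in range(obs, min(k, hits) + 1)
                if k - j <= n - hits
            )
            expected = total / comb(n, k)
            assert hypergeom_enrichment(n, hits, k, obs) == pytest.approx(
                expected, rel=1e-9, abs=1e-12
            )

    def test_monotone_decreasing_in_set_hits(self):
        ps = [hypergeom_enrichment(100, 20, 15, h) for h in range(0, 16)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            hypergeom_enrichment(10, 5, 12, 3)


class TestProgressionScan:
    def _states(self, rng, n=800, planted=None, k=3):
        genes = [f"m{i:04d}" for i in range(n)]
        vals = rng.normal(size=(n, k))
        if planted:
            for gi in planted:
                vals[gi] = np.sort(rng.normal(size=k)) + np.arange(k) * 5
        return pd.DataFrame(vals, index=genes)

    def test_planted_set_ranks_first_among_decoys(self, rng):
        planted_idx = list(range(40))
        states = self._states(rng, planted=planted_idx)
        genes = list(states.index)
        sets = {"PLANTED": [genes[i] for i in planted_idx]}
        for i in range(200):
            members = rng.choice(len(genes), size=30, replace=False)
            sets[f"D{i:03d}"] = [genes[j] for j in members]
        out = progression_scan(states, GeneSetCollection(sets))
        assert out.loc[0, "set_id"] == "PLANTED"

    def test_invariant_to_set_order_and_duplicates(self, rng):
        states = self._states(rng, n=200)
        genes = list(states.index)
        members = [genes[i] for i in range(30)]
        a = progression_scan(
            states, GeneSetCollection({"S": members})
        ).loc[0, "p"]
        b = progression_scan(
            states, GeneSetCollection({"S": members[::-1] + members[:5]})
        ).loc[0, "p"]
        assert a == b

    def test_one_to_many_homolog_expansion(self, rng):
        states = self._states(rng, n=100)
        mouse = list(states.index)
        hmap = HomologMap(
            (("HUMAN1", mouse[0]), ("HUMAN1", mouse[1]), ("HUMAN2", mouse[2]))
        )
        assert hmap.translate(["HUMAN1", "HUMAN2"]) == [
            ("HUMAN1", mouse[0]), ("HUMAN1", mouse[1]), ("HUMAN2", mouse[2]),
        ]
        out = progression_scan(
            states, GeneSetCollection({"S": ["HUMAN1", "HUMAN2"]}), homologs=hmap
        )
        # two human genes expand to three mouse genes, counted once each
        assert out.loc[0, "n_genes"] == 3

    def test_untranslated_set_skipped(self, rng):
        states = self._states(rng, n=50)
        hmap = HomologMap((("A", "not_in_matrix"),))
        out = progression_scan(
            states, GeneSetCollection({"S": ["A"]}), homologs=hmap
        )
        assert len(out) == 0

    def test_null_sets_rarely_significant(self, rng):
        n_reps_with_hit = 0
        for rep in range(20):
            rep_rng = np.random.default_rng(1000 + rep)
            states = self._states(rep_rng, n=600)
            genes = list(states.index)
            sets = {}
            for i in range(50):
                members = rep_rng.choice(len(genes), size=25, replace=False)
                sets[f"D{i}"] = [genes[j] for j in members]
            out = progression_scan(states, GeneSetCollection(sets))
            if out["q"].min() < 0.05:
                n_reps_with_hit += 1
        assert n_reps_with_hit <= 1  # min q >= 0.05 in at least 19 of 20


class TestPairwiseStage:
    def test_set_at_top_gives_auc_one(self):
        ranking = _ranking(300)
        res = pairwise_stage_enrichment(ranking, list(ranking.genes[:25]))
        assert res["AUC"] == 1.0

    def test_reversal_antisymmetry(self):
        ranking = _ranking(300)
        members = list(ranking.genes[50:80])
        a = pairwise_stage_enrichment(ranking, members)["AUC"]
        b = pairwise_stage_enrichment(ranking.reversed(), members)["AUC"]
        assert a == pytest.approx(1.0 - b, abs=1e-12)

    def test_planted_up_set_enriched_on_stage_contrast(self, rng):
        # synthetic fold-change contrast: planted genes get a +1 sd shift
        n = 1000
        genes = [f"g{i:04d}" for i in range(n)]
        fc = rng.normal(size=n)
        planted = list(range(100))
        fc[planted] += 1.0
        ranking = rank_genes(pd.Series(fc, index=genes))
        res = pairwise_stage_enrichment(ranking, [genes[i] for i in planted])
        assert res["AUC"] > 0.7
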