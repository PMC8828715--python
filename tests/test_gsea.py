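"""Ranked lists, enrichment scores, permutation NES, GMT handling."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_ks
from radiofuse.gsea import (
    RankedGeneList,
    enrichment_score,
    normalise_es,
    rank_genes,
    read_gmt,
    signature_enrichment,
    write_gmt,
)


def _ranked(n=20, seed=0, metric=None):
    genes = [f"g{i:02d}" for i in range(n)]
    if metric is None:
        rng = np.random.default_rng(seed)
        metric = np.sort(rng.normal(size=n))[::-1]
    return RankedGeneList(genes=genes, metric=np.asarray(metric, float))


class TestRankGenes:
    def test_descending_by_signed_rho(self):
        rl = rank_genes(pd.Series({"A": 0.9, "B": -0.2, "C": 0.5,
                                   **{f"x{i}": 0.0 for i in range(15)}}))
        assert rl.genes[0] == "A"
        assert rl.genes[1] == "C"
        assert rl.genes[-1] == "B"

    def test_ties_break_lexicographically(self):
        rl = rank_genes(pd.Series({g: 0.0 for g in
                                   [f"g{i:02d}" for i in range(16)]}))
        assert rl.genes == sorted(rl.genes)

    def test_small_universe_rejected(self):
        with pytest.raises(ValueError, match=">= 15"):
            rank_genes(pd.Series({f"g{i}": float(i) for i in range(10)}))

    def test_nan_metrics_dropped_with_warning(self):
        vals = {f"g{i:02d}": float(i) for i in range(20)}
        vals["g00"] = np.nan
        with pytest.warns(UserWarning, match="undefined"):
            rl = rank_genes(pd.Series(vals))
        assert "g00" not in rl.genes


class TestEnrichmentScore:
    def test_set_at_top_scores_one(self):
        rl = _ranked(4, metric=[3.0, 2.0, 1.0, 0.5])
        es, running = enrichment_score(rl, {rl.genes[0]})
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_set_at_bottom_scores_minus_one(self):
        rl = _ranked(4, metric=[3.0, 2.0, 1.0, 0.5])
        es, running = enrichment_score(rl, {rl.genes[-1]})
        # running sum: -1/3, -2/3, -1, 0 -> extreme deviation -1
        assert es == pytest.approx(-1.0)
        np.testing.assert_allclose(running,
                                   [-1 / 3, -2 / 3, -1.0, 0.0], atol=1e-12)

    def test_running_sum_starts_and_ends_at_zero(self):
        rl = _ranked(30, seed=1)
        es, running = enrichment_score(rl, set(rl.genes[3:9]))
        assert abs(running[-1]) < 1e-12
        assert abs(es) <= 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_unweighted_matches_brute_force_ks(self, seed):
        rng = np.random.default_rng(seed)
        rl = _ranked(20, seed=seed)
        members = set(rng.choice(rl.genes, 6, replace=False))
        es, _ = enrichment_score(rl, members, p=0.0)
        assert es == pytest.approx(brute_force_ks(rl.genes, members),
                                   abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reversal_antisymmetry_unweighted(self, seed):
        rng = np.random.default_rng(seed)
        rl = _ranked(25, seed=seed + 10)
        members = set(rng.choice(rl.genes, 7, replace=False))
        es_fwd, _ = enrichment_score(rl, members, p=0.0)
        rev = RankedGeneList(genes=rl.genes[::-1],
                             metric=-rl.metric[::-1])
        es_rev, _ = enrichment_score(rev, members, p=0.0)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_empty_intersection_rejected(self):
        rl = _ranked(10)
        with pytest.raises(ValueError, match="intersect"):
            enrichment_score(rl, {"nope"})

    def test_full_universe_set_rejected(self):
        rl = _ranked(10)
        with pytest.raises(ValueError, match="whole"):
            enrichment_score(rl, set(rl.genes))


class TestNormaliseES:
    def test_null_set_nes_centred_near_one(self):
        rng = np.random.default_rng(7)
        rl = _ranked(200, seed=7)
        nes_values = []
        for s in range(12):
            members = set(rng.choice(rl.genes, 20, replace=False))
            res = normalise_es(rl, members, n_perm=200, seed=s)
            nes_values.append(abs(res.nes))
        assert 0.8 <= np.mean(nes_values) <= 1.2

    def test_planted_top_concentration_detected(self):
        rl = _ranked(200, seed=8)
        res = normalise_es(rl, set(rl.genes[:20]), n_perm=500, seed=1)
        assert res.nes > 1.0
        assert res.p <= 2 / 501

    def test_seeded_determinism(self):
        rl = _ranked(80, seed=9)
        members = set(rl.genes[5:25])
        a = normalise_es(rl, members, n_perm=200, seed=3)
        b = normalise_es(rl, members, n_perm=200, seed=3)
        assert (a.nes, a.p) == (b.nes, b.p)

    def test_minimum_permutations_enforced(self):
        rl = _ranked(30)
        with pytest.raises(ValueError, match="n_perm"):
            normalise_es(rl, set(rl.genes[:5]), n_perm=10)


class TestSignatureEnrichment:
    def _tables(self, n_genes=60, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(n_genes)]
        rho = pd.DataFrame(rng.uniform(-0.9, 0.9, size=(1, n_genes)),
                           index=["feat"], columns=genes)
        p = pd.DataFrame(rng.uniform(0.1, 1.0, size=(1, n_genes)),
                         index=["feat"], columns=genes)
        return rho, p, genes

    def test_one_feature_signature_equals_per_set_results(self):
        rho, p, genes = self._tables()
        sets = {"S1": genes[:20], "S2": genes[20:40]}
        rep = signature_enrichment(rho, p, sets, n_perm=200, seed=4)
        assert rep["generated"]
        assert set(rep["terms"]) == {"S1", "S2"}
        for r in rep["results"]:
            assert r.source_feature == "feat"
            assert r.fallback_full_ranking  # no gene passes p < 0.001 here

    def test_oversized_sets_excluded_before_scoring(self):
        rho, p, genes = self._tables(n_genes=600)
        sets = {"huge": genes, "ok": genes[:30]}
        rep = signature_enrichment(rho, p, sets, size_bounds=(15, 500),
                                   n_perm=200, seed=5)
        assert "huge" not in rep["terms"]
        assert "ok" in rep["terms"]

    def test_empty_signature_reported_not_generated(self):
        rho = pd.DataFrame(columns=["g1", "g2"])
        p = pd.DataFrame(columns=["g1", "g2"])
        rep = signature_enrichment(rho, p, {"S": ["g1"]})
        assert rep == {"generated": False,
                       "reason": "signature not generated"}


def test_gmt_round_trip(tmp_path):
    sets = {"SET_A": ["g1", "g2", "g3"], "SET_B": ["g9", "g2"]}
    path = tmp_path / "x.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets
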