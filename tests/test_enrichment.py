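"""GSEA/ssGSEA engines against brute-force oracles, and subset scores."""

import numpy as np
import pandas as pd
import pytest

from cafstate import enrichment, synth
from cafstate.enrichment import SubsetSignature


def brute_force_es(genes, scores, gene_set, w):
    """Independent O(N*|S|) running-sum oracle, plain Python."""
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    hits = [genes[i] in gene_set for i in order]
    n, n_hits = len(genes), sum(hits)
    hit_total = sum(abs(scores[i]) ** w for i in order if genes[i] in gene_set)
    running, best = 0.0, 0.0
    for i, is_hit in zip(order, hits):
        if is_hit:
            running += (abs(scores[i]) ** w / hit_total) if hit_total else 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best = running
    return best


def brute_force_ssgsea(genes, expr, gene_set, alpha):
    order = sorted(range(len(genes)), key=lambda i: (-expr[i], genes[i]))
    n = len(genes)
    hit_w = [(n - pos) ** alpha if genes[i] in gene_set else 0.0
             for pos, i in enumerate(order)]
    total_hit = sum(hit_w)
    n_miss = sum(1 for i in order if genes[i] not in gene_set)
    score, cum_hit, cum_miss = 0.0, 0.0, 0.0
    for pos, i in enumerate(order):
        cum_hit += hit_w[pos] / total_hit
        if genes[i] not in gene_set:
            cum_miss += 1.0 / n_miss
        score += cum_hit - cum_miss
    return score


class TestGseaEs:
    @pytest.mark.parametrize(
        "gene_set,expected",
        [({"A"}, 1.0), ({"E"}, -1.0), ({"A", "B", "C", "D", "E"}, 1.0)],
    )
    def test_boundary_cases(self, gene_set, expected):
        ranked = pd.Series([5.0, 4, 3, 2, 1], index=list("ABCDE"))
        assert enrichment.gsea_es(ranked, gene_set) == pytest.approx(expected)

    def test_matches_brute_force_oracle(self, rng):
        """Exact agreement with the independent running-sum oracle, 100 random
        (list, set) pairs of length <= 50."""
        for _ in range(100):
            n = int(rng.integers(5, 51))
            genes = [f"g{i}" for i in range(n)]
            scores = rng.normal(size=n)
            k = int(rng.integers(1, n))
            gene_set = set(rng.choice(genes, size=k, replace=False))
            w = float(rng.choice([0.0, 1.0, 1.5]))
            ranked = pd.Series(scores, index=genes)
            assert enrichment.gsea_es(ranked, gene_set, w) == pytest.approx(
                brute_force_es(genes, scores, gene_set, w), abs=1e-12
            )

    def test_es_bounded_and_reversal_negates_at_w0(self, rng):
        genes = [f"g{i}" for i in range(40)]
        scores = np.sort(rng.normal(size=40))[::-1]
        gene_set = set(genes[5:15])
        es = enrichment.gsea_es(pd.Series(scores, index=genes), gene_set, 0.0)
        es_rev = enrichment.gsea_es(pd.Series(-scores, index=genes), gene_set, 0.0)
        assert -1.0 <= es <= 1.0
        assert es_rev == pytest.approx(-es, abs=1e-9)

    def test_empty_intersection_errors(self, ranked_list):
        with pytest.raises(ValueError):
            enrichment.gsea_es(ranked_list, {"NOT_A_GENE"})

    def test_duplicate_genes_rejected(self):
        ranked = pd.Series([1.0, 2.0], index=["A", "A"])
        with pytest.raises(ValueError):
            enrichment.gsea_es(ranked, {"A"})

    def test_agrees_with_gseapy(self, rng):
        """Independent cross-check against an external GSEA implementation."""
        gseapy = pytest.importorskip("gseapy")
        genes = [f"g{i}" for i in range(60)]
        scores = np.round(np.sort(rng.normal(size=60))[::-1], 6)
        gene_set = sorted(rng.choice(genes, size=10, replace=False))
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": genes, "score": scores}),
            gene_sets={"S": gene_set}, permutation_num=10, min_size=2,
            max_size=100, seed=1, outdir=None, weight=1.0, threads=1,
        )
        ours = enrichment.gsea_es(pd.Series(scores, index=genes), set(gene_set), 1.0)
        assert ours == pytest.approx(float(res.res2d["ES"].iloc[0]), abs=1e-4)


class TestPreranked:
    def test_seeded_determinism(self, ranked_list):
        s = set(ranked_list.index[:10])
        a = enrichment.gsea_preranked(ranked_list, s, n_perm=200, seed=7)
        b = enrichment.gsea_preranked(ranked_list, s, n_perm=200, seed=7)
        assert (a.nes, a.p_value) == (b.nes, b.p_value)

    def test_top_decile_strongly_enriched(self, ranked_list):
        s = set(ranked_list.index[:10])
        res = enrichment.gsea_preranked(ranked_list, s, n_perm=500, seed=3)
        assert res.es > 0 and res.nes > 1.5
        # p sits at its attainable floor: 1/(same-sign permutations + 1)
        assert res.p_value < 0.01

    def test_sign_consistency_and_p_range(self, ranked_list, rng):
        s = set(rng.choice(ranked_list.index, size=12, replace=False))
        res = enrichment.gsea_preranked(ranked_list, s, n_perm=200, seed=1)
        assert np.sign(res.nes) == np.sign(res.es)
        assert 0.0 < res.p_value <= 1.0

    def test_few_permutations_warns(self, ranked_list):
        with pytest.warns(UserWarning, match="permutations"):
            enrichment.gsea_preranked(ranked_list, set(ranked_list.index[:5]),
                                      n_perm=50, seed=0)


class TestSsgsea:
    def test_four_gene_oracle(self):
        expr = pd.Series([4.0, 3, 2, 1], index=list("ABCD"))
        assert enrichment.ssgsea_score(expr, {"A"}, alpha=0) == pytest.approx(2.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.25])
    def test_matches_brute_force(self, alpha, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            genes = [f"g{i}" for i in range(n)]
            expr = rng.uniform(0.1, 100.0, size=n)
            k = int(rng.integers(1, n))
            gene_set = set(rng.choice(genes, size=k, replace=False))
            ours = enrichment.ssgsea_score(pd.Series(expr, index=genes), gene_set, alpha)
            oracle = brute_force_ssgsea(genes, expr, gene_set, alpha)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_all_gene_set_boundary(self):
        expr = pd.Series([4.0, 3, 2, 1], index=list("ABCD"))
        # miss ECDF has no mass: score is the summed hit ECDF
        expected = sum((np.arange(1, 5)) / 4.0)
        assert enrichment.ssgsea_score(expr, set("ABCD"), alpha=0) == pytest.approx(expected)

    def test_monotone_transform_invariance_at_alpha0(self, rng):
        genes = [f"g{i}" for i in range(30)]
        expr = rng.uniform(1, 10, 30)
        s = set(rng.choice(genes, 8, replace=False))
        a = enrichment.ssgsea_score(pd.Series(expr, index=genes), s, alpha=0)
        b = enrichment.ssgsea_score(pd.Series(np.exp(expr), index=genes), s, alpha=0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_absent_set_errors(self):
        with pytest.raises(ValueError):
            enrichment.ssgsea_score(pd.Series([1.0], index=["A"]), {"B"})


class TestSubsetScores:
    def test_score_is_nes_difference(self):
        s = enrichment.CAFSubsetScore("myCAF", nes_up=2.0, nes_down=-1.5)
        assert s.score == pytest.approx(3.5)

    def test_concordant_profile_scores_positive(self, ranked_list):
        sig = SubsetSignature("myCAF", up=frozenset(ranked_list.index[:15]),
                              down=frozenset(ranked_list.index[-15:]))
        res = enrichment.caf_subset_score(ranked_list, sig, n_perm=300, seed=2)
        assert res.score > 0

    def test_swapped_signature_negates(self, ranked_list):
        up, down = frozenset(ranked_list.index[:15]), frozenset(ranked_list.index[-15:])
        fwd = enrichment.caf_subset_score(
            ranked_list, SubsetSignature("s", up, down), n_perm=500, seed=4)
        rev = enrichment.caf_subset_score(
            ranked_list, SubsetSignature("s", down, up), n_perm=500, seed=4)
        assert rev.score == pytest.approx(-fwd.score, abs=0.5)  # permutation noise

    def test_patient_score_uses_ssgsea(self, rng):
        genes = [f"g{i}" for i in range(50)]
        expr = pd.Series(np.sort(rng.uniform(1, 100, 50))[::-1], index=genes)
        sig = SubsetSignature("s", up=frozenset(genes[:10]), down=frozenset(genes[-10:]))
        assert enrichment.patient_subset_score(expr, sig) > 0
        swapped = SubsetSignature("s", up=frozenset(genes[-10:]), down=frozenset(genes[:10]))
        assert enrichment.patient_subset_score(expr, swapped) == pytest.approx(
            -enrichment.patient_subset_score(expr, sig), abs=1e-10
        )

    def test_overlapping_signature_rejected(self):
        with pytest.raises(ValueError):
            SubsetSignature("bad", up=frozenset("AB"), down=frozenset("BC"))


class TestBuildSignatures:
    def test_planted_markers_recovered(self, counts_truth):
        """>=90% of planted markers land in the correct up set at effect 2."""
        sigs = enrichment.build_signatures(counts_truth.counts, counts_truth.labels)
        for subset, markers in counts_truth.markers.items():
            hit = len(set(markers) & sigs[subset].up) / len(markers)
            assert hit >= 0.9, f"{subset}: {hit:.2f}"

    def test_small_subset_rejected(self, counts_truth):
        labels = counts_truth.labels.copy()
        labels.iloc[1:50] = "other"  # leaves one myCAF cell
        with pytest.raises(ValueError):
            enrichment.build_signatures(counts_truth.counts, labels)

    def test_single_subset_rejected(self, counts_truth):
        labels = pd.Series("same", index=counts_truth.counts.columns)
        with pytest.raises(ValueError):
            enrichment.build_signatures(counts_truth.counts, labels)


class TestTfConcordance:
    @staticmethod
    def profile(signs):
        return pd.DataFrame({"tf": [f"TF{i}" for i in range(len(signs))],
                             "nes": signs})

    def test_identical_profiles(self):
        p = self.profile([1.0, 2.0, -1.0, -3.0])
        pct, meta = enrichment.tf_concordance(p, p)
        assert pct == 100.0
        assert "definition" in meta

    def test_sign_flipped(self):
        p = self.profile([1.0, 2.0, -1.0, -3.0])
        q = p.assign(nes=-p["nes"])
        assert enrichment.tf_concordance(p, q)[0] == 0.0

    def test_half_agreeing(self):
        p = self.profile([1.0, 1.0, 1.0, 1.0])
        q = self.profile([1.0, 1.0, -1.0, -1.0])
        assert enrichment.tf_concordance(p, q)[0] == 50.0

    def test_union_denominator(self):
        p = self.profile([1.0, 1.0])
        q = pd.DataFrame({"tf": ["TF0", "TF1", "TF2"], "nes": [1.0, 1.0, 1.0]})
        pct, meta = enrichment.tf_concordance(p, q)
        assert meta["n_union"] == 3
        assert pct == pytest.approx(100.0 * 2 / 3)


def test_gmt_round_trip(tmp_path):
    sets = {"set_a": {"G1", "G2"}, "set_b": {"G3"}}
    path = tmp_path / "sets.gmt"
    enrichment.write_gmt(sets, path)
    assert enrichment.read_gmt(path) == sets


def test_signatures_to_gmt(tmp_path, counts_truth):
    sigs = enrichment.build_signatures(counts_truth.counts, counts_truth.labels)
    path = tmp_path / "sig.gmt"
    enrichment.signatures_to_gmt(sigs, path)
    loaded = enrichment.read_gmt(path)
    assert set(loaded) == {f"{s}_{d}" for s in sigs for d in ("up", "down")}
    assert loaded["myCAF_up"] == set(sigs["myCAF"].up)
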