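"""Locus association ranking and weighted-KS enrichment."""

import numpy as np
import pandas as pd
import pytest

from repmeth.gsea import (
    enrichment_score,
    gsea_permutation,
    locus_association_stats,
    tfbs_sets_from_annotation,
)
from tests.conftest import toy_beta_frame


def _brute_force_es(stats, member, p=1.0):
    """Independent step-by-step running-sum oracle."""
    n = len(stats)
    m = int(np.sum(member))
    total = sum(abs(s) ** p for s, mem in zip(stats, member) if mem)
    running, best = 0.0, 0.0
    for s, mem in zip(stats, member):
        running += (abs(s) ** p) / total if mem else -1.0 / (n - m)
        if abs(running) > abs(best):
            best = running
    return best


class TestLocusStats:
    def test_affine_locus_ranks_first(self):
        rng = np.random.default_rng(0)
        vals = rng.random((20, 15)) * 0.2 + 0.3
        x = rng.normal(50, 5, size=15)
        vals[4] = 0.3 + 0.005 * (x - x.min())
        m = toy_beta_frame(vals)
        stats = locus_association_stats(m, x)
        assert stats.index[0] == m.index[4]
        assert stats["rank"].iloc[0] == 1

    def test_independent_marker_statistics_symmetric(self):
        rng = np.random.default_rng(1)
        m = toy_beta_frame(rng.random((500, 30)))
        stats = locus_association_stats(m, rng.normal(size=30))
        assert abs(stats["t"].mean()) < 0.15
        assert abs((stats["t"] > 0).mean() - 0.5) < 0.06

    def test_tied_loci_adjacent_in_id_order(self):
        rng = np.random.default_rng(2)
        base = rng.random((4, 12))
        base[2] = base[0]          # identical loci -> identical statistics
        m = toy_beta_frame(base, loci=["cgB", "cgC", "cgA", "cgD"])
        stats = locus_association_stats(m, rng.normal(size=12))
        pos_a = stats.index.get_loc("cgA")
        pos_b = stats.index.get_loc("cgB")
        assert abs(pos_a - pos_b) == 1 and pos_a < pos_b


class TestEnrichmentScore:
    def test_frozen_ten_locus_worked_example(self):
        stats = np.array([5, 4, 3, 2, 1, 0.5, -1, -2, -3, -4], dtype=float)
        member = np.zeros(10, bool)
        member[[0, 2, 5]] = True
        es, peak = enrichment_score(stats, member, p=1.0)
        # hand computation: 5/8.5 - 1/7 + 3/8.5 peaks at position 2
        assert es == pytest.approx(8 / 8.5 - 1 / 7, abs=1e-12)
        assert peak == 2
        assert es == pytest.approx(_brute_force_es(stats, member), abs=1e-12)

    def test_top_block_unweighted_es_is_one(self):
        stats = np.linspace(3, -3, 12)
        member = np.zeros(12, bool)
        member[:4] = True
        es, peak = enrichment_score(stats, member, p=0.0)
        assert es == pytest.approx(1.0 - 0.0, abs=1e-12)
        assert peak == 3

    def test_interleaved_members_near_zero(self):
        stats = np.linspace(2, -2, 20)
        member = np.zeros(20, bool)
        member[::2] = True
        es, _ = enrichment_score(stats, member, p=0.0)
        assert abs(es) <= 0.1

    def test_running_sum_conserved(self):
        rng = np.random.default_rng(3)
        stats = np.sort(rng.normal(size=50))[::-1]
        member = rng.random(50) < 0.3
        member[0] = True
        n, m = 50, member.sum()
        w = np.abs(stats)
        steps = np.where(member, w / w[member].sum(), -1.0 / (n - m))
        assert np.cumsum(steps)[-1] == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_unweighted(self):
        rng = np.random.default_rng(4)
        stats = np.sort(rng.normal(size=30))[::-1]
        member = rng.random(30) < 0.25
        member[3] = True
        es1, _ = enrichment_score(stats, member, p=0.0)
        es2, _ = enrichment_score(stats * 7.3, member, p=0.0)
        assert es1 == pytest.approx(es2, abs=1e-14)

    def test_degenerate_sets_rejected(self):
        stats = np.arange(5.0)
        with pytest.raises(ValueError):
            enrichment_score(stats, np.zeros(5, bool))
        with pytest.raises(ValueError):
            enrichment_score(stats, np.ones(5, bool))


class TestGseaPermutation:
    @staticmethod
    def _matrix_and_sets(seed, n_loci=120, n_subj=25, n_sets=6, set_size=8):
        rng = np.random.default_rng(seed)
        m = toy_beta_frame(rng.random((n_loci, n_subj)) * 0.4 + 0.2)
        sets = {
            f"TF{i}": set(rng.choice(m.index, size=set_size, replace=False))
            for i in range(n_sets)
        }
        return m, sets, rng

    def test_b_minimum_enforced(self):
        m, sets, rng = self._matrix_and_sets(0)
        x = rng.normal(size=25)
        gsea_permutation(m, x, sets, B=100, seed=0)
        with pytest.raises(ValueError, match="100"):
            gsea_permutation(m, x, sets, B=50, seed=0)

    def test_size_filter_and_empty_error(self):
        m, sets, rng = self._matrix_and_sets(1)
        x = rng.normal(size=25)
        with pytest.raises(ValueError, match="size bounds"):
            gsea_permutation(m, x, sets, B=100, seed=0, min_set_size=50)

    def test_null_p_values_roughly_uniform(self):
        pvals = []
        for rep in range(12):
            m, sets, rng = self._matrix_and_sets(100 + rep)
            res = gsea_permutation(m, rng.normal(size=25), sets, B=150,
                                   seed=rep)
            pvals.extend(res.table["p"].tolist())
        pvals = np.asarray(pvals)
        assert (pvals <= 0.05).mean() < 0.15
        assert 0.3 < pvals.mean() < 0.7

    def test_injected_signal_set_wins(self):
        wins = 0
        reps = 10
        for rep in range(reps):
            m, sets, rng = self._matrix_and_sets(200 + rep)
            x = rng.normal(50, 5, size=25)
            target = sorted(sets["TF0"])
            shift = 0.012 * (x - x.mean())
            m.loc[target] = np.clip(m.loc[target].to_numpy() + shift, 0.001, 0.999)
            res = gsea_permutation(m, x, sets, B=500, seed=rep)
            wins += res.table.iloc[0]["set"] == "TF0"
        assert wins >= 0.9 * reps

    def test_sets_parsed_from_annotation(self):
        ann = pd.DataFrame({
            "tfbs_factors": ["TF001;TF002", "", "TF002"],
        }, index=pd.Index(["cg1", "cg2", "cg3"], name="locus_id"))
        sets = tfbs_sets_from_annotation(ann)
        assert sets == {"TF001": {"cg1"}, "TF002": {"cg1", "cg3"}}
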