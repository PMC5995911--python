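import numpy as np
import pandas as pd
import pytest

import poised as ps
from poised.bivalent import (GeneSignature, build_signature, classify_promoters,
                             enrichment_score, split_bivalent)
from poised.intervals import GenomicInterval
from poised.peaks import Peak

from conftest import per_base_mask, random_toy_intervals


def peak(start, end, chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end))


def promoter_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


class TestClassifyPromoters:
    def test_both_marks_is_bivalent(self):
        proms = promoter_frame([("g", "chr1", 1000, 3000)])
        out = classify_promoters(proms, [peak(0, 5000)], [peak(500, 2500)])
        assert out["state"].iloc[0] == "bivalent"

    def test_k4_only_is_active(self):
        proms = promoter_frame([("g", "chr1", 1000, 3000)])
        out = classify_promoters(proms, [peak(0, 5000)], [peak(10_000, 12_000)])
        assert out["state"].iloc[0] == "active"

    def test_k27_only_is_neither(self):
        proms = promoter_frame([("g", "chr1", 1000, 3000)])
        out = classify_promoters(proms, [], [peak(0, 5000)])
        assert out["state"].iloc[0] == "neither"

    def test_one_bp_intersection_suffices(self):
        proms = promoter_frame([("g", "chr1", 1000, 3000)])
        out = classify_promoters(proms, [peak(2999, 4000)], [peak(0, 1001)])
        assert out["state"].iloc[0] == "bivalent"

    def test_min_frac_requires_coverage(self):
        proms = promoter_frame([("g", "chr1", 0, 2000)])
        # K4 peak covers 40% of the promoter
        out = classify_promoters(proms, [peak(0, 800)], [], min_frac=0.5)
        assert out["state"].iloc[0] == "neither"
        out = classify_promoters(proms, [peak(0, 1000)], [], min_frac=0.5)
        assert out["state"].iloc[0] == "active"

    def test_duplicate_gene_ids_rejected(self):
        proms = promoter_frame([("g", "chr1", 0, 100), ("g", "chr1", 200, 300)])
        with pytest.raises(ValueError):
            classify_promoters(proms, [], [])

    def test_matches_per_base_oracle_random_toys(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            proms = promoter_frame([
                (f"g{i}", "toy", s, e)
                for i, (s, e) in enumerate(random_toy_intervals(rng, n=50, length=20_000, max_len=400))
            ])
            k4 = [peak(s, e, "toy") for s, e in random_toy_intervals(rng, n=20, length=20_000, max_len=600)]
            k27 = [peak(s, e, "toy") for s, e in random_toy_intervals(rng, n=20, length=20_000, max_len=600)]
            out = classify_promoters(proms, k4, k27)
            m4 = per_base_mask([(p.interval.start, p.interval.end) for p in k4], 20_000)
            m27 = per_base_mask([(p.interval.start, p.interval.end) for p in k27], 20_000)
            for row in out.itertuples(index=False):
                assert row.has_k4me3 == bool(m4[row.start:row.end].any())
                assert row.has_k27me3 == bool(m27[row.start:row.end].any())


class TestSplitBivalent:
    def states(self, genes):
        return pd.DataFrame({"gene_id": genes, "state": "bivalent"})

    def de(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2fc", "fdr", "baseline"])

    @pytest.mark.parametrize("lfc,fdr,group", [
        (1.5, 0.01, "up"),
        (1.0, 0.05, "up"),       # boundary values are inclusive
        (0.99, 0.001, "no_change"),
        (-1.0, 0.05, "down"),
        (-0.5, 0.001, "no_change"),
        (2.0, 0.06, "no_change"),  # significant fold change, FDR too high
    ])
    def test_threshold_assignment(self, lfc, fdr, group):
        split = split_bivalent(self.states(["g"]),
                               self.de([("g", lfc, fdr, 10.0)]))
        assert "g" in getattr(split, group)

    def test_partition_and_other(self):
        genes = [f"g{i}" for i in range(6)]
        de = self.de([
            ("g0", 2.0, 0.01, 1.0), ("g1", 1.0, 0.05, 1.0),
            ("g2", -2.0, 0.01, 1.0), ("g3", 0.0, 0.9, 1.0),
            ("g4", 5.0, 0.5, 1.0),
        ])  # g5 missing from the table
        split = split_bivalent(self.states(genes), de)
        assert split.up == {"g0", "g1"}
        assert split.down == {"g2"}
        assert split.no_change == {"g3", "g4", "g5"}
        assert split.other == split.down | split.no_change
        assert len(split.up) + len(split.down) + len(split.no_change) == 6

    def test_non_bivalent_genes_ignored(self):
        states = pd.DataFrame({"gene_id": ["a", "b"], "state": ["active", "bivalent"]})
        split = split_bivalent(states, self.de([("a", 3.0, 0.001, 1.0),
                                                ("b", 3.0, 0.001, 1.0)]))
        assert split.up == {"b"}


class TestBuildSignature:
    def de(self, pairs):
        return pd.DataFrame([(g, v, 0.01, 1.0) for g, v in pairs],
                            columns=["gene_id", "log2fc", "fdr", "baseline"])

    def test_threshold_inclusive(self):
        sig = build_signature(self.de([("g1", 6.0), ("g2", 5.0), ("g3", 4.9)]))
        assert sig.members == {"g1", "g2"}

    def test_empty_signature_raises(self):
        with pytest.raises(ValueError, match="empty"):
            build_signature(self.de([("g1", 0.0), ("g2", 0.0)]))

    def test_recovers_planted_strong_genes(self):
        # 20 genes planted at true log2FC = 6 among 180 nulls; low dispersion
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)],
            "archetype": "x",
            "chrom": "chr1", "strand": "+", "tss": 0,
            "promoter_start": 0, "promoter_end": 1,
            "true_log2fc": [6.0] * 20 + [0.0] * 180,
            "baseline": 500.0,
        })
        truth = ps.GroundTruth(genes, pd.DataFrame(), {}, {})
        cfg = ps.SimulationConfig(seed=9, dispersion=1e-3)
        de = ps.simulate_expression(truth, cfg)
        sig = build_signature(de, lfc_min=5.0)
        planted = set(genes["gene_id"][:20])
        assert len(sig.members & planted) >= 18


def running_sum_bruteforce(genes, metric, members, weight):
    """Independent prefix-walk oracle for the running-sum extremum."""
    order = np.argsort(-np.asarray(metric), kind="stable")
    genes = [genes[i] for i in order]
    metric = [metric[i] for i in order]
    hits = [g in members for g in genes]
    n, nh = len(genes), sum(hits)
    denom = sum(abs(m) ** weight for m, h in zip(metric, hits) if h)
    best, running = 0.0, 0.0
    for g, m, h in zip(genes, metric, hits):
        if h:
            running += (abs(m) ** weight) / denom if denom else 1.0 / nh
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


class TestEnrichmentScore:
    def ranked(self, values, genes=None):
        genes = genes or [f"g{i}" for i in range(len(values))]
        return pd.Series(values, index=genes)

    def test_signature_at_top_gives_high_positive_es(self):
        values = list(range(100, 0, -1))
        sig = GeneSignature("s", frozenset(f"g{i}" for i in range(5)))
        res = enrichment_score(self.ranked(values), sig, n_perm=100, seed=0)
        assert res.es > 0.9

    def test_exhaustive_oracle_on_ten_gene_lists(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(10)]
        for weight in (0.0, 1.0):
            for _ in range(25):
                metric = rng.normal(size=10).round(3).tolist()
                members = set(rng.choice(genes, size=3, replace=False))
                sig = GeneSignature("s", frozenset(members))
                res = enrichment_score(self.ranked(metric, genes), sig,
                                       weight=weight, n_perm=100, seed=1)
                want = running_sum_bruteforce(genes, metric, members, weight)
                assert res.es == pytest.approx(want, abs=1e-12)

    def test_all_hits_degenerate_rule(self):
        sig = GeneSignature("s", frozenset(f"g{i}" for i in range(10)))
        res = enrichment_score(self.ranked(list(range(10))), sig, n_perm=100, seed=0)
        assert res.es == 1.0

    def test_planted_enrichment_minimal_p(self):
        values = list(range(200, 0, -1))
        sig = GeneSignature("s", frozenset(f"g{i}" for i in range(10)))
        res = enrichment_score(self.ranked(values), sig, n_perm=500, seed=3)
        assert res.nes > 1.0
        # no same-sign permutation reaches the observed ES: p at its floor
        assert res.p == pytest.approx(1.0 / (1 + res.n_null_same_sign))
        assert res.p < 0.01

    def test_disjoint_signature_raises(self):
        sig = GeneSignature("s", frozenset(["absent"]))
        with pytest.raises(ValueError):
            enrichment_score(self.ranked([1.0, 2.0]), sig, n_perm=100, seed=0)

    def test_small_n_perm_rejected(self):
        sig = GeneSignature("s", frozenset(["g0"]))
        with pytest.raises(ValueError):
            enrichment_score(self.ranked([1.0, 2.0]), sig, n_perm=50, seed=0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(10)
        values = rng.normal(size=50).tolist()
        sig = GeneSignature("s", frozenset(f"g{i}" for i in range(0, 50, 7)))
        a = enrichment_score(self.ranked(values), sig, n_perm=200, seed=5)
        b = enrichment_score(self.ranked(values), sig, n_perm=200, seed=5)
        assert (a.es, a.nes, a.p) == (b.es, b.nes, b.p)
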