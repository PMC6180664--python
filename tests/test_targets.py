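"""Cis/trans target prediction and GO over-representation."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from lnckit import (
    AnnotationSet,
    DELRecord,
    GenomicInterval,
    cis_targets,
    go_enrichment,
    pearson_r,
    trans_targets,
)
from lnckit.intervals import make_transcript


def _del(lnc_id, chrom, start, end):
    return DELRecord(lnc_id, locus=GenomicInterval(chrom, start, end))


def _gene(gid, chrom, start, end, strand="+"):
    return make_transcript(gid, gid, chrom, strand, [(start, end)], "protein_coding")


def hypergeom_tail(k, N, K, n) -> float:
    """Exact upper tail P(X >= k) by enumeration with rational arithmetic."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return float(total)


class TestCis:
    def test_boundary_distance_inclusive(self):
        genes = AnnotationSet([_gene("G", "chr1", 10_000, 12_000)])
        hits = cis_targets([_del("L", "chr1", 22_000, 23_000)], genes)
        assert [(a.gene_id, a.distance) for a in hits] == [("G", 10_000)]
        none = cis_targets([_del("L", "chr1", 22_001, 23_000)], genes)
        assert none == []

    def test_overlapping_gene_is_distance_zero(self):
        genes = AnnotationSet([_gene("G", "chr1", 500, 2000)])
        hits = cis_targets([_del("L", "chr1", 1000, 1500)], genes)
        assert hits[0].distance == 0

    def test_other_chromosome_excluded(self):
        genes = AnnotationSet([_gene("G", "chr2", 0, 1000)])
        assert cis_targets([_del("L", "chr1", 0, 1000)], genes) == []

    def test_strand_blind(self):
        fwd = AnnotationSet([_gene("G", "chr1", 5000, 6000, "+")])
        rev = AnnotationSet([_gene("G", "chr1", 5000, 6000, "-")])
        d = [_del("L", "chr1", 0, 1000)]
        assert [a.gene_id for a in cis_targets(d, fwd)] == [
            a.gene_id for a in cis_targets(d, rev)
        ]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            genes = [
                _gene(f"G{i}", f"chr{rng.integers(1, 3)}",
                      s := int(rng.integers(0, 200_000)), s + int(rng.integers(500, 5000)))
                for i in range(25)
            ]
            dels = [
                _del(f"L{j}", f"chr{rng.integers(1, 3)}",
                     s := int(rng.integers(0, 200_000)), s + int(rng.integers(200, 3000)))
                for j in range(10)
            ]
            got = {
                (a.lnc_id, a.gene_id, a.distance)
                for a in cis_targets(dels, AnnotationSet(genes))
            }
            expected = set()
            for d in dels:
                for g in genes:
                    gap = d.locus.gap_to(g.interval)
                    if gap is not None and gap <= 10_000:
                        expected.add((d.lnc_id, g.transcript_id, gap))
            assert got == expected


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2, 3, 4, 5]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert pearson_r([1, 1, 1], [1, 2, 3]) is None

    def test_matches_closed_form(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            sx, sy = x - x.mean(), y - y.mean()
            expected = (sx @ sy) / math.sqrt((sx @ sx) * (sy @ sy))
            assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)


class TestTrans:
    def test_strict_threshold_excludes_equality(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r = pearson_r(x, y)
        d = pd.DataFrame([x], index=["L"])
        g = pd.DataFrame([y], index=["G"])
        pos, neg = trans_targets(d, g, r_threshold=abs(r), log_transform=False)
        assert pos == [] and neg == []

    def test_empty_del_set(self):
        g = pd.DataFrame(np.random.default_rng(0).random((3, 12)))
        pos, neg = trans_targets(g.iloc[:0], g, 0.7)
        assert pos == [] and neg == []

    def test_sample_mismatch_rejected(self):
        d = pd.DataFrame(np.ones((1, 12)))
        g = pd.DataFrame(np.ones((1, 12)), columns=range(1, 13))
        with pytest.raises(ValueError, match="same samples"):
            trans_targets(d, g)

    def test_sign_partition_and_magnitude_bound(self):
        rng = np.random.default_rng(3)
        d = pd.DataFrame(rng.random((5, 12)), index=[f"L{i}" for i in range(5)])
        g = pd.DataFrame(rng.random((30, 12)), index=[f"G{i}" for i in range(30)])
        pos, neg = trans_targets(d, g, r_threshold=0.3)
        assert all(0.3 < a.r <= 1.0 for a in pos)
        assert all(-1.0 <= a.r < -0.3 for a in neg)
        assert not ({(a.lnc_id, a.gene_id) for a in pos}
                    & {(a.lnc_id, a.gene_id) for a in neg})

    def test_planted_pairs_recovered(self, noisy_dataset):
        ds = noisy_dataset
        lncs = sorted({l for l, _, _ in ds.truth.expected_trans})
        genes = [f"PCG_{i:04d}" for i in range(1, 41)]
        pos, neg = trans_targets(
            ds.expression.values.loc[lncs], ds.expression.values.loc[genes]
        )
        found = {(a.lnc_id, a.gene_id, 1) for a in pos} | {
            (a.lnc_id, a.gene_id, -1) for a in neg
        }
        assert ds.truth.expected_trans <= found


class TestEnrichment:
    def _map(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "term_id", "namespace"]
        )

    def test_matches_closed_form_tail(self):
        background = [f"g{i}" for i in range(50)]
        target = background[:5]
        rows = [(g, "GO:1", "biological_process") for g in background[:8]]
        res = go_enrichment(target, background, self._map(rows))
        assert res[0].p_raw == pytest.approx(hypergeom_tail(5, 50, 8, 5), rel=1e-12)

    def test_term_annotating_everything_is_null(self):
        background = [f"g{i}" for i in range(20)]
        rows = [(g, "GO:all", "biological_process") for g in background]
        res = go_enrichment(background[:4], background, self._map(rows))
        assert res[0].p_raw == pytest.approx(1.0)

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            go_enrichment(["x"], ["a", "b"], self._map([]))

    def test_exhaustive_enumeration_small_instances(self):
        rng = np.random.default_rng(37)
        for _ in range(100):
            N = int(rng.integers(4, 13))
            background = [f"g{i}" for i in range(N)]
            n = int(rng.integers(1, N))
            K = int(rng.integers(1, N + 1))
            target = list(rng.choice(background, size=n, replace=False))
            annotated = list(rng.choice(background, size=K, replace=False))
            rows = [(g, "GO:x", "biological_process") for g in annotated]
            k = len(set(target) & set(annotated))
            res = go_enrichment(target, background, self._map(rows))
            if k == 0:
                assert res == []
            else:
                assert res[0].p_raw == pytest.approx(
                    hypergeom_tail(k, N, K, n), rel=1e-12
                )
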