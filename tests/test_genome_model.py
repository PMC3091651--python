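"""Circular coordinate arithmetic: origin distances, divergent pairs, coding density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repliorg.errors import CoordinateError, OrderingError
from repliorg.genome_model import (
    CircularGenome,
    circular_distance,
    coding_density,
    divergent_pair_gaps,
    gene_midpoint,
    gene_origin_distance,
    rotate_gene,
    rotate_genome,
)

from conftest import make_gene, random_genes


def brute_circular_distance(pos, L, origins):
    """Independent oracle: minimum over both arcs for every origin."""
    return min(min((pos - o) % L, (o - pos) % L) for o in origins)


class TestCircularDistance:
    @pytest.mark.parametrize(
        "L,origins,pos,expected",
        [
            (100, (0, 40), 0, 0),     # position on an origin
            (100, (0, 40), 40, 0),
            (100, (0, 40), 90, 10),   # shorter arc wraps past 0
            (10, (0,), 5, 5),         # antipodal maximum = L/2
            (100, (0,), 99, 1),
        ],
    )
    def test_examples(self, L, origins, pos, expected):
        assert circular_distance(pos, CircularGenome(L, origins)) == expected

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(1000):
            L = int(rng.integers(2, 1000))
            k = int(rng.integers(1, min(5, L)))
            origins = tuple(sorted(rng.choice(L, size=k, replace=False).tolist()))
            pos = int(rng.integers(0, L))
            g = CircularGenome(L, origins)
            assert circular_distance(pos, g) == brute_circular_distance(pos, L, origins)

    def test_bounded_by_half_length_and_zero_iff_origin(self, rng):
        for _ in range(200):
            L = int(rng.integers(2, 500))
            origins = tuple(sorted(rng.choice(L, size=2, replace=False).tolist()))
            g = CircularGenome(L, origins)
            pos = np.arange(L)
            d = circular_distance(pos, g)
            assert (d <= L / 2).all()
            assert set(pos[d == 0].tolist()) == set(origins)

    def test_out_of_range_position_rejected(self, toy_genome):
        with pytest.raises(CoordinateError):
            circular_distance(100, toy_genome)
        with pytest.raises(CoordinateError):
            circular_distance(-1, toy_genome)

    def test_vectorized_matches_scalar(self, toy_genome, rng):
        pos = rng.integers(0, 100, size=50)
        vec = circular_distance(pos, toy_genome)
        assert vec.tolist() == [circular_distance(int(p), toy_genome) for p in pos]


class TestGeneOriginDistance:
    def test_midpoint_distance(self):
        g = CircularGenome(100, (0,))
        assert gene_origin_distance(make_gene("a", 10, 20), g) == 15

    def test_wraparound_gene_midpoint(self):
        g = CircularGenome(100, (0,))
        gene = make_gene("a", 95, 5)
        assert gene_midpoint(gene, g) == 0
        assert gene_origin_distance(gene, g) == 0

    def test_gene_centred_on_origin(self):
        g = CircularGenome(100, (40,))
        assert gene_origin_distance(make_gene("a", 35, 45), g) == 0

    def test_invalid_coordinates_rejected(self):
        g = CircularGenome(100, (0,))
        with pytest.raises(CoordinateError):
            gene_origin_distance(make_gene("a", 10, 10), g)  # zero length
        with pytest.raises(CoordinateError):
            gene_origin_distance(make_gene("a", 150, 160), g)


class TestDivergentPairs:
    def test_same_strand_genes_yield_no_pairs(self):
        g = CircularGenome(1000, (0,))
        genes = [make_gene("a", 0, 100, "+"), make_gene("b", 150, 200, "+")]
        assert divergent_pair_gaps(genes, g) == []

    def test_divergent_pair_gap(self):
        g = CircularGenome(1000, (0,))
        genes = [make_gene("a", 0, 100, "-"), make_gene("b", 150, 200, "+")]
        (pair,) = divergent_pair_gaps(genes, g)
        assert (pair.upstream_id, pair.downstream_id, pair.gap_bp) == ("a", "b", 50)
        assert pair.midpoint_bp == 125

    def test_convergent_pair_excluded(self):
        # (+)(-) adjacency is convergent: 3' ends face, no shared upstream
        # region, so the a-b pair must not be emitted. (On a circle the
        # wrap-around b->a adjacency is independently divergent.)
        g = CircularGenome(1000, (0,))
        genes = [make_gene("a", 0, 100, "+"), make_gene("b", 150, 200, "-")]
        emitted = {(p.upstream_id, p.downstream_id)
                   for p in divergent_pair_gaps(genes, g)}
        assert ("a", "b") not in emitted
        # linear arrangement closed by a plus-strand gene: only b->c remains
        genes = [make_gene("a", 0, 100, "+"), make_gene("b", 150, 200, "-"),
                 make_gene("c", 300, 400, "+")]
        emitted = {(p.upstream_id, p.downstream_id)
                   for p in divergent_pair_gaps(genes, g)}
        assert emitted == {("b", "c")}

    def test_overlapping_divergent_pair_gap_zero(self):
        g = CircularGenome(1000, (0,))
        genes = [make_gene("a", 0, 100, "-"), make_gene("b", 80, 200, "+")]
        (pair,) = divergent_pair_gaps(genes, g)
        assert pair.gap_bp == 0

    def test_adjacency_wraps_across_zero(self):
        g = CircularGenome(1000, (0,))
        genes = [make_gene("b", 10, 100, "+"), make_gene("a", 900, 990, "-")]
        (pair,) = divergent_pair_gaps(genes, g)
        assert (pair.upstream_id, pair.downstream_id, pair.gap_bp) == ("a", "b", 20)

    def test_unsorted_input_rejected(self):
        g = CircularGenome(1000, (0,))
        genes = [make_gene("b", 150, 200, "+"), make_gene("a", 0, 100, "-")]
        with pytest.raises(OrderingError):
            divergent_pair_gaps(genes, g)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shift=st.integers(0, 9_999), seed=st.integers(0, 100))
    def test_gaps_invariant_under_rotation(self, shift, seed):
        g = CircularGenome(10_000, (0, 4_000))
        genes = random_genes(n=30, length=10_000, seed=seed)
        base = {(p.upstream_id, p.downstream_id, p.gap_bp)
                for p in divergent_pair_gaps(genes, g)}
        rotated = sorted((rotate_gene(x, shift, g) for x in genes),
                         key=lambda x: x.start)
        moved = {(p.upstream_id, p.downstream_id, p.gap_bp)
                 for p in divergent_pair_gaps(rotated, rotate_genome(g, shift))}
        assert base == moved


class TestCodingDensity:
    def test_empty_interval_has_zero_density(self):
        g = CircularGenome(100, (0,))
        assert coding_density([], (0, 100), g) == 0

    def test_full_cover(self):
        g = CircularGenome(100, (0,))
        assert coding_density([make_gene("a", 10, 60)], (10, 60), g) == 1

    def test_union_not_sum(self):
        g = CircularGenome(100, (0,))
        genes = [make_gene("a", 0, 40), make_gene("b", 30, 60)]
        assert coding_density(genes, (0, 100), g) == pytest.approx(0.6)

    def test_non_coding_genes_ignored(self):
        g = CircularGenome(100, (0,))
        genes = [make_gene("a", 0, 50, categories=("rrna_trna",))]
        assert coding_density(genes, (0, 100), g) == 0

    def test_zero_length_interval_rejected(self):
        g = CircularGenome(100, (0,))
        with pytest.raises(ValueError):
            coding_density([], (5, 5), g)

    def test_matches_per_bp_oracle_on_random_instances(self, rng):
        for _ in range(300):
            L = int(rng.integers(20, 1000))
            g = CircularGenome(L, (0,))
            genes = []
            covered = np.zeros(L, dtype=bool)
            for i in range(int(rng.integers(0, 8))):
                s = int(rng.integers(0, L))
                glen = int(rng.integers(1, L))
                e = s + glen
                genes.append(make_gene(f"g{i}", s, e if e <= L else e - L))
                idx = np.arange(s, e) % L
                covered[idx] = True
            a = int(rng.integers(0, L))
            blen = int(rng.integers(1, L))  # full circle not representable
            b = a + blen
            window = np.arange(a, b) % L
            expected = covered[window].mean()
            got = coding_density(genes, (a, b if b <= L else b - L), g)
            assert got == pytest.approx(expected, abs=1e-12)


class TestValidation:
    def test_origin_outside_genome_rejected(self):
        with pytest.raises(CoordinateError):
            CircularGenome(100, (0, 100))

    def test_duplicate_or_unsorted_origins_rejected(self):
        with pytest.raises(ValueError):
            CircularGenome(100, (10, 10))
        with pytest.raises(ValueError):
            CircularGenome(100, (40, 10))

    def test_empty_origins_rejected(self):
        with pytest.raises(ValueError):
            CircularGenome(100, ())

    def test_max_origin_distance(self):
        assert CircularGenome(100, (0, 40)).max_origin_distance == 30
        assert CircularGenome(10, (0,)).max_origin_distance == 5
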