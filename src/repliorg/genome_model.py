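"""Circular-chromosome data model.

A single circular chromosome with one or more replication origins, and a set
of annotated genes. All coordinate arithmetic is modular: positions live in
``[0, length_bp)``, gene spans are 0-based half-open ``[start, end)`` with
``end < start`` encoding a span that wraps across position 0.

The central quantity is the distance from a position to the *nearest*
replication origin measured along the circle, which under synchronous origin
firing and constant fork speed is a proxy for replication timing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import CoordinateError, OrderingError

#: Recognised gene category labels.
CATEGORY_LABELS = frozenset(
    {"core", "transposon", "rrna_trna", "txn_translation", "protein_coding"}
)


@dataclass(frozen=True)
class CircularGenome:
    """A circular chromosome of ``length_bp`` with ordered replication origins.

    Parameters
    ----------
    length_bp:
        Chromosome length in base pairs (positive).
    origins:
        Strictly increasing origin positions, each in ``[0, length_bp)``.
        At least one origin is required.
    """

    length_bp: int
    origins: tuple[int, ...]

    def __post_init__(self) -> None:
        if int(self.length_bp) <= 0:
            raise ValueError(f"length_bp must be positive, got {self.length_bp}")
        object.__setattr__(self, "length_bp", int(self.length_bp))
        origins = tuple(int(o) for o in self.origins)
        if not origins:
            raise ValueError("at least one replication origin is required")
        for o in origins:
            if not 0 <= o < self.length_bp:
                raise CoordinateError(
                    f"origin {o} outside [0, {self.length_bp})"
                )
        if any(b <= a for a, b in zip(origins, origins[1:])):
            raise ValueError(f"origins must be strictly increasing: {origins}")
        object.__setattr__(self, "origins", origins)

    @property
    def max_origin_distance(self) -> float:
        """Largest attainable origin distance: half the widest inter-origin arc."""
        o = np.asarray(self.origins, dtype=float)
        arcs = np.diff(np.append(o, o[0] + self.length_bp))
        return float(arcs.max()) / 2.0


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene on a circular chromosome.

    ``start``/``end`` are 0-based half-open; ``end < start`` encodes a span
    wrapping across position 0, and ``end == length_bp`` is a span ending at
    the last base. ``expression`` is a log2 cDNA/gDNA ratio or ``None`` when
    the gene was filtered out on the arrays.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    categories: frozenset = frozenset()
    expression: float | None = None
    cog_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "categories", frozenset(self.categories))


def gene_length(gene: GeneRecord, genome: CircularGenome) -> int:
    """Modular span length of ``gene`` on ``genome`` (always >= 1)."""
    L = genome.length_bp
    if not (0 <= gene.start < L and 0 <= gene.end <= L):
        raise CoordinateError(
            f"gene {gene.gene_id}: [{gene.start}, {gene.end}) invalid for L={L}"
        )
    n = (gene.end - gene.start) % L
    if n == 0:
        raise CoordinateError(
            f"gene {gene.gene_id}: zero/full-length span [{gene.start}, {gene.end})"
        )
    return n


def gene_midpoint(gene: GeneRecord, genome: CircularGenome) -> int:
    """Modular midpoint of the half-open gene span."""
    return (gene.start + gene_length(gene, genome) // 2) % genome.length_bp


def circular_distance(pos, genome: CircularGenome):
    """Distance (bp) from position(s) to the nearest replication origin.

    The distance is the shorter of the two arcs to each origin, minimised
    over origins; it lies in ``[0, length_bp / 2]``. Accepts a scalar or an
    array of positions, each in ``[0, length_bp)``.
    """
    arr = np.asarray(pos)
    L = genome.length_bp
    if np.any((arr < 0) | (arr >= L)):
        raise CoordinateError(f"position outside [0, {L}): {pos!r}")
    diff = np.abs(arr[..., None] - np.asarray(genome.origins))
    d = np.minimum(diff, L - diff).min(axis=-1)
    if arr.ndim == 0:
        return float(d)
    return d.astype(float)


def gene_origin_distance(gene: GeneRecord, genome: CircularGenome) -> float:
    """Origin distance of a gene, measured at its modular midpoint."""
    return circular_distance(gene_midpoint(gene, genome), genome)


@dataclass(frozen=True)
class DivergentPair:
    """Adjacent gene pair transcribed away from each other (-/+ order).

    ``gap_bp`` is the intergenic distance between the upstream gene's end and
    the downstream gene's start (0 when they overlap); ``midpoint_bp`` is the
    modular midpoint of that intergenic gap, used for window assignment.
    """

    upstream_id: str
    downstream_id: str
    gap_bp: int
    midpoint_bp: int


def divergent_pair_gaps(
    genes: Sequence[GeneRecord], genome: CircularGenome
) -> list[DivergentPair]:
    """Intergenic gaps of divergently transcribed adjacent gene pairs.

    Genes must be sorted by ``start``. For every pair of *immediately*
    adjacent genes where the upstream (lower-coordinate) gene is on the minus
    strand and the downstream gene on the plus strand — i.e. their 5' ends
    face each other across a shared upstream region — the intergenic gap is
    emitted. Adjacency wraps across position 0. Overlapping divergent pairs
    yield gap 0.
    """
    L = genome.length_bp
    starts = [g.start for g in genes]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise OrderingError("genes must be sorted by start coordinate")
    n = len(genes)
    if n < 2:
        return []
    pairs: list[DivergentPair] = []
    for i in range(n):
        up = genes[i]
        down = genes[(i + 1) % n]
        if up.strand != "-" or down.strand != "+":
            continue
        up_end = up.start + gene_length(up, genome)
        down_start = down.start + (L if i == n - 1 else 0)
        gap = max(0, down_start - up_end)
        mid = (up_end + gap // 2) % L
        pairs.append(DivergentPair(up.gene_id, down.gene_id, gap, mid))
    return pairs


def _coding_segments(
    genes: Iterable[GeneRecord], genome: CircularGenome
) -> list[tuple[int, int]]:
    """Merged, disjoint, sorted linear segments covered by protein-coding genes."""
    L = genome.length_bp
    raw: list[tuple[int, int]] = []
    for g in genes:
        if "protein_coding" not in g.categories:
            continue
        e = g.start + gene_length(g, genome)
        if e <= L:
            raw.append((g.start, e))
        else:  # wraps across 0
            raw.append((g.start, L))
            raw.append((0, e - L))
    raw.sort()
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class CodingCoverage:
    """Cumulative protein-coding coverage function over a circular genome.

    Precomputes the union of coding spans so that the covered length of any
    interval is answered in O(log n); used both for one-off density queries
    and for sliding-window tracks.
    """

    def __init__(self, genes: Iterable[GeneRecord], genome: CircularGenome):
        self.genome = genome
        segs = _coding_segments(genes, genome)
        self._starts = np.array([s for s, _ in segs], dtype=float)
        self._ends = np.array([e for _, e in segs], dtype=float)
        lens = self._ends - self._starts
        self._cum = np.concatenate([[0.0], np.cumsum(lens)])

    def covered_before(self, x):
        """Covered bp in the linear prefix ``[0, x)`` for x in ``[0, L]``."""
        x = np.asarray(x, dtype=float)
        if len(self._starts) == 0:
            return np.zeros(x.shape) if x.ndim else 0.0
        k = np.searchsorted(self._starts, x, side="right")
        prev = np.maximum(k - 1, 0)
        partial = self._cum[prev] + np.clip(
            x - self._starts[prev], 0.0, self._ends[prev] - self._starts[prev]
        )
        out = np.where(k > 0, partial, 0.0)
        return out if out.ndim else float(out)

    def interval_covered(self, a, b):
        """Covered bp of the circular interval ``[a, b)`` (b may wrap past 0)."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        L = float(self.genome.length_bp)
        fa, fb, fL = self.covered_before(a), self.covered_before(b), self._cum[-1]
        return np.where(b > a, fb - fa, fL - fa + fb)


def coding_density(
    genes: Sequence[GeneRecord],
    interval: tuple[int, int],
    genome: CircularGenome,
) -> float:
    """Fraction of the circular interval ``[a, b)`` covered by coding spans.

    Coverage is the union of protein-coding gene spans (overlaps counted
    once). ``b <= a`` encodes an interval wrapping across position 0; a
    zero-length interval is rejected.
    """
    a, b = interval
    L = genome.length_bp
    if not (0 <= a < L and 0 <= b <= L):
        raise CoordinateError(f"interval [{a}, {b}) invalid for L={L}")
    if a == b:
        raise ValueError(f"zero-length interval [{a}, {b})")
    length = b - a if b > a else L - a + b
    cov = CodingCoverage(genes, genome).interval_covered(a, b)
    return float(cov) / length


def rotate_gene(gene: GeneRecord, shift: int, genome: CircularGenome) -> GeneRecord:
    """Shift a gene's coordinates by ``shift`` bp around the circle."""
    L = genome.length_bp
    glen = gene_length(gene, genome)
    s = (gene.start + shift) % L
    e = s + glen
    return replace(gene, start=s, end=e if e <= L else e - L)


def rotate_genome(genome: CircularGenome, shift: int) -> CircularGenome:
    """Shift all origin positions by ``shift`` bp (re-sorted)."""
    L = genome.length_bp
    return CircularGenome(L, tuple(sorted((o + shift) % L for o in genome.origins)))
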