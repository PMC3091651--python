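"""Sliding- and non-overlapping-window feature tracks over a circular genome.

Features mirror the organisation gradients of interest: mean gene
expression, proportion of archaeal core genes, protein-coding density,
proportion of transposon genes, mean divergent-pair intergenic distance,
and the origin distance of the window midpoint itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .genome_model import (
    CircularGenome,
    CodingCoverage,
    DivergentPair,
    GeneRecord,
    circular_distance,
    divergent_pair_gaps,
    gene_midpoint,
)

FEATURES = (
    "mean_expression",
    "core_proportion",
    "coding_density",
    "transposon_proportion",
    "mean_divergent_gap",
    "origin_distance",
)


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry: 100 kb windows translocated in 1 kb steps by default."""

    size_bp: int = 100_000
    step_bp: int = 1_000
    mode: str = "sliding"

    def __post_init__(self) -> None:
        if self.mode not in ("sliding", "nonoverlapping"):
            raise ConfigError(f"unknown window mode {self.mode!r}")
        if self.size_bp < 1 or self.step_bp < 1:
            raise ConfigError("window size and step must be positive")
        if self.step_bp > self.size_bp:
            raise ConfigError(
                f"step ({self.step_bp}) must not exceed window size ({self.size_bp})"
            )


@dataclass(frozen=True)
class WindowGrid:
    """Concrete windows on one genome: start positions plus shared size."""

    length_bp: int
    size_bp: int
    starts: tuple[int, ...]

    @property
    def midpoints(self) -> np.ndarray:
        return (np.asarray(self.starts) + self.size_bp // 2) % self.length_bp

    def __len__(self) -> int:
        return len(self.starts)


def make_windows(genome: CircularGenome, spec: WindowSpec) -> WindowGrid:
    """Lay windows over the circle.

    Sliding mode yields ``ceil(L/step)`` windows starting at multiples of the
    step, wrapping across position 0; non-overlapping mode yields
    ``floor(L/size)`` abutting windows starting at 0.
    """
    L = genome.length_bp
    if spec.size_bp > L:
        raise ConfigError(f"window size {spec.size_bp} exceeds genome length {L}")
    if spec.mode == "sliding":
        n = -(-L // spec.step_bp)
        starts = tuple(i * spec.step_bp for i in range(n))
    else:
        n = L // spec.size_bp
        starts = tuple(i * spec.size_bp for i in range(n))
    return WindowGrid(L, spec.size_bp, starts)


@dataclass
class WindowTrack:
    """Per-window values of one named feature; NaN marks empty windows."""

    feature: str
    size_bp: int
    starts: np.ndarray
    midpoints: np.ndarray
    values: np.ndarray


def _membership(positions: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """Boolean (n_windows, n_positions): position inside window, modularly."""
    starts = np.asarray(grid.starts)
    rel = (positions[None, :] - starts[:, None]) % grid.length_bp
    return rel < grid.size_bp


def _masked_mean(member: np.ndarray, values: np.ndarray) -> np.ndarray:
    ok = member & np.isfinite(values)[None, :]
    counts = ok.sum(axis=1)
    sums = np.where(ok, values[None, :], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)


def window_feature(
    genes: Sequence[GeneRecord],
    grid: WindowGrid,
    feature: str,
    genome: CircularGenome,
    pairs: Sequence[DivergentPair] | None = None,
) -> WindowTrack:
    """Compute one feature track over the supplied windows.

    Gene membership is by modular gene midpoint; divergent pairs are
    assigned by the midpoint of their intergenic gap. Windows with no
    qualifying members carry NaN. For ``mean_divergent_gap``, ``pairs`` may
    be precomputed (otherwise derived from the gene list, which must then be
    sorted by start).
    """
    if feature not in FEATURES:
        raise ConfigError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    starts = np.asarray(grid.starts)
    mids = grid.midpoints

    if feature == "origin_distance":
        values = circular_distance(mids, genome)
    elif feature == "coding_density":
        cov = CodingCoverage(genes, genome)
        ends = starts + grid.size_bp
        values = cov.interval_covered(starts.astype(float), np.where(ends >= grid.length_bp, ends - grid.length_bp, ends).astype(float))
        # interval_covered treats b<=a as wrapping; windows spanning the full
        # circle are excluded by make_windows (size <= L)
        values = np.asarray(values, dtype=float) / grid.size_bp
    elif feature == "mean_divergent_gap":
        if pairs is None:
            pairs = divergent_pair_gaps(genes, genome)
        if len(pairs) == 0:
            values = np.full(len(grid), np.nan)
        else:
            pm = np.array([p.midpoint_bp for p in pairs])
            gaps = np.array([p.gap_bp for p in pairs], dtype=float)
            values = _masked_mean(_membership(pm, grid), gaps)
    else:
        gmids = np.array([gene_midpoint(g, genome) for g in genes])
        member = _membership(gmids, grid) if len(genes) else np.zeros((len(grid), 0), bool)
        if feature == "mean_expression":
            expr = np.array(
                [np.nan if g.expression is None else g.expression for g in genes]
            )
            values = _masked_mean(member, expr)
        elif feature == "core_proportion":
            pc = np.array(["protein_coding" in g.categories for g in genes])
            core = np.array(["core" in g.categories for g in genes]) & pc
            values = _ratio((member & core).sum(1), (member & pc).sum(1))
        else:  # transposon_proportion
            tx = np.array(["transposon" in g.categories for g in genes])
            values = _ratio((member & tx).sum(1), member.sum(1))

    return WindowTrack(feature, grid.size_bp, starts, np.asarray(mids), np.asarray(values, dtype=float))


def feature_tracks(
    genes: Sequence[GeneRecord],
    grid: WindowGrid,
    genome: CircularGenome,
    features: Sequence[str] = FEATURES,
) -> dict[str, WindowTrack]:
    """All requested feature tracks over one window grid."""
    pairs = divergent_pair_gaps(sorted(genes, key=lambda g: g.start), genome)
    return {
        f: window_feature(genes, grid, f, genome, pairs=pairs) for f in features
    }
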