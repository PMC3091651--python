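"""End-to-end orchestration: spots to expression to tracks to statistics.

Stages: spot filtering and normalisation -> per-gene expression -> origin
distance annotation (and core labelling when a COG matrix is supplied) ->
sliding and non-overlapping window tracks -> gene-level and window-level
rank correlations -> expression-stratified core/non-core bin analysis.
Every statistical result lands in a TSV; outputs are deterministic for a
given config and inputs.
"""

from __future__ import annotations

import hashlib
import json
from contextlib import contextmanager
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .array_expression import process_spot_table
from .config import RunConfig
from .core_genome import call_core_cogs, label_core_genes
from .errors import PipelineError
from .genome_model import (
    CircularGenome,
    GeneRecord,
    circular_distance,
    gene_midpoint,
)
from .org_stats import (
    bin_confound_analysis,
    category_predicate,
    correlate_subset,
    track_correlation_matrix,
)
from .window_tracks import feature_tracks, make_windows


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc


def annotate_genes(
    genes: Sequence[GeneRecord],
    genome: CircularGenome,
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy per-gene frame: coordinates, distance, categories, expression."""
    expr_map = (
        dict(zip(expression["gene_id"], expression["expression"]))
        if expression is not None
        else {}
    )
    rows = []
    for g in genes:
        mid = gene_midpoint(g, genome)
        own = np.nan if g.expression is None else g.expression
        rows.append(
            {
                "gene_id": g.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "midpoint": mid,
                "origin_distance": circular_distance(mid, genome),
                "categories": ",".join(sorted(g.categories)),
                "is_core": "core" in g.categories,
                "cog_id": g.cog_id or "",
                "expression": expr_map.get(g.gene_id, own),
            }
        )
    return pd.DataFrame(rows)


def gene_level_correlations(
    genes: Sequence[GeneRecord],
    genome: CircularGenome,
    exclude_categories: Sequence[str] = ("txn_translation",),
) -> pd.DataFrame:
    """Expression-vs-distance Spearman on the full set and standard subsets.

    Subsets: all genes with expression; excluding transcription/translation
    genes; core only; non-core only.
    """
    dist = lambda g: gene_origin_distance_cached(g, genome)
    expr = lambda g: g.expression
    subsets = {
        "all": category_predicate(),
        "core_only": category_predicate(require=("core",)),
        "noncore_only": lambda g: "core" not in g.categories,
    }
    if exclude_categories:
        subsets["excl_" + "_".join(exclude_categories)] = category_predicate(
            exclude=exclude_categories
        )
    rows = []
    for name, pred in subsets.items():
        try:
            res = correlate_subset(genes, dist, expr, pred)
        except ValueError:
            continue
        rows.append(
            {
                "subset": name,
                "feature_a": "origin_distance",
                "feature_b": "expression",
                "rho": res.statistic,
                "p": res.p_two_sided,
                "n": res.n,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


_midpoint_cache: dict = {}


def gene_origin_distance_cached(g: GeneRecord, genome: CircularGenome) -> float:
    key = (id(genome), g.gene_id, g.start, g.end)
    if key not in _midpoint_cache:
        _midpoint_cache[key] = float(
            circular_distance(gene_midpoint(g, genome), genome)
        )
    return _midpoint_cache[key]


def proximal_distal_fold(
    annotated: pd.DataFrame, quantile: float = 0.25
) -> float:
    """Mean linear expression ratio: origin-proximal vs origin-distal genes.

    Genes with expression are split at the given distance quantiles (nearest
    quarter vs farthest quarter by default) and the difference of mean log2
    expression is returned as a linear fold.
    """
    df = annotated.dropna(subset=["expression"])
    lo = df["origin_distance"].quantile(quantile)
    hi = df["origin_distance"].quantile(1 - quantile)
    near = df.loc[df["origin_distance"] <= lo, "expression"].mean()
    far = df.loc[df["origin_distance"] >= hi, "expression"].mean()
    return float(2.0 ** (near - far))


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of everything written."""
    config.validate_paths()
    genome = config.genome()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    written: dict[str, Path] = {}

    with _stage("load_genes"):
        genes = rio.read_genes(config.genes_path)

    with _stage("core_labelling"):
        if config.cog_matrix_path is not None:
            matrix = rio.read_cog_matrix(config.cog_matrix_path)
            core = call_core_cogs(matrix, config.excluded_genomes)
            genes = label_core_genes(genes, core)

    with _stage("expression"):
        spots = rio.read_spot_table(config.spots_path, config.spot_columns)
        expr = process_spot_table(spots)
        written["expression"] = outdir / "expression.tsv"
        rio.write_expression_table(expr, written["expression"])

    with _stage("distance_annotation"):
        expr_map = dict(zip(expr["gene_id"], expr["expression"]))
        genes = [replace(g, expression=expr_map.get(g.gene_id)) for g in genes]
        annotated = annotate_genes(genes, genome, expr)
        written["genes"] = outdir / "genes_annotated.tsv"
        annotated.to_csv(written["genes"], sep="\t", index=False, float_format="%.10g")

    with _stage("tracks"):
        sliding = feature_tracks(genes, make_windows(genome, config.window), genome)
        written["tracks_tsv"] = outdir / "tracks_sliding.tsv"
        rio.write_track_tsv(sliding, written["tracks_tsv"])
        for name, tr in sliding.items():
            p = outdir / "tracks" / f"{name}.bedgraph"
            rio.write_bedgraph(tr, genome.length_bp, p)
            written[f"bedgraph_{name}"] = p

    with _stage("statistics"):
        gene_stats = gene_level_correlations(
            genes, genome, config.exclude_categories
        )
        written["gene_correlations"] = outdir / "gene_correlations.tsv"
        rio.write_stats_tsv(gene_stats, written["gene_correlations"])

        table_tracks = feature_tracks(
            genes, make_windows(genome, config.table_window), genome
        )
        window_stats = track_correlation_matrix(table_tracks)
        written["window_correlations"] = outdir / "window_correlations.tsv"
        rio.write_stats_tsv(window_stats, written["window_correlations"])

    with _stage("bin_analysis"):
        df = annotated.dropna(subset=["expression"])
        if len(df) >= config.n_bins and df["is_core"].nunique() > 1:
            report = bin_confound_analysis(
                df["expression"].to_numpy(),
                df["is_core"].to_numpy(),
                df["origin_distance"].to_numpy(),
                n_bins=config.n_bins,
                alpha=config.alpha,
            )
            written["bin_report"] = outdir / "bin_report.tsv"
            report.rows.to_csv(
                written["bin_report"], sep="\t", index=False, float_format="%.6g"
            )
            (outdir / "bin_summary.txt").write_text(report.summary() + "\n")
            written["bin_summary"] = outdir / "bin_summary.txt"

    with _stage("run_log"):
        log = {
            "config_sha256": _config_hash(config),
            "n_genes": len(genes),
            "n_genes_with_expression": int(expr.shape[0]),
            "versions": _versions(),
        }
        written["run_log"] = outdir / "run_log.json"
        written["run_log"].write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")

    return written


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()


def _versions() -> dict[str, str]:
    import scipy

    from . import __version__

    return {
        "repliorg": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }
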