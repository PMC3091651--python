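"""Readers and writers for the interchange formats.

Conventions: GFF3 is 1-based inclusive (converted to the internal 0-based
half-open coordinates on read); bedGraph is 0-based half-open, with
wrap-around windows split into two lines; gene tables, spot tables, COG
matrices and statistics are plain TSV. Wrap-around genes (spans crossing
position 0) are representable in the TSV gene table (end < start) but not
in GFF3.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from .array_expression import SPOT_COLUMNS
from .errors import ParseError
from .genome_model import CircularGenome, GeneRecord
from .window_tracks import WindowTrack

GENE_TABLE_COLUMNS = ["gene_id", "start", "end", "strand", "categories", "cog_id", "expression"]


# ---------------------------------------------------------------------------
# Gene tables


def write_gene_table(genes: Sequence[GeneRecord], path) -> None:
    """TSV gene table: 0-based half-open, categories comma-joined."""
    rows = [
        {
            "gene_id": g.gene_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "categories": ",".join(sorted(g.categories)),
            "cog_id": g.cog_id if g.cog_id is not None else "",
            "expression": "" if g.expression is None else repr(g.expression),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TABLE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: gene table lacks columns {missing}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            genes.append(
                GeneRecord(
                    gene_id=row.gene_id,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    categories=frozenset(
                        c for c in getattr(row, "categories", "").split(",") if c
                    ),
                    expression=(
                        float(row.expression)
                        if getattr(row, "expression", "") != ""
                        else None
                    ),
                    cog_id=getattr(row, "cog_id", "") or None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}, line {i}: invalid gene record ({exc})") from exc
    return genes


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(
    genes: Sequence[GeneRecord], genome: CircularGenome, path, seqid: str = "chr"
) -> None:
    """GFF3 with 1-based inclusive coordinates; wrap-around genes rejected."""
    lines = ["##gff-version 3", f"##sequence-region {seqid} 1 {genome.length_bp}"]
    for g in genes:
        if g.end <= g.start:
            raise ValueError(
                f"gene {g.gene_id} wraps across position 0; "
                "GFF3 cannot represent it — use the TSV gene table"
            )
        attrs = [f"ID={g.gene_id}"]
        if g.categories:
            attrs.append(f"categories={','.join(sorted(g.categories))}")
        if g.cog_id:
            attrs.append(f"cog_id={g.cog_id}")
        if g.expression is not None:
            attrs.append(f"expression={g.expression!r}")
        lines.append(
            "\t".join(
                [
                    seqid,
                    "repliorg",
                    "gene",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[GeneRecord]:
    """Parse gene features from GFF3 (via gffutils, in-memory)."""
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as GFF3 ({exc})") from exc
    genes = []
    for feat in db.features_of_type("gene", order_by="start"):
        if feat.strand not in ("+", "-"):
            raise ParseError(f"{path}: gene {feat.id} lacks a +/- strand")
        cats = feat.attributes.get("categories", [])  # gffutils splits on ','
        expr = feat.attributes.get("expression", [None])[0]
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                categories=frozenset(c for c in cats if c),
                expression=float(expr) if expr is not None else None,
                cog_id=feat.attributes.get("cog_id", [None])[0],
            )
        )
    return genes


def read_genes(path) -> list[GeneRecord]:
    """Dispatch on extension: .gff/.gff3 or TSV gene table."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_gff3(path)
    return read_gene_table(path)


# ---------------------------------------------------------------------------
# Spot tables


def read_spot_table(path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a GenePix-like spot TSV.

    ``columns`` optionally maps canonical names (e.g. ``fg_cdna``) to the
    dialect's column headers (e.g. ``F635 Median``). ``quality_ok`` accepts
    booleans or 0/1; a GenePix-style ``Flags`` column can be mapped with
    flag values < 0 meaning bad.
    """
    df = pd.read_csv(path, sep="\t")
    if columns:
        rename = {v: k for k, v in columns.items()}
        missing = [v for v in columns.values() if v not in df.columns]
        if missing:
            raise ParseError(f"{path}: mapped columns absent: {missing}")
        df = df.rename(columns=rename)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: spot table lacks columns {missing}")
    df = df[SPOT_COLUMNS].copy()
    if df["quality_ok"].dtype != bool:
        df["quality_ok"] = df["quality_ok"].map(
            {True: True, False: False, 1: True, 0: False, "True": True, "False": False}
        )
        if df["quality_ok"].isna().any():
            raise ParseError(f"{path}: quality_ok must be boolean or 0/1")
        df["quality_ok"] = df["quality_ok"].astype(bool)
    return df


def write_spot_table(spots: pd.DataFrame, path) -> None:
    spots[SPOT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_expression_table(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_expression_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# COG matrices


def write_cog_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="cog_id")


def read_cog_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="cog_id")
    try:
        return df.astype(int)
    except ValueError as exc:
        raise ParseError(f"{path}: COG matrix cells must be integers ({exc})") from exc


# ---------------------------------------------------------------------------
# Tracks


def write_track_tsv(tracks: Mapping[str, WindowTrack], path) -> None:
    """Wide TSV: window start/midpoint plus one column per feature."""
    first = next(iter(tracks.values()))
    df = pd.DataFrame({"start": first.starts, "midpoint": first.midpoints})
    for name, tr in tracks.items():
        if len(tr.values) != len(df):
            raise ValueError("tracks do not share one window set")
        df[name] = tr.values
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_track_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_bedgraph(
    track: WindowTrack, length_bp: int, path, seqid: str = "chr"
) -> None:
    """bedGraph (0-based half-open); wrap-around windows split in two lines."""
    lines = [f'track type=bedGraph name="{track.feature}"']
    for s, v in zip(track.starts.tolist(), track.values.tolist()):
        if not np.isfinite(v):
            continue
        e = s + track.size_bp
        if e <= length_bp:
            lines.append(f"{seqid}\t{s}\t{e}\t{v:.10g}")
        else:
            lines.append(f"{seqid}\t{s}\t{length_bp}\t{v:.10g}")
            lines.append(f"{seqid}\t0\t{e - length_bp}\t{v:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_stats_tsv(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False, float_format="%.6g")
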