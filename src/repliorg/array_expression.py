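"""Two-channel spot intensities to per-gene expression values.

Labelled cDNA is co-hybridised with genomic DNA from stationary-phase cells;
since stationary cells hold fully replicated chromosomes, every locus is at
equal copy number in the gDNA channel and the background-subtracted
cDNA/gDNA log2 ratio estimates relative transcript abundance. Spots are
quality-filtered, per-array ratios are centred to mean zero, and per-gene
values are averaged first over replicate spots and then over arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FilteredInputError

#: Canonical spot-table columns (interchange TSV order).
SPOT_COLUMNS = [
    "array_id",
    "gene_id",
    "replicate",
    "fg_cdna",
    "bg_cdna",
    "fg_gdna",
    "bg_gdna",
    "quality_ok",
]

INTENSITY_COLUMNS = ["fg_cdna", "bg_cdna", "fg_gdna", "bg_gdna"]


@dataclass(frozen=True)
class SpotRecord:
    """One printed spot on one array: two channels of fg/bg intensity."""

    array_id: str
    gene_id: str
    replicate: int
    fg_cdna: float
    bg_cdna: float
    fg_gdna: float
    bg_gdna: float
    quality_ok: bool = True


def validate_spot_table(spots: pd.DataFrame) -> None:
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise ValueError(f"spot table lacks columns: {missing}")
    if (spots[INTENSITY_COLUMNS] < 0).any().any():
        raise ValueError("negative intensities in spot table")
    key = spots[["array_id", "gene_id", "replicate"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (array, gene, replicate) key: {dup}")


def filter_spots(spots: pd.DataFrame) -> pd.DataFrame:
    """Drop low-quality spots and spots without signal above background.

    Retains spots flagged OK whose foreground exceeds background in *both*
    channels (a spot at fg == bg carries no background-subtracted signal).
    Genes losing all their spots simply vanish from downstream tables. An
    empty result is allowed.
    """
    validate_spot_table(spots)
    keep = (
        spots["quality_ok"].astype(bool)
        & (spots["fg_cdna"] > spots["bg_cdna"])
        & (spots["fg_gdna"] > spots["bg_gdna"])
    )
    return spots.loc[keep].reset_index(drop=True)


def spot_log_ratio(spot) -> float | pd.Series:
    """log2 ratio of background-subtracted cDNA over gDNA intensity.

    Accepts a :class:`SpotRecord` or a filtered spot-table DataFrame. Any
    multiplicative probe effect common to both channels (probe amount,
    hybridisation efficiency) cancels exactly in the ratio.
    """
    if isinstance(spot, SpotRecord):
        num = spot.fg_cdna - spot.bg_cdna
        den = spot.fg_gdna - spot.bg_gdna
        if num <= 0 or den <= 0:
            raise FilteredInputError(
                f"spot ({spot.array_id}, {spot.gene_id}, {spot.replicate}) "
                "has fg <= bg; it should have been filtered out"
            )
        return float(np.log2(num / den))
    num = spot["fg_cdna"] - spot["bg_cdna"]
    den = spot["fg_gdna"] - spot["bg_gdna"]
    if (num <= 0).any() or (den <= 0).any():
        raise FilteredInputError("table contains fg <= bg spots; filter first")
    return np.log2(num / den)


def normalize_array(ratios) -> np.ndarray:
    """Centre one array's log ratios to mean zero."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("cannot normalize an empty array")
    return r - r.mean()


def normalize_table(spots: pd.DataFrame, ratio_col: str = "log_ratio") -> pd.DataFrame:
    """Mean-centre log ratios within each array."""
    if spots.empty:
        return spots
    out = spots.copy()
    out[ratio_col] = out.groupby("array_id")[ratio_col].transform(lambda r: r - r.mean())
    return out


def summarize_genes(spots: pd.DataFrame, ratio_col: str = "log_ratio") -> pd.DataFrame:
    """Per-gene expression: mean over replicate spots, then mean over arrays.

    The two-stage order matters: arrays contribute equally to the gene value
    regardless of how many replicate spots survived on each. Returns a frame
    with columns gene_id, expression, n_arrays, n_spots, sorted by gene_id.
    """
    if spots.empty:
        return pd.DataFrame(columns=["gene_id", "expression", "n_arrays", "n_spots"])
    per_array = spots.groupby(["gene_id", "array_id"], sort=True)[ratio_col].mean()
    expr = per_array.groupby("gene_id").mean()
    n_arrays = per_array.groupby("gene_id").size()
    n_spots = spots.groupby("gene_id").size()
    out = pd.DataFrame(
        {
            "gene_id": expr.index,
            "expression": expr.to_numpy(),
            "n_arrays": n_arrays.reindex(expr.index).to_numpy(),
            "n_spots": n_spots.reindex(expr.index).to_numpy(),
        }
    )
    return out.sort_values("gene_id", kind="stable").reset_index(drop=True)


def process_spot_table(spots: pd.DataFrame) -> pd.DataFrame:
    """Full spot-to-expression pipeline: filter, ratio, centre, average."""
    kept = filter_spots(spots)
    if kept.empty:
        return summarize_genes(kept.assign(log_ratio=[]))
    kept = kept.assign(log_ratio=spot_log_ratio(kept))
    kept = normalize_table(kept)
    return summarize_genes(kept)
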