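"""Archaeal core-gene calling from a genome x COG copy-count matrix.

A COG (cluster of orthologous groups) belongs to the core when it is present
in *single copy* in every considered genome: absence anywhere disqualifies
it, and so does any genome carrying two or more copies (multi-copy families,
such as an acetyl-CoA acetyltransferase COG with 11 copies in one genome,
are unlikely to be uniformly essential). Obligate symbionts with reduced
genomes can be excluded from the presence requirement.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence, Set

import pandas as pd

from .genome_model import GeneRecord


def validate_cog_matrix(matrix: pd.DataFrame) -> None:
    """A COG matrix is COGs (rows) x genomes (columns) of copy counts."""
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise ValueError("COG matrix has duplicate COG or genome ids")
    if not all(pd.api.types.is_integer_dtype(t) for t in matrix.dtypes):
        raise ValueError("COG copy counts must be integers")
    if (matrix < 0).any().any():
        raise ValueError("COG copy counts must be non-negative")


def call_core_cogs(
    matrix: pd.DataFrame, excluded_genomes: Iterable[str] = ()
) -> set[str]:
    """COGs present in exactly one copy in every non-excluded genome."""
    validate_cog_matrix(matrix)
    excluded = set(excluded_genomes)
    unknown = excluded - set(matrix.columns)
    if unknown:
        raise KeyError(f"excluded genomes not in matrix: {sorted(unknown)}")
    kept = [c for c in matrix.columns if c not in excluded]
    if not kept:
        raise ValueError("all genomes excluded; core set undefined")
    single = (matrix[kept] == 1).all(axis=1)
    return set(matrix.index[single])


def label_core_genes(
    genes: Sequence[GeneRecord], core_cogs: Set[str]
) -> list[GeneRecord]:
    """Set the 'core' category on exactly the genes whose COG is core.

    Genes without a COG assignment are non-core; a pre-existing core label
    is removed when the gene's COG is not in the set.
    """
    out = []
    for g in genes:
        is_core = g.cog_id is not None and g.cog_id in core_cogs
        cats = (g.categories - {"core"}) | ({"core"} if is_core else set())
        out.append(replace(g, categories=frozenset(cats)))
    return out
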