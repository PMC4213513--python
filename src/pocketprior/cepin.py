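"""Co-expressed protein interaction network (CePIN).

A cleaned PPI edge list is weighted with the Pearson correlation of the
endpoint genes' expression across a normal-tissue panel (quantile
normalised first, so every tissue shares one expression distribution).
Edges with PCC strictly above a threshold (default 0.5) are "functionally
similar"; edges with at least one pocket-mutated endpoint are "pocket
pairs".  The module's single statistical contrast asks whether pocket
pairs are enriched among functionally similar pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment_stats import ContingencyTable2x2, fisher_exact, odds_ratio

logger = logging.getLogger(__name__)

CEPIN_COLUMNS = ["gene_a", "gene_b", "pcc", "pocket_pair", "functionally_similar"]


@dataclass(frozen=True)
class PpiCleanReport:
    n_input: int
    n_kept: int
    n_self_loops: int
    n_duplicates: int


def clean_ppi(edges: pd.DataFrame | Iterable[tuple[str, str]]) -> tuple[pd.DataFrame, PpiCleanReport]:
    """Canonicalise an undirected edge list.

    Symbols upper-cased, pairs ordered ``gene_a < gene_b``, self-loops
    removed, duplicates (in either orientation) collapsed.  Idempotent.
    """
    if not isinstance(edges, pd.DataFrame):
        edges = pd.DataFrame(list(edges), columns=["gene_a", "gene_b"])
    df = edges.copy()
    df["gene_a"] = df["gene_a"].astype(str).str.upper()
    df["gene_b"] = df["gene_b"].astype(str).str.upper()
    n_input = len(df)
    lo = np.minimum(df["gene_a"], df["gene_b"])
    hi = np.maximum(df["gene_a"], df["gene_b"])
    df["gene_a"], df["gene_b"] = lo, hi
    self_loops = df["gene_a"] == df["gene_b"]
    df = df[~self_loops]
    dup = df.duplicated(["gene_a", "gene_b"])
    df = df[~dup].reset_index(drop=True)
    report = PpiCleanReport(n_input, len(df), int(self_loops.sum()), int(dup.sum()))
    return df, report


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common mean-of-sorted distribution.

    Each column's values are replaced by the across-column mean of the
    sorted columns at the corresponding rank; tied values receive the mean
    of the reference values their ranks span.  Within-column rank order is
    preserved and the sorted vectors of all columns come out identical.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if matrix.isna().any().any():
        raise ValueError("missing values must be imputed before normalization")
    values = matrix.to_numpy(dtype=float)
    order = np.argsort(values, axis=0, kind="mergesort")
    reference = np.take_along_axis(values, order, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        assigned = np.empty(n)
        assigned[order[:, j]] = reference
        # average reference values over groups of tied input values
        col = pd.Series(assigned).groupby(values[:, j]).transform("mean")
        out[:, j] = col.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pcc needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pcc undefined for a zero-variance vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class CepinBuildReport:
    n_edges_in: int
    n_edges_out: int
    n_dropped_missing_expression: int
    n_dropped_zero_variance: int


def build_cepin(
    edges: pd.DataFrame,
    matrix: pd.DataFrame,
    pocket_genes: Iterable[str],
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, CepinBuildReport]:
    """Attach PCC, pocket and similarity flags to each cleaned PPI edge.

    Edges whose endpoints are absent from the expression matrix, or whose
    expression has zero variance, are dropped and counted.  Similarity is
    strict: ``pcc > threshold``.
    """
    pocket = {g.upper() for g in pocket_genes}
    genes_present = set(matrix.index)
    values = matrix.to_numpy(dtype=float)
    std = values.std(axis=1)
    usable = {g for g, s in zip(matrix.index, std) if s > 0}
    n_zero_var_genes = len(genes_present - usable)
    if n_zero_var_genes:
        logger.info("%d genes dropped for zero expression variance", n_zero_var_genes)

    both_present = edges["gene_a"].isin(genes_present) & edges["gene_b"].isin(genes_present)
    n_missing = int((~both_present).sum())
    kept = edges[both_present]
    both_usable = kept["gene_a"].isin(usable) & kept["gene_b"].isin(usable)
    n_zero_var = int((~both_usable).sum())
    kept = kept[both_usable].reset_index(drop=True)

    # one standardized pass over the matrix, then per-edge dot products
    mean = values.mean(axis=1, keepdims=True)
    denom = np.where(std > 0, std, 1.0)
    z = (values - mean) / denom[:, None]
    row_of = {g: i for i, g in enumerate(matrix.index)}
    ia = kept["gene_a"].map(row_of).to_numpy()
    ib = kept["gene_b"].map(row_of).to_numpy()
    pccs = (z[ia] * z[ib]).mean(axis=1) if len(kept) else np.array([])

    out = pd.DataFrame(
        {
            "gene_a": kept["gene_a"],
            "gene_b": kept["gene_b"],
            "pcc": pccs,
            "pocket_pair": kept["gene_a"].isin(pocket) | kept["gene_b"].isin(pocket),
            "functionally_similar": pccs > threshold,
        }
    )
    report = CepinBuildReport(len(edges), len(out), n_missing, n_zero_var)
    return out, report


def pocket_pair_enrichment(cepin: pd.DataFrame) -> tuple[ContingencyTable2x2, float, float]:
    """Fisher contrast: pocket pairs vs the rest, similar vs not (one-sided greater)."""
    pocket = cepin["pocket_pair"]
    similar = cepin["functionally_similar"]
    table = ContingencyTable2x2(
        int((pocket & similar).sum()),
        int((pocket & ~similar).sum()),
        int((~pocket & similar).sum()),
        int((~pocket & ~similar).sum()),
    )
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("need at least one pocket pair and one non-pocket pair")
    if table.a + table.c == 0 or table.b + table.d == 0:
        logger.warning("degenerate similarity margin; enrichment test uninformative")
        return table, 1.0, odds_ratio(table)
    p, orat = fisher_exact(table, alternative="greater")
    return table, p, orat


# ---------------------------------------------------------------------------
# I/O


def read_ppi_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"gene_a", "gene_b"} - set(df.columns)
    if missing:
        raise ValueError(f"PPI edge list missing columns {sorted(missing)}")
    return df


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes in rows (first column), tissue labels as the remaining header."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str).str.upper()
    return df


def write_cepin(cepin: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cepin.to_csv(fh, sep="\t", index=False)
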