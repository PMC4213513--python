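"""The statistical core: pocket-enrichment screen and gene-set enrichment.

For each protein with pocket missense occurrences a 2x2 table contrasts its
pocket vs non-pocket missense counts against the pooled counts of every
other mapped protein (the "background").  The one-sided (greater) Fisher
exact test asks whether the protein's mutations concentrate in its pocket
region beyond the background rate; Benjamini-Hochberg adjustment across the
per-scope family of tests controls the false discovery rate (default
threshold 0.1).

The Fisher p-value is computed here by exact hypergeometric enumeration in
log space (no external statistical routine stands behind it); the BH step
delegates to statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import lgamma
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .mutation_mapping import MappedMutationSet

logger = logging.getLogger(__name__)

PAN_CANCER = "pan-cancer"

#: Relative tolerance for counting a table as "at least as extreme" in the
#: two-sided test (same convention as R's fisher.test).
_TWO_SIDED_EPS = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): target pocket/non-pocket vs background pocket/non-pocket."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", frozenset(m.upper() for m in self.members))


def _lchoose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def odds_ratio(table: ContingencyTable2x2) -> float:
    """Sample cross-product ratio, Haldane +0.5 in every cell when any cell is 0.

    Reported descriptively alongside the exact p-value; inference never
    uses it.
    """
    a, b, c, d = table.as_tuple()
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def fisher_exact(
    table: ContingencyTable2x2 | tuple[int, int, int, int],
    alternative: str = "greater",
) -> tuple[float, float]:
    """Exact Fisher test on a 2x2 table; returns ``(p_value, odds_ratio)``.

    With row/column margins fixed, cell ``a`` follows a hypergeometric law;
    'greater' sums P(X >= a), 'two-sided' sums the probabilities of all
    tables no more likely than the observed one (R convention, relative
    tolerance 1e-7).  All mass terms are evaluated through log-factorials,
    so arbitrarily large cells cannot overflow.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unsupported alternative {alternative!r}")
    a, b, c, d = table.as_tuple()
    n_total, row1, col1 = a + b + c + d, a + b, a + c
    lo = max(0, col1 - (n_total - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    log_denom = _lchoose(n_total, col1)
    log_pmf = np.array(
        [_lchoose(row1, x) + _lchoose(n_total - row1, col1 - x) - log_denom for x in support]
    )
    pmf = np.exp(log_pmf)
    if alternative == "greater":
        p = float(pmf[support >= a].sum())
    else:
        cutoff = log_pmf[support == a][0] + _TWO_SIDED_EPS
        p = float(pmf[log_pmf <= cutoff].sum())
    return min(1.0, max(0.0, p)), odds_ratio(table)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Per-gene screen


def _missense_counts(mset: MappedMutationSet, scope: str | None) -> pd.DataFrame:
    """Pocket / non-pocket missense occurrence counts per accession in scope."""
    rec = mset.records
    rec = rec[rec["mclass"] == "missense"]
    if scope is not None and scope != PAN_CANCER:
        rec = rec[rec["cancer_type"] == scope.lower()]
    counts = rec.groupby(["uniprot_acc", "in_pocket"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=[True, False], fill_value=0)
    counts.columns = ["pocket", "non_pocket"]
    return counts


def build_contingency(
    accession: str, mset: MappedMutationSet, scope: str | None = None
) -> ContingencyTable2x2:
    """2x2 missense table for one protein against the pooled background.

    The target protein is excluded from the background row so the four
    cells are disjoint.
    """
    counts = _missense_counts(mset, scope)
    if accession not in counts.index:
        raise KeyError(f"no missense occurrences for {accession!r} in scope {scope or PAN_CANCER!r}")
    a, b = int(counts.loc[accession, "pocket"]), int(counts.loc[accession, "non_pocket"])
    others = counts.drop(index=accession)
    return ContingencyTable2x2(a, b, int(others["pocket"].sum()), int(others["non_pocket"].sum()))


def run_per_gene_screen(
    mset: MappedMutationSet,
    scope: str | None = None,
    fdr_threshold: float = 0.1,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher screen over every protein with >= 1 pocket missense in scope.

    BH adjustment runs across exactly this family of tests; ``significant``
    marks ``fdr < fdr_threshold``.  Returns a table sorted by p-value with
    columns ``gene accession scope a b c d odds_ratio p fdr significant``.
    """
    scope_label = scope or PAN_CANCER
    counts = _missense_counts(mset, scope)
    tested = counts[counts["pocket"] > 0]
    cols = ["gene", "accession", "scope", "a", "b", "c", "d", "odds_ratio", "p", "fdr", "significant"]
    if tested.empty:
        logger.warning("scope %r has no pocket missense occurrences", scope_label)
        return pd.DataFrame(columns=cols)
    gene_of = (
        mset.records.drop_duplicates("uniprot_acc").set_index("uniprot_acc")["gene"].to_dict()
    )
    total_pocket = int(counts["pocket"].sum())
    total_non = int(counts["non_pocket"].sum())
    rows = []
    for acc, row in tested.iterrows():
        a, b = int(row["pocket"]), int(row["non_pocket"])
        table = ContingencyTable2x2(a, b, total_pocket - a, total_non - b)
        p, orat = fisher_exact(table, alternative=alternative)
        rows.append((gene_of.get(acc, acc), acc, scope_label, *table.as_tuple(), orat, p))
    out = pd.DataFrame(rows, columns=cols[:-2])
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values(["p", "accession"], kind="mergesort").reset_index(drop=True)


def select_top_cancer_types(mset: MappedMutationSet, k: int = 10) -> list[str]:
    """Cancer types ranked by pocket-mutation occurrence count (ties lexicographic)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = mset.pocket_records().groupby("cancer_type").size()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [t for t, _ in ranked[:k]]


def gene_set_enrichment(
    pocket_genes: Iterable[str],
    background_genes: Iterable[str],
    gene_set: GeneSet,
) -> tuple[ContingencyTable2x2, float, float]:
    """Is the gene set over-represented among pocket-mutated genes?

    Rows: {pocket genes, background genes}; columns: {in set, not in set};
    one-sided greater Fisher test.
    """
    pocket = {g.upper() for g in pocket_genes}
    background = {g.upper() for g in background_genes}
    if not pocket or not background:
        raise ValueError("pocket and background gene groups must be non-empty")
    if pocket & background:
        raise ValueError("pocket and background gene groups must be disjoint")
    table = ContingencyTable2x2(
        len(pocket & gene_set.members),
        len(pocket - gene_set.members),
        len(background & gene_set.members),
        len(background - gene_set.members),
    )
    p, orat = fisher_exact(table, alternative="greater")
    return table, p, orat


# ---------------------------------------------------------------------------
# I/O


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: one set per line — name, description, then member symbols."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:50]!r}")
        sets.append(GeneSet(fields[0], frozenset(fields[2:])))
    return sets


def write_screen_results(results: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        results.to_csv(fh, sep="\t", index=False)
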