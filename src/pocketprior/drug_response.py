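"""Drug-response stratification by pocket-mutation status.

Cancer cell lines are split into mutant and wild-type groups for one gene,
either by any mutation in the gene (``all_mutations``) or by mutations
mapped to the gene's pocket residues only (``pocket_only``), and the two
groups' ln(IC50) distributions for one drug are compared with the Wilcoxon
rank-sum test.  In ``pocket_only`` mode, lines carrying only non-pocket
mutations stay in the wild-type group by default (the split is a
partition); pass ``exclude_nonpocket_mutants=True`` to drop them instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .mutation_mapping import map_mutations
from .pocket_annotation import PocketAnnotationSet

logger = logging.getLogger(__name__)

MODES = ("all_mutations", "pocket_only")

#: Largest combined sample size for which the exact tie-free rank-sum
#: distribution is used; beyond it (or with ties) the normal approximation
#: with tie and continuity corrections applies.
EXACT_N_MAX = 20


@dataclass(frozen=True)
class StratifiedComparison:
    """Outcome of one gene x drug ln(IC50) group comparison."""

    gene: str
    drug: str
    mode: str
    n_mutant: int
    n_wildtype: int
    median_mutant: float | None
    median_wildtype: float | None
    p_value: float | None
    direction: str  # sensitive | resistant | none
    testable: bool


def read_pharmacology(path: str | Path, raw_ic50: bool = False) -> pd.DataFrame:
    """Read a drug x cell-line table; IC50 is ln-transformed at load.

    Columns ``cell_line drug`` plus either ``ln_ic50`` or (with
    ``raw_ic50=True``) ``ic50``.  Duplicate (cell_line, drug) rows are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"cell_line": str, "drug": str})
    if raw_ic50:
        if "ic50" not in df.columns:
            raise ValueError("raw_ic50=True requires an 'ic50' column")
        if (df["ic50"] <= 0).any():
            raise ValueError("raw IC50 values must be positive")
        df["ln_ic50"] = np.log(df["ic50"].astype(float))
    if "ln_ic50" not in df.columns:
        raise ValueError("pharmacology table needs an 'ln_ic50' column (or ic50 with raw_ic50=True)")
    if not np.isfinite(df["ln_ic50"]).all():
        raise ValueError("ln_ic50 values must be finite")
    if df.duplicated(["cell_line", "drug"]).any():
        raise ValueError("duplicate (cell_line, drug) pharmacology rows")
    return df[["cell_line", "drug", "ln_ic50"]]


def stratify(
    gene: str,
    profiles: pd.DataFrame,
    pockets: PocketAnnotationSet,
    mode: str = "pocket_only",
    universe: Iterable[str] | None = None,
    exclude_nonpocket_mutants: bool = False,
) -> tuple[frozenset[str], frozenset[str]]:
    """Split cell lines into (mutant, wild-type) for one gene.

    ``profiles`` is a mutation-catalog DataFrame whose ``sample_id`` is the
    cell-line id.  ``universe`` defaults to every line in ``profiles``; the
    returned groups partition it (unless non-pocket mutants are excluded).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    gene = gene.upper()
    lines = frozenset(universe) if universe is not None else frozenset(profiles["sample_id"])
    gene_rows = profiles[profiles["gene"].str.upper() == gene]
    any_mutant = frozenset(gene_rows["sample_id"]) & lines
    if mode == "all_mutations":
        mutant = any_mutant
        wildtype = lines - mutant
    else:
        accs = set(gene_rows["uniprot_acc"].unique())
        if not (accs & pockets.proteins):
            raise ValueError(f"gene {gene} has no pocket annotation; pocket_only mode undefined")
        mapped = map_mutations(gene_rows, pockets)
        mutant = frozenset(mapped.pocket_records()["sample_id"]) & lines
        wildtype = lines - mutant
        if exclude_nonpocket_mutants:
            wildtype = wildtype - any_mutant
    if not mutant:
        raise ValueError(f"no {mode} mutant cell line for gene {gene}")
    return mutant, frozenset(wildtype)


def wilcoxon_rank_sum(
    x: Iterable[float], y: Iterable[float], alternative: str = "two-sided"
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution for tie-free samples with combined n <= 20;
    otherwise the normal approximation with tie correction and continuity
    correction.  Two identical constant samples give p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= EXACT_N_MAX and not has_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


def compare_response(
    gene: str,
    drug: str,
    profiles: pd.DataFrame,
    pharmacology: pd.DataFrame,
    pockets: PocketAnnotationSet,
    mode: str = "pocket_only",
    alternative: str = "two-sided",
    alpha: float = 0.05,
    exclude_nonpocket_mutants: bool = False,
) -> StratifiedComparison:
    """Stratify on ``gene`` and compare ln(IC50) of ``drug`` between groups.

    The stratification universe is the set of lines with pharmacology for
    the drug.  Groups smaller than 2 make the comparison untestable (no
    p-value reported).  Direction is descriptive: 'sensitive' when the
    mutant median is lower and p < alpha, 'resistant' when higher.
    """
    drug_rows = pharmacology[pharmacology["drug"] == drug]
    if drug_rows.empty:
        raise ValueError(f"no pharmacology for drug {drug!r}")
    ic50 = drug_rows.set_index("cell_line")["ln_ic50"]
    mutant, wildtype = stratify(
        gene, profiles, pockets, mode=mode, universe=ic50.index,
        exclude_nonpocket_mutants=exclude_nonpocket_mutants,
    )
    x = ic50.loc[sorted(mutant)].to_numpy()
    y = ic50.loc[sorted(wildtype)].to_numpy()
    if x.size < 2 or y.size < 2:
        logger.warning("gene %s drug %s: group sizes %d/%d too small to test", gene, drug, x.size, y.size)
        return StratifiedComparison(gene.upper(), drug, mode, x.size, y.size,
                                    None, None, None, "none", False)
    p = wilcoxon_rank_sum(x, y, alternative=alternative)
    med_x, med_y = float(np.median(x)), float(np.median(y))
    direction = "none"
    if p < alpha:
        if med_x < med_y:
            direction = "sensitive"
        elif med_x > med_y:
            direction = "resistant"
    return StratifiedComparison(gene.upper(), drug, mode, x.size, y.size, med_x, med_y, p, direction, True)


def comparison_table(comparisons: Iterable[StratifiedComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])
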