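"""Map a protein-level somatic mutation catalog onto pocket residues.

A mutation occurrence lands "in pocket" when an annotated pocket residue of
the same protein matches both its UniProt position and its wild-type
residue.  A residue shared by several pockets contributes a single mapped
occurrence carrying every matching pocket id (no multi-pocket double
counting).  Mutations on proteins without any pocket annotation are outside
the analysis universe: they can contribute neither pocket nor comparable
non-pocket counts at the structure level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._aa import AA_ORDER, STANDARD_AA
from .pocket_annotation import PocketAnnotationSet

logger = logging.getLogger(__name__)

MCLASSES = ("missense", "silent", "nonsense", "indel", "complex")

CATALOG_COLUMNS = ["sample_id", "cancer_type", "gene", "uniprot_acc", "wt", "pos", "alt", "indel_flag"]
MAPPED_COLUMNS = CATALOG_COLUMNS + ["mclass", "in_pocket", "pocket_ids"]


def derive_mutation_class(wt_residue: str, alt_residue: str, indel_flag: bool = False) -> str:
    """Classify one protein-level change.

    indel flag wins; then stop gain ('*'), identity (silent), standard
    substitution (missense); anything else is 'complex'.
    """
    if wt_residue not in STANDARD_AA:
        raise ValueError(f"invalid wild-type residue {wt_residue!r}")
    if indel_flag:
        return "indel"
    if alt_residue == "*":
        return "nonsense"
    if alt_residue == wt_residue:
        return "silent"
    if alt_residue in STANDARD_AA:
        return "missense"
    return "complex"


def _derive_classes(df: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [derive_mutation_class(w, a, f) for w, a, f in zip(df["wt"], df["alt"], df["indel_flag"])],
        index=df.index,
        dtype=object,
    )


def read_mutation_catalog(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like protein-level catalog TSV.

    Columns: ``sample_id cancer_type gene uniprot_acc wt pos alt indel_flag``.
    Cancer-type labels are normalised to lower case, gene symbols to upper
    case; the mutation class is derived, not trusted from the file.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"sample_id": str, "cancer_type": str, "gene": str, "uniprot_acc": str, "wt": str, "alt": str},
    )
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation catalog missing columns {sorted(missing)}")
    df = df[CATALOG_COLUMNS].copy()
    df["cancer_type"] = df["cancer_type"].str.lower()
    df["gene"] = df["gene"].str.upper()
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        raise ValueError("UniProt positions are 1-based; found pos < 1")
    df["indel_flag"] = df["indel_flag"].astype(bool)
    df["mclass"] = _derive_classes(df)
    return df


def collapse_unique_variants(catalog: pd.DataFrame) -> pd.DataFrame:
    """Collapse recurrent occurrences onto unique (accession, wt, pos, alt) variants.

    Statistics default to per-occurrence counting (one row per sample
    carrying the variant); this collapse supports catalog-style summaries.
    """
    return catalog.drop_duplicates(["uniprot_acc", "wt", "pos", "alt"]).reset_index(drop=True)


@dataclass
class MappedMutationSet:
    """Mutation catalog partitioned into pocket / non-pocket occurrences.

    ``records`` carries the catalog columns plus ``mclass``, ``in_pocket``
    and ``pocket_ids`` (';'-joined sorted pocket ids, empty when outside
    every pocket).  Each input occurrence appears exactly once.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MAPPED_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"mapped mutation table missing columns {sorted(missing)}")
        self.records = self.records[MAPPED_COLUMNS].reset_index(drop=True)
        self.records = self.records.astype(
            {"in_pocket": bool, "indel_flag": bool, "pos": int, "pocket_ids": str}
        )
        bad = self.records["in_pocket"] != (self.records["pocket_ids"] != "")
        if bad.any():
            raise ValueError("in_pocket flag inconsistent with pocket_ids")

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.records["uniprot_acc"].unique())

    def pocket_records(self) -> pd.DataFrame:
        return self.records[self.records["in_pocket"]]

    def counts(self) -> pd.Series:
        """Occurrence counts per (protein, cancer_type, mclass, in_pocket)."""
        return self.records.groupby(["uniprot_acc", "cancer_type", "mclass", "in_pocket"]).size()

    def __len__(self) -> int:
        return len(self.records)


def map_mutations(mutations: pd.DataFrame, pockets: PocketAnnotationSet) -> MappedMutationSet:
    """Map catalog occurrences onto pocket residues.

    An occurrence is in-pocket iff some pocket residue matches its
    (accession, position) and the annotated residue equals the mutation's
    wild-type residue; a wild-type mismatch at a pocket position stays
    non-pocket (and is logged).  Occurrences on proteins absent from the
    pocket annotation are excluded from the returned set.
    """
    df = mutations.copy()
    if "mclass" not in df.columns:
        df["mclass"] = _derive_classes(df)
    df = df[df["uniprot_acc"].isin(pockets.proteins)].reset_index(drop=True)
    if df.empty:
        return MappedMutationSet(pd.DataFrame(columns=MAPPED_COLUMNS))

    pk = pockets.residues.drop_duplicates(["uniprot_acc", "pocket_id", "position"])
    merged = (
        df[["uniprot_acc", "pos", "wt"]]
        .reset_index()
        .merge(
            pk,
            left_on=["uniprot_acc", "pos", "wt"],
            right_on=["uniprot_acc", "position", "residue"],
            how="inner",
        )
    )
    ids = merged.groupby("index")["pocket_id"].agg(lambda s: ";".join(sorted(set(s))))
    df["pocket_ids"] = df.index.map(ids).fillna("")
    df["in_pocket"] = df["pocket_ids"] != ""

    # wild-type mismatches at annotated positions are worth a log line
    pos_only = (
        df.loc[~df["in_pocket"], ["uniprot_acc", "pos"]]
        .merge(pk, left_on=["uniprot_acc", "pos"], right_on=["uniprot_acc", "position"])
    )
    if len(pos_only):
        logger.info(
            "%d non-pocket occurrences sit at annotated positions with a wild-type mismatch",
            pos_only.shape[0],
        )
    return MappedMutationSet(df)


def summarize_by_class(mset: MappedMutationSet) -> pd.DataFrame:
    """Pocket-occurrence counts and percentages per mutation class (Fig-1B style)."""
    pocket = mset.pocket_records()
    if pocket.empty:
        return pd.DataFrame(columns=["mclass", "count", "percent"])
    counts = pocket.groupby("mclass").size().sort_values(ascending=False)
    out = counts.rename("count").reset_index()
    out["percent"] = 100.0 * out["count"] / out["count"].sum()
    return out


def per_protein_averages(mset: MappedMutationSet) -> tuple[float, float]:
    """(mean pocket mutations, mean pocket missense) per pocket-mutated protein.

    Both means use the count of proteins carrying at least one pocket
    mutation as denominator and are reported to 1 decimal.
    """
    pocket = mset.pocket_records()
    n_proteins = pocket["uniprot_acc"].nunique()
    if n_proteins == 0:
        raise ValueError("no protein has a pocket mutation")
    mean_all = len(pocket) / n_proteins
    mean_missense = int((pocket["mclass"] == "missense").sum()) / n_proteins
    return round(mean_all, 1), round(mean_missense, 1)


def top_genes_by_pocket_missense(mset: MappedMutationSet, k: int) -> list[tuple[str, int]]:
    """Top-k genes by pocket missense occurrences; ties break lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pocket = mset.pocket_records()
    counts = pocket[pocket["mclass"] == "missense"].groupby("gene").size()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(g, int(c)) for g, c in ranked[:k]]


def amino_acid_spectrum(mset: MappedMutationSet, group_by: str = "cancer_type") -> pd.DataFrame:
    """Wild-type amino acid x group counts of pocket missense occurrences.

    Always returns all 20 amino-acid rows; column sums equal per-group
    pocket missense totals.
    """
    if group_by not in ("cancer_type", "gene"):
        raise ValueError("group_by must be 'cancer_type' or 'gene'")
    pocket = mset.pocket_records()
    missense = pocket[pocket["mclass"] == "missense"]
    if missense.empty:
        return pd.DataFrame(index=list(AA_ORDER), dtype=np.int64)
    mat = (
        missense.groupby(["wt", group_by]).size().unstack(fill_value=0)
        .reindex(list(AA_ORDER), fill_value=0)
    )
    return mat.astype(np.int64)


def write_mapped_set(mset: MappedMutationSet, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        mset.records.to_csv(fh, sep="\t", index=False)


def read_mapped_set(path: str | Path) -> MappedMutationSet:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"sample_id": str, "cancer_type": str, "gene": str, "uniprot_acc": str,
               "wt": str, "alt": str, "mclass": str, "pocket_ids": str},
    )
    df["pocket_ids"] = df["pocket_ids"].fillna("")
    df["indel_flag"] = df["indel_flag"].astype(bool)
    df["in_pocket"] = df["in_pocket"].astype(bool)
    return MappedMutationSet(df)
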