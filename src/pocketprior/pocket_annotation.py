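"""Ligand-binding pocket annotation: PKT parsing, SIFTS translation, filtering.

Pocket annotations arrive as ``PKT`` record blocks embedded in otherwise
ordinary PDB-format files (the output convention of an LPC-style pocket
detector).  A block opens with a header line ::

    PKT  <pocket_index>  <n_residues>  <ligand_tag>

followed by exactly ``n_residues`` residue stub lines ::

    PKT  RES <res_name> <chain> <res_seq>[<icode>]

Residue numbers on PKT lines are author (PDB) numbering; they are
translated to 1-based UniProt sequence positions through a SIFTS-style
residue-level mapping table, then filtered to an allowed-protein list
(human proteins, minus a configurable exclusion list that defaults to
titin, Q8WZ42).  All downstream modules work exclusively in UniProt
coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._aa import AA_3TO1

logger = logging.getLogger(__name__)

#: Accessions removed from every analysis unless overridden (titin: its
#: extreme length makes it a perennial false positive in mutation counts).
DEFAULT_EXCLUDED: frozenset[str] = frozenset({"Q8WZ42"})

SIFTS_COLUMNS = ["pdb_id", "chain", "res_seq", "icode", "uniprot_acc", "uniprot_pos", "uniprot_res"]
POCKET_COLUMNS = ["uniprot_acc", "pocket_id", "residue", "position"]

_RES_SEQ_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


class PktFormatError(ValueError):
    """A PKT block is malformed; the whole file is rejected."""


@dataclass(frozen=True)
class PdbPocketResidue:
    """One pocket-member residue in PDB (author) coordinates."""

    structure_id: str
    chain_id: str
    pocket_index: int
    residue_name: str
    residue_seq: int
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.residue_name not in AA_3TO1:
            raise PktFormatError(f"non-standard residue name {self.residue_name!r}")
        if self.pocket_index < 1:
            raise PktFormatError(f"pocket_index must be >= 1, got {self.pocket_index}")


@dataclass(frozen=True)
class TranslationReport:
    """Accounting of residues lost during PDB -> UniProt translation."""

    n_input: int
    n_translated: int
    unmapped: int
    mismatched: int

    def __post_init__(self) -> None:
        assert self.n_input == self.n_translated + self.unmapped + self.mismatched


@dataclass
class PocketAnnotationSet:
    """Pocket residues in UniProt coordinates.

    ``residues`` has columns ``uniprot_acc, pocket_id, residue, position``
    with ``pocket_id = "<structure_id>:<pocket_index>"`` and 1-based
    positions.  A residue shared by two pockets appears once per pocket.
    """

    residues: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=POCKET_COLUMNS))

    def __post_init__(self) -> None:
        missing = set(POCKET_COLUMNS) - set(self.residues.columns)
        if missing:
            raise ValueError(f"pocket residue table missing columns {sorted(missing)}")
        self.residues = self.residues[POCKET_COLUMNS].reset_index(drop=True)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.residues["uniprot_acc"].unique())

    def __len__(self) -> int:
        return len(self.residues)


def _parse_pkt_residue_line(tokens: list[str], lineno: int) -> tuple[str, str, int, str]:
    if len(tokens) != 5 or tokens[1] != "RES":
        raise PktFormatError(f"line {lineno}: malformed PKT residue line")
    res_name, chain, seq_token = tokens[2], tokens[3], tokens[4]
    if res_name not in AA_3TO1:
        raise PktFormatError(f"line {lineno}: non-standard residue name {res_name!r}")
    if len(chain) != 1:
        raise PktFormatError(f"line {lineno}: chain id must be a single character, got {chain!r}")
    m = _RES_SEQ_RE.match(seq_token)
    if m is None:
        raise PktFormatError(f"line {lineno}: non-integer residue number {seq_token!r}")
    return res_name, chain, int(m.group(1)), m.group(2)


def parse_pkt_records(pdb_text: str, structure_id: str | None = None) -> list[PdbPocketResidue]:
    """Parse all PKT blocks out of one PDB-format file.

    Non-PKT records are ignored.  The structure id is taken from the
    ``HEADER`` record (columns 63-66) when present, else from
    ``structure_id``.  Any malformed PKT line rejects the whole file with
    a :class:`PktFormatError` naming the offending line.
    """
    residues: list[PdbPocketResidue] = []
    current: tuple[int, int] | None = None  # (pocket_index, declared n_residues)
    n_seen = 0

    def _close_block(lineno: int) -> None:
        nonlocal current, n_seen
        if current is not None and n_seen != current[1]:
            raise PktFormatError(
                f"line {lineno}: pocket {current[0]} declared {current[1]} residues, found {n_seen}"
            )
        current, n_seen = None, 0

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        tokens = line.split()
        if line[:6].strip() == "HEADER" and structure_id is None:
            structure_id = line[62:66].strip() or tokens[-1]
            continue
        if not tokens or tokens[0] != "PKT":
            continue
        if len(tokens) >= 2 and tokens[1] == "RES":
            if current is None:
                raise PktFormatError(f"line {lineno}: PKT residue line outside a PKT block")
            if structure_id is None:
                raise PktFormatError("structure id unknown: no HEADER record and none supplied")
            res_name, chain, res_seq, icode = _parse_pkt_residue_line(tokens, lineno)
            residues.append(
                PdbPocketResidue(structure_id, chain, current[0], res_name, res_seq, icode)
            )
            n_seen += 1
        else:
            _close_block(lineno)
            if len(tokens) != 4:
                raise PktFormatError(f"line {lineno}: malformed PKT header line")
            try:
                pocket_index, n_res = int(tokens[1]), int(tokens[2])
            except ValueError as exc:
                raise PktFormatError(f"line {lineno}: non-integer PKT header field") from exc
            if pocket_index < 1 or n_res < 1:
                raise PktFormatError(f"line {lineno}: PKT header fields must be positive")
            current = (pocket_index, n_res)
    _close_block(lineno=len(pdb_text.splitlines()) + 1)
    return residues


def _validate_mapping(mapping: pd.DataFrame) -> pd.DataFrame:
    missing = set(SIFTS_COLUMNS) - set(mapping.columns)
    if missing:
        raise ValueError(f"mapping table missing columns {sorted(missing)}")
    mapping = mapping.copy()
    mapping["icode"] = mapping["icode"].fillna("").astype(str).str.strip()
    key = ["pdb_id", "chain", "res_seq", "icode"]
    if mapping.duplicated(key).any():
        dup = mapping[mapping.duplicated(key, keep=False)].iloc[0]
        raise ValueError(f"mapping table has duplicate key {tuple(dup[key])}")
    # Chimeric chains (one chain -> several accessions) are rejected as
    # malformed: single-chain, single-protein structures are assumed.
    per_chain = mapping.groupby(["pdb_id", "chain"])["uniprot_acc"].nunique()
    if (per_chain > 1).any():
        bad = per_chain[per_chain > 1].index[0]
        raise ValueError(f"chain {bad} maps to multiple UniProt accessions (chimeric chain)")
    return mapping


def translate_to_uniprot(
    pdb_residues: Sequence[PdbPocketResidue], mapping: pd.DataFrame
) -> tuple[pd.DataFrame, TranslationReport]:
    """Translate PKT residues to UniProt coordinates via a SIFTS-style table.

    Residues with no mapping row are dropped and counted as ``unmapped``;
    residues whose 1-letter translation disagrees with the mapping's
    ``uniprot_res`` are dropped and counted as ``mismatched``.  Lossy
    mapping is expected behaviour (real SIFTS coverage is incomplete), so
    losses are reported, not raised.
    """
    mapping = _validate_mapping(mapping)
    lut = {
        (r.pdb_id, r.chain, int(r.res_seq), r.icode): (r.uniprot_acc, int(r.uniprot_pos), r.uniprot_res)
        for r in mapping.itertuples(index=False)
    }
    rows: list[tuple[str, str, str, int]] = []
    unmapped = mismatched = 0
    for res in pdb_residues:
        hit = lut.get((res.structure_id, res.chain_id, res.residue_seq, res.insertion_code))
        if hit is None:
            unmapped += 1
            continue
        acc, pos, uni_res = hit
        one = AA_3TO1[res.residue_name]
        if one != uni_res:
            mismatched += 1
            logger.debug(
                "residue identity mismatch at %s:%s %s%d%s (PKT %s vs mapping %s)",
                res.structure_id, res.chain_id, res.residue_name, res.residue_seq,
                res.insertion_code, one, uni_res,
            )
            continue
        rows.append((acc, f"{res.structure_id}:{res.pocket_index}", one, pos))
    out = pd.DataFrame(rows, columns=POCKET_COLUMNS)
    report = TranslationReport(len(pdb_residues), len(out), unmapped, mismatched)
    if report.unmapped or report.mismatched:
        logger.info(
            "translated %d/%d pocket residues (%d unmapped, %d mismatched)",
            report.n_translated, report.n_input, report.unmapped, report.mismatched,
        )
    return out, report


def filter_proteins(
    annotations: PocketAnnotationSet,
    allowed: Iterable[str] | None = None,
    excluded: Iterable[str] = DEFAULT_EXCLUDED,
) -> PocketAnnotationSet:
    """Keep residues of accessions in ``allowed`` and not in ``excluded``.

    ``allowed=None`` means "all accessions present".  Idempotent.  An empty
    result warns rather than fails.
    """
    residues = annotations.residues
    keep = ~residues["uniprot_acc"].isin(set(excluded))
    if allowed is not None:
        keep &= residues["uniprot_acc"].isin(set(allowed))
    out = PocketAnnotationSet(residues[keep])
    if len(annotations) and not len(out):
        logger.warning("protein filter removed every pocket residue")
    return out


# ---------------------------------------------------------------------------
# I/O


def read_sifts_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"pdb_id": str, "chain": str, "icode": str})
    return _validate_mapping(df)


def read_accession_list(path: str | Path) -> frozenset[str]:
    """One accession per line; blank lines and '#' comments ignored."""
    accs = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            accs.add(line)
    return frozenset(accs)


def read_pocket_table(path: str | Path) -> PocketAnnotationSet:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"uniprot_acc": str, "pocket_id": str, "residue": str})
    return PocketAnnotationSet(df)


def write_pocket_table(annotations: PocketAnnotationSet, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        annotations.residues.to_csv(fh, sep="\t", index=False)


def load_pocket_annotations(
    pdb_dir: str | Path,
    sifts_path: str | Path,
    allowed: Iterable[str] | None = None,
    excluded: Iterable[str] = DEFAULT_EXCLUDED,
) -> tuple[PocketAnnotationSet, TranslationReport]:
    """Parse every ``*.pdb`` under ``pdb_dir`` and run the full annotation chain."""
    mapping = read_sifts_table(sifts_path)
    residues: list[PdbPocketResidue] = []
    for pdb_path in sorted(Path(pdb_dir).glob("*.pdb")):
        residues.extend(parse_pkt_records(pdb_path.read_text()))
    table, report = translate_to_uniprot(residues, mapping)
    annotations = filter_proteins(PocketAnnotationSet(table), allowed=allowed, excluded=excluded)
    return annotations, report
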