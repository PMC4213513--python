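import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pocketprior.mutation_mapping import MAPPED_COLUMNS, MappedMutationSet
from pocketprior.pocket_annotation import POCKET_COLUMNS, PocketAnnotationSet

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


PDB_TWO_POCKETS = """\
HEADER    SYNTHETIC POCKET LIBRARY                01-JAN-14   1ABC
REMARK 100 HAND-BUILT PARSER FIXTURE
ATOM      1  CA  ALA A  42      11.104  13.207   2.100  1.00  0.00           C
PKT     1    3  GTP
PKT  RES ALA A 42
PKT  RES GLY A 12
PKT  RES GLN A 61
PKT     2    4  LIG
PKT  RES ALA A 42
PKT  RES ARG A 7
PKT  RES GLU A 17
PKT  RES LEU A 99
END
"""


@pytest.fixture
def pdb_two_pockets() -> str:
    """Hand-built PDB text: two PKT blocks (3 + 4 residues), ALA 42 in both."""
    return PDB_TWO_POCKETS


@pytest.fixture
def sifts_table() -> pd.DataFrame:
    """Mapping for 1ABC chain A: identity positions, GLN 61 left unmapped and
    GLU 17 given a deliberately mismatching UniProt residue."""
    rows = [
        ("1ABC", "A", 42, "", "P01112", 42, "A"),
        ("1ABC", "A", 12, "", "P01112", 12, "G"),
        ("1ABC", "A", 7, "", "P01112", 7, "R"),
        ("1ABC", "A", 17, "", "P01112", 17, "K"),  # PKT says GLU -> mismatch
        ("1ABC", "A", 99, "", "P01112", 99, "L"),
    ]
    return pd.DataFrame(
        rows, columns=["pdb_id", "chain", "res_seq", "icode", "uniprot_acc", "uniprot_pos", "uniprot_res"]
    )


def make_pockets(rows) -> PocketAnnotationSet:
    """rows: (uniprot_acc, pocket_id, residue, position)."""
    return PocketAnnotationSet(pd.DataFrame(rows, columns=POCKET_COLUMNS))


def make_mset(rows) -> MappedMutationSet:
    """rows: (gene, uniprot_acc, cancer_type, mclass, in_pocket[, pocket_ids[, wt]]).

    Fills the remaining catalog columns with placeholders; each row is one
    occurrence.
    """
    records = []
    for i, row in enumerate(rows):
        gene, acc, ctype, mclass, in_pocket = row[:5]
        pocket_ids = row[5] if len(row) > 5 else ("pk:1" if in_pocket else "")
        wt = row[6] if len(row) > 6 else "A"
        alt = {"missense": "V" if wt != "V" else "L", "silent": wt, "nonsense": "*",
               "indel": "-", "complex": "X"}[mclass]
        records.append(
            (f"S{i:04d}", ctype, gene, acc, wt, i + 1, alt, mclass == "indel",
             mclass, in_pocket, pocket_ids)
        )
    return MappedMutationSet(pd.DataFrame(records, columns=MAPPED_COLUMNS))
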