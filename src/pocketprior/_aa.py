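"""Shared amino-acid code tables.

Only the 20 standard proteinogenic residues are accepted anywhere in the
pipeline; modified residues (MSE, SEP, ...) are rejected at parse time.
"""

from Bio.Data.IUPACData import protein_letters_3to1

#: 3-letter (upper case) -> 1-letter code, standard residues only.
AA_3TO1: dict[str, str] = {k.upper(): v for k, v in protein_letters_3to1.items()}

#: 1-letter -> 3-letter (upper case).
AA_1TO3: dict[str, str] = {v: k.upper() for k, v in protein_letters_3to1.items()}

#: The 20 standard 1-letter codes.
STANDARD_AA: frozenset[str] = frozenset(AA_3TO1.values())

#: Canonical row order for amino-acid spectra (alphabetical 1-letter).
AA_ORDER: tuple[str, ...] = tuple(sorted(STANDARD_AA))
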