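"""Genetic-code lookups shared across the package (standard nuclear code)."""

from __future__ import annotations

import itertools

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: The 61 sense codons, sorted lexicographically.
SENSE_CODONS: tuple[str, ...] = tuple(
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)

#: Sense codon -> one-letter amino acid.
CODON_TO_AA: dict[str, str] = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

#: One-letter amino acid -> tuple of synonymous codons.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_c,)


def codons_for(amino_acids: str) -> tuple[str, ...]:
    """All sense codons encoding any of the given one-letter amino acids."""
    out: list[str] = []
    for aa in amino_acids:
        if aa not in AA_TO_CODONS:
            raise KeyError(f"unknown amino acid {aa!r}")
        out.extend(AA_TO_CODONS[aa])
    return tuple(out)
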