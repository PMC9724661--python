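"""Small DNA/RNA sequence helpers shared across modules."""
from __future__ import annotations

from Bio.Data.IUPACData import ambiguous_dna_values

DNA_BASES = "ACGT"
_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")

#: IUPAC degeneracy code for each non-empty subset of {A, C, G, T}.
#: "X" in biopython aliases "N"; the canonical "N" wins.
IUPAC_FOR_SET: dict[frozenset, str] = {}
for _code, _bases in ambiguous_dna_values.items():
    if _code == "X":
        continue
    IUPAC_FOR_SET[frozenset(_bases)] = _code

SET_FOR_IUPAC: dict[str, frozenset] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items() if code != "X"
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving)."""
    return seq.translate(_RC_TABLE)[::-1]


def validate_dna(seq: str, name: str = "sequence", allow_empty: bool = False) -> str:
    """Upper-case and validate a strict A/C/G/T string, raising ValueError otherwise."""
    if not isinstance(seq, str):
        raise ValueError(f"{name} must be a string, got {type(seq).__name__}")
    seq = seq.upper()
    if not seq:
        if allow_empty:
            return seq
        raise ValueError(f"{name} must be non-empty")
    bad = set(seq) - set(DNA_BASES)
    if bad:
        raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    return seq


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases; 0.0 for an empty string."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def to_rna(seq: str) -> str:
    """DNA -> RNA alphabet (T -> U)."""
    return seq.replace("T", "U").replace("t", "u")
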