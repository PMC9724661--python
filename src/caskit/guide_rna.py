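"""tracrRNA evidence detection and single-guide RNA assembly.

A tracrRNA-encoding region next to a CRISPR locus shows three sequence-level
signatures: a segment complementary to the CRISPR repeat (the anti-repeat), a
block conserved across related loci, and a GC-rich inverted repeat that can
fold into a terminator-like hairpin. This module detects all three by pure
sequence geometry (DNA-level Watson-Crick complementarity; no thermodynamic
folding) and assembles sgRNA variants by joining the tracrRNA 3' end to the
repeat 5' end through a GAAA tetraloop, followed by the spacer.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .sequtils import gc_fraction, revcomp, to_rna, validate_dna

TETRALOOP = "GAAA"
SPACER_LENGTH_RANGE = (18, 24)

#: Variant conventions: which optional segments each sgRNA design carries.
#: Designs 1 and 3 keep the unstructured tracrRNA 5' region; designs 3 and 4
#: keep the terminator-like hairpin.
SGRNA_VARIANTS: dict[int, dict[str, bool]] = {
    1: {"five_prime_region": True, "terminator_hairpin": False},
    2: {"five_prime_region": False, "terminator_hairpin": False},
    3: {"five_prime_region": True, "terminator_hairpin": True},
    4: {"five_prime_region": False, "terminator_hairpin": True},
}


@dataclass(frozen=True)
class AntiRepeatHit:
    """A locus segment whose reverse complement matches part of the repeat.

    Coordinates are 1-based closed on the scanned sequence's forward frame;
    ``strand`` tells which strand of the locus carries the anti-repeat.
    """

    start: int
    end: int
    strand: str
    length: int
    n_mismatches: int
    repeat_start: int
    repeat_end: int
    sequence: str


@dataclass(frozen=True)
class ConservedBlock:
    """A maximal substring present identically in every input sequence."""

    sequence: str
    length: int
    identity: float  # percent; exact-match semantics give 100.0
    positions: tuple[int, ...]  # 1-based start in each input


@dataclass(frozen=True)
class Hairpin:
    """A perfect inverted repeat: stem of Watson-Crick pairs around a loop."""

    start: int        # 1-based start of the left arm
    stem_length: int
    loop_length: int
    gc_fraction: float
    sequence: str     # left arm + loop + right arm


@dataclass(frozen=True)
class SgRnaDesign:
    """An assembled single-guide RNA (RNA alphabet)."""

    variant: int
    five_prime_region: str
    tracr_segment: str
    terminator_hairpin: str
    tetraloop: str
    repeat_segment: str
    spacer: str

    @property
    def sequence(self) -> str:
        return (self.five_prime_region + self.tracr_segment
                + self.terminator_hairpin + self.tetraloop
                + self.repeat_segment + self.spacer)

    def fasta_header(self) -> str:
        return (f"sgRNA_variant{self.variant} "
                f"five_prime={'yes' if self.five_prime_region else 'no'} "
                f"hairpin3={'yes' if self.terminator_hairpin else 'no'} "
                f"spacer_len={len(self.spacer)}")


# ---------------------------------------------------------------------------
# Anti-repeat search
# ---------------------------------------------------------------------------

def find_anti_repeat(sequence: str, repeat: str, min_len: int = 10,
                     max_mismatches: int | None = None) -> list[AntiRepeatHit]:
    """Scan both strands for the longest segments whose reverse complement
    matches a repeat substring of length >= ``min_len``.

    ``max_mismatches`` defaults to one mismatch per 12 bases of ``min_len``
    (i.e. ``min_len // 12``). Hits never start or end on a mismatch and are
    ranked by (length desc, mismatches asc, position). Complementarity is
    DNA-level Watson-Crick only (no G.U wobble).
    """
    sequence = validate_dna(sequence, "sequence")
    repeat = validate_dna(repeat, "repeat")
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    if len(repeat) < min_len:
        raise ValueError("repeat shorter than min_len")
    if max_mismatches is None:
        max_mismatches = min_len // 12

    hits: list[AntiRepeatHit] = []
    n = len(sequence)
    # A + strand segment that is the revcomp of a repeat substring appears
    # directly as a substring of revcomp(repeat); scan per diagonal.
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        ref = revcomp(repeat)
        m = len(ref)
        for offset in range(-(m - 1), len(seq)):
            # diagonal: seq[i] vs ref[i - offset]
            i0 = max(0, offset)
            i1 = min(len(seq), offset + m)
            if i1 - i0 < min_len:
                continue
            match = [seq[i] == ref[i - offset] for i in range(i0, i1)]
            hits.extend(_windows_on_diagonal(
                match, i0, offset, strand, seq, n, repeat, min_len,
                max_mismatches))
    # dedupe (same footprint) and rank
    seen = set()
    unique = []
    for h in sorted(hits, key=lambda h: (-h.length, h.n_mismatches, h.start,
                                         h.strand, h.repeat_start)):
        key = (h.start, h.end, h.strand, h.repeat_start)
        if key in seen:
            continue
        seen.add(key)
        unique.append(h)
    return unique


def _windows_on_diagonal(match, i0, offset, strand, seq, n, repeat,
                         min_len, max_mm):
    """Maximal windows with <= max_mm mismatches along one alignment diagonal."""
    out = []
    left = 0
    mism = 0
    for right in range(len(match)):
        if not match[right]:
            mism += 1
        while mism > max_mm:
            if not match[left]:
                mism -= 1
            left += 1
        # trim flanking mismatches
        lo, hi = left, right
        while lo <= hi and not match[lo]:
            lo += 1
        while hi >= lo and not match[hi]:
            hi -= 1
        length = hi - lo + 1
        if length < min_len:
            continue
        # keep only windows maximal to the right (next position breaks budget
        # or is the end); cheap over-reporting is removed by ranking/dedupe
        if right + 1 < len(match) and match[right + 1]:
            continue
        seq_start = i0 + lo          # 0-based on the scanned strand
        seq_end = i0 + hi
        nmm = sum(1 for k in range(lo, hi + 1) if not match[k])
        ref_start = seq_start - offset   # position in revcomp(repeat)
        ref_end = seq_end - offset
        # convert back to repeat coordinates (1-based)
        rep_len = len(repeat)
        rep_start = rep_len - ref_end
        rep_end = rep_len - ref_start
        if strand == "+":
            start, end = seq_start + 1, seq_end + 1
        else:
            start, end = n - seq_end, n - seq_start
        out.append(AntiRepeatHit(
            start=start, end=end, strand=strand, length=length,
            n_mismatches=nmm, repeat_start=rep_start, repeat_end=rep_end,
            sequence=(seq[seq_start:seq_end + 1])))
    return out


# ---------------------------------------------------------------------------
# Conserved blocks
# ---------------------------------------------------------------------------

def find_conserved_blocks(sequences: list[str],
                          min_len: int = 8) -> list[ConservedBlock]:
    """Maximal substrings present identically in all inputs (exact common
    substrings), with 1-based start positions per input, sorted by length.

    A block is maximal when no common substring strictly contains it.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    seqs = [validate_dna(s, f"sequences[{i}]") for i, s in enumerate(sequences)]
    s0 = min(seqs, key=len)
    others = [s for s in seqs if s is not s0]

    common: set[str] = set()
    for L in range(len(s0), min_len - 1, -1):
        for i in range(len(s0) - L + 1):
            sub = s0[i:i + L]
            if sub in common:
                continue
            if all(sub in s for s in others):
                common.add(sub)
    # maximality: drop blocks contained in a longer common block
    maximal = [sub for sub in common
               if not any(sub != other and sub in other for other in common)]
    blocks = [
        ConservedBlock(
            sequence=sub, length=len(sub), identity=100.0,
            positions=tuple(s.find(sub) + 1 for s in seqs))
        for sub in maximal
    ]
    return sorted(blocks, key=lambda b: (-b.length, b.sequence))


# ---------------------------------------------------------------------------
# Hairpins
# ---------------------------------------------------------------------------

def find_hairpins(sequence: str, min_stem: int = 4,
                  loop_range: tuple[int, int] = (3, 8)) -> list[Hairpin]:
    """Perfect inverted repeats: a stem of >= ``min_stem`` Watson-Crick pairs
    enclosing a loop with length in ``loop_range``.

    For each loop placement the stem is grown outward maximally, so each
    (loop position, loop length) yields at most one hairpin. Overlapping
    hairpins are allowed; ranking is (stem length desc, stem GC desc,
    position).
    """
    sequence = validate_dna(sequence, "sequence")
    if min_stem < 3:
        raise ValueError("min_stem must be >= 3")
    lo, hi = loop_range
    if lo < 3 or hi > 12 or lo > hi:
        raise ValueError("loop_range must lie within [3, 12]")

    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    n = len(sequence)
    found: dict[tuple[int, int, int], Hairpin] = {}
    for loop_len in range(lo, hi + 1):
        for loop_start in range(1, n - loop_len):
            i = loop_start - 1
            j = loop_start + loop_len
            stem = 0
            while i >= 0 and j < n and (sequence[i], sequence[j]) in pairs:
                stem += 1
                i -= 1
                j += 1
            if stem < min_stem:
                continue
            left_start = loop_start - stem      # 0-based
            key = (left_start, stem, loop_len)
            if key not in found:
                arm = sequence[left_start:left_start + stem]
                full = sequence[left_start:left_start + 2 * stem + loop_len]
                found[key] = Hairpin(start=left_start + 1, stem_length=stem,
                                     loop_length=loop_len,
                                     gc_fraction=gc_fraction(arm),
                                     sequence=full)
    return sorted(found.values(),
                  key=lambda h: (-h.stem_length, -h.gc_fraction, h.start))


# ---------------------------------------------------------------------------
# sgRNA assembly
# ---------------------------------------------------------------------------

def design_sgrna(tracr_segment: str, repeat: str, spacer: str,
                 variant: int = 1, five_prime_region: str = "",
                 terminator_hairpin: str = "",
                 repeat_5p_length: int | None = None) -> SgRnaDesign:
    """Assemble an sgRNA: [5' region +] tracr 3' end [+ hairpin 3] + GAAA
    tetraloop + repeat 5' end + spacer, converted to the RNA alphabet.

    The spacer must be 18-24 nt (the screened range; 20 nt is the preferred
    design). ``variant`` (1-4) selects which optional segments are included
    per :data:`SGRNA_VARIANTS`; the default variant 1 with a 20-nt spacer is
    the chosen configuration.
    """
    if variant not in SGRNA_VARIANTS:
        raise ValueError(f"variant must be in {sorted(SGRNA_VARIANTS)}")
    lo, hi = SPACER_LENGTH_RANGE
    spacer = validate_dna(spacer, "spacer")
    if not lo <= len(spacer) <= hi:
        raise ValueError(
            f"spacer length {len(spacer)} outside the screened range "
            f"[{lo}, {hi}] nt")
    tracr_segment = validate_dna(tracr_segment, "tracr_segment")
    repeat = validate_dna(repeat, "repeat")
    five_prime_region = validate_dna(five_prime_region, "five_prime_region",
                                     allow_empty=True)
    terminator_hairpin = validate_dna(terminator_hairpin, "terminator_hairpin",
                                      allow_empty=True)
    flags = SGRNA_VARIANTS[variant]
    repeat_segment = repeat[:repeat_5p_length] if repeat_5p_length else repeat
    return SgRnaDesign(
        variant=variant,
        five_prime_region=to_rna(five_prime_region) if flags["five_prime_region"] else "",
        tracr_segment=to_rna(tracr_segment),
        terminator_hairpin=to_rna(terminator_hairpin) if flags["terminator_hairpin"] else "",
        tetraloop=TETRALOOP,
        repeat_segment=to_rna(repeat_segment),
        spacer=to_rna(spacer),
    )


def write_sgrna_fasta(designs: list[SgRnaDesign], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for d in designs:
            fh.write(f">{d.fasta_header()}\n{d.sequence}\n")
    return path
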