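"""Adapter-junction mapping, cleavage-peak calling and overhang geometry.

Reads produced by the adapter-ligation protocol (or its simulated
counterpart) are assigned a single junction position per strand in
PAM-anchored coordinates (nt downstream of the PAM, 1-based, on the strand in
question). Per-position ligation frequencies are then compared with an
empty-vector control profile to call cleavage peaks, and the target/nontarget
strand calls combine into a staggered-overhang summary.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .sequtils import revcomp
from .synthetic_data import ADAPTER, LibraryLayout, OrientedLayout, SimulatedReadSet

STRANDS = ("TS", "NTS")


@dataclass
class LigationProfile:
    """Per-position adapter-junction counts and frequencies for one strand."""

    strand: str
    counts: dict[int, int]
    n_positions: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be TS or NTS, got {self.strand!r}")
        for pos in self.counts:
            if not 1 <= pos <= self.n_positions:
                raise ValueError(
                    f"position {pos} outside construct bounds 1..{self.n_positions}")

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    def frequency(self, pos: int) -> float:
        n = self.n_reads
        return self.counts.get(pos, 0) / n if n else 0.0

    def frequencies(self) -> pd.Series:
        idx = pd.RangeIndex(1, self.n_positions + 1, name="position")
        counts = pd.Series({p: c for p, c in self.counts.items()},
                           dtype=float).reindex(idx, fill_value=0.0)
        n = self.n_reads
        return counts / n if n else counts

    @classmethod
    def uniform_prior(cls, strand: str, n_positions: int,
                      pseudocount: int = 1) -> "LigationProfile":
        """A flat control profile, for use when no empty-vector data exist."""
        return cls(strand=strand,
                   counts={p: pseudocount for p in range(1, n_positions + 1)},
                   n_positions=n_positions)


@dataclass
class MappingResult:
    """Profiles for both strands plus per-read junction assignments."""

    profiles: dict[str, LigationProfile]
    assignments: pd.DataFrame  # read_id, strand, position, pam
    n_unmapped: int
    layout: LibraryLayout
    target: str

    @property
    def n_reads(self) -> int:
        return len(self.assignments) + self.n_unmapped

    def to_tsv(self, path: str | Path,
               control: "MappingResult | None" = None,
               min_enrichment: float = 5.0,
               min_fraction: float = 0.01) -> Path:
        """Write a per-position table (strand, position, count, frequency,
        control_frequency, enrichment)."""
        rows = []
        for strand in STRANDS:
            prof = self.profiles[strand]
            freqs = prof.frequencies()
            if control is not None:
                call = call_cut_sites(prof, control.profiles[strand],
                                      min_enrichment=min_enrichment,
                                      min_fraction=min_fraction)
                ctrl_freqs = control.profiles[strand].frequencies()
                enr = call.enrichment
            else:
                ctrl_freqs = pd.Series(np.nan, index=freqs.index)
                enr = pd.Series(np.nan, index=freqs.index)
            for pos in freqs.index:
                rows.append({
                    "strand": strand, "position": int(pos),
                    "count": prof.counts.get(int(pos), 0),
                    "frequency": freqs[pos],
                    "control_frequency": ctrl_freqs[pos],
                    "enrichment": enr[pos],
                })
        path = Path(path)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path


@dataclass
class CutSiteCall:
    """Cleavage peaks for one strand, relative to a control profile.

    ``peak_positions`` is empty and ``no_cleavage`` is True when no position
    passes both the enrichment and the frequency thresholds.
    """

    strand: str
    peak_positions: tuple[int, ...]
    enrichment: pd.Series = field(repr=False)
    modal_position: int | None
    window: tuple[int, int] | None
    tied_modal: bool = False
    min_enrichment: float = 5.0
    min_fraction: float = 0.01

    @property
    def no_cleavage(self) -> bool:
        return not self.peak_positions

    def to_dict(self) -> dict:
        return {
            "strand": self.strand,
            "peak_positions": list(self.peak_positions),
            "modal_position": self.modal_position,
            "window": list(self.window) if self.window else None,
            "tied_modal": self.tied_modal,
            "no_cleavage": self.no_cleavage,
            "min_enrichment": self.min_enrichment,
            "min_fraction": self.min_fraction,
        }


@dataclass(frozen=True)
class OverhangSummary:
    """Staggered-end geometry from paired TS/NTS cut calls.

    Lengths are TS position minus NTS position (both PAM-anchored); positive
    lengths are 5' overhangs, zero is blunt, negative are 3' overhangs.
    """

    min_length: int
    max_length: int
    modal_length: int | None
    polarity: str  # "5prime" | "blunt" | "3prime" | "mixed"


# ---------------------------------------------------------------------------
# Junction assignment
# ---------------------------------------------------------------------------

def _iter_reads(reads) -> Iterable[tuple[str, str]]:
    """Normalize supported read inputs to (read_id, sequence) pairs."""
    if isinstance(reads, SimulatedReadSet):
        yield from zip(reads.reads["read_id"], reads.reads["sequence"])
    elif isinstance(reads, pd.DataFrame):
        yield from zip(reads["read_id"], reads["sequence"])
    elif isinstance(reads, (str, Path)):
        path = Path(reads)
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield rec.id, str(rec.seq).upper()
    else:
        for item in reads:
            yield item[0], item[1]


def _assign_one(seq: str, oriented: OrientedLayout,
                template: str) -> tuple[str, int, str] | None:
    """Map one read to (strand, junction position, observed PAM k-mer)."""
    if seq.endswith(ADAPTER) and not seq.startswith(ADAPTER):
        strand = "NTS"
        genomic = seq[: -len(ADAPTER)]
    elif seq.startswith(ADAPTER):
        strand = "TS"
        genomic = revcomp(seq[len(ADAPTER):])
    else:
        return None
    j = len(genomic)
    pos = j - oriented.proto_start
    if not 1 <= pos <= oriented.n_positions:
        return None
    # genomic must equal the oriented template prefix, N positions wildcarded
    for a, b in zip(genomic, template):
        if b != "N" and a != b:
            return None
    L = oriented.layout.randomized_length
    pam = genomic[oriented.proto_start - L: oriented.proto_start]
    return strand, pos, pam


def map_adapter_junctions(reads, layout: LibraryLayout,
                          target: str = "T2",
                          max_unmapped_fraction: float = 0.5) -> MappingResult:
    """Assign each read one junction position on its strand and tally profiles.

    Reads that do not carry the adapter at an end, do not match the layout
    flanks exactly, or imply a junction outside the construct are tallied as
    unmapped (never silently dropped); more than ``max_unmapped_fraction``
    unmapped is a hard error.
    """
    oriented = layout.oriented(target)
    template = oriented.prefix + "N" * layout.randomized_length + oriented.proto_and_right

    ids: list[str] = []
    strands: list[str] = []
    positions: list[int] = []
    pams: list[str] = []
    n_unmapped = 0
    n_total = 0
    for read_id, seq in _iter_reads(reads):
        n_total += 1
        hit = _assign_one(seq, oriented, template)
        if hit is None:
            n_unmapped += 1
            continue
        strand, pos, pam = hit
        ids.append(read_id)
        strands.append(strand)
        positions.append(pos)
        pams.append(pam)

    if n_total and n_unmapped / n_total > max_unmapped_fraction:
        raise ValueError(
            f"{n_unmapped}/{n_total} reads unmapped "
            f"(> {max_unmapped_fraction:.0%}); reads and layout disagree")

    assignments = pd.DataFrame({
        "read_id": ids, "strand": strands, "position": positions, "pam": pams,
    })
    profiles = {}
    for strand in STRANDS:
        sub = assignments[assignments["strand"] == strand]
        counts = sub["position"].value_counts().to_dict()
        profiles[strand] = LigationProfile(
            strand=strand,
            counts={int(k): int(v) for k, v in counts.items()},
            n_positions=oriented.n_positions)
    return MappingResult(profiles=profiles, assignments=assignments,
                         n_unmapped=n_unmapped, layout=layout, target=target)


# ---------------------------------------------------------------------------
# Peak calling and overhang geometry
# ---------------------------------------------------------------------------

def call_cut_sites(target: LigationProfile, control: LigationProfile,
                   min_enrichment: float = 5.0,
                   min_fraction: float = 0.01) -> CutSiteCall:
    """Call cleavage peaks as positions enriched over the control profile.

    A peak needs target frequency >= ``min_fraction`` and enrichment
    (target frequency over control frequency plus a Laplace-style pseudo
    frequency 1/(control reads + positions)) >= ``min_enrichment``. Modal
    position maximizes target frequency among peaks; ties break toward the
    PAM-proximal (smaller) position with a warning.
    """
    if target.strand != control.strand:
        raise ValueError("target and control profiles are for different strands")
    if target.n_positions != control.n_positions:
        raise ValueError("target and control profiles have different layouts")
    if control.n_reads == 0:
        raise ValueError(
            "control profile has zero reads; use "
            "LigationProfile.uniform_prior() as the control instead")

    tfreq = target.frequencies()
    cfreq = control.frequencies()
    pseudo = 1.0 / (control.n_reads + target.n_positions)
    enrichment = tfreq / (cfreq + pseudo)
    peaks = tuple(int(p) for p in tfreq.index
                  if enrichment[p] >= min_enrichment and tfreq[p] >= min_fraction)

    modal = None
    tied = False
    window = None
    if peaks:
        peak_freqs = tfreq[list(peaks)]
        best = peak_freqs.max()
        at_best = [int(p) for p in peak_freqs.index if peak_freqs[p] == best]
        modal = min(at_best)
        tied = len(at_best) > 1
        if tied:
            warnings.warn(
                f"{target.strand}: modal ligation position tied at {at_best}; "
                f"reporting the PAM-proximal position {modal}", stacklevel=2)
        window = (min(peaks), max(peaks))
    return CutSiteCall(strand=target.strand, peak_positions=peaks,
                       enrichment=enrichment, modal_position=modal,
                       window=window, tied_modal=tied,
                       min_enrichment=min_enrichment, min_fraction=min_fraction)


def _peaks_of(call) -> tuple[tuple[int, ...], int | None]:
    if isinstance(call, CutSiteCall):
        return call.peak_positions, call.modal_position
    peaks = tuple(sorted(int(p) for p in call))
    return peaks, None


def compute_overhang(ts, nts) -> OverhangSummary:
    """Overhang geometry from TS and NTS cut calls (or plain peak sets).

    For a TS cut at ``t`` and an NTS cut at ``n`` (both nt downstream of the
    PAM on their own strand) the overhang length is ``t - n``: positive means
    a 5' overhang, zero blunt, negative a 3' overhang. Min/max run over the
    peak windows.
    """
    ts_peaks, ts_modal = _peaks_of(ts)
    nts_peaks, nts_modal = _peaks_of(nts)
    if not ts_peaks or not nts_peaks:
        raise ValueError("both strands need at least one called peak")
    min_len = min(ts_peaks) - max(nts_peaks)
    max_len = max(ts_peaks) - min(nts_peaks)
    modal = ts_modal - nts_modal if ts_modal is not None and nts_modal is not None \
        else None
    if min_len > 0:
        polarity = "5prime"
    elif max_len < 0:
        polarity = "3prime"
    elif min_len == 0 and max_len == 0:
        polarity = "blunt"
    else:
        polarity = "mixed"
    return OverhangSummary(min_length=min_len, max_length=max_len,
                           modal_length=modal, polarity=polarity)
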