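"""Candidate-selection geometry for CRISPR loci on pre-annotated contigs.

A locus is worth pursuing as a putative new class 2 system when, within a
window around a CRISPR array, the adaptation genes cas1 and cas2 co-occur
with a large (>= 1,500 bp) undefined open reading frame on the same strand
and close to them — an operon-like arrangement. Homology assignment of the
cas labels happens upstream and is out of scope here; this module only
applies the geometric rules and reports machine-readable reasons for every
rejection.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

GENE_LABELS = ("cas1", "cas2", "cas4", "unknown", "other")

GENE_COLUMNS = ("id", "start", "end", "strand", "label")
ARRAY_COLUMNS = ("start", "end", "repeat", "n_spacers")


@dataclass
class AnnotatedLocus:
    """A contig with labelled genes and CRISPR arrays (1-based, closed)."""

    contig_id: str
    length: int
    genes: pd.DataFrame   # id, start, end, strand, label
    arrays: pd.DataFrame  # start, end, repeat, n_spacers

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        self.arrays = self.arrays.reset_index(drop=True)
        offenders = []
        for _, g in self.genes.iterrows():
            if not (1 <= g["start"] <= g["end"] <= self.length):
                offenders.append(f"gene {g['id']}: [{g['start']}, {g['end']}]")
            if g["strand"] not in ("+", "-"):
                offenders.append(f"gene {g['id']}: strand {g['strand']!r}")
            if g["label"] not in GENE_LABELS:
                offenders.append(f"gene {g['id']}: label {g['label']!r}")
        for i, a in self.arrays.iterrows():
            if not (1 <= a["start"] <= a["end"] <= self.length):
                offenders.append(f"array {i}: [{a['start']}, {a['end']}]")
        if offenders:
            raise ValueError("malformed annotations: " + "; ".join(offenders))

    @classmethod
    def from_tsv(cls, genes_path: str | Path, arrays_path: str | Path,
                 contig_id: str = "contig", length: int | None = None
                 ) -> "AnnotatedLocus":
        genes = pd.read_csv(genes_path, sep="\t")
        arrays = pd.read_csv(arrays_path, sep="\t")
        missing = set(GENE_COLUMNS) - set(genes.columns)
        if missing:
            raise ValueError(f"gene table missing columns {sorted(missing)}")
        missing = set(ARRAY_COLUMNS) - set(arrays.columns)
        if missing:
            raise ValueError(f"array table missing columns {sorted(missing)}")
        if length is None:
            length = int(max(genes["end"].max(), arrays["end"].max()))
        return cls(contig_id=contig_id, length=length, genes=genes,
                   arrays=arrays)

    @classmethod
    def from_gff3(cls, path: str | Path, length: int | None = None
                  ) -> "AnnotatedLocus":
        """Minimal GFF3 reader: ``gene`` rows (attribute ``label=``) and
        ``repeat_region`` rows (attributes ``repeat=``, ``n_spacers=``)."""
        genes, arrays = [], []
        contig = "contig"
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    continue
                seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
                contig = seqid
                attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
                if ftype == "gene":
                    genes.append({"id": attr.get("ID", f"gene{len(genes)}"),
                                  "start": int(start), "end": int(end),
                                  "strand": strand,
                                  "label": attr.get("label", "unknown")})
                elif ftype == "repeat_region":
                    arrays.append({"start": int(start), "end": int(end),
                                   "repeat": attr.get("repeat", ""),
                                   "n_spacers": int(attr.get("n_spacers", 0))})
        genes_df = pd.DataFrame(genes, columns=list(GENE_COLUMNS))
        arrays_df = pd.DataFrame(arrays, columns=list(ARRAY_COLUMNS))
        if length is None:
            ends = [g["end"] for g in genes] + [a["end"] for a in arrays]
            length = max(ends) if ends else 0
        return cls(contig_id=contig, length=length, genes=genes_df,
                   arrays=arrays_df)


@dataclass
class CandidateSystem:
    """One evaluated large-unknown-ORF candidate with pass/fail reasons."""

    effector_id: str
    orf_bp: int
    strand: str
    distance_to_cas_bp: int
    strand_concordant: bool
    array_distance_bp: int
    truncated_window: bool
    passed: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "effector_id": self.effector_id,
            "orf_bp": self.orf_bp,
            "strand": self.strand,
            "distance_to_cas_bp": self.distance_to_cas_bp,
            "strand_concordant": self.strand_concordant,
            "array_distance_bp": self.array_distance_bp,
            "truncated_window": self.truncated_window,
            "passed": self.passed,
            "reasons": list(self.reasons),
        }


def _interval_gap(a_start, a_end, b_start, b_end) -> int:
    """bp between two closed intervals; 0 when they touch or overlap."""
    if a_end < b_start:
        return b_start - a_end - 1
    if b_end < a_start:
        return a_start - b_end - 1
    return 0


def select_candidates(locus: AnnotatedLocus, window_bp: int = 20000,
                      min_orf_bp: int = 1500,
                      max_gap_bp: int = 5000) -> list[CandidateSystem]:
    """Evaluate the operon-geometry rules around each CRISPR array.

    Requirements, applied within ``window_bp`` of an array: cas1 AND cas2
    present; an unknown-label gene of length >= ``min_orf_bp`` on the same
    strand as both, within ``max_gap_bp`` of the nearer of them. When cas1 or
    cas2 is absent from every window the result is empty; otherwise every
    evaluated unknown ORF is returned with its pass/fail verdict and reasons.
    Windows clipped by the contig ends are flagged truncated, not rejected.
    """
    results: dict[str, CandidateSystem] = {}
    genes = locus.genes
    for _, arr in locus.arrays.iterrows():
        win_start = arr["start"] - window_bp
        win_end = arr["end"] + window_bp
        truncated = win_start < 1 or win_end > locus.length
        win_start = max(win_start, 1)
        win_end = min(win_end, locus.length)
        inside = genes[(genes["end"] >= win_start) & (genes["start"] <= win_end)]
        cas1 = inside[inside["label"] == "cas1"]
        cas2 = inside[inside["label"] == "cas2"]
        if cas1.empty or cas2.empty:
            continue
        unknowns = inside[inside["label"] == "unknown"]
        for _, g in unknowns.iterrows():
            orf_bp = int(g["end"] - g["start"] + 1)
            reasons: list[str] = []
            if orf_bp < min_orf_bp:
                reasons.append(f"orf_too_short:{orf_bp}<{min_orf_bp}")
            same_strand = pd.concat([cas1, cas2])
            concordant = bool(((cas1["strand"] == g["strand"]).any())
                              and ((cas2["strand"] == g["strand"]).any()))
            if not concordant:
                reasons.append("strand_discordant_with_cas1_cas2")
            gaps = [
                _interval_gap(g["start"], g["end"], c["start"], c["end"])
                for _, c in same_strand.iterrows()
            ]
            gap = int(min(gaps))
            if gap > max_gap_bp:
                reasons.append(f"too_far_from_cas:{gap}>{max_gap_bp}")
            array_gap = _interval_gap(g["start"], g["end"],
                                      arr["start"], arr["end"])
            cand = CandidateSystem(
                effector_id=str(g["id"]), orf_bp=orf_bp, strand=g["strand"],
                distance_to_cas_bp=gap, strand_concordant=concordant,
                array_distance_bp=int(array_gap), truncated_window=truncated,
                passed=not reasons, reasons=tuple(reasons))
            prev = results.get(cand.effector_id)
            # the same ORF seen from several arrays keeps its best verdict
            if prev is None or (cand.passed and not prev.passed):
                results[cand.effector_id] = cand
    return sorted(results.values(), key=lambda c: c.effector_id)


def candidates_to_tsv(candidates: list[CandidateSystem],
                      path: str | Path) -> Path:
    path = Path(path)
    rows = [c.to_dict() for c in candidates]
    df = pd.DataFrame(rows, columns=[
        "effector_id", "orf_bp", "strand", "distance_to_cas_bp",
        "strand_concordant", "array_distance_bp", "truncated_window",
        "passed", "reasons"])
    if len(df):
        df["reasons"] = df["reasons"].map(lambda r: ",".join(r) if r else "")
    df.to_csv(path, sep="\t", index=False)
    return path
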