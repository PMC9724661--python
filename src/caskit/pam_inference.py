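"""PAM motif inference from reads supporting cleavage peaks.

Reads whose adapter junction falls inside a called peak window contribute the
randomized k-mer they carry (reported 5'->3' on the protospacer-bearing
strand, positions -L..-1 with -1 adjacent to the protospacer). The k-mers are
summarized as a position frequency matrix with a background correction (the
starting-library composition, or uniform), a per-position information content
in bits (relative entropy against the background), and an IUPAC consensus.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cutsite_mapping import CutSiteCall, MappingResult, map_adapter_junctions
from .sequtils import DNA_BASES, IUPAC_FOR_SET
from .synthetic_data import LibraryLayout, PamLibrary


@dataclass
class PamMatrix:
    """Counts, frequencies, background, enrichment and information content.

    All tables are 4 x L (bases A,C,G,T by rows, PAM positions -L..-1 by
    columns). Frequencies include the pseudocount and each column sums to 1.
    ``info_bits`` is the per-position relative entropy
    ``sum_b f_b log2(f_b / g_b)`` against the background ``g``.
    """

    counts: pd.DataFrame
    frequencies: pd.DataFrame
    background: pd.DataFrame
    pseudocount: float
    n_kmers: int

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def enrichment(self) -> pd.DataFrame:
        return self.frequencies / self.background

    @property
    def info_bits(self) -> pd.Series:
        f = self.frequencies.to_numpy()
        g = self.background.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log2(f / g), 0.0)
        return pd.Series(terms.sum(axis=0), index=self.counts.columns,
                         name="info_bits")

    def to_tsv(self, path: str | Path) -> Path:
        """Plain TSV: one row per base, one column per PAM position (counts),
        followed by frequency rows."""
        path = Path(path)
        counts = self.counts.copy()
        counts.insert(0, "table", "count")
        freqs = self.frequencies.copy()
        freqs.insert(0, "table", "frequency")
        out = pd.concat([counts, freqs])
        out.index.name = "base"
        out.to_csv(path, sep="\t")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, pseudocount: float = 0.0,
                 background: pd.DataFrame | None = None) -> "PamMatrix":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        raw.index.name = None
        counts = raw[raw["table"] == "count"].drop(columns="table")
        counts.columns = counts.columns.astype(int)
        counts = counts.astype(int)
        freqs = raw[raw["table"] == "frequency"].drop(columns="table")
        freqs.columns = freqs.columns.astype(int)
        if background is None:
            background = pd.DataFrame(0.25, index=list(DNA_BASES),
                                      columns=counts.columns)
        n = int(counts.to_numpy().sum(axis=0)[0]) if counts.shape[1] else 0
        return cls(counts=counts, frequencies=freqs.astype(float),
                   background=background, pseudocount=pseudocount, n_kmers=n)


@dataclass
class PamConsensus:
    """IUPAC summary of a :class:`PamMatrix` at an inclusion threshold."""

    iupac: str
    included: tuple[frozenset, ...]
    include_threshold: float
    positions: tuple[int, ...]

    @property
    def trimmed(self) -> str:
        """Consensus with leading/trailing N runs removed (reported, not
        applied to the canonical string)."""
        return self.iupac.strip("N")

    def to_dict(self) -> dict:
        return {
            "iupac": self.iupac,
            "trimmed": self.trimmed,
            "include_threshold": self.include_threshold,
            "positions": list(self.positions),
            "included_bases": ["".join(sorted(s)) for s in self.included],
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def extract_pam_kmers(reads, layout: LibraryLayout,
                      peaks: CutSiteCall | Mapping[str, CutSiteCall],
                      target: str = "T2",
                      mapping: MappingResult | None = None) -> Counter:
    """k-mer multiset from reads whose junction lies in a peak window.

    ``peaks`` is a single strand's :class:`CutSiteCall` or a mapping
    ``{strand: call}``; only reads on a strand with a non-empty call
    contribute. Pass a precomputed ``mapping`` to avoid re-mapping the reads.
    """
    if isinstance(peaks, CutSiteCall):
        peaks = {peaks.strand: peaks}
    windows = {}
    for strand, call in peaks.items():
        if call.no_cleavage:
            continue
        windows[strand] = set(call.peak_positions)
    if not windows:
        raise ValueError("no non-empty cut-site call supplied")

    if mapping is None:
        mapping = map_adapter_junctions(reads, layout, target=target)
    asg = mapping.assignments
    kmers: Counter = Counter()
    for strand, window in windows.items():
        sub = asg[(asg["strand"] == strand) & (asg["position"].isin(window))]
        kmers.update(sub["pam"].tolist())
    if kmers and len(next(iter(kmers))) < layout.randomized_length:
        raise ValueError("reads too short to span the randomized region")
    return kmers


def background_from_library(library: PamLibrary) -> pd.DataFrame:
    """Empirical per-position base composition of the starting library."""
    return library.base_frequencies()


def build_pam_matrix(kmers: Counter | Iterable[str],
                     background: pd.DataFrame | str = "uniform",
                     pseudocount: float = 0.5) -> PamMatrix:
    """Position frequency matrix with background enrichment.

    ``background`` is either "uniform" or a 4 x L frequency table (e.g. from
    :func:`background_from_library`). A Jeffreys-style pseudocount of 0.5 per
    cell is added before normalizing.
    """
    if not isinstance(kmers, Counter):
        kmers = Counter(kmers)
    if not kmers:
        raise ValueError("need at least one k-mer")
    lengths = {len(k) for k in kmers}
    if len(lengths) != 1:
        raise ValueError(f"k-mers have mixed lengths {sorted(lengths)}")
    L = lengths.pop()
    positions = list(range(-L, 0))

    counts = np.zeros((4, L), dtype=np.int64)
    base_row = {b: i for i, b in enumerate(DNA_BASES)}
    for kmer, n in kmers.items():
        for j, base in enumerate(kmer):
            if base not in base_row:
                raise ValueError(f"non-ACGT base {base!r} in k-mer {kmer!r}")
            counts[base_row[base], j] += n
    counts_df = pd.DataFrame(counts, index=list(DNA_BASES), columns=positions)

    if isinstance(background, str):
        if background != "uniform":
            raise ValueError("background must be 'uniform' or a frequency table")
        bg = pd.DataFrame(0.25, index=list(DNA_BASES), columns=positions)
    else:
        bg = background.copy()
        if list(bg.columns) != positions:
            if bg.shape[1] != L:
                raise ValueError(
                    f"background has {bg.shape[1]} positions, k-mers have {L}")
            bg.columns = positions
        bg = bg.loc[list(DNA_BASES)]
        if (bg.to_numpy() <= 0).any():
            # guard zero background cells so enrichment stays defined
            bg = (bg + 1e-9).div((bg + 1e-9).sum(axis=0), axis=1)

    smoothed = counts + pseudocount
    freqs = pd.DataFrame(smoothed / smoothed.sum(axis=0),
                         index=list(DNA_BASES), columns=positions)
    return PamMatrix(counts=counts_df, frequencies=freqs, background=bg,
                     pseudocount=pseudocount, n_kmers=sum(kmers.values()))


def call_consensus(matrix: PamMatrix,
                   include_threshold: float = 0.85) -> PamConsensus:
    """IUPAC consensus: per position, include bases in decreasing frequency
    until the cumulative frequency reaches ``include_threshold``.

    Positions needing all four bases become N. Leading/trailing N runs are
    reported via :attr:`PamConsensus.trimmed` but never removed from the
    canonical string.
    """
    if not 0.0 < include_threshold <= 1.0:
        raise ValueError("include_threshold must be in (0, 1]")
    codes = []
    included = []
    for pos in matrix.frequencies.columns:
        col = matrix.frequencies[pos]
        # decreasing frequency, alphabetical tie-break for determinism
        order = sorted(DNA_BASES, key=lambda b: (-col[b], b))
        cum = 0.0
        chosen: list[str] = []
        for base in order:
            chosen.append(base)
            cum += col[base]
            if cum >= include_threshold:
                break
        included.append(frozenset(chosen))
        codes.append(IUPAC_FOR_SET[frozenset(chosen)])
    return PamConsensus(iupac="".join(codes), included=tuple(included),
                        include_threshold=include_threshold,
                        positions=tuple(matrix.frequencies.columns))


def export_motif(matrix: PamMatrix, consensus: PamConsensus,
                 out_dir: str | Path, name: str = "pam",
                 logo: bool = False) -> dict[str, Path]:
    """Write the matrix (TSV), a MEME minimal motif, a JSON consensus report,
    and optionally a logo image.

    Text outputs regenerate bit-identically under fixed inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["matrix_tsv"] = matrix.to_tsv(out_dir / f"{name}_matrix.tsv")

    # MEME minimal motif format: columns A C G T, rows per position
    probs = matrix.frequencies.T[list(DNA_BASES)].to_numpy()
    probs = probs / probs.sum(axis=1, keepdims=True)
    meme_path = out_dir / f"{name}.meme"
    with open(meme_path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: +\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {consensus.iupac} {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {matrix.length} "
                 f"nsites= {matrix.n_kmers} E= 0\n")
        for row in probs:
            # round to 6 dp but keep the printed row summing to exactly 1
            vals = [round(p, 6) for p in row[:-1]]
            vals.append(round(1.0 - sum(vals), 6))
            fh.write(" " + " ".join(f"{p:.6f}" for p in vals) + "\n")
    paths["meme"] = meme_path

    report = {
        "iupac": consensus.iupac,
        "trimmed": consensus.trimmed,
        "thresholds": {"include_threshold": consensus.include_threshold,
                       "pseudocount": matrix.pseudocount},
        "n_kmers": matrix.n_kmers,
        "info_bits": {str(p): float(v) for p, v in matrix.info_bits.items()},
    }
    report_path = out_dir / f"{name}_consensus.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    paths["consensus_json"] = report_path

    if logo:
        paths["logo"] = _draw_logo(matrix, out_dir / f"{name}_logo.png")
    return paths


def _draw_logo(matrix: PamMatrix, path: Path) -> Path:
    """Minimal information-content sequence logo (stacked scaled letters)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    info = matrix.info_bits
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * matrix.length, 2.5))
    for i, pos in enumerate(matrix.frequencies.columns):
        col = matrix.frequencies[pos]
        total = info[pos]
        y = 0.0
        for base in sorted(DNA_BASES, key=lambda b: col[b]):
            h = col[base] * total
            if h <= 0:
                continue
            ax.text(i + 0.5, y + h / 2, base, ha="center", va="center",
                    fontsize=30 * min(h, 2.0) / 2.0 + 2,
                    color=colors[base], fontweight="bold")
            y += h
    ax.set_xlim(0, matrix.length)
    ax.set_ylim(0, 2.05)
    ax.set_xticks(np.arange(matrix.length) + 0.5)
    ax.set_xticklabels([str(p) for p in matrix.frequencies.columns])
    ax.set_ylabel("bits")
    ax.set_xlabel("PAM position")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
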