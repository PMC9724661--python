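"""Seeded generators for every input the characterization pipeline consumes.

The module emulates, with known ground truth, the data types produced when a
class 2 CRISPR nuclease is characterized biochemically:

* a plasmid library whose protospacer target carries a fully randomized PAM
  region flanked by two fixed targets in opposite orientations (``T1``/``T2``),
* PAM-gated double-strand cleavage with staggered cut positions, captured as
  adapter-ligated junction reads plus a uniform spurious-ligation background,
* an intergenic locus region carrying tracrRNA evidence (conserved block,
  anti-repeat, terminator-like hairpin) next to a repeat-spacer array,
* kinetic and binding datasets drawn from the closed forms implemented in
  :mod:`caskit.kinetics`.

All randomness flows through a single integer seed; identical inputs and seed
give byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import kinetics as _kin
from .sequtils import DNA_BASES, SET_FOR_IUPAC, revcomp, validate_dna

#: Double-stranded adapter sequence ligated to cleavage-product junctions.
ADAPTER = "GTCAGGTTCA"

#: Default probability per construct position of a spurious (background)
#: adapter ligation on a molecule; a free fixture parameter, not a measured
#: quantity.
DEFAULT_BACKGROUND_RATE = 0.001

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = {b: i for i, b in enumerate(DNA_BASES)}


# ---------------------------------------------------------------------------
# Library layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryLayout:
    """Geometry of the randomized-PAM plasmid insert.

    The top strand reads ``flank_left + t1 + N*randomized_length + t2 +
    flank_right``. The two fixed protospacer targets flank the randomized
    region on opposite sides so both possible PAM orientations (5' of T2 on
    the top strand, 5' of T1 on the bottom strand) are interrogated by one
    construct.

    Coordinates are 1-based. PAM positions are numbered ``-randomized_length
    .. -1`` walking 5' away from the protospacer; protospacer positions are
    ``1 .. L`` walking 3' from the PAM on the protospacer-bearing strand.
    """

    t1: str
    t2: str
    randomized_length: int = 7
    flank_left: str = "AGTGACCTGCAATCGTCAGT"
    flank_right: str = "TGACTTCGAGGACTTGGCAT"

    def __post_init__(self) -> None:
        if self.randomized_length < 1:
            raise ValueError("randomized_length must be >= 1")
        for name in ("t1", "t2", "flank_left", "flank_right"):
            object.__setattr__(self, name, validate_dna(getattr(self, name), name))

    # -- derived geometry ---------------------------------------------------

    @property
    def template(self) -> str:
        """Top-strand insert with the randomized region shown as ``N``s."""
        return (self.flank_left + self.t1 + "N" * self.randomized_length
                + self.t2 + self.flank_right)

    def molecule_sequence(self, pam: str) -> str:
        """Full top-strand sequence of a molecule with the given heptamer."""
        if len(pam) != self.randomized_length:
            raise ValueError(
                f"randomized region must be {self.randomized_length} nt, got {len(pam)}")
        return self.flank_left + self.t1 + pam + self.t2 + self.flank_right

    def oriented(self, target: str = "T2") -> "OrientedLayout":
        """Orientation-agnostic view with the PAM 5' of the chosen target.

        For ``T2`` this is the top strand as written; for ``T1`` it is the
        reverse complement of the construct, in which the T1 protospacer sits
        3' of the randomized region on the viewed strand.
        """
        if target not in ("T1", "T2"):
            raise ValueError("target must be 'T1' or 'T2'")
        if target == "T2":
            prefix = self.flank_left + self.t1
            proto_and_right = self.t2 + self.flank_right
        else:
            prefix = revcomp(self.flank_right + self.t2)
            proto_and_right = revcomp(self.flank_left + self.t1)
        return OrientedLayout(
            layout=self,
            target=target,
            prefix=prefix,
            proto_and_right=proto_and_right,
        )


@dataclass(frozen=True)
class OrientedLayout:
    """A :class:`LibraryLayout` viewed with the PAM 5' of one target."""

    layout: LibraryLayout
    target: str
    prefix: str            # viewed strand 5' of the randomized region
    proto_and_right: str   # protospacer + distal flank, 3' of the PAM

    @property
    def proto_start(self) -> int:
        """0-based index of protospacer position 1 on the viewed strand."""
        return len(self.prefix) + self.layout.randomized_length

    @property
    def n_positions(self) -> int:
        """Number of junction positions downstream of the PAM."""
        return len(self.proto_and_right)

    def oriented_pam(self, pam: str) -> str:
        """The randomized region read 5'->3' on the viewed strand."""
        return pam if self.target == "T2" else revcomp(pam)

    def molecule_sequence(self, pam: str) -> str:
        """Viewed-strand sequence of a molecule (``pam`` given in T2 frame)."""
        return self.prefix + self.oriented_pam(pam) + self.proto_and_right


@dataclass(frozen=True)
class LibraryMolecule:
    """One simulated plasmid molecule with its ground-truth randomized region."""

    index: int
    pam: str
    layout: LibraryLayout = field(repr=False)

    @property
    def sequence(self) -> str:
        return self.layout.molecule_sequence(self.pam)


class PamLibrary(Sequence):
    """A collection of :class:`LibraryMolecule` sharing one layout."""

    def __init__(self, layout: LibraryLayout, pams: list[str], seed: int | None):
        self.layout = layout
        self.pams = pams
        self.seed = seed

    def __len__(self) -> int:
        return len(self.pams)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [LibraryMolecule(j, self.pams[j], self.layout)
                    for j in range(*i.indices(len(self)))]
        return LibraryMolecule(i, self.pams[i], self.layout)

    def base_frequencies(self) -> pd.DataFrame:
        """Per-position base frequencies of the randomized region (T2 frame)."""
        L = self.layout.randomized_length
        counts = np.zeros((4, L), dtype=np.int64)
        codes = _encode_pams(self.pams, L)
        for j in range(L):
            counts[:, j] = np.bincount(codes[:, j], minlength=4)
        freq = counts / max(len(self), 1)
        return pd.DataFrame(freq, index=list(DNA_BASES), columns=range(-L, 0))


def _encode_pams(pams: Sequence[str], length: int) -> np.ndarray:
    """(n, L) uint8 base codes for a list of equal-length DNA strings."""
    if len(pams) == 0:
        return np.zeros((0, length), dtype=np.uint8)
    raw = np.frombuffer("".join(pams).encode("ascii"), dtype=np.uint8)
    codes = np.empty_like(raw)
    for base, code in _CODE_OF.items():
        codes[raw == ord(base)] = code
    return codes.reshape(len(pams), length)


def make_pam_library(layout: LibraryLayout, n_molecules: int,
                     seed: int | None = None) -> PamLibrary:
    """Draw ``n_molecules`` plasmids with independently uniform random
    randomized regions.

    Deterministic under a fixed seed; every molecule's full insert sequence is
    reconstructible from the layout plus its heptamer.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    rng = np.random.default_rng(seed)
    L = layout.randomized_length
    codes = rng.integers(0, 4, size=(n_molecules, L), dtype=np.uint8)
    big = _BASE_LUT[codes].tobytes().decode("ascii")
    pams = [big[i * L:(i + 1) * L] for i in range(n_molecules)]
    return PamLibrary(layout, pams, seed)


# ---------------------------------------------------------------------------
# Recognition and cut models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecognitionModel:
    """Per-position base-acceptance weights plus a global cleavage efficiency.

    A molecule is cleaved with probability ``efficiency * prod(weight[pos][base])``
    over the randomized positions (times ``topology_factor`` when the substrate
    is flagged linear rather than supercoiled). A strict consensus model has
    weights in {0, 1}.
    """

    weights: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    efficiency: float = 1.0
    topology_factor: float = 1.0

    def __post_init__(self) -> None:
        for val, name in ((self.efficiency, "efficiency"),
                          (self.topology_factor, "topology_factor")):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for pos, row in self.weights.items():
            if pos >= 0:
                raise ValueError(f"PAM positions are negative (-L..-1), got {pos}")
            for base, w in row.items():
                if base not in DNA_BASES:
                    raise ValueError(f"unknown base {base!r} at position {pos}")
                if not 0.0 <= w <= 1.0:
                    raise ValueError(f"weight for {base} at {pos} must be in [0, 1]")

    @classmethod
    def from_consensus(cls, iupac: str, efficiency: float = 1.0,
                       topology_factor: float = 1.0) -> "RecognitionModel":
        """Strict {0,1} model from an IUPAC string read 5'->3' (position -L..-1)."""
        iupac = iupac.upper()
        L = len(iupac)
        weights: dict[int, dict[str, float]] = {}
        for i, code in enumerate(iupac):
            if code not in SET_FOR_IUPAC:
                raise ValueError(f"unknown IUPAC code {code!r}")
            accepted = SET_FOR_IUPAC[code]
            if accepted == frozenset("ACGT"):
                continue
            pos = i - L
            weights[pos] = {b: (1.0 if b in accepted else 0.0) for b in DNA_BASES}
        return cls(weights=weights, efficiency=efficiency,
                   topology_factor=topology_factor)

    def weight_matrix(self, length: int) -> np.ndarray:
        """(4, L) weight array over bases x PAM positions -L..-1."""
        mat = np.ones((4, length))
        for pos, row in self.weights.items():
            j = pos + length
            if not 0 <= j < length:
                raise ValueError(
                    f"position {pos} outside randomized region of length {length}")
            for base, w in row.items():
                mat[_CODE_OF[base], j] = w
        return mat

    def acceptance_probability(self, pam: str) -> float:
        """Cleavage probability of one molecule (supercoiled substrate)."""
        L = len(pam)
        mat = self.weight_matrix(L)
        p = self.efficiency
        for j, base in enumerate(pam):
            p *= mat[_CODE_OF[base], j]
        return p

    def null(self) -> "RecognitionModel":
        """The matched empty-vector control: efficiency 0."""
        return dataclasses.replace(self, efficiency=0.0)


@dataclass(frozen=True)
class CutModel:
    """Per-strand distributions of the junction position downstream of the PAM.

    A position ``p`` means the strand is cut immediately after the ``p``-th
    protospacer nucleotide counting 3' from the PAM on the strand in question
    (1-based).
    """

    ts: Mapping[int, float]
    nts: Mapping[int, float]

    def __post_init__(self) -> None:
        for name, dist in (("ts", self.ts), ("nts", self.nts)):
            if not dist:
                raise ValueError(f"{name} distribution is empty")
            total = 0.0
            for pos, p in dist.items():
                if not (isinstance(pos, (int, np.integer)) and pos >= 1):
                    raise ValueError(f"{name} position {pos!r} must be a positive integer")
                if p < 0:
                    raise ValueError(f"{name} probability at {pos} is negative")
                total += p
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")

    @classmethod
    def cas12l_default(cls) -> "CutModel":
        """Staggered-cut defaults: TS mass at 23-24 (modal 24), NTS uniform 15-18."""
        return cls(ts={23: 0.35, 24: 0.65},
                   nts={15: 0.25, 16: 0.25, 17: 0.25, 18: 0.25})

    def validate_against(self, oriented: OrientedLayout) -> None:
        limit = oriented.n_positions
        for name, dist in (("TS", self.ts), ("NTS", self.nts)):
            for pos in dist:
                if pos > limit:
                    raise ValueError(
                        f"{name} cut position {pos} is outside the construct "
                        f"(max junction position {limit})")

    def _sampler(self, dist: Mapping[int, float]):
        positions = np.array(sorted(dist), dtype=np.int64)
        probs = np.array([dist[p] for p in positions], dtype=float)
        probs = probs / probs.sum()
        return positions, probs


# ---------------------------------------------------------------------------
# Cleavage simulation -> adapter-ligated junction reads
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReadSet:
    """Adapter-ligated junction reads plus their ground-truth manifest.

    ``reads`` columns: ``read_id, sequence, strand (TS/NTS), pam, cut_pos,
    source (cleavage/background)``. Reads are oriented so that every read
    spans from the library backbone through the randomized region to the
    adapter at the junction: NTS reads end with :data:`ADAPTER`, TS reads
    start with it (reverse-complement geometry).
    """

    layout: LibraryLayout
    target: str
    reads: pd.DataFrame
    seed: int | None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def n_cleaved_molecules(self) -> int:
        return int(self.provenance.get("n_cleaved", 0))

    def manifest(self) -> pd.DataFrame:
        return self.reads[["read_id", "strand", "pam", "cut_pos", "source"]].copy()

    def manifest_to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.manifest().to_csv(path, sep="\t", index=False)
        return path

    def _records(self) -> Iterable[SeqRecord]:
        for row in self.reads.itertuples(index=False):
            rec = SeqRecord(Seq(row.sequence), id=row.read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(row.sequence)
            yield rec

    def to_fastq(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            SeqIO.write(self._records(), fh, "fastq")
        return path

    def to_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            SeqIO.write(self._records(), fh, "fasta")
        return path


def simulate_cleavage(molecules: PamLibrary,
                      model: RecognitionModel,
                      cuts: CutModel,
                      background_rate: float = DEFAULT_BACKGROUND_RATE,
                      seed: int | None = None,
                      target: str = "T2",
                      linear_substrate: bool = False) -> SimulatedReadSet:
    """PAM-gated cleavage of a library followed by adapter ligation.

    Each molecule is cleaved with probability ``efficiency *
    prod(per-position base weights)`` (times the topology factor for linear
    substrates); a cleaved molecule yields one TS and one NTS junction read at
    positions drawn from ``cuts``. Independently, every molecule yields a
    spurious background junction at a uniform random position and strand with
    probability ``background_rate * n_positions``. A control set is obtained
    with ``model.null()`` (efficiency 0).
    """
    if not 0.0 <= background_rate < 1.0:
        raise ValueError("background_rate must be in [0, 1)")
    layout = molecules.layout
    oriented = layout.oriented(target)
    cuts.validate_against(oriented)

    rng = np.random.default_rng(seed)
    n = len(molecules)
    L = layout.randomized_length

    # cleavage gate, vectorized over molecules
    if n:
        codes = _encode_pams([oriented.oriented_pam(p) for p in molecules.pams], L)
        wmat = model.weight_matrix(L)
        probs = model.efficiency * np.prod(
            wmat[codes, np.arange(L)[None, :]], axis=1)
        if linear_substrate:
            probs = probs * model.topology_factor
        cleaved = rng.random(n) < probs
    else:
        cleaved = np.zeros(0, dtype=bool)
    idx_cleaved = np.flatnonzero(cleaved)

    ts_pos_all, ts_p = cuts._sampler(cuts.ts)
    nts_pos_all, nts_p = cuts._sampler(cuts.nts)
    ts_draw = rng.choice(ts_pos_all, size=idx_cleaved.size, p=ts_p)
    nts_draw = rng.choice(nts_pos_all, size=idx_cleaved.size, p=nts_p)

    # background junctions: one per molecule with prob rate * n_positions
    p_bg = background_rate * oriented.n_positions
    bg_mask = rng.random(n) < min(p_bg, 1.0) if n else np.zeros(0, dtype=bool)
    idx_bg = np.flatnonzero(bg_mask)
    bg_pos = rng.integers(1, oriented.n_positions + 1, size=idx_bg.size)
    bg_strand = rng.integers(0, 2, size=idx_bg.size)  # 0 = TS, 1 = NTS

    prefix = oriented.prefix
    proto_start = oriented.proto_start
    tail = oriented.proto_and_right

    def junction_read(pam_oriented: str, pos: int, strand: str) -> str:
        upstream = prefix + pam_oriented + tail[:pos]
        if strand == "NTS":
            return upstream + ADAPTER
        return ADAPTER + revcomp(upstream)

    read_ids, seqs, strands, pams_out, positions, sources = [], [], [], [], [], []
    counter = 0

    def emit(mol_idx: int, pos: int, strand: str, source: str) -> None:
        nonlocal counter
        pam = molecules.pams[mol_idx]
        read_ids.append(f"read{counter:08d}")
        seqs.append(junction_read(oriented.oriented_pam(pam), int(pos), strand))
        strands.append(strand)
        pams_out.append(pam)
        positions.append(int(pos))
        sources.append(source)
        counter += 1

    for k, mol_idx in enumerate(idx_cleaved):
        emit(mol_idx, ts_draw[k], "TS", "cleavage")
        emit(mol_idx, nts_draw[k], "NTS", "cleavage")
    for k, mol_idx in enumerate(idx_bg):
        emit(mol_idx, bg_pos[k], "TS" if bg_strand[k] == 0 else "NTS", "background")

    reads = pd.DataFrame({
        "read_id": read_ids,
        "sequence": seqs,
        "strand": strands,
        "pam": pams_out,
        "cut_pos": positions,
        "source": sources,
    })
    provenance = {
        "n_molecules": n,
        "n_cleaved": int(idx_cleaved.size),
        "n_background": int(idx_bg.size),
        "target": target,
        "efficiency": model.efficiency,
        "background_rate": background_rate,
        "seed": seed,
    }
    return SimulatedReadSet(layout=layout, target=target, reads=reads,
                            seed=seed, provenance=provenance)


# ---------------------------------------------------------------------------
# Synthetic tracrRNA locus
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLocus:
    """An intergenic region with embedded guide-RNA features plus an array."""

    sequence: str
    features: pd.DataFrame  # feature, start, end, strand, present, sequence
    repeat: str
    seed: int | None

    def feature(self, name: str) -> pd.Series:
        rows = self.features[self.features["feature"] == name]
        if rows.empty:
            raise KeyError(name)
        return rows.iloc[0]

    @property
    def intergenic(self) -> str:
        """The tracrRNA-bearing portion 5' of the repeat-spacer array.

        Anti-repeat and conserved-block scans should run on this region:
        the array's own repeat copies trivially complement the repeat.
        """
        array_start = int(self.feature("crispr_array")["start"])
        return self.sequence[: array_start - 1]

    def to_fasta(self, path: str | Path, record_id: str = "synthetic_locus") -> Path:
        path = Path(path)
        SeqIO.write([SeqRecord(Seq(self.sequence), id=record_id, description="")],
                    path, "fasta")
        return path

    def features_to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.features.to_csv(path, sep="\t", index=False)
        return path


def _random_dna(rng: np.random.Generator, n: int,
                p: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> str:
    if n == 0:
        return ""
    codes = rng.choice(4, size=n, p=np.asarray(p) / np.sum(p))
    return _BASE_LUT[codes].tobytes().decode("ascii")


def make_synthetic_locus(repeat: str,
                         n_spacers: int = 4,
                         anti_repeat_span: tuple[int, int] = (1, 13),
                         conserved_block: str = "",
                         seed: int | None = None,
                         hairpin_arm_len: int = 8,
                         hairpin_loop_len: int = 4,
                         spacer_len: int = 32) -> SyntheticLocus:
    """Emit an intergenic sequence with tracrRNA evidence plus a repeat-spacer
    array, with ground-truth coordinates (1-based, closed intervals).

    The intergenic portion embeds, 5'->3': the conserved block, the reverse
    complement of the chosen repeat span (the anti-repeat), and a GC-rich
    inverted repeat forming a terminator-like hairpin. Empty
    ``conserved_block`` or zero-length hairpin arms are permitted; the feature
    table then marks those features absent.
    """
    repeat = validate_dna(repeat, "repeat")
    conserved_block = validate_dna(conserved_block, "conserved_block",
                                   allow_empty=True)
    start_in_repeat, span_len = anti_repeat_span
    if span_len < 1 or start_in_repeat < 1:
        raise ValueError("anti_repeat_span must be 1-based with positive length")
    if start_in_repeat + span_len - 1 > len(repeat):
        raise ValueError(
            f"repeat ({len(repeat)} nt) shorter than requested span "
            f"{start_in_repeat}+{span_len}-1")
    if n_spacers < 1:
        raise ValueError("n_spacers must be >= 1")
    rng = np.random.default_rng(seed)

    repeat_span = repeat[start_in_repeat - 1: start_in_repeat - 1 + span_len]
    anti_repeat = revcomp(repeat_span)

    gc_bias = (0.1, 0.4, 0.4, 0.1)  # A, C, G, T
    left_arm = _random_dna(rng, hairpin_arm_len, gc_bias)
    loop = _random_dna(rng, hairpin_loop_len if hairpin_arm_len else 0)
    right_arm = revcomp(left_arm)

    pad1 = _random_dna(rng, 30)
    pad2 = _random_dna(rng, 10)
    pad3 = _random_dna(rng, 20)
    gap = _random_dna(rng, 40)
    if hairpin_arm_len:
        # non-pairing flanks so the embedded stem cannot extend outward by
        # chance and ground-truth coordinates stay exact
        pad2 = pad2[:-1] + "A"
        pad3 = "A" + pad3[1:]

    parts: list[tuple[str, str, bool]] = [
        ("pad", pad1, False),
        ("conserved_block", conserved_block, bool(conserved_block)),
        ("anti_repeat", anti_repeat, True),
        ("pad", pad2, False),
        ("terminator_hairpin", left_arm + loop + right_arm, bool(hairpin_arm_len)),
        ("pad", pad3, False),
        ("gap", gap, False),
    ]
    spacers = [_random_dna(rng, spacer_len) for _ in range(n_spacers)]
    array_seq = repeat + "".join(s + repeat for s in spacers)

    seq_parts: list[str] = []
    rows: list[dict] = []
    cursor = 0

    def push(name: str, s: str, present: bool, record: bool = True) -> None:
        nonlocal cursor
        seq_parts.append(s)
        if record and name not in ("pad", "gap"):
            rows.append({
                "feature": name,
                "start": cursor + 1 if s else pd.NA,
                "end": cursor + len(s) if s else pd.NA,
                "strand": "+",
                "present": present,
                "sequence": s,
            })
        cursor += len(s)

    for name, s, present in parts:
        push(name, s, present)

    array_start = cursor
    push("crispr_array", array_seq, True)
    # per-unit coordinates within the array
    unit_cursor = array_start
    for i in range(n_spacers + 1):
        rows.append({"feature": f"repeat_{i + 1}", "start": unit_cursor + 1,
                     "end": unit_cursor + len(repeat), "strand": "+",
                     "present": True, "sequence": repeat})
        unit_cursor += len(repeat)
        if i < n_spacers:
            rows.append({"feature": f"spacer_{i + 1}", "start": unit_cursor + 1,
                         "end": unit_cursor + spacer_len, "strand": "+",
                         "present": True, "sequence": spacers[i]})
            unit_cursor += spacer_len

    features = pd.DataFrame(rows, columns=["feature", "start", "end", "strand",
                                           "present", "sequence"])
    features["start"] = features["start"].astype("Int64")
    features["end"] = features["end"].astype("Int64")
    return SyntheticLocus(sequence="".join(seq_parts), features=features,
                          repeat=repeat, seed=seed)


# ---------------------------------------------------------------------------
# Kinetic / binding datasets
# ---------------------------------------------------------------------------

KINETIC_DESIGNS = ("gel_timecourse", "fq_trace", "mm_velocity", "binding_titration")


def simulate_kinetics(params: Mapping[str, float],
                      design: str,
                      noise_sd: float = 0.0,
                      seed: int | None = None,
                      grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Generate a kinetic trace or titration table from the exact closed forms.

    Designs and their parameters (all concentrations molar, time in seconds):

    * ``gel_timecourse`` / ``fq_trace``: single exponential association
      ``A * (1 - exp(-k t))`` with ``A`` a percent amplitude in [0, 100] and
      ``k >= 0`` (s^-1); columns ``time_s, signal``.
    * ``mm_velocity``: Michaelis-Menten initial velocities on a substrate
      grid (defaults to the reporter concentrations 0.001-2 uM) with either
      ``vmax`` or ``kcat`` + ``enzyme_conc``, and ``km > 0``; columns
      ``conc_M, v0_M_per_s``.
    * ``binding_titration``: tight-binding quadratic isotherm with ``kd >= 0``
      and substrate ``s > 0``; columns ``conc_M, bound_M``.

    ``noise_sd = 0`` gives analytically exact values; otherwise i.i.d.
    Gaussian noise of that SD (signal units) is added.
    """
    if design not in KINETIC_DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {KINETIC_DESIGNS}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    if design in ("gel_timecourse", "fq_trace"):
        A = float(params["A"])
        k = float(params["k"])
        if not 0.0 <= A <= 100.0:
            raise ValueError("amplitude A must be in [0, 100] (percent)")
        if k < 0:
            raise ValueError("rate k must be >= 0")
        if grid is None:
            grid = (np.arange(0, 1801, 60) if design == "gel_timecourse"
                    else np.arange(0, 3601, 30))
        t = np.asarray(grid, dtype=float)
        y = _kin.exponential_association(t, A, k)
        if noise_sd:
            y = y + rng.normal(0.0, noise_sd, size=t.shape)
        return pd.DataFrame({"time_s": t, "signal": y})

    if design == "mm_velocity":
        km = float(params["km"])
        if km <= 0:
            raise ValueError("km must be > 0")
        if "vmax" in params:
            vmax = float(params["vmax"])
        else:
            vmax = float(params["kcat"]) * float(params["enzyme_conc"])
        if vmax < 0:
            raise ValueError("vmax must be >= 0")
        X = np.asarray(_kin.REPORTER_CONCENTRATIONS_M if grid is None else grid,
                       dtype=float)
        if np.any(X <= 0):
            raise ValueError("substrate concentrations must be > 0")
        v = _kin.michaelis_menten(X, vmax, km)
        if noise_sd:
            v = v + rng.normal(0.0, noise_sd, size=X.shape)
        return pd.DataFrame({"conc_M": X, "v0_M_per_s": v})

    # binding_titration
    kd = float(params["kd"])
    S = float(params.get("s", _kin.EMSA_SUBSTRATE_CONC_M))
    if kd < 0:
        raise ValueError("kd must be >= 0")
    if S <= 0:
        raise ValueError("substrate concentration s must be > 0")
    x = np.asarray(np.logspace(-10.5, -7.0, 12) if grid is None else grid,
                   dtype=float)
    y = _kin.binding_isotherm(x, kd, S)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return pd.DataFrame({"conc_M": x, "bound_M": y})
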