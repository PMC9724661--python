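# Methods

`caskit` re-implements, as a tested library, the desk-side computational
workflow used when a new class 2 CRISPR nuclease is characterized
biochemically: randomized-PAM library cleavage analysis (cut-site mapping and
PAM consensus inference), tracrRNA/sgRNA discovery from locus sequence,
cleavage and collateral-nuclease kinetics, and operon-geometry triage of
candidate loci. Because the raw sequencing and fluorescence data behind such
a study are not reproducible at desk scale, a first-class synthetic-data
module generates every input with known ground truth; the analysis modules
are validated by round-tripping against that ground truth and against
independent brute-force oracles.

## The randomized-PAM library model

The simulated plasmid insert is `flank_left + T1 + N7 + T2 + flank_right`:
a fully randomized region (default 7 nt) flanked by two fixed protospacer
targets in opposite orientations, so a single construct interrogates both
possible PAM placements (5′ of T2 on the top strand, 5′ of T1 on the
bottom strand). Coordinates are 1-based; PAM positions are numbered −L..−1
walking 5′ away from the protospacer and protospacer positions 1..L walking
3′ from the PAM on the strand in question. Analyses default to the T2
orientation; the T1 orientation is generated by the same code path on the
reverse complement and serves as a negative control.

**Recognition model.** A molecule is cleaved with probability
`efficiency × Π_p w_p(base_p)` over the randomized positions, where each
weight lies in [0, 1]. A strict consensus (weights in {0, 1}) built from an
IUPAC string reproduces motif-gated cleavage exactly: under `NNNNCCY`,
512/16384 = 3.125 % of a uniform library is cleavable (verified by full
enumeration). Substrate topology enters only as a single multiplicative
`topology_factor` applied to molecules flagged linear — a scalar efficiency
knob, not a DNA-mechanics model.

**Cut model.** Cleavage positions are junctions "after the p-th nucleotide
downstream of the PAM, on the strand in question". The default staggered-cut
distribution puts target-strand (TS) mass on {23: 0.35, 24: 0.65} — peaks
after the 23rd and 24th positions with the mode at 24 — and nontarget-strand
(NTS) mass uniformly on {15, 16, 17, 18}. The exact empirical frequencies
behind the published ligation profiles are not printed anywhere, so these
two distributions are the package's own defaults, chosen once to reproduce
the reported peak windows and modal position.

**Read geometry.** Each cleaved molecule emits one TS and one NTS junction
read. Reads emulate the enrichment amplicon of the adapter-ligation
protocol: they span from the library backbone through the randomized region
to the adapter at the junction (NTS reads are a top-strand prefix ending in
the adapter; TS reads start with the adapter followed by the reverse
complement of the PAM-side fragment). This makes every mapped read carry
both its junction position and its PAM k-mer, which is what lets the PAM
step reuse the cut-site mapping. PCR amplification bias and sequencing
errors are not simulated (the analyses operate on post-trimming reads); a
uniform spurious-ligation background stands in for everything the
empty-vector control is meant to absorb. Every molecule yields one
background junction at a uniform random position and strand with probability
`0.001 × n_positions` per molecule; the 0.001/position default is a fixture
parameter, not a measured value.

**What passing tests show.** Round-trip tests demonstrate that the mapping,
peak-calling and consensus machinery is internally correct under the stated
noise model. They do not exercise read-level error modes, library synthesis
bias, or alignment to imperfect references — real sequencing data would need
a trimming/alignment front end that is deliberately out of scope.

## Cut-site calling

Per-strand ligation profiles are junction counts normalized per strand. A
position is called a cleavage peak when its target frequency is at least
`min_fraction` (default 0.01) and its enrichment over the control profile is
at least `min_enrichment` (default 5). Enrichment uses a Laplace-style guard:
`target_freq / (control_freq + 1/(control_reads + P))` with `P` the number
of positions, so an empty control cell never divides by zero. The published
analysis says only "elevated frequency"; both thresholds are configurable
and echoed in every report. The modal position maximizes target frequency
among peaks; exact ties break toward the PAM-proximal (smaller) position
with an explicit warning flag. A call with no passing position is an
explicit "no cleavage detected" value — the CLI maps it to exit status 3,
distinct from failure.

With background-only data at very small read counts (a few reads per
position) Poisson fluctuation can clear both thresholds; the defaults are
calibrated for libraries of tens of thousands of molecules, where the
matched control suppresses the background exactly.

**Overhang geometry.** For a TS cut at `t` and an NTS cut at `n` (both
PAM-anchored on their own strand) the overhang length is `t − n`; positive
lengths are 5′ overhangs, zero is blunt, negative are 3′. Min/max run over
the peak windows: TS {23, 24} × NTS {15–18} gives 5–9 nt 5′ overhangs.

## PAM inference

Reads whose junction falls inside a peak window contribute their randomized
k-mer (read 5′→3′ on the protospacer-bearing strand, positions −7..−1). The
position frequency matrix adds a Jeffreys-style pseudocount of 0.5 per cell
before normalizing; the background is the empirical starting-library
composition when available (mirroring a depletion-style correction), else
uniform. Per-position information is the relative entropy
`Σ_b f_b log2(f_b / g_b)` in bits: 2 bits for a fixed base, 1 bit for a
two-base set, ≈0 at unconstrained positions. The IUPAC consensus includes
bases per position in decreasing frequency until the cumulative frequency
reaches `include_threshold` (default 0.85, chosen so that a uniform
position needs all four bases → N, while two- and three-base sets at
realistic contamination levels map to their exact code). Whether published
logos show raw or background-normalized frequencies is ambiguous, so both
tables are emitted (TSV matrix, MEME minimal motif, JSON report; optional
matplotlib logo).

## Guide-RNA discovery

Anti-repeat search finds, on both strands, the longest contiguous segments
whose reverse complement matches any repeat substring with at most
`max_mismatches` (default `min_len // 12`, i.e. ~1 per 12 bases — the
tolerance is not stated anywhere, so it is exposed). Complementarity is
DNA-level Watson–Crick only; no G·U wobble, because the anti-repeat is
identified at the DNA locus level. Conserved blocks are exact maximal common
substrings across loci. Hairpin calls are pure inverted-repeat geometry — a
stem of ≥ `min_stem` perfect pairs around a loop of 3–12 nt, grown
maximally outward per loop placement, ranked by stem length then stem GC —
deliberately not a thermodynamic folding prediction; the secondary-structure
tool behind the original annotations is unnamed, so free-energy folding is a
non-goal and the geometric scan is a stand-in, not a reproduction. All three
detectors are tested against brute-force oracles on sequences up to 500 nt.

sgRNAs are assembled as `[5′ region +] tracr 3′ end [+ terminator hairpin]
+ GAAA tetraloop + repeat 5′ end + spacer`, converted to RNA. Variants 1–4
toggle the unstructured 5′ region and the terminator-like hairpin
(1: +5′/−hairpin, 2: −5′/−hairpin, 3: +5′/+hairpin, 4: −5′/+hairpin); the
exact truncation points are configurable because they are not printed.
Spacers are restricted to the screened 18–24 nt range; variant 1 with a
20-nt spacer is the preferred design.

## Kinetics and binding

All closed forms are implemented exactly as printed:

* gel densitometry: `fraction cleaved (%) = 100 · Ip / (Ip + Is)`;
* capillary electrophoresis: the same ratio over peak areas after dropping
  peaks below 50 RFU;
* exponential association: `A (1 − e^{−kt})`, fitted with `A` bounded to
  the data range and `k ≥ 0`; a flat-zero trace returns `A = 0` with a
  degeneracy flag rather than a meaningless rate;
* FQ conversion: `c_cl = (F_t − F_uncl(c0)) / (S_cl − S_ucl)`. The printed
  formula omits intercepts; standard curves are fitted as full lines and the
  uncleaved line is evaluated at `c0`, which reduces to the printed form
  when intercepts are equal. Converted concentrations are clipped to
  `[0, c0]` with clip events counted; indistinguishable slopes raise
  (the reporter does not resolve quenching);
* Michaelis–Menten: `v = Vmax·X/(KM+X)`, `kcat = Vmax/E` with
  `E = 0.1 nM`, efficiency `kcat/KM`. Initial velocities from raw traces
  use a linear fit over the first max(5, 10 %) points with its R² reported;
* tight binding: `bound = ½[(Kd+x+S) − √((Kd+x+S)² − 4xS)]` with
  `S = 2 nM`, preceded by the intensity conversion
  `c_bound = I_b/(I_b+I_f) · c0`.

Numerical choices: all fits are bounded least squares (`scipy`) with a
three-point multi-start on the rate/KM/Kd guess to avoid local minima, and
inputs are internally rescaled to O(1) (velocities by their maximum,
binding by S) so convergence is exact at molar magnitudes — noise-free data
are recovered to better than 1e-6 relative across randomized parameters.
When every substrate concentration sits far below the fitted KM the fit is
flagged `km_unidentifiable`; the efficiency (the identifiable ratio) is
still reported. KM values for the recovery fixtures are derived from the
published constants as `kcat ÷ (kcat/KM)` because KM itself is not printed.

## Locus triage

Candidate selection applies the published geometry rules to pre-annotated
contigs: within 20 kb of a CRISPR array (clipped at contig ends, with a
truncation flag), cas1 and cas2 must both be present, and an unknown-label
gene of ≥ 1,500 bp must lie on the same strand as both and within
`max_gap_bp` of the nearer one. "Close to" is quantified as 5,000 bp by
default — no number is printed for it — and every rejection carries a
machine-readable reason. Homology labelling (the profile searches that
assign cas1/cas2) is upstream and out of scope. The filter is monotone by
construction: raising the ORF threshold never adds candidates, widening the
window never removes them; both properties are tested on randomized loci.

## Problem sizes

The test suite and the acceptance script run the library pipeline at
220,000–330,000 molecules, sized so that strict CCY/CCB gating yields about
10,000 cleaved molecules (≥ 20,000 junction reads); consensus-recovery
property tests size each run as `⌈5500 / acceptance fraction⌉` molecules so
every random model is tested at ≥ 5,000 cleaved molecules. Kinetic recovery
uses the seven-point reporter grid (0.001–2 μM; eight points including
0.05 μM for the comparator enzyme). Everything is seeded; identical inputs
and seed give byte-identical outputs (images excepted).

## Known limitations

* No read-level error model, no PCR/synthesis bias, no demultiplexing or
  quality trimming: real FASTQ data must be pre-trimmed and must match the
  declared layout exactly.
* Hairpin and anti-repeat detection are sequence-geometric; they will not
  reproduce folding-based structure panels.
* The topology knob is phenomenological; temperature and supercoiling are
  not modelled mechanistically.
* The binding fit reports a residual-variance confidence interval, which is
  degenerate (width → 0) on noise-free data.
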