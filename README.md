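# caskit

A characterization toolkit for class 2 CRISPR nucleases, built for
biochemists and computational biologists who analyze randomized-PAM library
cleavage experiments, hunt for tracrRNAs in locus sequence, fit cleavage and
collateral-nuclease kinetics, and triage candidate CRISPR operons. It was
written around the workflow used to characterize compact type V effectors
with C-rich PAM recognition (Cas12l-like systems), but every stage is
parameterized and reusable.

Because the raw deep-sequencing and fluorescence data behind such studies
are not desk-reproducible, the package includes a first-class, seeded
synthetic-data module that generates every input with known ground truth —
PAM-library reads, empty-vector controls, guide-RNA loci and kinetic
datasets — which is also how the test suite validates the analysis code.

## What it computes

**PAM-library cleavage analysis.** A plasmid library carries a fully
randomized region (7N by default) flanked by two fixed protospacer targets.
Cleavage products are captured by adapter ligation; the per-position
ligation frequency on each strand, compared against an empty-vector
control, reveals where the nuclease cuts. For a target-strand (TS) cut at
position *t* and nontarget-strand (NTS) cut at *n* (both counted 3′ of the
PAM on their own strand), the overhang length is *t − n* (positive = 5′
overhang). Reads supporting the cleavage peaks yield the PAM k-mers, which
are summarized as a position frequency matrix with per-position information
content (relative entropy vs the starting-library background, in bits) and
an IUPAC consensus.

**Guide-RNA discovery.** Anti-repeat detection (longest complement of the
CRISPR repeat in the locus, with a mismatch budget), maximal conserved
blocks across loci, inverted-repeat hairpin calls, and sgRNA assembly
(tracrRNA 3′ end + 5′-GAAA-3′ tetraloop + repeat 5′ end + 18–24 nt spacer).

**Kinetics and binding.** Gel and capillary-electrophoresis
fraction-cleaved, single-exponential association *A*(1 − e^(−kt)),
fluorophore-quencher standard-curve conversion, Michaelis–Menten fits with
k_cat = V_max/E and catalytic efficiency k_cat/K_M, and the tight-binding
quadratic isotherm for K_d from mobility-shift titrations.

**Locus triage.** The operon-geometry filter for new candidate systems:
cas1 + cas2 within 20 kb of a CRISPR array plus a ≥ 1,500 bp unknown ORF on
the same strand nearby, with machine-readable rejection reasons.

## Worked example

```python
import caskit as ck

layout = ck.LibraryLayout(t1="GCCTAAGTCAGGATCAATCCGTTGCAGGTA",
                          t2="CTGATGGTCCATGTCTGTTACTCGCCTGTA")
lib = ck.make_pam_library(layout, 50_000, seed=7)
model = ck.RecognitionModel.from_consensus("NNNNCCY")   # strict C-rich PAM
cuts = ck.CutModel.cas12l_default()                     # TS 23-24, NTS 15-18

reads = ck.simulate_cleavage(lib, model, cuts, seed=8)
control = ck.simulate_cleavage(lib, model.null(), cuts, seed=9)
mapped = ck.map_adapter_junctions(reads, layout)
ctrl = ck.map_adapter_junctions(control, layout)
ts = ck.call_cut_sites(mapped.profiles["TS"], ctrl.profiles["TS"])
nts = ck.call_cut_sites(mapped.profiles["NTS"], ctrl.profiles["NTS"])
ov = ck.compute_overhang(ts, nts)

kmers = ck.extract_pam_kmers(reads, layout, {"TS": ts, "NTS": nts},
                             mapping=mapped)
matrix = ck.build_pam_matrix(kmers,
                             background=ck.background_from_library(lib))
consensus = ck.call_consensus(matrix)

print(f"cleaved molecules: {reads.n_cleaved_molecules} / {len(lib)}")
print(f"TS peaks {ts.peak_positions}, modal {ts.modal_position}")
print(f"NTS peaks {nts.peak_positions}")
print(f"overhang {ov.min_length}-{ov.max_length} nt, {ov.polarity}")
print(f"PAM consensus: {consensus.iupac} (trimmed: {consensus.trimmed})")
```

Output:

```
cleaved molecules: 1623 / 50000
TS peaks (23, 24), modal 24
NTS peaks (15, 16, 17, 18)
overhang 5-9 nt, 5prime
PAM consensus: NNNNCCY (trimmed: CCY)
```

Only about 3 % of the library is cleaved — exactly the fraction of uniform
7-mers satisfying a strict CCY rule (512/16384) — and the called cut
windows reconstruct the 5–9 nt 5′-staggered end. A kinetics example:

```python
table = ck.simulate_kinetics({"kcat": 0.44, "enzyme_conc": 1e-10,
                              "km": 6.769e-7}, "mm_velocity")
fit = ck.fit_michaelis_menten(table["conc_M"], table["v0_M_per_s"], 1e-10)
print(f"kcat = {fit.kcat:.3f} /s, KM = {fit.km*1e6:.3f} uM, "
      f"kcat/KM = {fit.efficiency:.3g} /M/s")
```

```
kcat = 0.440 /s, KM = 0.677 uM, kcat/KM = 6.5e+05 /M/s
```

The velocities are noise-free values of the Michaelis–Menten closed form on
the collateral-assay reporter grid (0.001–2 μM at E = 0.1 nM); the fit
recovers the generating turnover and efficiency to optimizer precision.

## Command line

The same pipeline is scriptable via the `caskit` CLI
(`simulate`, `map`, `pam`, `guide`, `kinetics`, `locus`, `all`):

```bash
caskit all --seed 7 --out runs/demo          # simulate -> map -> consensus
caskit kinetics --table v0.tsv --design michaelis_menten --out runs/kin
```

Every run directory contains a `MANIFEST.json` with the fully resolved
configuration, seed and package version, plus a line-delimited JSON log.
Exit status 3 means "no cleavage detected" — a valid scientific result —
as opposed to a runtime failure.

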