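import numpy as np
import pandas as pd
import pytest

import caskit as ck

T1 = "GCCTAAGTCAGGATCAATCCGTTGCAGGTA"
T2 = "CTGATGGTCCATGTCTGTTACTCGCCTGTA"
REPEAT = "GTTGCAAGGGATTGAGCCCCGTAAGGGGATTGCGAC"
CONSERVED_17 = "ACGGTTCACCGTGGCAA"


@pytest.fixture
def layout() -> ck.LibraryLayout:
    return ck.LibraryLayout(t1=T1, t2=T2)


@pytest.fixture
def cut_model() -> ck.CutModel:
    return ck.CutModel.cas12l_default()


@pytest.fixture
def run_pam_pipeline(layout, cut_model):
    """Factory running simulate -> map -> call -> extract -> consensus."""

    def _run(consensus: str, n_molecules: int, seed: int,
             background_rate: float = 0.001, efficiency: float = 1.0,
             cuts: ck.CutModel | None = None,
             include_threshold: float = 0.85) -> dict:
        cuts = cuts or cut_model
        lib = ck.make_pam_library(layout, n_molecules, seed=seed)
        model = ck.RecognitionModel.from_consensus(consensus,
                                                   efficiency=efficiency)
        reads = ck.simulate_cleavage(lib, model, cuts,
                                     background_rate=background_rate,
                                     seed=seed + 1)
        control = ck.simulate_cleavage(lib, model.null(), cuts,
                                       background_rate=background_rate,
                                       seed=seed + 2)
        mapped = ck.map_adapter_junctions(reads, layout)
        mapped_control = ck.map_adapter_junctions(control, layout)
        calls = {}
        for s in ("TS", "NTS"):
            ctrl = mapped_control.profiles[s]
            if ctrl.n_reads == 0:  # zero-background runs: flat prior control
                ctrl = ck.LigationProfile.uniform_prior(
                    s, mapped.profiles[s].n_positions)
            calls[s] = ck.call_cut_sites(mapped.profiles[s], ctrl)
        out = {"library": lib, "reads": reads, "control": control,
               "mapped": mapped, "mapped_control": mapped_control,
               "calls": calls, "consensus": None, "matrix": None}
        active = {s: c for s, c in calls.items() if not c.no_cleavage}
        if active:
            kmers = ck.extract_pam_kmers(reads, layout, active, mapping=mapped)
            matrix = ck.build_pam_matrix(
                kmers, background=ck.background_from_library(lib))
            out["matrix"] = matrix
            out["consensus"] = ck.call_consensus(
                matrix, include_threshold=include_threshold)
        return out

    return _run


def random_annotated_locus(rng: np.random.Generator) -> ck.AnnotatedLocus:
    """A random contig with one array and a handful of labelled genes."""
    length = 50_000
    array_start = int(rng.integers(5_000, 40_000))
    arrays = pd.DataFrame([{"start": array_start, "end": array_start + 600,
                            "repeat": REPEAT, "n_spacers": 6}])
    labels = ["cas1", "cas2", "cas4"] + ["unknown"] * int(rng.integers(1, 4)) \
        + ["other"] * int(rng.integers(0, 3))
    rows = []
    for i, label in enumerate(labels):
        start = int(rng.integers(1, length - 4000))
        glen = int(rng.integers(300, 3500))
        rows.append({"id": f"g{i}", "start": start, "end": start + glen,
                     "strand": rng.choice(["+", "-"]), "label": label})
    return ck.AnnotatedLocus("c", length, pd.DataFrame(rows), arrays)
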