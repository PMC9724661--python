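"""Simulator unit tests: library composition, cleavage gating, locus and
kinetic generators, seed determinism."""
import itertools

import numpy as np
import pandas as pd
import pytest

import caskit as ck
from caskit import synthetic_data as sd
from caskit.sequtils import revcomp

from conftest import CONSERVED_17, REPEAT


def brute_force_accepted_fraction(consensus: str) -> float:
    """Enumerate all 4^L randomized regions against a strict IUPAC rule."""
    from caskit.sequtils import SET_FOR_IUPAC
    sets = [SET_FOR_IUPAC[c] for c in consensus]
    n_accept = sum(
        all(b in s for b, s in zip(kmer, sets))
        for kmer in itertools.product("ACGT", repeat=len(consensus)))
    return n_accept / 4 ** len(consensus)


class TestMakePamLibrary:
    def test_empty_library(self, layout):
        lib = ck.make_pam_library(layout, 0, seed=1)
        assert len(lib) == 0

    def test_randomized_region_length_is_seven(self, layout):
        lib = ck.make_pam_library(layout, 50, seed=1)
        assert all(len(m.pam) == 7 for m in lib)
        assert layout.randomized_length == 7

    def test_base_frequencies_within_binomial_bound(self, layout):
        n = 20_000
        lib = ck.make_pam_library(layout, n, seed=3)
        freqs = lib.base_frequencies().to_numpy()
        sd5 = 5 * np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(freqs - 0.25) < sd5)

    def test_molecule_sequence_reconstructible(self, layout):
        lib = ck.make_pam_library(layout, 5, seed=2)
        for mol in lib:
            assert mol.sequence == layout.molecule_sequence(mol.pam)
            assert mol.pam in mol.sequence

    def test_seed_determinism(self, layout):
        a = ck.make_pam_library(layout, 1000, seed=11)
        b = ck.make_pam_library(layout, 1000, seed=11)
        assert a.pams == b.pams
        c = ck.make_pam_library(layout, 1000, seed=12)
        assert a.pams != c.pams

    def test_negative_count_rejected(self, layout):
        with pytest.raises(ValueError):
            ck.make_pam_library(layout, -1, seed=0)

    def test_non_acgt_layout_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            ck.LibraryLayout(t1="ACGTX", t2="ACGT")


class TestSimulateCleavage:
    def test_zero_activity_control(self, layout, cut_model):
        lib = ck.make_pam_library(layout, 500, seed=1)
        model = ck.RecognitionModel.from_consensus("NNNNCCY", efficiency=0.0)
        silent = ck.simulate_cleavage(lib, model, cut_model,
                                      background_rate=0.0, seed=2)
        assert len(silent) == 0
        noisy = ck.simulate_cleavage(lib, model, cut_model,
                                     background_rate=0.01, seed=2)
        assert len(noisy) > 0
        assert set(noisy.reads["source"]) == {"background"}

    def test_strict_ccy_cleaved_fraction_matches_enumeration(self, layout,
                                                             cut_model):
        expected = brute_force_accepted_fraction("NNNNCCY")
        assert expected == 512 / 16384  # 3.125 %
        n = 60_000
        lib = ck.make_pam_library(layout, n, seed=5)
        model = ck.RecognitionModel.from_consensus("NNNNCCY")
        rs = ck.simulate_cleavage(lib, model, cut_model,
                                  background_rate=0.0, seed=6)
        frac = rs.n_cleaved_molecules / n
        sd5 = 5 * np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < sd5

    def test_degenerate_cut_distribution_round_trip(self, layout):
        cuts = ck.CutModel(ts={10: 1.0}, nts={4: 1.0})
        lib = ck.make_pam_library(layout, 300, seed=7)
        rs = ck.simulate_cleavage(lib, ck.RecognitionModel(), cuts,
                                  background_rate=0.0, seed=8)
        mapped = ck.map_adapter_junctions(rs, layout)
        ts = mapped.assignments.query("strand == 'TS'")["position"]
        assert set(ts) == {10}

    def test_cut_position_outside_construct_named_in_error(self, layout):
        far = layout.oriented("T2").n_positions + 5
        cuts = ck.CutModel(ts={far: 1.0}, nts={4: 1.0})
        lib = ck.make_pam_library(layout, 10, seed=1)
        with pytest.raises(ValueError, match=str(far)):
            ck.simulate_cleavage(lib, ck.RecognitionModel(), cuts, seed=2)

    def test_background_rate_validation(self, layout, cut_model):
        lib = ck.make_pam_library(layout, 10, seed=1)
        with pytest.raises(ValueError):
            ck.simulate_cleavage(lib, ck.RecognitionModel(), cut_model,
                                 background_rate=1.5, seed=2)

    def test_seed_determinism_byte_identical(self, layout, cut_model):
        lib = ck.make_pam_library(layout, 2000, seed=1)
        model = ck.RecognitionModel.from_consensus("NNNNCCY")
        a = ck.simulate_cleavage(lib, model, cut_model, seed=9)
        b = ck.simulate_cleavage(lib, model, cut_model, seed=9)
        assert a.reads.to_csv() == b.reads.to_csv()

    def test_t1_orientation_reads_map_in_t1_frame(self, layout, cut_model):
        lib = ck.make_pam_library(layout, 3000, seed=13)
        model = ck.RecognitionModel.from_consensus("NNNNCCY")
        rs = ck.simulate_cleavage(lib, model, cut_model, seed=14, target="T1")
        mapped = ck.map_adapter_junctions(rs, layout, target="T1")
        assert mapped.n_unmapped == 0
        # in the T1 frame the gating PAM is the revcomp of the stored heptamer
        truth = rs.reads.query("source == 'cleavage'")
        assert all(revcomp(p).endswith(("CCC", "CCT"))
                   for p in truth["pam"].head(50))

    def test_linear_topology_factor_reduces_cleavage(self, layout, cut_model):
        lib = ck.make_pam_library(layout, 30_000, seed=15)
        model = ck.RecognitionModel(efficiency=1.0, topology_factor=0.2)
        sc = ck.simulate_cleavage(lib, model, cut_model,
                                  background_rate=0.0, seed=16)
        lin = ck.simulate_cleavage(lib, model, cut_model, background_rate=0.0,
                                   seed=16, linear_substrate=True)
        assert lin.n_cleaved_molecules < 0.5 * sc.n_cleaved_molecules


class TestSyntheticLocus:
    def test_anti_repeat_ground_truth_length(self):
        loc = ck.make_synthetic_locus(REPEAT, anti_repeat_span=(24, 13), seed=1)
        ar = loc.feature("anti_repeat")
        assert int(ar["end"]) - int(ar["start"]) + 1 == 13
        # the embedded segment is the revcomp of the chosen repeat span
        assert ar["sequence"] == revcomp(REPEAT[23:36])

    def test_conserved_block_recovered_across_loci(self):
        seqs = [ck.make_synthetic_locus(REPEAT, conserved_block=CONSERVED_17,
                                        anti_repeat_span=(24, 13),
                                        seed=100 + i).intergenic
                for i in range(4)]
        blocks = ck.find_conserved_blocks(seqs)
        top = blocks[0]
        assert top.identity == 100.0
        assert CONSERVED_17 in top.sequence
        assert top.length >= 17

    def test_feature_omission(self):
        loc = ck.make_synthetic_locus(REPEAT, conserved_block="",
                                      hairpin_arm_len=0, seed=2)
        assert not loc.feature("terminator_hairpin")["present"]
        assert not loc.feature("conserved_block")["present"]
        assert loc.feature("anti_repeat")["present"]
        assert len(loc.sequence) > 0

    def test_repeat_shorter_than_span_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            ck.make_synthetic_locus("ACGTACGT", anti_repeat_span=(1, 13), seed=1)

    def test_coordinates_round_trip(self):
        loc = ck.make_synthetic_locus(REPEAT, conserved_block=CONSERVED_17,
                                      anti_repeat_span=(24, 13), seed=3)
        for _, row in loc.features.iterrows():
            if not row["present"]:
                continue
            s, e = int(row["start"]), int(row["end"])
            assert loc.sequence[s - 1:e] == row["sequence"]


class TestSimulateKinetics:
    def test_rate_zero_gives_flat_zero(self):
        tr = ck.simulate_kinetics({"A": 50.0, "k": 0.0}, "gel_timecourse")
        assert np.all(tr["signal"] == 0.0)

    def test_half_life_closed_form(self):
        k = 0.1
        t_half = np.log(2) / k
        tr = ck.simulate_kinetics({"A": 80.0, "k": k}, "fq_trace",
                                  grid=[0.0, t_half, 5 * t_half])
        assert tr["signal"][1] == pytest.approx(40.0, rel=1e-12)

    def test_mm_velocity_one_per_reporter_concentration(self):
        df = ck.simulate_kinetics({"kcat": 0.44, "enzyme_conc": 1e-10,
                                   "km": 6.77e-7}, "mm_velocity")
        from caskit.kinetics import REPORTER_CONCENTRATIONS_M
        assert list(df["conc_M"]) == list(REPORTER_CONCENTRATIONS_M)
        assert len(df) == 7

    def test_noise_free_is_exact_and_noise_is_seeded(self):
        exact = ck.simulate_kinetics({"A": 60.0, "k": 0.05}, "gel_timecourse")
        assert np.allclose(
            exact["signal"],
            60.0 * (1 - np.exp(-0.05 * exact["time_s"])))
        n1 = ck.simulate_kinetics({"A": 60.0, "k": 0.05}, "gel_timecourse",
                                  noise_sd=1.0, seed=4)
        n2 = ck.simulate_kinetics({"A": 60.0, "k": 0.05}, "gel_timecourse",
                                  noise_sd=1.0, seed=4)
        pd.testing.assert_frame_equal(n1, n2)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ck.simulate_kinetics({"A": 150.0, "k": 0.1}, "gel_timecourse")
        with pytest.raises(ValueError):
            ck.simulate_kinetics({"A": 50.0, "k": 0.1}, "gel_timecourse",
                                 noise_sd=-1.0)
        with pytest.raises(ValueError):
            ck.simulate_kinetics({"kd": -1e-9}, "binding_titration")
        with pytest.raises(ValueError):
            ck.simulate_kinetics({"A": 1.0, "k": 0.1}, "no_such_design")
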