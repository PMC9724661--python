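"""Anti-repeat search, conserved blocks, hairpin geometry and sgRNA assembly,
checked against brute-force oracles on short sequences."""
import numpy as np
import pytest

import caskit as ck
from caskit.guide_rna import TETRALOOP
from caskit.sequtils import revcomp

from conftest import CONSERVED_17, REPEAT

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def brute_force_best_anti_repeat(sequence, repeat, min_len, max_mm):
    """All-pairs scan: best (length, -mismatches) complement segment."""
    best = None
    for s in (sequence, revcomp(sequence)):
        n = len(s)
        for i in range(n):
            for L in range(min_len, min(len(repeat), n - i) + 1):
                seg = s[i:i + L]
                rc = revcomp(seg)
                for j in range(len(repeat) - L + 1):
                    sub = repeat[j:j + L]
                    if rc[0] != sub[0] or rc[-1] != sub[-1]:
                        continue
                    mm = sum(a != b for a, b in zip(rc, sub))
                    if mm > max_mm:
                        continue
                    key = (L, -mm)
                    if best is None or key > best:
                        best = key
    return best


def brute_force_hairpins(sequence, min_stem, loop_range):
    """All maximal (start, stem, loop) perfect inverted repeats."""
    n = len(sequence)
    out = set()
    for start in range(n):
        for loop in range(loop_range[0], loop_range[1] + 1):
            for stem in range(min_stem, n):
                end = start + 2 * stem + loop
                if end > n:
                    break
                ok = all(
                    (sequence[start + k], sequence[end - 1 - k]) in _PAIRS
                    for k in range(stem))
                if not ok:
                    continue
                # outward-maximal: one more enclosing pair must be impossible
                i, j = start - 1, end
                extendable = (i >= 0 and j < n
                              and (sequence[i], sequence[j]) in _PAIRS)
                if not extendable:
                    out.add((start + 1, stem, loop))
    return out


class TestFindAntiRepeat:
    def test_exact_embedded_complement(self):
        rng = np.random.default_rng(41)
        insert = revcomp(REPEAT[-13:])
        seq = random_dna(rng, 60) + insert + random_dna(rng, 60)
        hits = ck.find_anti_repeat(seq, REPEAT, min_len=10, max_mismatches=0)
        top = hits[0]
        assert (top.length, top.n_mismatches) == (13, 0)
        assert top.strand == "+"
        assert seq[top.start - 1:top.end] == insert
        assert top.repeat_start == len(REPEAT) - 13 + 1

    def test_random_sequence_no_hits(self):
        rng = np.random.default_rng(42)
        # brute-force-verified absence of any >=12-mer complement
        for _ in range(5):
            seq = random_dna(rng, 80)
            best = brute_force_best_anti_repeat(seq, REPEAT, 12, 0)
            got = ck.find_anti_repeat(seq, REPEAT, min_len=12,
                                      max_mismatches=0)
            assert (best is None) == (len(got) == 0)

    def test_top_hit_matches_brute_force_with_mismatches(self):
        rng = np.random.default_rng(43)
        for trial in range(4):
            # plant an imperfect anti-repeat (one internal mismatch)
            span = REPEAT[8:8 + 14]
            mutated = list(revcomp(span))
            mutated[6] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[6]]
            seq = (random_dna(rng, 60) + "".join(mutated)
                   + random_dna(rng, 70))
            best = brute_force_best_anti_repeat(seq, REPEAT, 10, 1)
            top = ck.find_anti_repeat(seq, REPEAT, min_len=10,
                                      max_mismatches=1)[0]
            assert (top.length, -top.n_mismatches) == best

    def test_minus_strand_hit_coordinates_round_trip(self):
        rng = np.random.default_rng(44)
        insert = REPEAT[5:18]  # the repeat itself: complement on minus strand
        seq = random_dna(rng, 50) + insert + random_dna(rng, 50)
        hits = [h for h in ck.find_anti_repeat(seq, REPEAT, min_len=12,
                                               max_mismatches=0)
                if h.strand == "-"]
        assert hits
        top = hits[0]
        assert revcomp(seq[top.start - 1:top.end]) == top.sequence

    def test_validation(self):
        with pytest.raises(ValueError):
            ck.find_anti_repeat("ACGT" * 20, REPEAT, min_len=5)
        with pytest.raises(ValueError, match="non-ACGT"):
            ck.find_anti_repeat("ACGTN", REPEAT)


class TestFindConservedBlocks:
    def test_planted_seventeen_mer(self):
        rng = np.random.default_rng(45)
        seqs = [random_dna(rng, 40) + CONSERVED_17 + random_dna(rng, 40)
                for _ in range(4)]
        top = ck.find_conserved_blocks(seqs)[0]
        assert top.length == 17
        assert top.sequence == CONSERVED_17
        assert top.identity == 100.0
        for seq, pos in zip(seqs, top.positions):
            assert seq[pos - 1:pos - 1 + 17] == CONSERVED_17

    def test_identical_sequences_whole_block(self):
        blocks = ck.find_conserved_blocks([REPEAT, REPEAT])
        assert blocks[0].sequence == REPEAT

    def test_no_common_substring(self):
        blocks = ck.find_conserved_blocks(["A" * 30, "C" * 30], min_len=8)
        assert blocks == []

    def test_brute_force_all_substring_intersection(self):
        rng = np.random.default_rng(46)
        for _ in range(5):
            seqs = [random_dna(rng, 30) for _ in range(3)]
            got = {b.sequence for b in ck.find_conserved_blocks(seqs,
                                                                min_len=4)}
            subs = [
                {s[i:i + L] for L in range(4, len(s) + 1)
                 for i in range(len(s) - L + 1)} for s in seqs]
            common = set.intersection(*subs)
            maximal = {s for s in common
                       if not any(s != o and s in o for o in common)}
            assert got == maximal

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            ck.find_conserved_blocks([REPEAT])


class TestFindHairpins:
    def test_worked_example(self):
        hp = ck.find_hairpins("GGGGC" + "AAAA" + "GCCCC", min_stem=5)
        assert len(hp) == 1
        assert (hp[0].stem_length, hp[0].loop_length) == (5, 4)
        # the GGGGC arm is all G/C, so the stem GC fraction is exactly 1
        assert hp[0].gc_fraction == pytest.approx(1.0)

    def test_homopolymer_has_none(self):
        assert ck.find_hairpins("A" * 60, min_stem=4) == []

    def test_synthetic_locus_terminator_recovered(self):
        loc = ck.make_synthetic_locus(REPEAT, anti_repeat_span=(24, 13),
                                      seed=47, hairpin_arm_len=8)
        truth = loc.feature("terminator_hairpin")
        hits = ck.find_hairpins(loc.intergenic, min_stem=5)
        top = hits[0]
        assert top.start == int(truth["start"])
        assert top.stem_length >= 8

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(48)
        for _ in range(5):
            seq = random_dna(rng, 120)
            got = {(h.start, h.stem_length, h.loop_length)
                   for h in ck.find_hairpins(seq, min_stem=3,
                                             loop_range=(3, 6))}
            assert got == brute_force_hairpins(seq, 3, (3, 6))

    def test_coordinates_round_trip(self):
        rng = np.random.default_rng(49)
        seq = random_dna(rng, 150)
        for h in ck.find_hairpins(seq, min_stem=3, loop_range=(3, 8)):
            span = seq[h.start - 1:h.start - 1 + 2 * h.stem_length
                       + h.loop_length]
            assert span == h.sequence

    def test_validation(self):
        with pytest.raises(ValueError):
            ck.find_hairpins("ACGT" * 10, min_stem=2)
        with pytest.raises(ValueError):
            ck.find_hairpins("ACGT" * 10, loop_range=(1, 5))


class TestDesignSgrna:
    TRACR = "GGCACCGAGTCGGTGGTGC"
    HAIRPIN3 = "GGGCGCGCAAAAGCGCGCCC"
    SPACER20 = "ACGTACGTACGTACGTACGT"

    def test_default_variant_one_twenty_nt_spacer(self):
        d = ck.design_sgrna(self.TRACR, REPEAT, self.SPACER20)
        assert d.variant == 1
        assert len(d.spacer) == 20
        assert d.terminator_hairpin == ""

    def test_tetraloop_junction_contiguous(self):
        from caskit.sequtils import to_rna
        d = ck.design_sgrna(self.TRACR, REPEAT, self.SPACER20)
        assert (to_rna(self.TRACR) + TETRALOOP + to_rna(REPEAT)) in d.sequence

    def test_hairpin3_excluded_by_variant(self):
        from caskit.sequtils import to_rna
        d1 = ck.design_sgrna(self.TRACR, REPEAT, self.SPACER20, variant=1,
                             terminator_hairpin=self.HAIRPIN3)
        d3 = ck.design_sgrna(self.TRACR, REPEAT, self.SPACER20, variant=3,
                             terminator_hairpin=self.HAIRPIN3)
        assert to_rna(self.HAIRPIN3) not in d1.sequence
        assert to_rna(self.HAIRPIN3) in d3.sequence

    def test_five_prime_region_by_variant(self):
        five = "ATTTGAGAGTTTGG"
        d1 = ck.design_sgrna(self.TRACR, REPEAT, self.SPACER20, variant=1,
                             five_prime_region=five)
        d2 = ck.design_sgrna(self.TRACR, REPEAT, self.SPACER20, variant=2,
                             five_prime_region=five)
        assert d1.sequence.startswith("AUUUGAGAGUUUGG")
        assert not d2.sequence.startswith("AUUUGAGAGUUUGG")

    def test_rna_alphabet_and_length_identity(self):
        d = ck.design_sgrna(self.TRACR, REPEAT, self.SPACER20)
        assert set(d.sequence) <= set("ACGU")
        assert len(d.sequence) == sum(map(len, (
            d.five_prime_region, d.tracr_segment, d.terminator_hairpin,
            d.tetraloop, d.repeat_segment, d.spacer)))

    @pytest.mark.parametrize("n", [17, 25])
    def test_spacer_outside_screened_range(self, n):
        with pytest.raises(ValueError, match=r"\[18, 24\]"):
            ck.design_sgrna(self.TRACR, REPEAT, "A" * n)

    def test_deterministic_assembly(self):
        a = ck.design_sgrna(self.TRACR, REPEAT, self.SPACER20)
        b = ck.design_sgrna(self.TRACR, REPEAT, self.SPACER20)
        assert a.sequence == b.sequence
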