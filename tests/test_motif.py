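"""PWM construction and scanning: closed forms, exhaustive oracle, probe checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regvar.motif import (
    AlleleProbePair,
    allelic_motif_effect,
    consensus_core_match,
    in_silico_amplicon,
    load_foxa_core_pfm,
    make_allele_probes,
    pfm_to_pwm,
    read_jaspar_pfm,
    reverse_complement,
    scan_all_windows,
    scan_best_hit,
    PFM,
)
from regvar.simulate import (
    PROBE_SENSE_ALT,
    PROBE_SENSE_REF,
    PROBE_SNP_OFFSET,
)

BASES = "ACGT"


def brute_force_best(pwm, seq):
    """Independent exhaustive scan: pure-python, both strands."""
    L = pwm.length
    best = None
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for o in range(len(s) - L + 1):
            score = sum(
                pwm.logodds[BASES.index(b), j] for j, b in enumerate(s[o : o + L])
            )
            offset = o if strand == "+" else len(seq) - L - o
            key = (score, strand == "+", -offset)
            if best is None or key > best[0]:
                best = (key, offset, strand, score)
    return best[1], best[2], best[3]


class TestJasparParsing:
    def test_single_column_consensus(self):
        pfm = read_jaspar_pfm(">M1 test\nA [10]\nC [0]\nG [0]\nT [0]\n")[0]
        assert pfm.length == 1
        assert pfm.consensus == "A"

    def test_bracketed_and_bare_dialects_agree(self):
        bracketed = ">M1 tf\nA [ 1 2 3 ]\nC [ 4 5 6 ]\nG [ 7 8 9 ]\nT [ 1 1 1 ]\n"
        bare = ">M1 tf\n1 2 3\n4 5 6\n7 8 9\n1 1 1\n"
        p1, p2 = read_jaspar_pfm(bracketed)[0], read_jaspar_pfm(bare)[0]
        np.testing.assert_array_equal(p1.counts, p2.counts)

    def test_row_order_irrelevant_when_labeled(self):
        shuffled = ">M1 tf\nT [ 1 1 1 ]\nG [ 7 8 9 ]\nA [ 1 2 3 ]\nC [ 4 5 6 ]\n"
        p = read_jaspar_pfm(shuffled)[0]
        np.testing.assert_array_equal(p.counts[0], [1, 2, 3])
        np.testing.assert_array_equal(p.counts[3], [1, 1, 1])

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            read_jaspar_pfm(">M1 tf\nA [1 2]\nC [1 2 3]\nG [1 2]\nT [1 2]\n")

    def test_missing_base_row_rejected(self):
        with pytest.raises(ValueError, match="4 base rows"):
            read_jaspar_pfm(">M1 tf\nA [1]\nC [1]\nG [1]\n")

    def test_bundled_fixture_consensus(self, foxa_pfm):
        assert foxa_pfm.length == 7
        assert foxa_pfm.consensus == "TGTTTAC"


class TestPfmToPwm:
    def test_uniform_counts_uniform_background_all_zero(self):
        pfm = PFM("u", "u", np.full((4, 3), 5.0))
        pwm = pfm_to_pwm(pfm)
        np.testing.assert_allclose(pwm.logodds, 0.0, atol=1e-12)
        assert pwm.max_score == pwm.min_score == 0.0

    def test_single_column_closed_form(self):
        # A=3, pseudocount 1, uniform bg: score(A) = log2((3.25/4)/0.25)
        pfm = PFM("m", "m", np.array([[3.0], [0.0], [0.0], [0.0]]))
        pwm = pfm_to_pwm(pfm, pseudocount=1.0)
        assert pwm.logodds[0, 0] == pytest.approx(math.log2(3.25))
        assert pwm.logodds[1, 0] == pytest.approx(math.log2(0.25))

    def test_count_scaling_converges_as_pseudocount_vanishes(self):
        counts = np.array([[8.0, 1.0], [2.0, 3.0], [1.0, 5.0], [1.0, 3.0]])
        small = pfm_to_pwm(PFM("m", "m", counts), pseudocount=1e-9)
        scaled = pfm_to_pwm(PFM("m", "m", counts * 10), pseudocount=1e-9)
        np.testing.assert_allclose(small.logodds, scaled.logodds, atol=1e-6)

    def test_matches_biopython_pssm(self):
        """Independent cross-check of the log-odds construction."""
        Bio_motifs = pytest.importorskip("Bio.motifs")
        counts = {"A": [3, 0, 2], "C": [1, 7, 0], "G": [0, 1, 1], "T": [4, 0, 5]}
        pfm = PFM("m", "m", np.array([counts[b] for b in BASES], dtype=float))
        pwm = pfm_to_pwm(pfm, pseudocount=1.0)
        motif = Bio_motifs.Motif(alphabet="ACGT", counts=counts)
        pssm = motif.counts.normalize(pseudocounts=0.25).log_odds()
        ours = {b: list(pwm.logodds[BASES.index(b)]) for b in BASES}
        for b in BASES:
            np.testing.assert_allclose(ours[b], list(pssm[b]), atol=1e-9)

    def test_zero_background_rejected(self):
        pfm = PFM("m", "m", np.ones((4, 2)))
        with pytest.raises(ValueError, match="positive"):
            pfm_to_pwm(pfm, background=[0.5, 0.5, 0.0, 0.0])


class TestScanning:
    def test_consensus_scores_max_on_plus_strand(self, foxa_pwm):
        hit = scan_best_hit(foxa_pwm, "TGTTTAC")
        assert (hit.offset, hit.strand) == (0, "+")
        assert hit.score == pytest.approx(foxa_pwm.max_score)
        assert hit.rel_score == pytest.approx(1.0)

    def test_reverse_complement_of_consensus_scores_max_on_minus(self, foxa_pwm):
        hit = scan_best_hit(foxa_pwm, reverse_complement("TGTTTAC"))
        assert hit.strand == "-"
        assert hit.score == pytest.approx(foxa_pwm.max_score)

    def test_strand_symmetry_of_best_score(self, foxa_pwm, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list(BASES), size=40))
            s1 = scan_best_hit(foxa_pwm, seq).score
            s2 = scan_best_hit(foxa_pwm, reverse_complement(seq)).score
            assert s1 == pytest.approx(s2, abs=1e-12)

    def test_ambiguity_codes_rejected(self, foxa_pwm):
        with pytest.raises(ValueError, match="non-ACGT"):
            scan_best_hit(foxa_pwm, "TGTNTACAA")

    def test_printed_probe_windows(self, foxa_pwm):
        t_hit = scan_best_hit(foxa_pwm, PROBE_SENSE_ALT)
        assert (t_hit.offset, t_hit.strand) == (7, "+")
        assert PROBE_SENSE_ALT[7:14] == "TGTTTAC"
        assert t_hit.rel_score == pytest.approx(1.0)
        c_hit = scan_best_hit(foxa_pwm, PROBE_SENSE_REF)
        assert c_hit.score < t_hit.score

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_best_hit_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(3, 9))
        counts = rng.integers(0, 20, size=(4, L)).astype(float)
        counts[rng.integers(0, 4), :] += 1  # keep column sums positive
        pwm = pfm_to_pwm(PFM("m", "m", counts))
        seq = "".join(rng.choice(list(BASES), size=int(rng.integers(L, 60))))
        hit = scan_best_hit(pwm, seq)
        offset, strand, score = brute_force_best(pwm, seq)
        assert (hit.offset, hit.strand) == (offset, strand)
        assert hit.score == pytest.approx(score, abs=1e-9)


class TestConsensusCoreMatch:
    def test_embedded_consensus_found(self, foxa_pwm, rng):
        seq = "ACCGGA" + "TGTTTAC" + "GGATCC"
        assert consensus_core_match(foxa_pwm, seq) >= 1

    def test_all_a_sequence_has_no_core(self, foxa_pwm):
        assert consensus_core_match(foxa_pwm, "A" * 30) == 0

    def test_printed_probes_t_one_c_zero(self, foxa_pwm):
        assert consensus_core_match(foxa_pwm, PROBE_SENSE_ALT, 0.8) == 1
        assert consensus_core_match(foxa_pwm, PROBE_SENSE_REF, 0.8) == 0


class TestAllelicEffect:
    def probes(self):
        return make_allele_probes(PROBE_SENSE_REF, PROBE_SNP_OFFSET, "C", "T", "rs11257655")

    def test_printed_pair_call_created(self, foxa_pwm):
        effect = allelic_motif_effect(foxa_pwm, self.probes())
        assert effect.call == "created"
        assert effect.delta > 0

    def test_swap_negates_delta_and_mirrors_call(self, foxa_pwm):
        p = self.probes()
        swapped = AlleleProbePair(
            variant_id=p.variant_id, ref_seq=p.alt_seq, alt_seq=p.ref_seq,
            snp_offset=p.snp_offset,
        )
        e1 = allelic_motif_effect(foxa_pwm, p)
        e2 = allelic_motif_effect(foxa_pwm, swapped)
        assert e2.delta == pytest.approx(-e1.delta)
        assert (e1.call, e2.call) == ("created", "disrupted")

    def test_motif_absent_from_both_alleles_neutral(self, foxa_pwm):
        probes = make_allele_probes("A" * 10 + "C" + "A" * 10, 10, "C", "G")
        effect = allelic_motif_effect(foxa_pwm, probes)
        assert effect.call == "neutral"


class TestMakeAlleleProbes:
    def test_printed_pair_lengths_and_sequences(self):
        p = make_allele_probes(PROBE_SENSE_REF, PROBE_SNP_OFFSET, "C", "T")
        assert len(p.ref_seq) == len(p.alt_seq) == 21
        assert p.alt_seq == PROBE_SENSE_ALT

    def test_antisense_matches_printed_oligos(self):
        p = make_allele_probes(PROBE_SENSE_REF, PROBE_SNP_OFFSET, "C", "T")
        assert p.alt_antisense == "ATGCCCAGTAAACACTTGCCC"
        assert p.ref_antisense == "ATGCCCAGTAGACACTTGCCC"

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            make_allele_probes(PROBE_SENSE_REF, PROBE_SNP_OFFSET, "C", "C")

    def test_sequence_allele_mismatch_rejected(self):
        with pytest.raises(ValueError, match="expected ref allele"):
            make_allele_probes(PROBE_SENSE_REF, PROBE_SNP_OFFSET, "T", "C")


class TestInSilicoAmplicon:
    def test_constructed_template_length(self, rng):
        fwd = "".join(rng.choice(list(BASES), size=20))
        rev = "".join(rng.choice(list(BASES), size=20))
        spacer = "".join(rng.choice(list(BASES), size=10))
        template = fwd + spacer + reverse_complement(rev)
        assert in_silico_amplicon(template, fwd, rev) == [50]

    def test_absent_primers_give_empty_result(self):
        assert in_silico_amplicon("A" * 100, "C" * 20, "G" * 20) == []

    def test_chip_primer_pair_on_synthetic_locus(self, rng):
        """The ChIP primer pair yields its designed single 99-bp product."""
        fwd = "CTACTGCTTCTCCGGACTCG"
        rev = "TGGCCTCAAGAGGGAGATAA"
        middle = "".join(rng.choice(list(BASES), size=99 - len(fwd) - len(rev)))
        locus = (
            "".join(rng.choice(list(BASES), size=60))
            + fwd + middle + reverse_complement(rev)
            + "".join(rng.choice(list(BASES), size=60))
        )
        assert in_silico_amplicon(locus, fwd, rev) == [99]

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="15 nt"):
            in_silico_amplicon("A" * 50, "ACGT", "ACGTACGTACGTACG")
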