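"""In-silico PCR, IUPAC digestion, assay design and genotype calling."""

import itertools

import numpy as np
import pytest

from kdrkit.errors import AmbiguousProductError, PrimerBindingError, ValidationError
from kdrkit.rflp import (
    IUPAC,
    Amplicon,
    PrimerPair,
    RestrictionEnzyme,
    call_genotype,
    digest,
    find_cut_sites,
    find_discriminating_enzymes,
    in_silico_pcr,
    observable_pattern,
    reverse_complement,
)
from kdrkit.simulate import AEKDR_PRIMERS


def cut_sites_oracle(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Brute force: expand the IUPAC recognition to every concrete word and
    scan both strands by substring comparison."""
    words = ["".join(p) for p in itertools.product(*[IUPAC[b] for b in enzyme.recognition])]
    L = len(enzyme.recognition)
    cuts = set()
    for w in words:
        wrc = reverse_complement(w)
        for i in range(len(seq) - L + 1):
            chunk = seq[i : i + L]
            if chunk == w:
                cuts.add(i + enzyme.cut_offset_top)
            if chunk == wrc:
                cuts.add(i + L - enzyme.cut_offset_bottom)
    return sorted(c for c in cuts if 0 < c < len(seq))


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindCutSites:
    def test_no_motif_no_cuts(self, bsabi):
        assert find_cut_sites("ACGT" * 30, bsabi) == []

    def test_degenerate_site(self, bsabi):
        # GATCCGGATC matches GATNNNNATC; blunt cut after 5 recognition bases
        seq = "AA" + "GATCCGGATC" + "AA"
        assert find_cut_sites(seq, bsabi) == [2 + 5]

    def test_palindromic_blunt_cuts_mirror_under_reverse_complement(self, bsabi):
        # blunt palindromic recognition: cut coordinates mirror exactly
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 300)
        cuts = find_cut_sites(seq, bsabi)
        mirrored = sorted(len(seq) - c for c in find_cut_sites(reverse_complement(seq), bsabi))
        assert cuts == mirrored

    def test_overhang_cuts_shift_by_overhang_under_reverse_complement(self, ssii):
        # for a 2-nt 5' overhang the top cut of the reverse complement is the
        # mirrored bottom cut: same number of double-strand cleavage events
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 300)
        cuts = find_cut_sites(seq, ssii)
        rc_cuts = find_cut_sites(reverse_complement(seq), ssii)
        assert len(cuts) == len(rc_cuts)
        overhang = ssii.cut_offset_bottom - ssii.cut_offset_top
        for c, m in zip(cuts, sorted(len(seq) - c for c in rc_cuts)):
            assert abs(c - m) <= overhang

    def test_ambiguity_codes_in_sequence_rejected(self, bsabi):
        with pytest.raises(ValidationError):
            find_cut_sites("ACGTNACGT", bsabi)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed, enzymes):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 2000)
        for enz in enzymes:
            assert find_cut_sites(seq, enz) == cut_sites_oracle(seq, enz)

    def test_agrees_with_biopython(self, amplicons, bsabi, ssii):
        Restriction = pytest.importorskip("Bio.Restriction")
        from Bio.Seq import Seq

        for name, amp in amplicons.items():
            for mine, ref in ((bsabi, Restriction.BsaBI), (ssii, Restriction.SsiI)):
                ours = [c + 1 for c in find_cut_sites(amp.sequence, mine)]
                assert ours == ref.search(Seq(amp.sequence)), (name, mine.name)


class TestDigest:
    def test_survey_fragment_sizes(self, amplicons, bsabi, ssii):
        assert digest(amplicons["mut_1520I"], bsabi).fragment_lengths == (143, 28)
        assert digest(amplicons["mut_1534C"], ssii).fragment_lengths == (103, 68)
        assert digest(amplicons["wild"], bsabi).fragment_lengths == (171,)
        assert digest(amplicons["wild"], ssii).fragment_lengths == (171,)

    def test_fragment_conservation_on_random_sequences(self, enzymes):
        rng = np.random.default_rng(9)
        for _ in range(10):
            seq = random_dna(rng, int(rng.integers(50, 1500)))
            amp = Amplicon(seq, 1, len(seq))
            for enz in enzymes:
                res = digest(amp, enz)
                assert sum(res.fragment_lengths) == len(seq)
                assert res.n_fragments == len(res.cut_positions) + 1


class TestInSilicoPcr:
    def test_assay_amplicon_is_171_bp(self, amplicons):
        amp = in_silico_pcr(amplicons["wild"].sequence, AEKDR_PRIMERS)
        assert len(amp) == 171

    def test_template_equal_to_amplicon_is_identity(self, amplicons):
        seq = amplicons["wild"].sequence
        amp = in_silico_pcr(seq, AEKDR_PRIMERS)
        assert amp.sequence == seq
        assert (amp.template_start, amp.template_end) == (1, 171)

    def test_both_template_strands_searched(self, amplicons):
        rng = np.random.default_rng(2)
        template = random_dna(rng, 55) + amplicons["wild"].sequence + random_dna(rng, 70)
        fwd = in_silico_pcr(template, AEKDR_PRIMERS)
        rev = in_silico_pcr(reverse_complement(template), AEKDR_PRIMERS)
        assert fwd.sequence == rev.sequence == amplicons["wild"].sequence

    def test_no_binding_raises(self):
        with pytest.raises(PrimerBindingError):
            in_silico_pcr("ACGT" * 60, AEKDR_PRIMERS)

    def test_multiple_products_raise(self, amplicons):
        seq = amplicons["wild"].sequence
        with pytest.raises(AmbiguousProductError):
            in_silico_pcr(seq + "ACGTACGTAC" + seq[:-10] + seq[-30:], AEKDR_PRIMERS)

    def test_single_mismatch_tolerance(self, amplicons):
        seq = amplicons["wild"].sequence
        mutated = "A" + seq[1:]  # first primer base damaged (T -> A)
        with pytest.raises(PrimerBindingError):
            in_silico_pcr(mutated, AEKDR_PRIMERS)
        assert in_silico_pcr(mutated, AEKDR_PRIMERS, max_mismatch=1).sequence == mutated


class TestAssayDesign:
    def test_1520_assay_selects_bsabi_only(self, amplicons, enzymes):
        assays = find_discriminating_enzymes(
            amplicons["wild"], amplicons["mut_1520I"], enzymes, locus_name="T1520"
        )
        assert [a.enzyme.name for a in assays] == ["BsaBI"]
        assert assays[0].pattern("wild") == frozenset({171})
        # 28 bp product is below gel resolution: mutant shows 143 only
        assert assays[0].pattern("mutant") == frozenset({143})

    def test_1534_assay_selects_ssii_only(self, amplicons, enzymes):
        assays = find_discriminating_enzymes(
            amplicons["wild"], amplicons["mut_1534C"], enzymes, locus_name="F1534"
        )
        assert [a.enzyme.name for a in assays] == ["SsiI"]
        assert assays[0].pattern("mutant") == frozenset({103, 68})

    def test_identical_alleles_give_no_assay(self, amplicons, enzymes):
        assert find_discriminating_enzymes(amplicons["wild"], amplicons["wild"], enzymes) == []

    def test_empty_database_rejected(self, amplicons):
        with pytest.raises(ValidationError):
            find_discriminating_enzymes(amplicons["wild"], amplicons["mut_1520I"], [])

    def test_assay_round_trip_calls_three_genotypes(self, amplicons, enzymes):
        """For every designed assay the three predicted band patterns map
        back to the three genotypes."""
        for mutant in ("mut_1520I", "mut_1534C"):
            for assay in find_discriminating_enzymes(
                amplicons["wild"], amplicons[mutant], enzymes
            ):
                wild, mut = assay.pattern("wild"), assay.pattern("mutant")
                assert call_genotype(assay, wild).genotype == "wild_hom"
                assert call_genotype(assay, mut).genotype == "mut_hom"
                assert call_genotype(assay, wild | mut).genotype == "het"

    def test_masking_monotonicity(self, amplicons, bsabi):
        frags = digest(amplicons["mut_1520I"], bsabi).fragment_lengths
        patterns = [observable_pattern(frags, min_detectable_bp=m) for m in (0, 20, 50, 150, 200)]
        for small, large in zip(patterns, patterns[1:]):
            assert large <= small

    def test_gel_resolution_merges_close_bands(self):
        assert observable_pattern([100, 104, 171], min_detectable_bp=50, resolution_bp=5) == {
            104,
            171,
        }


class TestGenotypeCalling:
    @pytest.mark.parametrize(
        "bands, genotype",
        [
            ([171], "wild_hom"),  # TT
            ([171, 143], "het"),  # TI
            ([143], "mut_hom"),  # II
            ([200], "uninterpretable"),
        ],
    )
    def test_t1520_diagnostic_rules(self, amplicons, bsabi, bands, genotype, enzymes):
        assay = find_discriminating_enzymes(
            amplicons["wild"], amplicons["mut_1520I"], [bsabi], locus_name="T1520"
        )[0]
        assert call_genotype(assay, bands).genotype == genotype

    def test_f1534_heterozygote(self, amplicons, ssii):
        assay = find_discriminating_enzymes(
            amplicons["wild"], amplicons["mut_1534C"], [ssii], locus_name="F1534"
        )[0]
        assert call_genotype(assay, [171, 103, 68]).genotype == "het"

    def test_empty_band_set_rejected(self, amplicons, bsabi):
        assay = find_discriminating_enzymes(
            amplicons["wild"], amplicons["mut_1520I"], [bsabi]
        )[0]
        with pytest.raises(ValidationError):
            call_genotype(assay, [])


def test_primer_pair_validation():
    with pytest.raises(ValidationError):
        PrimerPair("ACGTACGT", "ACGTACGTACGT")  # too short
    with pytest.raises(ValidationError):
        PrimerPair("ACGTACGTACN", "ACGTACGTACGT")  # ambiguity code
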