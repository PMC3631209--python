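import numpy as np
import pytest

from mqfpcr import catalog
from mqfpcr.insilico_pcr import (
    enumerate_amplicons,
    find_binding_sites,
    screen_exclusions,
    validate_assay,
)
from mqfpcr.primer_design import CandidateAssay, PlannedAmplicon
from mqfpcr.seqcore import (
    GenomicInterval,
    Primer,
    SeqRecord,
    expand_degenerate,
    revcomp,
)
from mqfpcr.synth_data import ParalogGenomeSpec, make_paralog_genome

from _oracles import brute_force_sites


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


CORE = "TGACCTGGAACCTGTGAGTC"


class TestFindBindingSites:
    def test_single_planted_site_matches_brute_force(self):
        rng = np.random.default_rng(8)
        template = SeqRecord(id="t", seq=_random_seq(rng, 100) + CORE + _random_seq(rng, 100))
        primer = Primer("p", CORE)
        sites = find_binding_sites(primer, template, max_mismatch=0)
        oracle = brute_force_sites(expand_degenerate(CORE), template.seq)
        assert [(s.start - 1, s.strand) for s in sites] == oracle
        assert len(sites) == 1 and sites[0].strand == "+"
        assert sites[0].start == 101 and sites[0].end == 100 + len(CORE)

    def test_minus_strand_site(self):
        rng = np.random.default_rng(9)
        template = SeqRecord(id="t", seq=_random_seq(rng, 80) + revcomp(CORE) + _random_seq(rng, 80))
        sites = find_binding_sites(Primer("p", CORE), template, max_mismatch=0)
        assert len(sites) == 1 and sites[0].strand == "-"

    def test_degenerate_core_matches_both_embeddings(self):
        """A primer with an R base binds both the A and the G template."""
        core = catalog.WBS.reverse.core  # contains R
        rng = np.random.default_rng(10)
        for concrete in expand_degenerate(core):
            template = SeqRecord(id="t", seq=_random_seq(rng, 60) + concrete + _random_seq(rng, 60))
            sites = find_binding_sites(Primer("p", core), template, max_mismatch=0)
            assert any(s.strand == "+" for s in sites)

    def test_zero_mismatch_agrees_with_exact_search_everywhere(self):
        rng = np.random.default_rng(11)
        # short core in a long template: expect some chance hits on both strands
        core = "ACGTACGTACGTACG"
        template = SeqRecord(id="t", seq=_random_seq(rng, 5000) + core + _random_seq(rng, 50))
        sites = find_binding_sites(Primer("p", core), template, max_mismatch=0)
        oracle = brute_force_sites([core], template.seq)
        assert sorted((s.start - 1, s.strand) for s in sites) == oracle

    def test_three_prime_mismatch_blocks_binding(self):
        rng = np.random.default_rng(12)
        damaged = CORE[:-1] + ("A" if CORE[-1] != "A" else "C")
        template = SeqRecord(id="t", seq=_random_seq(rng, 50) + damaged + _random_seq(rng, 50))
        assert find_binding_sites(Primer("p", CORE), template, max_mismatch=2) == []

    def test_internal_mismatches_tolerated(self):
        rng = np.random.default_rng(13)
        mutated = list(CORE)
        mutated[3] = "A" if CORE[3] != "A" else "C"
        mutated[8] = "A" if CORE[8] != "A" else "C"
        template = SeqRecord(id="t", seq=_random_seq(rng, 50) + "".join(mutated) + _random_seq(rng, 50))
        sites = find_binding_sites(Primer("p", CORE), template, max_mismatch=2)
        assert len(sites) == 1 and sites[0].mismatch_count == 2


FWD = Primer("F", "TGACCTGGAACCTGTGAGTC", tail="GTTTTCCCAGTCACGAC", role="forward")
REV = Primer("R", "CAGGTACCTGAACGGATCTG", tail="GTTTCTT", role="reverse")


def _template_with_product(rng, inner_len):
    inner = _random_seq(rng, inner_len)
    return FWD.core + inner + revcomp(REV.core)


class TestEnumerateAmplicons:
    def test_construction_identity(self):
        rng = np.random.default_rng(20)
        seq = _template_with_product(rng, 60)
        amps = enumerate_amplicons(FWD, REV, [SeqRecord(id="t", seq=seq)])
        assert len(amps) == 1
        amp = amps[0]
        assert amp.size_untailed == len(FWD.core) + 60 + len(REV.core)
        assert amp.size_tailed == amp.size_untailed + 24

    def test_strand_invariance(self):
        rng = np.random.default_rng(21)
        seq = _random_seq(rng, 30) + _template_with_product(rng, 60) + _random_seq(rng, 30)
        fwd_amps = enumerate_amplicons(FWD, REV, [SeqRecord(id="t", seq=seq)])
        rc_amps = enumerate_amplicons(FWD, REV, [SeqRecord(id="t", seq=revcomp(seq))])
        assert len(fwd_amps) == len(rc_amps) == 1
        assert fwd_amps[0].size_untailed == rc_amps[0].size_untailed
        assert {fwd_amps[0].strand, rc_amps[0].strand} == {"+", "-"}

    def test_two_templates_size_difference(self):
        rng = np.random.default_rng(22)
        t1 = SeqRecord(id="a", seq=_template_with_product(rng, 60))
        t2 = SeqRecord(id="b", seq=_template_with_product(rng, 55))
        amps = enumerate_amplicons(FWD, REV, [t1, t2])
        sizes = sorted(a.size_untailed for a in amps)
        assert len(amps) == 2 and sizes[1] - sizes[0] == 5


def _toy_assay(delta=3):
    return CandidateAssay(
        name="toy",
        forward=FWD,
        reverse=REV,
        amplicons=[
            PlannedAmplicon(GenomicInterval("chr7", 100, 200), 101, 125, "test"),
            PlannedAmplicon(GenomicInterval("chr18", 500, 597), 98, 122, "control"),
        ],
        delta_size=delta,
    )


class TestScreenExclusions:
    def test_overlap_fails(self):
        ok, overlaps = screen_exclusions(_toy_assay(), [GenomicInterval("chr7", 150, 160)])
        assert not ok and len(overlaps) == 1

    def test_other_chromosome_passes(self):
        ok, overlaps = screen_exclusions(_toy_assay(), [GenomicInterval("chr8", 100, 200)])
        assert ok and overlaps == []

    def test_adjacent_interval_passes(self):
        ok, _ = screen_exclusions(_toy_assay(), [GenomicInterval("chr7", 201, 300)])
        assert ok

    def test_missing_chromosome_treated_clear(self):
        ok, _ = screen_exclusions(_toy_assay(), [GenomicInterval("chr1", 1, 10)])
        assert ok


class TestValidateAssay:
    def test_planted_pair_is_valid(self, planted_delta2):
        report = validate_assay(planted_delta2["assay"], planted_delta2["genome"])
        assert report.valid and report.n_products == 2
        roles = sorted(a.role for a in report.amplicons)
        assert roles == ["control", "test"]

    def test_third_site_invalidates(self, planted_delta2):
        genome = planted_delta2["genome"]
        assay = planted_delta2["assay"]
        rng = np.random.default_rng(30)
        extra = SeqRecord(
            id="chromC",
            seq=_random_seq(rng, 40)
            + expand_degenerate(assay.forward.core)[0]
            + _random_seq(rng, 50)
            + revcomp(expand_degenerate(assay.reverse.core)[0])
            + _random_seq(rng, 40),
        )
        report = validate_assay(assay, genome + [extra])
        assert not report.valid and report.n_products == 3

    def test_delta_zero_unresolvable(self):
        genome, truth = make_paralog_genome(ParalogGenomeSpec(delta=0, seed=40))
        fwd = Primer("F", truth.fwd_site, role="forward")
        rev = Primer("R", revcomp(truth.rev_site), role="reverse")
        amps = enumerate_amplicons(fwd, rev, genome)
        assert len(amps) == 2
        assert amps[0].size_untailed == amps[1].size_untailed
        assay = _toy_assay()
        assay.forward = fwd
        assay.reverse = rev
        report = validate_assay(assay, genome)
        assert not report.valid and "unresolvable" in report.reason
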