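"""Read classification: mismatch binning, circular alignment, region labels."""

import numpy as np
import pytest

from retrozyme.annotate import RetrozymeLocus
from retrozyme.rna import (
    ReadClassification,
    align_reads_to_refs,
    assign_region,
    bin_mismatch_pct,
    contigs_vs_genome,
    mismatch_spectrum,
    StrictContig,
)
from retrozyme.seq_io import Interval, Read, revcomp

from conftest import random_dna


@pytest.fixture(scope="module")
def refset():
    rng = np.random.default_rng(31)
    return {"refA": random_dna(rng, 900), "refB": random_dna(rng, 700)}


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1) % 4]
    return "".join(out)


class TestAlignment:
    def test_verbatim_read_is_perfect(self, refset):
        read = Read("r1", refset["refA"][100:200])
        cls, dropped = align_reads_to_refs([read], refset)
        assert dropped == 0
        c = cls[0]
        assert (c.best_ref_id, c.mismatches, c.bin) == ("refA", 0, "perfect")
        assert (c.ref_start, c.ref_end) == (100, 200)

    def test_one_substitution_in_100nt_is_one_percent(self, refset):
        read = Read("r1", _mutate(refset["refA"][100:200], [50]))
        c = align_reads_to_refs([read], refset)[0][0]
        assert c.mismatches == 1
        assert c.mismatch_pct == pytest.approx(1.0)
        assert c.bin == "1%"

    def test_thirteen_substitutions_fall_in_wide_bin(self, refset):
        read = Read("r1", _mutate(refset["refA"][100:200], list(range(3, 94, 7))))
        c = align_reads_to_refs([read], refset)[0][0]
        assert c.mismatches == 13
        assert c.bin == "3-13%"

    def test_minus_strand_read_recovered(self, refset):
        read = Read("r1", revcomp(refset["refB"][50:150]))
        c = align_reads_to_refs([read], refset)[0][0]
        assert (c.best_ref_id, c.strand, c.mismatches) == ("refB", "-", 0)

    def test_junction_spanning_read_aligns_on_circle(self, refset):
        ref = refset["refA"]
        read = Read("r1", ref[-40:] + ref[:60])
        c = align_reads_to_refs([read], refset, circular=True)[0][0]
        assert c.mismatches == 0
        assert c.ref_start == len(ref) - 40

    def test_foreign_read_dropped_and_counted(self, refset, rng):
        cls, dropped = align_reads_to_refs(
            [Read("junk", random_dna(rng, 100)),
             Read("ok", refset["refA"][:100])], refset
        )
        assert dropped == 1 and len(cls) == 1

    def test_reference_tie_goes_to_lowest_id(self, refset):
        shared = refset["refA"][200:300]
        refs = {"refA": refset["refA"], "refZ": shared + refset["refB"]}
        c = align_reads_to_refs([Read("r", shared)], refs)[0][0]
        assert c.best_ref_id == "refA"


class TestBinning:
    @pytest.mark.parametrize(
        "pct,expected",
        [(0.0, "perfect"), (0.4, "perfect"), (0.5, "1%"), (1.0, "1%"),
         (1.6, "2%"), (2.4, "2%"), (2.5, "3-13%"), (13.0, "3-13%"),
         (13.4, "3-13%"), (13.6, ">13%"), (25.0, ">13%")],
    )
    def test_round_half_up_binning(self, pct, expected):
        assert bin_mismatch_pct(pct) == expected

    def test_spectrum_counts_and_normalization(self):
        def fake(n, mm):
            return [
                ReadClassification(f"r{mm}_{i}", "x", "+", mm, 100, 0, 100)
                for i in range(n)
            ]

        cls = fake(51, 0) + fake(22, 1) + fake(12, 2) + fake(15, 7)
        spec = mismatch_spectrum(cls)
        assert spec == {
            "perfect": 0.51, "1%": 0.22, "2%": 0.12, "3-13%": 0.15, ">13%": 0.0
        }
        assert sum(spec.values()) == pytest.approx(1.0)

    def test_bins_partition_every_read(self, rng):
        cls = [
            ReadClassification(f"r{i}", "x", "+", int(m), 100, 0, 100)
            for i, m in enumerate(rng.integers(0, 30, size=200))
        ]
        spec = mismatch_spectrum(cls)
        assert sum(spec.values()) == pytest.approx(1.0)


def _locus_for(ref_id, L_ltr=350, L_cr=600):
    total = 2 * L_ltr + L_cr
    return RetrozymeLocus(
        id=ref_id, scaffold_id="sc", strand="+",
        ltr5=Interval("sc", 0, L_ltr),
        cr=Interval("sc", L_ltr, L_ltr + L_cr),
        ltr3=Interval("sc", L_ltr + L_cr, total),
        group="Group 2", completeness="full",
    )


class TestRegionAssignment:
    def test_read_inside_ltr(self):
        c = ReadClassification("r", "ref1", "+", 0, 100, 10, 110)
        assert assign_region(c, {"ref1": _locus_for("ref1")}) == "LTR"

    def test_read_inside_group2_cr(self):
        c = ReadClassification("r", "ref1", "+", 0, 100, 400, 500)
        assert assign_region(c, {"ref1": _locus_for("ref1")}) == "CR_group2"

    def test_exact_tie_is_junction(self):
        c = ReadClassification("r", "ref1", "+", 0, 100, 300, 400)
        assert assign_region(c, {"ref1": _locus_for("ref1")}) == "junction"

    def test_unannotated_reference_rejected(self):
        c = ReadClassification("r", "nope", "+", 0, 100, 0, 100)
        with pytest.raises(ValueError, match="annotation"):
            assign_region(c, {})


class TestContigsVsGenome:
    def test_error_free_contig_is_identical(self, refset):
        contig = StrictContig("c1", refset["refA"][50:450], [("r", 0)])
        rows = contigs_vs_genome([contig], refset)
        assert rows[0]["identical"] and rows[0]["best_identity"] == 1.0

    def test_diverged_contig_identity_close_to_truth(self, refset):
        seq = _mutate(refset["refA"][50:450], list(range(5, 400, 20)))  # 5% diverged
        rows = contigs_vs_genome([StrictContig("c1", seq, [("r", 0)])], refset)
        assert rows[0]["best_identity"] == pytest.approx(0.95, abs=0.005)
        assert not rows[0]["identical"]

    def test_empty_contig_list(self, refset):
        assert contigs_vs_genome([], refset) == []
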