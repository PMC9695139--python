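"""RNA-level models: monomer excision, PCR amplicons, miRNA-site scanning."""

import numpy as np
import pytest

from retrozyme.annotate import excise_monomer, predict_amplicon, scan_mirna_sites
from retrozyme.ribozyme import build_hammerhead_cassette, detect_hammerhead
from retrozyme.seq_io import revcomp, rotate_circle

from conftest import random_dna


@pytest.fixture(scope="module")
def dimeric_transcript():
    """Transcript carrying two ribozyme cassettes, as an LTR-CR-LTR RNA would."""
    rng = np.random.default_rng(3)
    cassette = build_hammerhead_cassette()
    ltr = random_dna(rng, 40) + cassette + random_dna(rng, 80)
    cr = random_dna(rng, 300)
    transcript = ltr + cr + ltr
    unit = len(ltr) + len(cr)
    return transcript, unit


class TestExciseMonomer:
    def test_monomer_between_first_two_cleavage_sites(self, dimeric_transcript):
        transcript, unit = dimeric_transcript
        matches = detect_hammerhead(transcript)
        assert len(matches) == 2
        monomer = excise_monomer(transcript, matches)
        assert monomer is not None
        assert len(monomer) == unit  # unit-length RNA
        assert monomer[0] == "G"  # downstream product of self-cleavage starts with G
        first = min(m.cleavage_site for m in matches)
        assert monomer == transcript[first : first + unit]

    def test_fewer_than_two_sites_yields_none(self, dimeric_transcript):
        transcript, _ = dimeric_transcript
        assert excise_monomer(transcript, []) is None
        one = detect_hammerhead(transcript)[:1]
        assert excise_monomer(transcript, one) is None

    def test_monomer_length_invariant_under_rotation(self, dimeric_transcript):
        """Rotating the circular element before transcription keeps the unit length."""
        transcript, unit = dimeric_transcript
        circle = transcript[:unit]
        for off in (1, 57, unit - 3):
            rotated = rotate_circle(circle, off)
            dimer = rotated + rotated
            matches = detect_hammerhead(dimer)
            if len(matches) >= 2:
                assert len(excise_monomer(dimer, matches)) == unit


@pytest.fixture(scope="module")
def template():
    rng = np.random.default_rng(17)
    return random_dna(rng, 800)


class TestAmplicon:

    def test_convergent_pair_on_linear_template(self, template):
        fwd = template[100:120]
        rev = revcomp(template[300:320])
        amps = predict_amplicon(template, False, fwd, rev)
        assert len(amps) == 1
        a = amps[0]
        assert (a.start, a.end) == (100, 320)
        assert a.length == 220 and not a.spans_junction

    def test_divergent_pair_on_linear_template_is_empty(self, template):
        fwd = template[300:320]
        rev = revcomp(template[100:120])
        assert predict_amplicon(template, False, fwd, rev) == []

    def test_divergent_pair_on_circle_spans_junction(self, template):
        fwd = template[300:320]
        rev = revcomp(template[100:120])
        amps = predict_amplicon(template, True, fwd, rev)
        assert len(amps) == 1
        a = amps[0]
        assert a.spans_junction
        # around the circle: 800 - 300 + 120
        assert a.length == len(template) - 300 + 120

    def test_circular_length_matches_rotation_oracle(self, template):
        """Rotate the circle so the primers become convergent and recompute."""
        fwd = template[300:320]
        rev = revcomp(template[100:120])
        a = predict_amplicon(template, True, fwd, rev)[0]
        rotated = rotate_circle(template, 250)  # fwd site now upstream of rev site
        lin = predict_amplicon(rotated, False, fwd, rev)
        assert len(lin) == 1
        assert lin[0].length == a.length

    def test_rotation_invariance_of_circular_products(self, template):
        fwd = template[300:320]
        rev = revcomp(template[100:120])
        ref = predict_amplicon(template, True, fwd, rev)
        for off in (13, 399, 641):
            rot = predict_amplicon(rotate_circle(template, off), True, fwd, rev)
            assert [a.length for a in rot] == [a.length for a in ref]

    def test_primer_with_n_rejected(self, template):
        with pytest.raises(Exception):
            predict_amplicon(template, False, "ACGTNACGTACGTACG", template[:20])

    def test_short_primer_rejected(self, template):
        with pytest.raises(ValueError, match="15"):
            predict_amplicon(template, False, "ACGTACGTAC", template[:20])


class TestMirnaScan:
    def test_planted_perfect_complement_found(self, rng):
        mirna = random_dna(rng, 21)
        site = revcomp(mirna)
        element = random_dna(rng, 300) + site + random_dna(rng, 300)
        hits = scan_mirna_sites(element, {"mir1": mirna})
        assert ("mir1", 300, 0) in hits

    def test_five_mismatch_site_excluded_at_default_threshold(self, rng):
        mirna = random_dna(rng, 21)
        site = list(revcomp(mirna))
        for p in [1, 5, 9, 13, 17]:
            site[p] = "ACGT"[("ACGT".index(site[p]) + 1) % 4]
        element = random_dna(rng, 100) + "".join(site) + random_dna(rng, 100)
        hits = [h for h in scan_mirna_sites(element, {"m": mirna}) if h[1] == 100]
        assert hits == []

    def test_empty_mirna_set(self, rng):
        assert scan_mirna_sites(random_dna(rng, 200), {}) == []

    def test_agrees_with_sliding_window_counter(self, rng):
        element = random_dna(rng, 400)
        mirna = random_dna(rng, 20)
        probe = revcomp(mirna)
        doubled = element + element
        expected = []
        for s in range(len(element)):
            w = doubled[s : s + len(probe)]
            mm = sum(1 for a, b in zip(w, probe) if a != b)
            if mm <= 8:
                expected.append((s, mm))
        got = [(p, mm) for _, p, mm in scan_mirna_sites(element, {"m": mirna},
                                                        max_mismatches=8)]
        assert sorted(got) == sorted(expected)

    def test_mirna_length_validated(self, rng):
        with pytest.raises(ValueError, match="19-24"):
            scan_mirna_sites(random_dna(rng, 100), {"m": "ACGTACGTACGT"})
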