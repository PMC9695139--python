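"""Homology scanning against an independent Smith-Waterman oracle."""

import numpy as np
import pytest

from retrozyme.homology import filter_hits, import_hits, scan_genome
from retrozyme.seq_io import Scaffold, revcomp

from conftest import random_dna

MATCH, MISMATCH, GAP = 1, -2, -3


def sw_oracle(query: str, target: str):
    """Plain O(nm) Smith-Waterman with linear gaps; returns (score, t0, t1, matches, cols)."""
    n, m = len(query), len(target)
    H = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + (MATCH if query[i - 1] == target[j - 1] else MISMATCH)
            H[i, j] = max(0, diag, H[i - 1, j] + GAP, H[i, j - 1] + GAP)
    score = int(H.max())
    i, j = map(int, np.unravel_index(H.argmax(), H.shape))
    t1 = j
    matches = cols = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = MATCH if query[i - 1] == target[j - 1] else MISMATCH
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += query[i - 1] == target[j - 1]
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + GAP:
            i -= 1
        else:
            j -= 1
        cols += 1
    return score, j, t1, matches, cols


@pytest.fixture(scope="module")
def query352():
    rng = np.random.default_rng(42)
    return random_dna(rng, 352)


class TestScanGenome:
    def test_verbatim_planting_recovered_exactly(self, query352):
        rng = np.random.default_rng(7)
        bg = random_dna(rng, 10_000)
        sc = Scaffold("s1", bg[:4000] + query352 + bg[4000:])
        hits = scan_genome([sc], query352)
        assert len(hits) == 1
        h = hits[0]
        assert (h.interval.start, h.interval.end) == (4000, 4352)
        assert h.identity == 1.0 and h.interval.strand == "+"

    def test_reverse_complement_planting(self, query352):
        rng = np.random.default_rng(8)
        bg = random_dna(rng, 10_000)
        sc = Scaffold("s1", bg[:4000] + revcomp(query352) + bg[4000:])
        hits = scan_genome([sc], query352)
        assert len(hits) == 1
        assert hits[0].interval.strand == "-"
        assert (hits[0].interval.start, hits[0].interval.end) == (4000, 4352)

    def test_diverged_copy_matches_sw_oracle(self, query352):
        rng = np.random.default_rng(9)
        copy = list(query352)
        for pos in rng.choice(352, size=35, replace=False):  # ~10% divergence
            copy[pos] = "ACGT"[(("ACGT".index(copy[pos])) + 1 + rng.integers(3)) % 4]
        planted = "".join(copy)
        bg = random_dna(rng, 1600)
        sc = Scaffold("s1", bg[:800] + planted + bg[800:])
        hits = scan_genome([sc], query352)
        assert len(hits) == 1
        score, t0, t1, matches, cols = sw_oracle(query352, sc.seq)
        h = hits[0]
        assert h.score == score
        assert (h.interval.start, h.interval.end) == (t0, t1)
        assert h.identity == pytest.approx(matches / cols)

    def test_strand_symmetry(self, query352, rng):
        bg = random_dna(rng, 3000)
        sc = Scaffold("s1", bg[:1000] + query352 + bg[1000:])
        mirror = Scaffold("s1", revcomp(sc.seq))
        fwd = scan_genome([sc], query352)
        rev = scan_genome([mirror], query352)
        L = len(sc.seq)
        assert len(fwd) == len(rev) == 1
        assert rev[0].interval.start == L - fwd[0].interval.end
        assert rev[0].interval.end == L - fwd[0].interval.start
        assert rev[0].interval.strand != fwd[0].interval.strand

    def test_multiple_planted_copies_all_recovered(self, query352, rng):
        # n diverged copies at >=85% identity: precision = recall = 1
        n = 5
        segments, truth = [], []
        pos = 0
        for i in range(n):
            gap = random_dna(rng, 900)
            copy = list(query352)
            for p in rng.choice(352, size=20, replace=False):
                copy[p] = "ACGT"[("ACGT".index(copy[p]) + 1) % 4]
            segments += [gap, "".join(copy)]
            pos += len(gap)
            truth.append((pos, pos + 352))
            pos += 352
        sc = Scaffold("s1", "".join(segments) + random_dna(rng, 500))
        hits = scan_genome([sc], query352)
        assert len(hits) == n
        for h, (t0, t1) in zip(hits, truth):
            assert abs(h.interval.start - t0) <= 2 and abs(h.interval.end - t1) <= 2

    def test_query_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError, match="shorter than seed"):
            scan_genome([Scaffold("s", "ACGT" * 100)], "ACGTACG")


class TestImportFilter:
    def _write(self, tmp_path, lines):
        p = tmp_path / "h.tsv"
        p.write_text("".join(lines))
        return p

    def test_plus_strand_conversion(self, tmp_path):
        p = self._write(tmp_path, ["q\ts\t100.0\t100\t0\t0\t1\t100\t101\t200\t1e-30\t185\n"])
        h = import_hits(p)[0]
        assert (h.interval.start, h.interval.end, h.interval.strand) == (100, 200, "+")

    def test_minus_strand_conversion(self, tmp_path):
        p = self._write(tmp_path, ["q\ts\t100.0\t100\t0\t0\t1\t100\t200\t101\t1e-30\t185\n"])
        h = import_hits(p)[0]
        assert (h.interval.start, h.interval.end, h.interval.strand) == (100, 200, "-")

    def test_pident_scaled_to_fraction(self, tmp_path):
        p = self._write(tmp_path, ["q\ts\t88.4\t100\t11\t0\t1\t100\t101\t200\t1e-30\t120\n"])
        assert import_hits(p)[0].identity == pytest.approx(0.884)

    def test_filter_thresholds(self, tmp_path):
        lines = [
            "q\ts\t50.0\t100\t50\t0\t1\t100\t101\t200\t1e-30\t20\n",
            "q\ts\t95.0\t100\t5\t0\t1\t100\t301\t400\t1e-30\t170\n",
            "q\ts\t95.0\t30\t1\t0\t1\t30\t501\t530\t1e-30\t50\n",
            "q\ts\t95.0\t100\t5\t0\t1\t100\t701\t800\t1e-3\t170\n",
        ]
        hits = import_hits(self._write(tmp_path, lines))
        kept = filter_hits(hits, max_evalue_like=1e-10, min_identity=0.70, min_length=50)
        assert len(kept) == 1 and kept[0].interval.start == 300

    def test_filter_preserves_all_passing(self, tmp_path):
        lines = [
            f"q\ts\t98.0\t100\t2\t0\t1\t100\t{i * 500 + 1}\t{i * 500 + 100}\t1e-30\t170\n"
            for i in range(83)
        ]
        hits = import_hits(self._write(tmp_path, lines))
        assert len(filter_hits(hits)) == 83

    def test_empty_list(self):
        assert filter_hits([]) == []
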