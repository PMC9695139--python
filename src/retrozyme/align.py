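"""Internal alignment helpers shared across modules.

Two backends are used:

* :class:`Bio.Align.PairwiseAligner` for scored global/local alignments where
  the scoring scheme matters (locus boundary work, LTR mismatch counting,
  homology refinement);
* ``edlib`` for fast edit-distance queries where every difference counts one
  (read classification, contig-vs-genome identity, CR grouping).
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional

import edlib
from Bio import Align


@lru_cache(maxsize=None)
def _aligner(mode: str, match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap
    a.extend_gap_score = gap
    return a


def global_mismatch_count(a: str, b: str, *, match: float = 1.0, mismatch: float = -1.0,
                          gap: float = -2.0) -> int:
    """Substitutions plus gap columns in one optimal global alignment of a vs b.

    Each alignment column holding either a substitution or a gap character
    counts exactly one, giving reproducible integer "mismatch" semantics.
    """
    if not a or not b:
        raise ValueError("global_mismatch_count requires nonempty sequences")
    aligner = _aligner("global", match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sum(1 for x, y in zip(sa, sb) if x != y or x == "-" or y == "-")


def local_align(query: str, target: str, *, match: float = 1.0, mismatch: float = -2.0,
                gap: float = -3.0):
    """Best local (Smith-Waterman) alignment of query against target.

    Returns a dict with score, query/target spans (0-based half-open over the
    maximal aligned region), aligned_length (columns), matches, mismatches and
    gap columns, or None when nothing aligns with positive score.
    """
    aligner = _aligner("local", match, mismatch, gap)
    alns = aligner.align(query, target)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    sq, st = str(aln[0]), str(aln[1])
    matches = mismatches = gaps = 0
    for x, y in zip(sq, st):
        if x == "-" or y == "-":
            gaps += 1
        elif x == y:
            matches += 1
        else:
            mismatches += 1
    qblocks, tblocks = aln.aligned
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    tstart, tend = int(tblocks[0][0]), int(tblocks[-1][1])
    return {
        "score": float(aln.score),
        "query_start": qstart,
        "query_end": qend,
        "target_start": tstart,
        "target_end": tend,
        "aligned_length": len(sq),
        "matches": matches,
        "mismatches": mismatches,
        "gaps": gaps,
    }


def edit_distance(a: str, b: str) -> int:
    """Global (NW) edit distance: substitutions and indels each count one."""
    if not a and not b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def global_identity(a: str, b: str) -> float:
    """1 - editDistance / max(len); a distribution-free pairwise identity."""
    if not a or not b:
        return 0.0
    return 1.0 - edit_distance(a, b) / max(len(a), len(b))


def infix_align(query: str, target: str, max_distance: Optional[int] = None):
    """Best end-to-end placement of ``query`` inside ``target`` (edlib HW mode).

    Gaps count as mismatches (unit-cost edits).  Returns (distance, start, end)
    on the target, or None if no placement within ``max_distance``.
    """
    if not query or not target:
        return None
    k = -1 if max_distance is None else max_distance
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return res["editDistance"], start, end + 1  # edlib end is inclusive


def best_hamming_placement(query: str, target: str) -> tuple[int, int]:
    """Minimum-Hamming ungapped placement of query within target.

    Returns (mismatches, start).  Used for boundary refinement where the two
    sequences are known to differ by substitutions only, so the full-length
    placement is exact.  Raises if target is shorter than query.
    """
    n, m = len(target), len(query)
    if m > n:
        raise ValueError("query longer than target")
    best = (m + 1, -1)
    for s in range(n - m + 1):
        d = 0
        window = target[s : s + m]
        if window == query:
            return 0, s
        for x, y in zip(window, query):
            if x != y:
                d += 1
                if d >= best[0]:
                    break
        if d < best[0]:
            best = (d, s)
    return best
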