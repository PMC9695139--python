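"""Descriptor-based detection of Type III hammerhead ribozymes.

The motif is searched on the DNA (coding) strand of an element, written
5'->3' with the topology of a cis-cleaving hammerhead entered and exited
through helix III::

    [III 5' arm] CUGANGA [II 5' arm] loop2 [II 3' arm] GAAA [I 5' arm] loop1 [I 3' arm] NUH | [III 3' arm]
                 ^ core box 1                           ^ core box 2                       ^ cleavage

Helices I and II are closed by loops inside the motif; helix III is formed by
the flanking arms, so in a circular monomer RNA the motif is closed on
itself.  The scissile bond sits immediately 3' of the NUH triplet (H = A, C
or U) that closes helix I, and the first nucleotide of the downstream
cleavage product is reported as the monomer 5' end.

Detection is purely descriptor-driven: core box 1 (``CUGANGA``) and core box 2
(``GAAA``) are located with at most one substitution each at the conserved
catalytic positions, helix II requires >= 3 consecutive Watson-Crick pairs
between the segments adjacent to the boxes, and helices I and III require
>= 3 pairs flanking the catalytic core.  Substitutions at catalytic positions
are reported and clear ``core_intact`` without suppressing the match; no
thermodynamic folding is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .seq_io import Interval, revcomp

#: conserved box sequences on the DNA strand (U -> T); box 1 position 4 is N
BOX1 = "CTGANGA"
BOX2 = "GAAA"
_BOX1_CONSERVED = (0, 1, 2, 3, 5, 6)

_MIN_STEM = 3
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class Stem:
    """A paired helix: 5' arm [start5, end5), 3' arm [start3, end3)."""

    start5: int
    end5: int
    start3: int
    end3: int
    length: int


@dataclass(frozen=True)
class RibozymeMatch:
    interval: Interval  # element-local coordinates of the whole motif
    box1_pos: int
    box2_pos: int
    stems: tuple[Stem, Stem, Stem]  # helices I, II, III
    cleavage_site: int  # element-local index of the first nt of the downstream product
    core_intact: bool
    core_substitutions: tuple[tuple[int, str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.box1_pos >= self.box2_pos:
            raise ValueError("box 1 must precede box 2")
        if self.core_substitutions and self.core_intact:
            raise ValueError("core substitutions imply core_intact=False")


def _pairs(a: str, b: str) -> bool:
    return (a, b) in _WC


def _box_substitutions(seq: str, pos: int, box: str, conserved) -> Optional[list]:
    """Substitutions at conserved positions; None when more than one (no match)."""
    subs = []
    for i in conserved:
        obs = seq[pos + i]
        if obs != box[i]:
            subs.append((pos + i, obs, box[i]))
            if len(subs) > 1:
                return None
    return subs


def _stem_len(seq: str, end5: int, start3: int, max_out5: int, max_out3: int) -> int:
    """Consecutive WC pairs between seq[end5-1-i] and seq[start3+i], growing outward."""
    n = 0
    while n < max_out5 and n < max_out3:
        i5, i3 = end5 - 1 - n, start3 + n
        if i5 < 0 or i3 >= len(seq) or not _pairs(seq[i5], seq[i3]):
            break
        n += 1
    return n


def detect_hammerhead(seq: str, seq_id: str = "element",
                      box2_min_gap: int = 10, box2_max_gap: int = 60,
                      helix1_max_span: int = 60) -> list[RibozymeMatch]:
    """Scan one sequence (element-local, plus strand) for hammerhead motifs.

    Returns all non-overlapping matches, best first (fewest core
    substitutions, then leftmost).  Sequences shorter than 40 nt cannot hold
    the minimal motif and raise ``ValueError``.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) < 40:
        raise ValueError("sequence too short to contain a hammerhead motif")

    candidates: list[RibozymeMatch] = []
    for p in range(len(seq) - len(BOX1) + 1):
        subs1 = _box_substitutions(seq, p, BOX1, _BOX1_CONSERVED)
        if subs1 is None:
            continue
        for q in range(p + box2_min_gap, min(p + box2_max_gap + 1, len(seq) - len(BOX2) + 1)):
            subs2 = _box_substitutions(seq, q, BOX2, range(len(BOX2)))
            if subs2 is None:
                continue
            # helix II: arms adjacent to box1 (3' side) and box2 (5' side)
            room = (q - (p + 7)) // 2
            h2 = _stem_len_inner(seq, p + 7, q, room)
            if h2 < _MIN_STEM:
                continue
            # helix I: arm starts right after box2; find its partner closing with NUH
            match = _close_helix1(seq, p, q, subs1, subs2, seq_id, helix1_max_span)
            if match is not None:
                candidates.append(match)

    candidates.sort(key=lambda m: (len(m.core_substitutions), m.interval.start))
    kept: list[RibozymeMatch] = []
    for m in candidates:
        if all(
            m.interval.end <= k.interval.start or m.interval.start >= k.interval.end
            for k in kept
        ):
            kept.append(m)
    kept.sort(key=lambda m: m.interval.start)
    return kept


def _stem_len_inner(seq: str, arm5_start: int, arm3_end: int, max_len: int) -> int:
    """Consecutive WC pairs growing inward from both segment boundaries."""
    n = 0
    while n < max_len:
        i5, i3 = arm5_start + n, arm3_end - 1 - n
        if i5 >= i3 or not _pairs(seq[i5], seq[i3]):
            break
        n += 1
    return n


def _close_helix1(seq: str, p: int, q: int, subs1, subs2, seq_id: str,
                  helix1_max_span: int) -> Optional[RibozymeMatch]:
    arm_start = q + 4
    for r in range(arm_start + 2 * _MIN_STEM + 1, min(arm_start + helix1_max_span, len(seq) - 2)):
        # NUH triplet closing helix I: positions r, r+1, r+2
        if seq[r + 1] != "T" or seq[r + 2] not in "ACT":
            continue
        h1 = _stem_len_inner(seq, arm_start, r, (r - arm_start) // 2)
        if h1 < _MIN_STEM:
            continue
        # helix III: >=3 pairs flanking the core (5' of box1, 3' of the NUH triplet)
        h3 = _stem_len(seq, p, r + 3, p, len(seq) - (r + 3))
        if h3 < _MIN_STEM:
            continue
        h2 = _stem_len_inner(seq, p + 7, q, (q - (p + 7)) // 2)
        cleavage = r + 3
        subs = tuple(subs1 + subs2)
        stems = (
            Stem(arm_start, arm_start + h1, r - h1, r, h1),
            Stem(p + 7, p + 7 + h2, q - h2, q, h2),
            Stem(p - h3, p, cleavage, cleavage + h3, h3),
        )
        return RibozymeMatch(
            interval=Interval(seq_id, p - h3, cleavage + h3, "+"),
            box1_pos=p,
            box2_pos=q,
            stems=stems,
            cleavage_site=cleavage,
            core_intact=not subs,
            core_substitutions=subs,
        )
    return None


# ---------------------------------------------------------------------------
# Synthetic motif construction (shared with the genome simulator)
# ---------------------------------------------------------------------------


def build_hammerhead_cassette(stem1: str = "GCAC", stem2: str = "GGCA", stem3: str = "AGCC",
                              loop1: str = "TTCG", loop2: str = "TCTT",
                              nuh: str = "GTC") -> str:
    """Assemble a synthetic Type III hammerhead cassette satisfying the descriptor.

    The default arms give three 4-bp helices; the downstream cleavage product
    begins with G (``revcomp(stem3)[0]``), matching the observed monomer 5'
    end.  This is a synthetic test construct, not any natural ribozyme
    sequence.
    """
    if nuh[1] != "T" or nuh[2] not in "ACT":
        raise ValueError("third segment must be an NUH triplet (U=T, H in {A,C,T})")
    return (
        stem3 + BOX1.replace("N", "T") + stem2 + loop2 + revcomp(stem2)
        + BOX2 + stem1 + loop1 + revcomp(stem1) + nuh + revcomp(stem3)
    )


def cassette_cleavage_offset(cassette_kwargs: Optional[dict] = None) -> int:
    """Offset of the cleavage site within a cassette built with the same arguments."""
    kw = cassette_kwargs or {}
    stem1 = kw.get("stem1", "GCAC")
    stem2 = kw.get("stem2", "GGCA")
    stem3 = kw.get("stem3", "AGCC")
    loop1 = kw.get("loop1", "TTCG")
    loop2 = kw.get("loop2", "TCTT")
    return (
        len(stem3) + len(BOX1) + 2 * len(stem2) + len(loop2) + len(BOX2)
        + 2 * len(stem1) + len(loop1) + 3
    )
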