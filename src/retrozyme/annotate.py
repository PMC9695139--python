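"""Structural annotation: homology hits -> annotated retrozyme loci.

A retrozyme locus is two near-identical LTRs (each ~300-400 bp, carrying a
hammerhead ribozyme) around a group-specific central region (CR) whose ends
hold the primer-binding site (PBS, complementary to the tRNA-Met 3'
terminus) and a polypurine tract (PPT).  The element is flanked by a 4-nt
target-site duplication (TSD).  The number of substitutions between the two
LTRs of one element dates its integration: LTRs are identical at insertion
and diverge with the host genome afterwards.

This module pairs LTR hits into candidate elements, refines boundaries,
detects TSD/PBS/PPT and ribozymes, counts LTR-LTR mismatches, clusters loci
into CR groups, and models the RNA-level events used downstream (monomer
excision at ribozyme cleavage sites, divergent-primer amplicons on circular
templates, miRNA-site support).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from . import seq_io
from .align import best_hamming_placement, global_identity, global_mismatch_count
from .homology import HomologyHit
from .ribozyme import RibozymeMatch, detect_hammerhead
from .seq_io import Interval, Scaffold, extract, revcomp


@dataclass
class RetrozymeLocus:
    """An annotated genomic retrozyme element.

    Completeness classes: ``full`` (two LTRs + CR), ``cr_partial`` (a CR with
    at most one intact LTR), ``ltr_fragment`` (an isolated LTR hit).  On
    minus-strand elements the 5' LTR is the rightmost interval in plus
    coordinates; all intervals are stored on plus coordinates with the strand
    flag deciding orientation.
    """

    id: str
    scaffold_id: str
    strand: str
    ltr5: Optional[Interval]
    ltr3: Optional[Interval]
    cr: Optional[Interval]
    tsd: Optional[str] = None
    pbs: Optional[Interval] = None
    ppt: Optional[Interval] = None
    ribozymes: list[RibozymeMatch] = field(default_factory=list)
    ltr_mismatches: int = 0
    group: str = ""
    completeness: str = "full"
    tandem: bool = False

    def __post_init__(self) -> None:
        if self.completeness == "full":
            if self.ltr5 is None or self.ltr3 is None or self.cr is None:
                raise ValueError(f"{self.id}: full locus requires both LTRs and a CR")
            left, right = (self.ltr5, self.ltr3) if self.strand == "+" else (self.ltr3, self.ltr5)
            if not left.end <= self.cr.start <= self.cr.end <= right.start:
                raise ValueError(f"{self.id}: LTR/CR intervals out of order")
        if self.tsd is not None and len(self.tsd) != 4:
            raise ValueError(f"{self.id}: TSD must be exactly 4 nt")

    @property
    def span(self) -> Interval:
        parts = [iv for iv in (self.ltr5, self.cr, self.ltr3) if iv is not None]
        return Interval(
            self.scaffold_id,
            min(iv.start for iv in parts),
            max(iv.end for iv in parts),
            self.strand,
        )

    def element_seq(self, scaffold_seq: str) -> str:
        """Element sequence in its own 5'->3' orientation."""
        return extract(scaffold_seq, self.span)


@dataclass(frozen=True)
class GroupAssignment:
    locus_id: str
    group: str
    max_cr_identity_within: float
    max_cr_identity_between: float


class GroupingError(ValueError):
    """Single-linkage chaining joined loci whose CRs share no significant similarity."""


# ---------------------------------------------------------------------------
# LTR pairing
# ---------------------------------------------------------------------------


def pair_ltrs(hits: Sequence[HomologyHit], min_ltr_len: int = 250, max_ltr_len: int = 450,
              min_cr_len: int = 100, max_cr_len: int = 1500,
              cr_hits: Sequence[HomologyHit] = (), locus_prefix: str = "RZ",
              ) -> list[RetrozymeLocus]:
    """Pair same-scaffold, same-strand LTR hits into candidate loci.

    Consecutive length-window LTR hits separated by a CR-range gap become one
    ``full`` candidate; chains of three or more equally spaced LTR hits are
    merged into a single candidate flagged ``tandem`` (an incomplete tandem
    repeat of the element).  Unpaired LTR hits next to a CR hit become
    ``cr_partial``; remaining unpaired hits become ``ltr_fragment``.
    """
    for lo, hi in ((min_ltr_len, max_ltr_len), (min_cr_len, max_cr_len)):
        if not 0 < lo <= hi:
            raise ValueError("length windows must be positive and ordered")

    by_key: dict[tuple[str, str], list[HomologyHit]] = {}
    for h in hits:
        by_key.setdefault((h.interval.scaffold_id, h.interval.strand), []).append(h)

    loci: list[RetrozymeLocus] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{locus_prefix}{counter}"

    leftovers: list[HomologyHit] = []
    for (scaffold_id, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.interval.start)
        ltr_like = [h for h in group if min_ltr_len <= len(h.interval) <= max_ltr_len]
        other = [h for h in group if h not in ltr_like]
        leftovers.extend(other)

        i = 0
        while i < len(ltr_like):
            # grow a chain of CR-range-spaced LTR hits starting at i
            chain = [ltr_like[i]]
            j = i + 1
            while j < len(ltr_like):
                gap = ltr_like[j].interval.start - chain[-1].interval.end
                if not min_cr_len <= gap <= max_cr_len:
                    break
                if len(chain) >= 2:
                    # tandem repeats of one unit are equally spaced; an
                    # unrelated element at a different spacing must not chain
                    first_gap = chain[1].interval.start - chain[0].interval.end
                    if abs(gap - first_gap) > 30:
                        break
                chain.append(ltr_like[j])
                j += 1
            if len(chain) >= 2:
                left, right = chain[0].interval, chain[-1].interval
                cr = Interval(scaffold_id, chain[0].interval.end,
                              chain[1].interval.start, strand)
                ltr5, ltr3 = (left, right) if strand == "+" else (right, left)
                loci.append(
                    RetrozymeLocus(
                        id=next_id(), scaffold_id=scaffold_id, strand=strand,
                        ltr5=ltr5, ltr3=ltr3, cr=cr,
                        completeness="full", tandem=len(chain) >= 3,
                    )
                )
                i = j
            else:
                leftovers.append(ltr_like[i])
                i += 1

    # leftover LTR hits: cr_partial when a CR hit sits alongside, else ltr_fragment
    cr_by_key: dict[tuple[str, str], list[HomologyHit]] = {}
    for h in cr_hits:
        cr_by_key.setdefault((h.interval.scaffold_id, h.interval.strand), []).append(h)
    used_cr: set[tuple[str, str, int]] = set()
    for h in sorted(leftovers, key=lambda h: (h.interval.scaffold_id, h.interval.start)):
        iv = h.interval
        key = (iv.scaffold_id, iv.strand)
        adjacent_cr = None
        for idx, ch in enumerate(cr_by_key.get(key, [])):
            if (*key, idx) in used_cr:
                continue
            gap = max(ch.interval.start - iv.end, iv.start - ch.interval.end)
            if gap <= 50:
                adjacent_cr = (idx, ch)
                break
        if adjacent_cr is not None:
            idx, ch = adjacent_cr
            used_cr.add((*key, idx))
            five_prime_side = (iv.end <= ch.interval.start) == (iv.strand == "+")
            loci.append(
                RetrozymeLocus(
                    id=next_id(), scaffold_id=iv.scaffold_id, strand=iv.strand,
                    ltr5=iv if five_prime_side else None,
                    ltr3=None if five_prime_side else iv,
                    cr=ch.interval, completeness="cr_partial",
                )
            )
        else:
            loci.append(
                RetrozymeLocus(
                    id=next_id(), scaffold_id=iv.scaffold_id, strand=iv.strand,
                    ltr5=iv, ltr3=None, cr=None, completeness="ltr_fragment",
                )
            )
    return loci


def _refine_interval(scaffold_seq: str, iv: Interval, probe: str,
                     pad: int = 40) -> Interval:
    """Full-probe-length minimum-Hamming placement around a (possibly trimmed) hit."""
    w0 = max(0, min(iv.start, iv.end - len(probe)) - pad)
    w1 = min(len(scaffold_seq), max(iv.end, iv.start + len(probe)) + pad)
    _, off = best_hamming_placement(probe, scaffold_seq[w0:w1])
    return Interval(iv.scaffold_id, w0 + off, w0 + off + len(probe), iv.strand)


def refine_boundaries(locus: RetrozymeLocus, scaffold_seq: str,
                      ltr_query: Optional[str] = None) -> RetrozymeLocus:
    """Re-delimit LTR boundaries by full-length ungapped placement.

    Local alignment trims mismatched ends, so a hit against a diverged LTR
    copy can start or stop a few bases inside the true element.  The two
    LTRs of one element were identical at integration and diverge mostly by
    substitutions afterwards, so a full-length minimum-Hamming placement
    recovers exact boundaries: the left LTR is first re-placed with the
    search query (when given), then every other LTR of the element is
    re-placed with the refined left LTR sequence.  Refinement assumes
    substitution-dominated divergence, the expected regime for young
    elements; indel-riddled copies keep their local-alignment boundaries in
    spirit (the minimum-Hamming placement is then merely approximate).
    """
    if locus.completeness != "full":
        return locus
    left, right = sorted((locus.ltr5, locus.ltr3), key=lambda iv: iv.start)
    if ltr_query:
        left = _refine_interval(scaffold_seq, left, ltr_query)
    anchor_seq = scaffold_seq[left.start : left.end]
    right = _refine_interval(scaffold_seq, right, anchor_seq)
    if locus.tandem:
        # the CR ends at the *second* LTR of the chain; re-place it too
        mid = _refine_interval(
            scaffold_seq,
            Interval(locus.scaffold_id, locus.cr.end,
                     locus.cr.end + len(anchor_seq), locus.strand),
            anchor_seq,
        )
        cr_end = mid.start
    else:
        cr_end = right.start
    cr = Interval(locus.scaffold_id, left.end, cr_end, locus.strand)
    ltr5, ltr3 = (left, right) if locus.strand == "+" else (right, left)
    return replace(locus, ltr5=ltr5, ltr3=ltr3, cr=cr)


# ---------------------------------------------------------------------------
# Element features
# ---------------------------------------------------------------------------


def detect_tsd(scaffold_seq: str, locus: RetrozymeLocus) -> Optional[str]:
    """The 4-nt target-site duplication, or None.

    Requires an exact 4/4 match between the 4 nt immediately 5' and 3' of the
    element on the plus strand; N-containing or mismatched flanks yield None.
    Elements at a scaffold edge yield None rather than an error.
    """
    span = locus.span
    if span.start < 4 or span.end + 4 > len(scaffold_seq):
        return None
    left = scaffold_seq[span.start - 4 : span.start]
    right = scaffold_seq[span.end : span.end + 4]
    if "N" in left or "N" in right or left != right:
        return None
    return left


def find_pbs(cr_seq: str, trna_3prime_seq: str, window: int = 30,
             min_complementary: int = 10) -> Optional[tuple[int, int]]:
    """Locate the primer-binding site in the first ``window`` nt of the CR.

    The PBS is the reverse complement of a 3'-terminal substring of the
    tRNA-Met sequence, at least ``min_complementary`` nt long.  The longest
    (then leftmost) match fully inside the window is returned as a CR-local
    (start, end) span; None when absent.
    """
    trna = seq_io.normalize_dna(trna_3prime_seq, allow_n=False, context="tRNA 3' sequence")
    if len(trna) < min_complementary:
        raise ValueError("tRNA 3' sequence shorter than min_complementary")
    region = cr_seq[:window]
    for length in range(len(trna), min_complementary - 1, -1):
        probe = revcomp(trna[-length:])
        pos = region.find(probe)
        if pos >= 0 and pos + length <= window:
            return (pos, pos + length)
    return None


def find_ppt(cr_seq: str, window: int = 40, min_len: int = 10,
             min_purine_frac: float = 0.9) -> Optional[tuple[int, int]]:
    """Locate the polypurine tract in the last ``window`` nt of the CR.

    Returns the longest run (ties -> nearest the CR 3' end) of length >=
    ``min_len`` whose purine (A/G) fraction is >= ``min_purine_frac``, as a
    CR-local (start, end) span.  A run must begin and end on a purine.
    """
    if window > len(cr_seq):
        window = len(cr_seq)
    tail_off = len(cr_seq) - window
    tail = cr_seq[tail_off:]
    is_pur = [c in "AG" for c in tail]
    best: Optional[tuple[int, int]] = None
    for i in range(len(tail)):
        if not is_pur[i]:
            continue
        purines = 0
        for j in range(i + 1, len(tail) + 1):
            if is_pur[j - 1]:
                purines += 1
            length = j - i
            if (length >= min_len and is_pur[j - 1]
                    and purines / length >= min_purine_frac):
                cand = (i, j)
                if (
                    best is None
                    or length > best[1] - best[0]
                    or (length == best[1] - best[0] and i > best[0])
                ):
                    best = cand
    if best is None:
        return None
    return (tail_off + best[0], tail_off + best[1])


def count_ltr_mismatches(ltr5_seq: str, ltr3_seq: str) -> int:
    """Mismatches between the two LTRs of one element.

    Global alignment (match +1, mismatch -1, gap -2); the count is
    substitutions plus gap columns, so a 1-nt indel contributes 1.
    """
    return global_mismatch_count(ltr5_seq, ltr3_seq)


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


def classify_groups(loci: Sequence[RetrozymeLocus], cr_seqs: dict[str, str],
                    grouping_identity: float = 0.80,
                    significance_identity: float = 0.50) -> list[GroupAssignment]:
    """Single-linkage clustering of loci on pairwise global CR identity.

    Loci join one group when linked by identity >= ``grouping_identity``.
    Groups are labelled "Group 1", "Group 2", ... in decreasing size order
    (ties by smallest member locus id).  If chaining ever joins a pair below
    ``significance_identity`` a :class:`GroupingError` is raised: such CRs
    share no significant similarity and must not share a group.  Loci without
    an extractable CR are excluded (they are simply absent from the result).
    """
    ids = [loc.id for loc in loci if loc.id in cr_seqs and cr_seqs[loc.id]]
    n = len(ids)
    ident: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            ident[(ids[i], ids[j])] = global_identity(cr_seqs[ids[i]], cr_seqs[ids[j]])

    def pid(a: str, b: str) -> float:
        if a == b:
            return 1.0
        return ident.get((a, b), ident.get((b, a), 0.0))

    # union-find single linkage
    parent = {x: x for x in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), v in ident.items():
        if v >= grouping_identity:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    clusters: dict[str, list[str]] = {}
    for x in ids:
        clusters.setdefault(find(x), []).append(x)
    ordered = sorted(clusters.values(), key=lambda ms: (-len(ms), min(ms)))

    assignments: list[GroupAssignment] = []
    for gi, members in enumerate(ordered, 1):
        label = f"Group {gi}"
        for a in members:
            for b in members:
                if a != b and pid(a, b) < significance_identity:
                    raise GroupingError(
                        f"loci {a} and {b} chained into {label} despite CR identity "
                        f"{pid(a, b):.2f} < {significance_identity}"
                    )
        for m in sorted(members):
            within = max((pid(m, o) for o in members if o != m), default=1.0)
            between = max(
                (pid(m, o) for other in ordered if other is not members for o in other),
                default=0.0,
            )
            assignments.append(GroupAssignment(m, label, within, between))
    return assignments


# ---------------------------------------------------------------------------
# RNA-level models
# ---------------------------------------------------------------------------


def excise_monomer(transcript_seq: str,
                   ribozyme_matches: Sequence[RibozymeMatch]) -> Optional[str]:
    """Unit-length monomer released by double ribozyme self-cleavage.

    With at least two cleavage sites on the transcript the monomer is the
    sequence between the first and second scissile bond; its first nucleotide
    is the nucleotide immediately 3' of the first cut (observed to be G in
    5'-RACE of self-processed retrozyme RNA).  Fewer than two sites: None.
    """
    sites = sorted(m.cleavage_site for m in ribozyme_matches)
    if len(sites) < 2:
        return None
    return transcript_seq[sites[0] : sites[1]]


@dataclass(frozen=True)
class Amplicon:
    start: int
    end: int  # may exceed template length on a circle (junction-spanning)
    length: int
    spans_junction: bool


def predict_amplicon(template_seq: str, is_circular: bool, fwd_primer: str,
                     rev_primer: str, max_len: int = 5000) -> list[Amplicon]:
    """Exact-binding PCR products on a linear or circular template.

    The forward primer binds the sense strand where it occurs verbatim; the
    reverse primer binds antisense where its reverse complement occurs.  On a
    circular template binding sites are searched on the doubled sequence, so
    divergent primer pairs yield a junction-spanning product; on a linear
    template divergent primers yield nothing.  Product length runs from the
    first base of the forward site to the last base of the reverse site
    inclusive.
    """
    fwd = seq_io.normalize_dna(fwd_primer, allow_n=False, context="forward primer")
    rev = seq_io.normalize_dna(rev_primer, allow_n=False, context="reverse primer")
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    L = len(template_seq)
    search = template_seq + template_seq if is_circular else template_seq
    rev_site = revcomp(rev)

    def occurrences(pattern: str, limit: int) -> list[int]:
        out, pos = [], search.find(pattern)
        while pos >= 0 and pos < limit:
            out.append(pos)
            pos = search.find(pattern, pos + 1)
        return out

    fwd_sites = occurrences(fwd, L if is_circular else L)
    rev_sites = occurrences(rev_site, len(search))
    amps: list[Amplicon] = []
    seen: set[tuple[int, int]] = set()
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev)
            length = end - f
            if r < f + len(fwd):
                continue
            if length > max_len:
                continue
            if is_circular and length > L:
                continue  # one lap only: longer products are concatemer repeats
            key = (f % L if is_circular else f, length)
            if key in seen:
                continue
            seen.add(key)
            amps.append(
                Amplicon(start=f, end=end, length=length,
                         spans_junction=bool(is_circular and end > L))
            )
    amps.sort(key=lambda a: (a.start, a.length))
    return amps


def scan_mirna_sites(retrozyme_seq: str, mirna_set: dict[str, str],
                     max_mismatches: int = 4, circular: bool = True,
                     ) -> list[tuple[str, int, int]]:
    """Potential miRNA target sites on a retrozyme RNA.

    Slides the reverse complement of each miRNA along the element (on the
    doubled sequence when circular) and reports (mirna_id, position,
    mismatches) for sites with at most ``max_mismatches`` ("less than five"
    at the default).  miRNAs must be 19-24 nt.
    """
    L = len(retrozyme_seq)
    target = retrozyme_seq + retrozyme_seq if circular else retrozyme_seq
    out: list[tuple[str, int, int]] = []
    for mid, mseq in sorted(mirna_set.items()):
        m = seq_io.normalize_dna(mseq, allow_n=False, context=f"miRNA {mid}")
        if not 19 <= len(m) <= 24:
            raise ValueError(f"miRNA {mid}: length {len(m)} outside 19-24 nt")
        probe = revcomp(m)
        seen: set[int] = set()
        for s in range(min(L, len(target) - len(probe) + 1)):
            mm = sum(1 for a, b in zip(target[s : s + len(probe)], probe) if a != b)
            if mm <= max_mismatches and s % L not in seen:
                seen.add(s % L)
                out.append((mid, s % L, mm))
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def annotate_genome(scaffolds: Sequence[Scaffold], ltr_hits: Sequence[HomologyHit],
                    cr_hits: Sequence[HomologyHit] = (), trna_3prime: Optional[str] = None,
                    ltr_query: Optional[str] = None,
                    min_ltr_len: int = 250, max_ltr_len: int = 450,
                    min_cr_len: int = 100, max_cr_len: int = 1500,
                    grouping_identity: float = 0.80, significance_identity: float = 0.50,
                    locus_prefix: str = "RZ") -> list[RetrozymeLocus]:
    """Full annotation pass: pair, refine, feature-detect, group.

    Returns loci sorted by scaffold and start.  Group labels are attached to
    full loci from CR clustering; partial and fragment loci keep an empty
    group label.
    """
    seqs = {s.id: s.seq for s in scaffolds}
    loci = pair_ltrs(ltr_hits, min_ltr_len, max_ltr_len, min_cr_len, max_cr_len,
                     cr_hits=cr_hits, locus_prefix=locus_prefix)
    out: list[RetrozymeLocus] = []
    cr_seqs: dict[str, str] = {}
    for locus in loci:
        seq = seqs[locus.scaffold_id]
        locus = refine_boundaries(locus, seq, ltr_query=ltr_query)
        locus.tsd = detect_tsd(seq, locus)
        if locus.completeness == "full":
            cr_seq = extract(seq, locus.cr)
            cr_seqs[locus.id] = cr_seq
            if trna_3prime:
                span = find_pbs(cr_seq, trna_3prime)
                if span is not None:
                    locus.pbs = _cr_local_to_scaffold(locus, span)
            span = find_ppt(cr_seq)
            if span is not None:
                locus.ppt = _cr_local_to_scaffold(locus, span)
            locus.ltr_mismatches = count_ltr_mismatches(
                extract(seq, locus.ltr5), extract(seq, locus.ltr3)
            )
            span_len = len(locus.span)
            for ltr, off in ((locus.ltr5, 0), (locus.ltr3, span_len - len(locus.ltr3))):
                ltr_seq = extract(seq, ltr)
                if len(ltr_seq) >= 40:
                    locus.ribozymes.extend(
                        _shift_match(m, off)
                        for m in detect_hammerhead(ltr_seq, seq_id=locus.id)
                    )
        out.append(locus)

    full = [loc for loc in out if loc.completeness == "full"]
    if full:
        for ga in classify_groups(full, cr_seqs, grouping_identity, significance_identity):
            next(loc for loc in full if loc.id == ga.locus_id).group = ga.group
    out.sort(key=lambda loc: (loc.scaffold_id, loc.span.start))
    return out


def monomer_annotation(locus: RetrozymeLocus) -> RetrozymeLocus:
    """Re-express a full locus in monomer coordinates (one LTR then the CR).

    The circular monomer RNA of an element is one LTR plus one CR; region
    assignment against monomer references needs spans in that coordinate
    system rather than the genomic two-LTR layout.
    """
    if locus.completeness != "full":
        raise ValueError("monomer annotation requires a full locus")
    L = len(locus.ltr5)
    total = L + len(locus.cr)
    return RetrozymeLocus(
        id=locus.id, scaffold_id=f"{locus.id}.monomer", strand="+",
        ltr5=Interval(f"{locus.id}.monomer", 0, L), ltr3=None,
        cr=Interval(f"{locus.id}.monomer", L, total),
        group=locus.group, completeness="cr_partial",
        ltr_mismatches=locus.ltr_mismatches,
    )


def _shift_match(m: RibozymeMatch, offset: int) -> RibozymeMatch:
    """Translate a ribozyme match from LTR-local to element-local coordinates."""
    if offset == 0:
        return m
    from .ribozyme import Stem

    return replace(
        m,
        interval=Interval(m.interval.scaffold_id, m.interval.start + offset,
                          m.interval.end + offset, m.interval.strand),
        box1_pos=m.box1_pos + offset,
        box2_pos=m.box2_pos + offset,
        stems=tuple(
            Stem(s.start5 + offset, s.end5 + offset, s.start3 + offset,
                 s.end3 + offset, s.length)
            for s in m.stems
        ),
        cleavage_site=m.cleavage_site + offset,
        core_substitutions=tuple(
            (pos + offset, obs, exp) for pos, obs, exp in m.core_substitutions
        ),
    )


def _cr_local_to_scaffold(locus: RetrozymeLocus, span: tuple[int, int]) -> Interval:
    """Map a CR-local (start, end) span to scaffold plus-strand coordinates."""
    s, e = span
    if locus.strand == "+":
        return Interval(locus.scaffold_id, locus.cr.start + s, locus.cr.start + e, "+")
    return Interval(locus.scaffold_id, locus.cr.end - e, locus.cr.end - s, "-")
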