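"""Transcriptome analysis of retrozyme RNA populations.

Two analyses are implemented:

* per-read classification against the closest genomic retrozyme copy, with
  mismatch-percentage binning ({perfect, 1%, 2%, 3-13%, >13%} for 100-nt
  reads, where one substitution is one percent) and LTR/CR region assignment;
* a deliberately strict overlap assembler that forbids any mismatch within an
  overlap and caps the new sequence added by each merge at 25 nt, so that a
  contig can never anchor foreign reads on a long single-read overhang.  This
  conservatism is the point: genomic retrozyme copies are close in sequence
  and a permissive assembler would chimerize reads from different RNA
  molecules.

Circular references are handled by doubling the sequence, so junction-
spanning reads from circular monomer RNA align without special cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .annotate import RetrozymeLocus
from .seq_io import Read, revcomp

BINS = ("perfect", "1%", "2%", "3-13%", ">13%")


@dataclass
class ReadClassification:
    read_id: str
    best_ref_id: str
    strand: str
    mismatches: int
    aligned_len: int
    ref_start: int  # placement on the (un-doubled) reference, mod unit length
    ref_end: int    # may exceed unit length for junction-spanning placements
    region: Optional[str] = None

    @property
    def mismatch_pct(self) -> float:
        return 100.0 * self.mismatches / self.aligned_len

    @property
    def bin(self) -> str:
        return bin_mismatch_pct(self.mismatch_pct)


def bin_mismatch_pct(pct: float) -> str:
    """Round-half-up of the mismatch percentage to the binning categories."""
    b = int(pct + 0.5)
    if b == 0:
        return "perfect"
    if b == 1:
        return "1%"
    if b == 2:
        return "2%"
    if b <= 13:
        return "3-13%"
    return ">13%"


def align_reads_to_refs(reads: Sequence[Read], refs: dict[str, str],
                        circular: bool = True, min_identity: float = 0.85,
                        ) -> tuple[list[ReadClassification], int]:
    """Classify each read against its minimum-mismatch reference.

    Every read is aligned end-to-end (read-global, reference-infix; gaps count
    as mismatches) on both strands against every reference, doubled when
    ``circular``.  Ties between references go to the lexicographically lowest
    reference id.  Reads whose best identity falls below ``min_identity`` are
    dropped; the second return value counts them.
    """
    if not refs:
        raise ValueError("reference set is empty")
    if not reads:
        raise ValueError("read set is empty")
    targets = {
        rid: (seq + seq if circular and len(seq) > 0 else seq)
        for rid, seq in refs.items()
    }
    out: list[ReadClassification] = []
    dropped = 0
    for read in reads:
        best: Optional[tuple[int, str, str, int, int]] = None
        max_k = int(len(read.seq) * (1 - min_identity))
        for rid in sorted(targets):
            for strand, qseq in (("+", read.seq), ("-", revcomp(read.seq))):
                res = edlib.align(qseq, targets[rid], mode="HW", task="locations",
                                  k=max_k if best is None else min(max_k, best[0]))
                d = res["editDistance"]
                if d < 0:
                    continue
                start, end = res["locations"][0]
                cand = (d, rid, strand, start, end + 1)
                if best is None or cand[0] < best[0]:
                    best = cand
        if best is None:
            dropped += 1
            continue
        d, rid, strand, start, end = best
        L = len(refs[rid])
        if circular and start >= L:
            start, end = start - L, end - L
        out.append(
            ReadClassification(
                read_id=read.id, best_ref_id=rid, strand=strand,
                mismatches=d, aligned_len=len(read.seq),
                ref_start=start, ref_end=end,
            )
        )
    return out, dropped


def assign_region(classification: ReadClassification,
                  annotated_loci: dict[str, RetrozymeLocus]) -> str:
    """Label a classified read by majority overlap with LTR vs CR spans.

    ``annotated_loci`` maps reference id to the locus the reference sequence
    was extracted from; spans are interpreted element-locally.  A read whose
    footprint overlaps LTR and CR equally is labelled ``junction``; CR labels
    carry the group of the reference locus (``CR_group1`` / ``CR_group2``).
    """
    locus = annotated_loci.get(classification.best_ref_id)
    if locus is None or locus.cr is None or (locus.ltr5 is None and locus.ltr3 is None):
        raise ValueError(
            f"reference {classification.best_ref_id} lacks LTR/CR annotation"
        )
    span = locus.span
    L = len(span)

    def element_local(iv) -> tuple[int, int]:
        if locus.strand == "+":
            return iv.start - span.start, iv.end - span.start
        return span.end - iv.end, span.end - iv.start

    # a monomer reference carries a single LTR; a genomic element has two
    ltr_spans = [element_local(iv) for iv in (locus.ltr5, locus.ltr3) if iv is not None]
    cr_span = element_local(locus.cr)

    def footprint_overlap(a0: int, a1: int) -> tuple[int, int]:
        ltr = cr = 0
        # footprint may wrap the circular junction: split into unit-length pieces
        pieces = []
        s, e = a0, a1
        while s < e:
            s0 = s % L
            chunk = min(e - s, L - s0)
            pieces.append((s0, s0 + chunk))
            s += chunk
        for p0, p1 in pieces:
            for b0, b1 in ltr_spans:
                ltr += max(0, min(p1, b1) - max(p0, b0))
            cr += max(0, min(p1, cr_span[1]) - max(p0, cr_span[0]))
        return ltr, cr

    ltr, cr = footprint_overlap(classification.ref_start, classification.ref_end)
    if ltr == cr:
        return "junction"
    if ltr > cr:
        return "LTR"
    g = locus.group.replace("Group ", "group") if locus.group else "group?"
    return f"CR_{g}"


def mismatch_spectrum(classifications: Sequence[ReadClassification]) -> dict[str, float]:
    """Fraction of classified reads in each mismatch bin (sums to 1)."""
    if not classifications:
        raise ValueError("no classifications to summarize")
    counts = {b: 0 for b in BINS}
    for c in classifications:
        counts[c.bin] += 1
    n = len(classifications)
    return {b: counts[b] / n for b in BINS}


# ---------------------------------------------------------------------------
# Strict contig assembly
# ---------------------------------------------------------------------------


@dataclass
class StrictContig:
    """An exact-overlap contig with its member-read placements.

    Invariant (re-checked by :func:`audit_contigs`): every member read matches
    the contig verbatim at its recorded offset, and every recorded extension
    is within the cap active at assembly time.
    """

    id: str
    seq: str
    members: list[tuple[str, int]]
    extension_log: list[int] = field(default_factory=list)


def _best_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest exact suffix(a)/prefix(b) overlap >= min_overlap, else 0."""
    max_o = min(len(a), len(b))
    for o in range(max_o, min_overlap - 1, -1):
        if a.endswith(b[:o]):
            return o
    return 0


def assemble_strict(reads: Sequence[Read], min_overlap: int = 20,
                    max_extension: int = 25,
                    exact_threshold: int = 10) -> list[StrictContig]:
    """Strict exact-overlap assembly with a per-merge extension cap.

    A merge joins two contigs whose sequences share an exact suffix/prefix
    overlap of at least ``min_overlap`` nt (or where one contains the other
    verbatim); it is legal only when the new sequence it adds relative to
    the larger contig is at most ``max_extension`` nt.  A single mismatch in
    an overlap forbids the merge.  Unmergeable reads remain singleton
    contigs.

    Up to ``exact_threshold`` reads the assembler solves the merge-order
    problem exactly (exhaustive search with memoization, minimizing the
    number of contigs and then the total assembled length, with a canonical
    tie-break); beyond that it applies the globally best merge greedily
    (longest overlap, then lexicographically smallest contig-id pair, where
    a contig is identified by its smallest member read id).  Both modes are
    deterministic and independent of input read order.
    """
    if min_overlap < 15:
        raise ValueError("min_overlap must be >= 15")
    ids = [r.id for r in reads]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate read ids: {dup}")

    contigs: dict[str, StrictContig] = {
        r.id: StrictContig(id=r.id, seq=r.seq, members=[(r.id, 0)]) for r in reads
    }
    if len(reads) <= exact_threshold:
        return _finalize(_assemble_exact(list(contigs.values()),
                                         min_overlap, max_extension))

    def candidate(a: StrictContig, b: StrictContig):
        """Best legal merge of b onto the end of a (or containment), or None."""
        if len(b.seq) <= len(a.seq):
            pos = a.seq.find(b.seq)
            if pos >= 0:
                return (len(b.seq), a.id, b.id, "contain", pos)
        o = _best_overlap(a.seq, b.seq, min_overlap)
        # extension = new sequence added relative to the larger contig; this
        # is what the 25-nt cap limits (the contig may grow by at most that
        # much per added read), and it keeps prepending a short read to a
        # long contig legal while still rejecting long-overhang anchoring
        if o and min(len(a.seq), len(b.seq)) - o <= max_extension:
            return (o, a.id, b.id, "extend", o)
        return None

    # candidate merges are maintained incrementally: recomputing the full
    # pair table after every merge is quadratic per round and dominates at
    # realistic library sizes
    cands: dict[tuple[str, str], tuple] = {}
    keys = sorted(contigs)
    for ka in keys:
        for kb in keys:
            if ka != kb:
                c = candidate(contigs[ka], contigs[kb])
                if c is not None:
                    cands[(ka, kb)] = c

    while cands:
        # longest overlap first, then smallest id pair
        o, ka, kb, kind, arg = min(cands.values(), key=lambda c: (-c[0], c[1], c[2]))
        a, b = contigs.pop(ka), contigs.pop(kb)
        merged = _merge_pair(a, b, kind, arg)
        for pair in [p for p in cands if ka in p or kb in p]:
            del cands[pair]
        for other in contigs:
            c = candidate(merged, contigs[other])
            if c is not None:
                cands[(merged.id, other)] = c
            c = candidate(contigs[other], merged)
            if c is not None:
                cands[(other, merged.id)] = c
        contigs[merged.id] = merged

    return _finalize(list(contigs.values()))


def _merge_pair(a: StrictContig, b: StrictContig, kind: str, arg: int) -> StrictContig:
    if kind == "contain":
        merged_seq, offset_b, extension = a.seq, arg, 0
    else:
        merged_seq = a.seq + b.seq[arg:]
        offset_b = len(a.seq) - arg
        extension = min(len(a.seq), len(b.seq)) - arg
    return StrictContig(
        id=min(a.id, b.id),
        seq=merged_seq,
        members=a.members + [(rid, off + offset_b) for rid, off in b.members],
        extension_log=a.extension_log + b.extension_log + [extension],
    )


def _assemble_exact(state: list[StrictContig], min_overlap: int,
                    max_extension: int) -> list[StrictContig]:
    """Exhaustive merge-order search minimizing (n contigs, total length).

    Explores every legal merge sequence (all overlap lengths, not only the
    longest per pair) with memoization on the canonical state; among optimal
    terminal assemblies the canonically smallest one is returned, so the
    result is deterministic and input-order independent.
    """
    best: list = [None]  # (n, total_len, canon, state)
    seen: set = set()

    def canon(st: list[StrictContig]):
        return tuple(
            sorted((c.seq, tuple(sorted(m[0] for m in c.members))) for c in st)
        )

    def legal_merges(st: list[StrictContig]):
        out = []
        for i, a in enumerate(st):
            for j, b in enumerate(st):
                if i == j:
                    continue
                if len(b.seq) <= len(a.seq):
                    pos = a.seq.find(b.seq)
                    if pos >= 0:
                        out.append((i, j, "contain", pos))
                top = min(len(a.seq), len(b.seq))
                for o in range(top, min_overlap - 1, -1):
                    if top - o > max_extension:
                        continue
                    if a.seq.endswith(b.seq[:o]):
                        out.append((i, j, "extend", o))
        return out

    def dfs(st: list[StrictContig]):
        key = canon(st)
        if key in seen:
            return
        seen.add(key)
        options = legal_merges(st)
        if not options:
            obj = (len(st), sum(len(c.seq) for c in st), key)
            if best[0] is None or obj < best[0][:3]:
                best[0] = (*obj, [dataclass_copy(c) for c in st])
            return
        for i, j, kind, arg in options:
            merged = _merge_pair(st[i], st[j], kind, arg)
            rest = [c for k, c in enumerate(st) if k not in (i, j)]
            dfs(rest + [merged])

    def dataclass_copy(c: StrictContig) -> StrictContig:
        return StrictContig(c.id, c.seq, list(c.members), list(c.extension_log))

    dfs(state)
    return best[0][3]


def _finalize(contigs: list[StrictContig]) -> list[StrictContig]:
    out = sorted(contigs, key=lambda c: min(m[0] for m in c.members))
    for i, c in enumerate(out, 1):
        c.id = f"contig_{i:04d}"
        c.members.sort(key=lambda m: (m[1], m[0]))
    return out


def audit_contigs(contigs: Sequence[StrictContig], reads: Sequence[Read],
                  max_extension: int = 25) -> None:
    """Post-hoc verification of the strict-assembly invariants.

    Raises ``AssertionError`` when any member placement mismatches its contig
    or any logged extension exceeds the cap.
    """
    read_seqs = {r.id: r.seq for r in reads}
    for c in contigs:
        for rid, off in c.members:
            seq = read_seqs[rid]
            if c.seq[off : off + len(seq)] != seq:
                raise AssertionError(f"{c.id}: member {rid} mismatches contig at {off}")
        for ext in c.extension_log:
            if ext > max_extension:
                raise AssertionError(f"{c.id}: extension {ext} exceeds cap {max_extension}")
        longest = max(len(read_seqs[rid]) for rid, _ in c.members)
        if len(c.seq) < longest:
            raise AssertionError(f"{c.id}: shorter than its longest member read")


def contigs_vs_genome(contigs: Sequence[StrictContig], genome_refs: dict[str, str],
                      circular: bool = True) -> list[dict]:
    """Best identity of each contig against extracted genomic retrozyme copies.

    Identity is end-to-end on the contig (infix on the reference, doubled for
    circular monomer coordinates; both strands); ``identical`` marks perfect
    matches, the quantity the genome comparison of assembled RNA reports.
    """
    rows: list[dict] = []
    targets = {
        rid: (seq + seq if circular else seq) for rid, seq in genome_refs.items()
    }
    for c in contigs:
        best = None
        for rid in sorted(targets):
            for qseq in (c.seq, revcomp(c.seq)):
                res = edlib.align(qseq, targets[rid], mode="HW", task="distance")
                d = res["editDistance"]
                if d >= 0 and (best is None or d < best[0]):
                    best = (d, rid)
        d, rid = best if best is not None else (len(c.seq), "")
        identity = 1.0 - d / len(c.seq)
        rows.append(
            {
                "contig_id": c.id,
                "best_ref_id": rid,
                "best_identity": identity,
                "identical": d == 0,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Tag / insertion detection
# ---------------------------------------------------------------------------


def find_insertion(seq: str, reference: str) -> Optional[tuple[int, str]]:
    """The single contiguous segment present in ``seq`` but not ``reference``.

    Anchors the two sequences by their longest common prefix and suffix and
    returns (reference position, inserted sequence); when the insertion
    boundary is ambiguous (its ends repeat the flanking sequence) the
    leftmost placement is reported.  This is the tool for recovering an
    artificial tag planted in a reporter construct from sequenced RNA; it
    assumes the flanks themselves are otherwise identical.  Returns None
    when ``seq`` is not longer than ``reference`` or the flanks mismatch.
    """
    ins_len = len(seq) - len(reference)
    if ins_len <= 0:
        return None
    p = 0
    while p < len(reference) and seq[p] == reference[p]:
        p += 1
    s = 0
    while s < len(reference) and seq[len(seq) - 1 - s] == reference[len(reference) - 1 - s]:
        s += 1
    if p + s < len(reference):
        return None  # flanks diverge beyond a single inserted segment
    p = min(p, len(reference) - s)
    return p, seq[p : p + ins_len]
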