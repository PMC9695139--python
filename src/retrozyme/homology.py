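"""Homology search for LTR- and CR-related intervals in genome scaffolds.

The internal scanner mirrors the behaviour of a nucleotide BLAST search at the
scale this pipeline targets: exact k-mer seeding on both strands, clustering
of seeds by diagonal, and Smith-Waterman refinement of each seeded region
(match +1, mismatch -2, gap -3).  Externally computed hits in BLAST outfmt-6
can be imported instead, so the discovery step is interchangeable with a real
BLAST run.

``evalue_like`` is a Karlin-Altschul-style surrogate computed from the
alignment score and the search-space size.  It orders and filters hits the way
an E-value does but is not calibrated to any particular BLAST release.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from . import seq_io
from .align import local_align
from .seq_io import Interval, Scaffold

# Ungapped Karlin-Altschul parameters for match +1 / mismatch -2 (surrogate).
_KA_LAMBDA = 1.28
_KA_K = 0.46


@dataclass(frozen=True)
class HomologyHit:
    """A local alignment of a query against a scaffold region."""

    query_id: str
    interval: Interval
    identity: float
    aligned_length: int
    mismatches: int
    gaps: int
    score: float
    evalue_like: float

    def __post_init__(self) -> None:
        if self.mismatches + self.gaps > self.aligned_length:
            raise ValueError("mismatches + gaps exceed aligned length")


def _evalue_like(score: float, query_len: int, genome_len: int) -> float:
    e = _KA_K * query_len * genome_len * math.exp(-_KA_LAMBDA * score)
    return float(e)


def _seed_clusters(scaffold_seq: str, kmer_index: dict[str, list[int]], k: int,
                   query_len: int) -> list[tuple[int, int]]:
    """Cluster seed matches into candidate scaffold windows.

    Seeds are grouped when they share a diagonal within a small band and lie
    within a query length of each other; each cluster yields a window padded
    by the query length so the refinement alignment can run to the true ends.
    """
    seeds: list[tuple[int, int]] = []  # (diagonal, scaffold position)
    n = len(scaffold_seq)
    for i in range(n - k + 1):
        for qpos in kmer_index.get(scaffold_seq[i : i + k], ()):
            seeds.append((i - qpos, i))
    if not seeds:
        return []
    seeds.sort()
    band = 16
    clusters: list[list[tuple[int, int]]] = []
    for seed in seeds:
        placed = False
        for cl in clusters:
            if abs(seed[0] - cl[-1][0]) <= band and abs(seed[1] - cl[-1][1]) <= query_len:
                cl.append(seed)
                placed = True
                break
        if not placed:
            clusters.append([seed])
    # one window per diagonal cluster: neighbouring element copies sit on
    # different diagonals and must each get their own refinement alignment
    # (a merged window would report only the best-scoring copy)
    windows: list[tuple[int, int]] = []
    for cl in clusters:
        lo = max(0, min(pos for _, pos in cl) - query_len)
        hi = min(n, max(pos for _, pos in cl) + query_len + k)
        windows.append((lo, hi))
    return sorted(set(windows))


def scan_genome(scaffolds: Sequence[Scaffold], query_seq: str, query_id: str = "query",
                k: int = 12, min_identity: float = 0.70, min_length: int = 50,
                ) -> list[HomologyHit]:
    """Find query-homologous intervals on both strands of every scaffold.

    Hits are reported on plus-strand coordinates with a strand flag, sorted by
    scaffold then start; overlapping same-strand hits are collapsed to the
    maximal-scoring one.
    """
    query = seq_io.normalize_dna(query_seq, allow_n=False, context="query")
    if k < 8:
        raise ValueError("seed size k must be >= 8")
    if len(query) < k:
        raise ValueError(f"query length {len(query)} shorter than seed size {k}")

    kmer_index: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        kmer_index.setdefault(query[i : i + k], []).append(i)

    genome_len = sum(len(s) for s in scaffolds)
    hits: list[HomologyHit] = []
    for scaffold in scaffolds:
        for strand in "+-":
            seq = scaffold.seq if strand == "+" else seq_io.revcomp(scaffold.seq)
            for lo, hi in _seed_clusters(seq, kmer_index, k, len(query)):
                aln = local_align(query, seq[lo:hi])
                if aln is None:
                    continue
                if aln["aligned_length"] < min_length:
                    continue
                ident = aln["matches"] / aln["aligned_length"]
                if ident < min_identity:
                    continue
                t0, t1 = lo + aln["target_start"], lo + aln["target_end"]
                if strand == "-":
                    t0, t1 = len(seq) - t1, len(seq) - t0
                hits.append(
                    HomologyHit(
                        query_id=query_id,
                        interval=Interval(scaffold.id, t0, t1, strand),
                        identity=ident,
                        aligned_length=aln["aligned_length"],
                        mismatches=aln["mismatches"],
                        gaps=aln["gaps"],
                        score=aln["score"],
                        evalue_like=_evalue_like(aln["score"], len(query), genome_len),
                    )
                )
    return _dedupe(hits)


def _dedupe(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Collapse overlapping same-strand hits of one query to the best-scoring one."""
    hits = sorted(
        hits, key=lambda h: (h.interval.scaffold_id, h.interval.start, -h.score)
    )
    kept: list[HomologyHit] = []
    for h in hits:
        drop = False
        for i, other in enumerate(kept):
            if (
                h.query_id == other.query_id
                and h.interval.strand == other.interval.strand
                and h.interval.overlap(other.interval) > 0
            ):
                if h.score > other.score:
                    kept[i] = h
                drop = True
                break
        if not drop:
            kept.append(h)
    kept.sort(key=lambda h: (h.interval.scaffold_id, h.interval.start))
    return kept


def import_hits(path) -> list[HomologyHit]:
    """Import BLAST outfmt-6 hits, converting to internal conventions.

    1-based inclusive subject coordinates become 0-based half-open; rows with
    ``sstart > send`` encode a minus-strand hit.  ``pident`` is divided by 100.
    """
    out: list[HomologyHit] = []
    for row in seq_io.read_blast_tab(path):
        sstart, send = row["sstart"], row["send"]
        strand = "+" if sstart <= send else "-"
        lo, hi = (sstart, send) if strand == "+" else (send, sstart)
        out.append(
            HomologyHit(
                query_id=row["qseqid"],
                interval=Interval(row["sseqid"], lo - 1, hi, strand),
                identity=row["pident"] / 100.0,
                aligned_length=row["length"],
                mismatches=row["mismatch"],
                gaps=max(0, row["length"] - row["mismatch"]
                         - round(row["pident"] / 100.0 * row["length"])),
                score=row["bitscore"],
                evalue_like=row["evalue"],
            )
        )
    return out


def export_hits(hits: Iterable[HomologyHit], path) -> None:
    """Write hits as outfmt-6-compatible TSV (coordinates back to 1-based)."""
    with open(path, "w") as fh:
        for h in hits:
            iv = h.interval
            sstart, send = (iv.start + 1, iv.end) if iv.strand == "+" else (iv.end, iv.start + 1)
            matches = h.aligned_length - h.mismatches - h.gaps
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        h.query_id, iv.scaffold_id, f"{100 * h.identity:.2f}",
                        h.aligned_length, h.mismatches, h.gaps,
                        1, matches, sstart, send,
                        f"{h.evalue_like:.2e}", f"{h.score:.1f}",
                    ]
                )
                + "\n"
            )


def filter_hits(hits: Sequence[HomologyHit], max_evalue_like: float = 1e-10,
                min_identity: float = 0.70, min_length: int = 50) -> list[HomologyHit]:
    """Subset of hits passing all thresholds, order preserved."""
    for t in (max_evalue_like, min_identity, min_length):
        if not math.isfinite(t):
            raise ValueError("thresholds must be finite")
    return [
        h
        for h in hits
        if h.evalue_like <= max_evalue_like
        and h.identity >= min_identity
        and h.aligned_length >= min_length
    ]
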