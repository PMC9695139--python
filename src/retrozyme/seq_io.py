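"""Sequence I/O and circular-sequence utilities.

All coordinates inside the package are 0-based half-open on the plus strand of
the scaffold; writers convert at the boundary (GFF3 is 1-based inclusive, BED
stays 0-based half-open).  DNA is normalized on ingest: uppercased, ``U``
mapped to ``T``.  ``N`` is tolerated in genome scaffolds but rejected in
primer/query sequences, where ambiguity would silently change matching
semantics.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ParseError(ValueError):
    """Raised for malformed input files; carries file/line context."""


def normalize_dna(seq: str, *, allow_n: bool = True, context: str = "sequence") -> str:
    """Uppercase, map U->T, and validate against the DNA alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ParseError(f"{context}: invalid characters {sorted(bad)}")
    if not allow_n and "N" in s:
        raise ParseError(f"{context}: ambiguous base N not allowed here")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rotate_circle(seq: str, offset: int) -> str:
    """Rotate a circular sequence so that position ``offset`` becomes position 0.

    ``offset`` must satisfy ``0 <= offset < len(seq)``; rotating by the full
    length is an error rather than a silent identity, to catch off-by-one
    callers early.
    """
    if not 0 <= offset < len(seq):
        raise ValueError(f"rotation offset {offset} out of range [0, {len(seq)})")
    return seq[offset:] + seq[:offset]


@dataclass(frozen=True)
class Scaffold:
    """A genome scaffold: uppercase DNA over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("scaffold id must be nonempty")
        if not self.seq:
            raise ValueError(f"scaffold {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Read:
    """A sequencing read with optional per-base quality."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"read {self.id}: quality length {len(self.qual)} != sequence length {len(self.seq)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on the plus strand of a scaffold."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.scaffold_id != other.scaffold_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def extract(scaffold_seq: str, interval: Interval) -> str:
    """Extract interval sequence; minus-strand intervals are reverse-complemented."""
    if interval.end > len(scaffold_seq):
        raise ValueError(
            f"interval end {interval.end} beyond scaffold length {len(scaffold_seq)}"
        )
    s = scaffold_seq[interval.start : interval.end]
    return revcomp(s) if interval.strand == "-" else s


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _open_text(path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fasta(path, *, dna: bool = True, allow_n: bool = True) -> list[tuple[str, str]]:
    """Read FASTA records in file order as ``(id, seq)`` pairs.

    Sequences are uppercased and, in DNA mode, U is mapped to T.  Duplicate
    ids, empty records and headerless leading sequence raise :class:`ParseError`
    naming the offending line.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        header: Optional[str] = None
        header_line = 0
        chunks: list[str] = []

        def flush() -> None:
            if header is None:
                return
            if not chunks:
                raise ParseError(f"{path}:{header_line}: empty FASTA record {header!r}")
            seq = "".join(chunks)
            if dna:
                seq = normalize_dna(seq, allow_n=allow_n, context=f"{path}:{header!r}")
            else:
                seq = seq.upper()
            records.append((header, seq))

        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                if header in seen:
                    raise ParseError(f"{path}:{lineno}: duplicate id {header!r}")
                seen.add(header)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence before first '>' header")
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, *, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path, *, dna: bool = True) -> list[Read]:
    """Read 4-line FASTQ records; enforces seq/qual length equality."""
    reads: list[Read] = []
    with _open_text(path) as fh:
        lineno = 0
        while True:
            head = fh.readline()
            if not head:
                break
            lineno += 1
            head = head.rstrip("\n")
            if not head.startswith("@"):
                raise ParseError(f"{path}:{lineno}: expected '@' header, got {head[:20]!r}")
            rid = head[1:].split()[0] if head[1:].split() else ""
            if not rid:
                raise ParseError(f"{path}:{lineno}: empty FASTQ header")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ParseError(f"{path}:{lineno}: truncated FASTQ record {rid!r}")
            lineno += 3
            if not plus.startswith("+"):
                raise ParseError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(qual) != len(seq):
                raise ParseError(
                    f"{path}:{lineno}: read {rid!r} quality length {len(qual)} != sequence length {len(seq)}"
                )
            if dna:
                seq = normalize_dna(seq, context=f"{path}:{rid!r}")
            reads.append(Read(rid, seq, qual))
    return reads


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_SOURCE = "retrozyme"


def _gff3_attrs(pairs: Sequence[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs)


def write_gff3(loci, path, scaffold_lengths: Optional[dict[str, int]] = None) -> None:
    """Write annotated retrozyme loci as GFF3.

    One ``retrozyme`` parent feature per locus with child features LTR5, LTR3,
    CR, PBS, PPT, TSD and ribozyme where detected.  Coordinates are converted
    to the GFF3 convention (1-based inclusive).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            parts = [iv for iv in (locus.ltr5, locus.cr, locus.ltr3) if iv is not None]
            if not parts:
                continue
            start = min(iv.start for iv in parts)
            end = max(iv.end for iv in parts)
            if scaffold_lengths is not None:
                slen = scaffold_lengths.get(locus.scaffold_id)
                if slen is not None and end > slen:
                    raise ValueError(
                        f"locus {locus.id}: interval end {end} beyond scaffold "
                        f"{locus.scaffold_id} length {slen}"
                    )
            attrs = [
                ("ID", locus.id),
                ("group", locus.group.replace(" ", "_") if locus.group else "NA"),
                ("ltr_mismatches", str(locus.ltr_mismatches)),
                ("completeness", locus.completeness),
                ("tandem", str(locus.tandem).lower()),
            ]
            if locus.tsd:
                attrs.append(("tsd", locus.tsd))
            fh.write(
                "\t".join(
                    [
                        locus.scaffold_id,
                        _SOURCE,
                        "retrozyme",
                        str(start + 1),
                        str(end),
                        ".",
                        locus.strand,
                        ".",
                        _gff3_attrs(attrs),
                    ]
                )
                + "\n"
            )

            def child(ftype: str, iv: Interval, extra: Sequence[tuple[str, str]] = ()) -> None:
                fh.write(
                    "\t".join(
                        [
                            locus.scaffold_id,
                            _SOURCE,
                            ftype,
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            locus.strand,
                            ".",
                            _gff3_attrs(
                                [("ID", f"{locus.id}.{ftype}"), ("Parent", locus.id), *extra]
                            ),
                        ]
                    )
                    + "\n"
                )

            if locus.ltr5 is not None:
                child("LTR5", locus.ltr5)
            if locus.cr is not None:
                child("CR", locus.cr)
            if locus.ltr3 is not None:
                child("LTR3", locus.ltr3)
            if locus.tsd:
                # TSD flanks: 4 nt immediately 5' and 3' of the element
                if start >= 4:
                    child("TSD", Interval(locus.scaffold_id, start - 4, start, locus.strand))
                child("TSD", Interval(locus.scaffold_id, end, end + 4, locus.strand))
            if locus.pbs is not None:
                child("PBS", locus.pbs)
            if locus.ppt is not None:
                child("PPT", locus.ppt)
            for i, rz in enumerate(locus.ribozymes, 1):
                child(
                    "ribozyme",
                    rz.interval,
                    [
                        ("cleavage_site", str(rz.cleavage_site)),
                        ("core_intact", str(rz.core_intact).lower()),
                    ],
                )


def read_gff3(path) -> list[dict]:
    """Parse a GFF3 file back into plain feature dicts (round-trip support)."""
    feats: list[dict] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            attrs = {}
            for item in fields[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            feats.append(
                {
                    "seqid": fields[0],
                    "type": fields[2],
                    "start": int(fields[3]) - 1,  # back to 0-based half-open
                    "end": int(fields[4]),
                    "strand": fields[6],
                    "attrs": attrs,
                }
            )
    return feats


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------


def write_bed(intervals: Iterable[tuple[Interval, str]], path) -> None:
    """Write (interval, name) pairs as BED6 (0-based half-open, as stored)."""
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(f"{iv.scaffold_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_blast_tab(path) -> list[dict]:
    """Read BLAST outfmt-6 tabular rows into dicts of typed fields.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore.  Non-numeric fields raise :class:`ParseError` with
    the line number.
    """
    cols = (
        "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
    ).split()
    types = [str, str, float, int, int, int, int, int, int, int, float, float]
    rows: list[dict] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            row = {}
            for name, typ, val in zip(cols, types, fields):
                try:
                    row[name] = typ(val)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {val!r} in column {name}"
                    ) from None
            rows.append(row)
    return rows
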