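"""Bisulfite-sequencing analysis: conversion, calling and comparison.

Bisulfite treatment converts unmethylated cytosines to uracil (read as T
after PCR) while 5-methylcytosine is protected, so a retained C in a
sequenced clone marks a methylated position.  Calls are made per reference
cytosine per clone, with the plant sequence contexts CpG, CHG and CHH
(H = A, C or T) assigned from the reference — the three contexts are
maintained by different methyltransferase pathways, and RNA-directed DNA
methylation is the one that writes CHH marks.

Only plus-strand cytosines of the amplicon are called: the clones derive
from a PCR product of converted DNA, so strand-resolved calling is not
available.  Incomplete conversion is a nuisance parameter of the simulation,
not corrected for in calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import edlib
import numpy as np
from scipy import stats

from .seq_io import normalize_dna

CONTEXTS = ("CpG", "CHG", "CHH")
METHYLATED, UNMETHYLATED, UNCALLABLE = "methylated", "unmethylated", "uncallable"


def cytosine_contexts(reference_seq: str) -> list[tuple[int, str]]:
    """(position, context) for every plus-strand C in the reference.

    Context: CpG when followed by G; CHG when the base after next is G; CHH
    otherwise.  Cytosines too close to the 3' end for their context to be
    determined default to CHH (missing bases treated as H).
    """
    ref = reference_seq
    sites = []
    for i, base in enumerate(ref):
        if base != "C":
            continue
        nxt = ref[i + 1] if i + 1 < len(ref) else None
        nxt2 = ref[i + 2] if i + 2 < len(ref) else None
        if nxt == "G":
            ctx = "CpG"
        elif nxt2 == "G":
            ctx = "CHG"
        else:
            ctx = "CHH"
        sites.append((i, ctx))
    return sites


def bisulfite_convert(seq: str, methylation_map: set[int], conversion_rate: float = 1.0,
                      rng: Optional[np.random.Generator] = None,
                      seed: Optional[int] = None) -> str:
    """Apply in-silico bisulfite conversion to one molecule.

    Unmethylated C becomes T with probability ``conversion_rate``; methylated
    C and all other bases are untouched.  Positions in ``methylation_map``
    must be cytosines.
    """
    if not 0 < conversion_rate <= 1:
        raise ValueError("conversion_rate must be in (0, 1]")
    seq = normalize_dna(seq, context="bisulfite input")
    for pos in methylation_map:
        if seq[pos] != "C":
            raise ValueError(f"methylation_map position {pos} is {seq[pos]}, not C")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = list(seq)
    for i, base in enumerate(out):
        if base == "C" and i not in methylation_map:
            if conversion_rate >= 1.0 or rng.random() < conversion_rate:
                out[i] = "T"
    return "".join(out)


@dataclass
class MethylationTable:
    """Per-cytosine, per-clone methylation calls against one reference."""

    reference_id: str
    sites: list[tuple[int, str]]
    calls: dict[str, list[str]]  # clone id -> one call per site
    excluded_clones: list[str] = field(default_factory=list)

    def _counts(self, context: Optional[str] = None) -> tuple[int, int]:
        meth = unmeth = 0
        for calls in self.calls.values():
            for (pos, ctx), call in zip(self.sites, calls):
                if context is not None and ctx != context:
                    continue
                if call == METHYLATED:
                    meth += 1
                elif call == UNMETHYLATED:
                    unmeth += 1
        return meth, unmeth

    @property
    def pct_methylated(self) -> float:
        meth, unmeth = self._counts()
        if meth + unmeth == 0:
            raise ValueError("no callable sites")
        return 100.0 * meth / (meth + unmeth)

    def pct_by_context(self) -> dict[str, float]:
        out = {}
        for ctx in CONTEXTS:
            meth, unmeth = self._counts(ctx)
            out[ctx] = 100.0 * meth / (meth + unmeth) if meth + unmeth else float("nan")
        return out

    def clone_fractions(self) -> dict[str, float]:
        """Per-clone fraction of callable cytosines that are methylated."""
        out = {}
        for cid, calls in self.calls.items():
            meth = sum(1 for c in calls if c == METHYLATED)
            unmeth = sum(1 for c in calls if c == UNMETHYLATED)
            if meth + unmeth:
                out[cid] = meth / (meth + unmeth)
        return out


def _map_clone_to_reference(clone: str, ref: str) -> Optional[list[Optional[str]]]:
    """Per-reference-position clone base (None at deletions)."""
    if clone == ref:
        return list(clone)
    res = edlib.align(clone, ref, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, clone, ref)
    q, t = nice["query_aligned"], nice["target_aligned"]
    out: list[Optional[str]] = []
    for qc, tc in zip(q, t):
        if tc == "-":
            continue  # insertion in clone: no reference position consumed
        out.append(None if qc == "-" else qc)
    return out


def call_methylation(clone_seqs: dict[str, str], reference_seq: str,
                     reference_id: str = "reference",
                     min_identity_non_c: float = 0.90) -> MethylationTable:
    """Call methylation per reference cytosine across sequenced clones.

    At each reference C: clone base C -> methylated, T -> unmethylated,
    anything else (including a deletion) -> uncallable.  Clones whose
    identity to the reference *outside* C positions falls below
    ``min_identity_non_c`` are excluded and reported — bisulfite conversion
    only ever touches cytosines, so divergence elsewhere marks a foreign or
    chimeric clone.
    """
    ref = normalize_dna(reference_seq, context="reference")
    sites = cytosine_contexts(ref)
    c_positions = {pos for pos, _ in sites}
    table = MethylationTable(reference_id=reference_id, sites=sites, calls={})
    for cid in sorted(clone_seqs):
        clone = normalize_dna(clone_seqs[cid], context=f"clone {cid}")
        mapped = _map_clone_to_reference(clone, ref)
        non_c = [(rb, cb) for i, (rb, cb) in enumerate(zip(ref, mapped))
                 if i not in c_positions]
        matches = sum(1 for rb, cb in non_c if cb == rb)
        if non_c and matches / len(non_c) < min_identity_non_c:
            table.excluded_clones.append(cid)
            continue
        calls = []
        for pos, _ctx in sites:
            base = mapped[pos]
            if base == "C":
                calls.append(METHYLATED)
            elif base == "T":
                calls.append(UNMETHYLATED)
            else:
                calls.append(UNCALLABLE)
        table.calls[cid] = calls
    return table


def compare_methylation(target_table: MethylationTable,
                        control_table: MethylationTable,
                        method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U on per-clone methylation fractions.

    Returns (U, p).  ``method`` is passed to scipy (``"exact"`` enumerates the
    null distribution, the sensible choice at <= 10 clones per arm; ``"auto"``
    selects it at these sizes anyway).  Requires at least two clones with
    callable sites in each table.
    """
    x = list(target_table.clone_fractions().values())
    y = list(control_table.clone_fractions().values())
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each table needs >= 2 clones with callable sites")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
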