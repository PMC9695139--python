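"""Synthetic data with full ground truth for every pipeline stage.

The simulators generate inputs with the statistical structure the analysis
assumes, so each stage can be tested as a parameter-recovery problem:

* genomes with planted retrozyme elements — full-length (two LTRs around a
  group-specific CR, 4-nt TSD, PBS/PPT, a hammerhead cassette in each LTR,
  configurable LTR-LTR divergence, optional tandem copies), CR-partial
  truncations, and isolated LTR fragments;
* circular-RNA populations diverged from a genomic copy by r rounds of
  rolling-circle replication at per-base, per-round substitution rate
  epsilon, so the expected divergence after r rounds is 1 - (1-eps)^r;
* 100-nt single-end reads with uniform starts on the circle (junction
  spanning) and uniform strand;
* small-RNA libraries with a configurable length distribution and LTR bias;
* bisulfite clone sets with independent per-context methylation rates.

Every simulator is a pure function of its configuration including the seed.
The planted hammerhead cassette is a synthetic Type III construct that
satisfies the descriptor; it is a test fixture, not any natural ribozyme
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotate import RetrozymeLocus
from .methylation import bisulfite_convert, cytosine_contexts
from .ribozyme import build_hammerhead_cassette
from .seq_io import Interval, Read, Scaffold, revcomp

#: 24-nt artificial tag carried by the systemic-transport reporter construct,
#: inserted into a hairpin loop of the CR to distinguish transgene-derived
#: RNA from genome-encoded copies.
TAG_24NT = "GATTACAAGGATGACGATGACAAG"

#: synthetic default for the tRNA-Met 3'-terminal sequence the PBS pairs with
#: (tRNA-styled: T-arm motif plus the universal 3'-CCA); always configurable.
DEFAULT_TRNA_3P = "TGGTTCGATTCCCACCA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CASSETTE = build_hammerhead_cassette()
_CASSETTE_OFFSET_IN_LTR = 40  # cassette position within every simulated LTR


@dataclass
class GenomeSimConfig:
    n_scaffolds: int = 6
    scaffold_len: int = 30_000
    gc: float = 0.38
    n_full: int = 9
    n_cr_partial: int = 5
    n_ltr_fragment: int = 20
    ltr_len: int = 350
    cr_len_by_group: dict[str, int] = field(
        default_factory=lambda: {"Group 1": 600, "Group 2": 450}
    )
    #: group label of each full element, in planting order
    full_groups: list[str] = field(
        default_factory=lambda: ["Group 1"] * 7 + ["Group 2"] * 2
    )
    #: planted LTR-LTR substitution counts per full element (0-32)
    ltr_divergence: list[int] = field(
        default_factory=lambda: [2, 0, 1, 7, 12, 20, 32, 0, 9]
    )
    #: ids (RZ<i>, 1-based planting order) planted as incomplete tandem repeats
    tandem_loci: list[str] = field(default_factory=lambda: ["RZ3", "RZ9"])
    between_group_ltr_divergence: float = 0.08
    within_group_ltr_divergence: float = 0.01
    within_group_cr_divergence: float = 0.02
    trna_3prime: str = DEFAULT_TRNA_3P
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_full, self.n_cr_partial, self.n_ltr_fragment) < 0:
            raise ValueError("element counts must be >= 0")
        if len(self.full_groups) != self.n_full:
            raise ValueError("full_groups must name a group per full element")
        if len(self.ltr_divergence) != self.n_full:
            raise ValueError("ltr_divergence must give a count per full element")
        if any(d < 0 for d in self.ltr_divergence):
            raise ValueError("ltr_divergence counts must be >= 0")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        for g in self.full_groups:
            if g not in self.cr_len_by_group:
                raise ValueError(f"no CR length configured for {g!r}")


@dataclass
class ReplicationSimConfig:
    n_molecules: int = 1000
    #: rounds of replication r -> probability; defaults to a point mass
    rounds_distribution: dict[int, float] = field(default_factory=lambda: {10: 1.0})
    error_rate: float = 0.001
    source_locus: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.rounds_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"rounds_distribution sums to {total}, not 1")
        if any(r < 0 for r in self.rounds_distribution):
            raise ValueError("round counts must be >= 0")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")


@dataclass
class GroundTruth:
    """Per-record provenance for everything a simulator emits."""

    loci: list[RetrozymeLocus] = field(default_factory=list)
    #: query/template sequences the discovery stage needs
    templates: dict[str, str] = field(default_factory=dict)
    #: molecule id -> (rounds, tuple of substituted positions)
    molecule_lineages: dict[str, tuple[int, tuple[int, ...]]] = field(default_factory=dict)
    #: read id -> (molecule id, start offset on circle, strand)
    read_origins: dict[str, tuple[str, int, str]] = field(default_factory=dict)
    #: clone id -> set of methylated C positions
    methylation_maps: dict[str, set[int]] = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


def _substitute(rng: np.random.Generator, seq: str, positions: Sequence[int]) -> str:
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out)


def _mutable_positions(length: int, protected: Sequence[tuple[int, int]]) -> np.ndarray:
    mask = np.ones(length, dtype=bool)
    for a, b in protected:
        mask[a:b] = False
    return np.flatnonzero(mask)


def _mutate_rate(rng: np.random.Generator, seq: str, rate: float,
                 protected: Sequence[tuple[int, int]]) -> str:
    allowed = _mutable_positions(len(seq), protected)
    hits = allowed[rng.random(allowed.size) < rate]
    return _substitute(rng, seq, hits)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


def simulate_genome(config: GenomeSimConfig) -> tuple[list[Scaffold], GroundTruth]:
    """Plant retrozyme elements in random-background scaffolds.

    Full elements carry an exact 4-nt TSD, a PBS (reverse complement of the
    configured tRNA-Met 3' 12-mer) at the CR 5' end, a purine-run PPT near
    the CR 3' end, an intact hammerhead cassette in both LTRs, and exactly
    the configured number of substitutions between their two LTRs.
    Divergence never touches the cassette, the PBS or the PPT — the
    functionally constrained parts of real elements — so planted feature
    coordinates and mismatch counts stay exact.  Deterministic per seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    cassette_span = (_CASSETTE_OFFSET_IN_LTR, _CASSETTE_OFFSET_IN_LTR + len(_CASSETTE))
    base = _random_dna(rng, config.ltr_len - len(_CASSETTE), config.gc)
    base_ltr = (
        base[: _CASSETTE_OFFSET_IN_LTR] + _CASSETTE + base[_CASSETTE_OFFSET_IN_LTR :]
    )
    group_ltr = {}
    group_cr = {}
    pbs = revcomp(config.trna_3prime[-12:])
    for gi, (group, cr_len) in enumerate(sorted(config.cr_len_by_group.items())):
        group_ltr[group] = (
            base_ltr
            if gi == 0
            else _mutate_rate(rng, base_ltr, config.between_group_ltr_divergence,
                              [cassette_span])
        )
        cr = _random_dna(rng, cr_len, config.gc)
        ppt = _BASES[[0, 2]][rng.integers(2, size=12)].tobytes().decode()  # A/G run
        cr = pbs + cr[len(pbs) : cr_len - 16] + ppt + cr[cr_len - 4 :]
        group_cr[group] = cr

    truth = GroundTruth(
        templates={
            "ltr_query": base_ltr,
            "trna_3prime": config.trna_3prime,
            **{f"cr_query_{g.replace(' ', '_')}": s for g, s in group_cr.items()},
        }
    )

    # build element sequences and their internal layout
    builds: list[tuple[str, str, dict]] = []  # (locus id, element seq, layout info)
    for i in range(config.n_full):
        locus_id = f"RZ{i + 1}"
        group = config.full_groups[i]
        cr_len = len(group_cr[group])
        ltr5 = _mutate_rate(rng, group_ltr[group], config.within_group_ltr_divergence,
                            [cassette_span])
        cr = _mutate_rate(
            rng, group_cr[group], config.within_group_cr_divergence,
            [(0, len(pbs)), (cr_len - 16, cr_len - 4)],
        )
        d = config.ltr_divergence[i]
        allowed = _mutable_positions(len(ltr5), [cassette_span])
        sub_pos = rng.choice(allowed, size=d, replace=False) if d else []
        ltr3 = _substitute(rng, ltr5, sub_pos)
        tandem = locus_id in config.tandem_loci
        if tandem:
            element = ltr5 + cr + ltr5 + cr + ltr3
        else:
            element = ltr5 + cr + ltr3
        builds.append(
            (
                locus_id,
                element,
                {
                    "completeness": "full",
                    "tandem": tandem,
                    "group": group,
                    "ltr_len": len(ltr5),
                    "cr_len": len(cr),
                    "ltr_mismatches": int(d),
                    "tsd": True,
                },
            )
        )
    for i in range(config.n_cr_partial):
        group = sorted(config.cr_len_by_group)[i % len(config.cr_len_by_group)]
        ltr = _mutate_rate(rng, group_ltr[group], config.within_group_ltr_divergence,
                           [cassette_span])
        cr_len = len(group_cr[group])
        cr = _mutate_rate(
            rng, group_cr[group], config.within_group_cr_divergence,
            [(0, len(pbs)), (cr_len - 16, cr_len - 4)],
        )
        builds.append(
            (
                f"RZp{i + 1}",
                ltr + cr,
                {"completeness": "cr_partial", "tandem": False, "group": group,
                 "ltr_len": len(ltr), "cr_len": len(cr), "ltr_mismatches": 0,
                 "tsd": False},
            )
        )
    for i in range(config.n_ltr_fragment):
        frag_len = int(rng.integers(120, 201))
        start = int(rng.integers(0, config.ltr_len - frag_len))
        frag = base_ltr[start : start + frag_len]
        builds.append(
            (
                f"RZf{i + 1}",
                frag,
                {"completeness": "ltr_fragment", "tandem": False, "group": "",
                 "ltr_len": frag_len, "cr_len": 0, "ltr_mismatches": 0, "tsd": False},
            )
        )

    # distribute across scaffolds, planting sequentially with random spacers
    per_scaffold: list[list[tuple[str, str, dict]]] = [
        [] for _ in range(config.n_scaffolds)
    ]
    for j, b in enumerate(builds):
        per_scaffold[j % config.n_scaffolds].append(b)

    scaffolds: list[Scaffold] = []
    for si in range(config.n_scaffolds):
        name = f"scaffold_{si + 1}"
        content = per_scaffold[si]
        # real retrozyme copies are dispersed: keep >max_cr_len of background
        # between planted elements so geometry alone cannot chain neighbours
        min_gap = 2000
        needed = sum(len(el) for _, el, _ in content) + (min_gap + 50) * (len(content) + 1)
        if needed > config.scaffold_len:
            raise ValueError(
                f"{name}: elements need {needed} nt but scaffold_len is "
                f"{config.scaffold_len}; increase scaffold_len or n_scaffolds"
            )
        slack = config.scaffold_len - sum(len(el) for _, el, _ in content)
        cuts = np.sort(rng.choice(slack - min_gap * (len(content) + 1),
                                  size=len(content), replace=False)) if content else []
        segments: list[str] = []
        pos = 0
        prev_cut = 0
        for idx, (locus_id, element, info) in enumerate(content):
            gap_len = min_gap + int(cuts[idx] - prev_cut)
            prev_cut = int(cuts[idx])
            gap = _random_dna(rng, gap_len, config.gc)
            segments.append(gap)
            pos += gap_len
            start = pos
            segments.append(element)
            pos += len(element)
            if info["tsd"]:
                tsd = gap[-4:]
                segments.append(tsd)
                pos += 4
            else:
                tsd = None
            truth.loci.append(
                _truth_locus(locus_id, name, start, info, tsd)
            )
        tail = config.scaffold_len - pos
        if tail > 0:
            segments.append(_random_dna(rng, tail, config.gc))
        scaffolds.append(Scaffold(name, "".join(segments)))
    return scaffolds, truth


def _truth_locus(locus_id: str, scaffold_id: str, start: int, info: dict,
                 tsd: Optional[str]) -> RetrozymeLocus:
    L, C = info["ltr_len"], info["cr_len"]
    kind = info["completeness"]
    if kind == "full":
        n_units = 2 if info["tandem"] else 1
        ltr5 = Interval(scaffold_id, start, start + L)
        ltr3_start = start + n_units * (L + C)
        ltr3 = Interval(scaffold_id, ltr3_start, ltr3_start + L)
        cr = Interval(scaffold_id, start + L, start + L + C)
        return RetrozymeLocus(
            id=locus_id, scaffold_id=scaffold_id, strand="+",
            ltr5=ltr5, ltr3=ltr3, cr=cr, tsd=tsd,
            ltr_mismatches=info["ltr_mismatches"], group=info["group"],
            completeness="full", tandem=info["tandem"],
        )
    if kind == "cr_partial":
        return RetrozymeLocus(
            id=locus_id, scaffold_id=scaffold_id, strand="+",
            ltr5=Interval(scaffold_id, start, start + L), ltr3=None,
            cr=Interval(scaffold_id, start + L, start + L + C),
            completeness="cr_partial",
        )
    return RetrozymeLocus(
        id=locus_id, scaffold_id=scaffold_id, strand="+",
        ltr5=Interval(scaffold_id, start, start + L), ltr3=None, cr=None,
        completeness="ltr_fragment",
    )


def element_monomer(locus: RetrozymeLocus, scaffold_seq: str) -> str:
    """Unit-length circular monomer RNA of a full element: one LTR + one CR.

    Self-cleavage in each LTR releases a monomer spanning from the cleavage
    site in the 5' LTR to the same site in the 3' LTR, i.e. exactly one LTR
    plus one CR of sequence, here taken in genomic phase (LTR then CR).
    """
    if locus.completeness != "full":
        raise ValueError("monomer requires a full element")
    ltr = scaffold_seq[locus.ltr5.start : locus.ltr5.end]
    cr = scaffold_seq[locus.cr.start : locus.cr.end]
    monomer = ltr + cr
    return revcomp(monomer) if locus.strand == "-" else monomer


def insert_tag(element_seq: str, cr_span: tuple[int, int], tag: str = TAG_24NT) -> str:
    """Insert a tag sequence at the midpoint of the CR (a tolerated site)."""
    mid = (cr_span[0] + cr_span[1]) // 2
    return element_seq[:mid] + tag + element_seq[mid:]


# ---------------------------------------------------------------------------
# Replication / reads
# ---------------------------------------------------------------------------


def simulate_replication(circle_seq: str, config: ReplicationSimConfig,
                         ) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Diverge a circular RNA by rounds of error-prone replication.

    Each molecule independently draws its round count r from the configured
    distribution and then accumulates substitutions over r rounds at per-base
    rate ``error_rate`` (uniform over the three alternative bases), so the
    expected per-base divergence from the source is 1 - (1 - eps)^r.
    """
    config.validate()
    if not circle_seq:
        raise ValueError("empty source circle")
    rng = np.random.default_rng(config.seed)
    L = len(circle_seq)
    source = np.frombuffer(circle_seq.encode(), dtype=np.uint8).copy()
    rounds_vals = np.array(sorted(config.rounds_distribution))
    probs = np.array([config.rounds_distribution[r] for r in rounds_vals], dtype=float)
    rounds = rng.choice(rounds_vals, size=config.n_molecules, p=probs / probs.sum())

    mols = np.tile(source, (config.n_molecules, 1))
    max_r = int(rounds.max()) if config.n_molecules else 0
    for rnd in range(max_r):
        active = rounds > rnd
        if not active.any() or config.error_rate == 0:
            continue
        hits = rng.random((int(active.sum()), L)) < config.error_rate
        rows = np.flatnonzero(active)
        for k, row in enumerate(rows):
            for col in np.flatnonzero(hits[k]):
                current = mols[row, col]
                alts = _BASES[_BASES != current]
                mols[row, col] = alts[rng.integers(3)]

    truth = GroundTruth()
    population: list[tuple[str, str]] = []
    for m in range(config.n_molecules):
        mid = f"mol_{m + 1:05d}"
        seq = mols[m].tobytes().decode()
        subs = tuple(int(i) for i in np.flatnonzero(mols[m] != source))
        truth.molecule_lineages[mid] = (int(rounds[m]), subs)
        population.append((mid, seq))
    return population, truth


def simulate_reads(population: Sequence[tuple[str, str]], n_reads: int,
                   read_len: int = 100, seed: int = 0,
                   ) -> tuple[list[Read], GroundTruth]:
    """Uniform reads from circular molecules (junction-spanning, both strands)."""
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    reads: list[Read] = []
    if n_reads and not population:
        raise ValueError("empty population")
    for i in range(n_reads):
        mi = int(rng.integers(len(population)))
        mol_id, seq = population[mi]
        if read_len > len(seq):
            raise ValueError("read_len exceeds molecule length")
        start = int(rng.integers(len(seq)))
        doubled = seq + seq
        fragment = doubled[start : start + read_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = revcomp(fragment)
        rid = f"read_{i + 1:06d}"
        reads.append(Read(rid, fragment, "I" * read_len))
        truth.read_origins[rid] = (mol_id, start, strand)
    return reads, truth


def simulate_small_rnas(element_seq: str, ltr_spans: Sequence[tuple[int, int]],
                        cr_span: tuple[int, int], n: int,
                        length_dist: Optional[dict[int, float]] = None,
                        ltr_bias: float = 0.816, seed: int = 0,
                        ) -> tuple[list[Read], GroundTruth]:
    """Error-free small RNAs drawn from LTR or CR spans of one element.

    Each read comes from an LTR span with probability ``ltr_bias`` (choosing
    between the element's LTR copies uniformly), otherwise from the CR; its
    length is drawn from ``length_dist`` (default: a 24-nt-dominated siRNA
    mixture), its start is uniform within the region, and its strand uniform.
    """
    if not 0 <= ltr_bias <= 1:
        raise ValueError("ltr_bias must be in [0, 1]")
    if length_dist is None:
        length_dist = {21: 0.05, 22: 0.05, 23: 0.10, 24: 0.70, 25: 0.10}
    for ln in length_dist:
        if not 18 <= ln <= 30:
            raise ValueError("length distribution support must lie in 18-30 nt")
    rng = np.random.default_rng(seed)
    lens = np.array(sorted(length_dist))
    lprobs = np.array([length_dist[l] for l in lens], dtype=float)
    lprobs = lprobs / lprobs.sum()
    truth = GroundTruth()
    reads: list[Read] = []
    for i in range(n):
        n_len = int(rng.choice(lens, p=lprobs))
        if rng.random() < ltr_bias:
            span = ltr_spans[int(rng.integers(len(ltr_spans)))]
            region = "LTR"
        else:
            span = cr_span
            region = "CR"
        start = int(rng.integers(span[0], span[1] - n_len + 1))
        seq = element_seq[start : start + n_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        rid = f"srna_{i + 1:06d}"
        reads.append(Read(rid, seq, "I" * n_len))
        truth.read_origins[rid] = (region, start, strand)
    return reads, truth


# ---------------------------------------------------------------------------
# Bisulfite clones
# ---------------------------------------------------------------------------


def simulate_bisulfite_clones(reference: str, per_context_rates: dict[str, float],
                              n_clones: int = 20, conversion_rate: float = 1.0,
                              seed: int = 0,
                              ) -> tuple[dict[str, str], GroundTruth]:
    """Clone sequences after per-context methylation and bisulfite conversion.

    Each clone draws an independent methylation state for every cytosine from
    its context rate (CpG/CHG/CHH), then undergoes conversion at
    ``conversion_rate``.  Ground truth records the planted map per clone.
    """
    for ctx, rate in per_context_rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"{ctx}: methylation rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sites = cytosine_contexts(reference)
    truth = GroundTruth()
    clones: dict[str, str] = {}
    for c in range(n_clones):
        cid = f"clone_{c + 1:03d}"
        meth = {
            pos
            for pos, ctx in sites
            if rng.random() < per_context_rates.get(ctx, 0.0)
        }
        clones[cid] = bisulfite_convert(reference, meth, conversion_rate, rng=rng)
        truth.methylation_maps[cid] = meth
    return clones, truth
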