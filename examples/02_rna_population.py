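"""Analyse a retrozyme RNA population: classification, spectrum, assembly.

Starts from one annotated element's circular monomer RNA, replicates it for
10 rounds at a per-base error rate of 0.001 (rolling-circle RNA-to-RNA
replication accumulates substitutions), sequences 100-nt reads, and runs the
transcriptome analysis: per-read mismatch classification against the genomic
copy, the mismatch spectrum, and strict exact-overlap assembly.
"""

from retrozyme import (
    align_reads_to_refs,
    assemble_strict,
    contigs_vs_genome,
    mismatch_spectrum,
    simulate_genome,
    simulate_reads,
    simulate_replication,
)
from retrozyme.rna import audit_contigs
from retrozyme.seq_io import Read, revcomp
from retrozyme.simulate import GenomeSimConfig, ReplicationSimConfig, element_monomer

scaffolds, truth = simulate_genome(GenomeSimConfig(seed=1))
seqs = {s.id: s.seq for s in scaffolds}
locus = next(l for l in truth.loci if l.completeness == "full")
monomer = element_monomer(locus, seqs[locus.scaffold_id])
print(f"source: {locus.id}, circular monomer of {len(monomer)} nt")

population, _ = simulate_replication(
    monomer,
    ReplicationSimConfig(n_molecules=150, rounds_distribution={10: 1.0},
                         error_rate=0.001, seed=2),
)
reads, _ = simulate_reads(population, n_reads=600, read_len=100, seed=3)

cls, dropped = align_reads_to_refs(reads, {locus.id: monomer}, circular=True)
spectrum = mismatch_spectrum(cls)
expected = 100 * (1 - (1 - 0.001) ** 10)
mean = sum(c.mismatch_pct for c in cls) / len(cls)
print(f"\nclassified {len(cls)} reads ({dropped} dropped)")
print(f"mean mismatch: {mean:.2f}%  (theory for 10 rounds at 1e-3: {expected:.2f}%)")
print("mismatch spectrum (fraction of reads):")
for b, f in spectrum.items():
    print(f"  {b:>8}: {f:.3f}")

# orient reads to the reference strand, then assemble strictly: no mismatch
# is tolerated in an overlap and each merge may add at most 25 nt, so reads
# from different RNA molecules are never chimerized into one contig
by_id = {r.id: r for r in reads}
oriented = [
    Read(c.read_id, by_id[c.read_id].seq if c.strand == "+" else revcomp(by_id[c.read_id].seq))
    for c in cls
]
contigs = assemble_strict(oriented, min_overlap=20, max_extension=25)
audit_contigs(contigs, oriented)
rows = contigs_vs_genome(contigs, {locus.id: monomer})
identical = sum(r["identical"] for r in rows)
print(f"\nstrict assembly: {len(contigs)} contigs, "
      f"{identical} ({100 * identical / len(contigs):.1f}%) identical to the genomic copy")
print("the rest differ from the genome: replication errors carried by the RNA population")
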