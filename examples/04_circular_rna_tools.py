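"""Circular-RNA logic: self-cleavage, divergent primers, reporter tags.

Three small analyses that all hinge on retrozyme RNA being circular:
monomer excision at hammerhead cleavage sites, divergent-primer products
that only form on circular/concatemeric templates, and recovery of a 24-nt
reporter tag from a tagged construct.  Also scans for potential miRNA
binding sites.
"""

import numpy as np

from retrozyme import detect_hammerhead, excise_monomer, predict_amplicon
from retrozyme.annotate import scan_mirna_sites
from retrozyme.rna import find_insertion
from retrozyme.seq_io import revcomp
from retrozyme.simulate import (
    GenomeSimConfig,
    TAG_24NT,
    element_monomer,
    insert_tag,
    simulate_genome,
)

scaffolds, truth = simulate_genome(GenomeSimConfig(seed=1))
seqs = {s.id: s.seq for s in scaffolds}
locus = next(l for l in truth.loci if l.completeness == "full" and not l.tandem)
element = seqs[locus.scaffold_id][locus.span.start : locus.span.end]
monomer = element_monomer(locus, seqs[locus.scaffold_id])

# --- self-cleavage: the primary transcript spans LTR-CR-LTR ---------------
matches = detect_hammerhead(element)
print(f"hammerhead motifs in the primary transcript: {len(matches)}")
for m in matches:
    print(f"  cleavage after position {m.cleavage_site}, core intact: {m.core_intact}")
excised = excise_monomer(element, matches)
print(f"excised monomer: {len(excised)} nt, 5' nucleotide {excised[0]!r} "
      f"(unit length {len(monomer)} nt)")

# --- divergent primers detect circular templates --------------------------
fwd = monomer[500:520]
rev = revcomp(monomer[100:120])  # binding site upstream of fwd: divergent pair
linear = predict_amplicon(monomer, is_circular=False, fwd_primer=fwd, rev_primer=rev)
circular = predict_amplicon(monomer, is_circular=True, fwd_primer=fwd, rev_primer=rev)
print(f"\ndivergent primers on linear template: {len(linear)} products")
print(f"divergent primers on circular template: {len(circular)} products")
for a in circular:
    print(f"  product of {a.length} nt, spans junction: {a.spans_junction}")

# --- reporter tag recovery ------------------------------------------------
tagged = insert_tag(monomer, (len(locus.ltr5), len(monomer)))
pos, inserted = find_insertion(tagged, monomer)
print(f"\nreporter tag recovered at CR position {pos}: {len(inserted)} nt")

# --- miRNA binding-site scan ----------------------------------------------
rng = np.random.default_rng(0)
mirnas = {f"mir{i}": "".join("ACGU"[j] for j in rng.integers(0, 4, 21))
          for i in range(20)}
sites = scan_mirna_sites(monomer, mirnas, max_mismatches=4)
print(f"\nsites with fewer than five mismatches to {len(mirnas)} random miRNAs: "
      f"{len(sites)}")
print("an 'miRNA sponge' role would need such sites; their absence argues against it")
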