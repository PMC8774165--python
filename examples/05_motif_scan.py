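"""Scan variants for gains and losses of RNA-level binding sequences.

For each variant, exact-match occurrences of RBP binding sequences, miRNA
seeds, and miRNA-matching 3'-UTR sites are compared between the reference
and variant windows; miRNA-derived motifs are matched via the reverse
complement of the given sequence.
"""

from collections import Counter

from comut import Motif, generate_motif_fixture, scan_motif_alterations
from comut.impact import scan_mutations

# a single hand-built case: the substitution destroys the planted RBP site
motif = Motif("SRSF1_like", "RBP", "ACGTAC")
context = "TTTTTTACGTACTTTTTT"
events = scan_motif_alterations(("chr17", 9, "G", "A"), context, [motif])
for e in events:
    print(f"{e.chromosome}:{e.position} {e.ref_allele}>{e.alt_allele} "
          f"{e.direction} of {e.motif_id} ({e.motif_class})")

# a generated fixture with known planted gains and losses, incl. indels
fixture = generate_motif_fixture(seed=0, n_events=40)
found = scan_mutations(fixture.mutations, fixture.reference, fixture.motifs)
by_direction = Counter(e.direction for e in found)
print(f"fixture events found: {len(found)} "
      f"({by_direction['gain']} gains, {by_direction['loss']} losses)")
truth_hit = {(e.mutation, e.motif_id, e.direction) for e in found} == fixture.truth
print(f"scanner output equals the planted truth: {truth_hit}")
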