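"""Per-site probabilities of rare-allele site patterns under a two-population tree.

Builds a model of two populations (4 haploids each) that merge 0.002
scaled time units ago (= 4,640 years at the default unit scale), and
prints the probability that a random genomic site shows each joint
derived-allele pattern, together with the expected total genealogy
length that controls the monomorphic fraction.
"""

from rarecoal import (
    Branch,
    DemographyModel,
    JoinEvent,
    UnitScale,
    pattern_probabilities,
    total_tree_length,
)

u = UnitScale()
model = DemographyModel(
    branches=[Branch("A", 1.0, 4), Branch("B", 0.5, 4)],
    joins=[JoinEvent(0.002, "A", "B", 2.0)],
)

patterns = [(1, 0), (0, 1), (1, 1), (2, 0), (2, 2)]
probs = pattern_probabilities(model, patterns, u)

print("pattern (derived copies in A, B) -> probability per site")
for pat, p in zip(patterns, probs):
    print(f"  {pat}: {p:.3e}")
print(
    "A site is monomorphic unless a mutation falls on the genealogy;"
    f" expected total tree length = {total_tree_length(model, u):.3f}"
    " scaled units, so the fraction of variant sites is about"
    f" {u.scaled_theta * total_tree_length(model, u):.4f}."
)
print(
    "Sharing patterns like (1,1) are rarer than private ones like (1,0):"
    " the lineages must survive back to the common ancestral population"
    " before coalescing."
)
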