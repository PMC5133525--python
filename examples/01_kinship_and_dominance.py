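"""Kinship and dominance coefficients from a three-generation pedigree.

Builds a small family (grandparents, two married siblings, three
grandchildren), computes the additive kinship matrix Phi and the dominance
matrix Delta, and prints coefficients for a few notable pairs.
"""

from pedlasso import build_matrices
from pedlasso.pedigree import Pedigree

rows = [
    ("GF", None, None), ("GM", None, None),          # grandparents
    ("P1", "GF", "GM"), ("P2", "GF", "GM"),          # their children (sibs)
    ("S1", None, None), ("S2", None, None),          # in-marrying spouses
    ("C1a", "P1", "S1"), ("C1b", "P1", "S1"),        # full sibs
    ("C2", "P2", "S2"),                              # their first cousin
]
members = [("FAM", iid) for iid, _, _ in rows]
parents = {
    ("FAM", iid): ((("FAM", f), ("FAM", m)) if f else (None, None))
    for iid, f, m in rows
}
ped = Pedigree(members=members, parents=parents)
rel = build_matrices(ped)

idx = {k[1]: i for i, k in enumerate(rel.sample_order)}
pairs = [("P1", "P2"), ("P1", "C1a"), ("C1a", "C1b"), ("C1a", "C2"), ("GF", "S1")]
print(f"{'pair':>12}  {'phi':>7}  {'Delta':>7}")
for a, b in pairs:
    print(f"{a + '-' + b:>12}  {rel.phi[idx[a], idx[b]]:7.4f}  {rel.delta[idx[a], idx[b]]:7.4f}")

# phi is the probability a random allele from each individual is identical by
# descent (0.25 for sibs and parent-offspring, 0.0625 for first cousins);
# Delta is the probability the pair shares BOTH alleles IBD (0.25 for sibs,
# 0 for parent-offspring and for single first cousins).
print("\nmax parental kinship (inbreeding audit):", ped.inbreeding_audit())
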