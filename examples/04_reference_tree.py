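"""From published measurements to an ultrametric species tree.

Loads the bundled table of compositional statistics and scaling exponents
for 32 vertebrate mitochondrial genomes, recomputes the three evolutionary
indices per species, and clusters the species by Euclidean distance in
(v1, v2, v3) space with group-average (UPGMA) linkage.
"""

from dnawalk import FeatureVector, euclidean_distances, to_newick, upgma
from dnawalk.datasets import load_vertebrate_reference

ref = load_vertebrate_reference()
vectors = [
    FeatureVector.from_measurements(
        id=r.species, xi=r.xi, H=r.H,
        alpha_RY=r.alpha_RY, alpha_SW=r.alpha_SW, alpha_KM=r.alpha_KM,
        beta_RY=r.beta_RY, beta_SW=r.beta_SW, beta_KM=r.beta_KM,
    )
    for r in ref.itertuples()
]

print("recomputed indices (first five species):")
for fv in vectors[:5]:
    print(f"  {fv.id:<30s} v1={fv.v1:+.4f}  v2={fv.v2:+.4f}  v3={fv.v3:+.4f}")

tree = upgma(euclidean_distances(vectors))
print(f"\nUPGMA tree over {len(vectors)} species, root height "
      f"{tree.merges[-1].height:.4f} (half the final average distance)")

newick = to_newick(tree)
print("\nNewick (truncated):")
print(newick[:200] + " ...")
print("\nEvery leaf is equidistant from the root (ultrametric): heights are")
print("merge averages/2, so cophenetic distance = 2 x lowest-common-ancestor height.")
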