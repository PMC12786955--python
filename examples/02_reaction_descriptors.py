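"""From a mapped reaction SMILES to a compressed descriptor vector.

A mapped reaction is collapsed into a condensed graph of reaction (one graph
whose bonds carry both the reactant-side and product-side order), path
fragments of 2–4 atoms are counted, and a PCA fitted on a corpus compresses
the counts into the descriptor vector the models consume.
"""

from condvae import (apply_compressor, build_cgr, enumerate_fragments,
                     fit_compressor, parse_mapped_reaction)
from condvae.synthetic import GeneratorSpec, generate_dataset

rxn_smiles = "[CH2:1]=[CH2:2].[H][H]>>[CH3:1][CH3:2]"
rxn = parse_mapped_reaction(rxn_smiles)
cgr = build_cgr(rxn)
print(f"reaction: {rxn_smiles}")
print(f"unmapped reagents kept as metadata: {rxn.reagents}")
dynamic = [(a, b) for a, b, d in cgr.edges(data="dynamic") if d]
print(f"CGR: {cgr.number_of_nodes()} atoms, {cgr.number_of_edges()} bonds, "
      f"{len(dynamic)} dynamic bond(s) {dynamic}")

table = enumerate_fragments(cgr, 2, 4)
print(f"fragments: {table.counts}   ('=>-' marks a double bond that became single)")

# fit the compressor on a synthetic corpus, transform the query
records = generate_dataset(GeneratorSpec(n_transformations=200, seed=0))
corpus = [enumerate_fragments(build_cgr(parse_mapped_reaction(r.smiles)),
                              2, 4, charges=True)
          for r in records[:200]]
comp = fit_compressor(corpus, target_variance=0.95, max_dim=500)
print(f"\ncorpus of {len(corpus)} reactions -> vocabulary of "
      f"{len(comp.vocabulary)} fragments, compressed to {comp.dim} dims "
      f"({comp.explained_variance_ratio.sum():.1%} variance)")
x = apply_compressor(comp, corpus[0])
print("descriptor of first corpus reaction:",
      [round(float(v), 2) for v in x[:5]], "…")
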