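"""Generate a synthetic contaminated assembly and census its single-copy genes.

The simulated assembly mixes a 2 Mbp eukaryotic host with three complete
0.5 Mbp bacterial genomes.  The census counts hits per bacterial
single-copy gene across all scaffolds; the mode of that count array is the
expected number of complete bacterial genomes hiding in the assembly.
"""

from binsift import SimulationConfig, census, generate_dataset

ds = generate_dataset(SimulationConfig(seed=1))
print(f"assembly: {len(ds.scaffolds)} scaffolds, {len(ds.contigs.splits)} splits, "
      f"{sum(ds.contigs.scaffold_lengths.values()):,} bp")

cen = census(ds.hits, ds.collection)
counts = cen.to_series()
print(f"single-copy genes hit at least once: {(counts > 0).sum()} / {len(ds.collection)}")
print(f"estimated_bacterial_genomes: {cen.estimated_genomes} "
      f"(multimodal: {str(cen.multimodal).lower()})")
# The mode equals the number of planted contaminants (3): most genes are hit
# exactly once per complete bacterial genome, so the most frequent per-gene
# hit count reveals how many genomes are present.
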