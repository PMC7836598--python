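"""Derive a hypoxia signature from two simulated tumor/normal studies.

Each study plants a +2 log2 mean shift (a 4-fold change) in 30
hypoxia-hallmark genes in the tumor samples; the screen keeps genes
with fold-change > 2 at BH-adjusted p < 0.05 in *both* studies and
intersects them with the hallmark set.
"""

from hyposig import SyntheticConfig, generate_de_studies, generate_gene_sets
from hyposig.datatypes import PipelineConfig
from hyposig.pipeline import derive_signature_from_studies
from hyposig.simulate import planted_genes

config = SyntheticConfig(n_genes=2000, hallmark_size=200, emt_size=200,
                         n_planted=30, n_tumor=20, n_normal=20, seed=7)
hallmark, _emt = generate_gene_sets(config)
studies = generate_de_studies(config, hallmark)

signature, de_tables = derive_signature_from_studies(studies, hallmark, PipelineConfig())
planted = set(planted_genes(config, hallmark))

for i, de in enumerate(de_tables, start=1):
    n_up = ((de["fold_change"] > 2) & (de["adjusted_p"] < 0.05)).sum()
    print(f"study {i}: {n_up} genes pass fold-change > 2 and adjusted p < 0.05")
print(f"signature: {len(signature)} genes after intersection with the hallmark set")
print(f"planted genes recovered: {len(set(signature) & planted)} of {len(planted)}")
# The signature should contain exactly the 30 planted hallmark genes:
# upregulation must replicate in both studies AND lie in the hallmark set.
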