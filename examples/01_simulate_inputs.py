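"""Generate a complete synthetic input set with planted ground truth.

Writes a counts table, sample sheet, annotation (GFF3 + BED), promoter and
genome FASTA, replicated narrowPeak files, and a truth.json recording every
planted label, into ./example_inputs/.
"""

from uprnet.simulate import SimulationConfig, write_inputs

config = SimulationConfig(seed=42, n_genes=800, deg_fraction=0.4)
truth = write_inputs(config, "example_inputs")

print(f"genes simulated:        {config.n_genes}")
print(f"planted DEGs:           {len(truth.deg_genes)}")
for pair, genes in sorted(truth.ddeg_genes.items()):
    print(f"planted DDEGs {pair}: {len(genes)}")
print(f"planted module genes:   {len(truth.module_of_gene)}")
print(f"promoters with motifs:  {len(truth.cre_positions)}")

# The planted labels are what the pipeline stages should recover: DEG calls
# should find the planted DEGs, the genotype comparison the DDEGs, and the
# peak filter exactly the Tm-specific peak identifiers in truth.json.
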