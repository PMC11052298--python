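"""Codon adaptation on one synthetic genome: I_TE weights, DITE, N_AC.

Parses a generated genome, derives I_TE weights from its highly
expressed genes against a GC-based mutational background, and contrasts
the two expression classes.
"""

import tempfile

from transelect.codon_adaptation import (
    adaptation,
    codon_frequencies,
    ite_weights,
    n_ac,
    optimal_codon,
)
from transelect.genome_io import classify_expression, parse_genbank
from transelect.synthetic_data import PanelConfig, generate_panel

config = PanelConfig(seed=11, n_species=1, n_heg=50, n_rest=300,
                     gc_targets=(50.0,))
with tempfile.TemporaryDirectory() as out:
    generate_panel(config, out_dir=out)
    genome = parse_genbank(f"{out}/species_R1.gb", rank_gt=1)

classify_expression(genome.cds)
heg, rest = genome.genes("HEG"), genome.genes("REST")

weights = ite_weights(codon_frequencies(heg), genome.gc_percent)
result = adaptation(heg, rest, weights)
pool = n_ac(genome.trna)

print(f"genome: {genome.meta.species_name}  GC% = {genome.gc_percent:.1f}  "
      f"{genome.n_cds} CDS, {genome.trna_count} tRNA genes")
print(f"mean I_TE  HEG  = {result.mean_heg:.4f}")
print(f"mean I_TE  REST = {result.mean_rest:.4f}")
print(f"DITE            = {result.dite:.4f}   (> 0: HEG codon usage is "
      "better adapted than the genomic average)")
print(f"N_AC            = {pool.value:.2f}    (61 = uniform anticodon pool; "
      "low values mean copies concentrate on few anticodons)")
print("example optimal codons:",
      {aa: optimal_codon(weights, aa) for aa in ("K", "F", "A")})
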