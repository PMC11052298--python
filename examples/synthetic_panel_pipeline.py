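"""Generate a synthetic panel and run the full pipeline over it.

Builds five annotated genomes whose translation features follow the
cross-species models (machinery counts, start/stop preference, codon
selection, SD motifs), writes them as GenBank, re-parses them, and fits
the statistical layer on the recovered summaries — a closed loop from
generative model to refitted model.
"""

import tempfile

from transelect.pipeline import run_pipeline
from transelect.synthetic_data import PanelConfig, generate_panel

config = PanelConfig(seed=42, n_species=5, n_heg=40, n_rest=200,
                     gc_targets=(45.0, 48.0, 52.0, 56.0, 60.0))

with tempfile.TemporaryDirectory() as panel_dir:
    generate_panel(config, out_dir=panel_dir)
    result = run_pipeline(panel_dir, compute_structure=False)

cols = ["species", "RankGT", "GC%", "N_rrn", "N_tRNA", "DITE", "N_AC"]
print(result.species_summary[cols].to_string(
    index=False, float_format=lambda v: f"{v:.3f}"))
print()
aug = result.regressions["aug"]
print(f"refitted AUG% RankGT coefficient: {aug['RankGT']:.3f} "
      "(generating model used -2.54)")
print(f"refitted tRNA floor: {result.fits['trna'].c:.1f} "
      "(generating model used 30)")
print("  -> machinery counts fall with rank, DITE shrinks, and the "
      "anticodon pool diversifies, as built into the generator.")
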