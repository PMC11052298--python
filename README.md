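# transelect

Footprints of differential selection for **translation efficiency** across
bacterial species.

Bacterial generation times span three orders of magnitude — minutes in
*Vibrio natriegens*, weeks in *Mycobacterium leprae*. A cell that must
duplicate its proteome in minutes is under far stronger selection to
optimise its translation machinery than one that has days to do so.
`transelect` extracts, per annotated genome, the features where that
selection leaves a record, and fits the cross-species models that relate
them to ranked generation time (RankGT, 1 = fastest):

* **machinery investment** — rRNA operon count `N_rrn` and tRNA gene count
  `N_tRNA`, modelled as floor-exponential decays
  `N_rrn = 1 + a·e^(−b·RankGT)` and `N_tRNA = c + a·e^(−b·RankGT)`
  (a genome needs at least one operon; `c` estimates the minimal tRNA set);
* **initiation** — start-codon usage (AUG% per expression class), upstream
  nucleotide-frequency and PWM profiles around the Shine–Dalgarno (SD)
  region, a likelihood-ratio (G) test of C-vs-U avoidance near the SD, and
  the aSD match distance `D_toStart`;
* **termination** — stop-codon usage (UAA%, the codon with the lowest
  readthrough rate);
* **elongation** — the index of translation efficiency `I_TE` (a CAI-style
  geometric mean of mutation-corrected codon weights), its class contrast
  `DITE = mean I_TE(HEG) − mean I_TE(REST)`, and Wright-style effective
  numbers of codons/anticodons (`ENC`, `N_AC`);
* **mRNA structure** — sliding-window (40 nt) minimum folding energy
  profiles anchored on the start or stop codon, summarised as `MeanMFE`
  over the SD-region window;
* a **statistical layer** — OLS with class dummies and interactions, rank
  regressions, and deterministic multi-start nonlinear fits;
* a **synthetic-genome generator** that emits GenBank panels with all of
  the above structure and a ground-truth manifest, so every stage is
  testable without downloads.

Genes are split into highly expressed genes (**HEG**: ribosomal proteins,
RNA polymerase core, elongation factors, configurable by name pattern) and
the rest (**REST**); pseudogenes are excluded everywhere.

## Worked example

Fitting the start-codon model on the packaged nine-species summary
(`examples/printed_table_regressions.py`):

```
AUG% ~ RankGT + GC% + GE  (HEG=0, REST=1)
           Coefficient  Standard Error     t Stat    p-Value
Intercept    125.85528         8.60272   14.62970    0.00000
RankGT        -2.53863         0.76412   -3.32229    0.00503
GC%           -0.52069         0.19491   -2.67147    0.01825
GE            -9.17674         2.94435   -3.11673    0.00758
R-squared = 0.820

HEG: AUG% = 125.86 -2.54 RankGT -0.52 GC%
REST: AUG% = 116.68 -2.54 RankGT -0.52 GC%
```

AUG usage drops ~2.5 percentage points per rank step toward longer
generations (after controlling for genomic GC%, a proxy for mutation
bias), and highly expressed genes prefer AUG ~9 points more than the
rest — both signatures of stronger selection in fast growers. The same
script prints the MeanMFE model (R² = 0.982, with a GC%×class
interaction), the rank regression of DITE on RankGT (R² = 0.8784), and
the machinery fits, whose estimated minimal tRNA set rounds to 30 genes.

Other examples: `examples/synthetic_panel_pipeline.py` (generate → parse →
refit closed loop), `examples/codon_adaptation_demo.py` (I_TE/DITE/N_AC on
one genome), `examples/folding_profile.py` (start-anchored MFE profiles).

A thin CLI wraps the same functions:

```sh
transelect synth-panel --out panel/ --seed 42
transelect run --genomes panel/ --out results/
transelect regress --model aug
```

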