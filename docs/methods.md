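# Methods

This note records the models the package implements, the defaults and why
they were chosen, and what the synthetic data does and does not emulate.

## Feature extraction

Genomes are read from GenBank flat files (Biopython). Coordinates are
0-based half-open internally; GenBank's 1-based inclusive convention is
converted at the I/O boundary. Multi-replicon genomes are pooled per
species, with genome length and GC% computed over the concatenation.
Coding sequences are extracted strand-aware (joins resolved), together
with 60 nt of upstream context 5′ of the start codon and 60 nt downstream
of the stop codon, truncated only at replicon edges. GC% is
100·(G+C)/(A+C+G+T) with ambiguity codes excluded from both numerator and
denominator.

Expression classes are assigned by gene-name pattern. The default HEG
spec — `rps*`, `rpl*`, `rpm*`, `rpoA/B/C`, `tuf*`, `fusA` — covers
ribosomal proteins, the RNA polymerase core, and elongation factors; it is
fully overridable (patterns and/or explicit locus tags) because any fixed
list of "known highly expressed genes" is a judgement call. Pseudogenes
(`/pseudo`, `/pseudogene`) are flagged at parse time and excluded from all
statistics. The genetic code is fixed to bacterial translation table 11;
genomes using table 4 (Mollicutes) are out of scope.

rRNA operons are counted as the number of annotated 16S rRNA genes: each
operon carries one 16S–23S–5S set, so the 16S copy number is a robust
proxy that avoids fragile co-location clustering. A parsed genome with no
16S annotation returns 0 with a warning, since a functional genome needs
at least one operon.

## Initiation signals

Upstream sequences are right-aligned so site 60 abuts the start codon and
the start codon occupies sites 61–63; shorter upstreams contribute only to
the sites they cover (how ragged upstreams were aligned is a convention
choice and is documented here so it is not changed silently).

PWM scores are log2 odds against a background distribution:
`score(site,b) = log2((count+pc·bg(b))/(N+pc)/bg(b))`, pseudocount `pc=1`
by default so absent bases stay finite; 0 means usage at the background
rate. The default background is the species' genome-wide nucleotide
frequencies; a gene-set-specific background is selectable.

The C-vs-U avoidance test is a likelihood-ratio G test on the 2×2 table of
C/U counts in a site window (default 45–55, configurable; narrowing to
48–53 strengthens the contrast) for HEG vs REST upstreams:
`G = 2·Σ O·ln(O/E)`, df = 1.

`D_toStart` scans the upstream region for the best antiparallel
Watson–Crick+GU match against the aSD core (default the 3′-terminal
`CCUCCUUA` of 16S rRNA, whose mRNA complement is the `UAAGGAGG` SD core).
The score is the longest run of consecutive pairs; ties break toward the
start codon; runs shorter than 4 are reported missing. The distance is
counted from the 3′-most paired upstream base to the first base of the
start codon. Free-energy-based SD scoring is deliberately out of scope.

## Codon adaptation

`I_TE` is a CAI-style geometric mean with mutation-corrected weights. For
codon c in synonymous family S:

    raw(c) = (p_HEG(c) + ε) / (p_bg(c) + ε),   w(c) = raw(c) / max_S raw

with ε = 0.5/(family HEG count) guarding zero frequencies. The default
background `p_bg` is the codon distribution expected from genome-wide GC
under position-independent base frequencies (P(G)=P(C)=GC/2); the observed
REST codon table can be substituted. Per gene, I_TE is the geometric mean
of w over codons, excluding the start codon (analysed separately), the
stop codon, and the Met/Trp families (no synonymous choice). DITE is the
unweighted HEG mean minus the REST mean; under no elongation selection
both classes see the same mutation pressure and DITE ≈ 0.

Effective numbers use Wright's homozygosity formula per family,
`F = (n·Σp² − 1)/(n − 1)`, class means over the 2-, 3-, 4- and 6-fold
degeneracy classes, and `N = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, capped
at 61. Families with n ≤ 1 or F ≤ 0 are excluded from their class mean; a
class with no usable family is imputed from its neighbouring classes
(standard ENC practice; Ile alone carries class 3). `N_AC` applies the
same formula to the tRNA gene pool, with anticodons copy-number-weighted
by default (one count per gene; a distinct-anticodon mode is available)
and the initiator tRNA counted in the Met family (excludable by flag).
Wobble decoding is not modelled: each anticodon belongs to the family of
its annotated amino acid.

## Secondary structure

MFE is computed over 40-nt sliding windows (step 1); the mid-window site
is window start + 19 (1-based). Start scans fold 60 nt upstream + the
first 61 nt of CDS (start codon at sites 61–63); stop scans fold the last
60 nt of CDS + 60 nt downstream (stop codon at sites 58–60). Genes
lacking full flanking context are excluded with a logged count. `MeanMFE`
is the mean of the aggregated (per-site mean) curve over mid-window sites
46–65 — the window spanning the SD region and start codon; per-site 95%
limits are the normal approximation mean ± 1.96·SE. All folding is at
37 °C for every species.

Two folding engines satisfy one contract. The default is the ViennaRNA
thermodynamic folder (Python bindings) when importable. The built-in
engine is a Zuker-style dynamic program over a compact embedded
nearest-neighbor parameter subset: stacking energies for all
Watson–Crick+GU stack combinations, hairpin-loop penalties by length
(Jacobson–Stockmayer extrapolation beyond 9), a single interior/bulge
penalty by total unpaired length, an affine multiloop cost, minimum
hairpin loop 3, no dangles or coaxial refinements, interior loops capped
at 30 unpaired bases. Its energies are exactly loop-decomposable, so an
explicit structure scorer shares the same rules and an exhaustive
enumeration over all structures of short sequences provides an
independent oracle; the test suite verifies engine = enumeration to 1e-9
on random sequences up to 18 nt. The two engines use different parameter
sets and are never compared numerically; both respect MFE ≤ 0 (0 = no
structure).

## Statistical layer

Species-level responses are fit by OLS with expression class encoded
HEG = 0 / REST = 1 and optional pairwise interactions; SEs use the
unbiased residual variance, p values are two-tailed, and a helper exposes
p/2 for declared one-tailed predictions (never silently). The AUG% and
UAA% models use genomic GC% and no interaction; the MeanMFE model uses
class-specific GC% and keeps the GC%×class interaction — model forms are
exposed explicitly rather than selected automatically. Class equations
are derived by substituting the class code into the fitted model, folding
interactions into class-specific slopes.

Rank transforms are midranks (ties averaged). Floor-exponential fits use
deterministic multi-start local least squares over decay-rate starts
b ∈ {0.05, 0.1, 0.2, 0.5, 1, 2}, with a and c initialised from the data
range and the best RSS kept; fits are unweighted and c unconstrained (a
negative floor would be reported, not clipped). On the packaged
nine-species machinery counts the estimated tRNA floor is ~29.9,
rounding to 30 genes.

A note on printed-table precision: the packaged AUG% input is recomputed
at full precision from the start-codon counts rather than taken from the
4-dp rounded percentage column, because the published coefficient table
was clearly fit on unrounded values and rounding the inputs perturbs the
refit in the 5th decimal place. The MeanMFE input exists only at 4-dp
precision, so its refitted coefficients can match the published table
only to ~1e-4.

## Synthetic data

The generator emits GenBank genomes whose statistics follow the models
above, with a manifest recording every drawn quantity. Defaults define
the study conditions: 9 species with genomic GC% targets equal to the
nine-species panel's values; machinery models `N_rrn = 1 + 14.6·e^(−0.27x)`
and `N_tRNA = 30 + 125·e^(−0.24x)` (least-squares fits of the published
counts); AUG/UAA probabilities from the published per-class linear models,
clamped to [0.01, 0.99] since the linear forms are unbounded; 60 HEG +
600 REST genes and 3 pseudogenes per species; gene lengths uniform
300–1500 nt in frame (desk-scale speed); ~25% of genes on the minus
strand. Codon usage is a per-family mixture — with selection strength s
emit the species' designated optimal codon, else draw from the
GC-conditioned background — with s_HEG = 0.70 − 0.06(x−1) and
s_REST = 0.25 − 0.02(x−1), a minimal model yielding a positive,
rank-decreasing DITE. The tRNA pool guarantees one gene per family plus
the initiator, then concentrates extra copies on optimal-codon anticodons
with probability q = 0.90 − 0.08(x−1), so N_AC trends upward with rank.
Upstream regions carry an `AGGAGG` SD core ending 7 ± 2 nt before the
start codon, written base-by-base with fidelity 0.9 (HEG) / 0.6 (REST);
C-avoidance and the weaker HEG structure arise implicitly from the
purine-rich motif. A null mode draws both classes from one codon
distribution with equal SD fidelity, for calibrating DITE, PWM and
MeanMFE class differences near zero.

Not emulated: realistic operon/intergenic architecture, amino-acid
composition, wobble decoding, phylogenetic correlation between species,
and rank-dependent structure strength beyond what the SD motif and GC%
induce. Passing tests on synthetic panels therefore demonstrate that the
pipeline recovers the generative structure it assumes — not that real
genomes obey it; the printed-table regressions carry the empirical
evidence.

## Problem sizes and determinism

Test and example panels use 4–9 species with tens to hundreds of genes
per class; the parameter-recovery experiment uses the full default panel
(9 × 660 genes, seed 42) and checks that the generating RankGT
coefficient lies inside the refitted 95% CI. Structure scans subsample a
per-class gene cap (default 40) since per-gene profiles are the slow
stage. All randomness flows from a single integer seed per panel;
identical configurations produce byte-identical GenBank output.

## Known limitations

* The HEG list is a pattern approximation of "known highly expressed
  genes"; results on real genomes depend on it and it should be reviewed
  per organism.
* The built-in folding engine's parameter subset is compact, not a full
  Turner set; absolute MFE values differ from thermodynamic folders, and
  only within-engine contrasts are meaningful.
* `N_AC` from gene copy number assumes copy number tracks tRNA abundance
  (empirically reasonable, but an approximation).
* Cross-species fits on nine species cannot support parameter-rich models
  or phylogenetically independent contrasts; ranked generation time
  equates rank steps of very different absolute magnitude.
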