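"""Codon and anticodon adaptation: I_TE, DITE, and effective numbers.

The index of translation efficiency (I_TE) is a CAI-style geometric mean
of per-codon weights, with weights corrected for the background mutation
pattern: within each synonymous family the weight of codon c is the ratio
of its frequency among highly expressed genes to its expected frequency
under the background model, renormalised so the best codon of each family
has weight 1.  The default background is the codon distribution expected
from genome-wide GC content (position-independent base frequencies);
alternatively the observed codon table of the REST gene class can serve
as background.

DITE = mean I_TE over HEGs minus mean I_TE over REST genes.  With no
selection on elongation, both classes see the same mutational pressure and
DITE is expected to be 0; stronger selection on highly expressed genes
pushes DITE up.

The effective number of codons (Wright's ENC) and its anticodon analogue
N_AC use per-family homozygosity F = (n*sum(p_i^2) - 1)/(n - 1) averaged
within synonymy classes:  N = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    FAMILY_SIZE,
    SENSE_CODONS,
    codon_for_anticodon,
    to_dna,
)
from .genome_io import GeneRecord, TRNAGene

logger = logging.getLogger(__name__)

#: amino acids excluded from I_TE scoring (no synonymous choice)
_UNSCORED_AA = {"M", "W"}


@dataclass
class CodonUsageTable:
    """Counts (or expected pseudo-counts) over the 61 sense codons."""

    counts: dict[str, float] = field(default_factory=dict)
    skipped_genes: int = 0

    def family_frequencies(self, aa: str) -> dict[str, float]:
        """Relative frequencies within one synonymous family (sum to 1)."""
        codons = AA_TO_CODONS[aa]
        total = sum(self.counts.get(c, 0.0) for c in codons)
        if total == 0:
            return {c: 0.0 for c in codons}
        return {c: self.counts.get(c, 0.0) / total for c in codons}

    def family_total(self, aa: str) -> float:
        return sum(self.counts.get(c, 0.0) for c in AA_TO_CODONS[aa])


@dataclass
class ITEWeights:
    """Per-codon weights in (0, 1], max 1 within each family."""

    weights: dict[str, float]
    background: str = "gc"


@dataclass
class AdaptationResult:
    per_gene: dict[str, float]
    mean_heg: float
    mean_rest: float

    @property
    def dite(self) -> float:
        return self.mean_heg - self.mean_rest


@dataclass
class EffectiveNumberResult:
    """Wright-style effective number with its per-family homozygosities."""

    value: float
    family_f: dict[str, float]
    class_means: dict[int, float]
    clamped: bool = False


def _scorable_codons(seq: str) -> list[str]:
    """Codons of a CDS entering I_TE: start and stop excluded, Met/Trp and
    unrecognised triplets skipped."""
    seq = to_dna(seq)
    out = []
    for i in range(3, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        aa = CODON_TO_AA.get(codon)
        if aa is None or aa in _UNSCORED_AA:
            continue
        out.append(codon)
    return out


def codon_frequencies(genes: Iterable[GeneRecord | str]) -> CodonUsageTable:
    """Count sense codons over a gene set.

    The first codon of every gene is excluded (start-codon bias is analysed
    separately) and so is the stop codon.  Genes whose length is not a
    multiple of 3 are skipped with a warning count.
    """
    counts: Counter[str] = Counter()
    skipped = 0
    for gene in genes:
        seq = gene.coding_sequence if isinstance(gene, GeneRecord) else gene
        seq = to_dna(seq)
        if len(seq) % 3 != 0:
            skipped += 1
            continue
        for i in range(3, len(seq), 3):
            codon = seq[i:i + 3]
            if codon in CODON_TO_AA:
                counts[codon] += 1
    if skipped:
        logger.warning("%d genes with length not divisible by 3 skipped", skipped)
    return CodonUsageTable(counts=dict(counts), skipped_genes=skipped)


def background_from_gc(gc_percent: float) -> CodonUsageTable:
    """Expected codon usage under position-independent base frequencies.

    With genome GC fraction g, P(G) = P(C) = g/2 and P(A) = P(T) =
    (1-g)/2; a codon's expected weight is the product over its three
    positions.  Only within-family relative frequencies matter downstream.
    """
    g = gc_percent / 100.0
    if not 0 < g < 1:
        raise ValueError("GC% must be strictly between 0 and 100")
    p = {"G": g / 2, "C": g / 2, "A": (1 - g) / 2, "T": (1 - g) / 2}
    counts = {c: p[c[0]] * p[c[1]] * p[c[2]] for c in SENSE_CODONS}
    return CodonUsageTable(counts=counts)


def ite_weights(heg_table: CodonUsageTable,
                background: CodonUsageTable | float,
                background_label: str | None = None) -> ITEWeights:
    """Mutation-corrected relative adaptiveness of each sense codon.

    For codon c in family S:  raw(c) = (p_HEG(c) + eps) / (p_bg(c) + eps),
    weight(c) = raw(c) / max_S raw, with eps = 0.5 / (family HEG count)
    guarding against zero frequencies.  ``background`` is either a codon
    table (e.g. from REST genes) or a genomic GC percentage.  A family
    entirely absent from the HEG table falls back to weight 1 for all its
    codons, with a warning.
    """
    if isinstance(background, (int, float)):
        bg_table = background_from_gc(float(background))
        label = background_label or f"gc:{float(background):.4f}"
    else:
        bg_table = background
        label = background_label or "codon-table"
    weights: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        if aa in _UNSCORED_AA:
            for c in codons:
                weights[c] = 1.0
            continue
        total = heg_table.family_total(aa)
        if total == 0:
            logger.warning("family %s absent from HEG codon table; weights set to 1", aa)
            for c in codons:
                weights[c] = 1.0
            continue
        eps = 0.5 / total
        p_heg = heg_table.family_frequencies(aa)
        p_bg = bg_table.family_frequencies(aa)
        raw = {c: (p_heg[c] + eps) / (p_bg[c] + eps) for c in codons}
        top = max(raw.values())
        for c in codons:
            weights[c] = raw[c] / top
    return ITEWeights(weights=weights, background=label)


def gene_ite(gene: GeneRecord | str, weights: ITEWeights) -> float:
    """I_TE of one gene: geometric mean of weights over scorable codons."""
    seq = gene.coding_sequence if isinstance(gene, GeneRecord) else gene
    codons = _scorable_codons(seq)
    if not codons:
        return math.nan
    log_sum = sum(math.log(weights.weights[c]) for c in codons)
    return math.exp(log_sum / len(codons))


def adaptation(heg_genes: Iterable[GeneRecord],
               rest_genes: Iterable[GeneRecord],
               weights: ITEWeights) -> AdaptationResult:
    """Per-gene I_TE for both classes, class means, and DITE."""
    per_gene: dict[str, float] = {}
    means = {}
    for label, genes in (("HEG", list(heg_genes)), ("REST", list(rest_genes))):
        if not genes:
            raise ValueError(f"no genes in class {label}: DITE undefined")
        scores = []
        for i, g in enumerate(genes):
            s = gene_ite(g, weights)
            tag = g.locus_tag if isinstance(g, GeneRecord) else f"{label}_{i}"
            per_gene[tag] = s
            if not math.isnan(s):
                scores.append(s)
        means[label] = sum(scores) / len(scores)
    return AdaptationResult(per_gene=per_gene, mean_heg=means["HEG"],
                            mean_rest=means["REST"])


def dite(mean_heg: float, mean_rest: float) -> float:
    """Difference in mean I_TE between expression classes."""
    return mean_heg - mean_rest


def anticodon_families(trnas: Iterable[TRNAGene],
                       include_initiator: bool = True,
                       copy_number_weighted: bool = True) -> dict[str, Counter]:
    """Group tRNA genes into synonymous families keyed by amino acid.

    Each tRNA gene contributes one count for its anticodon (copy-number
    weighting, the default) or each distinct anticodon one count.  The
    family of an anticodon is taken from the annotated amino acid, so
    wobble-decoding rules are not modelled.
    """
    fams: dict[str, Counter] = {}
    for t in trnas:
        if t.is_initiator and not include_initiator:
            continue
        fams.setdefault(t.amino_acid, Counter())
        fams[t.amino_acid][t.anticodon] += 1
    if not copy_number_weighted:
        fams = {aa: Counter({u: 1 for u in cnt}) for aa, cnt in fams.items()}
    return fams


def codon_families(table: CodonUsageTable) -> dict[str, Counter]:
    """Synonymous-family view of a codon usage table (for ENC)."""
    fams: dict[str, Counter] = {}
    for codon, count in table.counts.items():
        aa = CODON_TO_AA[codon]
        fams.setdefault(aa, Counter())
        if count:
            fams[aa][codon] += count
    return fams


def effective_number(units_by_family: Mapping[str, Mapping[str, float]],
                     cap: float = 61.0) -> EffectiveNumberResult:
    """Wright's effective number over synonymous families.

    F = (n*sum(p_i^2) - 1)/(n - 1) per family with n > 1 units; families
    with n <= 1 or F <= 0 are excluded from their class mean.  Class means
    are combined as 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6; a class with no usable
    family is imputed from the mean of its neighbouring classes (standard
    ENC practice: F3 from (F2+F4)/2 when Ile is unusable).  Values above
    ``cap`` are clamped with a warning flag.
    """
    family_f: dict[str, float] = {}
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, units in units_by_family.items():
        k = FAMILY_SIZE.get(aa)
        if k is None or k == 1:
            continue
        n = sum(units.values())
        if n <= 1:
            logger.warning("family %s has <=1 unit; excluded from class mean", aa)
            continue
        sum_p2 = sum((c / n) ** 2 for c in units.values())
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        if f <= 0:
            logger.warning("family %s has non-positive homozygosity; excluded", aa)
            continue
        family_f[aa] = f
        by_class[k].append(f)

    class_order = [2, 3, 4, 6]
    class_means: dict[int, float] = {
        k: sum(v) / len(v) for k, v in by_class.items() if v
    }
    if not class_means:
        raise ValueError("no usable synonymous family for effective number")
    for k in class_order:
        if k in class_means:
            continue
        idx = class_order.index(k)
        neighbours = [class_means[c] for c in
                      (class_order[idx - 1:idx] + class_order[idx + 1:idx + 2])
                      if c in class_means]
        if not neighbours:  # fall back to any available class
            neighbours = list(class_means.values())
        class_means[k] = sum(neighbours) / len(neighbours)

    value = (2.0 + 9.0 / class_means[2] + 1.0 / class_means[3]
             + 5.0 / class_means[4] + 3.0 / class_means[6])
    clamped = value > cap
    if clamped:
        logger.warning("effective number %.3f exceeds cap %.1f; clamped", value, cap)
        value = cap
    return EffectiveNumberResult(value=value, family_f=family_f,
                                 class_means=class_means, clamped=clamped)


def n_ac(trnas: Iterable[TRNAGene], include_initiator: bool = True,
         copy_number_weighted: bool = True) -> EffectiveNumberResult:
    """Effective number of anticodons of a genome's tRNA gene pool."""
    fams = anticodon_families(trnas, include_initiator=include_initiator,
                              copy_number_weighted=copy_number_weighted)
    # anticodon pools can at most reach the number of distinct anticodons
    cap = 61.0
    return effective_number(fams, cap=cap)


def optimal_codon(weights: ITEWeights, aa: str) -> str:
    """Codon of maximal weight within one family (ties -> alphabetical)."""
    codons = AA_TO_CODONS[aa]
    return max(sorted(codons), key=lambda c: weights.weights[c])
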