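"""Sliding-window minimum folding energy (MFE) around start and stop codons.

The folding engine is pluggable.  The default engine is the ViennaRNA
thermodynamic folder (via its Python bindings) at 37 C when the bindings
are importable; the package also ships a self-contained nearest-neighbor
dynamic program (`NearestNeighborEngine`) with a compact embedded
parameter set: stacking energies for Watson-Crick and GU stacks, hairpin
and interior/bulge loop length penalties, an affine multiloop cost, a
minimum hairpin loop of 3, and no dangling-end refinements.  The built-in
engine's energies are exactly loop-decomposable, so any candidate
structure can be scored independently with :func:`score_structure` — the
basis of its exhaustive-enumeration validation.

Anchor conventions (sites are 1-based mid-window positions):

* start scan — 60 nt upstream + first 61 nt of CDS (121 nt), so the start
  codon occupies sites 61-63;
* stop scan — last 60 nt of CDS (57 nt tail + stop) + 60 nt downstream
  (120 nt), so the stop codon occupies sites 58-60.

The MeanMFE summary averages the aggregated mean curve over mid-window
sites 46-65, the region spanning the SD sequence and the start codon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np

from .genetic_code import to_rna
from .genome_io import GeneRecord

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# embedded nearest-neighbor parameter subset (kcal/mol, 37 C)

_RT_LOOP = 1.75 * 0.616  # Jacobson-Stockmayer extrapolation prefactor

#: stacking energy keyed by (closing pair, enclosed pair); pair = (5' base,
#: 3' base) of the outer pair read toward the helix interior
STACK: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.9, ("AU", "CG"): -2.2, ("AU", "GC"): -2.1,
    ("AU", "UA"): -1.1, ("AU", "GU"): -0.6, ("AU", "UG"): -1.4,
    ("CG", "AU"): -2.1, ("CG", "CG"): -3.3, ("CG", "GC"): -2.4,
    ("CG", "UA"): -2.1, ("CG", "GU"): -1.4, ("CG", "UG"): -2.1,
    ("GC", "AU"): -2.4, ("GC", "CG"): -3.4, ("GC", "GC"): -3.3,
    ("GC", "UA"): -2.2, ("GC", "GU"): -1.5, ("GC", "UG"): -2.5,
    ("GU", "AU"): -1.3, ("GU", "CG"): -2.5, ("GU", "GC"): -2.1,
    ("GU", "UA"): -1.4, ("GU", "GU"): -0.5, ("GU", "UG"): -0.4,
    ("UA", "AU"): -1.3, ("UA", "CG"): -2.4, ("UA", "GC"): -2.1,
    ("UA", "UA"): -0.9, ("UA", "GU"): -1.0, ("UA", "UG"): -1.3,
    ("UG", "AU"): -1.0, ("UG", "CG"): -1.5, ("UG", "GC"): -1.4,
    ("UG", "UA"): -0.6, ("UG", "GU"): -0.2, ("UG", "UG"): -0.5,
}

_HAIRPIN = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_INTERIOR = {1: 3.8, 2: 3.0, 3: 3.5, 4: 4.2, 5: 4.6, 6: 5.0}
ML_CLOSE, ML_BRANCH, ML_UNPAIRED = 3.4, 0.4, 0.0
MIN_HAIRPIN = 3
MAX_INTERIOR = 30

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
              ("G", "U"), ("U", "G")}


def hairpin_energy(size: int) -> float:
    if size < MIN_HAIRPIN:
        return math.inf
    if size in _HAIRPIN:
        return _HAIRPIN[size]
    return _HAIRPIN[9] + _RT_LOOP * math.log(size / 9.0)


def interior_energy(size: int) -> float:
    """Bulge/interior loop penalty by total unpaired length."""
    if size in _INTERIOR:
        return _INTERIOR[size]
    return _INTERIOR[6] + _RT_LOOP * math.log(size / 6.0)


def _pairable(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL


def score_structure(seq: str, pairs: Iterable[tuple[int, int]]) -> float:
    """Free energy of an explicit structure under the embedded parameters.

    ``pairs`` is a set of 0-based (i, j) base pairs (i < j), required to be
    non-crossing with hairpin loops of at least MIN_HAIRPIN unpaired
    bases.  The energy is the sum over the loop decomposition: hairpin,
    stack, interior/bulge, and multiloop terms; the exterior loop is free.
    """
    s = to_rna(seq)
    pairs = sorted((min(i, j), max(i, j)) for i, j in pairs)
    for i, j in pairs:
        if not _pairable(s[i], s[j]) or j - i - 1 < MIN_HAIRPIN:
            return math.inf
    # direct children of each pair (and of the exterior)
    energy = 0.0
    for idx, (i, j) in enumerate(pairs):
        children = []
        k = idx + 1
        while k < len(pairs) and pairs[k][0] < j:
            ci, cj = pairs[k]
            if ci > i and cj < j:
                children.append((ci, cj))
                # skip everything nested inside this child
                k += 1
                while k < len(pairs) and pairs[k][0] < cj:
                    k += 1
            else:
                return math.inf  # crossing
        if not children:
            energy += hairpin_energy(j - i - 1)
        elif len(children) == 1:
            ci, cj = children[0]
            unpaired = (ci - i - 1) + (j - cj - 1)
            if unpaired == 0:
                energy += STACK[(s[i] + s[j], s[ci] + s[cj])]
            else:
                energy += interior_energy(unpaired)
        else:
            inner = sum(cj - ci + 1 for ci, cj in children)
            unpaired = (j - i - 1) - inner
            energy += (ML_CLOSE + ML_BRANCH * (1 + len(children))
                       + ML_UNPAIRED * unpaired)
    return energy


class FoldEngine(Protocol):
    name: str

    def mfe(self, seq: str) -> float: ...


class NearestNeighborEngine:
    """Zuker-style dynamic program over the embedded parameter subset.

    Deterministic, dependency-free, and exactly consistent with
    :func:`score_structure`; interior loops are capped at MAX_INTERIOR
    unpaired bases (irrelevant below ~35 nt windows).
    """

    name = "nearest-neighbor"

    def mfe(self, seq: str) -> float:
        s = to_rna(seq)
        n = len(s)
        if n < MIN_HAIRPIN + 2:
            return 0.0
        INF = math.inf
        V = [[INF] * n for _ in range(n)]
        WM = [[INF] * n for _ in range(n)]
        pairable = [[_pairable(s[i], s[j]) for j in range(n)] for i in range(n)]

        for span in range(MIN_HAIRPIN + 1, n):
            for i in range(n - span):
                j = i + span
                if pairable[i][j]:
                    best = hairpin_energy(j - i - 1)
                    # stacks and interior/bulge loops
                    for k in range(i + 1, j):
                        gap_left = k - i - 1
                        if gap_left > MAX_INTERIOR:
                            break
                        lmin = max(k + MIN_HAIRPIN + 1,
                                   j - 1 - (MAX_INTERIOR - gap_left))
                        for l in range(max(lmin, k + 1), j):
                            vkl = V[k][l]
                            if vkl == INF:
                                continue
                            unpaired = gap_left + (j - l - 1)
                            if unpaired == 0:
                                cand = STACK[(s[i] + s[j], s[k] + s[l])] + vkl
                            else:
                                cand = interior_energy(unpaired) + vkl
                            if cand < best:
                                best = cand
                    # multiloop: >= 2 branches inside the closing pair
                    for k in range(i + 1, j - 1):
                        left, right = WM[i + 1][k], WM[k + 1][j - 1]
                        if left < INF and right < INF:
                            cand = ML_CLOSE + ML_BRANCH + left + right
                            if cand < best:
                                best = cand
                    V[i][j] = best
                # WM: >= 1 multiloop branch over [i, j]
                best_wm = INF
                if V[i][j] < INF:
                    best_wm = V[i][j] + ML_BRANCH
                if WM[i][j - 1] < INF:
                    best_wm = min(best_wm, WM[i][j - 1] + ML_UNPAIRED)
                if i + 1 <= j and WM[i + 1][j] < INF:
                    best_wm = min(best_wm, WM[i + 1][j] + ML_UNPAIRED)
                for k in range(i, j):
                    if WM[i][k] < INF and WM[k + 1][j] < INF:
                        cand = WM[i][k] + WM[k + 1][j]
                        if cand < best_wm:
                            best_wm = cand
                WM[i][j] = best_wm
            # spans shorter than the minimum hairpin still need WM seeds
        # exterior loop
        W = [0.0] * (n + 1)
        for j in range(n):
            best = W[j]
            for i in range(j):
                if V[i][j] < INF:
                    cand = W[i] + V[i][j]
                    if cand < best:
                        best = cand
            W[j + 1] = best
        return min(0.0, W[n])


class ViennaEngine:
    """Thermodynamic folding through the ViennaRNA Python bindings."""

    name = "viennarna"

    def __init__(self, temperature: float = 37.0):
        import RNA  # deferred: optional engine

        self._rna = RNA
        self.temperature = temperature
        if temperature != 37.0:
            md = RNA.md()
            md.temperature = temperature
            self._md = md
        else:
            self._md = None

    def mfe(self, seq: str) -> float:
        seq = to_rna(seq)
        if self._md is None:
            _, e = self._rna.fold(seq)
        else:
            fc = self._rna.fold_compound(seq, self._md)
            _, e = fc.mfe()
        return min(0.0, float(e))


def default_engine() -> FoldEngine:
    try:
        return ViennaEngine()
    except ImportError:
        return NearestNeighborEngine()


# ---------------------------------------------------------------------------
# profiles

@dataclass
class MFEProfile:
    """Per-gene sliding-window MFE curve (1-based mid-window sites)."""

    sites: np.ndarray
    mfe: np.ndarray


@dataclass
class AggregatedProfile:
    """Mean curve with normal-approximation 95% limits, per site."""

    sites: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n: int


def fold_mfe(seq: str, engine: FoldEngine | None = None) -> float:
    """MFE (kcal/mol, <= 0) of one window; < 6 nt cannot fold (0)."""
    if len(seq) < MIN_HAIRPIN + 2 + 1:
        return 0.0
    engine = engine or default_engine()
    return engine.mfe(seq)


def sliding_mfe(sequence: str, window: int = 40, step: int = 1,
                engine: FoldEngine | None = None) -> MFEProfile:
    """Sliding-window MFE profile; mid-window site = window start + 19."""
    seq = to_rna(sequence)
    L = len(seq)
    if L < window:
        logger.warning("sequence of %d nt shorter than window %d; empty profile",
                       L, window)
        return MFEProfile(sites=np.array([], dtype=int), mfe=np.array([]))
    engine = engine or default_engine()
    starts = range(0, L - window + 1, step)
    sites = np.array([i + 1 + (window // 2 - 1) for i in starts], dtype=int)
    values = np.array([engine.mfe(seq[i:i + window]) for i in starts])
    return MFEProfile(sites=sites, mfe=values)


def assemble_start_region(gene: GeneRecord, upstream: int = 60,
                          cds_take: int = 61) -> str | None:
    """Upstream + CDS head with the start codon at sites 61-63.

    Genes lacking the full upstream context (replicon edge) or a long
    enough CDS are excluded (None).
    """
    if len(gene.upstream_60) < upstream or len(gene.coding_sequence) < cds_take:
        return None
    return gene.upstream_60[-upstream:] + gene.coding_sequence[:cds_take]


def assemble_stop_region(gene: GeneRecord, tail: int = 60,
                         downstream: int = 60) -> str | None:
    """CDS tail + downstream with the stop codon at sites 58-60."""
    if len(gene.coding_sequence) < tail or len(gene.downstream_of_stop) < downstream:
        return None
    return gene.coding_sequence[-tail:] + gene.downstream_of_stop[:downstream]


def aggregate_profiles(profiles: Sequence[MFEProfile]) -> AggregatedProfile:
    """Per-site mean curve and 95% limits (mean +/- 1.96 * SE)."""
    profiles = [p for p in profiles if p.sites.size]
    if not profiles:
        raise ValueError("no profiles to aggregate")
    sites = profiles[0].sites
    for p in profiles[1:]:
        if not np.array_equal(p.sites, sites):
            raise ValueError("profiles are not on a common site grid")
    mat = np.vstack([p.mfe for p in profiles])
    mean = mat.mean(axis=0)
    n = mat.shape[0]
    if n > 1:
        se = mat.std(axis=0, ddof=1) / math.sqrt(n)
    else:
        se = np.zeros_like(mean)
    return AggregatedProfile(sites=sites, mean=mean, lower=mean - 1.96 * se,
                             upper=mean + 1.96 * se, n=n)


def mean_mfe_summary(aggregated: AggregatedProfile,
                     site_lo: int = 46, site_hi: int = 65) -> float:
    """Mean of the aggregated curve over mid-window sites [site_lo, site_hi]."""
    mask = (aggregated.sites >= site_lo) & (aggregated.sites <= site_hi)
    covered = set(aggregated.sites[mask].tolist())
    if covered != set(range(site_lo, site_hi + 1)):
        raise ValueError(f"aggregated profile does not cover sites "
                         f"{site_lo}-{site_hi}")
    return float(aggregated.mean[mask].mean())


def class_mean_mfe(genes: Iterable[GeneRecord], engine: FoldEngine | None = None,
                   anchor: str = "start", max_genes: int | None = None
                   ) -> tuple[AggregatedProfile, float]:
    """Aggregate start- (or stop-) anchored profiles and their MeanMFE.

    Genes without full flanking context are skipped with a logged count;
    ``max_genes`` subsamples deterministically (first k) for speed.
    """
    engine = engine or default_engine()
    assemble = assemble_start_region if anchor == "start" else assemble_stop_region
    profiles, skipped, used = [], 0, 0
    for g in genes:
        if max_genes is not None and used >= max_genes:
            break
        region = assemble(g)
        if region is None:
            skipped += 1
            continue
        profiles.append(sliding_mfe(region, engine=engine))
        used += 1
    if skipped:
        logger.warning("%d genes lacked full flanking context for the %s scan",
                       skipped, anchor)
    agg = aggregate_profiles(profiles)
    return agg, mean_mfe_summary(agg)
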