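"""Translation-initiation signals: start-codon usage, upstream nucleotide
profiles, PWM scores around the Shine-Dalgarno region, the C-versus-U
avoidance G-test, and the aSD match distance D_toStart.

Site numbering follows the figure convention used throughout the package:
upstream sequences are right-aligned so that site 60 abuts the start codon
and the start codon occupies sites 61-63.  Shorter-than-60 upstreams
contribute only to the sites they cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import to_rna
from .genome_io import GeneRecord

RNA_ALPHABET = ("A", "C", "G", "U")

#: RNA base pairs permitted in SD/aSD duplexes: Watson-Crick plus GU wobble
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


@dataclass
class StartCodonTable:
    """Start-codon counts for one gene group (AUG / GUG / YUG / AUH)."""

    aug: int
    gug: int
    yug: int  # CUG + UUG
    auh: int  # AUA + AUC + AUU
    other: int
    n: int

    @property
    def aug_percent(self) -> float:
        return 100.0 * self.aug / self.n


@dataclass
class GTestResult:
    """Likelihood-ratio (G) test of independence on a 2x2 count table."""

    statistic: float
    df: int
    p_value: float
    percent_c_group1: float
    percent_c_group2: float


@dataclass
class SDMatch:
    """Best aSD complementary match within one upstream region."""

    locus_tag: str
    match_length: int
    d_to_start: int


def _upstreams(genes_or_seqs) -> list[str]:
    out = []
    for item in genes_or_seqs:
        seq = item.upstream_60 if isinstance(item, GeneRecord) else item
        out.append(to_rna(seq))
    return out


def start_codon_usage(genes: Iterable[GeneRecord],
                      class_filter: str | None = None) -> StartCodonTable:
    """Tabulate start codons for a gene set, optionally one expression class.

    Codons outside the canonical/near-canonical set are counted in an
    ``other`` bucket; AUG% is computed over the full group size N so
    percentages stay comparable across species.
    """
    counts = {"aug": 0, "gug": 0, "yug": 0, "auh": 0, "other": 0}
    n = 0
    for g in genes:
        if class_filter is not None and g.expression_class != class_filter:
            continue
        start = to_rna(g.start_codon)
        n += 1
        if start == "AUG":
            counts["aug"] += 1
        elif start == "GUG":
            counts["gug"] += 1
        elif start in ("CUG", "UUG"):
            counts["yug"] += 1
        elif start in ("AUA", "AUC", "AUU"):
            counts["auh"] += 1
        else:
            counts["other"] += 1
    if n == 0:
        raise ValueError("no genes to tabulate start codons for")
    return StartCodonTable(n=n, **counts)


def positional_frequencies(upstreams: Iterable[str | GeneRecord],
                           length: int = 60) -> pd.DataFrame:
    """Per-site nucleotide frequencies over right-aligned upstream regions.

    Returns a DataFrame indexed by site 1..``length`` (site ``length``
    abuts the start codon) with columns A/C/G/U summing to 1 at every
    covered site; ambiguity codes are excluded from that site's
    denominator.
    """
    seqs = _upstreams(upstreams)
    if not seqs:
        raise ValueError("no upstream sequences supplied")
    counts = np.zeros((length, 4), dtype=float)
    for seq in seqs:
        seq = seq[-length:]
        offset = length - len(seq)
        for i, base in enumerate(seq):
            if base in RNA_ALPHABET:
                counts[offset + i, RNA_ALPHABET.index(base)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, np.nan)
    return pd.DataFrame(freqs, index=pd.RangeIndex(1, length + 1, name="site"),
                        columns=list(RNA_ALPHABET))


def pwm_scores(upstreams: Iterable[str | GeneRecord],
               background_freqs: Mapping[str, float],
               pseudocount: float = 1.0,
               length: int = 60) -> pd.DataFrame:
    """Position weight matrix of log2 odds against background frequencies.

    score(site, b) = log2( (count(site,b) + pc*bg(b)) / (N_site + pc) / bg(b) ).
    Zero means usage at the background rate, positive overuse, negative
    avoidance; the pseudocount keeps every cell finite.
    """
    bg = np.array([background_freqs[b] for b in RNA_ALPHABET], dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background frequencies must all be positive")
    bg = bg / bg.sum()
    seqs = _upstreams(upstreams)
    if not seqs:
        raise ValueError("no upstream sequences supplied")
    counts = np.zeros((length, 4), dtype=float)
    for seq in seqs:
        seq = seq[-length:]
        offset = length - len(seq)
        for i, base in enumerate(seq):
            if base in RNA_ALPHABET:
                counts[offset + i, RNA_ALPHABET.index(base)] += 1
    n_site = counts.sum(axis=1, keepdims=True)
    scores = np.log2((counts + pseudocount * bg) / (n_site + pseudocount) / bg)
    return pd.DataFrame(scores, index=pd.RangeIndex(1, length + 1, name="site"),
                        columns=list(RNA_ALPHABET))


def count_c_u(upstreams: Iterable[str | GeneRecord],
              site_lo: int = 45, site_hi: int = 55,
              length: int = 60) -> tuple[int, int]:
    """Count C and U nucleotides within a site window of the SD region."""
    c = u = 0
    for seq in _upstreams(upstreams):
        seq = seq[-length:]
        offset = length - len(seq)
        for i, base in enumerate(seq):
            site = offset + i + 1
            if site_lo <= site <= site_hi:
                if base == "C":
                    c += 1
                elif base == "U":
                    u += 1
    return c, u


def c_vs_u_test(c1: int, u1: int, c2: int, u2: int) -> GTestResult:
    """Likelihood-ratio chi-square (G) test comparing C:U composition.

    G = 2 * sum O*ln(O/E) over the 2x2 table with independence
    expectations; p from chi-square with 1 df.  Cells with O = 0
    contribute zero to the sum.
    """
    obs = np.array([[c1, u1], [c2, u2]], dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=1) == 0) or np.any(obs.sum(axis=0) == 0):
        raise ValueError("G-test undefined with a zero row or column sum")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum()
    p = float(stats.chi2.sf(g, df=1))
    return GTestResult(statistic=float(g), df=1, p_value=p,
                       percent_c_group1=100.0 * c1 / (c1 + u1),
                       percent_c_group2=100.0 * c2 / (c2 + u2))


def _pairs_with(mrna_base: str, asd_base: str) -> bool:
    return (mrna_base, asd_base) in _PAIRS


def d_to_start(gene: GeneRecord | str,
               asd: str = "CCUCCUUA",
               min_match: int = 4) -> SDMatch | None:
    """Distance from the best aSD-paired region to the start codon.

    ``asd`` is the 3'-terminal core of the 16S rRNA given 5'->3' (default
    CCUCCUUA, whose mRNA complement is the UAAGGAGG Shine-Dalgarno core).
    The upstream region is scanned for the alignment maximising the length
    of a run of consecutive Watson-Crick or GU pairs between mRNA and the
    antiparallel aSD; ties are broken toward the start codon.  Matches
    shorter than ``min_match`` are reported as missing (None).

    ``d_to_start`` is the number of nucleotides between the 3'-most paired
    upstream base and the first base of the start codon.
    """
    if len(asd) < 4:
        raise ValueError("aSD core must be at least 4 nt")
    if isinstance(gene, GeneRecord):
        upstream = to_rna(gene.upstream_60)
        locus = gene.locus_tag
    else:
        upstream = to_rna(gene)
        locus = ""
    asd_rev = to_rna(asd)[::-1]  # 3'->5', antiparallel to the mRNA
    m, L = len(asd_rev), len(upstream)
    best: tuple[int, int] | None = None  # (run length, run end index)
    for offset in range(L - min_match + 1):
        run = 0
        for t in range(min(m, L - offset)):
            if _pairs_with(upstream[offset + t], asd_rev[t]):
                run += 1
                end = offset + t
                cand = (run, end)
                if best is None or cand[0] > best[0] or (
                        cand[0] == best[0] and cand[1] > best[1]):
                    best = cand
            else:
                run = 0
    if best is None or best[0] < min_match:
        return None
    run_len, end_idx = best
    return SDMatch(locus_tag=locus, match_length=run_len,
                   d_to_start=L - 1 - end_idx)


def sd_report(genes: Sequence[GeneRecord], asd: str = "CCUCCUUA",
              min_match: int = 4) -> pd.DataFrame:
    """Per-gene D_toStart table; genes without a qualifying match get NaN."""
    rows = []
    for g in genes:
        match = d_to_start(g, asd=asd, min_match=min_match)
        rows.append({
            "locus_tag": g.locus_tag,
            "match_length": match.match_length if match else 0,
            "d_to_start": match.d_to_start if match else math.nan,
        })
    return pd.DataFrame(rows)
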