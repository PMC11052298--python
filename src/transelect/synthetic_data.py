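"""Synthetic annotated-genome panels with known ground truth.

The generator emulates the statistical structure the cross-species
analysis assumes, so every pipeline stage can be exercised and verified
without downloading real genomes:

* machinery counts follow the floor-exponential models
  N_rrn = round(1 + a*exp(-b*rank)) and N_tRNA = round(c + a*exp(-b*rank));
* start/stop codon choice is Bernoulli with AUG / UAA probabilities from
  the published per-class linear models in RankGT and GC%, clamped to
  [0.01, 0.99] (the linear models are descriptive and unbounded);
* sense-codon usage is a per-family mixture: with selection strength s the
  family's designated optimal codon is emitted, otherwise a draw from a
  GC-conditioned background; s is higher in HEGs and declines with rank,
  yielding a positive, rank-decreasing DITE;
* the tRNA pool covers every family and concentrates extra copies on the
  anticodons of optimal codons with a rank-declining probability, so the
  effective number of anticodons rises with rank;
* upstream regions are background sequence at the species GC% with an
  AGGAGG Shine-Dalgarno core written in at a configurable offset with
  class-dependent per-base fidelity.

Every panel is produced from a mandatory seed and is byte-identical for
identical configurations; the ground-truth manifest suffices to recompute
each expected summary statistic without re-parsing sequences.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genetic_code import (
    AA1_TO_AA3,
    AA_TO_CODONS,
    FAMILY_SIZE,
    anticodon_for,
    revcomp,
)
from .codon_adaptation import background_from_gc

_BASES = np.array(list("ACGT"))

#: Table-2-shaped defaults: least-squares fits of the machinery models
DEFAULT_RRN_MODEL = {"a": 14.6, "b": 0.27}          # floor fixed at 1
DEFAULT_TRNA_MODEL = {"c": 30.0, "a": 125.0, "b": 0.24}

#: published per-class AUG% / UAA% linear models (intercept, rank, gc)
DEFAULT_START_MODEL = {"HEG": (125.86, -2.54, -0.52),
                       "REST": (116.68, -2.54, -0.52)}
DEFAULT_STOP_MODEL = {"HEG": (197.95, -3.78, -2.22),
                      "REST": (180.60, -3.78, -2.22)}

#: genomic GC% targets of the nine-species panel
DEFAULT_GC_TARGETS = (45.0, 47.3, 50.8, 43.5, 38.2, 67.4, 64.1, 65.6, 57.8)

SD_MOTIF = "AGGAGG"

#: relative amino-acid usage in generated proteins (multi-codon families
#: uniform; Met/Trp rare so they perturb I_TE scoring little)
_AA_WEIGHTS = {aa: (1.0 if FAMILY_SIZE[aa] > 1 else 0.3) for aa in AA_TO_CODONS}


@dataclass
class PanelConfig:
    """Generative settings for one synthetic species panel."""

    seed: int
    n_species: int = 9
    gc_targets: tuple[float, ...] = DEFAULT_GC_TARGETS
    rrn_a: float = DEFAULT_RRN_MODEL["a"]
    rrn_b: float = DEFAULT_RRN_MODEL["b"]
    trna_c: float = DEFAULT_TRNA_MODEL["c"]
    trna_a: float = DEFAULT_TRNA_MODEL["a"]
    trna_b: float = DEFAULT_TRNA_MODEL["b"]
    n_heg: int = 60
    n_rest: int = 600
    n_pseudo: int = 3
    selection_heg: tuple[float, float] = (0.70, 0.06)   # s = s0 - slope*(rank-1)
    selection_rest: tuple[float, float] = (0.25, 0.02)
    anticodon_conc: tuple[float, float] = (0.90, 0.08)  # q = q0 - slope*(rank-1)
    sd_offset: int = 7
    sd_offset_jitter: int = 2
    sd_fidelity: dict = field(default_factory=lambda: {"HEG": 0.9, "REST": 0.6})
    min_codons: int = 100   # 300 nt
    max_codons: int = 500   # 1500 nt
    fraction_minus_strand: float = 0.25

    def gc_for_rank(self, rank: int) -> float:
        if len(self.gc_targets) >= self.n_species:
            return float(self.gc_targets[rank - 1])
        return 45.0 + 15.0 * (rank - 1) / max(1, self.n_species - 1)


def _clamp_prob(x: float) -> float:
    return min(0.99, max(0.01, x))


def n_rrn_for_rank(config: PanelConfig, rank: int) -> int:
    return max(1, round(1.0 + config.rrn_a * math.exp(-config.rrn_b * rank)))


def n_trna_for_rank(config: PanelConfig, rank: int) -> int:
    return round(config.trna_c + config.trna_a * math.exp(-config.trna_b * rank))


def start_prob(config: PanelConfig, cls: str, rank: int, gc: float) -> float:
    i, r, g = DEFAULT_START_MODEL[cls]
    return _clamp_prob((i + r * rank + g * gc) / 100.0)


def stop_prob(config: PanelConfig, cls: str, rank: int, gc: float) -> float:
    i, r, g = DEFAULT_STOP_MODEL[cls]
    return _clamp_prob((i + r * rank + g * gc) / 100.0)


def selection_strength(config: PanelConfig, cls: str, rank: int,
                       selection_off: bool = False) -> float:
    s0, slope = (config.selection_rest if (cls == "REST" or selection_off)
                 else config.selection_heg)
    return min(0.95, max(0.02, s0 - slope * (rank - 1)))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _family_background(gc_percent: float) -> dict[str, tuple[list[str], np.ndarray]]:
    table = background_from_gc(gc_percent)
    out = {}
    for aa, codons in AA_TO_CODONS.items():
        freqs = table.family_frequencies(aa)
        cs = list(codons)
        p = np.array([freqs[c] for c in cs])
        out[aa] = (cs, p / p.sum())
    return out


def _draw_gene(rng: np.random.Generator, cls: str, rank: int, gc: float,
               config: PanelConfig, optimal: dict[str, str],
               fam_bg, p_aug: float, p_uaa: float,
               selection_off: bool) -> tuple[str, str, str]:
    """Return (cds, start_codon, stop_codon)."""
    start = "ATG" if rng.random() < p_aug else ("GTG" if rng.random() < 0.7 else "TTG")
    if rng.random() < p_uaa:
        stop = "TAA"
    else:
        stop = "TGA" if rng.random() < 0.6 else "TAG"
    s = selection_strength(config, cls, rank, selection_off)
    n_codons = int(rng.integers(config.min_codons, config.max_codons + 1))
    aas = list(_AA_WEIGHTS)
    aa_p = np.array(list(_AA_WEIGHTS.values()))
    aa_p = aa_p / aa_p.sum()
    chosen_aas = rng.choice(len(aas), size=n_codons - 2, p=aa_p)
    codons = [start]
    for idx in chosen_aas:
        aa = aas[idx]
        cs, p = fam_bg[aa]
        if FAMILY_SIZE[aa] > 1 and rng.random() < s:
            codons.append(optimal[aa])
        else:
            codons.append(cs[int(rng.choice(len(cs), p=p))])
    codons.append(stop)
    return "".join(codons), start, stop


def _upstream(rng: np.random.Generator, gc: float, cls: str,
              config: PanelConfig) -> tuple[str, int]:
    """60-nt upstream with the SD core written in; returns (seq, offset)."""
    seq = list(_random_bases(rng, 60, gc))
    jitter = config.sd_offset_jitter
    offset = int(config.sd_offset if jitter == 0 else
                 rng.integers(config.sd_offset - jitter,
                              config.sd_offset + jitter + 1))
    fidelity = config.sd_fidelity[cls]
    end = 60 - offset          # exclusive end of motif
    startm = end - len(SD_MOTIF)
    if startm >= 0:
        for k, base in enumerate(SD_MOTIF):
            if rng.random() < fidelity:
                seq[startm + k] = base
    return "".join(seq), offset


def _trna_pool(rng: np.random.Generator, n_trna: int, rank: int,
               config: PanelConfig, optimal: dict[str, str]) -> list[dict]:
    """tRNA gene list: full family coverage, then skewed extra copies."""
    q0, slope = config.anticodon_conc
    q = min(0.95, max(0.05, q0 - slope * (rank - 1)))
    pool: list[dict] = []
    families = sorted(AA_TO_CODONS)
    # guaranteed decoding set: one tRNA per family (anticodon of the
    # optimal codon) plus the initiator
    pool.append({"aa": "M", "anticodon": "CAU", "initiator": True})
    for aa in families:
        pool.append({"aa": aa, "anticodon": anticodon_for(optimal[aa]),
                     "initiator": False})
    fam_sizes = np.array([FAMILY_SIZE[aa] for aa in families], dtype=float)
    fam_p = fam_sizes / fam_sizes.sum()
    while len(pool) < n_trna:
        aa = families[int(rng.choice(len(families), p=fam_p))]
        codons = AA_TO_CODONS[aa]
        if len(codons) == 1 or rng.random() < q:
            anticodon = anticodon_for(optimal[aa])
        else:
            anticodon = anticodon_for(codons[int(rng.integers(len(codons)))])
        pool.append({"aa": aa, "anticodon": anticodon, "initiator": False})
    return pool[:n_trna]


_HEG_STEMS = ["rps", "rpl", "rpm"]


def _heg_name(i: int) -> str:
    stem = _HEG_STEMS[i % 3]
    return f"{stem}{chr(ord('A') + (i // 3) % 26)}{i // 78 if i >= 78 else ''}"


def generate_species(rng: np.random.Generator, rank: int, config: PanelConfig,
                     selection_off: bool = False) -> tuple[SeqRecord, dict]:
    """One synthetic genome (SeqRecord) plus its ground-truth entry."""
    gc = config.gc_for_rank(rank) / 100.0
    gc_pct = gc * 100.0
    name = f"Synthetica simulans R{rank}"
    n_rrn = n_rrn_for_rank(config, rank)
    n_trna = n_trna_for_rank(config, rank)
    if n_trna < len(AA_TO_CODONS) + 1:
        raise ValueError(f"infeasible config: N_tRNA={n_trna} cannot cover "
                         f"all {len(AA_TO_CODONS)} families plus initiator")
    optimal = {aa: AA_TO_CODONS[aa][int(rng.integers(len(AA_TO_CODONS[aa])))]
               for aa in sorted(AA_TO_CODONS)}
    fam_bg = _family_background(gc_pct)
    p_aug = {c: start_prob(config, c, rank, gc_pct) for c in ("HEG", "REST")}
    p_uaa = {c: stop_prob(config, c, rank, gc_pct) for c in ("HEG", "REST")}

    chunks: list[str] = []
    features: list[SeqFeature] = []
    gene_truth: list[dict] = []
    pos = 0

    def emit(seq_chunk: str) -> int:
        nonlocal pos
        chunks.append(seq_chunk)
        start = pos
        pos += len(seq_chunk)
        return start

    gene_plan = ([("HEG", False)] * config.n_heg
                 + [("REST", False)] * config.n_rest
                 + [("REST", True)] * config.n_pseudo)
    heg_i = 0
    for gi, (cls, pseudo) in enumerate(gene_plan):
        locus = f"SYN{rank:02d}_{gi + 1:04d}"
        if cls == "HEG" and not pseudo:
            gname = _heg_name(heg_i)
            heg_i += 1
        else:
            gname = f"y{locus[-4:]}"
        sd_cls = "REST" if (selection_off and cls == "HEG") else cls
        upstream, sd_off = _upstream(rng, gc, sd_cls, config)
        cds, start_codon, stop_codon = _draw_gene(
            rng, cls, rank, gc_pct, config, optimal, fam_bg,
            p_aug[cls], p_uaa[cls], selection_off)
        downstream = _random_bases(rng, 60, gc)
        minus = rng.random() < config.fraction_minus_strand
        block = upstream + cds + downstream
        if minus:
            block = revcomp(block)
            cds_start, cds_end = len(downstream), len(downstream) + len(cds)
        else:
            cds_start, cds_end = len(upstream), len(upstream) + len(cds)
        emit(_random_bases(rng, 10, gc))  # spacer
        block_at = emit(block)
        quals = {"locus_tag": [locus], "gene": [gname], "transl_table": ["11"]}
        if pseudo:
            quals["pseudo"] = [""]
        features.append(SeqFeature(
            FeatureLocation(block_at + cds_start, block_at + cds_end,
                            strand=-1 if minus else 1),
            type="CDS", qualifiers=quals))
        gene_truth.append({"locus_tag": locus, "gene": gname,
                           "class": None if pseudo else cls,
                           "start_codon": start_codon, "stop_codon": stop_codon,
                           "strand": "-" if minus else "+",
                           "pseudo": pseudo, "sd_offset": sd_off})

    # rRNA operons: one 16S + 23S + 5S set per operon
    for oi in range(n_rrn):
        for product, length in (("16S ribosomal RNA", 120),
                                ("23S ribosomal RNA", 180),
                                ("5S ribosomal RNA", 60)):
            at = emit(_random_bases(rng, length, gc))
            features.append(SeqFeature(
                FeatureLocation(at, at + length, strand=1), type="rRNA",
                qualifiers={"locus_tag": [f"SYN{rank:02d}_r{oi + 1:02d}"],
                            "product": [product]}))
        emit(_random_bases(rng, 20, gc))

    trna_truth = _trna_pool(rng, n_trna, rank, config, optimal)
    for ti, t in enumerate(trna_truth):
        at = emit(_random_bases(rng, 76, gc))
        aa3 = "fMet" if t["initiator"] else AA1_TO_AA3[t["aa"]]
        features.append(SeqFeature(
            FeatureLocation(at, at + 76, strand=1), type="tRNA",
            qualifiers={"locus_tag": [f"SYN{rank:02d}_t{ti + 1:03d}"],
                        "product": [f"tRNA-{aa3}"],
                        "anticodon": [f"(pos:{at + 34}..{at + 36},aa:{aa3},"
                                      f"seq:{t['anticodon'].lower()})"]}))

    record = SeqRecord(Seq("".join(chunks)), id=f"SYN{rank:02d}.1",
                       name=f"SYN{rank:02d}", description=f"{name} synthetic genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["organism"] = name
    record.annotations["date"] = "01-JAN-2024"
    record.annotations["topology"] = "circular"
    record.features = features

    truth = {
        "species": name, "rank_gt": rank, "gc_target": gc_pct,
        "n_rrn": n_rrn, "n_trna": n_trna,
        "p_aug": p_aug, "p_uaa": p_uaa,
        "selection": {c: selection_strength(config, c, rank, selection_off)
                      for c in ("HEG", "REST")},
        "optimal_codons": optimal,
        "sd_offset": config.sd_offset,
        "genes": gene_truth,
        "trna": trna_truth,
    }
    return record, truth


def generate_panel(config: PanelConfig, out_dir: str | Path | None = None,
                   selection_off: bool = False
                   ) -> tuple[list[SeqRecord], dict]:
    """Generate the full panel; optionally write GenBank files + manifest.

    Returns the list of SeqRecords (one per species, rank order) and the
    ground-truth manifest.  With ``out_dir`` set, writes
    ``species_R<rank>.gb`` files, ``manifest.json``, and an
    ``expected_summary.tsv`` of generator-side expectations.
    """
    rng = np.random.default_rng(config.seed)
    records, species_truth = [], []
    for rank in range(1, config.n_species + 1):
        rec, truth = generate_species(rng, rank, config, selection_off)
        records.append(rec)
        species_truth.append(truth)
    manifest = {"config": asdict(config), "selection_off": selection_off,
                "species": species_truth}
    if out_dir is not None:
        write_panel(records, manifest, out_dir)
    return records, manifest


def null_panel(config: PanelConfig, out_dir: str | Path | None = None
               ) -> tuple[list[SeqRecord], dict]:
    """Panel with selection switched off: HEG and REST codon usage drawn
    from the same distribution and equal SD fidelity, for calibrating the
    null behaviour of DITE, PWM scores, and class MeanMFE differences."""
    return generate_panel(config, out_dir=out_dir, selection_off=True)


def write_panel(records: list[SeqRecord], manifest: dict,
                out_dir: str | Path) -> list[Path]:
    from Bio import SeqIO

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec, truth in zip(records, manifest["species"]):
        path = out_dir / f"species_R{truth['rank_gt']}.gb"
        SeqIO.write([rec], str(path), "genbank")
        paths.append(path)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out_dir / "expected_summary.tsv", "w") as fh:
        fh.write("species\trank_gt\tgc_target\tn_rrn\tn_trna\t"
                 "p_aug_heg\tp_aug_rest\tp_uaa_heg\tp_uaa_rest\t"
                 "s_heg\ts_rest\n")
        for t in manifest["species"]:
            fh.write(f"{t['species']}\t{t['rank_gt']}\t{t['gc_target']:.2f}\t"
                     f"{t['n_rrn']}\t{t['n_trna']}\t"
                     f"{t['p_aug']['HEG']:.4f}\t{t['p_aug']['REST']:.4f}\t"
                     f"{t['p_uaa']['HEG']:.4f}\t{t['p_uaa']['REST']:.4f}\t"
                     f"{t['selection']['HEG']:.4f}\t{t['selection']['REST']:.4f}\n")
    return paths
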