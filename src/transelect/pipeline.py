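"""End-to-end orchestration: genomes -> per-species summary -> regressions.

Two entry modes mirror the two kinds of inputs the analysis accepts:

* ``run_pipeline`` parses annotated genomes (real or synthetic), computes
  every translation-machinery feature per species and expression class,
  and fits the cross-species models on the result;
* the ``*_regression`` helpers run the statistical layer directly on a
  species-summary table (e.g. the packaged published fixtures), bypassing
  the sequence stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import datasets
from .codon_adaptation import (
    adaptation,
    codon_frequencies,
    ite_weights,
    n_ac,
)
from .genome_io import AnnotatedGenome, classify_expression, parse_genbank
from .initiation_signals import start_codon_usage
from .regression_suite import (
    NonlinearFitResult,
    RegressionResult,
    fit_floor_exponential,
    ols_fit,
    rank_regression,
    rank_transform,
)
from .structure_scan import FoldEngine, class_mean_mfe, default_engine
from .termination_signals import stop_codon_usage

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Pipeline outputs: summary tables plus fitted models."""

    class_summary: pd.DataFrame     # one row per species x class
    species_summary: pd.DataFrame   # one row per species
    regressions: dict[str, RegressionResult] = field(default_factory=dict)
    fits: dict[str, NonlinearFitResult] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.class_summary.to_csv(out_dir / "class_summary.tsv", sep="\t",
                                  index=False)
        self.species_summary.to_csv(out_dir / "species_summary.tsv", sep="\t",
                                    index=False)
        for name, reg in self.regressions.items():
            reg.as_frame().to_csv(out_dir / f"regression_{name}.tsv", sep="\t")
        fits = {name: {"a": f.a, "b": f.b, "c": f.c, "rss": f.rss,
                       "converged": f.converged}
                for name, f in self.fits.items()}
        with open(out_dir / "machinery_fits.json", "w") as fh:
            json.dump(fits, fh, indent=1)


# ---------------------------------------------------------------------------
# fixture-table regressions (printed-table mode)

def aug_regression(table: pd.DataFrame | None = None) -> RegressionResult:
    """AUG% ~ RankGT + GC% + GE (HEG=0, REST=1), no interactions."""
    if table is None:
        table = datasets.load_aug_percent()
    return ols_fit(table, "AUG%", ["RankGT", "GC%", "GE"])


def uaa_regression(table: pd.DataFrame) -> RegressionResult:
    """UAA% ~ RankGT + GC% + GE."""
    return ols_fit(table, "UAA%", ["RankGT", "GC%", "GE"])


def mean_mfe_regression(table: pd.DataFrame | None = None) -> RegressionResult:
    """MeanMFE ~ RankGT + GC% + GE + GC%xGE (the best published model)."""
    if table is None:
        table = datasets.load_mean_mfe()
    return ols_fit(table, "MeanMFE", ["RankGT", "GC%", "GE"],
                   interactions=[("GC%", "GE")])


def dite_rank_regression(table: pd.DataFrame | None = None) -> RegressionResult:
    """Ranked DITE on RankGT."""
    if table is None:
        table = datasets.load_dite()
    return rank_regression(rank_transform(table["DITE"]), table["RankGT"])


def machinery_fits(table: pd.DataFrame | None = None
                   ) -> dict[str, NonlinearFitResult]:
    """Floor-exponential fits: N_rrn (floor fixed at 1) and N_tRNA (free)."""
    if table is None:
        table = datasets.load_machinery_counts()
    return {
        "rrn": fit_floor_exponential(table["RankGT"], table["N_rrn"], floor=1.0),
        "trna": fit_floor_exponential(table["RankGT"], table["N_tRNA"]),
    }


# ---------------------------------------------------------------------------
# full pipeline

def _species_rows(genome: AnnotatedGenome, engine: FoldEngine | None,
                  structure_max_genes: int | None,
                  compute_structure: bool) -> tuple[list[dict], dict]:
    heg = genome.genes("HEG")
    rest = genome.genes("REST")
    if not heg or not rest:
        raise RuntimeError(f"species {genome.meta.species_name!r}: empty "
                           f"expression class (HEG={len(heg)}, REST={len(rest)})")
    genome_gc = genome.gc_percent
    heg_table = codon_frequencies(heg)
    weights = ite_weights(heg_table, genome_gc)
    adapt = adaptation(heg, rest, weights)
    nac = n_ac(genome.trna)

    rows = []
    for cls, genes in (("HEG", heg), ("REST", rest)):
        starts = start_codon_usage(genes)
        stops = stop_codon_usage(genes)
        row = {
            "species": genome.meta.species_name,
            "RankGT": genome.meta.rank_gt,
            "GE": cls,
            "GC%": genome_gc,
            "class_GC%": (sum(g.gc_percent for g in genes) / len(genes)),
            "N": len(genes),
            "AUG%": starts.aug_percent,
            "UAA%": stops.uaa_percent,
        }
        if compute_structure:
            _, summary = class_mean_mfe(genes, engine=engine,
                                        max_genes=structure_max_genes)
            row["MeanMFE"] = summary
        rows.append(row)

    species_row = {
        "species": genome.meta.species_name,
        "RankGT": genome.meta.rank_gt,
        "L_genome": genome.genome_length,
        "N_CDS": genome.n_cds,
        "GC%": genome_gc,
        "N_rrn": genome.rrn_count,
        "N_tRNA": genome.trna_count,
        "ITE_HEG": adapt.mean_heg,
        "ITE_REST": adapt.mean_rest,
        "DITE": adapt.dite,
        "N_AC": nac.value,
    }
    return rows, species_row


def _resolve_inputs(genomes) -> list[tuple[list[Path], int | None, str | None]]:
    """Accept a panel directory, a list of paths, or (paths, rank) tuples."""
    if isinstance(genomes, (str, Path)) and Path(genomes).is_dir():
        panel = Path(genomes)
        manifest_path = panel / "manifest.json"
        ranks: dict[str, int] = {}
        if manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())
            ranks = {t["species"]: t["rank_gt"] for t in manifest["species"]}
        out = []
        for path in sorted(panel.glob("*.gb")) + sorted(panel.glob("*.gbk")):
            out.append(([path], None, None))
        if not out:
            raise FileNotFoundError(f"no GenBank files in {panel}")
        return [(paths, ranks.get(_peek_organism(paths[0])), None)
                for paths, _, _ in out]
    out = []
    for item in genomes:
        if isinstance(item, (str, Path)):
            out.append(([Path(item)], None, None))
        else:
            paths, rank = item
            if isinstance(paths, (str, Path)):
                paths = [paths]
            out.append(([Path(p) for p in paths], rank, None))
    return out


def _peek_organism(path: Path) -> str:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "genbank"))
    return rec.annotations.get("organism", rec.id)


def run_pipeline(genomes, heg_spec: Sequence[str] | None = None,
                 engine: FoldEngine | None = None,
                 compute_structure: bool = True,
                 structure_max_genes: int | None = 40) -> PipelineResult:
    """Full analysis over a set of annotated genomes.

    Parameters
    ----------
    genomes
        A synthetic-panel directory (GenBank files + manifest), a list of
        GenBank paths, or a list of ``(paths, rank_gt)`` tuples for
        multi-replicon genomes.
    heg_spec
        Gene-name patterns defining the highly expressed class.
    engine, compute_structure, structure_max_genes
        Folding engine for the MFE stage; the stage can be disabled, and
        ``structure_max_genes`` caps the per-class gene count folded
        (None = all genes).
    """
    if engine is None and compute_structure:
        engine = default_engine()
    class_rows, species_rows = [], []
    for paths, rank, name in _resolve_inputs(genomes):
        genome = parse_genbank(paths, species_name=name, rank_gt=rank)
        classify_expression(genome.cds, heg_spec=heg_spec)
        logger.info("species %s: %d CDS (%d pseudo), %d tRNA, %d rrn",
                    genome.meta.species_name, len(genome.cds),
                    len(genome.cds) - genome.n_cds, genome.trna_count,
                    genome.rrn_count)
        rows, srow = _species_rows(genome, engine, structure_max_genes,
                                   compute_structure)
        class_rows.extend(rows)
        species_rows.append(srow)

    class_summary = pd.DataFrame(class_rows)
    species_summary = pd.DataFrame(species_rows)
    if species_summary["RankGT"].isna().any():
        # rank by species order when no manifest/explicit ranks given
        species_summary["RankGT"] = range(1, len(species_summary) + 1)
        rank_map = dict(zip(species_summary["species"],
                            species_summary["RankGT"]))
        class_summary["RankGT"] = class_summary["species"].map(rank_map)

    result = PipelineResult(class_summary=class_summary,
                            species_summary=species_summary)
    if len(species_summary) >= 3:
        result.regressions["aug"] = aug_regression(class_summary)
        result.regressions["uaa"] = uaa_regression(class_summary)
        if compute_structure:
            mfe_table = class_summary.rename(columns={"GC%": "genomic_GC%",
                                                      "class_GC%": "GC%"})
            result.regressions["mean_mfe"] = mean_mfe_regression(mfe_table)
        result.regressions["dite_rank"] = dite_rank_regression(species_summary)
    if len(species_summary) >= 4:
        result.fits = machinery_fits(species_summary)
    return result
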