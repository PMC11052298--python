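"""Parsing of annotated bacterial genomes from GenBank flat files.

Extracts protein-coding genes (with strand-aware coding sequence and
upstream/downstream context), tRNA genes with their anticodons, and rRNA
genes; computes composition statistics; and classifies genes into the
highly-expressed (HEG) versus remaining (REST) expression groups by
gene-name pattern.

Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
convention is converted at the I/O boundary by Biopython.  Multi-replicon
genomes (e.g. the two Vibrio chromosomes) are pooled into one
:class:`AnnotatedGenome`, with genome length and GC% computed over the
concatenation.
"""

from __future__ import annotations

import fnmatch
import gzip
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .genetic_code import AA3_TO_AA1, revcomp, to_rna

logger = logging.getLogger(__name__)

#: gene-name patterns treated as highly expressed by default: ribosomal
#: proteins, RNA polymerase core subunits, and elongation factors.
DEFAULT_HEG_PATTERNS: tuple[str, ...] = (
    "rps*", "rpl*", "rpm*", "rpoA", "rpoB", "rpoC", "tuf*", "fusA",
)

#: start codons recognised under translation table 11 plus the near-
#: canonical AUH set that start-codon tables report.
VALID_STARTS: tuple[str, ...] = ("ATG", "GTG", "TTG", "CTG", "ATT", "ATC", "ATA")


@dataclass
class SpeciesMeta:
    """Species identity and its generation-time rank within a panel."""

    species_name: str
    rank_gt: int | None = None
    accession_ids: list[str] = field(default_factory=list)


@dataclass
class GeneRecord:
    """One protein-coding gene with strand-aware sequence context.

    ``coding_sequence`` is the sense-strand CDS 5'->3' (first three nt are
    the annotated start codon, last three the stop codon when complete).
    ``upstream_60`` is the region immediately 5' of the start codon on the
    sense strand (shorter only at a replicon edge).
    """

    locus_tag: str
    gene_name: str = ""
    strand: str = "+"
    coding_sequence: str = ""
    upstream_60: str = ""
    downstream_of_stop: str = ""
    expression_class: str | None = None  # "HEG" | "REST" | None (pseudo)
    is_pseudo: bool = False
    gc_percent: float = float("nan")
    length_multiple_of_three: bool = True

    @property
    def start_codon(self) -> str:
        return self.coding_sequence[:3]

    @property
    def stop_codon(self) -> str:
        return self.coding_sequence[-3:]


@dataclass
class TRNAGene:
    """A tRNA gene identified by amino acid and 5'->3' anticodon (RNA)."""

    amino_acid: str  # one-letter code
    anticodon: str   # RNA, 5'->3'
    locus_tag: str = ""
    is_initiator: bool = False


@dataclass
class AnnotatedGenome:
    """A parsed genome: features pooled over replicons plus summary stats."""

    meta: SpeciesMeta
    sequences: list[str] = field(default_factory=list)
    cds: list[GeneRecord] = field(default_factory=list)
    trna: list[TRNAGene] = field(default_factory=list)
    rrna_products: list[str] = field(default_factory=list)

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    @property
    def n_cds(self) -> int:
        """Number of protein-coding genes after pseudogene exclusion."""
        return sum(1 for g in self.cds if not g.is_pseudo)

    @property
    def trna_count(self) -> int:
        return len(self.trna)

    @property
    def rrn_count(self) -> int:
        return count_rrn_operons(self)

    @property
    def gc_percent(self) -> float:
        return composition("".join(self.sequences))

    def genes(self, expression_class: str | None = None,
              include_pseudo: bool = False) -> list[GeneRecord]:
        out = []
        for g in self.cds:
            if g.is_pseudo and not include_pseudo:
                continue
            if expression_class is not None and g.expression_class != expression_class:
                continue
            out.append(g)
        return out


class GenBankParseError(ValueError):
    """Raised when a GenBank record cannot be interpreted."""


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


_ANTICODON_SEQ_RE = re.compile(r"seq\s*:\s*([acgutACGUT]{3})")
_PRODUCT_AA_RE = re.compile(r"tRNA-([A-Za-z]{3})")


def _parse_trna(feature, locus_tag: str) -> TRNAGene | None:
    product = (feature.qualifiers.get("product") or [""])[0]
    is_init = "fMet" in product or "ini" in product.lower()
    aa1 = ""
    m = _PRODUCT_AA_RE.search(product)
    if m and m.group(1) in AA3_TO_AA1:
        aa1 = AA3_TO_AA1[m.group(1)]
    elif "fMet" in product:
        aa1 = "M"
    anticodon = ""
    for qual in feature.qualifiers.get("anticodon", []):
        m = _ANTICODON_SEQ_RE.search(qual)
        if m:
            anticodon = to_rna(m.group(1).upper())
            break
    if not anticodon or not aa1:
        logger.warning("tRNA %s lacks usable anticodon/product annotation; skipped",
                       locus_tag or product)
        return None
    return TRNAGene(amino_acid=aa1, anticodon=anticodon,
                    locus_tag=locus_tag, is_initiator=is_init)


def parse_genbank(paths: Sequence[str | Path] | str | Path,
                  species_name: str | None = None,
                  rank_gt: int | None = None,
                  upstream_length: int = 60,
                  downstream_length: int = 60) -> AnnotatedGenome:
    """Parse one genome (possibly multi-replicon) from GenBank flat files.

    Parameters
    ----------
    paths
        One path or a list of paths; each file may hold several records.
        Gzipped files (``*.gz``) are transparently decompressed.
    species_name, rank_gt
        Override the organism annotation / attach a generation-time rank.
    upstream_length, downstream_length
        Length of the 5' context captured upstream of the start codon and
        downstream of the stop codon (truncated at replicon edges).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    meta = SpeciesMeta(species_name=species_name or "", rank_gt=rank_gt)
    genome = AnnotatedGenome(meta=meta)

    for path in paths:
        path = Path(path)
        try:
            with _open_maybe_gzip(path) as fh:
                records = list(SeqIO.parse(fh, "genbank"))
        except Exception as exc:  # malformed flat file
            raise GenBankParseError(f"cannot parse GenBank file {path}: {exc}") from exc
        if not records:
            raise GenBankParseError(f"no GenBank records found in {path}")
        for record in records:
            _ingest_record(genome, record, upstream_length, downstream_length)
            meta.accession_ids.append(record.id)
            if not meta.species_name:
                meta.species_name = record.annotations.get("organism", record.id)
    return genome


def _ingest_record(genome: AnnotatedGenome, record, up_len: int, down_len: int) -> None:
    seq = str(record.seq).upper()
    genome.sequences.append(seq)
    n = len(seq)
    for feature in record.features:
        if feature.type == "CDS":
            genome.cds.append(_parse_cds(feature, seq, n, up_len, down_len, record.id))
        elif feature.type == "tRNA":
            locus = (feature.qualifiers.get("locus_tag") or [""])[0]
            trna = _parse_trna(feature, locus)
            if trna is not None:
                genome.trna.append(trna)
        elif feature.type == "rRNA":
            product = (feature.qualifiers.get("product") or [""])[0]
            genome.rrna_products.append(product)


def _parse_cds(feature, seq: str, n: int, up_len: int, down_len: int,
               record_id: str) -> GeneRecord:
    quals = feature.qualifiers
    locus = (quals.get("locus_tag") or [""])[0]
    name = (quals.get("gene") or [""])[0]
    pseudo = "pseudo" in quals or "pseudogene" in quals
    # feature.extract resolves joins and minus-strand complements
    cds = str(feature.extract(seq))
    strand = "+" if (feature.location.strand or 1) >= 0 else "-"
    start = int(feature.location.start)
    end = int(feature.location.end)
    if strand == "+":
        upstream = seq[max(0, start - up_len):start]
        downstream = seq[end:end + down_len]
    else:
        upstream = revcomp(seq[end:min(n, end + up_len)])
        downstream = revcomp(seq[max(0, start - down_len):start])
    ok3 = len(cds) % 3 == 0
    if not ok3:
        logger.warning("CDS %s in %s has length %d not divisible by 3",
                       locus or name, record_id, len(cds))
    if cds[:3] not in VALID_STARTS:
        logger.warning("CDS %s in %s starts with non-canonical codon %s",
                       locus or name, record_id, cds[:3])
    gc = composition(cds) if cds.strip("N") else float("nan")
    return GeneRecord(locus_tag=locus, gene_name=name, strand=strand,
                      coding_sequence=cds, upstream_60=upstream,
                      downstream_of_stop=downstream, is_pseudo=pseudo,
                      gc_percent=gc, length_multiple_of_three=ok3)


def count_rrn_operons(genome: AnnotatedGenome) -> int:
    """Number of rRNA operons, proxied by the count of 16S rRNA genes.

    Each operon carries one 16S-23S-5S set, so counting 16S copies avoids
    fragile co-location clustering.  A genome with no annotated rRNA at all
    returns 0 with a warning (every functional genome needs at least one
    operon).
    """
    n16 = sum(1 for p in genome.rrna_products if "16S" in p)
    if n16 == 0:
        warnings.warn(
            f"no 16S rRNA genes annotated in {genome.meta.species_name!r}; "
            "operon count 0 is biologically impossible for a complete genome",
            stacklevel=2,
        )
    return n16


def classify_expression(genes: Iterable[GeneRecord],
                        heg_spec: Sequence[str] | None = None,
                        heg_locus_tags: Iterable[str] = ()) -> list[GeneRecord]:
    """Label every non-pseudo gene HEG or REST (in place; list returned).

    ``heg_spec`` is a list of shell-style gene-name patterns (default:
    ribosomal proteins, RNA polymerase core, elongation factors);
    ``heg_locus_tags`` adds explicit locus tags.  Pseudogenes are labelled
    neither and are excluded from all downstream statistics.
    """
    if heg_spec is None:
        heg_spec = DEFAULT_HEG_PATTERNS
    heg_spec = list(heg_spec)
    tags = set(heg_locus_tags)
    if not heg_spec and not tags:
        raise ValueError("empty HEG specification: DITE is undefined without HEGs")
    genes = list(genes)
    for g in genes:
        if g.is_pseudo:
            g.expression_class = None
            continue
        is_heg = g.locus_tag in tags or any(
            fnmatch.fnmatchcase(g.gene_name, pat) for pat in heg_spec
        )
        g.expression_class = "HEG" if is_heg else "REST"
    return genes


def composition(seq_or_genes) -> float:
    """GC percentage, 100*(G+C)/(A+C+G+T); ambiguity codes excluded."""
    if isinstance(seq_or_genes, AnnotatedGenome):
        seq = "".join(seq_or_genes.sequences)
    elif isinstance(seq_or_genes, str):
        seq = seq_or_genes
    else:  # iterable of GeneRecord
        seq = "".join(g.coding_sequence for g in seq_or_genes)
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous nucleotides")
    return 100.0 * gc / (gc + at)


def write_feature_table(genome: AnnotatedGenome, path: str | Path) -> None:
    """Per-gene TSV: locus_tag, class, start codon, stop codon, GC%."""
    with open(path, "w") as fh:
        fh.write("locus_tag\tclass\tstart_codon\tstop_codon\tgc_percent\n")
        for g in genome.cds:
            cls = "pseudo" if g.is_pseudo else (g.expression_class or "")
            fh.write(f"{g.locus_tag}\t{cls}\t{to_rna(g.start_codon)}\t"
                     f"{to_rna(g.stop_codon)}\t{g.gc_percent:.4f}\n")
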