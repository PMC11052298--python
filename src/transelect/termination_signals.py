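"""Stop-codon usage statistics per expression class.

UAA carries the lowest readthrough error rate of the three stop codons
(UGA > UAG > UAA), so selection for termination efficiency predicts
elevated UAA usage in highly expressed genes and in short-generation
species.  Genes whose annotated coding sequence does not end in a
canonical stop (truncated annotations) are excluded from N with a logged
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .genetic_code import to_rna
from .genome_io import GeneRecord

logger = logging.getLogger(__name__)


@dataclass
class StopCodonTable:
    uaa: int
    uag: int
    uga: int
    n: int                 # genes with a canonical stop
    excluded: int          # genes without one

    @property
    def uaa_percent(self) -> float:
        return 100.0 * self.uaa / self.n

    @property
    def proportions(self) -> dict[str, float]:
        return {"UAA": self.uaa / self.n, "UAG": self.uag / self.n,
                "UGA": self.uga / self.n}


def stop_codon_usage(genes: Iterable[GeneRecord],
                     class_filter: str | None = None) -> StopCodonTable:
    """Tabulate stop codons for a gene set, optionally one expression class."""
    counts = {"UAA": 0, "UAG": 0, "UGA": 0}
    n = excluded = 0
    for g in genes:
        if class_filter is not None and g.expression_class != class_filter:
            continue
        stop = to_rna(g.stop_codon)
        if stop in counts:
            counts[stop] += 1
            n += 1
        else:
            excluded += 1
    if n == 0:
        raise ValueError("no genes with canonical stop codons")
    if excluded:
        logger.warning("%d genes without a canonical stop codon excluded", excluded)
    return StopCodonTable(uaa=counts["UAA"], uag=counts["UAG"],
                          uga=counts["UGA"], n=n, excluded=excluded)
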