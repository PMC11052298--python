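"""Bacterial genetic code (translation table 11) and synonymous-family layout.

All sequence handling in the package is DNA-alphabet internally (A/C/G/T);
RNA spellings are produced only at reporting boundaries.  The synonymous
family structure (2-, 3-, 4- and 6-fold degenerate amino acids plus the
Met/Trp singletons) drives both the codon-adaptation weights and Wright's
effective-number formula.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

BASES = "ACGT"
RNA_BASES = "ACGU"

COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

START_CODONS_T11 = tuple(sorted(_TABLE11.start_codons))
STOP_CODONS = tuple(sorted(_TABLE11.stop_codons))  # TAA, TAG, TGA

#: codon (DNA) -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)

#: one-letter amino acid -> tuple of synonymous codons (DNA)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: degeneracy class (family size) per amino acid
FAMILY_SIZE: dict[str, int] = {aa: len(c) for aa, c in AA_TO_CODONS.items()}

#: amino acids by synonymy class; class 1 = Met, Trp
SYNONYMY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _k in sorted(FAMILY_SIZE.items()):
    SYNONYMY_CLASSES.setdefault(_k, ())
    SYNONYMY_CLASSES[_k] += (_aa,)

AA3_TO_AA1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}


def revcomp(seq: str) -> str:
    """Reverse complement (DNA or RNA input; complement preserves case)."""
    return seq.translate(COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def anticodon_for(codon: str) -> str:
    """Watson-Crick anticodon (RNA, 5'->3') decoding the given codon."""
    return to_rna(revcomp(to_dna(codon)))


def codon_for_anticodon(anticodon: str) -> str:
    """Codon (DNA) decoded by a 5'->3' anticodon under strict WC pairing."""
    return to_dna(revcomp(to_dna(anticodon)))
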