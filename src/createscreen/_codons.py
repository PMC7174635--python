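"""Packaged E. coli K-12 codon usage and codon-choice policies.

Usage values are per-1000-codons frequencies of the standard E. coli K-12
usage table. They drive two deterministic choices made by the cassette
designer: the codon installed for an amino-acid substitution (the most
frequent codon of the target amino acid) and the synonymous alternative used
for control cassettes and PAM/seed disruptions (the most frequent synonymous
codon that differs from the wild-type codon at the required position).
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

# fmt: off
CODON_USAGE_PER_1000: dict[str, float] = {
    "TTT": 22.2, "TTC": 16.6, "TTA": 13.9, "TTG": 13.7,
    "CTT": 11.0, "CTC": 11.0, "CTA": 3.9,  "CTG": 52.6,
    "ATT": 30.3, "ATC": 25.1, "ATA": 4.4,  "ATG": 27.9,
    "GTT": 18.3, "GTC": 15.3, "GTA": 10.9, "GTG": 26.4,
    "TCT": 8.5,  "TCC": 8.6,  "TCA": 7.2,  "TCG": 8.9,
    "CCT": 7.0,  "CCC": 5.5,  "CCA": 8.4,  "CCG": 23.2,
    "ACT": 9.0,  "ACC": 23.4, "ACA": 7.1,  "ACG": 14.4,
    "GCT": 15.3, "GCC": 25.5, "GCA": 20.1, "GCG": 33.6,
    "TAT": 16.2, "TAC": 12.2, "TAA": 2.0,  "TAG": 0.2,
    "CAT": 12.9, "CAC": 9.7,  "CAA": 15.3, "CAG": 28.8,
    "AAT": 17.7, "AAC": 21.7, "AAA": 33.6, "AAG": 10.3,
    "GAT": 32.1, "GAC": 19.1, "GAA": 39.4, "GAG": 17.8,
    "TGT": 5.2,  "TGC": 6.4,  "TGA": 1.0,  "TGG": 15.2,
    "CGT": 20.9, "CGC": 22.0, "CGA": 3.6,  "CGG": 5.4,
    "AGT": 8.8,  "AGC": 16.1, "AGA": 2.1,  "AGG": 1.2,
    "GGT": 24.7, "GGC": 29.6, "GGA": 8.0,  "GGG": 11.1,
}
# fmt: on

_STANDARD = CodonTable.unambiguous_dna_by_id[11]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: amino acid -> codons, most used first (deterministic tie-break by codon string)
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in _STANDARD.forward_table.items():
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in CODONS_BY_AA:
    CODONS_BY_AA[_aa].sort(key=lambda c: (-CODON_USAGE_PER_1000[c], c))

#: amino acid -> single most frequent codon
PREFERRED_CODON: dict[str, str] = {aa: codons[0] for aa, codons in CODONS_BY_AA.items()}


def translate(cds: str) -> str:
    """Translate a CDS (table 11); a trailing stop is stripped."""
    protein = str(Seq(cds).translate(table=11))
    return protein[:-1] if protein.endswith("*") else protein


def codon_to_aa(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


def synonymous_alternatives(codon: str) -> list[str]:
    """Synonymous codons differing from `codon`, most used first."""
    aa = codon_to_aa(codon)
    if aa == "*":
        return []
    return [c for c in CODONS_BY_AA[aa] if c != codon.upper()]


def has_synonymous_alternative(aa: str) -> bool:
    return len(CODONS_BY_AA.get(aa, [])) > 1
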