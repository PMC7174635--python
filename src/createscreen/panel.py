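"""The global-regulator panel: sublibrary definitions G1-G5.

The screen partitions targeted residues of 23 E. coli global regulators into
five sublibraries by functional category: G1 active sites, G2/G3 DNA-binding
sites (two gene groups), G4 dimerization interfaces, and G5 predicted
(structure-derived) functional residues. The packaged default panel records,
for each sublibrary, its category, its gene list and the number of designed
variants it contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .targets import CATEGORIES


@dataclass(frozen=True)
class Sublibrary:
    name: str
    category: str
    genes: tuple[str, ...]
    designed_variants: int | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in sublibrary {self.name}")


@dataclass(frozen=True)
class PanelConfig:
    """Regulator panel: ordered sublibraries and the derived gene union."""

    sublibraries: tuple[Sublibrary, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.sublibraries:
            raise ValueError("panel must define at least one sublibrary")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for sub in self.sublibraries for g in sub.genes)

    def sublibraries_for(self, gene: str, category: str) -> list[Sublibrary]:
        return [
            s
            for s in self.sublibraries
            if s.category == category and gene in s.genes
        ]

    def total_designed_variants(self) -> int:
        if any(s.designed_variants is None for s in self.sublibraries):
            raise ValueError("panel lacks designed-variant counts")
        return sum(s.designed_variants for s in self.sublibraries)

    @classmethod
    def from_yaml(cls, path) -> "PanelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        subs = tuple(
            Sublibrary(
                name=entry["name"],
                category=entry["category"],
                genes=tuple(entry["genes"]),
                designed_variants=entry.get("designed_variants"),
            )
            for entry in data["sublibraries"]
        )
        return cls(sublibraries=subs)


#: the screen's regulator panel: 23 genes across five sublibraries
DEFAULT_PANEL = PanelConfig(
    sublibraries=(
        Sublibrary(
            "G1",
            "active_site",
            (
                "hns", "cspA", "arcA", "fur", "narL", "lrp", "mlc", "ihfB",
                "cspE", "crp", "phoB", "dnaA", "rpoS", "rpoE", "fnr", "soxR",
                "ihfA", "fis",
            ),
            7000,
        ),
        Sublibrary(
            "G2",
            "dna_binding",
            ("cspA", "arcA", "narL", "lrp", "mlc", "ihfB", "cspE", "argP", "crp"),
            7340,
        ),
        Sublibrary(
            "G3",
            "dna_binding",
            (
                "phoB", "cytR", "dnaA", "soxS", "rpoS", "rpoN", "rpoE", "fnr",
                "soxR", "ihfA", "fis",
            ),
            7400,
        ),
        Sublibrary(
            "G4",
            "dimerization",
            (
                "arcA", "fur", "narL", "mlc", "ihfB", "crp", "phoB", "cytR",
                "rpoE", "soxR", "ihfA", "fis",
            ),
            5260,
        ),
        Sublibrary(
            "G5",
            "predicted",
            (
                "hns", "cspA", "arcA", "fur", "narL", "lrp", "mlc", "cspE",
                "argP", "crp", "phoB", "cytR", "dnaA", "soxS", "rpoS", "fnr",
                "soxR", "ihfA", "fis", "rpoH",
            ),
            7340,
        ),
    )
)
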