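"""Selection of functional residues to mutagenize.

Functional residues of the regulator panel come from two sources: curated
annotation records (feature tables merged from protein databases) and
ligand-proximal residues computed from experimental structures — every
polymer residue with an atom within a fixed radius (default 5 Angstrom,
inclusive) of any ligand atom. Residues are then partitioned into the
panel's sublibraries by functional category.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

CATEGORIES = frozenset({"active_site", "dna_binding", "dimerization", "predicted"})

DEFAULT_LIGAND_RADIUS = 5.0  # Angstrom, inclusive boundary

#: hetero residue names never treated as ligands (water, buffer/cryo agents, common ions)
DEFAULT_SOLVENT_EXCLUDE = frozenset(
    {"HOH", "DOD", "WAT", "NA", "CL", "K", "MG", "CA", "ZN", "SO4", "PO4",
     "GOL", "EDO", "ACT", "PEG", "DMS", "MPD", "TRS", "NO3", "FMT"}
)

_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: site-type text -> closed category set; lookups are case/punctuation-insensitive
SITE_TYPE_SYNONYMS: dict[str, str] = {
    "active site": "active_site",
    "active sites": "active_site",
    "active_site": "active_site",
    "catalytic site": "active_site",
    "catalytic residue": "active_site",
    "binding site": "active_site",
    "ligand binding": "active_site",
    "ligand binding site": "active_site",
    "dna binding": "dna_binding",
    "dna binding site": "dna_binding",
    "dna binding sites": "dna_binding",
    "dna_binding": "dna_binding",
    "dna contact": "dna_binding",
    "helix turn helix": "dna_binding",
    "dimerization": "dimerization",
    "dimerisation": "dimerization",
    "dimer interface": "dimerization",
    "oligomerization": "dimerization",
    "predicted": "predicted",
    "predicted site": "predicted",
    "structure predicted": "predicted",
}


class FeatureTableError(ValueError):
    """Record-level failures while parsing a feature table."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """One panel protein: identifier plus amino-acid sequence."""

    gene_name: str
    aa_sequence: str

    def __post_init__(self):
        seq = self.aa_sequence.upper()
        # an initial formyl-Met is recorded as plain M upstream
        bad = set(seq) - _AA20
        if bad:
            raise ValueError(f"{self.gene_name}: non-standard residues {sorted(bad)}")
        object.__setattr__(self, "aa_sequence", seq)

    @property
    def length(self) -> int:
        return len(self.aa_sequence)


@dataclass(frozen=True, order=True)
class FunctionalAnnotation:
    gene_name: str
    position: int  # 1-based residue index
    category: str
    source: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass(frozen=True)
class StructureAtom:
    residue_index: int
    residue_name: str
    atom_name: str
    x: float
    y: float
    z: float
    is_ligand: bool = False

    def __post_init__(self):
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("atom coordinates must be finite")
        if not self.is_ligand and self.residue_index < 1:
            raise ValueError("polymer residue_index must be positive")


def normalize_site_type(text: str) -> tuple[str, bool]:
    """Map free site-type text onto the closed category set.

    Returns (category, matched). Unmatched strings fall into ``predicted``,
    the catch-all category, and ``matched`` is False.
    """
    key = " ".join(
        text.lower().replace("-", " ").replace("/", " ").replace("_", " ").split()
    )
    if key in SITE_TYPE_SYNONYMS:
        return SITE_TYPE_SYNONYMS[key], True
    # parenthetical qualifiers such as "metal binding (predicted)"
    if "(" in key:
        inner = key[key.index("(") + 1 : key.rindex(")")] if ")" in key else ""
        for part in (inner, key[: key.index("(")].strip()):
            if part in SITE_TYPE_SYNONYMS:
                return SITE_TYPE_SYNONYMS[part], True
    if "predicted" in key:
        return "predicted", True
    return "predicted", False


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table TSV with columns gene, position, site_type, source."""
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def parse_feature_table(
    table: pd.DataFrame,
    proteins: dict[str, ProteinRecord],
) -> list[FunctionalAnnotation]:
    """Normalize raw annotation rows into deduplicated FunctionalAnnotations.

    Rows with unknown genes, non-integer positions or out-of-range positions
    are record-level errors, reported together with their row index.
    """
    problems: list[str] = []
    out: set[FunctionalAnnotation] = set()
    for idx, row in table.iterrows():
        gene = str(row["gene"]).strip()
        if gene not in proteins:
            problems.append(f"row {idx}: unknown gene {gene!r}")
            continue
        try:
            position = int(str(row["position"]).strip())
        except (TypeError, ValueError):
            problems.append(f"row {idx}: non-integer position {row['position']!r}")
            continue
        if not 1 <= position <= proteins[gene].length:
            problems.append(
                f"row {idx}: position {position} outside {gene} "
                f"(length {proteins[gene].length})"
            )
            continue
        category, matched = normalize_site_type(str(row["site_type"]))
        if not matched:
            warnings.warn(
                f"row {idx}: site type {row['site_type']!r} not recognized; "
                f"assigned to the catch-all 'predicted' category"
            )
        out.add(
            FunctionalAnnotation(
                gene_name=gene,
                position=position,
                category=category,
                source=str(row.get("source", "")),
            )
        )
    if problems:
        raise FeatureTableError(problems)
    # dedup ignores source text: same (gene, position, category) collapses
    seen: dict[tuple, FunctionalAnnotation] = {}
    for ann in sorted(out):
        seen.setdefault((ann.gene_name, ann.position, ann.category), ann)
    return sorted(seen.values())


def read_structure_atoms(
    path, solvent_exclude: frozenset[str] = DEFAULT_SOLVENT_EXCLUDE
) -> list[StructureAtom]:
    """Parse a PDB-format coordinate file into StructureAtoms.

    Hetero records whose residue name is not in the solvent exclusion list
    are flagged as ligand atoms (covers cofactors such as a [2Fe-2S]
    cluster); water and common buffer components are dropped entirely.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", path)
    atoms: list[StructureAtom] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                hetflag, resseq, _ = residue.id
                is_het = hetflag.strip() != ""
                resname = residue.get_resname().strip()
                if is_het and resname in solvent_exclude:
                    continue
                for atom in residue:
                    x, y, z = atom.coord
                    atoms.append(
                        StructureAtom(
                            residue_index=int(resseq),
                            residue_name=resname,
                            atom_name=atom.get_name(),
                            x=float(x),
                            y=float(y),
                            z=float(z),
                            is_ligand=is_het,
                        )
                    )
        break  # first model only
    return atoms


def ligand_proximal_residues(
    atoms: list[StructureAtom], radius: float = DEFAULT_LIGAND_RADIUS
) -> set[int]:
    """Residues with any atom within `radius` (inclusive) of any ligand atom."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not atoms:
        raise StructureError("empty structure")
    ligand = [a for a in atoms if a.is_ligand]
    polymer = [a for a in atoms if not a.is_ligand]
    if not ligand:
        raise StructureError("structure contains no ligand atoms")
    if not polymer:
        return set()
    lig_xyz = np.array([[a.x, a.y, a.z] for a in ligand])
    pol_xyz = np.array([[a.x, a.y, a.z] for a in polymer])
    tree = cKDTree(lig_xyz)
    dists, _ = tree.query(pol_xyz, k=1)
    hits = dists <= radius
    return {polymer[i].residue_index for i in np.nonzero(hits)[0]}


def annotate_structure_hits(
    gene_name: str, residues: set[int], category: str, source: str = "structure"
) -> list[FunctionalAnnotation]:
    """Tag structure-derived residues with a category per panel configuration."""
    return [
        FunctionalAnnotation(gene_name, pos, category, source)
        for pos in sorted(residues)
    ]


@dataclass
class TargetSet:
    """Per-gene functional residues and their sublibrary partition."""

    per_gene: dict[str, set[tuple[int, str]]] = field(default_factory=dict)
    sublibraries: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    unassigned: list[tuple[str, int, str]] = field(default_factory=list)

    def residue_count(self, gene: str | None = None) -> int:
        if gene is not None:
            return len({p for p, _ in self.per_gene.get(gene, set())})
        return sum(
            len({p for p, _ in pairs}) for pairs in self.per_gene.values()
        )

    def summary(self) -> dict:
        return {
            "sublibraries": {
                name: {
                    "n_residues": len(entries),
                    "n_genes": len({g for g, _, _ in entries}),
                }
                for name, entries in self.sublibraries.items()
            },
            "n_genes": len(self.per_gene),
            "n_unassigned": len(self.unassigned),
        }

    def to_frame(self, proteins: dict[str, ProteinRecord] | None = None) -> pd.DataFrame:
        rows = []
        for name in sorted(self.sublibraries):
            for gene, pos, category in self.sublibraries[name]:
                wt = (
                    proteins[gene].aa_sequence[pos - 1]
                    if proteins and gene in proteins
                    else ""
                )
                rows.append(
                    {
                        "gene": gene,
                        "position": pos,
                        "wt_aa": wt,
                        "category": category,
                        "sublibrary": name,
                    }
                )
        return pd.DataFrame(
            rows, columns=["gene", "position", "wt_aa", "category", "sublibrary"]
        )

    def write(self, tsv_path, json_path=None, proteins=None) -> None:
        self.to_frame(proteins).to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


def build_target_sets(annotations, panel) -> TargetSet:
    """Partition annotated residues into the panel's sublibraries.

    Each (gene, position, category) is placed in every sublibrary whose
    category matches and whose gene list contains the gene; a gene can
    therefore appear in several sublibraries. Annotations whose gene/category
    pair belongs to no sublibrary are reported as unassigned.
    """
    annotations = sorted(set(annotations))
    if not panel.sublibraries:
        raise ValueError("empty panel")
    panel_genes = panel.genes
    target = TargetSet(
        sublibraries={s.name: [] for s in panel.sublibraries},
    )
    for ann in annotations:
        if ann.gene_name not in panel_genes:
            raise ValueError(f"gene {ann.gene_name!r} not in panel")
        target.per_gene.setdefault(ann.gene_name, set()).add(
            (ann.position, ann.category)
        )
        subs = panel.sublibraries_for(ann.gene_name, ann.category)
        if not subs:
            target.unassigned.append((ann.gene_name, ann.position, ann.category))
            continue
        for sub in subs:
            target.sublibraries[sub.name].append(
                (ann.gene_name, ann.position, ann.category)
            )
    for gene in sorted(panel_genes):
        if gene not in target.per_gene:
            warnings.warn(f"gene {gene} has zero targeted residues")
            target.per_gene[gene] = set()
    for name in target.sublibraries:
        target.sublibraries[name] = sorted(set(target.sublibraries[name]))
    target.unassigned = sorted(set(target.unassigned))
    return target
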