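from __future__ import annotations

import numpy as np
import pytest

from createscreen import GeneModel, StructureAtom, random_gene_model


def pdb_atom_line(record, serial, name, resname, chain, resseq, x, y, z, element):
    return (
        f"{record:<6}{serial:>5} {name:^4} {resname:>3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}"
    )


@pytest.fixture
def toy_gene() -> GeneModel:
    """Small deterministic gene with generous flanks for full-arm designs."""
    rng = np.random.default_rng(7)
    return random_gene_model(rng, "toyA", n_internal_codons=40, flank=160)


@pytest.fixture
def gene_models() -> dict[str, GeneModel]:
    rng = np.random.default_rng(11)
    models = {}
    for i in range(3):
        m = random_gene_model(rng, f"g{i}", n_internal_codons=30, flank=160)
        models[m.gene_name] = m
    return models


def random_structure(rng: np.random.Generator, n_residues=10, atoms_per_residue=3, n_ligand=3):
    atoms = []
    for res in range(1, n_residues + 1):
        center = rng.uniform(-8, 8, size=3)
        for k in range(atoms_per_residue):
            x, y, z = center + rng.normal(0, 1.0, size=3)
            atoms.append(
                StructureAtom(res, "ALA", f"C{k}", float(x), float(y), float(z))
            )
    for k in range(n_ligand):
        x, y, z = rng.uniform(-4, 4, size=3)
        atoms.append(
            StructureAtom(0 - k, "FES", f"FE{k}", float(x), float(y), float(z), is_ligand=True)
        )
    return atoms
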