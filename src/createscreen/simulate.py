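"""Synthetic screens: selection dynamics and amplicon sequencing.

The generative model is multiplicative selection in log2 units: a cassette
with fitness f changes its relative frequency by an expected factor 2**(f*t)
over t selection epochs relative to a neutral (f = 0) cassette,

    p_i' = p_i * 2**(f_i * t) / sum_j p_j * 2**(f_j * t),

and observed counts are multinomial draws at the sequencing depth from p
(pre-selection) and p' (post-selection). Sequencing of the ~450-bp cassette
amplicon (cassette plus constant vector flanks) is emulated as paired-end
reads carrying a per-sample barcode on R1, with i.i.d. substitution errors
and constant placeholder qualities. A truth table ties every read back to
its cassette and planted fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import _seqarray as sa
from .design import (
    DEFAULT_LAYOUT,
    GeneModel,
    OligoPool,
    design_pool,
)

_FLANK_RNG = np.random.default_rng(20200421)
#: constant vector flanks taking the 230-nt cassette to a ~450-nt amplicon
VECTOR_FLANK_5 = "".join(_FLANK_RNG.choice(list("ACGT"), size=110))
VECTOR_FLANK_3 = "".join(_FLANK_RNG.choice(list("ACGT"), size=110))
AMPLICON_LENGTH = 450


def amplicon_sequence(cassette_sequence: str) -> str:
    """The sequenced region: 5' vector flank + cassette + 3' vector flank."""
    return VECTOR_FLANK_5 + cassette_sequence + VECTOR_FLANK_3


@dataclass
class LibraryState:
    """Relative cassette abundances in the pooled library."""

    ids: list[str]
    abundances: np.ndarray

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.ids) != len(self.abundances):
            raise ValueError("ids and abundances differ in length")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        total = self.abundances.sum()
        if total <= 0:
            raise ValueError("all-zero abundances")
        if abs(total - 1.0) > 1e-9:
            self.abundances = self.abundances / total

    @classmethod
    def uniform(cls, ids) -> "LibraryState":
        ids = list(ids)
        return cls(ids, np.full(len(ids), 1.0 / len(ids)))

    @classmethod
    def skewed(cls, ids, rng: np.random.Generator, sigma: float = 0.6) -> "LibraryState":
        """Log-normally skewed abundances, emulating uneven synthesis/cloning."""
        ids = list(ids)
        w = rng.lognormal(mean=0.0, sigma=sigma, size=len(ids))
        return cls(ids, w / w.sum())


@dataclass
class SelectionParams:
    fitness: dict[str, float]
    epochs: float = 1.0
    depth: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not all(np.isfinite(list(self.fitness.values()) or [0.0])):
            raise ValueError("fitness values must be finite")


@dataclass
class SelectionResult:
    ids: list[str]
    counts_pre: np.ndarray
    counts_post: np.ndarray
    p_pre: np.ndarray
    p_post: np.ndarray
    fitness: np.ndarray

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cassette_id": self.ids,
                "f": self.fitness,
                "p_pre": self.p_pre,
                "p_post": self.p_post,
                "count_pre": self.counts_pre,
                "count_post": self.counts_post,
            }
        )


def expected_post_frequencies(
    p: np.ndarray, fitness: np.ndarray, epochs: float
) -> np.ndarray:
    w = p * np.exp2(fitness * epochs)
    return w / w.sum()


def simulate_selection(state: LibraryState, params: SelectionParams) -> SelectionResult:
    """Draw pre-/post-selection count vectors under the multiplicative model.

    Cassettes absent from the fitness map are neutral (f = 0).
    """
    f = np.array([params.fitness.get(i, 0.0) for i in state.ids])
    p_pre = state.abundances
    p_post = expected_post_frequencies(p_pre, f, params.epochs)
    rng = np.random.default_rng(params.seed)
    counts_pre = rng.multinomial(params.depth, p_pre)
    counts_post = rng.multinomial(params.depth, p_post)
    return SelectionResult(
        ids=list(state.ids),
        counts_pre=counts_pre,
        counts_post=counts_post,
        p_pre=p_pre,
        p_post=p_post,
        fitness=f,
    )


@dataclass
class ReadSimParams:
    read_length: int = 250
    error_rate: float = 0.003
    barcodes: dict[str, str] = field(default_factory=dict)
    depth: int | None = None  # resample to this many pairs; None = one pair per count
    seed: int = 0
    amplicon_length: int = AMPLICON_LENGTH

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must be in [0, 1)")
        if 2 * self.read_length < self.amplicon_length:
            raise ValueError("reads too short to overlap across the amplicon")
        for sample, bc in self.barcodes.items():
            if self.read_length <= len(bc):
                raise ValueError(f"reads shorter than barcode for sample {sample}")


@dataclass
class ReadSet:
    """Paired reads for one sample, as ASCII arrays plus read ids."""

    sample: str
    ids: list[str]
    r1: np.ndarray
    r2: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def r1_strings(self) -> list[str]:
        return sa.decode_batch(self.r1)

    def r2_strings(self) -> list[str]:
        return sa.decode_batch(self.r2)

    def write_fastq(self, r1_path, r2_path) -> None:
        sa.write_fastq(r1_path, self.ids, self.r1_strings())
        sa.write_fastq(r2_path, self.ids, self.r2_strings())


def _inject_errors(reads: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitution errors in place; always to a different base."""
    if rate == 0 or reads.size == 0:
        return reads
    mask = rng.random(reads.shape) < rate
    n = int(mask.sum())
    if n == 0:
        return reads
    # map ACGT -> 0..3, shift by 1..3 mod 4, map back
    code = np.zeros(256, dtype=np.uint8)
    for k, b in enumerate(b"ACGT"):
        code[b] = k
    orig = code[reads[mask]]
    shifted = (orig + rng.integers(1, 4, size=n)) % 4
    reads[mask] = sa.DNA_BYTES[shifted]
    return reads


def simulate_amplicon_reads(
    amplicons: dict[str, str],
    counts: dict[str, int],
    sample: str,
    params: ReadSimParams,
) -> ReadSet:
    """Emit one barcoded read pair per sequenced molecule of a sample.

    R1 = sample barcode + 5' amplicon prefix; R2 = reverse complement of the
    amplicon suffix; substitution errors at the configured rate over all read
    bases (barcode included).
    """
    if sample not in params.barcodes:
        raise ValueError(f"no barcode assigned to sample {sample!r}")
    barcode = params.barcodes[sample]
    ids_order = sorted(counts)
    missing = [i for i in ids_order if i not in amplicons]
    if missing:
        raise ValueError(f"counted cassettes without sequence: {missing[:5]}")
    lengths = {len(amplicons[i]) for i in ids_order}
    if lengths and lengths != {params.amplicon_length}:
        raise ValueError(
            f"amplicon lengths {sorted(lengths)} != configured {params.amplicon_length}"
        )
    rng = np.random.default_rng(params.seed)
    count_vec = np.array([counts[i] for i in ids_order], dtype=int)
    if params.depth is not None:
        total = count_vec.sum()
        if total == 0:
            raise ValueError("cannot resample from all-zero counts")
        count_vec = rng.multinomial(params.depth, count_vec / total)
    amp = sa.encode_batch([amplicons[i] for i in ids_order]) if ids_order else np.empty((0, 0), np.uint8)
    idx = np.repeat(np.arange(len(ids_order)), count_vec)
    prefix = params.read_length - len(barcode)
    bc = sa.encode(barcode)
    r1 = np.empty((len(idx), params.read_length), dtype=np.uint8)
    r1[:, : len(bc)] = bc
    r1[:, len(bc) :] = amp[idx, :prefix]
    r2 = sa.revcomp_array(amp[idx])[:, : params.read_length]
    _inject_errors(r1, params.error_rate, rng)
    _inject_errors(r2, params.error_rate, rng)
    ids = []
    for i, c in zip(ids_order, count_vec):
        ids.extend(f"{sample}:{i}:{k}" for k in range(int(c)))
    return ReadSet(sample=sample, ids=ids, r1=r1, r2=r2)


def write_config_echo(path, selection: SelectionParams, reads: ReadSimParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "selection": {
                    "epochs": selection.epochs,
                    "depth": selection.depth,
                    "seed": selection.seed,
                    "n_nonzero_fitness": sum(
                        1 for v in selection.fitness.values() if v != 0
                    ),
                },
                "reads": {
                    "read_length": reads.read_length,
                    "error_rate": reads.error_rate,
                    "barcodes": reads.barcodes,
                    "depth": reads.depth,
                    "seed": reads.seed,
                    "amplicon_length": reads.amplicon_length,
                },
            },
            fh,
        )


# ---------------------------------------------------------------------------
# whole-screen generator

_STOPS = {"TAA", "TAG", "TGA"}


def random_gene_model(
    rng: np.random.Generator, name: str, n_internal_codons: int = 40, flank: int = 150
) -> GeneModel:
    """A random gene: ATG + stop-free random codons + TAA, with flanks."""
    codons = ["ATG"]
    while len(codons) < n_internal_codons + 1:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    cds = "".join(codons)
    left = "".join(rng.choice(list("ACGT"), size=flank))
    right = "".join(rng.choice(list("ACGT"), size=flank))
    return GeneModel(
        gene_name=name,
        genomic_sequence=left + cds + right,
        cds_start=flank,
        cds_end=flank + len(cds),
        strand="+",
    )


@dataclass
class ScreenData:
    """Everything a downstream analysis needs, plus the ground truth."""

    pool: OligoPool
    gene_models: dict[str, GeneModel]
    amplicons: dict[str, str]
    selection: SelectionResult
    reads: dict[str, ReadSet]  # keyed "pre"/"post"
    barcodes: dict[str, str]
    planted: dict[str, float]
    epochs: float


DEFAULT_BARCODES = {"pre": "ACGTAC", "post": "TGCAGT"}

_SUB_ALPHABET = "ADEFGHIKLNPQRSTVWY"  # order from which per-residue alphabets are drawn


def simulate_screen(
    seed: int,
    n_residues: int = 50,
    subs_per_residue: int = 9,
    n_planted: int = 10,
    effect_range: tuple[float, float] = (2.0, 5.0),
    epochs: float = 1.0,
    depth: int = 100_000,
    error_rate: float = 0.003,
    skew_sigma: float = 0.6,
    n_genes: int = 2,
    barcodes: dict[str, str] = None,
) -> ScreenData:
    """Generate a full synthetic screen with known per-cassette fitness.

    Designs (subs_per_residue + 1 control) cassettes for each of n_residues
    residues across random genes, skews the pool, plants log2-per-epoch
    effects in n_planted substitution cassettes, runs one pre/post selection
    at the given depth, and sequences both timepoints as barcoded paired
    reads. Defaults give 500 cassettes with 50 synonymous controls.
    """
    rng = np.random.default_rng(seed)
    barcodes = dict(barcodes or DEFAULT_BARCODES)
    per_gene = -(-n_residues // n_genes)  # ceil
    gene_models: dict[str, GeneModel] = {}
    chosen: list[tuple[str, int]] = []
    alphabet_of: dict[tuple[str, int], str] = {}
    cassettes = []
    gi = 0
    while len(chosen) < n_residues:
        name = f"gene{gi:02d}"
        gi += 1
        model = random_gene_model(rng, name, n_internal_codons=max(40, per_gene + 12))
        protein = model.protein()
        # skip Met/Trp so every residue supports a synonymous control
        eligible = [
            i + 1
            for i, aa in enumerate(protein)
            if i > 0 and aa not in "MW"
        ]
        rng.shuffle(eligible)
        picked = []
        for pos in eligible:
            if len(chosen) + len(picked) >= n_residues:
                break
            wt = protein[pos - 1]
            alpha = "".join(a for a in _SUB_ALPHABET if a != wt)[:subs_per_residue]
            trial = design_pool(
                {name: model},
                [(name, pos)],
                mutation_alphabet=alpha,
                include_controls=True,
            )
            if len(trial) == subs_per_residue + 1:
                picked.append(pos)
                alphabet_of[(name, pos)] = alpha
                cassettes.extend(trial.cassettes)
        if picked:
            gene_models[name] = model
            chosen.extend((name, pos) for pos in picked)
    pool = OligoPool(cassettes=cassettes, layout=DEFAULT_LAYOUT)

    amplicons = {c.cassette_id: amplicon_sequence(c.full_sequence) for c in pool.cassettes}
    state = LibraryState.skewed(list(amplicons), rng, sigma=skew_sigma)

    non_controls = [c.cassette_id for c in pool.cassettes if not c.variant.is_control]
    planted_ids = list(rng.choice(non_controls, size=n_planted, replace=False))
    lo, hi = effect_range
    planted = {cid: float(rng.uniform(lo, hi)) for cid in planted_ids}

    sel_params = SelectionParams(
        fitness=planted, epochs=epochs, depth=depth, seed=int(rng.integers(2**31))
    )
    selection = simulate_selection(state, sel_params)

    read_params_pre = ReadSimParams(
        error_rate=error_rate, barcodes=barcodes, seed=int(rng.integers(2**31))
    )
    read_params_post = ReadSimParams(
        error_rate=error_rate, barcodes=barcodes, seed=int(rng.integers(2**31))
    )
    reads = {
        "pre": simulate_amplicon_reads(
            amplicons,
            dict(zip(selection.ids, selection.counts_pre.tolist())),
            "pre",
            read_params_pre,
        ),
        "post": simulate_amplicon_reads(
            amplicons,
            dict(zip(selection.ids, selection.counts_post.tolist())),
            "post",
            read_params_post,
        ),
    }
    return ScreenData(
        pool=pool,
        gene_models=gene_models,
        amplicons=amplicons,
        selection=selection,
        reads=reads,
        barcodes=barcodes,
        planted=planted,
        epochs=epochs,
    )
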