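"""Design of 230-nt trackable editing cassettes.

Each targeted variant gets one cassette carrying (i) a 20-nt spacer whose
genomic protospacer sits next to an NGG PAM close to the target codon, and
(ii) a homology repair arm that installs the mutant codon together with a
synonymous change that destroys the PAM (or, when that is impossible or
would leave an exact duplicate of the spacer inside the arm, a synonymous
change in the seed region next to the cut site). The cassette is also the
sequencing barcode of its variant, so the designer additionally keeps the
literal spacer unique within the assembled oligo wherever the disruption
rules permit. Synonymous control cassettes — DNA changed, protein unchanged —
are designed per residue and later define the null fitness distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codons import (
    PREFERRED_CODON,
    codon_to_aa,
    has_synonymous_alternative,
    synonymous_alternatives,
    translate,
)
from ._seqarray import revcomp

CASSETTE_LENGTH = 230
SPACER_LENGTH = 20
DEFAULT_SEARCH_WINDOW = 30  # nt around the target codon scanned for PAMs
SEED_LENGTH = 10  # PAM-proximal protospacer bases eligible for seed disruption


class DesignError(ValueError):
    pass


class SpacerNotFound(DesignError):
    pass


class ControlUnavailable(DesignError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """A gene plus genomic flanks; CDS as 0-based half-open coordinates."""

    gene_name: str
    genomic_sequence: str
    cds_start: int
    cds_end: int
    strand: str = "+"

    def __post_init__(self):
        object.__setattr__(self, "genomic_sequence", self.genomic_sequence.upper())
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(f"{self.gene_name}: CDS length not divisible by 3")
        if not 0 <= self.cds_start < self.cds_end <= len(self.genomic_sequence):
            raise ValueError(f"{self.gene_name}: CDS outside genomic sequence")

    def cds(self, genomic: str | None = None) -> str:
        seq = (genomic or self.genomic_sequence)[self.cds_start : self.cds_end]
        return revcomp(seq) if self.strand == "-" else seq

    def protein(self, genomic: str | None = None) -> str:
        return translate(self.cds(genomic))

    @property
    def n_residues(self) -> int:
        return len(self.protein())

    def codon_span(self, residue: int) -> tuple[int, int]:
        """Genomic (+ strand) half-open span of a 1-based residue's codon."""
        if not 1 <= residue <= (self.cds_end - self.cds_start) // 3:
            raise ValueError(f"residue {residue} outside CDS")
        if self.strand == "+":
            start = self.cds_start + 3 * (residue - 1)
        else:
            start = self.cds_end - 3 * residue
        return start, start + 3

    def codon(self, residue: int, genomic: str | None = None) -> str:
        """Gene-strand codon of a residue."""
        s, e = self.codon_span(residue)
        cod = (genomic or self.genomic_sequence)[s:e]
        return revcomp(cod) if self.strand == "-" else cod

    def residue_of_genomic_pos(self, pos: int) -> int | None:
        """1-based residue whose codon covers genomic position `pos`, if any."""
        if not self.cds_start <= pos < self.cds_end:
            return None
        if self.strand == "+":
            return (pos - self.cds_start) // 3 + 1
        return (self.cds_end - 1 - pos) // 3 + 1


@dataclass(frozen=True, order=True)
class VariantSpec:
    gene_name: str
    residue_position: int
    wt_aa: str
    mut_aa: str
    is_control: bool = False

    def __post_init__(self):
        if self.is_control and self.mut_aa != self.wt_aa:
            raise ValueError("control variants keep the wild-type amino acid")

    @property
    def label(self) -> str:
        if self.is_control:
            return f"{self.wt_aa}{self.residue_position}{self.wt_aa}.syn"
        return f"{self.wt_aa}{self.residue_position}{self.mut_aa}"


@dataclass(frozen=True)
class SpacerChoice:
    spacer: str
    pam: str
    pam_strand: str
    pam_pos: int  # + strand coordinate of the PAM triplet's leftmost base
    cut_site: int  # + strand boundary index of the blunt cut

    def protospacer_intact(self, genomic: str) -> bool:
        """Does the genome still carry a perfect protospacer + NGG here?"""
        p = self.pam_pos
        if self.pam_strand == "+":
            return (
                genomic[p - SPACER_LENGTH : p] == self.spacer
                and genomic[p + 1 : p + 3] == "GG"
            )
        return (
            revcomp(genomic[p + 3 : p + 3 + SPACER_LENGTH]) == self.spacer
            and genomic[p : p + 2] == "CC"
        )


@dataclass(frozen=True)
class CassetteLayout:
    """Fixed priming/junction segments flanking arm and spacer; total 230 nt."""

    p5: str = "GCCTTAACGGTCAGT"  # 15 nt
    junction: str = "CGGTACCTGAGCTAAGCTAG"  # 20 nt
    p3: str = "ACTGGCTTTAGACGTCCAGGTTCGAAGGCATCA"  # 33 nt

    @property
    def arm_length(self) -> int:
        n = CASSETTE_LENGTH - len(self.p5) - len(self.junction) - SPACER_LENGTH - len(self.p3)
        return n

    def __post_init__(self):
        if self.arm_length < 23:
            raise DesignError(
                "layout segments leave no room for a repair arm within "
                f"{CASSETTE_LENGTH} nt"
            )

    def assemble(self, repair_arm: str, spacer: str) -> str:
        return self.p5 + repair_arm + self.junction + spacer + self.p3

    def slice_spacer(self, full_sequence: str) -> str:
        start = len(self.p5) + self.arm_length + len(self.junction)
        return full_sequence[start : start + SPACER_LENGTH]

    def slice_arm(self, full_sequence: str) -> str:
        return full_sequence[len(self.p5) : len(self.p5) + self.arm_length]


DEFAULT_LAYOUT = CassetteLayout()


@dataclass(frozen=True)
class Cassette:
    cassette_id: str
    variant: VariantSpec
    spacer: str
    pam: str
    pam_strand: str
    repair_arm: str
    full_sequence: str
    edit_offset: int  # position of the mutated codon within repair_arm
    pam_disruption: str
    sublibrary: str | None = None
    cut_site: int | None = field(default=None, compare=False)
    arm_span: tuple[int, int] | None = field(default=None, compare=False)
    notes: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self):
        if len(self.full_sequence) != CASSETTE_LENGTH:
            raise DesignError(
                f"{self.cassette_id}: cassette is {len(self.full_sequence)} nt, "
                f"expected {CASSETTE_LENGTH}"
            )
        if len(self.spacer) != SPACER_LENGTH:
            raise DesignError(f"{self.cassette_id}: spacer must be {SPACER_LENGTH} nt")

    def spacer_occurrences(self) -> int:
        n, start = 0, 0
        while True:
            i = self.full_sequence.find(self.spacer, start)
            if i < 0:
                return n
            n += 1
            start = i + 1


@dataclass
class OligoPool:
    cassettes: list[Cassette]
    failures: list[dict] = field(default_factory=list)
    layout: CassetteLayout = DEFAULT_LAYOUT

    def __post_init__(self):
        ids = [c.cassette_id for c in self.cassettes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DesignError(f"duplicate cassette ids: {dup}")

    def __len__(self) -> int:
        return len(self.cassettes)

    def by_id(self) -> dict[str, Cassette]:
        return {c.cassette_id: c for c in self.cassettes}

    def controls(self) -> list[Cassette]:
        return [c for c in self.cassettes if c.variant.is_control]

    def by_sublibrary(self) -> dict[str, list[Cassette]]:
        out: dict[str, list[Cassette]] = {}
        for c in self.cassettes:
            out.setdefault(c.sublibrary or "", []).append(c)
        return out


def enumerate_variants(
    targets,
    gene_models: dict[str, GeneModel],
    mutation_alphabet: str | None = None,
    include_controls: bool = True,
) -> tuple[list[VariantSpec], list[dict]]:
    """Expand targeted residues into per-variant specs.

    Per residue: one substitution spec per non-wild-type amino acid of the
    alphabet (default: all 19) plus one synonymous control when the wild-type
    amino acid has more than one codon; single-codon residues (Met, Trp) get
    a control-unavailable log entry instead of a silent drop. Output is
    sorted gene-major, position-minor, mutant amino acid alphabetical.
    """
    specs: set[VariantSpec] = set()
    log: list[dict] = []
    for gene, position in targets:
        model = gene_models[gene]
        wt = model.protein()[position - 1]
        alphabet = mutation_alphabet or "ACDEFGHIKLMNPQRSTVWY"
        for aa in alphabet:
            if aa == wt:
                continue
            specs.add(VariantSpec(gene, position, wt, aa, is_control=False))
        if include_controls:
            if has_synonymous_alternative(wt):
                specs.add(VariantSpec(gene, position, wt, wt, is_control=True))
            else:
                log.append(
                    {
                        "gene": gene,
                        "position": position,
                        "wt_aa": wt,
                        "reason": "control-unavailable: single-codon amino acid",
                    }
                )
    return sorted(specs, key=lambda v: (v.gene_name, v.residue_position, v.mut_aa, v.is_control)), log


def find_spacer_candidates(
    gene_model: GeneModel,
    residue_position: int,
    search_window: int = DEFAULT_SEARCH_WINDOW,
) -> list[tuple[float, SpacerChoice]]:
    """All NGG protospacers on either strand whose blunt cut site (between
    protospacer positions 17 and 18) lies within `search_window` nt of the
    target codon midpoint. Returns (distance, choice) pairs, best first;
    ties break + strand first, then leftmost genomic coordinate."""
    g = gene_model.genomic_sequence
    c0, _ = gene_model.codon_span(residue_position)
    mid = c0 + 1.5
    out: list[tuple[float, int, int, SpacerChoice]] = []
    for p in range(SPACER_LENGTH, len(g) - 2):
        if g[p + 1 : p + 3] == "GG":
            cut = p - 3
            d = abs(cut - mid)
            if d <= search_window:
                out.append(
                    (
                        d,
                        0,
                        p - SPACER_LENGTH,
                        SpacerChoice(
                            spacer=g[p - SPACER_LENGTH : p],
                            pam=g[p : p + 3],
                            pam_strand="+",
                            pam_pos=p,
                            cut_site=cut,
                        ),
                    )
                )
    for q in range(0, len(g) - (SPACER_LENGTH + 3) + 1):
        if g[q : q + 2] == "CC":
            cut = q + 6
            d = abs(cut - mid)
            if d <= search_window:
                out.append(
                    (
                        d,
                        1,
                        q,
                        SpacerChoice(
                            spacer=revcomp(g[q + 3 : q + 3 + SPACER_LENGTH]),
                            pam=revcomp(g[q : q + 3]),
                            pam_strand="-",
                            pam_pos=q,
                            cut_site=cut,
                        ),
                    )
                )
    out.sort(key=lambda t: t[:3])
    return [(d, choice) for d, _, _, choice in out]


def select_spacer(
    gene_model: GeneModel,
    residue_position: int,
    search_window: int = DEFAULT_SEARCH_WINDOW,
) -> SpacerChoice:
    candidates = find_spacer_candidates(gene_model, residue_position, search_window)
    if not candidates:
        raise SpacerNotFound(
            f"{gene_model.gene_name} residue {residue_position}: no NGG PAM "
            f"within {search_window} nt of the target codon"
        )
    return candidates[0][1]


def _mutant_codon(gene_model: GeneModel, variant: VariantSpec) -> str:
    """Gene-strand codon installed for this variant (codon policy)."""
    wt_codon = gene_model.codon(variant.residue_position)
    if variant.is_control:
        alts = synonymous_alternatives(wt_codon)
        if not alts:
            raise ControlUnavailable(
                f"{variant.gene_name} {variant.label}: no synonymous codon"
            )
        return alts[0]
    return PREFERRED_CODON[variant.mut_aa]


def _apply_codon(gene_model: GeneModel, genomic: str, residue: int, codon: str) -> str:
    s, e = gene_model.codon_span(residue)
    plus = revcomp(codon) if gene_model.strand == "-" else codon
    return genomic[:s] + plus + genomic[e:]


def _disruption_codon_indices(gene_model: GeneModel, positions) -> list[int]:
    residues = {
        r
        for p in positions
        if (r := gene_model.residue_of_genomic_pos(p)) is not None
    }
    return sorted(residues)


@dataclass(frozen=True)
class RepairDesign:
    repair_arm: str
    edit_offset: int
    pam_disruption: str
    arm_span: tuple[int, int]
    edited_genomic: str
    notes: tuple[str, ...] = ()


def design_repair_arm(
    gene_model: GeneModel,
    variant: VariantSpec,
    spacer_choice: SpacerChoice,
    arm_length: int = DEFAULT_LAYOUT.arm_length,
) -> RepairDesign:
    """Build the homology arm carrying the codon edit plus PAM/seed disruption.

    Disruption preference: a synonymous change inside the NGG itself, then a
    synonymous change in the seed (<= 10 nt from the cut site); candidates
    that would leave a literal duplicate of the spacer inside the arm are
    deprioritized so the cassette stays uniquely trackable. If the amino-acid
    edit already destroys the protospacer/PAM match, no extra change is made.
    """
    g = gene_model.genomic_sequence
    c0, c3 = gene_model.codon_span(variant.residue_position)
    arm_start = c0 - (arm_length - 3) // 2
    arm_end = arm_start + arm_length
    if arm_start < 0 or arm_end > len(g):
        raise DesignError(
            f"{variant.gene_name} {variant.label}: {arm_length}-nt arm exceeds "
            "the provided genomic sequence"
        )

    new_codon = _mutant_codon(gene_model, variant)
    edited = _apply_codon(gene_model, g, variant.residue_position, new_codon)

    wt_protein = gene_model.protein()
    expect = list(wt_protein)
    expect[variant.residue_position - 1] = variant.mut_aa
    expect = "".join(expect)
    if gene_model.protein(edited) != expect:
        raise DesignError(
            f"{variant.gene_name} {variant.label}: codon policy broke the "
            "translation contract"
        )

    notes: list[str] = []

    def finish(genomic: str, description: str, extra_notes=()) -> RepairDesign:
        arm = genomic[arm_start:arm_end]
        return RepairDesign(
            repair_arm=arm,
            edit_offset=c0 - arm_start,
            pam_disruption=description,
            arm_span=(arm_start, arm_end),
            edited_genomic=genomic,
            notes=tuple(notes) + tuple(extra_notes),
        )

    spacer = spacer_choice.spacer
    if not spacer_choice.protospacer_intact(edited):
        extra = ()
        arm_preview = edited[arm_start:arm_end]
        if spacer_choice.pam_strand == "+" and spacer in arm_preview:
            extra = ("duplicate-spacer: edit destroyed the PAM but the arm retains the spacer",)
        return finish(edited, "edit-overlaps-PAM", extra)

    # candidate synonymous disruptions: PAM GG first, then the seed region
    if spacer_choice.pam_strand == "+":
        pam_gg = [spacer_choice.pam_pos + 1, spacer_choice.pam_pos + 2]
        seed = range(spacer_choice.pam_pos - SEED_LENGTH, spacer_choice.pam_pos)
    else:
        pam_gg = [spacer_choice.pam_pos, spacer_choice.pam_pos + 1]
        seed = range(spacer_choice.pam_pos + 3, spacer_choice.pam_pos + 3 + SEED_LENGTH)

    candidates: list[tuple[str, str]] = []  # (description, edited genomic)
    for kind, positions in (("PAM", pam_gg), ("seed", list(seed))):
        for res in _disruption_codon_indices(gene_model, positions):
            if res == variant.residue_position or res > len(wt_protein):
                continue  # skip the edited codon and the stop codon
            s, e = gene_model.codon_span(res)
            if s < arm_start or e > arm_end:
                continue
            current = gene_model.codon(res, edited)
            if codon_to_aa(current) != wt_protein[res - 1]:
                continue  # codon altered by the primary edit; leave it alone
            for alt in synonymous_alternatives(current):
                trial = _apply_codon(gene_model, edited, res, alt)
                if spacer_choice.protospacer_intact(trial):
                    continue
                if gene_model.protein(trial) != expect:
                    continue
                desc = f"{kind}:codon{res}:{current}>{alt}"
                candidates.append((desc, trial))
            if candidates and kind == "PAM":
                break
        if candidates:
            break  # prefer PAM disruptions; fall through to seed only if none

    if not candidates:
        raise DesignError(
            f"{variant.gene_name} {variant.label}: no synonymous PAM or seed "
            "disruption available"
        )

    def leaves_duplicate(genomic: str) -> bool:
        return (
            spacer_choice.pam_strand == "+"
            and spacer in genomic[arm_start:arm_end]
        )

    unique = [c for c in candidates if not leaves_duplicate(c[1])]
    if not unique and spacer_choice.pam_strand == "+":
        # PAM-only change keeps the arm copy of the spacer: retry seed-side
        for res in _disruption_codon_indices(gene_model, list(seed)):
            if res == variant.residue_position or res > len(wt_protein):
                continue  # skip the edited codon and the stop codon
            s, e = gene_model.codon_span(res)
            if s < arm_start or e > arm_end:
                continue
            current = gene_model.codon(res, edited)
            if codon_to_aa(current) != wt_protein[res - 1]:
                continue
            for alt in synonymous_alternatives(current):
                trial = _apply_codon(gene_model, edited, res, alt)
                if spacer_choice.protospacer_intact(trial):
                    continue
                if gene_model.protein(trial) != expect:
                    continue
                if not leaves_duplicate(trial):
                    unique.append((f"seed:codon{res}:{current}>{alt}", trial))
            if unique:
                break

    if unique:
        desc, genomic = unique[0]
    else:
        desc, genomic = candidates[0]
        notes.append("duplicate-spacer: no disruption could remove the arm copy")
    return finish(genomic, desc)


def assemble_cassette(
    variant: VariantSpec,
    spacer_choice: SpacerChoice,
    repair: RepairDesign,
    layout: CassetteLayout = DEFAULT_LAYOUT,
    cassette_id: str | None = None,
    sublibrary: str | None = None,
) -> Cassette:
    if len(repair.repair_arm) != layout.arm_length:
        raise DesignError(
            f"repair arm is {len(repair.repair_arm)} nt; layout expects "
            f"{layout.arm_length}"
        )
    full = layout.assemble(repair.repair_arm, spacer_choice.spacer)
    cassette = Cassette(
        cassette_id=cassette_id or f"{variant.gene_name}_{variant.label}",
        variant=variant,
        spacer=spacer_choice.spacer,
        pam=spacer_choice.pam,
        pam_strand=spacer_choice.pam_strand,
        repair_arm=repair.repair_arm,
        full_sequence=full,
        edit_offset=repair.edit_offset,
        pam_disruption=repair.pam_disruption,
        sublibrary=sublibrary,
        cut_site=spacer_choice.cut_site,
        arm_span=repair.arm_span,
        notes=repair.notes,
    )
    n = cassette.spacer_occurrences()
    if n != 1 and not any(note.startswith("duplicate-spacer") for note in cassette.notes):
        return replace(cassette, notes=cassette.notes + (f"spacer occurs {n}x in oligo",))
    return cassette


def design_pool(
    gene_models: dict[str, GeneModel],
    targets,
    mutation_alphabet: str | None = None,
    include_controls: bool = True,
    layout: CassetteLayout = DEFAULT_LAYOUT,
    search_window: int = DEFAULT_SEARCH_WINDOW,
    sublibrary_of=None,
) -> OligoPool:
    """Design one cassette per variant over the targeted residues.

    `targets` is an iterable of (gene, residue_position) pairs;
    `sublibrary_of`, if given, maps (gene, position) -> sublibrary name.
    Variants that cannot be designed are recorded in the failure log, never
    silently dropped.
    """
    variants, log = enumerate_variants(
        targets, gene_models, mutation_alphabet, include_controls
    )
    cassettes: list[Cassette] = []
    failures: list[dict] = list(log)
    spacer_cache: dict[tuple[str, int], SpacerChoice | SpacerNotFound] = {}
    for variant in variants:
        key = (variant.gene_name, variant.residue_position)
        if key not in spacer_cache:
            try:
                spacer_cache[key] = select_spacer(
                    gene_models[variant.gene_name],
                    variant.residue_position,
                    search_window,
                )
            except SpacerNotFound as exc:
                spacer_cache[key] = exc
        choice = spacer_cache[key]
        if isinstance(choice, SpacerNotFound):
            failures.append(
                {
                    "gene": variant.gene_name,
                    "position": variant.residue_position,
                    "variant": variant.label,
                    "reason": str(choice),
                }
            )
            continue
        try:
            repair = design_repair_arm(
                gene_models[variant.gene_name], variant, choice, layout.arm_length
            )
        except DesignError as exc:
            failures.append(
                {
                    "gene": variant.gene_name,
                    "position": variant.residue_position,
                    "variant": variant.label,
                    "reason": str(exc),
                }
            )
            continue
        sub = sublibrary_of(key) if sublibrary_of else None
        cassettes.append(
            assemble_cassette(variant, choice, repair, layout, sublibrary=sub)
        )
    return OligoPool(cassettes=cassettes, failures=failures, layout=layout)


# ---------------------------------------------------------------------------
# pool I/O

DESIGN_TSV_COLUMNS = [
    "cassette_id", "gene", "position", "wt_aa", "mut_aa", "is_control",
    "spacer", "pam", "pam_strand", "pam_disruption", "sublibrary", "edit_offset",
]


def pool_to_frame(pool: OligoPool) -> pd.DataFrame:
    rows = []
    for c in pool.cassettes:
        rows.append(
            {
                "cassette_id": c.cassette_id,
                "gene": c.variant.gene_name,
                "position": c.variant.residue_position,
                "wt_aa": c.variant.wt_aa,
                "mut_aa": c.variant.mut_aa,
                "is_control": c.variant.is_control,
                "spacer": c.spacer,
                "pam": c.pam,
                "pam_strand": c.pam_strand,
                "pam_disruption": c.pam_disruption,
                "sublibrary": c.sublibrary or "",
                "edit_offset": c.edit_offset,
            }
        )
    return pd.DataFrame(rows, columns=DESIGN_TSV_COLUMNS)


def write_oligo_pool(pool: OligoPool, fasta_path, tsv_path, failures_path=None) -> None:
    """Write the pool as a cassette FASTA plus a design TSV (and failure log)."""
    if not pool.cassettes:
        raise DesignError("refusing to write an empty pool")
    records = [
        SeqRecord(Seq(c.full_sequence), id=c.cassette_id, description="")
        for c in pool.cassettes
    ]
    SeqIO.write(records, fasta_path, "fasta")
    pool_to_frame(pool).to_csv(tsv_path, sep="\t", index=False)
    if failures_path is not None:
        pd.DataFrame(pool.failures).to_csv(failures_path, sep="\t", index=False)


def read_oligo_pool(fasta_path, tsv_path, layout: CassetteLayout = DEFAULT_LAYOUT) -> OligoPool:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    table = pd.read_csv(tsv_path, sep="\t", keep_default_na=False)
    cassettes = []
    for _, row in table.iterrows():
        full = seqs[row["cassette_id"]]
        is_control = str(row["is_control"]).lower() in ("true", "1")
        variant = VariantSpec(
            gene_name=row["gene"],
            residue_position=int(row["position"]),
            wt_aa=row["wt_aa"],
            mut_aa=row["mut_aa"],
            is_control=is_control,
        )
        cassettes.append(
            Cassette(
                cassette_id=row["cassette_id"],
                variant=variant,
                spacer=layout.slice_spacer(full),
                pam=row["pam"],
                pam_strand=row["pam_strand"],
                repair_arm=layout.slice_arm(full),
                full_sequence=full,
                edit_offset=int(row["edit_offset"]),
                pam_disruption=row["pam_disruption"],
                sublibrary=row["sublibrary"] or None,
            )
        )
    return OligoPool(cassettes=cassettes, layout=layout)


def write_design_summary(pool: OligoPool, path) -> None:
    summary = {
        "n_cassettes": len(pool),
        "n_controls": len(pool.controls()),
        "n_failures": len(pool.failures),
        "by_sublibrary": {k: len(v) for k, v in sorted(pool.by_sublibrary().items())},
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)


# gene model I/O: FASTA of genomic segments + TSV (gene, cds_start, cds_end, strand)
def read_gene_models(fasta_path, tsv_path) -> dict[str, GeneModel]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    table = pd.read_csv(tsv_path, sep="\t")
    models = {}
    for _, row in table.iterrows():
        models[row["gene"]] = GeneModel(
            gene_name=row["gene"],
            genomic_sequence=seqs[row["gene"]],
            cds_start=int(row["cds_start"]),
            cds_end=int(row["cds_end"]),
            strand=str(row["strand"]),
        )
    return models
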