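import numpy as np
import pytest

from createscreen import (
    CassetteLayout,
    GeneModel,
    OligoPool,
    VariantSpec,
    design_pool,
    design_repair_arm,
    enumerate_variants,
    random_gene_model,
    read_oligo_pool,
    select_spacer,
    write_oligo_pool,
)
from createscreen.design import (
    CASSETTE_LENGTH,
    DEFAULT_LAYOUT,
    DesignError,
    SpacerNotFound,
    pool_to_frame,
)

from helpers_oracles import recut_sites, revcomp_naive, spacer_oracle


def make_gene(cds_codons, flank="AT" * 80, name="g"):
    cds = "".join(cds_codons)
    return GeneModel(name, flank + cds + flank, len(flank), len(flank) + len(cds))


class TestEnumerateVariants:
    def test_leucine_residue_yields_19_substitutions_plus_control(self):
        gene = make_gene(["ATG", "CTG", "TAA"])  # M L *
        variants, log = enumerate_variants([("g", 2)], {"g": gene})
        assert len(variants) == 20 and not log
        controls = [v for v in variants if v.is_control]
        assert len(controls) == 1 and controls[0].mut_aa == "L"
        assert len({v.mut_aa for v in variants if not v.is_control}) == 19

    def test_tryptophan_control_is_logged_not_silently_dropped(self):
        gene = make_gene(["ATG", "TGG", "TAA"])  # M W *
        variants, log = enumerate_variants([("g", 2)], {"g": gene})
        assert len(variants) == 19
        assert len(log) == 1 and "control-unavailable" in log[0]["reason"]

    def test_output_sorted_gene_major_position_minor(self):
        g1 = make_gene(["ATG", "CTG", "GCA", "TAA"], name="a")
        g2 = make_gene(["ATG", "AAA", "TAA"], name="b")
        variants, _ = enumerate_variants(
            [("b", 2), ("a", 3), ("a", 2)], {"a": g1, "b": g2}
        )
        keys = [(v.gene_name, v.residue_position) for v in variants]
        assert keys == sorted(keys)
        for prev, cur in zip(variants, variants[1:]):
            if (prev.gene_name, prev.residue_position) == (cur.gene_name, cur.residue_position):
                assert prev.mut_aa <= cur.mut_aa


class TestSelectSpacer:
    def test_matches_exhaustive_scan_oracle_on_random_genes(self):
        rng = np.random.default_rng(31)
        checked = 0
        for _ in range(40):
            model = random_gene_model(rng, "g", n_internal_codons=20, flank=40)
            residue = int(rng.integers(2, model.n_residues))
            expected = spacer_oracle(model, residue, 30)
            if expected is None:
                with pytest.raises(SpacerNotFound):
                    select_spacer(model, residue, 30)
                continue
            choice = select_spacer(model, residue, 30)
            assert (
                choice.spacer,
                choice.pam,
                choice.pam_strand,
                choice.pam_pos,
                choice.cut_site,
            ) == expected
            checked += 1
        assert checked >= 20

    def test_unique_adjacent_agg_is_chosen(self):
        # AT filler carries no NGG/CCN; a single AGG sits right after the codon
        seq = list("AT" * 60)
        seq[70:73] = "AGG"
        g = GeneModel("g", "".join(seq), 54, 72)
        choice = select_spacer(g, 3)  # codon at [60, 63)
        assert (choice.pam, choice.pam_strand, choice.pam_pos) == ("AGG", "+", 70)
        assert choice.spacer == "".join(seq[50:70])

    def test_equidistant_pams_break_tie_toward_plus_strand(self):
        seq = list("AT" * 60)
        seq[70:73] = "AGG"  # + strand cut at 67, codon midpoint 61.5
        seq[50:52] = "CC"  # - strand cut at 56, same 5.5-nt distance
        g = GeneModel("g", "".join(seq), 54, 72)
        choice = select_spacer(g, 3)
        assert choice.pam_strand == "+" and choice.pam_pos == 70

    def test_no_pam_within_window_raises(self):
        g = GeneModel("g", "AT" * 60, 54, 72)
        with pytest.raises(SpacerNotFound):
            select_spacer(g, 3)


class TestRepairArm:
    def test_substitution_changes_exactly_one_residue(self, toy_gene):
        protein = toy_gene.protein()
        residue = 20
        variant = VariantSpec(toy_gene.gene_name, residue, protein[residue - 1], "W")
        choice = select_spacer(toy_gene, residue)
        repair = design_repair_arm(toy_gene, variant, choice)
        edited_protein = toy_gene.protein(repair.edited_genomic)
        diffs = [
            i + 1 for i, (a, b) in enumerate(zip(protein, edited_protein)) if a != b
        ]
        assert diffs == [residue] and edited_protein[residue - 1] == "W"

    def test_control_translates_identically_but_differs_in_dna(self, toy_gene):
        protein = toy_gene.protein()
        residue = 15
        variant = VariantSpec(
            toy_gene.gene_name, residue, protein[residue - 1], protein[residue - 1], is_control=True
        )
        choice = select_spacer(toy_gene, residue)
        repair = design_repair_arm(toy_gene, variant, choice)
        assert toy_gene.protein(repair.edited_genomic) == protein
        assert repair.edited_genomic != toy_gene.genomic_sequence

    def test_edit_overlapping_pam_needs_no_extra_disruption(self):
        # codon AGG (Arg) supplies the PAM GG; mutating R->A destroys it
        flank = "AT" * 80
        gene = make_gene(
            ["ATG"] + ["ATA"] * 10 + ["AGG"] + ["TAT"] * 10 + ["TAA"], flank=flank
        )
        variant = VariantSpec("g", 12, "R", "A")
        choice = select_spacer(gene, 12)
        assert (choice.pam_strand, choice.pam_pos) == ("+", 193)
        repair = design_repair_arm(gene, variant, choice)
        assert repair.pam_disruption == "edit-overlaps-PAM"
        diffs = [
            i
            for i, (a, b) in enumerate(zip(gene.genomic_sequence, repair.edited_genomic))
            if a != b
        ]
        assert set(diffs) <= set(range(193, 196))


@pytest.fixture(scope="module")
def pool():
    rng = np.random.default_rng(97)
    models = {
        m.gene_name: m
        for m in (random_gene_model(rng, f"g{i}", 30, 160) for i in range(2))
    }
    targets = [(name, pos) for name in models for pos in (5, 12, 21)]
    return models, design_pool(models, targets)


class TestDesignedPools:
    def test_every_cassette_is_230_nt(self, pool):
        _, p = pool
        assert len(p) > 0
        assert {len(c.full_sequence) for c in p.cassettes} == {CASSETTE_LENGTH}

    def test_translation_contract_over_whole_pool(self, pool):
        models, p = pool
        for c in p.cassettes:
            model = models[c.variant.gene_name]
            s, e = c.arm_span
            edited = (
                model.genomic_sequence[:s] + c.repair_arm + model.genomic_sequence[e:]
            )
            wt = model.protein()
            mut = model.protein(edited)
            if c.variant.is_control:
                assert mut == wt
            else:
                diffs = [i + 1 for i, (a, b) in enumerate(zip(wt, mut)) if a != b]
                assert diffs == [c.variant.residue_position]
                assert mut[c.variant.residue_position - 1] == c.variant.mut_aa

    def test_spacer_exists_in_wild_type_and_recut_is_destroyed(self, pool):
        models, p = pool
        for c in p.cassettes:
            model = models[c.variant.gene_name]
            assert recut_sites(model.genomic_sequence, c.spacer) >= 1
            s, e = c.arm_span
            edited = (
                model.genomic_sequence[:s] + c.repair_arm + model.genomic_sequence[e:]
            )
            assert recut_sites(edited, c.spacer) == 0

    def test_spacer_is_unique_within_cassette(self, pool):
        _, p = pool
        for c in p.cassettes:
            if any(n.startswith("duplicate-spacer") for n in c.notes):
                continue
            assert c.spacer_occurrences() == 1

    def test_arm_differs_from_wild_type_only_at_intended_sites(self, pool):
        models, p = pool
        for c in p.cassettes:
            model = models[c.variant.gene_name]
            s, e = c.arm_span
            wt_arm = model.genomic_sequence[s:e]
            diffs = {i for i, (a, b) in enumerate(zip(wt_arm, c.repair_arm)) if a != b}
            allowed = set(range(c.edit_offset, c.edit_offset + 3))
            if c.pam_disruption not in ("edit-overlaps-PAM",):
                res = int(c.pam_disruption.split(":")[1].removeprefix("codon"))
                ds, de = model.codon_span(res)
                allowed |= set(range(ds - s, de - s))
            assert diffs <= allowed and diffs

    def test_design_is_deterministic(self, pool, tmp_path):
        models, p = pool
        targets = [(name, pos) for name in models for pos in (5, 12, 21)]
        q = design_pool(models, targets)
        assert pool_to_frame(p).equals(pool_to_frame(q))
        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_oligo_pool(p, a, tmp_path / "a.tsv")
        write_oligo_pool(q, b, tmp_path / "b.tsv")
        assert a.read_bytes() == b.read_bytes()


class TestLayoutAndAssembly:
    def test_default_layout_arithmetic(self):
        lay = DEFAULT_LAYOUT
        assert (len(lay.p5), lay.arm_length, len(lay.junction), 20, len(lay.p3)) == (
            15, 142, 20, 20, 33,
        )
        assert len(lay.p5) + lay.arm_length + len(lay.junction) + 20 + len(lay.p3) == 230

    def test_inconsistent_layout_is_a_configuration_error(self):
        with pytest.raises(DesignError):
            CassetteLayout(p5="A" * 100, junction="G" * 60, p3="T" * 60)

    def test_spacer_round_trips_through_layout_slicing(self, toy_gene):
        pool = design_pool({toy_gene.gene_name: toy_gene}, [(toy_gene.gene_name, 10)])
        for c in pool.cassettes:
            assert DEFAULT_LAYOUT.slice_spacer(c.full_sequence) == c.spacer
            assert DEFAULT_LAYOUT.slice_arm(c.full_sequence) == c.repair_arm


class TestPoolIO:
    def test_round_trip_reproduces_the_pool(self, toy_gene, tmp_path):
        pool = design_pool(
            {toy_gene.gene_name: toy_gene},
            [(toy_gene.gene_name, 8), (toy_gene.gene_name, 17)],
        )
        fasta, tsv = tmp_path / "pool.fasta", tmp_path / "pool.tsv"
        write_oligo_pool(pool, fasta, tsv)
        back = read_oligo_pool(fasta, tsv)
        assert back.cassettes == pool.cassettes

    def test_written_files_have_one_record_per_cassette(self, toy_gene, tmp_path):
        pool = design_pool({toy_gene.gene_name: toy_gene}, [(toy_gene.gene_name, 8)])
        fasta, tsv = tmp_path / "pool.fasta", tmp_path / "pool.tsv"
        write_oligo_pool(pool, fasta, tsv)
        assert fasta.read_text().count(">") == len(pool)
        assert len(tsv.read_text().strip().splitlines()) == len(pool) + 1

    def test_duplicate_cassette_ids_are_rejected(self, toy_gene):
        pool = design_pool({toy_gene.gene_name: toy_gene}, [(toy_gene.gene_name, 8)])
        with pytest.raises(DesignError, match="duplicate"):
            OligoPool(cassettes=pool.cassettes + pool.cassettes[:1])


def test_reverse_strand_genes_are_designed_correctly():
    rng = np.random.default_rng(13)
    fwd = random_gene_model(rng, "g", n_internal_codons=30, flank=160)
    rev = GeneModel(
        "g",
        revcomp_naive(fwd.genomic_sequence),
        len(fwd.genomic_sequence) - fwd.cds_end,
        len(fwd.genomic_sequence) - fwd.cds_start,
        strand="-",
    )
    assert rev.protein() == fwd.protein()
    pool = design_pool({"g": rev}, [("g", 10), ("g", 20)])
    assert len(pool) > 0
    for c in pool.cassettes:
        s, e = c.arm_span
        edited = rev.genomic_sequence[:s] + c.repair_arm + rev.genomic_sequence[e:]
        wt, mut = rev.protein(), rev.protein(edited)
        if c.variant.is_control:
            assert mut == wt
        else:
            diffs = [i + 1 for i, (a, b) in enumerate(zip(wt, mut)) if a != b]
            assert diffs == [c.variant.residue_position]
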