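import numpy as np
import pandas as pd
import pytest

from createscreen import (
    CountTable,
    MappingConfig,
    MergedRead,
    base_change_frequencies,
    demultiplex,
    editing_efficiency,
    map_reads,
    merge_pairs,
    merge_pairs_batch,
    sequence_identity,
)
from createscreen import _seqarray as sa
from createscreen.readproc import BarcodeCollisionError, MergeRejection

from helpers_oracles import hamming_naive, identity_naive, merge_oracle, revcomp_naive


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMergePairs:
    def test_partial_overlap_length_arithmetic(self):
        amp = "GATTACACTGGTAC"  # 14 nt
        r1, r2 = amp[:10], revcomp_naive(amp[4:14])
        merged = merge_pairs(r1, r2, min_overlap=4)
        assert isinstance(merged, MergedRead)
        assert merged.sequence == amp and len(merged.sequence) == 14
        assert merged.overlap_length == 6 and merged.overlap_mismatches == 0

    def test_full_reverse_complement_collapses_to_r1(self):
        r1 = "GATTACACTG"
        merged = merge_pairs(r1, revcomp_naive(r1))
        assert merged.sequence == r1 and merged.overlap_length == 10

    def test_overlap_disagreements_resolve_in_favor_of_r1(self):
        amp = "GATTACACTGGTAC"
        r1 = amp[:10]
        r2rc = amp[4:14]
        r2rc = r2rc[:2] + ("A" if r2rc[2] != "A" else "C") + r2rc[3:]  # 1 error in overlap
        merged = merge_pairs(r1, revcomp_naive(r2rc), min_overlap=4, max_overlap_mismatch_rate=0.2)
        assert merged.sequence[:10] == r1
        assert merged.overlap_mismatches == 1

    def test_unmergeable_pairs_are_rejected_with_reason(self):
        out = merge_pairs("AAAAAAAAAA", "AAAAAAAAAA")  # r2rc = TTTT...
        assert isinstance(out, MergeRejection) and "overlap" in out.reason

    def test_matches_exhaustive_shift_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            amp = random_dna(rng, 60)
            cut = int(rng.integers(10, 35))
            r1 = amp[: cut + 20]
            r2 = revcomp_naive(amp[cut:])
            # sprinkle substitution errors
            r1 = list(r1)
            for i in rng.integers(0, len(r1), size=2):
                r1[i] = "ACGT"[int(rng.integers(4))]
            r1 = "".join(r1)
            expected = merge_oracle(r1, r2, 10, 0.1)
            got = merge_pairs(r1, r2, 10, 0.1)
            if expected is None:
                assert isinstance(got, MergeRejection)
            else:
                assert (got.sequence, got.overlap_length, got.overlap_mismatches) == expected

    def test_batch_merge_equals_per_pair_merge(self):
        rng = np.random.default_rng(23)
        r1s, r2s = [], []
        for _ in range(50):
            amp = random_dna(rng, 80)
            r1s.append(amp[:50])
            r2s.append(revcomp_naive(amp[30:]))
        batch = merge_pairs_batch(sa.encode_batch(r1s), sa.encode_batch(r2s))
        single = [merge_pairs(a, b) for a, b in zip(r1s, r2s)]
        assert batch == single


class TestDemultiplex:
    BARCODES = {"s1": "ACGTAC", "s2": "TGCAGT"}

    def test_exact_match_assigns_and_strips_prefix(self):
        [(sample, seq)] = demultiplex(["ACGTACGGGG"], self.BARCODES)
        assert sample == "s1" and seq == "GGGG"

    def test_single_mismatch_within_tolerance_assigns(self):
        [(sample, seq)] = demultiplex(["ACGAACGGGG"], self.BARCODES, 1)
        assert sample == "s1" and seq == "GGGG"

    def test_distant_prefix_goes_to_unassigned(self):
        [(sample, seq)] = demultiplex(["AAAAAAGGGG"], self.BARCODES, 1)
        assert sample is None and seq == "AAAAAAGGGG"

    def test_colliding_barcodes_are_a_configuration_error(self):
        with pytest.raises(BarcodeCollisionError):
            demultiplex(["ACGTACGGGG"], {"s1": "ACGTAC", "s2": "ACGTAA"}, 1)


REFS = None


def _make_refs():
    rng = np.random.default_rng(29)
    base = random_dna(rng, 450)
    refs = {}
    for i in range(4):
        s = list(base)
        s[100 + i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[100 + i]]
        refs[f"c{i}"] = "".join(s)
    return refs, base


def _mutate(seq, positions):
    s = list(seq)
    for p in positions:
        s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
    return "".join(s)


class TestMapReads:
    refs, base = _make_refs()

    def test_exact_read_counts_for_its_cassette(self):
        table = map_reads([("s", self.refs["c2"])], self.refs)
        assert table.counts.loc["s", "c2"] == 1 and table.mapped_total("s") == 1

    def test_three_mismatches_accepted_in_mismatch_count_mode(self):
        read = _mutate(self.refs["c1"], [10, 200, 300])
        cfg = MappingConfig(mode="mismatch_count")
        table = map_reads([("s", read)], self.refs, cfg)
        assert table.counts.loc["s", "c1"] == 1

    def test_four_mismatches_rejected_in_mismatch_count_mode(self):
        read = _mutate(self.refs["c1"], [10, 200, 300, 400])
        cfg = MappingConfig(mode="mismatch_count")
        table = map_reads([("s", read)], self.refs, cfg)
        assert table.unmapped["s"] == 1

    def test_identity_mode_boundary_at_98_3_percent(self):
        # 7 mismatches / 450 = 98.44% > 98.3 -> mapped; 8 -> 98.22% -> unmapped
        seven = _mutate(self.refs["c1"], [10, 20, 30, 200, 300, 320, 400])
        eight = _mutate(self.refs["c1"], [10, 20, 30, 200, 300, 320, 400, 440])
        table = map_reads([("s", seven), ("s", eight)], self.refs)
        assert table.counts.loc["s", "c1"] == 1 and table.unmapped["s"] == 1

    def test_equal_best_reads_land_in_ambiguous_bin(self):
        # the common base sequence is 1 mismatch from every reference
        table = map_reads([("s", self.base)], self.refs)
        assert table.ambiguous["s"] == 1 and table.mapped_total("s") == 0

    def test_count_conservation_invariant(self):
        rng = np.random.default_rng(41)
        reads = []
        for _ in range(60):
            ref = self.refs[f"c{int(rng.integers(4))}"]
            k = int(rng.integers(0, 12))
            reads.append(("s", _mutate(ref, list(rng.choice(450, size=k, replace=False)))))
        table = map_reads(reads, self.refs)
        table.validate()
        assert table.total["s"] == 60

    def test_raising_identity_threshold_never_increases_counts(self):
        rng = np.random.default_rng(43)
        reads = []
        for _ in range(80):
            ref = self.refs[f"c{int(rng.integers(4))}"]
            k = int(rng.integers(0, 15))
            reads.append(("s", _mutate(ref, list(rng.choice(450, size=k, replace=False)))))
        previous = None
        for identity_min in (90.0, 95.0, 98.3, 99.5):
            table = map_reads(reads, self.refs, MappingConfig(identity_min=identity_min))
            counts = table.counts.loc["s"]
            if previous is not None:
                assert (counts <= previous).all()
            previous = counts

    def test_identity_matches_brute_force_oracle(self):
        rng = np.random.default_rng(47)
        for _ in range(100):
            ref = random_dna(rng, int(rng.integers(30, 120)))
            k = int(rng.integers(0, 10))
            read = _mutate(ref, list(rng.choice(len(ref), size=min(k, len(ref)), replace=False)))
            identity, mm = sequence_identity(read, ref)
            assert mm == hamming_naive(read, ref)
            assert identity == pytest.approx(identity_naive(read, ref))

    def test_empty_reference_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty reference"):
            map_reads([("s", "ACGT")], {})


class TestCountTableRoundTrip:
    def test_long_tsv_round_trip(self, tmp_path):
        refs, _ = _make_refs()
        reads = [("a", refs["c0"]), ("a", refs["c1"]), ("b", refs["c0"])]
        table = map_reads(reads, refs)
        path = tmp_path / "counts.tsv"
        table.write_tsv(path)
        back = CountTable.read_tsv(path)
        assert back.counts.equals(table.counts)
        assert back.total.equals(table.total)


class TestEditingEfficiency:
    def _table(self, mapped, unmapped):
        counts = pd.DataFrame({"mut": [mapped], "wt": [0]}, index=["s"])
        return CountTable(
            counts=counts,
            unmapped=pd.Series({"s": unmapped}),
            ambiguous=pd.Series({"s": 0}),
            total=pd.Series({"s": mapped + unmapped}),
        )

    def test_ratio_of_mutant_reads_to_total(self):
        assert editing_efficiency(self._table(80, 20), "s", ["mut"]) == 0.8

    def test_zero_mutant_reads_gives_zero(self):
        assert editing_efficiency(self._table(0, 50), "s", ["mut"]) == 0.0

    def test_zero_total_reads_is_missing_with_warning(self):
        with pytest.warns(UserWarning, match="zero total"):
            out = editing_efficiency(self._table(0, 0), "s", ["mut"])
        assert np.isnan(out)

    def test_matches_simulated_mutant_fraction(self):
        rng = np.random.default_rng(53)
        refs, _ = _make_refs()
        p_mut = 0.7
        n = 400
        is_mut = rng.random(n) < p_mut
        reads = [("s", refs["c1"] if m else refs["c0"]) for m in is_mut]
        table = map_reads(reads, refs)
        eff = editing_efficiency(table, "s", ["c1"])
        sd = np.sqrt(p_mut * (1 - p_mut) / n)
        assert abs(eff - p_mut) <= 3 * sd


class TestBaseChangeFrequencies:
    WT = "GATTACACTGGTACCAGGTTCAACGGTACGATCACGTGCA"  # 40 nt

    def test_perfect_read_denominator_definition(self):
        changed = _mutate(self.WT, [4])
        reads = [self.WT] * 40 + [changed] * 10
        freqs = base_change_frequencies(reads, self.WT)
        assert freqs[5] == pytest.approx(0.25)  # 10 changed / 40 perfect
        assert freqs.drop(5).eq(0).all()

    def test_all_perfect_reads_give_zero_frequencies(self):
        freqs = base_change_frequencies([self.WT] * 10, self.WT)
        assert freqs.eq(0).all()

    def test_no_perfect_reads_yields_missing_values(self):
        changed = _mutate(self.WT, [4])
        with pytest.warns(UserWarning, match="perfect"):
            freqs = base_change_frequencies([changed] * 5, self.WT)
        assert freqs.isna().all()

    def test_reads_below_wildtype_identity_threshold_are_dropped(self):
        # 3/40 mismatches = 92.5% < 95%: the read must not contribute
        noisy = _mutate(self.WT, [4, 10, 20])
        freqs = base_change_frequencies([self.WT] * 10 + [noisy], self.WT)
        assert freqs.eq(0).all()

    def test_total_read_denominator_option(self):
        changed = _mutate(self.WT, [4])
        reads = [self.WT] * 40 + [changed] * 10
        freqs = base_change_frequencies(reads, self.WT, denominator="total")
        assert freqs[5] == pytest.approx(10 / 50)
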