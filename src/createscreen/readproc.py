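"""Amplicon read processing: merge, demultiplex, map, tally.

Merging finds, per read pair, the longest suffix(R1)/prefix(revcomp R2)
overlap whose mismatch rate stays under a cap, resolving overlap
disagreements in favor of R1 (inputs carry constant qualities). Merged reads
are demultiplexed on their R1 barcode prefix, then mapped to the cassette
amplicon references under either of two rules: percent identity above a
threshold (default >98.3%) or at most a fixed number of mismatches (default
3) over the ~450-bp region. Equal-best hits to several references land in an
ambiguous bin rather than being assigned arbitrarily; every read is
accounted for (mapped + unmapped + ambiguous = total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
import yaml

from . import _seqarray as sa

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_OVERLAP_MISMATCH_RATE = 0.1

UNMAPPED = "__unmapped__"
AMBIGUOUS = "__ambiguous__"
TOTAL = "__total__"


@dataclass(frozen=True)
class MergedRead:
    sequence: str
    overlap_length: int
    overlap_mismatches: int
    sample_id: str | None = None


@dataclass(frozen=True)
class MergeRejection:
    reason: str
    sample_id: str | None = None


@dataclass(frozen=True)
class MappingConfig:
    mode: str = "identity_threshold"  # or "mismatch_count"
    identity_min: float = 98.3  # percent, strict lower bound
    max_mismatches: int = 3
    wt_identity_min: float = 95.0
    region_length: int = 450

    def __post_init__(self):
        if self.mode not in ("identity_threshold", "mismatch_count"):
            raise ValueError(f"unknown mapping mode {self.mode!r}")
        if not 0 < self.identity_min <= 100:
            raise ValueError("identity_min must be in (0, 100]")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "MappingConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def merge_pairs(
    r1: str,
    r2: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_overlap_mismatch_rate: float = DEFAULT_MAX_OVERLAP_MISMATCH_RATE,
) -> MergedRead | MergeRejection:
    """Assemble one read pair; the longest admissible overlap wins."""
    if not r1 or not r2:
        return MergeRejection("empty read")
    r2rc = sa.revcomp(r2)
    a, b = sa.encode(r1), sa.encode(r2rc)
    for v in range(min(len(a), len(b)), min_overlap - 1, -1):
        mm = int(np.count_nonzero(a[len(a) - v :] != b[:v]))
        if mm <= max_overlap_mismatch_rate * v:
            return MergedRead(
                sequence=r1 + r2rc[v:], overlap_length=v, overlap_mismatches=mm
            )
    return MergeRejection("no overlap satisfying the mismatch-rate cap")


def merge_pairs_batch(
    r1: np.ndarray,
    r2: np.ndarray,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_overlap_mismatch_rate: float = DEFAULT_MAX_OVERLAP_MISMATCH_RATE,
) -> list[MergedRead | MergeRejection]:
    """Vectorized merge of equal-length read pairs (rows of ASCII arrays).

    Semantics are identical to `merge_pairs` applied row by row.
    """
    if r1.ndim != 2 or r2.ndim != 2 or r1.shape[0] != r2.shape[0]:
        raise ValueError("expected matching 2-D read arrays")
    n, n1 = r1.shape
    n2 = r2.shape[1]
    b = sa.revcomp_array(r2)
    chosen_v = np.zeros(n, dtype=int)
    chosen_mm = np.zeros(n, dtype=int)
    unresolved = np.ones(n, dtype=bool)
    for v in range(min(n1, n2), min_overlap - 1, -1):
        if not unresolved.any():
            break
        rows = np.nonzero(unresolved)[0]
        mm = np.count_nonzero(r1[rows, n1 - v :] != b[rows, :v], axis=1)
        ok = mm <= max_overlap_mismatch_rate * v
        hit = rows[ok]
        chosen_v[hit] = v
        chosen_mm[hit] = mm[ok]
        unresolved[hit] = False
    out: list[MergedRead | MergeRejection] = []
    r1_strs = sa.decode_batch(r1)
    b_strs = sa.decode_batch(b)
    for i in range(n):
        if unresolved[i]:
            out.append(MergeRejection("no overlap satisfying the mismatch-rate cap"))
        else:
            v = int(chosen_v[i])
            out.append(
                MergedRead(
                    sequence=r1_strs[i] + b_strs[i][v:],
                    overlap_length=v,
                    overlap_mismatches=int(chosen_mm[i]),
                )
            )
    return out


class BarcodeCollisionError(ValueError):
    pass


def _check_barcodes(barcode_map: dict[str, str], max_mismatches: int) -> int:
    lengths = {len(b) for b in barcode_map.values()}
    if len(lengths) != 1:
        raise BarcodeCollisionError("barcodes must share one length")
    items = sorted(barcode_map.items())
    for i, (s1, b1) in enumerate(items):
        for s2, b2 in items[i + 1 :]:
            d = sa.hamming(b1, b2)
            if d <= 2 * max_mismatches:
                raise BarcodeCollisionError(
                    f"barcodes for {s1} and {s2} are only {d} mismatches apart"
                )
    return lengths.pop()


def demultiplex(
    reads: list[str],
    barcode_map: dict[str, str],
    max_barcode_mismatches: int = 1,
) -> list[tuple[str | None, str]]:
    """Assign each read to the unique barcode within tolerance of its prefix.

    Returns (sample_id, barcode-stripped sequence) per read; sample_id is
    None for unassigned reads (their sequence is left intact).
    """
    blen = _check_barcodes(barcode_map, max_barcode_mismatches)
    samples = sorted(barcode_map)
    bc = sa.encode_batch([barcode_map[s] for s in samples])
    out: list[tuple[str | None, str]] = []
    for read in reads:
        if len(read) < blen:
            out.append((None, read))
            continue
        prefix = sa.encode(read[:blen])
        dists = np.count_nonzero(bc != prefix, axis=1)
        best = int(dists.min())
        if best <= max_barcode_mismatches:
            out.append((samples[int(dists.argmin())], read[blen:]))
        else:
            out.append((None, read))
    return out


@dataclass
class CountTable:
    """Per-sample cassette counts plus unmapped/ambiguous accounting."""

    counts: pd.DataFrame  # index = sample, columns = cassette ids
    unmapped: pd.Series
    ambiguous: pd.Series
    total: pd.Series

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for sample in self.counts.index:
            mapped = int(self.counts.loc[sample].sum())
            lhs = mapped + int(self.unmapped[sample]) + int(self.ambiguous[sample])
            if lhs != int(self.total[sample]):
                raise ValueError(
                    f"count conservation violated for {sample}: "
                    f"{lhs} != {self.total[sample]}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def counts_for(self, sample: str) -> pd.Series:
        return self.counts.loc[sample]

    def mapped_total(self, sample: str) -> int:
        return int(self.counts.loc[sample].sum())

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for sample in self.counts.index:
            for cid, c in self.counts.loc[sample].items():
                rows.append({"sample": sample, "cassette_id": cid, "count": int(c)})
            rows.append({"sample": sample, "cassette_id": UNMAPPED, "count": int(self.unmapped[sample])})
            rows.append({"sample": sample, "cassette_id": AMBIGUOUS, "count": int(self.ambiguous[sample])})
            rows.append({"sample": sample, "cassette_id": TOTAL, "count": int(self.total[sample])})
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "CountTable":
        special = frame["cassette_id"].isin([UNMAPPED, AMBIGUOUS, TOTAL])
        wide = (
            frame[~special]
            .pivot(index="sample", columns="cassette_id", values="count")
            .fillna(0)
            .astype(int)
        )
        wide.columns.name = None
        spec = frame[special].pivot(
            index="sample", columns="cassette_id", values="count"
        )
        return cls(
            counts=wide,
            unmapped=spec[UNMAPPED].astype(int),
            ambiguous=spec[AMBIGUOUS].astype(int),
            total=spec[TOTAL].astype(int),
        )

    @classmethod
    def read_tsv(cls, path) -> "CountTable":
        return cls.from_long_frame(pd.read_csv(path, sep="\t"))


def sequence_identity(read: str, reference: str) -> tuple[float, int]:
    """Percent identity and mismatch count of read vs reference.

    Equal lengths: Hamming comparison over the full length. Unequal lengths:
    global edit distance with indels counted as mismatches, denominator = the
    longer sequence (alignment length of an end-gap-free co-linear
    alignment).
    """
    if len(read) == len(reference):
        mm = sa.hamming(read, reference)
        alen = len(read)
    else:
        mm = edlib.align(read, reference, mode="NW", task="distance")["editDistance"]
        alen = max(len(read), len(reference))
    return 100.0 * (alen - mm) / alen, int(mm)


def _accepted(identity: float, mismatches: int, config: MappingConfig) -> bool:
    if config.mode == "identity_threshold":
        return identity > config.identity_min
    return mismatches <= config.max_mismatches


def map_reads(
    merged_reads: list[tuple[str, str]],
    references: dict[str, str],
    config: MappingConfig = MappingConfig(),
) -> CountTable:
    """Count (sample, sequence) reads against cassette amplicon references.

    The best-scoring reference wins when it passes the configured rule;
    equal-best hits to two or more references are binned as ambiguous.
    """
    if not references:
        raise ValueError("empty reference set")
    ref_ids = sorted(references)
    ref_seqs = [references[r] for r in ref_ids]
    if len(set(ref_seqs)) != len(ref_seqs):
        raise ValueError("reference sequences are not unique")
    ref_len_set = {len(s) for s in ref_seqs}
    common_len = ref_len_set.pop() if len(ref_len_set) == 0 or len(ref_len_set) == 1 else None
    ref_arr = sa.encode_batch(ref_seqs) if common_len else None

    samples = sorted({s for s, _ in merged_reads})
    counts = {s: dict.fromkeys(ref_ids, 0) for s in samples}
    unmapped = dict.fromkeys(samples, 0)
    ambiguous = dict.fromkeys(samples, 0)
    totals = dict.fromkeys(samples, 0)

    # group equal-length reads for vectorized Hamming against the references
    by_len: dict[int, list[tuple[str, str]]] = {}
    for sample, seq in merged_reads:
        totals[sample] += 1
        by_len.setdefault(len(seq), []).append((sample, seq))

    for length, group in by_len.items():
        if common_len is not None and length == common_len:
            _map_group_hamming(group, ref_ids, ref_arr, config, counts, unmapped, ambiguous)
        else:
            for sample, seq in group:
                _map_single(seq, sample, ref_ids, ref_seqs, config, counts, unmapped, ambiguous)

    counts_df = pd.DataFrame.from_dict(counts, orient="index").reindex(
        index=samples, columns=ref_ids
    )
    return CountTable(
        counts=counts_df,
        unmapped=pd.Series(unmapped).reindex(samples),
        ambiguous=pd.Series(ambiguous).reindex(samples),
        total=pd.Series(totals).reindex(samples),
    )


def _map_group_hamming(group, ref_ids, ref_arr, config, counts, unmapped, ambiguous, chunk=256):
    length = ref_arr.shape[1]
    seqs = [seq for _, seq in group]
    samples = [s for s, _ in group]
    arr = sa.encode_batch(seqs)
    for start in range(0, len(group), chunk):
        block = arr[start : start + chunk]
        mm = np.count_nonzero(block[:, None, :] != ref_arr[None, :, :], axis=2)
        best = mm.min(axis=1)
        n_best = np.count_nonzero(mm == best[:, None], axis=1)
        identity = 100.0 * (length - best) / length
        for i in range(block.shape[0]):
            sample = samples[start + i]
            if not _accepted(float(identity[i]), int(best[i]), config):
                unmapped[sample] += 1
            elif n_best[i] > 1:
                ambiguous[sample] += 1
            else:
                counts[sample][ref_ids[int(mm[i].argmin())]] += 1


def _map_single(seq, sample, ref_ids, ref_seqs, config, counts, unmapped, ambiguous):
    scores = [sequence_identity(seq, ref) for ref in ref_seqs]
    mismatches = np.array([mm for _, mm in scores])
    best = int(mismatches.min())
    idx = np.nonzero(mismatches == best)[0]
    identity = scores[idx[0]][0]
    if not _accepted(identity, best, config):
        unmapped[sample] += 1
    elif len(idx) > 1:
        ambiguous[sample] += 1
    else:
        counts[sample][ref_ids[int(idx[0])]] += 1


def editing_efficiency(
    count_table: CountTable, sample: str, mutant_ids
) -> float:
    """Fraction of a sample's reads mapping to mutant (edited) genotypes."""
    mutant_ids = list(mutant_ids)
    unknown = set(mutant_ids) - set(count_table.counts.columns)
    if unknown:
        raise ValueError(f"unknown cassette ids: {sorted(unknown)[:5]}")
    total = int(count_table.total[sample])
    if total == 0:
        warnings.warn(f"sample {sample}: zero total reads; efficiency undefined")
        return float("nan")
    mutant = int(count_table.counts.loc[sample, mutant_ids].sum())
    return mutant / total


def base_change_frequencies(
    merged_sequences: list[str],
    wildtype_reference: str,
    config: MappingConfig = MappingConfig(),
    denominator: str = "perfect",
) -> pd.Series:
    """Per-position substitution frequency against the wild-type sequence.

    Reads with identity >= the wild-type threshold (default 95%) are
    retained; the frequency at each position is the number of retained reads
    substituted there divided by the number of retained reads with perfect
    (100%) identity. That perfect-read denominator can exceed-one by
    construction; `denominator="total"` switches to the conventional
    retained-read denominator. Positions are 1-based; an all-zero denominator
    yields missing values with a warning.
    """
    if not wildtype_reference:
        raise ValueError("empty wild-type reference")
    if denominator not in ("perfect", "total"):
        raise ValueError("denominator must be 'perfect' or 'total'")
    L = len(wildtype_reference)
    ref = sa.encode(wildtype_reference)
    retained = []
    for seq in merged_sequences:
        if len(seq) != L:
            continue  # length-discordant reads cannot be compared base-by-base
        identity, _ = sequence_identity(seq, wildtype_reference)
        if identity >= config.wt_identity_min:
            retained.append(seq)
    index = pd.RangeIndex(1, L + 1, name="position")
    if not retained:
        warnings.warn("no reads retained against the wild-type reference")
        return pd.Series(np.nan, index=index, name="frequency")
    arr = sa.encode_batch(retained)
    sub_counts = np.count_nonzero(arr != ref, axis=0)
    n_perfect = int(np.sum(np.all(arr == ref, axis=1)))
    denom = n_perfect if denominator == "perfect" else len(retained)
    if denom == 0:
        warnings.warn("no reads with perfect identity to the wild type")
        return pd.Series(np.nan, index=index, name="frequency")
    return pd.Series(sub_counts / denom, index=index, name="frequency")


def write_base_change_tsv(freqs: pd.Series, path) -> None:
    freqs.rename("frequency").to_frame().to_csv(path, sep="\t")
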