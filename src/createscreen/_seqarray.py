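"""Vectorized DNA sequence handling on ASCII uint8 arrays.

Reads and references are held as 2-D ``numpy.uint8`` arrays of ASCII codes
(one row per sequence) so that merging, demultiplexing and mapping can be
done with whole-array comparisons instead of per-base Python loops.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMPLEMENT[_a] = _b

DNA_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode one sequence as a 1-D uint8 ASCII array."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def encode_batch(seqs) -> np.ndarray:
    """Encode equal-length sequences as a 2-D array (rows = sequences)."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("encode_batch requires equal-length sequences")
    flat = np.frombuffer("".join(seqs).upper().encode("ascii"), dtype=np.uint8)
    return flat.reshape(len(seqs), lengths.pop()).copy()


def decode(row: np.ndarray) -> str:
    return row.tobytes().decode("ascii")


def decode_batch(arr: np.ndarray) -> list[str]:
    n, width = arr.shape
    flat = arr.tobytes().decode("ascii")
    return [flat[i * width : (i + 1) * width] for i in range(n)]


def revcomp(seq: str) -> str:
    return decode(_COMPLEMENT[encode(seq)][::-1])


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    """Reverse-complement each row of a 2-D array."""
    return _COMPLEMENT[arr][:, ::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(encode(a) != encode(b)))


def write_fastq(path, ids, seqs, quality_char: str = "I") -> None:
    """Write plain-text FASTQ with a constant placeholder quality."""
    with open(path, "w") as fh:
        for rid, seq in zip(ids, seqs):
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> tuple[list[str], list[str]]:
    """Read plain-text FASTQ; returns (ids, sequences). Qualities dropped."""
    ids: list[str] = []
    seqs: list[str] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # '+'
            fh.readline()  # quality
            ids.append(header.strip().lstrip("@").split()[0])
            seqs.append(seq)
    return ids, seqs
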