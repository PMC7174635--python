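"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops over characters and atom pairs, so they can certify the optimized
implementations.
"""

from __future__ import annotations

import math

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp_naive(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming_naive(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y)


def identity_naive(read: str, ref: str) -> float:
    return 100.0 * (len(read) - hamming_naive(read, ref)) / len(read)


def merge_oracle(r1: str, r2: str, min_overlap: int, max_rate: float):
    """Exhaustive shift search: the longest admissible suffix/prefix overlap.

    Returns (merged, overlap, mismatches) or None.
    """
    r2rc = revcomp_naive(r2)
    best = None
    for v in range(min_overlap, min(len(r1), len(r2)) + 1):
        mm = hamming_naive(r1[-v:], r2rc[:v])
        if mm <= max_rate * v:
            best = (r1 + r2rc[v:], v, mm)
    return best


def ligand_proximal_oracle(atoms, radius: float) -> set[int]:
    """All-pairs distance scan over polymer x ligand atoms."""
    ligand = [a for a in atoms if a.is_ligand]
    out = set()
    for a in atoms:
        if a.is_ligand:
            continue
        for l in ligand:
            d = math.dist((a.x, a.y, a.z), (l.x, l.y, l.z))
            if d <= radius:
                out.add(a.residue_index)
                break
    return out


def spacer_oracle(gene_model, residue: int, window: int):
    """Exhaustive scan of both strands for NGG PAMs; nearest-cut selection.

    Returns (spacer, pam, strand, pam_pos, cut) or None, applying the stated
    tie rule: + strand first, then leftmost genomic coordinate of the
    protospacer+PAM span.
    """
    g = gene_model.genomic_sequence
    c0, _ = gene_model.codon_span(residue)
    mid = c0 + 1.5
    candidates = []
    for p in range(len(g) - 2):
        if g[p + 1] == "G" and g[p + 2] == "G" and p >= 20:
            cut = p - 3
            d = abs(cut - mid)
            if d <= window:
                candidates.append((d, 0, p - 20, (g[p - 20 : p], g[p : p + 3], "+", p, cut)))
    for q in range(len(g) - 22):
        if g[q] == "C" and g[q + 1] == "C":
            cut = q + 6
            d = abs(cut - mid)
            if d <= window:
                candidates.append(
                    (
                        d,
                        1,
                        q,
                        (
                            revcomp_naive(g[q + 3 : q + 23]),
                            revcomp_naive(g[q : q + 3]),
                            "-",
                            q,
                            cut,
                        ),
                    )
                )
    if not candidates:
        return None
    candidates.sort(key=lambda t: t[:3])
    return candidates[0][3]


def recut_sites(genome: str, spacer: str) -> int:
    """Count perfect protospacer+NGG matches anywhere on either strand."""
    n = 0
    rc = revcomp_naive(spacer)
    for i in range(len(genome) - 22):
        if genome[i : i + 20] == spacer and genome[i + 21 : i + 23] == "GG":
            n += 1
        if genome[i : i + 2] == "CC" and genome[i + 3 : i + 23] == rc:
            n += 1
    return n
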