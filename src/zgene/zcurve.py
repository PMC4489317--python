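"""Phase-specific Z-curve encoding of ORFs.

The Z transformation maps the four frequencies of a nucleotide position
(fA, fC, fG, fT) onto three axes:

    x = (fA + fG) - (fC + fT)   purine vs pyrimidine
    y = (fA + fC) - (fG + fT)   amino vs keto
    z = (fA + fT) - (fG + fC)   weak vs strong hydrogen bonding

Because the four frequencies of a group sum to a constant, each group of 4
yields 3 independent variables (the 3/4 reduction).  An ORF is described by
phase-specific k-mer statistics, where the phase of a k-mer is the codon
position of its leading base.  Frequencies are conditional within a prefix
group: the quad fed to the Z transform is the distribution of the final
base given the preceding (k-1) bases and the phase.

Feature layout (length 765):

    block     k  phases                     prefix groups  variables
    mono      1  codon positions 1,2,3                 3       9
    di        2  positions 1-2, 2-3, 3-1              12      36
    tri       3  leading base at position 1,2,3       48     144
    tetra     4  leading base at position 1,2,3      192     576

Within a block the order is phase-major, then lexicographic prefix
(A<C<G<T), then (x, y, z).  The legacy 33-variable encoding keeps the mono
block plus the di phases 1-2 and 2-3 only (9 + 24).  The stop codon is
excluded from all counts; k-mer windows containing N are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import ZgeneError

N_FEATURES = 765
N_FEATURES_LEGACY = 33
BLOCK_SIZES = (9, 36, 144, 576)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = 4


@dataclass
class PhaseKmerCounts:
    """Occurrence counts of phase-specific k-mers.

    ``counts[p, m]`` is the number of windows of length k whose leading base
    sits at codon position p+1 and whose k-mer index is m (base-4 over
    A=0, C=1, G=2, T=3).  Windows containing N are excluded.
    """

    k: int
    counts: np.ndarray  # shape (3, 4**k), nonnegative ints

    def phase_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def _encode_codes(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ZgeneError(f"non-nucleotide character {bad!r}")
    return codes


def count_phase_kmers(orf_seq: str, k: int) -> PhaseKmerCounts:
    """Count phase-specific k-mers (k in 1..4) over a codon-aligned sequence.

    The sequence length must be divisible by 3 and at least one window must
    fit (len >= k).  Phase p (0-based) collects windows starting at codon
    position p+1, i.e. at sequence indices congruent to p modulo 3.
    """
    if k not in (1, 2, 3, 4):
        raise ZgeneError(f"k must be 1..4, got {k}")
    if len(orf_seq) % 3:
        raise ZgeneError("ORF length must be divisible by 3")
    if len(orf_seq) < k:
        raise ZgeneError(
            f"sequence of length {len(orf_seq)} shorter than one {k}-mer window"
        )
    codes = _encode_codes(orf_seq)
    return _count_phase_kmers_codes(codes, k)


def _count_phase_kmers_codes(codes: np.ndarray, k: int) -> PhaseKmerCounts:
    n = len(codes)
    counts = np.zeros((3, 4 ** k), dtype=np.int64)
    # window values by horner scheme over the whole sequence
    if n >= k:
        vals = codes[: n - k + 1].astype(np.int64)
        valid = codes[: n - k + 1] < 4
        for j in range(1, k):
            nxt = codes[j : n - k + 1 + j]
            vals = vals * 4 + np.minimum(nxt, 3).astype(np.int64)
            valid &= nxt < 4
        for p in range(3):
            idx = np.arange(p, n - k + 1, 3)
            v = vals[idx][valid[idx]]
            counts[p] = np.bincount(v, minlength=4 ** k)
    return PhaseKmerCounts(k=k, counts=counts)


def z_transform(freq_quad) -> tuple[float, float, float]:
    """Map four suffix-base frequencies (A, C, G, T) to (x, y, z)."""
    fa, fc, fg, ft = (float(v) for v in freq_quad)
    if min(fa, fc, fg, ft) < 0:
        raise ZgeneError("frequencies must be nonnegative")
    x = (fa + fg) - (fc + ft)
    y = (fa + fc) - (fg + ft)
    z = (fa + ft) - (fg + fc)
    return (x, y, z)


def _z_block(counts: np.ndarray, k: int, phases=(0, 1, 2)) -> np.ndarray:
    """Z variables for one k, conditional within prefix groups.

    ``counts`` has shape (3, 4**k); the result is phase-major, prefix
    lexicographic, (x, y, z) innermost: 3 * 4**(k-1) * |phases| values.
    Zero-occurrence prefix groups emit (0, 0, 0).
    """
    out = []
    for p in phases:
        quads = counts[p].reshape(4 ** (k - 1), 4).astype(float)
        totals = quads.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, quads / np.where(totals > 0, totals, 1), 0.0)
        fa, fc, fg, ft = freq[:, 0], freq[:, 1], freq[:, 2], freq[:, 3]
        xyz = np.stack(
            [(fa + fg) - (fc + ft), (fa + fc) - (fg + ft), (fa + ft) - (fg + fc)],
            axis=1,
        )
        out.append(xyz.ravel())
    return np.concatenate(out)


def encode_orf(orf_seq: str, drop_stop: bool = True) -> np.ndarray:
    """765-variable Z-curve feature vector of one ORF.

    The trailing stop codon is excluded by default (its composition is the
    same for every ORF and carries no signal).
    """
    body = orf_seq[:-3] if drop_stop else orf_seq
    if len(body) % 3 or len(body) < 12:
        raise ZgeneError(
            f"ORF body of length {len(body)} too short to encode (need >= 12 nt)"
        )
    codes = _encode_codes(body)
    blocks = [
        _z_block(_count_phase_kmers_codes(codes, k).counts, k) for k in (1, 2, 3, 4)
    ]
    vec = np.concatenate(blocks)
    assert vec.shape == (N_FEATURES,)
    return vec


def encode_orf_legacy(orf_seq: str, drop_stop: bool = True) -> np.ndarray:
    """Legacy 33-variable encoding: mono + dinucleotides at positions 1-2
    and 2-3 (9 + 24)."""
    body = orf_seq[:-3] if drop_stop else orf_seq
    if len(body) % 3 or len(body) < 6:
        raise ZgeneError(
            f"ORF body of length {len(body)} too short to encode (need >= 6 nt)"
        )
    codes = _encode_codes(body)
    mono = _z_block(_count_phase_kmers_codes(codes, 1).counts, 1)
    di = _z_block(_count_phase_kmers_codes(codes, 2).counts, 2, phases=(0, 1))
    vec = np.concatenate([mono, di])
    assert vec.shape == (N_FEATURES_LEGACY,)
    return vec


def encode_many(seqs, legacy: bool = False) -> np.ndarray:
    """Stack encodings of many ORF sequences into a (n, d) matrix."""
    enc = encode_orf_legacy if legacy else encode_orf
    if not seqs:
        return np.empty((0, N_FEATURES_LEGACY if legacy else N_FEATURES))
    return np.stack([enc(s) for s in seqs])


def export_feature_tsv(path, ids, matrix: np.ndarray) -> None:
    """Write a feature matrix as TSV: one row per ORF, id + d columns."""
    with open(path, "w") as fh:
        fh.write("orf_id\t" + "\t".join(f"f{i}" for i in range(matrix.shape[1])) + "\n")
        for oid, row in zip(ids, matrix):
            fh.write(oid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
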