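"""Candidate open-reading-frame enumeration in all six frames.

An ORF candidate runs from an allowed start codon to the first in-frame stop
codon (inclusive), with no internal in-frame stop.  For each stop codon the
*canonical* candidate uses the longest compatible start; every alternative
in-frame start between the previous stop and the canonical start is retained
as a candidate start list, so the translation-start relocator can choose
among them later.  Circular contigs are scanned as a doubled sequence and
origin-spanning ORFs are de-duplicated by their stop position modulo the
contig length.

Coordinates are 0-based half-open on the forward strand; for a minus-strand
ORF, ``seq`` is the reverse complement of the genomic slice and still begins
with the start codon.  For an origin-wrapping ORF, ``end`` exceeds the
contig length (interpret modulo the length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import GenomeSequence, ZgeneError

DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")
DEFAULT_STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_MIN_LEN = 90  # nt, stop codon included

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; errors on anything else."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ZgeneError(f"non-nucleotide character(s) {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class OrfCandidate:
    contig_id: str
    strand: str            # '+' or '-'
    start: int             # 0-based inclusive, forward-strand coords
    end: int               # 0-based exclusive (may exceed contig length if wraps)
    frame: int             # {0,1,2} on its own strand
    seq: str               # oriented sequence, start codon .. stop codon
    alt_start_offsets: list[int] = field(default_factory=lambda: [0])
    wraps: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def stop_coord_1based(self, contig_len: int | None = None) -> int:
        """1-based coordinate of the 3' terminus (strand-aware)."""
        if self.strand == "+":
            pos = self.end
        else:
            pos = self.start + 1
        if self.wraps and contig_len:
            pos = (pos - 1) % contig_len + 1
        return pos


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ZgeneError(f"non-nucleotide character {bad!r} in sequence")
    return codes


def _codon_values(codes: np.ndarray, frame: int) -> np.ndarray:
    n = (len(codes) - frame) // 3
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = codes[frame : frame + 3 * n].reshape(n, 3).astype(np.int64)
    vals = c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]
    vals[(c >= 4).any(axis=1)] = 64  # codons containing N are inert
    return vals


def _codon_set_values(codons) -> np.ndarray:
    out = []
    for c in codons:
        c = c.upper()
        if len(c) != 3 or set(c) - set("ACGT"):
            raise ZgeneError(f"invalid codon {c!r}")
        out.append(_CODE[ord(c[0])] * 16 + _CODE[ord(c[1])] * 4 + _CODE[ord(c[2])])
    return np.asarray(out, dtype=np.int64)


def _scan_strand(
    codes: np.ndarray,
    min_len: int,
    start_vals: np.ndarray,
    stop_vals: np.ndarray,
    all_starts: bool,
):
    """Yield (start_nt, end_nt, frame, alt_offsets) on one strand.

    Coordinates are relative to ``codes`` in its own orientation.
    """
    for frame in (0, 1, 2):
        vals = _codon_values(codes, frame)
        is_stop = np.isin(vals, stop_vals)
        is_start = np.isin(vals, start_vals)
        stop_idx = np.flatnonzero(is_stop)
        start_idx = np.flatnonzero(is_start)
        prev = -1
        for s in stop_idx:
            lo = np.searchsorted(start_idx, prev + 1)
            hi = np.searchsorted(start_idx, s)
            cands = start_idx[lo:hi]
            if cands.size:
                end_nt = frame + 3 * (int(s) + 1)
                if all_starts:
                    for c in cands:
                        start_nt = frame + 3 * int(c)
                        if end_nt - start_nt >= min_len:
                            yield start_nt, end_nt, frame, [0]
                else:
                    first = int(cands[0])
                    start_nt = frame + 3 * first
                    if end_nt - start_nt >= min_len:
                        offsets = [3 * (int(c) - first) for c in cands]
                        yield start_nt, end_nt, frame, offsets
            prev = int(s)


def extract_orfs(
    genome: GenomeSequence,
    min_len: int = DEFAULT_MIN_LEN,
    start_codons=DEFAULT_START_CODONS,
    stop_codons=DEFAULT_STOP_CODONS,
    all_starts: bool = False,
) -> list[OrfCandidate]:
    """Enumerate ORF candidates on both strands of one contig.

    With ``all_starts=False`` (default) one canonical candidate per stop is
    returned, carrying every compatible in-frame start as
    ``alt_start_offsets`` (offsets into ``seq``, ascending, first is 0).
    With ``all_starts=True`` every (start, stop) pair is emitted.  Circular
    contigs include origin-wrapping ORFs.  Ordering is deterministic by
    (contig, strand, end, start).
    """
    if min_len < 6 or min_len % 3:
        raise ZgeneError("min_len must be >= 6 and divisible by 3")
    start_vals = _codon_set_values(start_codons)
    stop_vals = _codon_set_values(stop_codons)

    L = len(genome)
    if genome.circular:
        scan_seq = genome.seq * 2
    else:
        scan_seq = genome.seq
    codes_f = _encode(scan_seq)
    # reverse complement codes (N stays N)
    codes_r = codes_f[::-1].copy()
    m = codes_r < 4
    codes_r[m] = 3 - codes_r[m]
    SL = len(scan_seq)

    raw: list[OrfCandidate] = []
    for strand, codes in (("+", codes_f), ("-", codes_r)):
        for start_nt, end_nt, frame, offsets in _scan_strand(
            codes, min_len, start_vals, stop_vals, all_starts
        ):
            if strand == "+":
                fstart, fend = start_nt, end_nt
            else:
                fstart, fend = SL - end_nt, SL - start_nt
            seq = scan_seq[fstart:fend]
            if strand == "-":
                seq = reverse_complement(seq)
            raw.append(
                OrfCandidate(
                    contig_id=genome.id, strand=strand, start=fstart,
                    end=fend, frame=frame, seq=seq,
                    alt_start_offsets=offsets,
                )
            )

    if not genome.circular:
        out = raw
    else:
        # De-duplicate by circular stop position; keep the longest version
        # of each ORF, shifted so that start < L.
        best: dict[tuple, OrfCandidate] = {}
        for orf in raw:
            if orf.length > L:
                continue
            if orf.strand == "+":
                stop_mod = orf.end % L  # position one past the stop codon
            else:
                stop_mod = orf.start % L
            key = (orf.strand, stop_mod)
            prev = best.get(key)
            if prev is None or orf.length > prev.length or (
                orf.length == prev.length and orf.start < prev.start
            ):
                best[key] = orf
        out = []
        for orf in best.values():
            if orf.start >= L:
                orf.start -= L
                orf.end -= L
            if orf.end > L:
                orf.wraps = True
            out.append(orf)

    out.sort(key=lambda o: (o.contig_id, o.strand, o.end, o.start))
    return out


def wrap_orfs(
    genome: GenomeSequence,
    min_len: int = DEFAULT_MIN_LEN,
    start_codons=DEFAULT_START_CODONS,
    stop_codons=DEFAULT_STOP_CODONS,
) -> list[OrfCandidate]:
    """Only the origin-spanning ORFs of a circular contig."""
    if not genome.circular:
        raise ZgeneError("wrap_orfs requires a circular contig")
    return [
        o
        for o in extract_orfs(genome, min_len, start_codons, stop_codons)
        if o.wraps
    ]


def orfs_for_genomes(genomes, **kwargs) -> list[OrfCandidate]:
    """Concatenate :func:`extract_orfs` over a genome set."""
    out: list[OrfCandidate] = []
    for g in genomes:
        out.extend(extract_orfs(g, **kwargs))
    return out
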