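"""End-to-end gene calling: ORF enumeration -> encoding -> self-trained
scoring -> overlap resolution -> translation-start relocation.

The start relocator is a simplified ribosome-binding-site scorer: among the
in-frame candidate starts of a retained gene it maximizes

    coding_score(truncated ORF) + lambda * SD_score

where SD_score is the best ungapped identity count of the Shine-Dalgarno
motif (AGGAGG by default) within a 5-13 nt spacer window upstream of the
candidate start.  The 3' terminus never changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import classifier as clf
from . import orf_model, zcurve
from .orf_model import OrfCandidate
from .sequence_io import GenomeSequence, ZgeneError

logger = logging.getLogger(__name__)


@dataclass
class CallerConfig:
    min_orf_len: int = orf_model.DEFAULT_MIN_LEN
    start_codons: tuple = orf_model.DEFAULT_START_CODONS
    stop_codons: tuple = orf_model.DEFAULT_STOP_CODONS
    seed_min_len: int = clf.DEFAULT_SEED_MIN_LEN
    min_positives: int = clf.DEFAULT_MIN_POSITIVES
    negative_policy: tuple = ("shuffled", "shadow")
    regularization: float = clf.DEFAULT_C
    threshold: float = 0.0
    null_z_min: float = 3.0      # min z vs the length-resolved null score
    max_overlap_nt: int = 30
    self_train_iterations: int = 1
    confidence_margin: float = 1.0
    sd_motif: str = "AGGAGG"
    sd_weight: float = 0.25      # lambda; SD and coding terms comparable spread
    sd_spacer: tuple = (5, 13)   # nt between motif 3' end and start codon
    max_start_candidates: int = 20
    relocate_starts: bool = True
    legacy: bool = False         # 33-variable encoding instead of 765
    seed: int = 42

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class GenePrediction:
    """A called gene in output convention (1-based inclusive)."""

    contig_id: str
    strand: str
    start: int
    end: int
    frame: int
    coding_score: float
    start_relocated: bool = False
    essentiality_score: float | None = None
    essentiality_call: bool | None = None
    gene_id: str = ""
    wraps: bool = False
    contig_len: int | None = None

    @property
    def length(self) -> int:
        if self.wraps and self.contig_len:
            return self.contig_len - self.start + 1 + self.end
        return self.end - self.start + 1

    @property
    def stop_coord(self) -> int:
        """1-based coordinate of the 3' terminus (end on +, start on -)."""
        return self.end if self.strand == "+" else self.start


def _orf_to_prediction(orf: OrfCandidate, score: float, contig_len: int) -> GenePrediction:
    start1 = orf.start + 1
    end1 = orf.end
    wraps = orf.wraps
    if wraps:
        end1 = (orf.end - 1) % contig_len + 1
    return GenePrediction(
        contig_id=orf.contig_id, strand=orf.strand, start=start1, end=end1,
        frame=orf.frame, coding_score=score, wraps=wraps, contig_len=contig_len,
    )


# ---------------------------------------------------------------------------
# Overlap resolution
# ---------------------------------------------------------------------------

def _select_max_weight(items, cap: int):
    """Exact maximum-total-score subset of linear candidates under the
    pairwise overlap cap.

    Two candidates conflict iff they overlap by more than ``cap``;
    equivalently their intervals shrunk by cap/2 on each side overlap, so
    the conflict graph is an interval graph and the maximum-weight
    independent set is found by the classic endpoint dynamic program.
    Returns indices into ``items``.  Ties prefer inclusion.
    """
    import bisect

    n = len(items)
    # doubled coordinates keep the half-cap shrink integral
    order = sorted(
        range(n),
        key=lambda i: (2 * items[i][0].end - cap, 2 * items[i][0].start + cap, i),
    )
    b = [2 * items[order[k]][0].end - cap for k in range(n)]
    a = [2 * items[order[k]][0].start + cap for k in range(n)]
    w = [items[order[k]][1] for k in range(n)]
    f = [0.0] * (n + 1)
    take = [False] * n
    pred = [0] * n
    for k in range(n):
        p = bisect.bisect_right(b, a[k], 0, k)
        with_k = w[k] + f[p]
        if with_k >= f[k] - 1e-12:
            f[k + 1] = max(with_k, f[k])
            take[k] = True
            pred[k] = p
        else:
            f[k + 1] = f[k]
    chosen = []
    k = n
    while k > 0:
        if take[k - 1]:
            chosen.append(order[k - 1])
            k = pred[k - 1]
        else:
            k -= 1
    return chosen


def _wrap_overlap(worf, other, L: int) -> int:
    """Overlap between an origin-wrapping candidate and any candidate, in
    forward coordinates modulo L."""
    segs = [(worf.start, min(worf.end, L)), (0, worf.end - L)]
    osegs = (
        [(other.start, min(other.end, L)), (0, max(other.end - L, 0))]
        if other.end > L
        else [(other.start, other.end)]
    )
    return sum(
        clf._interval_overlap(a, b, c, d) for a, b in segs for c, d in osegs
    )


def resolve_overlaps(scored_orfs, max_overlap_nt: int = 30, contig_lengths=None):
    """Retain the maximum-total-score set of candidates such that no two
    overlap by more than ``max_overlap_nt`` on either strand.

    Linear candidates are solved exactly per contig (interval-graph dynamic
    program); origin-wrapping candidates of circular contigs are then added
    in descending score order when compatible.  Deterministic; score ties
    prefer the longer, then leftmost candidate.
    """
    contig_lengths = contig_lengths or {}
    by_contig: dict[str, list] = {}
    for orf, sc in scored_orfs:
        by_contig.setdefault(orf.contig_id, []).append((orf, sc))
    retained = []
    for contig in sorted(by_contig):
        items = by_contig[contig]
        linear = [t for t in items if not t[0].wraps]
        wraps = [t for t in items if t[0].wraps]
        chosen = [linear[i] for i in _select_max_weight(linear, max_overlap_nt)]
        L = contig_lengths.get(contig)
        wraps.sort(key=lambda t: (-t[1], -t[0].length, t[0].start, t[0].strand))
        for worf, wsc in wraps:
            if L is None:
                ok = all(
                    clf._interval_overlap(worf.start, worf.end, o.start, o.end)
                    <= max_overlap_nt
                    for o, _ in chosen
                )
            else:
                ok = all(
                    _wrap_overlap(worf, o, L) <= max_overlap_nt for o, _ in chosen
                )
            if ok:
                chosen.append((worf, wsc))
        retained.extend(chosen)
    retained.sort(key=lambda t: (-t[1], -t[0].length, t[0].start, t[0].strand))
    return retained


# ---------------------------------------------------------------------------
# Start relocation
# ---------------------------------------------------------------------------

def sd_match_score(genome: GenomeSequence, orf: OrfCandidate, offset: int,
                   motif: str, spacer: tuple[int, int]) -> int:
    """Best ungapped identity count of ``motif`` upstream of the candidate
    start at ``offset`` nt into the ORF, over the allowed spacer range."""
    m = len(motif)
    L = len(genome)
    best = 0
    if orf.strand == "+":
        start_pos = orf.start + offset  # forward coord of candidate start
        for sp in range(spacer[0], spacer[1] + 1):
            lo = start_pos - sp - m
            if lo < 0:
                if not genome.circular:
                    continue
                lo += L
            window = genome.slice(lo, lo + m) if lo + m <= L or genome.circular else None
            if window is None or len(window) < m:
                continue
            best = max(best, sum(a == b for a, b in zip(window, motif)))
    else:
        # candidate start codon occupies forward [end-offset-3, end-offset);
        # upstream (5') lies at larger forward coordinates, reverse strand.
        end_pos = orf.end - offset
        rc_motif = orf_model.reverse_complement(motif)
        for sp in range(spacer[0], spacer[1] + 1):
            lo = end_pos + sp
            hi = lo + m
            if hi > L:
                if not genome.circular:
                    continue
            if lo >= L:
                lo -= L
                hi -= L
            window = genome.slice(lo, hi)
            if len(window) < m:
                continue
            best = max(best, sum(a == b for a, b in zip(window, rc_motif)))
    return best


def relocate_start(
    prediction: GenePrediction,
    orf: OrfCandidate,
    genome: GenomeSequence,
    model: clf.LinearModel,
    config: CallerConfig,
) -> GenePrediction:
    """Choose the candidate start maximizing coding + SD score.

    The 3' terminus is untouched; with a single candidate the prediction is
    returned unchanged.  Falls back to the canonical (longest) start when no
    candidate can be scored.
    """
    offsets = sorted(orf.alt_start_offsets)[: config.max_start_candidates]
    if len(offsets) <= 1:
        return prediction
    encode = zcurve.encode_orf_legacy if config.legacy else zcurve.encode_orf
    best_offset, best_val = None, -np.inf
    for off in offsets:
        sub = orf.seq[off:]
        if len(sub) < config.min_orf_len:
            continue
        try:
            coding = clf.score(model, encode(sub))
        except ZgeneError:
            continue
        sd = sd_match_score(genome, orf, off, config.sd_motif, config.sd_spacer)
        val = coding + config.sd_weight * sd
        if val > best_val + 1e-12:
            best_offset, best_val = off, val
    if best_offset is None or best_offset == 0:
        return prediction
    if orf.strand == "+":
        new_start = prediction.start + best_offset
        return replace(prediction, start=new_start, start_relocated=True)
    new_end = prediction.end - best_offset
    return replace(prediction, end=new_end, start_relocated=True)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def train_model(genomes, config: CallerConfig,
                orfs: list[OrfCandidate] | None = None,
                encodings: np.ndarray | None = None) -> clf.LinearModel:
    """Self-train the genome-specific linear model for a genome set."""
    if orfs is None:
        orfs = orf_model.orfs_for_genomes(
            genomes, min_len=config.min_orf_len,
            start_codons=config.start_codons, stop_codons=config.stop_codons,
        )
    sets = clf.build_training_sets(
        orfs,
        seed_min_len=config.seed_min_len,
        negative_policy=config.negative_policy,
        min_positives=config.min_positives,
        max_overlap_nt=config.max_overlap_nt,
        legacy=config.legacy,
        seed=config.seed,
    )
    model = clf.train(
        sets, regularization=config.regularization,
        threshold=config.threshold, seed=config.seed,
    )
    if config.self_train_iterations > 0:
        if encodings is None:
            encodings = zcurve.encode_many([o.seq for o in orfs], legacy=config.legacy)
        model = clf.retrain_iteration(
            model, encodings,
            confidence_margin=config.confidence_margin,
            iterations=config.self_train_iterations,
            regularization=config.regularization,
            seed=config.seed,
        )
    length_pool = [o.length for o in orfs if o.length < config.seed_min_len]
    if sets.positive_orfs and length_pool:
        model.calibration = clf.fit_null_calibration(
            model,
            [o.seq for o in sets.positive_orfs],
            length_pool,
            seed=config.seed,
            legacy=config.legacy,
        )
    return model


def predict_genes(
    genomes,
    config: CallerConfig | None = None,
    model: clf.LinearModel | None = None,
) -> list[GenePrediction]:
    """Run the full calling pipeline over a genome set.

    Deterministic given config + seed.  Predictions are sorted by
    (contig, start) and satisfy: length divisible by 3, stop codon at the
    3' terminus, coding score above the decision threshold.
    """
    config = config or CallerConfig()
    by_contig = {g.id: g for g in genomes}
    orfs = orf_model.orfs_for_genomes(
        genomes, min_len=config.min_orf_len,
        start_codons=config.start_codons, stop_codons=config.stop_codons,
    )
    if not orfs:
        return []
    encodings = zcurve.encode_many([o.seq for o in orfs], legacy=config.legacy)
    if model is None:
        model = train_model(genomes, config, orfs=orfs, encodings=encodings)
    scores = clf.score_matrix(model, encodings)
    if model.calibration is not None:
        zs = clf.calibrated_scores(model, encodings, [o.length for o in orfs])
    else:
        zs = np.full(len(orfs), np.inf)

    passed = [
        (o, float(s))
        for o, s, z in zip(orfs, scores, zs)
        if s > config.threshold and z > config.null_z_min
    ]
    retained = resolve_overlaps(
        passed, config.max_overlap_nt,
        contig_lengths={g.id: len(g) for g in genomes},
    )

    predictions: list[GenePrediction] = []
    for orf, sc in retained:
        genome = by_contig[orf.contig_id]
        pred = _orf_to_prediction(orf, sc, len(genome))
        if config.relocate_starts:
            pred = relocate_start(pred, orf, genome, model, config)
        predictions.append(pred)
    predictions.sort(key=lambda p: (p.contig_id, p.start, p.end, p.strand))
    for i, p in enumerate(predictions, start=1):
        p.gene_id = f"{p.contig_id}_g{i:05d}"
    logger.info("called %d genes from %d ORF candidates", len(predictions), len(orfs))
    return predictions
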