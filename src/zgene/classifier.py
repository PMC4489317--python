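"""Genome-specific self-trained linear coding/non-coding classifier.

No external labels are used.  Positive seeds are long ORFs (random ORFs of
that length are vanishingly rare under a null composition model); negatives
are nucleotide-order shuffles of the positives (identical base composition,
phase structure destroyed) plus opposite-strand shadow ORFs.  A max-margin
linear decision function is then fitted on the Z-curve features; an
optional self-training refinement pass relabels by confident scores and
refits.

Feature standardization (zero mean / unit variance on the training data) is
folded into the stored weights, so scoring is a plain dot product
``w . v + b`` and serialized models reproduce scores exactly.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import LinearSVC

from .orf_model import OrfCandidate
from .sequence_io import ZgeneError
from . import zcurve

logger = logging.getLogger(__name__)

DEFAULT_SEED_MIN_LEN = 480   # nt; the classic long-ORF seeding heuristic
DEFAULT_MIN_POSITIVES = 50
DEFAULT_C = 1.0

MODEL_FORMAT_VERSION = 1


@dataclass
class NullCalibration:
    """Length-resolved null model of the raw score.

    Under the no-signal null (shuffled sequence of the same composition)
    the raw score of an ORF of length L has mean mu(L) = a0 + a1/sqrt(L)
    and standard deviation sd(L) = b0 + b1/sqrt(L); the calibrated score
    (raw - mu) / sd is a z value against that null, so thresholding it
    controls the expected number of false calls per genome regardless of
    ORF length.
    """

    mu_coef: tuple[float, float]
    sd_coef: tuple[float, float]

    def mu(self, length: int) -> float:
        return self.mu_coef[0] + self.mu_coef[1] / math.sqrt(length)

    def sd(self, length: int) -> float:
        return max(self.sd_coef[0] + self.sd_coef[1] / math.sqrt(length), 1e-9)

    def z(self, raw_score, length):
        return (raw_score - self.mu(length)) / self.sd(length)


@dataclass
class LinearModel:
    """Linear decision function f(v) = w . v + b with a decision cutoff."""

    weights: np.ndarray
    bias: float
    threshold: float = 0.0
    calibration: NullCalibration | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "zgene-linear-model",
            "version": MODEL_FORMAT_VERSION,
            "n_features": self.n_features,
            "weights": [float(w) for w in self.weights],
            "bias": float(self.bias),
            "threshold": float(self.threshold),
        }
        if self.calibration is not None:
            payload["calibration"] = {
                "mu_coef": list(self.calibration.mu_coef),
                "sd_coef": list(self.calibration.sd_coef),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "LinearModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "zgene-linear-model":
            raise ZgeneError(f"{path}: not a zgene model file")
        calib = None
        if "calibration" in payload:
            calib = NullCalibration(
                mu_coef=tuple(payload["calibration"]["mu_coef"]),
                sd_coef=tuple(payload["calibration"]["sd_coef"]),
            )
        return cls(
            weights=np.array(payload["weights"], dtype=float),
            bias=payload["bias"],
            threshold=payload["threshold"],
            calibration=calib,
        )


@dataclass
class TrainingSets:
    positives: np.ndarray                 # (n_pos, d)
    negatives: np.ndarray                 # (n_neg, d)
    positive_orfs: list[OrfCandidate] = field(default_factory=list)
    positive_tags: list[str] = field(default_factory=list)
    negative_tags: list[str] = field(default_factory=list)

    @property
    def provenance(self) -> list[str]:
        """Per-sample origin tags, positives first then negatives."""
        return list(self.positive_tags) + list(self.negative_tags)


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Nucleotide-order shuffle of the coding body; the stop codon stays in
    place so the full sequence keeps its base composition and remains
    codon-aligned."""
    body = list(seq[:-3])
    rng.shuffle(body)
    return "".join(body) + seq[-3:]


def _interval_overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def build_training_sets(
    orfs: list[OrfCandidate],
    seed_min_len: int = DEFAULT_SEED_MIN_LEN,
    negative_policy=("shuffled", "shadow"),
    min_positives: int = DEFAULT_MIN_POSITIVES,
    max_overlap_nt: int = 30,
    legacy: bool = False,
    seed: int = 0,
) -> TrainingSets:
    """Self-training sets from a genome's own ORF candidates.

    Positives: canonical ORFs with length >= ``seed_min_len`` that do not
    overlap a longer candidate by more than ``max_overlap_nt``.  Negatives
    per policy: ``shuffled`` (nucleotide-order shuffles of each positive)
    and/or ``shadow`` (opposite-strand ORFs overlapping a positive).
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    long_orfs = sorted(
        (o for o in orfs if o.length >= seed_min_len),
        key=lambda o: (-o.length, o.contig_id, o.start),
    )
    # drop long ORFs dominated by a longer overlapping candidate
    kept: list[OrfCandidate] = []
    for o in long_orfs:
        dominated = any(
            k.contig_id == o.contig_id
            and _interval_overlap(o.start, o.end, k.start, k.end) > max_overlap_nt
            for k in kept
        )
        if not dominated:
            kept.append(o)
    if len(kept) < min_positives:
        raise ZgeneError(
            f"only {len(kept)} seed positives at seed_min_len={seed_min_len}; "
            f"need >= {min_positives}. Relax seed_min_len for this genome."
        )
    kept.sort(key=lambda o: (o.contig_id, o.start))

    pos_seqs = [o.seq for o in kept]
    pos_keys = {(o.contig_id, o.strand, o.end) for o in kept}

    neg_seqs: list[str] = []
    neg_tags: list[str] = []
    if "shuffled" in negative_policy:
        for s in pos_seqs:
            neg_seqs.append(shuffle_sequence(s, rng))
            neg_tags.append("shuffled")
        # shuffles truncated to the length distribution of sub-seed
        # candidates, so the boundary accounts for the higher feature
        # variance of short ORFs
        length_pool = [o.length for o in orfs if o.length < seed_min_len]
        if length_pool:
            for _ in range(2 * len(pos_seqs)):
                src = pos_seqs[int(rng.integers(len(pos_seqs)))]
                L = int(length_pool[int(rng.integers(len(length_pool)))])
                L = max(15, L - L % 3)
                neg_seqs.append(shuffle_sequence(src, rng)[:L])
                neg_tags.append("shuffled")
    if "shadow" in negative_policy:
        shadows = []
        for o in orfs:
            if (o.contig_id, o.strand, o.end) in pos_keys:
                continue
            for p in kept:
                if p.contig_id != o.contig_id or p.strand == o.strand:
                    continue
                ov = _interval_overlap(o.start, o.end, p.start, p.end)
                if ov >= 0.6 * o.length:
                    shadows.append(o)
                    break
        shadows.sort(key=lambda o: (-o.length, o.contig_id, o.start))
        for o in shadows[: len(pos_seqs)]:
            neg_seqs.append(o.seq)
            neg_tags.append("shadow")
    if not neg_seqs:
        raise ZgeneError(f"negative policy {negative_policy!r} produced no negatives")

    return TrainingSets(
        positives=zcurve.encode_many(pos_seqs, legacy=legacy),
        negatives=zcurve.encode_many(neg_seqs, legacy=legacy),
        positive_orfs=kept,
        positive_tags=["long_orf"] * len(kept),
        negative_tags=neg_tags,
    )


def train(
    sets: TrainingSets,
    regularization: float = DEFAULT_C,
    threshold: float = 0.0,
    seed: int = 0,
) -> LinearModel:
    """Fit a max-margin linear decision function on the training sets.

    Standardization parameters computed on the training data are folded into
    the returned weights and bias, so ``score`` is linear in the raw
    features.
    """
    X_pos, X_neg = sets.positives, sets.negatives
    if len(X_pos) == 0 or len(X_neg) == 0:
        raise ZgeneError("both classes must be non-empty")
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(X_pos)), -np.ones(len(X_neg))])
    std = X.std(axis=0)
    if not np.any(std > 1e-12):
        raise ZgeneError("degenerate training data: all features constant")
    mean = X.mean(axis=0)
    scale = np.where(std > 1e-12, std, 1.0)
    Xs = (X - mean) / scale

    svc = LinearSVC(
        C=regularization,
        loss="squared_hinge",
        dual=True,
        tol=1e-5,
        max_iter=50_000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter
        svc.fit(Xs, y)
    w_s = svc.coef_.ravel()
    b_s = float(svc.intercept_[0])
    # fold standardization into the linear form
    w = w_s / scale
    b = b_s - float(np.dot(w_s, mean / scale))

    model = LinearModel(weights=w, bias=b, threshold=threshold)
    acc = float(np.mean(np.sign(score_matrix(model, X) - 1e-300) == y))
    logger.info(
        "trained linear model: %d pos, %d neg, training separation %.4f",
        len(X_pos), len(X_neg), acc,
    )
    return model


def score(model: LinearModel, vector: np.ndarray) -> float:
    """Signed decision value w . v + b for one feature vector."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (model.n_features,):
        raise ZgeneError(
            f"feature dimension {vector.shape} does not match model "
            f"({model.n_features},)"
        )
    return float(np.dot(model.weights, vector) + model.bias)


def score_matrix(model: LinearModel, matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] != model.n_features:
        raise ZgeneError("feature dimension mismatch")
    return matrix @ model.weights + model.bias


def fit_null_calibration(
    model: LinearModel,
    source_seqs: list[str],
    length_pool,
    n_samples: int = 600,
    seed: int = 0,
    legacy: bool = False,
) -> NullCalibration:
    """Fit the length-resolved null score model from shuffled sequences.

    Null draws are nucleotide-order shuffles of the seed positives
    truncated to lengths sampled from the candidate-length pool; mean and
    spread are regressed on 1/sqrt(L).  The spread uses the absolute
    residual scaled to a Gaussian sd.
    """
    rng = np.random.default_rng(seed)
    length_pool = [int(x) for x in length_pool]
    if not source_seqs or not length_pool:
        raise ZgeneError("null calibration needs source sequences and lengths")
    seqs, lens = [], []
    for _ in range(n_samples):
        src = source_seqs[int(rng.integers(len(source_seqs)))]
        L = length_pool[int(rng.integers(len(length_pool)))]
        L = min(max(15, L - L % 3), len(src))
        seqs.append(shuffle_sequence(src, rng)[:L])
        lens.append(L)
    scores = score_matrix(model, zcurve.encode_many(seqs, legacy=legacy))
    x = 1.0 / np.sqrt(np.asarray(lens, dtype=float))
    A = np.vstack([np.ones_like(x), x]).T
    mu_coef, *_ = np.linalg.lstsq(A, scores, rcond=None)
    resid = scores - A @ mu_coef
    sd_coef, *_ = np.linalg.lstsq(A, np.abs(resid) * math.sqrt(math.pi / 2), rcond=None)
    return NullCalibration(
        mu_coef=(float(mu_coef[0]), float(mu_coef[1])),
        sd_coef=(float(sd_coef[0]), float(sd_coef[1])),
    )


def calibrated_scores(model: LinearModel, matrix: np.ndarray, lengths) -> np.ndarray:
    """Null z values of raw scores; requires a fitted calibration."""
    if model.calibration is None:
        raise ZgeneError("model has no null calibration")
    raw = score_matrix(model, matrix)
    lengths = np.asarray(lengths, dtype=float)
    mu = model.calibration.mu_coef[0] + model.calibration.mu_coef[1] / np.sqrt(lengths)
    sd = np.maximum(
        model.calibration.sd_coef[0] + model.calibration.sd_coef[1] / np.sqrt(lengths),
        1e-9,
    )
    return (raw - mu) / sd


def retrain_iteration(
    model: LinearModel,
    encodings: np.ndarray,
    confidence_margin: float = 1.0,
    iterations: int = 1,
    regularization: float = DEFAULT_C,
    seed: int = 0,
) -> LinearModel:
    """Self-training refinement: confident predictions become the new
    training sets and the model is refitted.

    If either refined class is empty the previous model is kept with a
    warning.  ``iterations=0`` is the identity.
    """
    current = model
    for _ in range(iterations):
        scores = score_matrix(current, encodings)
        pos = encodings[scores > confidence_margin]
        neg = encodings[scores < -confidence_margin]
        if len(pos) == 0 or len(neg) == 0:
            warnings.warn(
                "self-training iteration collapsed to a single class; "
                "keeping previous model",
                stacklevel=2,
            )
            return current
        current = train(
            TrainingSets(positives=pos, negatives=neg),
            regularization=regularization,
            threshold=current.threshold,
            seed=seed,
        )
    return current
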