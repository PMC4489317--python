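"""Benchmark statistics for coding and essentiality predictions.

Coding predictions are matched to the reference annotation by the 3'-terminus
rule: a prediction is correct iff it shares the annotated gene's stop-codon
terminus (contig, strand, stop coordinate), regardless of the start.  From
the matched counts:

    Sn       = correct / annotated
    PPV      = correct / predicted
    Accuracy = (Sn + PPV) / 2
    APR      = additional / annotated        (additional = predicted - correct)

Essentiality calls are scored per annotated gene; a gene is correct only if
it was both found by the caller and assigned the right essentiality class:

    Sn = correct essential / annotated essential
    Sp = correct nonessential / annotated nonessential
    OA = (correct essential + correct nonessential) / all annotated

Counts are integers and the statistics are exact rationals; floats are
derived views.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

from .sequence_io import ZgeneError


def _stop_key(obj) -> tuple:
    """3'-terminus identity key for anything with contig/strand/start/end
    attributes (1-based inclusive convention)."""
    stop = getattr(obj, "stop_coord", None)
    if stop is None:
        stop = obj.end if obj.strand == "+" else obj.start
    return (obj.contig_id, obj.strand, stop)


#: public alias — the matching key shared with the consensus module
stop_key = _stop_key


def match_by_stop(predicted, annotated):
    """One-to-one matching on (contig, strand, stop coordinate).

    Returns (matched_pairs, unmatched_predictions, unmatched_annotations).
    Duplicate stop keys within either input are de-duplicated (first kept)
    with a warning.
    """

    def _dedupe(items, label):
        seen: dict[tuple, object] = {}
        for it in items:
            k = _stop_key(it)
            if k in seen:
                warnings.warn(
                    f"duplicate 3' terminus {k} among {label}; keeping first",
                    stacklevel=3,
                )
                continue
            seen[k] = it
        return seen

    pred_by_key = _dedupe(predicted, "predictions")
    ann_by_key = _dedupe(annotated, "annotations")
    matched = [
        (pred_by_key[k], ann_by_key[k]) for k in pred_by_key if k in ann_by_key
    ]
    unmatched_pred = [v for k, v in pred_by_key.items() if k not in ann_by_key]
    unmatched_ann = [v for k, v in ann_by_key.items() if k not in pred_by_key]
    return matched, unmatched_pred, unmatched_ann


@dataclass
class CodingEvalReport:
    n_annotated: int
    n_predicted: int
    n_correct: int

    def __post_init__(self) -> None:
        if self.n_annotated <= 0:
            raise ZgeneError("evaluation requires a non-empty annotation")
        if self.n_correct > min(self.n_annotated, self.n_predicted):
            raise ZgeneError("n_correct exceeds n_annotated or n_predicted")

    @property
    def n_additional(self) -> int:
        return self.n_predicted - self.n_correct

    @property
    def sn_exact(self) -> Fraction:
        return Fraction(self.n_correct, self.n_annotated)

    @property
    def ppv_exact(self) -> Fraction:
        if self.n_predicted == 0:
            return Fraction(0)
        return Fraction(self.n_correct, self.n_predicted)

    @property
    def accuracy_exact(self) -> Fraction:
        return (self.sn_exact + self.ppv_exact) / 2

    @property
    def apr_exact(self) -> Fraction:
        return Fraction(self.n_additional, self.n_annotated)

    @property
    def sn(self) -> float:
        return float(self.sn_exact)

    @property
    def ppv(self) -> float:
        return float(self.ppv_exact)

    @property
    def accuracy(self) -> float:
        return float(self.accuracy_exact)

    @property
    def apr(self) -> float:
        return float(self.apr_exact)

    def to_dict(self, decimals: int | None = 4) -> dict:
        stats = {
            "Sn": self.sn, "PPV": self.ppv,
            "Accuracy": self.accuracy, "APR": self.apr,
        }
        if decimals is not None:
            stats = {k: round(v, decimals) for k, v in stats.items()}
        return {
            "n_annotated": self.n_annotated,
            "n_predicted": self.n_predicted,
            "n_correct": self.n_correct,
            "n_additional": self.n_additional,
            **stats,
        }


def coding_report(predicted, annotated) -> CodingEvalReport:
    """Match by 3' terminus and compute the four coding statistics."""
    annotated = list(annotated)
    if not annotated:
        raise ZgeneError("evaluation requires a non-empty annotation")
    matched, unmatched_pred, _ = match_by_stop(predicted, annotated)
    n_pred = len(matched) + len(unmatched_pred)
    # de-duplicated annotation count
    ann_keys = {_stop_key(a) for a in annotated}
    return CodingEvalReport(
        n_annotated=len(ann_keys), n_predicted=n_pred, n_correct=len(matched)
    )


def accuracy_from(sn: float, ppv: float) -> float:
    """Midpoint accuracy from already-computed Sn and PPV values."""
    return (sn + ppv) / 2


@dataclass
class EssentialityEvalReport:
    n_essential: int
    n_nonessential: int
    n_essential_correct: int
    n_nonessential_correct: int

    @property
    def sn(self) -> float:
        if self.n_essential == 0:
            warnings.warn("no annotated essential genes; Sn undefined", stacklevel=2)
            return math.nan
        return self.n_essential_correct / self.n_essential

    @property
    def sp(self) -> float:
        if self.n_nonessential == 0:
            warnings.warn("no annotated nonessential genes; Sp undefined", stacklevel=2)
            return math.nan
        return self.n_nonessential_correct / self.n_nonessential

    @property
    def oa(self) -> float:
        total = self.n_essential + self.n_nonessential
        if total == 0:
            raise ZgeneError("no annotated genes")
        return (self.n_essential_correct + self.n_nonessential_correct) / total

    def to_dict(self, decimals: int | None = 3) -> dict:
        stats = {"Sn": self.sn, "Sp": self.sp, "OA": self.oa}
        if decimals is not None:
            stats = {
                k: (round(v, decimals) if not math.isnan(v) else v)
                for k, v in stats.items()
            }
        return {
            "n_essential": self.n_essential,
            "n_nonessential": self.n_nonessential,
            "n_essential_correct": self.n_essential_correct,
            "n_nonessential_correct": self.n_nonessential_correct,
            **stats,
        }


def essentiality_report(truth_essential, predicted_essential) -> EssentialityEvalReport:
    """Score essentiality calls against the annotated truth.

    ``truth_essential``: mapping of gene key -> bool (annotated label).
    ``predicted_essential``: mapping of gene key -> bool for genes the
    pipeline found and called; a truth gene absent from it was either missed
    by the gene caller or left unscored and counts as incorrect for its
    class.
    """
    n_e = n_ne = c_e = c_ne = 0
    for key, is_ess in truth_essential.items():
        call = predicted_essential.get(key)
        if is_ess:
            n_e += 1
            c_e += int(call is True)
        else:
            n_ne += 1
            c_ne += int(call is False)
    return EssentialityEvalReport(
        n_essential=n_e, n_nonessential=n_ne,
        n_essential_correct=c_e, n_nonessential_correct=c_ne,
    )


def length_stratified_auc(
    scores_pos, lengths_pos, scores_neg, lengths_neg, bin_width: int = 60
) -> float:
    """Mann-Whitney AUC pooled within ORF-length bins.

    Raw classifier scores correlate with ORF length (longer sequences have
    tighter feature estimates), so a pooled AUC between classes with
    different length distributions conflates composition signal with
    length.  Comparing only pairs from the same length bin isolates the
    compositional discrimination; 0.5 means no signal at matched length.
    Returns NaN when no bin holds both classes.
    """
    import numpy as np

    bins: dict[int, tuple[list, list]] = {}
    for s, L in zip(scores_pos, lengths_pos):
        bins.setdefault(int(L) // bin_width, ([], []))[0].append(float(s))
    for s, L in zip(scores_neg, lengths_neg):
        bins.setdefault(int(L) // bin_width, ([], []))[1].append(float(s))
    num = den = 0.0
    for p, n in bins.values():
        if not p or not n:
            continue
        pa, na = np.asarray(p), np.asarray(n)
        num += float((pa[:, None] > na[None, :]).sum())
        num += 0.5 * float((pa[:, None] == na[None, :]).sum())
        den += len(p) * len(n)
    return num / den if den else math.nan


def aggregate_reports(reports, population_sd: bool = False) -> dict:
    """Per-statistic mean and standard deviation over several reports.

    Works for both report types (uses their ``to_dict`` statistics).  With a
    single report the sample SD is undefined and reported as 0.0 with a
    warning; population SD of one value is 0 by definition.
    """
    reports = list(reports)
    if not reports:
        raise ZgeneError("aggregate_reports needs at least one report")
    dicts = [r.to_dict(decimals=None) for r in reports]
    stat_names = [k for k in dicts[0] if not k.startswith("n_")]
    out = {}
    for name in stat_names:
        vals = [d[name] for d in dicts if not math.isnan(d[name])]
        n = len(vals)
        mean = sum(vals) / n
        if n == 1:
            if not population_sd:
                warnings.warn(
                    f"sample SD of a single {name} value is undefined; "
                    "reporting 0.0", stacklevel=2,
                )
            sd = 0.0
        else:
            ddof = 0 if population_sd else 1
            var = sum((v - mean) ** 2 for v in vals) / (n - ddof)
            sd = math.sqrt(var)
        out[name] = {"mean": mean, "sd": sd, "n": n}
    return out
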