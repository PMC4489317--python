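"""Distance-weighted essentiality scoring of predicted genes.

Each query protein is looked up in a panel of reference organisms with
known essentiality annotations.  A lookup yields one of three categories
(essential_hit, nonessential_hit, no_hit); the essentiality score of the
gene is the weight-normalized fraction of references reporting an
essential ortholog,

    score = sum_i w_i * e_i / sum_i w_i,     w_i = weight_fn(distance_i),

with e_i = 1 for an essential_hit and 0 otherwise, so the score is a convex
combination of {0,1} evidence and lies in [0,1].  The default weighting is
w = exp(-d), down-weighting distant references; the ortholog matcher is a
pluggable contract (a reciprocal-best-hit matcher over pairwise alignment
scores is provided; tests may use exact-id lookup fixtures).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .sequence_io import ZgeneError

logger = logging.getLogger(__name__)

ESSENTIAL_HIT = "essential_hit"
NONESSENTIAL_HIT = "nonessential_hit"
NO_HIT = "no_hit"

DEFAULT_CUTOFF = 0.5


def exp_decay_weight(distance: float) -> float:
    """Default evolutionary-distance weighting, w = exp(-d)."""
    return math.exp(-distance)


@dataclass
class ReferenceOrganism:
    id: str
    proteome: dict[str, str]           # gene id -> amino-acid sequence
    essential_ids: set[str]
    distance: float

    def __post_init__(self) -> None:
        extra = set(self.essential_ids) - set(self.proteome)
        if extra:
            raise ZgeneError(
                f"reference {self.id!r}: essential ids not in proteome: "
                f"{sorted(extra)[:3]!r}..."
            )
        if not math.isfinite(self.distance) or self.distance < 0:
            raise ZgeneError(f"reference {self.id!r}: invalid distance {self.distance}")


@dataclass
class EssentialityResult:
    gene_id: str
    score: float
    call: bool  # True = essential


class IdentityMatcher:
    """Fixture matcher: ortholog iff the exact gene id is present."""

    def __call__(self, query_id: str, query_seq: str, ref: ReferenceOrganism):
        return query_id if query_id in ref.proteome else None


class ReciprocalBestHitMatcher:
    """Reciprocal best hit under local pairwise alignment (BLOSUM62).

    A query's best-scoring reference protein counts as an ortholog only if
    the query is in turn that protein's best hit within the query proteome,
    and the alignment score clears ``min_score``.
    """

    def __init__(self, query_proteome: dict[str, str], min_score: float = 50.0):
        self.query_proteome = dict(query_proteome)
        self.min_score = min_score
        self._aligner = PairwiseAligner(mode="local")
        self._aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self._aligner.open_gap_score = -11
        self._aligner.extend_gap_score = -1

    def _best_hit(self, seq: str, proteome: dict[str, str]):
        best_id, best_score = None, -math.inf
        for pid in sorted(proteome):
            try:
                sc = self._aligner.score(seq, proteome[pid])
            except ValueError:
                continue
            if sc > best_score:
                best_id, best_score = pid, sc
        return best_id, best_score

    def __call__(self, query_id: str, query_seq: str, ref: ReferenceOrganism):
        hit_id, hit_score = self._best_hit(query_seq, ref.proteome)
        if hit_id is None or hit_score < self.min_score:
            return None
        back_id, _ = self._best_hit(ref.proteome[hit_id], self.query_proteome)
        if back_id != query_id:
            return None
        return hit_id


def ortholog_presence(
    query_id: str,
    query_seq: str,
    reference: ReferenceOrganism,
    matcher=None,
) -> str:
    """Categorize one (protein, reference) pair.

    Matcher failures are logged and degrade to ``no_hit``.
    """
    matcher = matcher or IdentityMatcher()
    try:
        hit = matcher(query_id, query_seq, reference)
    except Exception as exc:  # noqa: BLE001 — backend errors degrade gracefully
        logger.warning(
            "matcher failed for %r vs reference %r: %s", query_id, reference.id, exc
        )
        return NO_HIT
    if hit is None:
        return NO_HIT
    return ESSENTIAL_HIT if hit in reference.essential_ids else NONESSENTIAL_HIT


def essentiality_score(
    query_id: str,
    query_seq: str,
    references: list[ReferenceOrganism],
    matcher=None,
    weight_fn: Callable[[float], float] = exp_decay_weight,
) -> float:
    """Distance-weighted essential-ortholog fraction in [0, 1]."""
    if not references:
        raise ZgeneError("at least one reference organism is required")
    num = den = 0.0
    for ref in references:
        w = weight_fn(ref.distance)
        if w < 0:
            raise ZgeneError(f"negative weight for reference {ref.id!r}")
        cat = ortholog_presence(query_id, query_seq, ref, matcher)
        num += w * (cat == ESSENTIAL_HIT)
        den += w
    if den == 0:
        raise ZgeneError("all reference weights are zero")
    return num / den


def classify_essentiality(
    scores: dict[str, float], cutoff: float = DEFAULT_CUTOFF
) -> list[EssentialityResult]:
    """Threshold scores into essential / non-essential calls."""
    if not 0 <= cutoff <= 1:
        raise ZgeneError(f"cutoff must be in [0, 1], got {cutoff}")
    return [
        EssentialityResult(gene_id=g, score=s, call=s >= cutoff)
        for g, s in scores.items()
    ]


def score_proteins(
    proteins: dict[str, str],
    references: list[ReferenceOrganism],
    matcher=None,
    weight_fn: Callable[[float], float] = exp_decay_weight,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[EssentialityResult]:
    """Score and classify a whole predicted proteome."""
    scores = {
        gid: essentiality_score(gid, seq, references, matcher, weight_fn)
        for gid, seq in proteins.items()
    }
    return classify_essentiality(scores, cutoff)


def load_reference_dir(path: str | Path) -> list[ReferenceOrganism]:
    """Load reference organisms from a directory.

    Layout: per organism ``<id>.faa`` (FASTA proteome) and ``<id>.ess.tsv``
    (gene id, 0/1 essential flag), plus one ``distances.tsv``
    (organism id, distance).
    """
    path = Path(path)
    dist_file = path / "distances.tsv"
    if not dist_file.exists():
        raise ZgeneError(f"missing {dist_file}")
    distances = {}
    with open(dist_file) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            oid, d = line.split("\t")[:2]
            distances[oid] = float(d)
    refs = []
    for faa in sorted(path.glob("*.faa")):
        oid = faa.stem
        proteome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(faa), "fasta")}
        ess_file = path / f"{oid}.ess.tsv"
        essential = set()
        if ess_file.exists():
            with open(ess_file) as fh:
                for line in fh:
                    if not line.strip() or line.startswith("#"):
                        continue
                    gid, flag = line.rstrip("\n").split("\t")[:2]
                    if flag.strip() in ("1", "true", "True", "essential"):
                        essential.add(gid)
        if oid not in distances:
            raise ZgeneError(f"no distance listed for reference {oid!r}")
        refs.append(
            ReferenceOrganism(
                id=oid, proteome=proteome, essential_ids=essential,
                distance=distances[oid],
            )
        )
    if not refs:
        raise ZgeneError(f"no reference proteomes (*.faa) found in {path}")
    return refs
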