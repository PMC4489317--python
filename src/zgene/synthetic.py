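"""Synthetic genomes with planted genes, and essentiality reference fixtures.

The generator emulates the compositional contrast a phase-specific encoder
must detect: gene interiors are iid draws from a biased codon-usage table
over the 61 sense codons, while intergenic background is order-0 iid
nucleotide sequence with a configurable GC fraction.  Planted genes start
with ATG/GTG/TTG, end with a stop codon, sit on both strands without
overlap, and (by default) carry a planted AGGAGG Shine-Dalgarno motif
5-13 nt upstream of the true start.  A configurable fraction (default 10%,
echoing the strong class imbalance of real bacterial essentiality screens)
is labeled essential for the essentiality fixtures.

Everything is reproducible: identical spec + seed give byte-identical
sequences and truth tables.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .essentiality import ReferenceOrganism
from .orf_model import reverse_complement
from .sequence_io import (
    AnnotationRecord,
    GenomeSequence,
    ZgeneError,
    translate_gene,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)
assert len(SENSE_CODONS) == 61

START_CODON_PROBS = {"ATG": 0.85, "GTG": 0.10, "TTG": 0.05}


def sample_codon_table(bias_strength: float, seed: int) -> dict[str, float]:
    """A codon-usage table over the 61 sense codons.

    ``bias_strength`` scales a fixed Gaussian logit vector drawn from the
    seed; 0 gives the exactly uniform table, and larger values concentrate
    the table away from uniform monotonically (for a fixed seed).
    """
    if bias_strength < 0:
        raise ZgeneError("bias_strength must be >= 0")
    rng = np.random.default_rng(seed)
    logits = bias_strength * rng.standard_normal(len(SENSE_CODONS))
    p = np.exp(logits - logits.max())
    p /= p.sum()
    return dict(zip(SENSE_CODONS, p))


def kl_from_uniform(table: dict[str, float]) -> float:
    """Kullback-Leibler divergence of a codon table from uniform (nats)."""
    p = np.array([table[c] for c in SENSE_CODONS])
    u = 1.0 / len(SENSE_CODONS)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / u)))


@dataclass
class SyntheticGenomeSpec:
    length: int = 200_000
    n_genes: int = 150
    gene_len_min: int = 300          # nt, stop codon included
    gene_len_mean: int = 900
    codon_bias_strength: float = 0.5
    intergenic_gc: float = 0.5
    circular: bool = False
    essential_fraction: float = 0.1
    plant_sd: bool = True
    sd_motif: str = "AGGAGG"
    sd_spacer: tuple = (5, 13)
    min_gap: int = 30                # nt between consecutive genes
    seed: int = 0


@dataclass
class SyntheticGenome:
    genome: GenomeSequence
    truth: list[AnnotationRecord]
    essential: dict[str, bool]       # gene id -> label
    proteins: dict[str, str]         # gene id -> amino-acid sequence
    codon_table: dict[str, float]
    spec: SyntheticGenomeSpec = field(repr=False, default=None)


def _draw_gene(rng: np.random.Generator, spec: SyntheticGenomeSpec,
               codons: np.ndarray, probs: np.ndarray) -> str:
    # length = min + 3 * (Geom - 1); mean matches spec.gene_len_mean
    extra_mean = max(spec.gene_len_mean - spec.gene_len_min, 3) / 3
    p = min(1.0, 1.0 / extra_mean)
    n_extra = int(rng.geometric(p)) - 1
    n_codons = (spec.gene_len_min // 3) + n_extra  # incl. start + stop
    starts = list(START_CODON_PROBS)
    start = starts[rng.choice(len(starts), p=np.array(list(START_CODON_PROBS.values())))]
    interior = codons[rng.choice(len(codons), size=n_codons - 2, p=probs)]
    stop = STOP_CODONS[rng.integers(3)]
    return start + "".join(interior) + stop


def _intergenic(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Generate one genome with planted genes and its truth tables."""
    rng = np.random.default_rng(spec.seed)
    table = sample_codon_table(spec.codon_bias_strength, spec.seed)
    codons = np.array(SENSE_CODONS)
    probs = np.array([table[c] for c in SENSE_CODONS])

    genes = [_draw_gene(rng, spec, codons, probs) for _ in range(spec.n_genes)]
    strands = np.where(rng.random(spec.n_genes) < 0.5, "+", "-")
    total_gene_nt = sum(len(g) for g in genes)
    n_gaps = spec.n_genes + 1
    free = spec.length - total_gene_nt - n_gaps * spec.min_gap
    if free < 0:
        raise ZgeneError(
            f"{spec.n_genes} genes totalling {total_gene_nt} nt do not fit in "
            f"{spec.length} nt with {spec.min_gap} nt gaps"
        )
    # split the slack over the gaps
    extra = rng.multinomial(free, np.full(n_gaps, 1.0 / n_gaps))
    gap_lens = extra + spec.min_gap

    gaps = [_intergenic(rng, int(n), spec.intergenic_gc) for n in gap_lens]
    if spec.plant_sd:
        # carve the Shine-Dalgarno motif into the gap on each gene's 5' side
        m = spec.sd_motif
        rc = reverse_complement(m)
        for i, strand in enumerate(strands):
            spacer = int(rng.integers(spec.sd_spacer[0], spec.sd_spacer[1] + 1))
            if strand == "+":
                gap = gaps[i]  # gap preceding gene i; motif ends spacer nt
                cut = len(gap) - spacer - len(m)  # before the gene start
                if cut >= 0:
                    gaps[i] = gap[:cut] + m + gap[cut + len(m):]
            else:
                gap = gaps[i + 1]  # gap following gene i holds the 5' side
                if spacer + len(rc) <= len(gap):
                    gaps[i + 1] = gap[:spacer] + rc + gap[spacer + len(rc):]

    parts: list[str] = []
    truth: list[AnnotationRecord] = []
    essential: dict[str, bool] = {}
    proteins: dict[str, str] = {}
    pos = 0
    contig_id = f"synth{spec.seed}"
    for i, (gene, strand) in enumerate(zip(genes, strands)):
        parts.append(gaps[i])
        pos += len(gaps[i])
        placed = gene if strand == "+" else reverse_complement(gene)
        gid = f"{contig_id}_t{i + 1:04d}"
        truth.append(
            AnnotationRecord(
                contig_id=contig_id, start=pos + 1, end=pos + len(gene),
                strand=strand, gene_id=gid,
            )
        )
        essential[gid] = bool(rng.random() < spec.essential_fraction)
        proteins[gid] = translate_gene(gene)
        parts.append(placed)
        pos += len(gene)
    parts.append(gaps[-1])
    seq = "".join(parts)
    assert len(seq) == spec.length

    genome = GenomeSequence(id=contig_id, seq=seq, circular=spec.circular)
    for rec in truth:
        if rec.end > len(seq):
            raise ZgeneError("internal error: planted gene beyond genome end")
    return SyntheticGenome(
        genome=genome, truth=truth, essential=essential,
        proteins=proteins, codon_table=table, spec=spec,
    )


def generate_reference_set(
    synth: SyntheticGenome,
    n_refs: int = 5,
    ortholog_presence_essential: float = 0.9,
    ortholog_presence_nonessential: float = 0.1,
    distances=None,
    seed: int = 0,
) -> list[ReferenceOrganism]:
    """Reference organisms whose essential-hit pattern is Bernoulli against
    the synthetic truth labels.

    Every query protein is present in every reference proteome (so lookups
    always hit); a reference marks the ortholog essential with probability
    ``ortholog_presence_essential`` when the query gene is truly essential
    and ``ortholog_presence_nonessential`` otherwise.
    """
    for p in (ortholog_presence_essential, ortholog_presence_nonessential):
        if not 0 <= p <= 1:
            raise ZgeneError("presence probabilities must be in [0, 1]")
    if n_refs < 1:
        raise ZgeneError("at least one reference organism is required")
    if distances is None:
        distances = [1.0] * n_refs
    if len(distances) != n_refs:
        raise ZgeneError("len(distances) must equal n_refs")
    rng = np.random.default_rng(seed)
    refs = []
    for r in range(n_refs):
        essential_ids = {
            gid
            for gid, is_ess in synth.essential.items()
            if rng.random() < (
                ortholog_presence_essential if is_ess
                else ortholog_presence_nonessential
            )
        }
        refs.append(
            ReferenceOrganism(
                id=f"ref{r + 1:02d}",
                proteome=dict(synth.proteins),
                essential_ids=essential_ids,
                distance=float(distances[r]),
            )
        )
    return refs


def write_fixture_dir(synth: SyntheticGenome, out_dir: str | Path,
                      references: list[ReferenceOrganism] | None = None) -> None:
    """Emit FASTA + truth TSV + essentiality TSV (+ reference set dir)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = synth.genome
    with open(out_dir / "genome.fna", "w") as fh:
        fh.write(f">{g.id}\n")
        for i in range(0, len(g.seq), 70):
            fh.write(g.seq[i : i + 70] + "\n")
    with open(out_dir / "truth.tsv", "w") as fh:
        for rec in synth.truth:
            fh.write(f"{rec.contig_id}\t{rec.start}\t{rec.end}\t{rec.strand}\n")
    with open(out_dir / "truth.ess.tsv", "w") as fh:
        for gid, is_ess in synth.essential.items():
            fh.write(f"{gid}\t{int(is_ess)}\n")
    with open(out_dir / "spec.json", "w") as fh:
        d = dict(synth.spec.__dict__)
        d["sd_spacer"] = list(d["sd_spacer"])
        json.dump(d, fh, indent=1)
    if references:
        ref_dir = out_dir / "refs"
        ref_dir.mkdir(exist_ok=True)
        with open(ref_dir / "distances.tsv", "w") as fh:
            for ref in references:
                fh.write(f"{ref.id}\t{ref.distance!r}\n")
        for ref in references:
            with open(ref_dir / f"{ref.id}.faa", "w") as fh:
                for gid, seq in ref.proteome.items():
                    fh.write(f">{gid}\n{seq}\n")
            with open(ref_dir / f"{ref.id}.ess.tsv", "w") as fh:
                for gid in ref.proteome:
                    fh.write(f"{gid}\t{int(gid in ref.essential_ids)}\n")
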