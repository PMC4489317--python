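"""Genome and annotation I/O.

Reads multi-record FASTA genomes and RefSeq-style PTT / minimal TSV
annotations, and writes the four output artifacts of a prediction run:
a coordinates TSV, gene DNA FASTA (.ffn), protein FASTA (.faa) and an
essentiality TSV.

Coordinate conventions
----------------------
External files use 1-based inclusive coordinates with an explicit strand
column (the PTT convention); internally everything is 0-based half-open on
the forward strand.  A gene that wraps the origin of a circular contig is
written with start > end.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: NCBI translation table used for all conceptual translations.
GENETIC_CODE_TABLE = 11


class ZgeneError(Exception):
    """Base class for user-facing errors in this package."""


@dataclass
class GenomeSequence:
    """One contig: identifier, uppercase nucleotide string, circular flag."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ZgeneError(f"record {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ZgeneError(
                f"record {self.id!r}: non-nucleotide character(s) "
                f"{sorted(bad)!r} (alphabet is A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """0-based half-open slice; ``end`` may exceed the contig length on
        a circular contig, in which case the slice wraps the origin."""
        n = len(self.seq)
        if end <= n:
            return self.seq[start:end]
        if not self.circular:
            raise ZgeneError(
                f"slice [{start}, {end}) beyond linear contig {self.id!r}"
            )
        return (self.seq * 2)[start:end]


@dataclass
class AnnotationRecord:
    """A reference gene interval, 1-based inclusive, explicit strand."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ZgeneError(f"strand must be + or -, got {self.strand!r}")
        if self.end < self.start:
            raise ZgeneError(
                f"annotation {self.start}..{self.end}: end < start"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path, circular: bool = False) -> list[GenomeSequence]:
    """Read a (multi-)FASTA genome file into :class:`GenomeSequence` records.

    Lowercase is mapped to uppercase; any character outside {A,C,G,T,N}
    raises an error naming the offending record and character.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ZgeneError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(id=rec.id, seq=str(rec.seq), circular=circular))
    if not records:
        raise ZgeneError(f"no FASTA records found in {path}")
    return records


_PTT_LOCATION = re.compile(r"^(\d+)\.\.(\d+)$")


def read_annotation(
    path: str | Path,
    dialect: str = "auto",
    contig_id: str | None = None,
) -> list[AnnotationRecord]:
    """Read a reference annotation as PTT or minimal TSV.

    PTT: the RefSeq protein table; only the Location ("start..end") and
    Strand columns are used, header lines are skipped.  TSV: three columns
    (start, end, strand) or four (contig, start, end, strand), '#' comments
    skipped.  ``contig_id`` supplies the contig for files that carry none.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "ptt" if path.suffix.lower() == ".ptt" else "tsv"
    if dialect not in ("ptt", "tsv"):
        raise ZgeneError(f"unknown annotation dialect {dialect!r}")

    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "ptt":
                loc = fields[0].strip()
                m = _PTT_LOCATION.match(loc)
                if m is None:
                    # Preamble lines (genome title, "N proteins", column
                    # header) are skipped; a space-free field containing
                    # ".." is a data row with a broken Location.
                    if ".." in loc and " " not in loc:
                        raise ZgeneError(
                            f"{path}:{lineno}: malformed PTT location {loc!r}"
                        )
                    continue
                if len(fields) < 2:
                    raise ZgeneError(f"{path}:{lineno}: missing strand column")
                start, end = int(m.group(1)), int(m.group(2))
                strand = fields[1].strip()
                gene_id = fields[5].strip() if len(fields) > 5 else None
                cid = contig_id
            else:
                if len(fields) == 3:
                    cid = contig_id
                    s, e, strand = fields
                elif len(fields) >= 4:
                    cid, s, e, strand = fields[:4]
                else:
                    raise ZgeneError(
                        f"{path}:{lineno}: expected 3 or 4 tab-separated "
                        f"columns, got {len(fields)}"
                    )
                try:
                    start, end = int(s), int(e)
                except ValueError as exc:
                    raise ZgeneError(f"{path}:{lineno}: {exc}") from exc
                gene_id = None
            try:
                rec = AnnotationRecord(
                    contig_id=cid or "", start=start, end=end,
                    strand=strand, gene_id=gene_id,
                )
            except ZgeneError as exc:
                raise ZgeneError(f"{path}:{lineno}: {exc}") from exc
            if rec.length % 3 != 0:
                warnings.warn(
                    f"{path}:{lineno}: gene length {rec.length} not divisible "
                    f"by 3 (kept; annotation quirk)",
                    stacklevel=2,
                )
            records.append(rec)
    return records


def check_annotation_bounds(
    records: Iterable[AnnotationRecord], genomes: Sequence[GenomeSequence]
) -> None:
    """Raise if a record's coordinates exceed its contig length."""
    lengths = {g.id: len(g) for g in genomes}
    for rec in records:
        n = lengths.get(rec.contig_id)
        if n is not None and rec.end > n and not any(
            g.circular for g in genomes if g.id == rec.contig_id
        ):
            raise ZgeneError(
                f"annotation {rec.start}..{rec.end} beyond contig "
                f"{rec.contig_id!r} of length {n}"
            )


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

OUTPUT_OPTIONS = ("coords", "nucleotide", "protein", "essentiality")

#: out_prefix + suffix per output option (stable naming scheme).
OUTPUT_SUFFIXES = {
    "coords": ".coords.tsv",
    "nucleotide": ".ffn",
    "protein": ".faa",
    "essentiality": ".ess.tsv",
}


def gene_dna(prediction, genome: GenomeSequence) -> str:
    """Genomic DNA of a predicted gene, reverse-complemented on '-'."""
    start0 = prediction.start - 1
    end0 = prediction.end
    if end0 < start0:  # origin wrap on a circular contig
        end0 += len(genome)
    seq = genome.slice(start0, end0)
    if prediction.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def translate_gene(dna: str) -> str:
    """Conceptual translation (table 11), trailing stop removed, N -> X."""
    prot = str(Seq(dna).translate(table=GENETIC_CODE_TABLE))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def write_outputs(
    predictions,
    genomes: Sequence[GenomeSequence],
    out_prefix: str | Path,
    options: Iterable[str] = ("coords", "nucleotide", "protein"),
    header_comment: str | None = None,
) -> dict[str, Path]:
    """Write up to four output files for a prediction run.

    Returns a mapping of option name to the path written.  Requesting the
    essentiality file requires every prediction to carry an essentiality
    score.
    """
    options = list(options)
    for opt in options:
        if opt not in OUTPUT_OPTIONS:
            raise ZgeneError(f"unknown output option {opt!r}")
    by_contig = {g.id: g for g in genomes}
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _header(fh, comment_char="#"):
        if header_comment:
            fh.write(f"{comment_char} {header_comment}\n")

    if "essentiality" in options:
        missing = [p.gene_id for p in predictions if p.essentiality_score is None]
        if missing:
            raise ZgeneError(
                "essentiality output requested but predictions lack scores "
                f"(e.g. {missing[0]!r}); run the essentiality scorer first"
            )

    if "coords" in options:
        p = out_prefix.with_suffix(out_prefix.suffix + OUTPUT_SUFFIXES["coords"])
        with open(p, "w") as fh:
            _header(fh)
            fh.write("gene_id\tcontig\tstart\tend\tstrand\tlength\tcoding_score\n")
            for pred in predictions:
                fh.write(
                    f"{pred.gene_id}\t{pred.contig_id}\t{pred.start}\t"
                    f"{pred.end}\t{pred.strand}\t{pred.length}\t"
                    f"{pred.coding_score!r}\n"
                )
        written["coords"] = p

    if "nucleotide" in options:
        p = out_prefix.with_suffix(out_prefix.suffix + OUTPUT_SUFFIXES["nucleotide"])
        with open(p, "w") as fh:
            for pred in predictions:
                dna = gene_dna(pred, by_contig[pred.contig_id])
                fh.write(
                    f">{pred.gene_id} {pred.contig_id}:{pred.start}..{pred.end}"
                    f"({pred.strand})\n{dna}\n"
                )
        written["nucleotide"] = p

    if "protein" in options:
        p = out_prefix.with_suffix(out_prefix.suffix + OUTPUT_SUFFIXES["protein"])
        with open(p, "w") as fh:
            for pred in predictions:
                dna = gene_dna(pred, by_contig[pred.contig_id])
                fh.write(f">{pred.gene_id}\n{translate_gene(dna)}\n")
        written["protein"] = p

    if "essentiality" in options:
        p = out_prefix.with_suffix(out_prefix.suffix + OUTPUT_SUFFIXES["essentiality"])
        with open(p, "w") as fh:
            _header(fh)
            fh.write("gene_id\tessentiality_score\tcall\n")
            for pred in predictions:
                call = "essential" if pred.essentiality_call else "nonessential"
                fh.write(f"{pred.gene_id}\t{pred.essentiality_score!r}\t{call}\n")
        written["essentiality"] = p

    return written


def read_predictions_tsv(path: str | Path):
    """Read back a coords TSV written by :func:`write_outputs`."""
    from .gene_caller import GenePrediction  # local import; avoids a cycle

    preds = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gid, contig, start, end, strand, _length, score = line.rstrip("\n").split("\t")[:7]
            preds.append(
                GenePrediction(
                    contig_id=contig, strand=strand, start=int(start),
                    end=int(end), frame=0, coding_score=float(score),
                    gene_id=gid,
                )
            )
    return preds
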