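"""Transcription-unit (operon) prediction from gene order and spacing.

Adjacent genes on the same strand of the same replicon are joined into
one transcription unit (TU) when the intergenic gap between them is at
most ``max_intergenic_gap`` base pairs.  With 1-based inclusive
coordinates the gap between consecutive genes is
``start(next) - end(prev) - 1``, so abutting genes have gap 0 and
overlapping genes a negative gap (joined when ``allow_overlap``).
Strand changes, replicon boundaries, and gap breaches all start a new
TU; circular replicons are treated as linear.

The promoter-proximal ("first") gene of a TU is the lowest-coordinate
gene on the + strand and the highest-coordinate gene on the - strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from grntransfer.annotation_io import GenomeAnnotation
from grntransfer.errors import InvariantError, UsageError


@dataclass(frozen=True)
class OperonParams:
    """Distance rule for joining adjacent genes into one TU."""

    max_intergenic_gap: int = 50
    allow_overlap: bool = True

    def __post_init__(self) -> None:
        if self.max_intergenic_gap < 0:
            raise UsageError("max_intergenic_gap must be >= 0")


@dataclass
class TranscriptionUnit:
    """A maximal run of same-strand, closely spaced genes.

    ``genes`` are listed in transcription order: ascending coordinates
    on the + strand, descending on the - strand.  ``first_gene`` is the
    promoter-proximal gene, ``genes[0]``.
    """

    tu_id: str
    replicon_id: str
    strand: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise UsageError("a TU must contain at least one gene")

    @property
    def first_gene(self) -> str:
        return self.genes[0]

    def __len__(self) -> int:
        return len(self.genes)


def predict_tus(
    annotation: GenomeAnnotation, params: OperonParams = OperonParams()
) -> list[TranscriptionUnit]:
    """Partition all genes of a genome into transcription units."""
    tus: list[TranscriptionUnit] = []
    run: list = []  # genomic-order run of GeneRecords forming the open TU

    def close_run() -> None:
        if not run:
            return
        strand = run[0].strand
        ordered = run if strand == "+" else list(reversed(run))
        tus.append(
            TranscriptionUnit(
                tu_id=f"TU{len(tus) + 1:04d}",
                replicon_id=run[0].replicon_id,
                strand=strand,
                genes=[g.locus_id for g in ordered],
            )
        )
        run.clear()

    prev = None
    for gene in annotation.genes:
        if prev is not None:
            if (gene.replicon_id, gene.start) < (prev.replicon_id, prev.start):
                raise InvariantError("annotation is not sorted by (replicon, start)")
            gap = gene.start - prev.end - 1
            same_run = (
                gene.replicon_id == prev.replicon_id
                and gene.strand == prev.strand
                and gap <= params.max_intergenic_gap
                and (gap >= 0 or params.allow_overlap)
            )
            if not same_run:
                close_run()
        run.append(gene)
        prev = gene
    close_run()
    return tus


def first_gene_index(
    tus: Iterable[TranscriptionUnit],
) -> dict[str, tuple[str, bool, list[str]]]:
    """Index every gene by its TU membership.

    Returns ``{gene: (tu_id, is_first, downstream)}`` where
    ``downstream`` lists the co-transcribed genes after this one in
    transcription order.  A gene assigned to two TUs is an invariant
    breach.
    """
    index: dict[str, tuple[str, bool, list[str]]] = {}
    for tu in tus:
        for pos, gene in enumerate(tu.genes):
            if gene in index:
                raise InvariantError(f"gene {gene!r} belongs to two TUs")
            index[gene] = (tu.tu_id, pos == 0, tu.genes[pos + 1 :])
    return index


def write_tu_table(tus: Sequence[TranscriptionUnit], path: str | Path) -> None:
    """Emit the TU partition as TSV: tu_id, replicon, strand, gene list."""
    with open(path, "w") as fh:
        fh.write("tu_id\treplicon_id\tstrand\tgenes\n")
        for tu in tus:
            fh.write(f"{tu.tu_id}\t{tu.replicon_id}\t{tu.strand}\t"
                     + ",".join(tu.genes) + "\n")


def read_tu_table(path: str | Path) -> list[TranscriptionUnit]:
    tus: list[TranscriptionUnit] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("tu_id\t") or not line.strip():
                continue
            tu_id, replicon, strand, genes = line.rstrip("\n").split("\t")
            tus.append(
                TranscriptionUnit(
                    tu_id=tu_id,
                    replicon_id=replicon,
                    strand=strand,
                    genes=genes.split(","),
                )
            )
    return tus
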