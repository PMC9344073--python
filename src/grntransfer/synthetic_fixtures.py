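"""Self-contained toy ecosystems with planted ground truth.

Generates everything the pipeline consumes — genome annotations with
an operonic gene layout, toy proteomes, pairwise similarity hits,
and reference regulatory networks — together with the exact expected
outputs (planted TU partition, planted ortholog map, expected
transferred and TU-expanded networks), so every stage can be checked
against a known truth without any download.

Gene coordinates are laid out so the planted TU partition is exactly
what the operon model recovers at default parameters: intergenic gaps
within a TU stay at or below ``within_tu_gap_max`` (default 20 bp,
under the 50 bp joining threshold) and gaps between TUs start at
``between_tu_gap_min`` (default 200 bp, above it).  Proteins are
short random amino-acid strings (60-120 residues); orthologs are
substitution-mutated copies, so percent identity of a planted pair is
directly computable and unrelated sequences score near the 5%
random-match floor, far below the 25% identity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from grntransfer.annotation_io import (
    GRN,
    GeneRecord,
    GenomeAnnotation,
    HitRecord,
    RegulatoryInteraction,
)
from grntransfer.errors import UsageError
from grntransfer.operon_model import TranscriptionUnit
from grntransfer.orthology import OrthologMap

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic reference/target ecosystem."""

    n_genes: int = 60
    n_tfs: int = 8
    n_edges: int = 80
    ortholog_fraction: float = 0.7
    tu_size_mean: float = 2.0
    within_tu_gap_max: int = 20
    between_tu_gap_min: int = 200
    mutation_rate: float = 0.05
    n_novel_genes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs > self.n_genes:
            raise UsageError("n_tfs cannot exceed n_genes")
        if self.n_edges > self.n_tfs * self.n_genes:
            raise UsageError("n_edges exceeds the possible TF x gene pairs")
        if not 0 <= self.ortholog_fraction <= 1:
            raise UsageError("ortholog_fraction must be in [0, 1]")
        if self.tu_size_mean < 1:
            raise UsageError("tu_size_mean must be >= 1")
        if not 0 <= self.mutation_rate < 1:
            raise UsageError("mutation_rate must be in [0, 1)")
        if self.within_tu_gap_max >= self.between_tu_gap_min:
            raise UsageError("within-TU gaps must stay below between-TU gaps")


@dataclass
class ReferenceFixture:
    """A generated reference genome with its planted truth."""

    genome_id: str
    annotation: GenomeAnnotation
    proteome: dict[str, str]
    grn: GRN
    tus: list[TranscriptionUnit]


@dataclass
class TargetFixture:
    """A genome derived from a reference, with planted orthology truth."""

    genome_id: str
    annotation: GenomeAnnotation
    proteome: dict[str, str]
    ortholog_map: OrthologMap
    expected_transferred: GRN
    expected_expanded: GRN
    tus: list[TranscriptionUnit]
    conserved: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


def _random_protein(rng: np.random.Generator) -> str:
    length = int(rng.integers(60, 121))
    return "".join(rng.choice(_AMINO_ACIDS, size=length))


def _layout_genome(
    genome_id: str,
    gene_ids: Sequence[str],
    proteome: dict[str, str],
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> tuple[GenomeAnnotation, list[TranscriptionUnit]]:
    """Place genes on one replicon in operonic runs; return the planted
    annotation and TU partition (transcription order per strand)."""
    replicon = f"{genome_id}_chr"
    genes: list[GeneRecord] = []
    tus: list[TranscriptionUnit] = []
    pos = 1 + int(rng.integers(0, 100))
    i = 0
    while i < len(gene_ids):
        size = 1 + int(rng.poisson(spec.tu_size_mean - 1.0))
        size = min(size, len(gene_ids) - i)
        strand = "+" if rng.random() < 0.5 else "-"
        members: list[GeneRecord] = []
        for j in range(size):
            gid = gene_ids[i + j]
            length_nt = 3 * len(proteome[gid])
            members.append(
                GeneRecord(
                    genome_id=genome_id,
                    locus_id=gid,
                    ncbi_gene_id=f"N{gid}",
                    protein_id=f"P{gid}",
                    gene_name=f"name_{gid}",
                    product=f"hypothetical protein {gid}",
                    start=pos,
                    end=pos + length_nt - 1,
                    strand=strand,
                    replicon_id=replicon,
                    protein_sequence=proteome[gid],
                )
            )
            pos += length_nt + 1 + int(rng.integers(0, spec.within_tu_gap_max + 1))
        genes.extend(members)
        ordered = members if strand == "+" else list(reversed(members))
        tus.append(
            TranscriptionUnit(
                tu_id=f"TU{len(tus) + 1:04d}",
                replicon_id=replicon,
                strand=strand,
                genes=[g.locus_id for g in ordered],
            )
        )
        pos += spec.between_tu_gap_min + int(rng.integers(0, 100))
        i += size
    return GenomeAnnotation(genome_id=genome_id, genes=genes), tus


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------


def generate_reference(
    spec: FixtureSpec, genome_id: str = "refA"
) -> ReferenceFixture:
    """Generate a reference genome, proteome, GRN and planted TUs.

    Fully reproducible from ``spec.seed``; regulatory edges are drawn
    uniformly from TF x gene pairs without duplicates (self-loops
    excluded).
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"{genome_id}_g{i:03d}" for i in range(spec.n_genes)]
    proteome = {gid: _random_protein(rng) for gid in gene_ids}
    annotation, tus = _layout_genome(genome_id, gene_ids, proteome, spec, rng)

    tf_ids = list(rng.choice(gene_ids, size=spec.n_tfs, replace=False))
    possible = [
        (tf, tg) for tf in sorted(tf_ids) for tg in gene_ids if tf != tg
    ]
    if spec.n_edges > len(possible):
        raise UsageError("n_edges exceeds possible non-self TF x gene pairs")
    chosen = rng.choice(len(possible), size=spec.n_edges, replace=False)
    grn = GRN(genome_id)
    for serial, idx in enumerate(sorted(chosen), start=1):
        tf, tg = possible[idx]
        effect = "activation" if rng.random() < 0.5 else "repression"
        grn.add(
            RegulatoryInteraction(
                interaction_id=serial,
                tf=tf,
                tg=tg,
                effect=effect,
                annotations=[effect],
                provenance={(genome_id, "direct")},
            )
        )
    return ReferenceFixture(
        genome_id=genome_id,
        annotation=annotation,
        proteome=proteome,
        grn=grn,
        tus=tus,
    )


# ---------------------------------------------------------------------------
# Target derivation
# ---------------------------------------------------------------------------


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        options = _AMINO_ACIDS[_AMINO_ACIDS != chars[i]]
        chars[i] = options[rng.integers(0, len(options))]
    return "".join(chars)


def derive_target(
    reference: ReferenceFixture,
    spec: FixtureSpec,
    target_id: str = "tgtX",
) -> TargetFixture:
    """Derive a target genome conserving a fraction of reference genes.

    ``round(ortholog_fraction * n_genes)`` reference genes are copied
    with per-residue substitution probability ``mutation_rate``,
    shuffled into a fresh gene order and TU layout, and padded with
    ``n_novel_genes`` unrelated genes.  Alongside the genome the
    planted ortholog map and the exact expected outputs of orthology
    transfer and TU expansion are computed by exhaustive scans.
    """
    rng = np.random.default_rng(spec.seed + 104729)  # distinct stream
    ref_genes = sorted(reference.proteome)
    n_conserved = int(round(spec.ortholog_fraction * len(ref_genes)))
    conserved_ref = sorted(
        rng.choice(ref_genes, size=n_conserved, replace=False)
    )

    order = list(conserved_ref)
    rng.shuffle(order)
    conserved: dict[str, str] = {}
    proteome: dict[str, str] = {}
    target_ids: list[str] = []
    for j, ref_gene in enumerate(order):
        tid = f"{target_id}_g{j:03d}"
        conserved[ref_gene] = tid
        proteome[tid] = _mutate(reference.proteome[ref_gene], spec.mutation_rate, rng)
        target_ids.append(tid)
    for k in range(spec.n_novel_genes):
        tid = f"{target_id}_novel{k:02d}"
        proteome[tid] = _random_protein(rng)
        target_ids.append(tid)

    annotation, tus = _layout_genome(target_id, target_ids, proteome, spec, rng)

    pairs = []
    for ref_gene in sorted(conserved):
        tid = conserved[ref_gene]
        ident = sequence_identity(reference.proteome[ref_gene], proteome[tid])
        pairs.append((ref_gene, tid, _bit_score(ident, len(proteome[tid])), ident))
    omap = OrthologMap(
        genome_a=reference.genome_id,
        genome_b=target_id,
        pairs=pairs,
        genes_a=set(reference.proteome),
        genes_b=set(proteome),
    )

    # expected transfer: exhaustive both-endpoints-conserved scan
    expected = GRN(target_id)
    serial = 1
    for inter in sorted(reference.grn, key=lambda i: i.key):
        if inter.tf in conserved and inter.tg in conserved:
            expected.add(
                RegulatoryInteraction(
                    interaction_id=serial,
                    tf=conserved[inter.tf],
                    tg=conserved[inter.tg],
                    effect=inter.effect,
                    annotations=list(inter.annotations),
                    provenance={(reference.genome_id, "orthology")},
                )
            )
            serial += 1

    # expected TU expansion: direct scan of the planted target TUs
    expanded = expected.copy()
    head_of = {tu.genes[0]: tu for tu in tus}
    serial = len(expected) + 1
    for inter in sorted(expected, key=lambda i: i.key):
        tu = head_of.get(inter.tg)
        if tu is None:
            continue
        for downstream in tu.genes[1:]:
            expanded.add(
                RegulatoryInteraction(
                    interaction_id=serial,
                    tf=inter.tf,
                    tg=downstream,
                    effect=inter.effect,
                    annotations=list(inter.annotations),
                    provenance={(reference.genome_id, "tu_expansion")},
                )
            )
            serial += 1

    return TargetFixture(
        genome_id=target_id,
        annotation=annotation,
        proteome=proteome,
        ortholog_map=omap,
        expected_transferred=expected,
        expected_expanded=expanded,
        tus=tus,
        conserved=conserved,
    )


# ---------------------------------------------------------------------------
# Built-in similarity scoring
# ---------------------------------------------------------------------------


def sequence_identity(a: str, b: str) -> float:
    """Percent identity over the ungapped head-to-head alignment."""
    aln = min(len(a), len(b))
    if aln == 0:
        return 0.0
    matches = sum(1 for x, y in zip(a[:aln], b[:aln]) if x == y)
    return 100.0 * matches / aln


def _bit_score(identity: float, length: int) -> float:
    return round(2.0 * identity * length / 100.0, 1)


def _e_value(identity: float) -> float:
    # monotone decreasing in identity; crosses the 1e-5 threshold
    # around 20% identity so random-level hits fail the E-value filter
    return float(min(10.0, 10.0 ** (-identity / 4.0)))


def emit_hit_table(
    proteome_a: dict[str, str], proteome_b: dict[str, str]
) -> list[HitRecord]:
    """All-vs-all similarity hits between two toy proteomes.

    Identity is exact per-residue identity of the head-to-head
    alignment, coverage follows from the length ratio, and E-values
    decrease monotonically with identity.  Planted ortholog pairs
    (mutated copies) score near 100% identity; unrelated pairs sit at
    the ~5% random floor, far below every default threshold, so
    reciprocal best hits recover exactly the planted map.
    """
    hits: list[HitRecord] = []
    for qid in sorted(proteome_a):
        qseq = proteome_a[qid]
        for sid in sorted(proteome_b):
            sseq = proteome_b[sid]
            ident = sequence_identity(qseq, sseq)
            aln = min(len(qseq), len(sseq))
            hits.append(
                HitRecord(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=round(ident, 2),
                    alignment_length=aln,
                    e_value=_e_value(ident),
                    bit_score=_bit_score(ident, aln),
                    query_coverage=round(100.0 * aln / len(qseq), 2),
                    subject_coverage=round(100.0 * aln / len(sseq), 2),
                )
            )
    return hits


def hit_tables_for(
    reference: ReferenceFixture, target: TargetFixture
) -> tuple[list[HitRecord], list[HitRecord]]:
    """Convenience: the (A->B, B->A) hit tables for an RBH run."""
    ab = emit_hit_table(reference.proteome, target.proteome)
    ba = emit_hit_table(target.proteome, reference.proteome)
    return ab, ba
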