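"""Domain types and readers/writers for every on-disk artifact.

Covers genome annotations (GenBank flat files or a plain TSV dialect),
labeled protein FASTA, homogenized regulatory-interaction tables,
BLAST outfmt-6 similarity-hit tables, and network exports (TSV, SIF,
GraphML, Cytoscape JSON).

Conventions
-----------
* Coordinates are 1-based inclusive (GenBank convention).
* Any missing text field is stored as the literal token ``"NODATA"``;
  such a token is never usable as a gene identifier key.
* Labeled FASTA headers carry five pipe-delimited fields:
  NCBI gene ID | local gene ID | gene name | product | organism.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
from Bio import SeqIO

from grntransfer.errors import (
    EmptyAnnotationError,
    FormatError,
    UnknownGeneError,
    UsageError,
)

logger = logging.getLogger(__name__)

#: Placeholder for any missing text field.
NODATA = "NODATA"

#: Recognized regulatory-effect values.
EFFECTS = ("activation", "repression", "dual", "unknown")

# Heterogeneous source-database vocabularies mapped onto one effect enum.
_EFFECT_TOKENS = {
    "+": "activation",
    "activator": "activation",
    "activation": "activation",
    "-": "repression",
    "−": "repression",  # unicode minus
    "repressor": "repression",
    "repression": "repression",
    "+/-": "dual",
    "+/−": "dual",
    "dual": "dual",
}

#: Provenance derivation modes for a regulatory edge.
DERIVATIONS = ("direct", "orthology", "tu_expansion")


def parse_effect(tokens: Iterable[str]) -> str:
    """Map free-text annotation tokens onto the effect enum.

    The first recognizable token wins; unrecognized annotations yield
    ``"unknown"``.
    """
    for tok in tokens:
        eff = _EFFECT_TOKENS.get(tok.strip().lower())
        if eff is not None:
            return eff
    return "unknown"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneRecord:
    """One protein-coding gene of one genome.

    ``start``/``end`` are 1-based inclusive with ``start <= end``
    regardless of strand; ``strand`` is ``"+"`` or ``"-"``.
    """

    genome_id: str
    locus_id: str
    ncbi_gene_id: str = NODATA
    protein_id: str = NODATA
    gene_name: str = NODATA
    product: str = NODATA
    start: int = 1
    end: int = 1
    strand: str = "+"
    replicon_id: str = NODATA
    protein_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise UsageError(
                f"gene {self.locus_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise UsageError(f"gene {self.locus_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Ordered, stranded gene records of one genome.

    Genes are kept sorted by ``(replicon_id, start, end)``; intervals on
    the same replicon may abut or overlap.
    """

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._sort()

    def _sort(self) -> None:
        self.genes.sort(key=lambda g: (g.replicon_id, g.start, g.end, g.locus_id))

    def add(self, gene: GeneRecord) -> None:
        self.genes.append(gene)
        self._sort()

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def by_locus(self) -> dict[str, GeneRecord]:
        return {g.locus_id: g for g in self.genes}


@dataclass
class RegulatoryInteraction:
    """A directed TF -> target-gene edge with effect sign and provenance.

    ``provenance`` is a set of ``(source_organism, derivation)`` pairs;
    an edge derived from several references keeps one record with a
    multi-element provenance set.
    """

    interaction_id: int
    tf: str
    tg: str
    effect: str = "unknown"
    annotations: list[str] = field(default_factory=list)
    provenance: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise UsageError(f"unknown effect {self.effect!r}")
        for _, deriv in self.provenance:
            if deriv not in DERIVATIONS:
                raise UsageError(f"unknown derivation {deriv!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.tf, self.tg)

    def copy(self) -> "RegulatoryInteraction":
        return replace(
            self,
            annotations=list(self.annotations),
            provenance=set(self.provenance),
        )


class GRN:
    """A gene regulatory network: genes as nodes, TF->TG edges.

    Interactions are keyed by ``(tf, tg)`` so the edge set never holds
    duplicates; merging a duplicate key unions annotations and
    provenance, and conflicting effect signs collapse to ``"dual"``.
    """

    def __init__(
        self,
        organism: str,
        interactions: Iterable[RegulatoryInteraction] = (),
    ) -> None:
        self.organism = organism
        self._interactions: dict[tuple[str, str], RegulatoryInteraction] = {}
        for inter in interactions:
            self.add(inter)

    # -- mutation ----------------------------------------------------------

    def add(self, inter: RegulatoryInteraction) -> RegulatoryInteraction:
        """Add an interaction, merging with an existing (tf, tg) edge."""
        if NODATA in inter.key:
            raise UsageError("NODATA is not a legal gene identifier for an edge")
        existing = self._interactions.get(inter.key)
        if existing is None:
            self._interactions[inter.key] = inter.copy()
            return self._interactions[inter.key]
        for ann in inter.annotations:
            if ann not in existing.annotations:
                existing.annotations.append(ann)
        existing.provenance |= inter.provenance
        if existing.effect != inter.effect:
            if "unknown" in (existing.effect, inter.effect):
                known = inter.effect if existing.effect == "unknown" else existing.effect
                existing.effect = known
            else:
                existing.effect = "dual"
        return existing

    # -- access ------------------------------------------------------------

    @property
    def interactions(self) -> dict[tuple[str, str], RegulatoryInteraction]:
        return self._interactions

    def edges(self) -> set[tuple[str, str]]:
        return set(self._interactions)

    def __len__(self) -> int:
        return len(self._interactions)

    def __iter__(self) -> Iterator[RegulatoryInteraction]:
        return iter(self._interactions.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._interactions

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _ in self._interactions}

    @property
    def targets(self) -> set[str]:
        return {tg for _, tg in self._interactions}

    @property
    def genes(self) -> set[str]:
        return self.tfs | self.targets

    @property
    def node_roles(self) -> dict[str, str]:
        """Map gene -> role: ``TF`` (only out-edges), ``TG``, or ``both``."""
        roles: dict[str, str] = {}
        for gene in self.genes:
            is_tf = gene in self.tfs
            is_tg = gene in self.targets
            roles[gene] = "both" if (is_tf and is_tg) else ("TF" if is_tf else "TG")
        return roles

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(organism=self.organism)
        roles = self.node_roles
        for gene, role in sorted(roles.items()):
            g.add_node(gene, role=role)
        for inter in self._interactions.values():
            g.add_edge(
                inter.tf,
                inter.tg,
                effect=inter.effect,
                provenance=_provenance_str(inter.provenance),
            )
        return g

    def copy(self, organism: str | None = None) -> "GRN":
        return GRN(organism or self.organism, (i.copy() for i in self))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GRN):
            return NotImplemented
        if self.organism != other.organism or self.edges() != other.edges():
            return False
        for key, inter in self._interactions.items():
            o = other._interactions[key]
            if (inter.effect, inter.provenance) != (o.effect, o.provenance):
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"GRN({self.organism!r}, {len(self)} interactions, "
            f"{len(self.tfs)} TFs, {len(self.genes)} genes)"
        )


@dataclass
class HitRecord:
    """One pairwise protein similarity hit (BLAST outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    query_coverage: float = 100.0
    subject_coverage: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise UsageError(f"identity {self.percent_identity} outside [0, 100]")
        for cov in (self.query_coverage, self.subject_coverage):
            if not 0.0 <= cov <= 100.0:
                raise UsageError(f"coverage {cov} outside [0, 100]")
        if self.e_value < 0:
            raise UsageError(f"negative e-value {self.e_value}")


# ---------------------------------------------------------------------------
# Annotation IO
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "genome_id",
    "locus_id",
    "ncbi_gene_id",
    "protein_id",
    "gene_name",
    "product",
    "start",
    "end",
    "strand",
    "replicon_id",
    "protein_sequence",
]


def read_annotation(path: str | Path, dialect: str = "genbank") -> GenomeAnnotation:
    """Read a genome annotation from GenBank flat file or plain TSV.

    Every CDS feature yields one :class:`GeneRecord`; fields missing in
    the source become ``"NODATA"``.  Raises
    :class:`~grntransfer.errors.EmptyAnnotationError` when no CDS is
    found, :class:`~grntransfer.errors.FormatError` on unparseable
    input.
    """
    path = Path(path)
    if dialect == "genbank":
        return _read_genbank(path)
    if dialect == "tsv":
        return _read_annotation_tsv(path)
    raise UsageError(f"unknown annotation dialect {dialect!r}")


def _read_genbank(path: Path) -> GenomeAnnotation:
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise FormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not seq_records:
        raise FormatError(f"{path}: no GenBank records found")

    genome_id = NODATA
    genes: list[GeneRecord] = []
    for rec in seq_records:
        organism = rec.annotations.get("organism") or rec.annotations.get("source")
        if organism and genome_id == NODATA:
            genome_id = organism
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            q = feat.qualifiers
            gene_id = NODATA
            for xref in q.get("db_xref", []):
                if xref.startswith("GeneID:"):
                    gene_id = xref.split(":", 1)[1]
            translation = q.get("translation", [None])[0]
            try:
                start = int(feat.location.start) + 1  # Biopython is 0-based
                end = int(feat.location.end)
                strand = "-" if feat.location.strand == -1 else "+"
            except (TypeError, AttributeError) as exc:
                raise FormatError(
                    f"{path}: CDS feature without usable location: {feat}"
                ) from exc
            genes.append(
                GeneRecord(
                    genome_id=genome_id,
                    locus_id=q.get("locus_tag", [NODATA])[0] or NODATA,
                    ncbi_gene_id=gene_id,
                    protein_id=q.get("protein_id", [NODATA])[0] or NODATA,
                    gene_name=q.get("gene", [NODATA])[0] or NODATA,
                    product=q.get("product", [NODATA])[0] or NODATA,
                    start=start,
                    end=end,
                    strand=strand,
                    replicon_id=rec.id or NODATA,
                    protein_sequence=translation,
                )
            )
    if not genes:
        raise EmptyAnnotationError(f"{path}: zero CDS features")
    return GenomeAnnotation(genome_id=genome_id, genes=genes)


def _read_annotation_tsv(path: Path) -> GenomeAnnotation:
    genes: list[GeneRecord] = []
    genome_id = NODATA
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TSV_COLUMNS) - 1] != _TSV_COLUMNS[:-1]:
            raise FormatError(f"{path}: line 1: unexpected TSV header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise FormatError(f"{path}: line {lineno}: expected >=10 columns")
            try:
                start, end = int(parts[6]), int(parts[7])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            seq = parts[10] if len(parts) > 10 and parts[10] not in ("", NODATA) else None
            genes.append(
                GeneRecord(
                    genome_id=parts[0],
                    locus_id=parts[1],
                    ncbi_gene_id=parts[2],
                    protein_id=parts[3],
                    gene_name=parts[4],
                    product=parts[5],
                    start=start,
                    end=end,
                    strand=parts[8],
                    replicon_id=parts[9],
                    protein_sequence=seq,
                )
            )
            genome_id = parts[0]
    if not genes:
        raise EmptyAnnotationError(f"{path}: zero gene rows")
    return GenomeAnnotation(genome_id=genome_id, genes=genes)


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Serialize an annotation to the TSV dialect (lossless round-trip)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for g in annotation.genes:
            fh.write(
                "\t".join(
                    [
                        g.genome_id,
                        g.locus_id,
                        g.ncbi_gene_id,
                        g.protein_id,
                        g.gene_name,
                        g.product,
                        str(g.start),
                        str(g.end),
                        g.strand,
                        g.replicon_id,
                        g.protein_sequence or NODATA,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Labeled FASTA
# ---------------------------------------------------------------------------


def write_labeled_fasta(annotation: GenomeAnnotation, path: str | Path) -> int:
    """Write one FASTA entry per sequenced gene with a five-field header.

    Header: ``ncbi_gene_id|locus_id|gene_name|product|genome_id``.
    Records without a protein sequence are skipped with a logged
    warning; the number skipped is returned.
    """
    skipped = 0
    with open(path, "w") as fh:
        for g in annotation.genes:
            if not g.protein_sequence:
                skipped += 1
                continue
            header = "|".join(
                [g.ncbi_gene_id, g.locus_id, g.gene_name, g.product, g.genome_id]
            )
            fh.write(f">{header}\n{g.protein_sequence}\n")
    if skipped:
        logger.warning(
            "%s: skipped %d gene(s) without protein sequence", path, skipped
        )
    return skipped


def read_labeled_fasta(path: str | Path) -> GenomeAnnotation:
    """Read a labeled FASTA back into a (coordinate-less) annotation."""
    genes: list[GeneRecord] = []
    genome_id = NODATA
    offset = 1
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        if len(fields) != 5:
            raise FormatError(
                f"{path}: header {rec.description!r} does not carry 5 fields"
            )
        ncbi, locus, name, product, organism = fields
        genome_id = organism
        seq = str(rec.seq)
        genes.append(
            GeneRecord(
                genome_id=organism,
                locus_id=locus,
                ncbi_gene_id=ncbi,
                gene_name=name,
                product=product,
                start=offset,
                end=offset + max(len(seq), 1) - 1,
                protein_sequence=seq,
            )
        )
        offset += len(seq) + 1
    return GenomeAnnotation(genome_id=genome_id, genes=genes)


def read_proteome(path: str | Path) -> dict[str, str]:
    """Read any protein FASTA as ``{first header field: sequence}``.

    For labeled FASTA the key is the NCBI gene ID unless it is NODATA,
    in which case the local gene ID is used.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        key = fields[0]
        if key == NODATA and len(fields) > 1:
            key = fields[1]
        seqs[key] = str(rec.seq)
    return seqs


# ---------------------------------------------------------------------------
# Interaction tables
# ---------------------------------------------------------------------------


def read_interaction_table(
    path: str | Path,
    organism: str | None = None,
    derivation: str = "direct",
) -> GRN:
    """Read a homogenized regulatory-interaction table into a GRN.

    Tab-delimited with at least three columns: serial interaction
    number, TF, target gene; any further columns are free-text
    annotations carried opaquely.  Duplicate ``(tf, tg)`` rows collapse
    into one interaction with merged annotations.  The effect sign is
    parsed from annotation columns when a token is recognizable.
    """
    path = Path(path)
    name = organism if organism is not None else path.stem
    grn = GRN(name)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: row {lineno}: fewer than 3 columns")
            try:
                serial = int(parts[0])
            except ValueError:
                serial = lineno
            annotations = [p for p in parts[3:] if p != ""]
            grn.add(
                RegulatoryInteraction(
                    interaction_id=serial,
                    tf=parts[1],
                    tg=parts[2],
                    effect=parse_effect(annotations),
                    annotations=annotations,
                    provenance={(name, derivation)},
                )
            )
    return grn


def write_interaction_table(grn: GRN, path: str | Path) -> None:
    """Write a GRN in the homogenized interaction-table format.

    Columns: serial number, TF, target gene, then the free-text
    annotation columns (the effect token is guaranteed present so the
    sign survives a round-trip).
    """
    with open(path, "w") as fh:
        for serial, inter in enumerate(sorted(grn, key=lambda i: i.key), start=1):
            annotations = list(inter.annotations)
            if inter.effect != "unknown" and parse_effect(annotations) != inter.effect:
                annotations.insert(0, inter.effect)
            fh.write(
                "\t".join([str(serial), inter.tf, inter.tg] + annotations) + "\n"
            )


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------

_SIF_RELATION = {
    "activation": "activates",
    "repression": "represses",
    "dual": "dual",
    "unknown": "regulates",
}

_NET_TSV_COLUMNS = [
    "interaction_id",
    "tf",
    "tg",
    "effect",
    "annotations",
    "provenance",
]


def _provenance_str(prov: set[tuple[str, str]]) -> str:
    return ",".join(f"{org}:{deriv}" for org, deriv in sorted(prov))


def _parse_provenance(text: str) -> set[tuple[str, str]]:
    out: set[tuple[str, str]] = set()
    for item in text.split(","):
        if not item:
            continue
        org, _, deriv = item.rpartition(":")
        out.add((org, deriv))
    return out


def write_network(grn: GRN, path: str | Path, format: str = "tsv") -> None:
    """Export a GRN as TSV (lossless), SIF, GraphML, or Cytoscape JSON."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("# organism: " + grn.organism + "\n")
            fh.write("\t".join(_NET_TSV_COLUMNS) + "\n")
            for inter in sorted(grn, key=lambda i: i.key):
                fh.write(
                    "\t".join(
                        [
                            str(inter.interaction_id),
                            inter.tf,
                            inter.tg,
                            inter.effect,
                            ";".join(inter.annotations),
                            _provenance_str(inter.provenance),
                        ]
                    )
                    + "\n"
                )
    elif format == "sif":
        with open(path, "w") as fh:
            for inter in sorted(grn, key=lambda i: i.key):
                fh.write(f"{inter.tf}\t{_SIF_RELATION[inter.effect]}\t{inter.tg}\n")
    elif format == "graphml":
        nx.write_graphml(grn.to_networkx(), str(path))
    elif format == "cytoscape_json":
        data = nx.cytoscape_data(grn.to_networkx())
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
    else:
        raise UsageError(f"unknown network format {format!r}")


def read_network(path: str | Path, organism: str | None = None) -> GRN:
    """Read back a TSV network export written by :func:`write_network`."""
    path = Path(path)
    name = organism
    rows: list[RegulatoryInteraction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("# organism:"):
                if name is None:
                    name = line.split(":", 1)[1].strip()
                continue
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "interaction_id":
                continue
            if len(parts) < 6:
                raise FormatError(f"{path}: row {lineno}: expected 6 columns")
            rows.append(
                RegulatoryInteraction(
                    interaction_id=int(parts[0]),
                    tf=parts[1],
                    tg=parts[2],
                    effect=parts[3],
                    annotations=[a for a in parts[4].split(";") if a],
                    provenance=_parse_provenance(parts[5]),
                )
            )
    if name is None:
        name = path.stem
    return GRN(name, rows)


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------


def read_hit_table(
    path: str | Path,
    query_lengths: Mapping[str, int] | None = None,
    subject_lengths: Mapping[str, int] | None = None,
) -> list[HitRecord]:
    """Read pairwise similarity hits in the 12-column tabular dialect.

    Columns follow BLAST outfmt 6: qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore.  Optional columns
    13 and 14 carry explicit query/subject coverage percentages; when
    absent, coverage is computed as
    ``100 * alignment_length / sequence_length`` from the supplied
    length maps (100 if no lengths are available).
    """
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}: row {lineno}: fewer than 12 columns")
            try:
                pident = float(parts[2])
                length = int(parts[3])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: row {lineno}: non-numeric field: {exc}"
                ) from exc
            if len(parts) >= 14:
                qcov, scov = float(parts[12]), float(parts[13])
            else:
                qcov = _coverage(length, parts[0], query_lengths)
                scov = _coverage(length, parts[1], subject_lengths)
            hits.append(
                HitRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=pident,
                    alignment_length=length,
                    e_value=evalue,
                    bit_score=bitscore,
                    query_coverage=qcov,
                    subject_coverage=scov,
                )
            )
    return hits


def _coverage(aln_len: int, seq_id: str, lengths: Mapping[str, int] | None) -> float:
    if lengths is None:
        return 100.0
    if seq_id not in lengths:
        raise UnknownGeneError(f"no sequence length for {seq_id!r}")
    return min(100.0, 100.0 * aln_len / lengths[seq_id])


def write_hit_table(hits: Sequence[HitRecord], path: str | Path) -> None:
    """Write hits in the 14-column dialect (explicit coverages)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        str(h.alignment_length),
                        "0",
                        "0",
                        "1",
                        str(h.alignment_length),
                        "1",
                        str(h.alignment_length),
                        f"{h.e_value:.3g}",
                        f"{h.bit_score:.1f}",
                        f"{h.query_coverage:.2f}",
                        f"{h.subject_coverage:.2f}",
                    ]
                )
                + "\n"
            )
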