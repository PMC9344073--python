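"""Reciprocal-best-hit orthology between two proteomes.

Pairwise similarity hits (BLAST outfmt-6 dialect, or the built-in toy
scorer in :mod:`grntransfer.synthetic_fixtures`) are filtered on
E-value, coverage, and percent identity, then reduced to strict
reciprocal best hits (RBH): a pair (a, b) is kept iff b is a's
highest-scoring subject A->B and a is b's highest-scoring subject
B->A.  The result is a 1:1 gene correspondence map; co-ortholog
(1:many) groups are deliberately out of scope.

Default thresholds: E-value <= 1e-5, coverage >= 70% on both query and
subject, identity >= 25% — the parameterization commonly used for
transcription-factor ortholog detection in bacteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from grntransfer.annotation_io import NODATA, HitRecord
from grntransfer.errors import UnknownGeneError, UsageError


@dataclass(frozen=True)
class OrthologyParams:
    """Similarity thresholds a hit must pass in both directions."""

    max_evalue: float = 1e-5
    min_coverage: float = 70.0
    min_identity: float = 25.0

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise UsageError("max_evalue must be > 0")
        for name in ("min_coverage", "min_identity"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise UsageError(f"{name} must be in (0, 100]")


@dataclass
class OrthologMap:
    """1:1 ortholog pairs between two genomes, indexed both ways."""

    genome_a: str
    genome_b: str
    pairs: list[tuple[str, str, float, float]] = field(default_factory=list)
    #: optional full gene universes, used to distinguish "unmapped gene"
    #: from "gene unknown to either proteome"
    genes_a: set[str] | None = None
    genes_b: set[str] | None = None

    def __post_init__(self) -> None:
        self._a2b: dict[str, str] = {}
        self._b2a: dict[str, str] = {}
        for a, b, _, _ in self.pairs:
            if a in self._a2b or b in self._b2a:
                raise UsageError(f"ortholog pair ({a}, {b}) duplicates a gene")
            self._a2b[a] = b
            self._b2a[b] = a

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self, gene: str) -> str | None:
        return self._a2b.get(gene)

    def b_to_a(self, gene: str) -> str | None:
        return self._b2a.get(gene)

    def as_pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _, _ in self.pairs}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# genome_a: {self.genome_a}\n# genome_b: {self.genome_b}\n")
            fh.write("gene_a\tgene_b\tbit_score\tidentity\n")
            for a, b, score, ident in sorted(self.pairs):
                fh.write(f"{a}\t{b}\t{score:.1f}\t{ident:.2f}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologMap":
        genome_a = genome_b = "?"
        pairs: list[tuple[str, str, float, float]] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("# genome_a:"):
                    genome_a = line.split(":", 1)[1].strip()
                elif line.startswith("# genome_b:"):
                    genome_b = line.split(":", 1)[1].strip()
                elif line.startswith(("#", "gene_a\t")) or not line.strip():
                    continue
                else:
                    a, b, score, ident = line.rstrip("\n").split("\t")
                    pairs.append((a, b, float(score), float(ident)))
        return cls(genome_a=genome_a, genome_b=genome_b, pairs=pairs)


def filter_hits(
    hits: Iterable[HitRecord], params: OrthologyParams = OrthologyParams()
) -> list[HitRecord]:
    """Retain hits passing all three thresholds.

    A hit survives iff ``e_value <= max_evalue`` and
    ``min(query_coverage, subject_coverage) >= min_coverage`` and
    ``percent_identity >= min_identity``.
    """
    return [
        h
        for h in hits
        if h.e_value <= params.max_evalue
        and min(h.query_coverage, h.subject_coverage) >= params.min_coverage
        and h.percent_identity >= params.min_identity
    ]


def _best_hits(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Best subject per query: highest bit score, ties broken by lower
    e-value, higher identity, then lexicographic subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) > _hit_rank(cur):
            best[h.query_id] = h
    return best


def _hit_rank(h: HitRecord) -> tuple[float, float, float, list[int]]:
    # lexicographically *smaller* subject id wins, hence the negated bytes
    return (
        h.bit_score,
        -h.e_value,
        h.percent_identity,
        [-b for b in h.subject_id.encode()],
    )


def reciprocal_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    params: OrthologyParams = OrthologyParams(),
    genome_a: str = "A",
    genome_b: str = "B",
    genes_a: set[str] | None = None,
    genes_b: set[str] | None = None,
) -> OrthologMap:
    """Compute the filtered reciprocal-best-hit ortholog map A<->B."""
    fab = _best_hits(filter_hits(hits_ab, params))
    fba = _best_hits(filter_hits(hits_ba, params))
    pairs: list[tuple[str, str, float, float]] = []
    for a, hit in sorted(fab.items()):
        b = hit.subject_id
        back = fba.get(b)
        if back is not None and back.subject_id == a:
            pairs.append((a, b, hit.bit_score, hit.percent_identity))
    return OrthologMap(
        genome_a=genome_a,
        genome_b=genome_b,
        pairs=pairs,
        genes_a=genes_a,
        genes_b=genes_b,
    )


def map_gene(gene: str, omap: OrthologMap, direction: str = "a_to_b") -> str | None:
    """Return the ortholog of ``gene`` across the map, or None.

    ``direction`` is ``"a_to_b"`` or ``"b_to_a"``.  When the map
    carries gene universes, a gene absent from both proteomes raises
    :class:`~grntransfer.errors.UnknownGeneError`.  The NODATA token is
    never a valid query and never returned.
    """
    if gene == NODATA:
        raise UsageError("NODATA is not a mappable gene identifier")
    if direction == "a_to_b":
        result = omap.a_to_b(gene)
        universe = omap.genes_a
    elif direction == "b_to_a":
        result = omap.b_to_a(gene)
        universe = omap.genes_b
    else:
        raise UsageError(f"unknown direction {direction!r}")
    if result is None and universe is not None and gene not in universe:
        raise UnknownGeneError(f"{gene!r} not in proteome of either genome")
    return result
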