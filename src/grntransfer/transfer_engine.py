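"""Guilt-by-association transfer of regulatory interactions.

The core inference: a TF->TG edge of a reference organism is assigned
to a target genome whenever orthologs of both the TF and the TG exist
there (guilt by association).  Transferred edges whose target heads a
predicted transcription unit are then extended to the remaining genes
of that TU.  Predictions derived from several references are
integrated into one network, each edge keeping the full set of
(source organism, derivation) provenance pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from grntransfer.annotation_io import (
    GRN,
    GenomeAnnotation,
    NODATA,
    RegulatoryInteraction,
)
from grntransfer.errors import UsageError
from grntransfer.operon_model import TranscriptionUnit, first_gene_index
from grntransfer.orthology import OrthologMap

logger = logging.getLogger(__name__)

#: Regulator classes belonging to the basal transcription machinery,
#: excluded from the TF set by default.
BASAL_MACHINERY_TOKENS = frozenset(
    {"sigma factor", "antiterminator", "terminator", "sensor"}
)


@dataclass
class TransferConfig:
    """References and regulator-filtering policy for a transfer run."""

    references: list[tuple[str, GRN, dict[str, str]]] = field(default_factory=list)
    exclude_nontf_regulators: bool = True
    excluded_regulator_classes: frozenset[str] = BASAL_MACHINERY_TOKENS


@dataclass
class ReportRow:
    """New-interaction accounting for one target reference organism."""

    organism: str
    known_edges: int
    per_source_new: dict[str, int]
    tu_new: int
    total_new: int

    def percentages(self) -> dict[str, float]:
        """Per-source share of the total new interactions, in percent.

        Because one new edge can derive from several sources, the
        shares of a row may sum to more than 100.
        """
        out = {
            src: contribution_percentage(n, self.total_new)
            for src, n in self.per_source_new.items()
        }
        out["TUs"] = contribution_percentage(self.tu_new, self.total_new)
        return out


@dataclass
class TransferReport:
    """Cross-reference accounting: one row per target organism plus the
    pairwise overlap matrix of transferable edges."""

    rows: dict[str, ReportRow]
    overlap: dict[tuple[str, str], int]


def contribution_percentage(count: int, total: int) -> float:
    """Share of new interactions contributed by one source, in percent,
    truncated (not rounded) to 2 decimals; 0.0 for an empty total.

    Truncation matches the convention of published per-source share
    tables in this domain (e.g. 395 of 1,821 -> 21.69, 34 of 1,821 ->
    1.86).
    """
    if total == 0:
        return 0.0
    return math.floor(10000.0 * count / total + 1e-9) / 100.0


# ---------------------------------------------------------------------------
# Transfer
# ---------------------------------------------------------------------------


def _directional_lookup(omap: OrthologMap, ref_organism: str):
    """Return gene-mapping callable oriented from ``ref_organism``."""
    if omap.genome_a == ref_organism:
        return omap.a_to_b, omap.genome_b
    if omap.genome_b == ref_organism:
        return omap.b_to_a, omap.genome_a
    raise UsageError(
        f"ortholog map joins {omap.genome_a!r}/{omap.genome_b!r}, "
        f"not reference {ref_organism!r}"
    )


def transfer_interactions(
    ref_grn: GRN,
    omap: OrthologMap,
    target_organism: str | None = None,
) -> GRN:
    """Transfer every reference edge whose TF and TG both have orthologs.

    The new edge joins the two orthologs in the target genome; effect
    and annotations are copied and provenance is
    ``{(reference organism, "orthology")}``.  Edges with only one (or
    neither) endpoint mapped are dropped.
    """
    lookup, mapped_target = _directional_lookup(omap, ref_grn.organism)
    target = GRN(target_organism or mapped_target)
    serial = itertools.count(1)
    for inter in sorted(ref_grn, key=lambda i: i.key):
        tf_t = lookup(inter.tf)
        tg_t = lookup(inter.tg)
        if tf_t is None or tg_t is None or NODATA in (tf_t, tg_t):
            continue
        target.add(
            RegulatoryInteraction(
                interaction_id=next(serial),
                tf=tf_t,
                tg=tg_t,
                effect=inter.effect,
                annotations=list(inter.annotations),
                provenance={(ref_grn.organism, "orthology")},
            )
        )
    return target


def expand_by_tu(grn: GRN, tus: Iterable[TranscriptionUnit]) -> GRN:
    """Extend each edge across its target's transcription unit.

    For every edge TF->g where g is the first (promoter-proximal) gene
    of its TU, edges TF->d are added for each downstream gene d of the
    TU, with derivation ``tu_expansion`` and the same source organisms
    as the seed edge.  Edges pointing at internal TU genes are not
    expanded.  The operation is a closure: idempotent, extensive, and
    monotone in its input.
    """
    index = first_gene_index(tus)
    expanded = grn.copy()
    serial = itertools.count(max((i.interaction_id for i in grn), default=0) + 1)
    for inter in sorted(grn, key=lambda i: i.key):
        entry = index.get(inter.tg)
        if entry is None:
            continue
        _, is_first, downstream = entry
        if not is_first:
            continue
        sources = {org for org, _ in inter.provenance}
        for d in downstream:
            expanded.add(
                RegulatoryInteraction(
                    interaction_id=next(serial),
                    tf=inter.tf,
                    tg=d,
                    effect=inter.effect,
                    annotations=list(inter.annotations),
                    provenance={(org, "tu_expansion") for org in sources},
                )
            )
    return expanded


def integrate(networks: Sequence[GRN]) -> GRN:
    """Union several predictions for the same target genome.

    The same (tf, tg) edge arriving from several references collapses
    to one interaction with merged provenance; conflicting effect
    signs are recorded as ``dual``.
    """
    if not networks:
        raise UsageError("integrate() needs at least one network")
    organisms = {n.organism for n in networks}
    if len(organisms) > 1:
        raise UsageError(f"networks describe different target genomes: {organisms}")
    merged = GRN(networks[0].organism)
    for net in networks:
        for inter in sorted(net, key=lambda i: i.key):
            merged.add(inter)
    return merged


def filter_regulators(
    grn: GRN,
    annotation: GenomeAnnotation,
    config: TransferConfig | None = None,
) -> GRN:
    """Drop edges whose regulator belongs to the basal machinery.

    A regulator is excluded when its annotated product or gene name
    contains (case-insensitive) any excluded class token, e.g. "RNA
    polymerase sigma factor".  Regulators absent from the annotation
    are kept.
    """
    config = config or TransferConfig()
    if not config.exclude_nontf_regulators or not config.excluded_regulator_classes:
        return grn.copy()
    tokens = [t.lower() for t in sorted(config.excluded_regulator_classes)]
    by_locus = annotation.by_locus()

    def excluded(tf: str) -> bool:
        gene = by_locus.get(tf)
        if gene is None:
            return False
        text = f"{gene.product} {gene.gene_name}".lower()
        return any(tok in text for tok in tokens)

    kept = GRN(grn.organism)
    removed = 0
    for inter in sorted(grn, key=lambda i: i.key):
        if excluded(inter.tf):
            removed += 1
            continue
        kept.add(inter)
    if removed:
        logger.info(
            "%s: removed %d edge(s) with basal-machinery regulators",
            grn.organism,
            removed,
        )
    return kept


# ---------------------------------------------------------------------------
# Cross-reference accounting
# ---------------------------------------------------------------------------


def _map_between(
    maps: Mapping[tuple[str, str], OrthologMap], source: str, target: str
) -> OrthologMap | None:
    omap = maps.get((source, target))
    if omap is None:
        omap = maps.get((target, source))
    return omap


def cross_reference_report(
    ref_grns: Mapping[str, GRN],
    ortholog_maps: Mapping[tuple[str, str], OrthologMap],
    tus: Mapping[str, Sequence[TranscriptionUnit]] | None = None,
) -> TransferReport:
    """Account for the new interactions each reference gains from the others.

    For each reference organism R, the new interactions are the edges
    transferable into R from every other reference (orthology) plus
    the TU expansions of the resulting network (native and transferred
    edges alike), minus edges already present in R's own network.  The
    per-source share is ``100 * count(source) / total new``; since an
    edge may derive from several sources, row shares can exceed 100.
    """
    rows: dict[str, ReportRow] = {}
    overlap: dict[tuple[str, str], int] = {}
    for target_org, target_grn in ref_grns.items():
        known = target_grn.edges()
        transferred: list[GRN] = []
        per_source: dict[str, int] = {}
        for source_org, source_grn in ref_grns.items():
            if source_org == target_org:
                continue
            omap = _map_between(ortholog_maps, source_org, target_org)
            if omap is None:
                raise UsageError(
                    f"no ortholog map between {source_org!r} and {target_org!r}"
                )
            t = transfer_interactions(source_grn, omap, target_organism=target_org)
            new_from_source = t.edges() - known
            per_source[source_org] = len(new_from_source)
            overlap[(source_org, target_org)] = len(t.edges() & known)
            transferred.append(t)
        combined = integrate([target_grn.copy()] + transferred)
        orthology_new = combined.edges() - known
        if tus is not None and target_org in tus:
            expanded = expand_by_tu(combined, tus[target_org])
            tu_new_edges = expanded.edges() - combined.edges()
        else:
            tu_new_edges = set()
        rows[target_org] = ReportRow(
            organism=target_org,
            known_edges=len(known),
            per_source_new=per_source,
            tu_new=len(tu_new_edges),
            total_new=len(orthology_new | tu_new_edges),
        )
    return TransferReport(rows=rows, overlap=overlap)
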