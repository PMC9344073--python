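import numpy as np
import pytest

from grntransfer.annotation_io import (
    GRN,
    GeneRecord,
    GenomeAnnotation,
    RegulatoryInteraction,
)
from grntransfer.synthetic_fixtures import (
    FixtureSpec,
    derive_target,
    generate_reference,
)


def make_grn(organism, edges, effect="activation", derivation="direct"):
    """Build a GRN from (tf, tg) pairs with uniform effect/provenance."""
    grn = GRN(organism)
    for i, (tf, tg) in enumerate(edges, start=1):
        grn.add(
            RegulatoryInteraction(
                interaction_id=i,
                tf=tf,
                tg=tg,
                effect=effect,
                provenance={(organism, derivation)},
            )
        )
    return grn


def random_grn(rng, organism="net", n_tfs=5, n_genes=15, n_edges=20):
    """A random directed TF->gene network (no duplicate edges)."""
    tfs = [f"tf{i}" for i in range(n_tfs)]
    genes = tfs + [f"g{i}" for i in range(n_genes - n_tfs)]
    possible = [(tf, tg) for tf in tfs for tg in genes if tf != tg]
    idx = rng.choice(len(possible), size=min(n_edges, len(possible)), replace=False)
    return make_grn(organism, [possible[i] for i in sorted(idx)])


def linear_annotation(genome_id, layout):
    """Annotation from (locus, start, end, strand[, replicon]) tuples."""
    genes = []
    for item in layout:
        locus, start, end, strand = item[:4]
        replicon = item[4] if len(item) > 4 else "chr"
        genes.append(
            GeneRecord(
                genome_id=genome_id,
                locus_id=locus,
                start=start,
                end=end,
                strand=strand,
                replicon_id=replicon,
                protein_sequence="M" * 30,
            )
        )
    return GenomeAnnotation(genome_id=genome_id, genes=genes)


@pytest.fixture(scope="session")
def ecosystem():
    """One reference + derived target with planted truth (default spec)."""
    spec = FixtureSpec(seed=11)
    ref = generate_reference(spec, genome_id="refA")
    tgt = derive_target(ref, spec, target_id="tgtX")
    return spec, ref, tgt


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
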