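import numpy as np
import pytest

from duoburden.model import AnnotatedVariant, Consequence
from duoburden.simulate import SimulationConfig, generate_cohort


def make_variant(
    sample_id="S1",
    chrom="1",
    pos=1000,
    ref="A",
    alt="T",
    gene="GENEA",
    consequence=Consequence.NONSYNONYMOUS_SNV,
    alt_depth=20,
    total_depth=40,
    genotype_quality=60,
    mapping_quality=60,
    pop_afs=None,
    deleterious_votes=3,
    deleterious_total=4,
):
    return AnnotatedVariant(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        alt_depth=alt_depth,
        total_depth=total_depth,
        genotype_quality=genotype_quality,
        mapping_quality=mapping_quality,
        pop_afs=pop_afs or {},
        deleterious_votes=deleterious_votes,
        deleterious_total=deleterious_total,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort reused across read-only tests."""
    config = SimulationConfig(
        seed=42,
        n_duos_all=3,
        n_duos_aml=2,
        n_controls=3,
        n_genes=150,
        candidate_fraction=0.1,
        baseline_rate=0.6,
        planted_compound_het_genes=(("G0001", 1.0),),
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
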