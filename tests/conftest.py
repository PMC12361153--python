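import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from methvalley import CytosineSite, MethylomeSample, pool_samples, simulate_study
from methvalley.simulate import Compartment, LandscapePlan
from methvalley.io import GenomicInterval

STUDY_SEED = 7


def make_sample(records, chrom_sizes=None, tissue="root", replicate=1):
    """MethylomeSample from (chrom, pos, strand, context, meth, unmeth) tuples."""
    return MethylomeSample.from_records(
        [CytosineSite(*r) for r in records],
        sample_id=f"{tissue}_{replicate}", tissue=tissue, replicate=replicate,
        chrom_sizes=chrom_sizes,
    )


@pytest.fixture(scope="session")
def study():
    """The default demo study: 3 x 200 kb chromosomes, 2 tissues x 3 reps, 10x."""
    return simulate_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def pooled(study):
    return {
        tissue: pool_samples(study.samples_for(tissue), f"{tissue}_pooled", tissue)
        for tissue in study.plan.tissues
    }


@pytest.fixture(scope="session")
def null_study():
    """Identical-group null for DMR calibration: one 460-kb chromosome at a
    flat 50% methylation probability, pure binomial sampling (the chi-square
    test's own sampling model), 2 x 3 replicates at 10x."""
    size = 460_000
    plan = LandscapePlan(
        chrom_sizes={"chrN": size},
        compartments=[Compartment(GenomicInterval("chrN", 0, size), "background")],
        class_probs={"background": {"CG": 0.5, "CHG": 0.5, "CHH": 0.5}},
        beta_dispersion=None,
        seed=STUDY_SEED,
    )
    from methvalley.simulate import sample_methylome, simulate_genome

    _, catalog = simulate_genome(plan)
    samples = {
        (tissue, rep): sample_methylome(plan, catalog, tissue, rep)
        for tissue in plan.tissues
        for rep in range(1, plan.replicates + 1)
    }
    return plan, samples
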