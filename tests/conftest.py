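import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from chiffchaff import (
    AdmixtureScenario,
    DivergenceModel,
    GenotypeMatrix,
    default_template,
    draw_lineage_frequencies,
    simulate_genotypes,
)


def build_matrix(rows, groups, gq=None, dp=None, ids=None):
    """Small GenotypeMatrix from a per-site list of genotype codes.

    ``rows`` is a list of lists (sites x samples, codes 0/1/2/-1),
    ``groups`` a group label per sample.
    """
    geno = np.asarray(rows, dtype=np.int8)
    n_sites, n_samples = geno.shape
    sites = pd.DataFrame(
        {
            "contig": "1",
            "pos": np.arange(1, n_sites + 1),
            "ref": "A",
            "alt": "T",
        }
    )
    samples = pd.DataFrame(
        {
            "id": ids or [f"s{i + 1}" for i in range(n_samples)],
            "group": groups,
        }
    )
    return GenotypeMatrix(
        sites=sites,
        genotypes=geno,
        samples=samples,
        gq=None if gq is None else np.asarray(gq, dtype=np.int32),
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
    )


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def diverged_cohort():
    """Strongly diverged default cohort: many sample-fixed diagnostic sites."""
    model = DivergenceModel(n_sites=4000, fst=0.95, seed=11)
    scenario = AdmixtureScenario.default_cohort(10)
    freqs = draw_lineage_frequencies(model)
    matrix = simulate_genotypes(freqs, scenario, model)
    return model, scenario, freqs, matrix
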