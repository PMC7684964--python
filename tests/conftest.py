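import numpy as np
import pandas as pd
import pytest

from cstkit import (
    CentroidSet,
    default_cohort_spec,
    generate_cohort,
    to_relative_abundance,
)


@pytest.fixture()
def toy_counts_csv(tmp_path):
    """Two samples, three taxa, in the file contract."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "sampleID,read_count,Lactobacillus_crispatus,g_Streptococcus,Gardnerella_vaginalis\n"
        "s1,100,90,5,5\n"
        "s2,400,10,200,190\n"
    )
    return path


@pytest.fixture(scope="session")
def default_spec():
    return default_cohort_spec()


@pytest.fixture(scope="session")
def reference_centroids(default_spec):
    """The generator's 13 target profiles used directly as centroids."""
    return CentroidSet(default_spec.profiles.copy())


@pytest.fixture(scope="session")
def tight_cohort():
    """n=1000 cohort at concentration 200 with its relative abundances."""
    spec = default_cohort_spec(concentration=200)
    cohort = generate_cohort(spec, 1000, seed=20)
    props, _ = to_relative_abundance(cohort.table)
    return spec, cohort, props


def random_simplex(rng, size, n_vecs=1):
    """Uniform Dirichlet draws; rows on the simplex."""
    out = rng.dirichlet(np.ones(size), size=n_vecs)
    return out[0] if n_vecs == 1 else out
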