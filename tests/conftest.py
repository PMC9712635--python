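import numpy as np
import pandas as pd
import pytest

from selfline.io_formats import GenotypeTable, HET, HOM_ALT, HOM_REF, MISSING


def make_table(genotypes, positions=None, scaffold="chr1", is_variant=None, qual=None):
    """Build a GenotypeTable from a (samples x loci) code matrix."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_loci = g.shape
    if positions is None:
        positions = [100 * (j + 1) for j in range(n_loci)]
    if is_variant is None:
        is_variant = [True] * n_loci
    loci = pd.DataFrame(
        {
            "scaffold": [scaffold] * n_loci,
            "pos": positions,
            "ref": ["A"] * n_loci,
            "alt": ["G" if v else "" for v in is_variant],
            "is_variant": is_variant,
            "qual": qual if qual is not None else [100.0] * n_loci,
        }
    )
    return GenotypeTable(
        sample_ids=[f"s{i}" for i in range(n_samples)], loci=loci, genotypes=g
    )


def random_table(rng, n_samples=5, n_loci=50, p_missing=0.1, p_invariant=0.3):
    """Random small table with missing data and invariant sites."""
    is_variant = rng.random(n_loci) > p_invariant
    g = np.empty((n_samples, n_loci), dtype=np.int8)
    for j in range(n_loci):
        if is_variant[j]:
            p = rng.uniform(0.1, 0.9)
            g[:, j] = rng.choice(
                [HOM_REF, HET, HOM_ALT],
                size=n_samples,
                p=[p * p, 2 * p * (1 - p), (1 - p) ** 2],
            )
        else:
            g[:, j] = HOM_REF
    g[rng.random(g.shape) < p_missing] = MISSING
    return make_table(g, is_variant=list(is_variant))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
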