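import numpy as np
import pytest

from trajmap.longdata import LongitudinalData


def make_mixture_data(
    intercepts,
    pi,
    sigma=5.0,
    n=400,
    n_visits=3,
    slopes=None,
    seed=0,
    covariates=False,
):
    """Longitudinal data drawn from an intercept(/slope) mixture truth.

    Returns (data, true_groups). Time coding is visit index 0..T-1.
    """
    rng = np.random.default_rng(seed)
    k = len(intercepts)
    slopes = slopes if slopes is not None else [0.0] * k
    g = rng.choice(k, size=n, p=pi)
    t = np.tile(np.arange(n_visits, dtype=float), (n, 1))
    mu = np.asarray(intercepts)[g][:, None] + np.asarray(slopes)[g][:, None] * t
    cov_tv, cov_ti = {}, {}
    if covariates:
        age = rng.normal(50, 8, size=n)[:, None] + 5 * t
        sex = rng.binomial(1, 0.5, size=n).astype(float)
        mu = mu + 0.2 * (age - 50) + 4.0 * sex[:, None]
        cov_tv = {"AGE": age}
        cov_ti = {"SEX": sex}
    y = mu + rng.normal(0, sigma, size=(n, n_visits))
    data = LongitudinalData(
        individual_ids=np.array([str(i) for i in range(n)], dtype=object),
        family_ids=np.array(["0"] * n, dtype=object),
        times=t,
        values=y,
        mask=np.ones((n, n_visits), dtype=bool),
        covariates_tv=cov_tv,
        covariates_ti=cov_ti,
    )
    return data, g


@pytest.fixture(scope="session")
def two_group_data():
    """Well-separated two-group intercept-only mixture (100 vs 150, sigma 5)."""
    return make_mixture_data([100.0, 150.0], [0.6, 0.4], sigma=5.0, n=400, seed=11)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A tiny on-disk study bundle shared by IO/pipeline tests."""
    from trajmap.simulate import CausalGene, SimConfig, make_gaw18_like_bundle

    cfg = SimConfig(
        n_families=2,
        n_unrelated=80,
        n_replicates=4,
        causal_genes=[CausalGene(name="gene_01", ve=0.08)],
        null_region_sizes=(5, 8),
        seed=37,
    )
    outdir = tmp_path_factory.mktemp("bundle")
    paths = make_gaw18_like_bundle(cfg, outdir)
    return cfg, paths
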