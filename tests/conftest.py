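import arviz as az
import numpy as np
import pytest

import vascat as vc
from vascat.model import PARAM_NAMES


@pytest.fixture(scope="session")
def small_graded_cohort():
    """15 graded listeners x 1 continuum with the default design density."""
    pop = vc.PopulationConfig(n_subjects=15, n_continua=1,
                              archetype_mix={"graded": 1.0}, seed=2)
    profiles = vc.sample_population(pop)
    trials = vc.align_ratings(vc.generate_trials(profiles, pop))
    return pop, profiles, trials


@pytest.fixture(scope="session")
def small_graded_fit(small_graded_cohort):
    pop, profiles, trials = small_graded_cohort
    spec = vc.HierarchicalSpec(chains=2, warmup=400, draws=400, seed=3)
    post = vc.fit_continuum(trials, spec)
    return pop, profiles, trials, post


def make_fake_posterior(subject_ids, theta_means, jitter=0.0, seed=0,
                        continuum_id="c1", n_draws=20):
    """HierarchicalPosterior whose subject_theta draws center on given means.

    ``theta_means``: array (n_subjects, 5) on the latent scale.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta_means, dtype=float)[None, None, :, :]
    draws = np.repeat(np.repeat(theta, 2, axis=0), n_draws, axis=1)
    draws = draws + jitter * rng.standard_normal(draws.shape)
    mu = draws.mean(axis=2)
    idata = az.from_dict(
        posterior={"mu": mu, "tau": np.abs(mu) * 0 + 0.1,
                   "subject_theta": draws},
        dims={"mu": ["param"], "tau": ["param"],
              "subject_theta": ["subject", "param"]},
        coords={"param": list(PARAM_NAMES), "subject": list(subject_ids)},
    )
    return vc.HierarchicalPosterior(
        idata=idata, subject_ids=list(subject_ids), item_ids=[],
        spec=vc.HierarchicalSpec(), continuum_id=continuum_id)
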