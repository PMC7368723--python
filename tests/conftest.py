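import numpy as np
import pytest

import heterotic as ht


def make_matrix(calls, alleles=None, ind_prefix="i", marker_prefix="m"):
    """GenotypeMatrix from a plain list-of-lists dosage array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if alleles is None:
        alleles = [("A", "G")] * m
    return ht.GenotypeMatrix(
        individual_ids=[f"{ind_prefix}{i}" for i in range(n)],
        marker_ids=[f"{marker_prefix}{j}" for j in range(m)],
        alleles=alleles,
        calls=calls,
    )


@pytest.fixture(scope="session")
def panel_and_truth():
    """Moderate five-group panel used by several recovery tests."""
    cfg = ht.PanelConfig(n_markers=600, seed=11)
    return ht.simulate_panel(cfg)


@pytest.fixture(scope="session")
def separated_panel():
    """Nearly fixed groups: divergence close to its upper limit, no noise."""
    cfg = ht.PanelConfig(
        n_markers=200, fst=0.95, het_rate=0.0, missing_rate=0.0, n_mixed=0, seed=23
    )
    return ht.simulate_panel(cfg)


@pytest.fixture(scope="session")
def balanced_trial():
    """One-set 6x6 NCII trial, four environments, two replicates."""
    cfg = ht.TrialConfig(
        n_sets=1,
        males_per_set=6,
        females_per_set=6,
        n_envs=4,
        n_reps=2,
        mu=10.0,
        var_env=1.0,
        var_gca_m=0.35,
        var_gca_f=0.35,
        var_sca=0.30,
        var_gxe=0.5,
        var_error=2.0,
        heterosis_delta=0.0,
        seed=5,
    )
    from heterotic.simulate import default_parents

    males, females = default_parents(cfg)
    groups = {p: "1" for ps in males + females for p in ps}
    trial, truth = ht.simulate_ncii_trial(cfg, groups)
    return cfg, trial, truth
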