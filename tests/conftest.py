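import numpy as np
import pandas as pd
import pytest

from metasieve import SyntheticConfig, generate_literature


@pytest.fixture
def small_table() -> pd.DataFrame:
    """Hand-built table: one clearly significant, one marginal, one null group."""
    rows = [
        # P01/SAGAT: one strong significant + one weak nonsignificant
        ("P01", "1", "SAGAT", 0.60, 30, False, False, False),
        ("P01", "1", "SAGAT", 0.10, 30, False, False, False),
        # P02/SAGAT: marginal only (r just above the 0.10 critical value at n=24)
        ("P02", "1", "SAGAT", 0.30, 24, False, False, False),
        # P03/SPAM: all nonsignificant, one negative
        ("P03", "1", "SPAM", 0.05, 40, False, False, False),
        ("P03", "1", "SPAM", -0.40, 40, False, False, False),
        # P04/SPAM: significant alone
        ("P04", "1", "SPAM", 0.50, 28, True, False, False),
    ]
    return pd.DataFrame(
        rows,
        columns=["paper_id", "study_id", "measure", "r", "n", "overfit", "team_level", "ghost"],
    )


@pytest.fixture(scope="session")
def literature() -> pd.DataFrame:
    """One default synthetic literature, shared across tests."""
    return generate_literature(SyntheticConfig(), seed=20240)


@pytest.fixture(scope="session")
def replicate_harness():
    """Fits over many simulated literatures: recovery + CI/PI coverage.

    Shared by the recovery, coverage and prediction-interval checks so the
    expensive refitting happens once per session.
    """
    from metasieve import fit_three_level_reml

    truth = SyntheticConfig()
    rng = np.random.default_rng(555)
    rows = []
    tau_total = float(np.hypot(truth.tau1, truth.tau2))
    for _ in range(500):
        seed = int(rng.integers(2**31))
        df = generate_literature(truth, seed=seed)
        fit = fit_three_level_reml(df)
        new_effects = rng.normal(truth.mu_z, tau_total, size=20)
        rows.append(
            {
                "mu_z": fit.mu_z,
                "tau1": fit.tau1,
                "tau2": fit.tau2,
                "se_robust": fit.se_robust,
                "df_robust": fit.df_robust,
                "ci_lo": fit.ci_z[0],
                "ci_hi": fit.ci_z[1],
                "pi_lo": fit.pi_z[0],
                "pi_hi": fit.pi_z[1],
                "covered": fit.ci_z[0] <= truth.mu_z <= fit.ci_z[1],
                "pi_frac": float(np.mean((fit.pi_z[0] <= new_effects) & (new_effects <= fit.pi_z[1]))),
                "converged": fit.converged,
            }
        )
    return truth, pd.DataFrame(rows)
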