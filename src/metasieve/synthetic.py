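"""Simulated literatures with the structure the three-level model assumes.

Each paper i draws a between-paper deviation u_i ~ N(0, tau1^2); each of
its k_i effects draws a within-paper deviation w_ij ~ N(0, tau2^2); the
true correlation of effect (i, j) is tanh(mu_z + u_i + w_ij) and the
observed correlation is an exact bivariate-normal sample correlation at
the effect's sample size.  Defaults mirror the empirical structure of a
38-paper, ~241-effect literature on situation-awareness/performance
correlations: median sample size 24, median 3 effects per paper-measure
(mean ~6.3, heavy right tail), mu_z = 0.30, tau1 = 0.21, tau2 = 0.11.

The optional ghost filter models selective omission: each non-significant
effect disappears (or is flagged) with a set probability, significant
effects never do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectTableError, validate_effect_frame
from .filtering import FilterPolicy, classify_effects
from .sampling import sample_correlations

__all__ = ["SyntheticConfig", "generate_literature", "apply_ghost_filter"]

# shifted negative binomial for effects per paper-measure:
# k = 1 + NB(size, p); size=0.5 with mean 241/38 gives median 3, mean ~6.34
_K_SIZE = 0.5
_K_MEAN = 241.0 / 38.0

# discretized lognormal for sample sizes: median 24, heavy right tail
_N_MEDIAN = 24.0
_N_SIGMA = 0.65
_N_MIN, _N_MAX = 4, 200


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of a simulated literature (z scale for mu/tau)."""

    n_papers: int = 38
    mu_z: float = 0.30
    tau1: float = 0.21
    tau2: float = 0.11
    k_mean: float = _K_MEAN
    k_size: float = _K_SIZE
    n_median: float = _N_MEDIAN
    n_sigma: float = _N_SIGMA
    n_min: int = _N_MIN
    n_max: int = _N_MAX
    measure_labels: tuple[str, ...] = ("SAGAT", "SPAM", "EndOfTrial")
    measure_weights: tuple[float, ...] = (0.5, 0.2, 0.3)
    ghost_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_papers < 1:
            raise EffectTableError("n_papers must be >= 1")
        if self.tau1 < 0 or self.tau2 < 0:
            raise EffectTableError("tau components must be non-negative")
        if not (0.0 <= self.ghost_prob <= 1.0):
            raise EffectTableError("ghost_prob outside [0, 1]")
        if len(self.measure_labels) != len(self.measure_weights):
            raise EffectTableError("measure_labels and measure_weights differ in length")
        if not np.isclose(sum(self.measure_weights), 1.0):
            raise EffectTableError("measure_weights must sum to 1")
        if self.n_min < 4 or self.n_max < self.n_min:
            raise EffectTableError("require 4 <= n_min <= n_max")


def _draw_k(rng: np.random.Generator, size: int, cfg: SyntheticConfig) -> np.ndarray:
    p = cfg.k_size / (cfg.k_size + (cfg.k_mean - 1.0))
    return 1 + rng.negative_binomial(cfg.k_size, p, size=size)


def _draw_n(rng: np.random.Generator, size: int, cfg: SyntheticConfig) -> np.ndarray:
    out = np.empty(size, dtype=int)
    todo = np.arange(size)
    while todo.size:
        draw = np.rint(rng.lognormal(np.log(cfg.n_median), cfg.n_sigma, size=todo.size)).astype(int)
        ok = (draw >= cfg.n_min) & (draw <= cfg.n_max)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]  # redraw out-of-range sizes
    return out


def generate_literature(config: SyntheticConfig = SyntheticConfig(), seed: int | None = None) -> pd.DataFrame:
    """Generate one simulated effect table (valid per the canonical schema).

    ``seed`` overrides ``config.seed``; identical configuration and seed
    give an identical table.  The returned frame carries an extra
    ``true_z`` column (the per-effect true Fisher-z value) which table
    writers drop.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    width = max(2, len(str(config.n_papers)))
    rows_paper, rows_measure, ks = [], [], []
    u = rng.normal(0.0, config.tau1, size=config.n_papers)
    measures = rng.choice(config.measure_labels, size=config.n_papers, p=config.measure_weights)
    k_per = _draw_k(rng, config.n_papers, config)
    paper_ids = [f"P{i + 1:0{width}d}" for i in range(config.n_papers)]
    for pid, meas, k in zip(paper_ids, measures, k_per):
        rows_paper += [pid] * int(k)
        rows_measure += [meas] * int(k)
        ks.append(int(k))
    total = int(np.sum(k_per))
    paper_index = np.repeat(np.arange(config.n_papers), k_per)
    w = rng.normal(0.0, config.tau2, size=total)
    true_z = config.mu_z + u[paper_index] + w
    n = _draw_n(rng, total, config)
    r = sample_correlations(np.tanh(true_z), n, rng=rng, method="exact")
    df = pd.DataFrame(
        {
            "paper_id": rows_paper,
            "study_id": "1",
            "measure": rows_measure,
            "r": r,
            "n": n,
            "overfit": False,
            "team_level": False,
            "ghost": False,
        }
    )
    df = validate_effect_frame(df)
    df["true_z"] = true_z
    if config.ghost_prob > 0:
        df = apply_ghost_filter(df, config.ghost_prob, seed=int(rng.integers(2**31)))
    return df


def apply_ghost_filter(
    df: pd.DataFrame,
    ghost_prob: float,
    policy: FilterPolicy = FilterPolicy(),
    seed: int | None = None,
    mode: str = "drop",
) -> pd.DataFrame:
    """Selective omission: non-significant effects vanish with probability p.

    ``mode='drop'`` removes them; ``mode='flag'`` keeps them with
    ghost=True.  Significant and marginal effects are never touched —
    omission is conditional on the outcome, which is exactly what makes it
    bias the surviving literature upward.
    """
    if not (0.0 <= ghost_prob <= 1.0):
        raise EffectTableError("ghost_prob outside [0, 1]")
    if mode not in ("drop", "flag"):
        raise EffectTableError("mode must be 'drop' or 'flag'")
    extra = [c for c in df.columns if c not in validate_effect_frame(df).columns]
    frame = validate_effect_frame(df)
    for c in extra:
        frame[c] = df[c].to_numpy()
    rng = np.random.default_rng(seed)
    cats = classify_effects(frame["r"].to_numpy(), frame["n"].to_numpy(), policy)
    nonsig = cats == "nonsignificant"
    hit = nonsig & (rng.random(len(frame)) < ghost_prob)
    if mode == "drop":
        return frame.loc[~hit].reset_index(drop=True)
    frame.loc[hit, "ghost"] = True
    return frame


def expected_observed_z_variance(config: SyntheticConfig) -> float:
    """tau1^2 + tau2^2 + E[1/(n-3)] under the configured n distribution.

    Moment identity used by tests: the marginal variance of observed z
    decomposes into heterogeneity plus average sampling variance.
    """
    # E[1/(n-3)] by numerical expectation over the discretized lognormal
    n = np.arange(config.n_min, config.n_max + 1)
    lo = stats.norm.cdf((np.log(n - 0.5) - np.log(config.n_median)) / config.n_sigma)
    hi = stats.norm.cdf((np.log(n + 0.5) - np.log(config.n_median)) / config.n_sigma)
    pmf = hi - lo
    pmf /= pmf.sum()
    return float(config.tau1**2 + config.tau2**2 + np.sum(pmf / (n - 3.0)))
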