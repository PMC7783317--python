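"""Proportion of true effects beyond a threshold, with bootstrap uncertainty.

Calibrated (empirical-Bayes shrunken) per-effect estimates

    theta_ij = mu + sqrt(tau^2 / (tau^2 + v_ij)) * (z_ij - mu)

pull each observed z toward the pooled mean in proportion to its noise;
the fraction of calibrated estimates below a threshold estimates the
proportion of *true* effects below it.  A parametric normal version and
the raw count of observed effects are reported alongside.  Uncertainty
comes from a cluster bootstrap (papers resampled with replacement, the
model refit on each resample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .effects import (
    EffectTableError,
    fisher_z_variance,
    r_to_fisher_z,
    validate_effect_frame,
)
from .meta import MetaFit, fit_three_level_reml

__all__ = ["ThresholdResult", "calibrated_estimates", "prop_below"]

METHODS = ("calibrated", "parametric", "raw_count")


@dataclass
class ThresholdResult:
    """Proportion of effects below (or above) a threshold on the r scale."""

    q_r: float
    method: str
    direction: str
    proportion: float
    ci: tuple[float, float] | None
    n_boot: int
    seed: int | None
    n_effects: int

    @property
    def natural_frequency(self) -> int:
        """'About X out of N effects' — the rounded count implied by the proportion."""
        return int(round(self.proportion * self.n_effects))

    def to_dict(self) -> dict:
        return {
            "q_r": self.q_r,
            "method": self.method,
            "direction": self.direction,
            "proportion": self.proportion,
            "ci": list(self.ci) if self.ci is not None else None,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_effects": self.n_effects,
            "natural_frequency": self.natural_frequency,
        }


def calibrated_estimates(df: pd.DataFrame, fit: MetaFit) -> np.ndarray:
    """Shrunken true-effect estimates on the z scale, one per effect.

    Full shrinkage (all estimates at mu) when tau_total = 0; no shrinkage
    in the v -> 0 limit.  |theta - mu| <= |z - mu| always.
    """
    frame = validate_effect_frame(df)
    z = np.atleast_1d(r_to_fisher_z(frame["r"].to_numpy()))
    v = np.atleast_1d(fisher_z_variance(frame["n"].to_numpy()))
    t2 = fit.tau_total**2
    shrink = np.sqrt(t2 / (t2 + v)) if t2 > 0 else np.zeros_like(v)
    return fit.mu_z + shrink * (z - fit.mu_z)


def _point_proportion(frame: pd.DataFrame, fit: MetaFit, q_z: float, method: str, direction: str) -> float:
    if method == "calibrated":
        theta = calibrated_estimates(frame, fit)
        below = np.mean(theta < q_z)
    elif method == "parametric":
        if fit.tau_total == 0:
            below = float(q_z > fit.mu_z)
        else:
            below = stats.norm.cdf((q_z - fit.mu_z) / fit.tau_total)
    elif method == "raw_count":
        z = np.atleast_1d(r_to_fisher_z(frame["r"].to_numpy()))
        below = np.mean(z < q_z)
    else:
        raise EffectTableError(f"unknown method {method!r}; choose from {METHODS}")
    return float(below) if direction == "below" else float(1.0 - below)


def prop_below(
    df: pd.DataFrame,
    fit: MetaFit | None = None,
    q_r: float = 0.0,
    method: str = "calibrated",
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    direction: str = "below",
) -> ThresholdResult:
    """Proportion of effects below threshold ``q_r``, with a bootstrap CI.

    The threshold is supplied on the r scale and compared on the z scale.
    The bootstrap resamples clusters (papers) with replacement and refits
    the three-level model on each resample, so the interval reflects both
    estimation and sampling uncertainty; identical seed and data give an
    identical interval.  ``n_boot=0`` skips the bootstrap.
    """
    if not (-1.0 < q_r < 1.0):
        raise EffectTableError(f"threshold q_r={q_r} outside (-1, 1)")
    if direction not in ("below", "above"):
        raise EffectTableError("direction must be 'below' or 'above'")
    frame = validate_effect_frame(df)
    if fit is None:
        fit = fit_three_level_reml(frame)
    if method == "parametric" and fit.tau_total == 0:
        import warnings

        warnings.warn("tau_total = 0: parametric proportion is degenerate (0 or 1)", stacklevel=2)
    q_z = float(r_to_fisher_z(q_r))
    point = _point_proportion(frame, fit, q_z, method, direction)

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        cluster = frame[["paper_id", "study_id"]].astype(str).agg("/".join, axis=1)
        ids = np.array(sorted(cluster.unique()))
        groups = {cid: frame.loc[cluster == cid] for cid in ids}
        boots = np.empty(n_boot)
        for b in range(n_boot):
            draw = rng.choice(ids, size=len(ids), replace=True)
            parts = []
            for i, cid in enumerate(draw):
                g = groups[cid].copy()
                # relabel so repeated clusters stay distinct clusters
                g["paper_id"] = f"b{i}_" + g["paper_id"]
                parts.append(g)
            bframe = pd.concat(parts, ignore_index=True)
            try:
                bfit = fit_three_level_reml(bframe)
            except EffectTableError:
                boots[b] = point
                continue
            boots[b] = _point_proportion(bframe, bfit, q_z, method, direction)
        alpha = 1.0 - level
        ci = (
            float(np.quantile(boots, alpha / 2)),
            float(np.quantile(boots, 1.0 - alpha / 2)),
        )

    return ThresholdResult(
        q_r=q_r,
        method=method,
        direction=direction,
        proportion=point,
        ci=ci,
        n_boot=n_boot,
        seed=seed,
        n_effects=len(frame),
    )
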