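"""Significance filtering: classification, at-least-one scoring, filtered means.

Reconstructs the filtering rules under critique: an effect is kept only if
its one-tailed p-value (positive direction) clears alpha; a paper-measure
group receives a vote-count score of 1 if at least one effect is
significant, 0.5 if none are significant but at least one is marginal, and
0 only when every effect is non-significant.  The "guaranteed minimum"
(critical) correlation at each sample size makes explicit the floor the
filter imposes on everything it retains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectTableError, r_p_value, validate_effect_frame

__all__ = [
    "FilterPolicy",
    "PaperScore",
    "FilterResult",
    "critical_r",
    "classify_effects",
    "classify_effect",
    "predictiveness_score",
    "score_table",
    "filtered_mean",
    "filter_dataset",
    "measure_level_filtered_mean",
    "measure_level_filtered_means",
    "boundary_curve",
    "GROUP_KEYS",
]

#: Scoring / averaging unit: multi-experiment papers split into separate groups.
GROUP_KEYS = ["paper_id", "study_id", "measure"]

SIGNIFICANT = "significant"
MARGINAL = "marginal"
NONSIGNIFICANT = "nonsignificant"


@dataclass(frozen=True)
class FilterPolicy:
    """Significance-filter configuration.

    The marginal band is half-open on p: ``alpha_sig <= p < alpha_marginal``
    (p exactly 0.05 is marginal, not significant, because the quoted rules
    are strict inequalities).  Only positive correlations can qualify.
    """

    alpha_sig: float = 0.05
    alpha_marginal: float = 0.10
    tail: str = "one_sided_positive"
    require_positive: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_sig < self.alpha_marginal < 1.0):
            raise EffectTableError(
                f"require 0 < alpha_sig ({self.alpha_sig}) < alpha_marginal "
                f"({self.alpha_marginal}) < 1"
            )


@dataclass(frozen=True)
class PaperScore:
    """At-least-one vote-count score for one paper-measure group."""

    paper_id: str
    study_id: str
    measure: str
    score: float
    n_significant: int
    n_marginal: int
    n_nonsignificant: int

    @property
    def k(self) -> int:
        return self.n_significant + self.n_marginal + self.n_nonsignificant


@dataclass
class FilterResult:
    """Partition of an effect table under a FilterPolicy."""

    retained: pd.DataFrame
    discarded: pd.DataFrame
    group_means: pd.DataFrame  # one row per group: keys, filtered_mean, k, n_retained
    policy: FilterPolicy
    n_input: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_input = len(self.retained) + len(self.discarded)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_discarded(self) -> int:
        return len(self.discarded)

    @property
    def proportion_discarded(self) -> float:
        return self.n_discarded / self.n_input if self.n_input else float("nan")

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_discarded": self.n_discarded,
            "proportion_discarded": self.proportion_discarded,
            "alpha_sig": self.policy.alpha_sig,
            "alpha_marginal": self.policy.alpha_marginal,
        }


def critical_r(n, alpha: float = 0.05, tail: str = "one_sided_positive"):
    """Guaranteed-minimum (critical) correlation at sample size n.

    Smallest r whose p-value falls below alpha: for the one-sided positive
    test, ``t_crit / sqrt(t_crit^2 + n - 2)`` with ``t_crit`` the (1-alpha)
    central-t quantile at n-2 df.  Strictly decreasing in both n and alpha.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 4):
        raise EffectTableError("critical_r requires n >= 4")
    if not (0.0 < alpha < 1.0):
        raise EffectTableError(f"alpha {alpha} outside (0, 1)")
    if tail == "one_sided_positive":
        tcrit = stats.t.ppf(1.0 - alpha, n - 2.0)
    elif tail == "two_sided":
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 2.0)
    else:
        raise EffectTableError(f"unknown tail {tail!r}")
    out = tcrit / np.sqrt(tcrit**2 + n - 2.0)
    out = np.asarray(out)
    return out.item() if out.ndim == 0 else out


def classify_effects(r, n, policy: FilterPolicy = FilterPolicy()) -> np.ndarray:
    """Vectorized classification into significant / marginal / nonsignificant.

    Significance is recomputed from (r, n); any non-positive r is
    non-significant by the directional rule.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    n = np.broadcast_to(np.asarray(n, dtype=float), r.shape)
    p = np.atleast_1d(r_p_value(r, n, tail=policy.tail))
    out = np.full(r.shape, NONSIGNIFICANT, dtype=object)
    positive = r > 0 if policy.require_positive else np.ones_like(r, dtype=bool)
    out[positive & (p < policy.alpha_sig)] = SIGNIFICANT
    out[positive & (p >= policy.alpha_sig) & (p < policy.alpha_marginal)] = MARGINAL
    return out


def classify_effect(record, policy: FilterPolicy = FilterPolicy()) -> str:
    """Classify a single EffectRecord (or anything with .r and .n)."""
    return classify_effects(record.r, record.n, policy)[0]


def _classified(df: pd.DataFrame, policy: FilterPolicy) -> pd.DataFrame:
    df = validate_effect_frame(df)
    df = df.copy()
    df["category"] = classify_effects(df["r"].to_numpy(), df["n"].to_numpy(), policy)
    return df


def predictiveness_score(group: pd.DataFrame, policy: FilterPolicy = FilterPolicy()) -> PaperScore:
    """At-least-one score for one paper-measure group of effects.

    Adding an effect can never lower the score: one significant effect out
    of ten earns the same +1 as ten out of ten.
    """
    if len(group) == 0:
        raise EffectTableError("predictiveness_score: empty record group")
    g = _classified(group, policy)
    keys = g[GROUP_KEYS].drop_duplicates()
    if len(keys) > 1:
        raise EffectTableError(
            f"predictiveness_score expects one (paper, study, measure) group, got {len(keys)}"
        )
    cats = g["category"].to_numpy()
    n_sig = int((cats == SIGNIFICANT).sum())
    n_marg = int((cats == MARGINAL).sum())
    n_non = int((cats == NONSIGNIFICANT).sum())
    score = 1.0 if n_sig else (0.5 if n_marg else 0.0)
    pid, sid, meas = keys.iloc[0]
    return PaperScore(pid, sid, meas, score, n_sig, n_marg, n_non)


def score_table(df: pd.DataFrame, policy: FilterPolicy = FilterPolicy()) -> pd.DataFrame:
    """Scores for every group, as a tidy table (one row per group)."""
    g = _classified(df, policy)
    rows = []
    for keys, grp in g.groupby(GROUP_KEYS, sort=True):
        cats = grp["category"].to_numpy()
        n_sig = int((cats == SIGNIFICANT).sum())
        n_marg = int((cats == MARGINAL).sum())
        n_non = int((cats == NONSIGNIFICANT).sum())
        rows.append(
            dict(
                zip(GROUP_KEYS, keys),
                score=1.0 if n_sig else (0.5 if n_marg else 0.0),
                n_significant=n_sig,
                n_marginal=n_marg,
                n_nonsignificant=n_non,
                k=len(grp),
            )
        )
    return pd.DataFrame(rows)


def filtered_mean(group: pd.DataFrame, policy: FilterPolicy = FilterPolicy()) -> float:
    """Unweighted mean r over the significant + marginal effects of a group.

    Returns NaN (the absent marker) when nothing qualifies.  Any present
    value is bounded below by the smallest marginal critical r among the
    qualifying effects — the guaranteed minimum.
    """
    if len(group) == 0:
        raise EffectTableError("filtered_mean: empty record group")
    g = _classified(group, policy)
    keep = g["category"].isin([SIGNIFICANT, MARGINAL])
    if not keep.any():
        return float("nan")
    return float(g.loc[keep, "r"].mean())


def filter_dataset(df: pd.DataFrame, policy: FilterPolicy = FilterPolicy()) -> FilterResult:
    """Partition a full effect table and compute per-group filtered means."""
    g = _classified(df, policy)
    keep = g["category"].isin([SIGNIFICANT, MARGINAL])
    retained = g.loc[keep].drop(columns="category").reset_index(drop=True)
    discarded = g.loc[~keep].drop(columns="category").reset_index(drop=True)
    rows = []
    for keys, grp in g.groupby(GROUP_KEYS, sort=True):
        sel = grp["category"].isin([SIGNIFICANT, MARGINAL])
        rows.append(
            dict(
                zip(GROUP_KEYS, keys),
                filtered_mean=float(grp.loc[sel, "r"].mean()) if sel.any() else float("nan"),
                k=len(grp),
                n_retained=int(sel.sum()),
            )
        )
    return FilterResult(retained, discarded, pd.DataFrame(rows), policy)


def measure_level_filtered_mean(result: FilterResult, measure: str) -> float:
    """Unweighted mean over per-paper filtered means for one measure.

    Papers (groups), not effects, are the averaging unit; groups whose
    filtered mean is absent do not contribute.  NaN when no group qualifies.
    """
    gm = result.group_means
    sel = (gm["measure"] == measure) & gm["filtered_mean"].notna()
    if not sel.any():
        return float("nan")
    return float(gm.loc[sel, "filtered_mean"].mean())


def measure_level_filtered_means(result: FilterResult) -> pd.Series:
    """Per-measure filtered means plus an 'overall' entry.

    Two aggregation conventions exist for the overall cell (mean over all
    paper-level means, or mean of the per-measure means); both are exposed
    as 'overall' and 'overall_by_measure' since sources are ambiguous about
    the averaging unit.
    """
    gm = result.group_means
    present = gm.loc[gm["filtered_mean"].notna()]
    per_measure = present.groupby("measure")["filtered_mean"].mean()
    out = per_measure.copy()
    out.loc["overall"] = float(present["filtered_mean"].mean()) if len(present) else float("nan")
    out.loc["overall_by_measure"] = float(per_measure.mean()) if len(per_measure) else float("nan")
    return out


def boundary_curve(n_min: int = 5, n_max: int = 200, policy: FilterPolicy = FilterPolicy()) -> pd.DataFrame:
    """Guaranteed-minimum curves over a sample-size grid (figure data export)."""
    if n_min < 4 or n_max < n_min:
        raise EffectTableError("boundary_curve requires 4 <= n_min <= n_max")
    n = np.arange(n_min, n_max + 1)
    return pd.DataFrame(
        {
            "n": n,
            "critical_r_sig": critical_r(n, policy.alpha_sig, policy.tail),
            "critical_r_marginal": critical_r(n, policy.alpha_marginal, policy.tail),
        }
    )
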