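"""Three-level random-effects meta-analysis on the Fisher z scale.

Model: for effect j nested in cluster (paper/experiment) i,

    z_ij = mu + u_i + w_ij + e_ij,
    u_i  ~ N(0, tau1^2)   between-paper heterogeneity,
    w_ij ~ N(0, tau2^2)   within-paper heterogeneity,
    e_ij ~ N(0, v_ij),    v_ij = 1/(n_ij - 3) known sampling variance.

Variance components are estimated by REML with non-negativity enforced by
bounded optimization; the pooled mean is the GLS estimate at the fitted
components.  Inference on mu uses CR2 cluster-robust (sandwich) standard
errors with Satterthwaite degrees of freedom, clustering on papers (with
multi-experiment papers split into separate clusters).  All r-scale output
is tanh of z-scale output — correlations are never averaged directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .effects import (
    EffectTableError,
    fisher_z_to_r,
    fisher_z_variance,
    r_to_fisher_z,
    validate_effect_frame,
)
from .filtering import FilterPolicy, filter_dataset, measure_level_filtered_means

__all__ = [
    "MetaFit",
    "ComparisonReport",
    "fit_three_level_reml",
    "cluster_robust_ci",
    "prediction_interval",
    "i_squared",
    "compare_filtered_full",
    "reml_neg2_loglik",
]


@dataclass
class MetaFit:
    """Result of a three-level REML fit (z scale unless suffixed _r)."""

    mu_z: float
    tau1: float
    tau2: float
    se_model: float
    se_robust: float | None
    df_robust: float | None
    ci_z: tuple[float, float]
    ci_r: tuple[float, float]
    pi_z: tuple[float, float]
    pi_r: tuple[float, float]
    i2: float
    converged: bool
    n_effects: int
    n_clusters: int
    neg2_loglik: float
    level: float
    pi_df: float
    diagnostics: dict = field(default_factory=dict, repr=False)

    @property
    def tau_total(self) -> float:
        return float(np.hypot(self.tau1, self.tau2))

    @property
    def mu_r(self) -> float:
        return float(np.tanh(self.mu_z))

    def to_dict(self) -> dict:
        return {
            "mu_z": self.mu_z,
            "mu_r": self.mu_r,
            "tau1_z": self.tau1,
            "tau2_z": self.tau2,
            "tau_total_z": self.tau_total,
            "se_model_z": self.se_model,
            "se_robust_z": self.se_robust,
            "df_robust": self.df_robust,
            "ci_z": list(self.ci_z),
            "ci_r": list(self.ci_r),
            "pi_z": list(self.pi_z),
            "pi_r": list(self.pi_r),
            "i2_pct": self.i2,
            "converged": self.converged,
            "n_effects": self.n_effects,
            "n_clusters": self.n_clusters,
            "neg2_loglik": self.neg2_loglik,
            "level": self.level,
            "pi_df": self.pi_df,
        }


def _prepare(df: pd.DataFrame, cluster_cols=("paper_id", "study_id")):
    df = validate_effect_frame(df)
    cluster = df[list(cluster_cols)].astype(str).agg("/".join, axis=1)
    codes, _ = pd.factorize(cluster, sort=True)
    order = np.argsort(codes, kind="stable")
    z = r_to_fisher_z(df["r"].to_numpy())[order]
    v = fisher_z_variance(df["n"].to_numpy())[order]
    codes = codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    return np.atleast_1d(z), np.atleast_1d(v), codes, starts


def reml_neg2_loglik(tau1_sq: float, tau2_sq: float, z, v, starts) -> float:
    """-2 restricted log-likelihood (up to an additive constant).

    Cluster covariance tau1^2*J + diag(tau2^2 + v) is inverted in closed
    form (rank-one update), so each evaluation is O(total effects).
    """
    d = tau2_sq + v
    c = tau1_sq
    inv_d = 1.0 / d
    sd = np.add.reduceat(inv_d, starts)  # 1' D^-1 1 per cluster
    sz = np.add.reduceat(z * inv_d, starts)  # 1' D^-1 z
    szz = np.add.reduceat(z * z * inv_d, starts)  # z' D^-1 z
    logdet_d = np.add.reduceat(np.log(d), starts)
    denom = 1.0 + c * sd
    logdet = logdet_d + np.log(denom)
    one_vinv_one = sd / denom
    one_vinv_z = sz / denom
    z_vinv_z = szz - c * sz**2 / denom
    S = one_vinv_one.sum()
    quad = z_vinv_z.sum() - one_vinv_z.sum() ** 2 / S
    return float(logdet.sum() + np.log(S) + quad)


def _gls_mu(tau1_sq, tau2_sq, z, v, starts):
    d = tau2_sq + v
    inv_d = 1.0 / d
    sd = np.add.reduceat(inv_d, starts)
    sz = np.add.reduceat(z * inv_d, starts)
    denom = 1.0 + tau1_sq * sd
    S = (sd / denom).sum()
    mu = (sz / denom).sum() / S
    return mu, 1.0 / np.sqrt(S)


def _cluster_slices(codes, starts):
    bounds = list(starts) + [len(codes)]
    return [slice(bounds[i], bounds[i + 1]) for i in range(len(starts))]


def _sym_inv_sqrt(mat: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Moore-Penrose inverse square root of a symmetric PSD matrix."""
    w, q = np.linalg.eigh(mat)
    scale = max(w.max(), 1.0)
    inv = np.where(w > tol * scale, 1.0 / np.sqrt(np.clip(w, tol * scale, None)), 0.0)
    return (q * inv) @ q.T


def _cr2(mu, tau1_sq, tau2_sq, z, v, codes, starts):
    """CR2 sandwich SE of mu and Satterthwaite df, intercept-only GLS.

    Adjustment matrices satisfy A_j B_j A_j = V_j with
    B_j = V_j - 1 1'/S (the exact block form of (I-H) Phi (I-H)' under the
    model working covariance); df from the quadratic-form moments of the
    variance estimator assuming the working model holds.
    """
    m = len(starts)
    if m < 2:
        return None, None
    slices = _cluster_slices(codes, starts)
    # S = sum_j 1' V_j^-1 1 via closed form
    d = tau2_sq + v
    inv_d = 1.0 / d
    sd = np.add.reduceat(inv_d, starts)
    denom = 1.0 + tau1_sq * sd
    S = (sd / denom).sum()

    total = 0.0
    g = np.empty(m)
    a = np.empty(m)
    for j, sl in enumerate(slices):
        dj = d[sl]
        k = len(dj)
        Vj = tau1_sq * np.ones((k, k)) + np.diag(dj)
        Wj_one = np.linalg.solve(Vj, np.ones(k))
        Bj = Vj - np.ones((k, k)) / S
        Lj = np.linalg.cholesky(Vj)
        Aj = Lj @ _sym_inv_sqrt(Lj.T @ Bj @ Lj) @ Lj.T
        cj = Aj @ Wj_one
        ej = z[sl] - mu
        total += float(cj @ ej) ** 2
        a[j] = cj.sum()
        g[j] = float(cj @ Vj @ cj)
    se = np.sqrt(total) / S
    # Satterthwaite: df = tr(G)^2 / tr(G^2), G = diag(g) - a a' / S
    G = np.diag(g) - np.outer(a, a) / S
    tr = np.trace(G)
    tr2 = float((G * G).sum())
    df = tr**2 / tr2 if tr2 > 0 else float(m - 1)
    return float(se), float(df)


def fit_three_level_reml(
    df: pd.DataFrame,
    level: float = 0.95,
    fix_tau1: float | None = None,
    fix_tau2: float | None = None,
    cluster_cols=("paper_id", "study_id"),
    pi_df: float | None = None,
    tol: float = 1e-8,
) -> MetaFit:
    """Fit the three-level model by REML and assemble all inference.

    ``fix_tau1`` / ``fix_tau2`` pin an SD component (useful for reducing to
    a two-level model, e.g. with one effect per cluster where the split is
    not identified).  ``pi_df`` overrides the prediction-interval degrees of
    freedom (default: clusters - 2).
    """
    z, v, codes, starts = _prepare(df, cluster_cols)
    m = len(starts)
    ne = len(z)
    if m < 2:
        raise EffectTableError("three-level fit requires at least 2 clusters")

    free = [fix_tau1 is None, fix_tau2 is None]

    def unpack(theta):
        it = iter(theta)
        t1 = next(it) if free[0] else float(fix_tau1) ** 2
        t2 = next(it) if free[1] else float(fix_tau2) ** 2
        return t1, t2

    def objective(theta):
        return reml_neg2_loglik(*unpack(theta), z, v, starts)

    z_var = float(np.var(z)) if ne > 1 else 0.0
    ub = max(4.0 * z_var, 1.0)
    moment = max(z_var - float(np.mean(v)), 1e-4)
    start_grid = [
        [0.7 * moment, 0.3 * moment],
        [0.2 * moment, 0.2 * moment],
        [1e-6, 1e-6],
    ]
    best = None
    n_free = sum(free)
    if n_free == 0:
        theta_hat = np.array([])
        converged = True
        obj = objective(theta_hat)
    else:
        for s in start_grid:
            theta0 = np.array([x for x, f in zip(s, free) if f])
            res = optimize.minimize(
                objective,
                theta0,
                method="L-BFGS-B",
                bounds=[(0.0, ub)] * n_free,
                options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        theta_hat = best.x
        converged = bool(best.success)
        obj = float(best.fun)

    t1sq, t2sq = unpack(theta_hat)
    t1sq, t2sq = max(t1sq, 0.0), max(t2sq, 0.0)
    mu, se_model = _gls_mu(t1sq, t2sq, z, v, starts)
    se_robust, df_robust = _cr2(mu, t1sq, t2sq, z, v, codes, starts)

    if se_robust is not None:
        q = stats.t.ppf(1.0 - (1.0 - level) / 2.0, df_robust)
        ci_z = (mu - q * se_robust, mu + q * se_robust)
    else:
        q = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
        ci_z = (mu - q * se_model, mu + q * se_model)
    ci_r = (float(np.tanh(ci_z[0])), float(np.tanh(ci_z[1])))

    tau_total_sq = t1sq + t2sq
    pdf = float(pi_df) if pi_df is not None else max(float(m - 2), 1.0)
    se_pi = se_robust if se_robust is not None else se_model
    qp = stats.t.ppf(1.0 - (1.0 - level) / 2.0, pdf)
    half = qp * np.sqrt(tau_total_sq + se_pi**2)
    pi_z = (mu - half, mu + half)
    pi_r = (float(np.tanh(pi_z[0])), float(np.tanh(pi_z[1])))

    # Higgins-Thompson typical sampling variance from inverse-variance weights
    w = 1.0 / v
    v_typ = (ne - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum()) if ne > 1 else float(np.mean(v))
    i2 = 100.0 * tau_total_sq / (tau_total_sq + v_typ) if (tau_total_sq + v_typ) > 0 else 0.0

    return MetaFit(
        mu_z=float(mu),
        tau1=float(np.sqrt(t1sq)),
        tau2=float(np.sqrt(t2sq)),
        se_model=float(se_model),
        se_robust=se_robust,
        df_robust=df_robust,
        ci_z=(float(ci_z[0]), float(ci_z[1])),
        ci_r=ci_r,
        pi_z=(float(pi_z[0]), float(pi_z[1])),
        pi_r=pi_r,
        i2=float(i2),
        converged=converged,
        n_effects=ne,
        n_clusters=m,
        neg2_loglik=obj,
        level=level,
        pi_df=pdf,
        diagnostics={"v_typical": float(v_typ)},
    )


def cluster_robust_ci(
    fit: MetaFit,
    df: pd.DataFrame,
    level: float | None = None,
    cluster_cols=("paper_id", "study_id"),
) -> tuple[float, float]:
    """CR2 confidence interval for the pooled mean, on the r scale."""
    level = fit.level if level is None else level
    z, v, codes, starts = _prepare(df, cluster_cols)
    if len(starts) < 2:
        raise EffectTableError("cluster-robust inference requires at least 2 clusters")
    se, dfree = _cr2(fit.mu_z, fit.tau1**2, fit.tau2**2, z, v, codes, starts)
    q = stats.t.ppf(1.0 - (1.0 - level) / 2.0, dfree)
    return (float(np.tanh(fit.mu_z - q * se)), float(np.tanh(fit.mu_z + q * se)))


def prediction_interval(fit: MetaFit, level: float | None = None) -> tuple[float, float]:
    """Interval expected to contain the true effect of a new study (r scale).

    mu +/- t_{df} * sqrt(tau_total^2 + se^2) on the z scale, df = clusters-2
    unless overridden at fit time; collapses toward the mean's CI as
    heterogeneity vanishes (up to the df convention).
    """
    level = fit.level if level is None else level
    se = fit.se_robust if fit.se_robust is not None else fit.se_model
    q = stats.t.ppf(1.0 - (1.0 - level) / 2.0, fit.pi_df)
    half = q * np.sqrt(fit.tau_total**2 + se**2)
    return (float(np.tanh(fit.mu_z - half)), float(np.tanh(fit.mu_z + half)))


def i_squared(fit: MetaFit, df: pd.DataFrame) -> float:
    """Percent of total variance due to heterogeneity (Higgins-Thompson).

    100 * tau_total^2 / (tau_total^2 + v_typ), with v_typ the typical
    sampling variance computed from the inverse-variance weights.
    """
    frame = validate_effect_frame(df)
    v = fisher_z_variance(frame["n"].to_numpy())
    v = np.atleast_1d(v)
    ne = len(v)
    w = 1.0 / v
    v_typ = (ne - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum()) if ne > 1 else float(v.mean())
    t2 = fit.tau_total**2
    return float(100.0 * t2 / (t2 + v_typ)) if (t2 + v_typ) > 0 else 0.0


@dataclass
class ComparisonReport:
    """Filtered-mean vs full-model comparison (the Type M exaggeration)."""

    full_mean_r: float
    filtered_mean_r: float
    percent_higher: float
    type_m: float
    per_measure: pd.DataFrame
    fit: MetaFit

    def to_dict(self) -> dict:
        return {
            "full_mean_r": self.full_mean_r,
            "filtered_mean_r": self.filtered_mean_r,
            "percent_higher_pct": self.percent_higher,
            "type_m": self.type_m,
            "per_measure": self.per_measure.to_dict("records"),
        }


def compare_filtered_full(
    df: pd.DataFrame, policy: FilterPolicy = FilterPolicy(), level: float = 0.95
) -> ComparisonReport:
    """Run the filter and the full three-level model on the same table.

    The exaggeration ratio (Type M error of the filtered summary relative
    to the all-effects model) is computed on unrounded means.  Per-measure
    rows refit the model on each measure's subset where enough clusters
    exist.
    """
    frame = validate_effect_frame(df)
    result = filter_dataset(frame, policy)
    filtered = measure_level_filtered_means(result)
    fit = fit_three_level_reml(frame, level=level)
    full_r = fit.mu_r
    filt_r = float(filtered.get("overall", float("nan")))
    type_m = filt_r / full_r if full_r != 0 else float("nan")
    rows = []
    for measure in sorted(frame["measure"].unique()):
        sub = frame.loc[frame["measure"] == measure]
        try:
            sub_fit = fit_three_level_reml(sub, level=level)
            sub_full = sub_fit.mu_r
            sub_ci = sub_fit.ci_r
        except EffectTableError:
            sub_full, sub_ci = float("nan"), (float("nan"), float("nan"))
        sub_filt = float(filtered.get(measure, float("nan")))
        rows.append(
            {
                "measure": measure,
                "full_mean_r": sub_full,
                "full_ci_lower_r": sub_ci[0],
                "full_ci_upper_r": sub_ci[1],
                "filtered_mean_r": sub_filt,
                "type_m": sub_filt / sub_full if sub_full not in (0.0,) and np.isfinite(sub_full) else float("nan"),
                "n_effects": int(len(sub)),
            }
        )
    return ComparisonReport(
        full_mean_r=full_r,
        filtered_mean_r=filt_r,
        percent_higher=100.0 * (type_m - 1.0),
        type_m=type_m,
        per_measure=pd.DataFrame(rows),
        fit=fit,
    )
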