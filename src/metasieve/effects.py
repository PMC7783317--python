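"""Effect-size data model: Fisher-z transforms, intervals, p-values, table I/O.

Every downstream stage works on the Fisher z scale, where a Pearson
correlation r from a bivariate-normal sample of size n has approximate
sampling distribution N(arctanh(rho), 1/(n-3)).  This module owns the
record schema, the transforms, and the CSV round-trip; it makes no
filtering or modelling decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectRecord",
    "EffectTableError",
    "EFFECT_COLUMNS",
    "r_to_fisher_z",
    "fisher_z_to_r",
    "fisher_z_variance",
    "r_confidence_interval",
    "r_p_value",
    "read_effect_table",
    "write_effect_table",
    "records_to_frame",
    "frame_to_records",
    "validate_effect_frame",
]

#: Canonical column order of the effect table (UTF-8 CSV, booleans true/false).
EFFECT_COLUMNS = (
    "paper_id",
    "study_id",
    "measure",
    "r",
    "n",
    "overfit",
    "team_level",
    "ghost",
)


class EffectTableError(ValueError):
    """Raised when an effect table violates the schema or a record invariant."""


@dataclass(frozen=True)
class EffectRecord:
    """One reported effect: a Pearson correlation with its provenance flags.

    ``overfit`` marks results whose stated degrees of freedom exceed the
    sample size; ``team_level`` marks team-aggregated outcomes; ``ghost``
    marks effects that were assessed in the source study but unreported or
    underreported.  Flags are carried through I/O — inclusion is a
    downstream policy decision, never an ingestion decision.
    """

    paper_id: str
    study_id: str
    measure: str
    r: float
    n: int
    overfit: bool = False
    team_level: bool = False
    ghost: bool = False

    def __post_init__(self) -> None:
        if not (-1.0 < self.r < 1.0):
            raise EffectTableError(
                f"effect ({self.paper_id}, {self.study_id}, {self.measure}): "
                f"r={self.r} outside the open interval (-1, 1)"
            )
        if int(self.n) != self.n or self.n < 4:
            raise EffectTableError(
                f"effect ({self.paper_id}, {self.study_id}, {self.measure}): "
                f"n={self.n} must be an integer >= 4 (Fisher-z variance 1/(n-3))"
            )


def r_to_fisher_z(r):
    """Fisher z transform, ``z = arctanh(r)``.  Accepts scalars or arrays."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        bad = np.asarray(r)[np.abs(r) >= 1.0]
        raise EffectTableError(f"correlation(s) {bad!r} outside (-1, 1); z-transform infinite")
    out = np.arctanh(r)
    return out.item() if out.ndim == 0 else out


def fisher_z_to_r(z):
    """Inverse transform, ``r = tanh(z)``."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out.item() if out.ndim == 0 else out


def fisher_z_variance(n):
    """Sampling variance of Fisher z, ``1 / (n - 3)``."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 4):
        raise EffectTableError(f"sample size(s) {n[n < 4]!r} below 4; variance 1/(n-3) undefined")
    out = 1.0 / (n - 3.0)
    return out.item() if out.ndim == 0 else out


def r_confidence_interval(r, n, level: float = 0.95):
    """Fisher-z normal confidence interval for a single correlation.

    The interval is built on the z scale, ``z +/- q * sqrt(1/(n-3))`` with q
    the standard-normal quantile at ``1 - (1 - level)/2``, then mapped back
    with tanh.  Returns ``(lower, upper)`` on the r scale.
    """
    if not (0.0 < level < 1.0):
        raise EffectTableError(f"confidence level {level} outside (0, 1)")
    z = r_to_fisher_z(r)
    se = np.sqrt(fisher_z_variance(n))
    q = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    lo = fisher_z_to_r(z - q * se)
    hi = fisher_z_to_r(z + q * se)
    return lo, hi


def r_p_value(r, n, tail: str = "two_sided"):
    """P-value for H0: rho = 0 from the exact central-t reference.

    The test statistic is ``t = r * sqrt(n-2) / sqrt(1-r^2)`` with ``n-2``
    degrees of freedom — the null distribution is exact under bivariate
    normality, which is how the source literature reports significance.
    ``tail='one_sided_positive'`` returns the upper-tail probability, so a
    non-positive r yields p >= 0.5.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 4):
        raise EffectTableError("sample size below 4 in p-value computation")
    t = r * np.sqrt(n - 2.0) / np.sqrt(1.0 - r**2)
    if tail == "one_sided_positive":
        p = stats.t.sf(t, n - 2.0)
    elif tail == "two_sided":
        p = 2.0 * stats.t.sf(np.abs(t), n - 2.0)
    else:
        raise EffectTableError(f"unknown tail {tail!r}")
    p = np.asarray(p)
    return p.item() if p.ndim == 0 else p


_BOOL_MAP = {"true": True, "false": False, "True": True, "False": False, True: True, False: False}


def validate_effect_frame(df: pd.DataFrame, source: str = "<frame>") -> pd.DataFrame:
    """Coerce dtypes and enforce record invariants, reporting row numbers.

    Row numbers in error messages are 1-based data rows (header excluded).
    Returns a copy with canonical dtypes and column order.
    """
    missing = [c for c in EFFECT_COLUMNS if c not in df.columns]
    if missing:
        raise EffectTableError(f"{source}: missing column(s) {missing}")
    out = df.loc[:, list(EFFECT_COLUMNS)].copy()
    for col in ("paper_id", "study_id", "measure"):
        out[col] = out[col].astype(str)
    for col in ("overfit", "team_level", "ghost"):
        vals = out[col]
        try:
            out[col] = vals.map(lambda v: _BOOL_MAP[v] if not isinstance(v, (bool, np.bool_)) else bool(v)).astype(bool)
        except KeyError as exc:
            raise EffectTableError(f"{source}: column {col} has non-boolean value {exc.args[0]!r}") from None
    for col, caster in (("r", float), ("n", int)):
        try:
            out[col] = out[col].astype(caster)
        except (TypeError, ValueError) as exc:
            raise EffectTableError(f"{source}: column {col} not parsable as {caster.__name__}: {exc}") from None
    bad_r = np.abs(out["r"].to_numpy()) >= 1.0
    if bad_r.any():
        rows = (np.flatnonzero(bad_r) + 1).tolist()
        raise EffectTableError(f"{source}: |r| >= 1 at data row(s) {rows}")
    bad_n = out["n"].to_numpy() < 4
    if bad_n.any():
        rows = (np.flatnonzero(bad_n) + 1).tolist()
        raise EffectTableError(f"{source}: n < 4 at data row(s) {rows}")
    return out.reset_index(drop=True)


def read_effect_table(path) -> pd.DataFrame:
    """Read a validated effect table from CSV (schema in ``EFFECT_COLUMNS``)."""
    try:
        raw = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise EffectTableError(f"{path}: cannot parse CSV: {exc}") from exc
    return validate_effect_frame(raw, source=str(path))


def write_effect_table(df: pd.DataFrame, path) -> None:
    """Write the canonical schema columns as CSV with true/false booleans."""
    out = validate_effect_frame(df)
    out = out.copy()
    for col in ("overfit", "team_level", "ghost"):
        out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(path, index=False)


def records_to_frame(records: Iterable[EffectRecord]) -> pd.DataFrame:
    rows = [[getattr(rec, f.name) for f in fields(EffectRecord)] for rec in records]
    df = pd.DataFrame(rows, columns=list(EFFECT_COLUMNS))
    if df.empty:
        raise EffectTableError("empty record collection")
    return validate_effect_frame(df)


def frame_to_records(df: pd.DataFrame) -> list[EffectRecord]:
    df = validate_effect_frame(df)
    return [EffectRecord(**row) for row in df.to_dict("records")]
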