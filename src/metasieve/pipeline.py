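"""End-to-end report: filter, score, model, compare, threshold proportions.

One call produces everything the filtered-vs-full critique needs from a
single effect table: the filter partition and discard proportion, the
at-least-one scores, measure-level filtered means, the three-level fit
with robust CI / prediction interval / I^2, the Type M comparison, and the
proportion of effects below each filtered mean.  The bundle is plain JSON
with every numeric key naming its scale (``_r`` / ``_z`` / ``_pct``), and
is byte-identical for identical input, configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .effects import read_effect_table, validate_effect_frame
from .filtering import (
    FilterPolicy,
    filter_dataset,
    measure_level_filtered_means,
    score_table,
)
from .meta import compare_filtered_full
from .thresholds import prop_below

__all__ = ["RunConfig", "run_full_critique", "bundle_to_json"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Options of a full pipeline run."""

    alpha_sig: float = 0.05
    alpha_marginal: float = 0.10
    exclude_overfit: bool = False
    exclude_team_level: bool = False
    level: float = 0.95
    n_boot: int = 1000
    threshold_method: str = "calibrated"
    seed: int | None = None

    @property
    def policy(self) -> FilterPolicy:
        return FilterPolicy(alpha_sig=self.alpha_sig, alpha_marginal=self.alpha_marginal)


def _hash_frame(df: pd.DataFrame) -> str:
    payload = df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


def run_full_critique(table, config: RunConfig = RunConfig()) -> dict:
    """Run every stage on an effect table (path or DataFrame); return the bundle."""
    if isinstance(table, (str, Path)):
        frame = read_effect_table(table)
        source = str(table)
    else:
        frame = validate_effect_frame(table)
        source = "<frame>"
    if config.exclude_overfit:
        frame = frame.loc[~frame["overfit"]].reset_index(drop=True)
    if config.exclude_team_level:
        frame = frame.loc[~frame["team_level"]].reset_index(drop=True)

    policy = config.policy
    result = filter_dataset(frame, policy)
    scores = score_table(frame, policy)
    filtered_means = measure_level_filtered_means(result)
    comparison = compare_filtered_full(frame, policy, level=config.level)
    fit = comparison.fit

    thresholds = {}
    for name, q in filtered_means.items():
        if name == "overall_by_measure" or not np.isfinite(q) or not (-1 < q < 1):
            continue
        res = prop_below(
            frame,
            fit,
            q_r=float(q),
            method=config.threshold_method,
            n_boot=config.n_boot,
            seed=config.seed,
            level=config.level,
        )
        thresholds[name] = res.to_dict()

    bundle = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "input": source,
            "input_sha256": _hash_frame(frame),
            "seed": config.seed,
            "package_version": __version__,
            "config": asdict(config),
        },
        "data": {
            "n_effects": int(len(frame)),
            "n_papers": int(frame["paper_id"].nunique()),
            "median_n": float(frame["n"].median()),
            "median_k": float(scores["k"].median()) if len(scores) else float("nan"),
        },
        "filter": result.summary(),
        "scores": {
            "mean_score": float(scores["score"].mean()) if len(scores) else float("nan"),
            "n_groups": int(len(scores)),
            "share_score_1": float((scores["score"] == 1.0).mean()) if len(scores) else float("nan"),
            "table": scores.to_dict("records"),
        },
        "filtered_means_r": {k: (float(v) if np.isfinite(v) else None) for k, v in filtered_means.items()},
        "model": fit.to_dict(),
        "comparison": comparison.to_dict(),
        "threshold_proportions": thresholds,
    }
    return bundle


def bundle_to_json(bundle: dict, path=None, indent: int = 2) -> str:
    """Serialize deterministically (sorted keys, fixed float repr)."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    text = json.dumps(bundle, indent=indent, sort_keys=True, allow_nan=True, default=default)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
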