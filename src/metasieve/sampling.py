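"""Exact finite-sample draws of Pearson correlations.

The bivariate-normal route simulates n paired observations per draw and
correlates them — the exact finite-sample law, which matters because the
significance filter truncates at a sharp boundary.  The Fisher-z route
(normal noise on arctanh(rho) with variance 1/(n-3)) is the fast
approximation used for cross-checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_correlations"]


def sample_correlations(
    rho,
    n,
    size: int | None = None,
    rng: np.random.Generator | None = None,
    method: str = "exact",
    chunk: int = 200_000,
) -> np.ndarray:
    """Draw sample correlations at true correlation(s) ``rho`` and size(s) ``n``.

    ``rho`` and ``n`` may be scalars or equal-length arrays; ``size`` (only
    with scalar arguments) repeats the scalar configuration.  Draws are
    chunked so that exact sampling at large ``size`` stays within memory.
    """
    rng = np.random.default_rng() if rng is None else rng
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=int)
    if size is not None:
        if rho.ndim or n.ndim:
            raise ValueError("size= only combines with scalar rho and n")
        rho = np.full(size, float(rho))
        n = np.full(size, int(n))
    else:
        rho, n = np.broadcast_arrays(rho, n)
        rho = np.atleast_1d(rho).astype(float)
        n = np.atleast_1d(n).astype(int)
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("rho outside (-1, 1)")
    if np.any(n < 4):
        raise ValueError("n below 4")

    if method == "fisher_z":
        z = np.arctanh(rho) + rng.standard_normal(rho.shape) / np.sqrt(n - 3.0)
        return np.tanh(z)
    if method != "exact":
        raise ValueError(f"unknown sampling method {method!r}")

    out = np.empty(rho.shape, dtype=float)
    order = np.argsort(n, kind="stable")
    # process runs of equal n together; chunk long runs
    start = 0
    while start < len(order):
        stop = start
        nn = n[order[start]]
        while stop < len(order) and n[order[stop]] == nn:
            stop += 1
        idx = order[start:stop]
        for lo in range(0, len(idx), max(1, chunk // max(nn, 1))):
            sub = idx[lo : lo + max(1, chunk // max(nn, 1))]
            m = len(sub)
            x = rng.standard_normal((m, nn))
            e = rng.standard_normal((m, nn))
            rr = rho[sub][:, None]
            y = rr * x + np.sqrt(1.0 - rr**2) * e
            xc = x - x.mean(axis=1, keepdims=True)
            yc = y - y.mean(axis=1, keepdims=True)
            denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
            out[sub] = (xc * yc).sum(axis=1) / denom
        start = stop
    return out
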