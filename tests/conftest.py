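"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-implement the numerical primitives with
plain loops and explicit formulas, independent of the vectorized package
code they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_records():
    """Tiny survey table: one taxon, one region, spring + fall months."""
    rows = []
    g = np.random.default_rng(42)
    for year in range(1, 11):
        for month in (4, 5, 6, 10, 11):
            rows.append((year, month, "WB", "calfin", float(g.lognormal(1.0, 0.5))))
    return pd.DataFrame(
        rows, columns=["year", "month", "region", "taxon", "abundance_m3"]
    )


# ---------------------------------------------------------------------------
# brute-force EDM oracles


def brute_embed(x, E, tau):
    n = len(x)
    times = list(range((E - 1) * tau, n))
    rows = {t: [x[t - j * tau] for j in range(E)] for t in times}
    return rows, times


def _brute_weights(neighbors):
    """neighbors: list of (distance, idx), ascending; returns normalized w."""
    d1 = neighbors[0][0]
    if d1 == 0.0:
        w = [1.0 if d == 0.0 else 0.0 for d, _ in neighbors]
    else:
        w = [math.exp(-d / d1) for d, _ in neighbors]
    s = sum(w)
    return [wi / s for wi in w]


def brute_simplex_predictions(x, E, tau, tp):
    """Exhaustive leave-one-out simplex projection (loops, no numpy tricks)."""
    x = list(map(float, x))
    rows, times = brute_embed(x, E, tau)
    valid = [t for t in times if t + tp <= len(x) - 1]
    preds, obs = [], []
    for t in valid:
        cands = []
        for u in valid:
            if u == t:
                continue
            d = math.dist(rows[t], rows[u])
            cands.append((d, u))
        cands.sort(key=lambda du: (du[0], du[1]))
        nb = cands[: E + 1]
        w = _brute_weights(nb)
        preds.append(sum(wi * x[u + tp] for wi, (_, u) in zip(w, nb)))
        obs.append(x[t + tp])
    return np.array(preds), np.array(obs)


def brute_cross_map_predictions(x, y, E, tau):
    """Exhaustive full-library cross map: estimate x from y's embedding."""
    x = list(map(float, x))
    y = list(map(float, y))
    rows, times = brute_embed(y, E, tau)
    preds, obs = [], []
    for t in times:
        cands = []
        for u in times:
            if u == t:
                continue
            d = math.dist(rows[t], rows[u])
            cands.append((d, u))
        cands.sort(key=lambda du: (du[0], du[1]))
        nb = cands[: E + 1]
        w = _brute_weights(nb)
        preds.append(sum(wi * x[u] for wi, (_, u) in zip(w, nb)))
        obs.append(x[t])
    return np.array(preds), np.array(obs)


def brute_loess_at(x_obs, y_obs, x0, span, degree):
    """Direct tricube-weighted local polynomial regression at one point."""
    x_obs = np.asarray(x_obs, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    n = x_obs.size
    k = min(n, max(int(math.ceil(span * n)), degree + 1))
    d = np.abs(x_obs - x0)
    nearest = np.argsort(d, kind="stable")[:k]
    d_max = d[nearest].max()
    if d_max == 0:
        return float(y_obs[nearest].mean())
    w = (1.0 - np.clip(d[nearest] / d_max, 0, 1) ** 3) ** 3
    A = np.vstack([(x_obs[nearest] - x0) ** p for p in range(degree + 1)]).T
    W = np.diag(w)
    beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ y_obs[nearest])
    return float(beta[0])
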