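"""Paired one-tailed tests and change tables for before/after comparisons.

The analysis asks directional questions -- e.g. "does nestedness increase
when non-mutualistic links are removed?" -- so every test is one-tailed in
the hypothesized direction.  Wilcoxon signed-rank p-values are exact
(enumeration of the sign distribution, midranks for ties, zero differences
dropped) up to n = 25 and normal-approximated with continuity correction
above.  Spearman rank correlations are exact by permutation up to n = 8.
The Bernoulli-process (binomial point) probability summarizes how unlikely
the observed number of significant tests is under a global null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import UndefinedMetricError

_INCREASE = {"increase", "positive", "greater"}
_DECREASE = {"decrease", "negative", "less"}


def _check_direction(direction: str) -> str:
    if direction in _INCREASE:
        return "increase"
    if direction in _DECREASE:
        return "decrease"
    raise ValueError(f"direction must be increase/decrease, got {direction!r}")


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    p: float
    n: int            # pairs used after dropping zero differences
    direction: str


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Exact distribution of W+ (on doubled ranks) over all sign patterns."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts / counts.sum()


def wilcoxon_one_tailed(before: Sequence[float], after: Sequence[float],
                        direction: str) -> WilcoxonResult:
    """Paired one-tailed Wilcoxon signed-rank test on ``after - before``.

    Zero differences are dropped; ties receive midranks.  For n <= 25 the
    p-value is exact over the 2^n sign assignments; above that a normal
    approximation with tie correction and continuity correction is used.
    """
    direction = _check_direction(direction)
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before and after must have the same length")
    diffs = after - before
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        raise UndefinedMetricError("all paired differences are zero")
    if n < 3:
        raise UndefinedMetricError(f"need >= 3 nonzero differences, got {n}")
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    if n <= 25:
        double_ranks = np.rint(2 * ranks).astype(int)
        dist = _signed_rank_distribution(double_ranks)
        w2 = int(round(2 * w_plus))
        cdf = np.cumsum(dist)
        if direction == "increase":
            # large W+ favors the alternative "after > before"
            p = float(1.0 - (cdf[w2 - 1] if w2 >= 1 else 0.0))
        else:
            p = float(cdf[w2])
    else:
        mean = n * (n + 1) / 4.0
        tie_sizes = np.array([np.sum(ranks == r) for r in np.unique(ranks)])
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_sizes**3 - tie_sizes).sum() / 48.0
        sd = math.sqrt(var)
        if direction == "increase":
            p = float(sps.norm.sf((w_plus - mean - 0.5) / sd))
        else:
            p = float(sps.norm.cdf((w_plus - mean + 0.5) / sd))
    return WilcoxonResult(statistic=w_plus, p=min(p, 1.0), n=n, direction=direction)


@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    direction: str


def spearman_one_tailed(x: Sequence[float], y: Sequence[float],
                        direction: str = "increase") -> SpearmanResult:
    """One-tailed Spearman rank correlation (midranks).

    ``direction='increase'`` tests the positive alternative (no change in
    ranks expected -> positive correlation); a non-significant p under that
    alternative flags a change in ranks.  Exact permutation p for n <= 8,
    t-approximation above.
    """
    direction = _check_direction(direction)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedMetricError("rank correlation undefined for a constant vector")
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
            total += 1
            if direction == "increase":
                count += r >= rho - 1e-12
            else:
                count += r <= rho + 1e-12
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        if direction == "increase":
            p = float(sps.t.sf(t, df=n - 2))
        else:
            p = float(sps.t.cdf(t, df=n - 2))
    return SpearmanResult(rho=rho, p=float(p), n=n, direction=direction)


def moran_probability(n_tests: int, n_significant: int, alpha: float = 0.05) -> float:
    """Bernoulli-process probability of exactly K significant tests in N.

    ``p = [N! / ((N-K)! K!)] * alpha^K * (1 - alpha)^(N-K)`` -- the exact
    binomial point probability of observing K rejections among N
    independent tests at level alpha when every null is true.
    """
    if not 0 <= n_significant <= n_tests:
        raise ValueError("need 0 <= K <= N")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(
        math.comb(n_tests, n_significant)
        * alpha**n_significant
        * (1.0 - alpha) ** (n_tests - n_significant)
    )


# -- change tables ---------------------------------------------------------

#: Hypothesized direction of change of each network-level metric after
#: removing non-mutualistic links.
NETWORK_DIRECTIONS: Mapping[str, str] = {
    "size": "decrease",
    "weighted_connectance": "increase",
    "wnodf": "increase",
    "h2_prime": "decrease",
    "modularity_q": "decrease",
    "robustness": "decrease",
}

#: Hypothesized direction of change of each species-level metric.
SPECIES_DIRECTIONS: Mapping[str, str] = {
    "degree": "decrease",
    "frequency": "decrease",
    "d_prime": "decrease",
    "resilience_75": "decrease",
    "strength": "increase",
}

#: Which guild each species-level metric belongs to.
SPECIES_GUILDS: Mapping[str, str] = {
    "degree": "plant",
    "frequency": "plant",
    "d_prime": "plant",
    "resilience_75": "plant",
    "strength": "bird",
}


def _cv_percent(changes: np.ndarray) -> float:
    changes = changes[~np.isnan(changes)]
    mean = changes.mean()
    if len(changes) < 2 or mean == 0:
        return float("nan")
    return float(100.0 * changes.std(ddof=1) / abs(mean))


def _safe_test(fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except UndefinedMetricError:
        return None


def build_comparison_tables(
    network_reports: pd.DataFrame,
    species_reports: pd.DataFrame,
    before_state: str = "original",
    after_state: str = "pruned_all",
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Assemble before/after change tables with one-tailed tests.

    ``network_reports``: tidy frame with columns network_id, state, metric,
    value.  ``species_reports``: tidy frame with columns network_id, state,
    guild, species, metric, value (missing values as NaN).

    Returns four frames: ``network_level`` (mean absolute and percentage
    change, range, CV%, Wilcoxon and Spearman results per metric),
    ``species_level`` (per-network means averaged across networks, pooled
    Wilcoxon), ``per_network`` (species-level Wilcoxon p per network), and
    ``moran`` (number of significant tests per family and its Bernoulli
    probability).
    """
    tables: dict[str, pd.DataFrame] = {}

    # -- network level ----------------------------------------------------
    net_rows = []
    pivot = network_reports.pivot_table(
        index=["network_id", "metric"], columns="state", values="value", aggfunc="first"
    )
    for state in (before_state, after_state):
        if state not in pivot.columns:
            missing = sorted(network_reports["network_id"].unique())
            raise ValueError(f"missing state {state!r} for networks {missing}")
    incomplete = pivot[pivot[[before_state, after_state]].isna().any(axis=1)]
    if len(incomplete):
        raise ValueError(
            "missing state for network(s): "
            + ", ".join(sorted({i[0] for i in incomplete.index}))
        )
    for metric, direction in NETWORK_DIRECTIONS.items():
        sub = pivot.xs(metric, level="metric")
        if sub.empty:
            continue
        before = sub[before_state].to_numpy(dtype=float)
        after = sub[after_state].to_numpy(dtype=float)
        changes = after - before
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * changes / np.abs(before)
        wres = _safe_test(wilcoxon_one_tailed, before, after, direction)
        sres = _safe_test(spearman_one_tailed, before, after, "increase")
        net_rows.append(
            {
                "metric": metric,
                "direction": direction,
                "n_networks": len(changes),
                "mean_abs_change": changes.mean(),
                "mean_pct_change": np.nanmean(pct),
                "range_min": changes.min(),
                "range_max": changes.max(),
                "cv_pct": _cv_percent(changes),
                "wilcoxon_p": wres.p if wres else float("nan"),
                "spearman_rho": sres.rho if sres else float("nan"),
                "spearman_p": sres.p if sres else float("nan"),
            }
        )
    tables["network_level"] = pd.DataFrame(net_rows)

    # -- species level -----------------------------------------------------
    sp_pivot = species_reports.pivot_table(
        index=["network_id", "guild", "species", "metric"],
        columns="state",
        values="value",
        aggfunc="first",
    ).reset_index()
    sp_rows = []
    grid_rows = []
    for metric, direction in SPECIES_DIRECTIONS.items():
        guild = SPECIES_GUILDS[metric]
        sub = sp_pivot[(sp_pivot["metric"] == metric) & (sp_pivot["guild"] == guild)]
        if sub.empty:
            continue
        # degree/frequency keep zeros; other metrics drop NaN pairs
        paired = sub.dropna(subset=[before_state, after_state])
        before = paired[before_state].to_numpy(dtype=float)
        after = paired[after_state].to_numpy(dtype=float)
        changes = after - before
        per_net_means = []
        per_net_pct = []
        for nid, g in paired.groupby("network_id"):
            b = g[before_state].to_numpy(dtype=float)
            a = g[after_state].to_numpy(dtype=float)
            per_net_means.append((a - b).mean())
            if b.mean() != 0:
                per_net_pct.append(100.0 * (a - b).mean() / abs(b.mean()))
            wres = _safe_test(wilcoxon_one_tailed, b, a, direction)
            grid_rows.append(
                {
                    "metric": metric,
                    "network_id": nid,
                    "n": len(b),
                    "mean_change": (a - b).mean(),
                    "wilcoxon_p": wres.p if wres else float("nan"),
                }
            )
        wres = _safe_test(wilcoxon_one_tailed, before, after, direction)
        sres = _safe_test(spearman_one_tailed, before, after, "increase")
        sp_rows.append(
            {
                "metric": metric,
                "guild": guild,
                "direction": direction,
                "n_species": len(changes),
                "mean_abs_change": float(np.mean(per_net_means)),
                "mean_pct_change": float(np.mean(per_net_pct)) if per_net_pct else float("nan"),
                "range_min": float(np.min(per_net_means)),
                "range_max": float(np.max(per_net_means)),
                "species_min": changes.min(),
                "species_max": changes.max(),
                "cv_pct": _cv_percent(changes),
                "wilcoxon_p": wres.p if wres else float("nan"),
                "spearman_rho": sres.rho if sres else float("nan"),
                "spearman_p": sres.p if sres else float("nan"),
            }
        )
    tables["species_level"] = pd.DataFrame(sp_rows)
    tables["per_network"] = pd.DataFrame(grid_rows)

    # -- multiple-test summary --------------------------------------------
    moran_rows = []
    for family, frame in (("network_level", tables["network_level"]),
                          ("species_level", tables["species_level"])):
        ps = frame["wilcoxon_p"].dropna() if len(frame) else pd.Series(dtype=float)
        N = int(len(ps))
        K = int((ps < alpha).sum())
        moran_rows.append(
            {
                "family": family,
                "n_tests": N,
                "n_significant": K,
                "alpha": alpha,
                "moran_p": moran_probability(N, K, alpha) if N else float("nan"),
            }
        )
    tables["moran"] = pd.DataFrame(moran_rows)
    return tables
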