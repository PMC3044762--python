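"""Analysis statistics: stimulus-pair selectivity, decision performance,
group weight matrices, cross-correlograms, and the selectivity-performance
sigmoid.

The central quantity is the per-neuron stimulus-pair selectivity

    s_i = (max_p r_ip - mean_p r_ip) / mean_p r_ip

over the four pair responses r_ip: 0 for a cell responding equally to all
four pairs, 3 for a cell responding to exactly one.  The network value is
the mean of s_i over all excitatory cells (optionally over active cells
only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

PAIR_LABELS = ("AB", "AD", "CB", "CD")


@dataclass
class SelectivityResult:
    per_cell: np.ndarray  # s_i in [0, 3]
    mean: float  # network value over the included cells
    included: np.ndarray  # bool, which cells entered the mean
    mode: str  # all | active_only


@dataclass
class PerformanceTrace:
    bin_fractions: np.ndarray  # fraction correct per bin
    bin_size: int
    final: float  # performance of the final bin (fraction)
    classification: str  # reliable | borderline | unreliable


@dataclass
class GroupWeightMatrix:
    matrix: np.ndarray  # 4x4 mean weight change, NaN where a group is empty
    diagonal_subtracted: np.ndarray  # row diagonal removed
    labels: tuple = PAIR_LABELS


@dataclass
class SigmoidFitResult:
    x0: float
    delta: float
    r_squared: float


@dataclass
class CorrelogramResult:
    lags: np.ndarray  # bin centers, ms
    counts: np.ndarray
    bin_width: float
    max_lag: float


def selectivity(rates_per_pair) -> float:
    """Stimulus-pair selectivity of one cell from its four pair rates."""
    r = np.asarray(rates_per_pair, dtype=float)
    if r.shape != (4,):
        raise ValueError("expected exactly four pair rates")
    if (r < 0).any():
        raise ValueError("rates must be nonnegative")
    m = r.mean()
    if m == 0.0:
        return 0.0
    return float((r.max() - m) / m)


def network_selectivity(rate_matrix, include: str = "all",
                        active_floor: float = 0.5) -> SelectivityResult:
    """Per-cell selectivity and its network mean for a (cells x 4) rate
    matrix.  ``include='active_only'`` drops cells whose mean rate across
    pairs is below ``active_floor`` Hz (silent cells otherwise enter the
    mean with s = 0)."""
    r = np.asarray(rate_matrix, dtype=float)
    if r.ndim != 2 or r.shape[1] != 4:
        raise ValueError("rate matrix must be (n_cells, 4)")
    if (r < 0).any():
        raise ValueError("rates must be nonnegative")
    means = r.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(means > 0, (r.max(axis=1) - means) / np.where(means > 0, means, 1.0), 0.0)
    if include == "all":
        keep = np.ones(len(s), dtype=bool)
    elif include == "active_only":
        keep = means >= active_floor
    else:
        raise ValueError("include must be 'all' or 'active_only'")
    mean = float(s[keep].mean()) if keep.any() else 0.0
    return SelectivityResult(s, mean, keep, include)


def performance_bins(correct_flags, bin_size: int = 40,
                     final_k_bins: int = 1) -> PerformanceTrace:
    """Fraction-correct in consecutive trial bins plus the
    classification: reliable >= 85%, borderline 76-84%, unreliable <= 75%,
    judged on the mean of the final ``final_k_bins`` full bins."""
    flags = np.asarray(correct_flags, dtype=bool)
    n_bins = flags.size // bin_size
    if n_bins < 1:
        raise ValueError("need at least one full bin of trials")
    binned = flags[:n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    final = float(binned[-final_k_bins:].mean())
    pct = 100.0 * final
    if pct >= 85.0:
        cls = "reliable"
    elif pct > 75.0:
        cls = "borderline"
    else:
        cls = "unreliable"
    return PerformanceTrace(binned, bin_size, final, cls)


def classify_change(initial: float, final: float) -> str:
    """Improved / worsened / unchanged by the 5% rule on network mean
    selectivity.  A zero initial value with any positive final value counts
    as improved."""
    if initial < 0 or final < 0:
        raise ValueError("selectivity values must be nonnegative")
    if initial == 0.0:
        return "improved" if final > 0 else "unchanged"
    if final > 1.05 * initial:
        return "improved"
    if final < 0.95 * initial:
        return "worsened"
    return "unchanged"


def preferred_pairs(rate_matrix, active_floor: float = 0.0) -> np.ndarray:
    """Preferred pair index per cell: argmax of the four probe rates,
    ties broken toward the lowest pair index.

    Cells whose mean rate falls below ``active_floor`` get index -1
    (no meaningful preference); they are excluded by
    ``group_weight_matrix``."""
    r = np.asarray(rate_matrix, dtype=float)
    pref = np.argmax(r, axis=1)
    if active_floor > 0:
        pref = np.where(r.mean(axis=1) >= active_floor, pref, -1)
    return pref


def group_weight_matrix(weights_before: np.ndarray, weights_after: np.ndarray,
                        pref_pre: np.ndarray, pref_post: np.ndarray,
                        mask: Optional[np.ndarray] = None) -> GroupWeightMatrix:
    """Mean weight change between cell groups labelled by preferred pair.

    Entry (g, h) averages dW over existing synapses from cells preferring
    pair g to cells preferring pair h; empty groups give NaN.  The
    diagonal-subtracted variant removes each row's within-group value,
    exposing cross-inhibition as positive off-diagonal structure.
    """
    dw = np.asarray(weights_after, dtype=float) - np.asarray(weights_before, dtype=float)
    if mask is None:
        mask = np.asarray(weights_before) > 0
    out = np.full((4, 4), np.nan)
    for g in range(4):
        pre_sel = np.asarray(pref_pre) == g
        for h in range(4):
            post_sel = np.asarray(pref_post) == h
            m = mask[np.ix_(pre_sel, post_sel)]
            if m.any():
                out[g, h] = dw[np.ix_(pre_sel, post_sel)][m].mean()
    diag_sub = out - np.diag(out)[:, None]
    return GroupWeightMatrix(out, diag_sub)


def cross_correlogram(train_a, train_b, max_lag: float = 50.0,
                      bin_width: float = 2.0) -> CorrelogramResult:
    """Histogram of lags (t_b - t_a) over all spike pairs within +/-max_lag."""
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    edges = np.arange(-max_lag, max_lag + bin_width / 2, bin_width)
    if a.size == 0 or b.size == 0:
        centers = (edges[:-1] + edges[1:]) / 2
        return CorrelogramResult(centers, np.zeros(centers.size, dtype=np.int64),
                                 bin_width, max_lag)
    lags = (b[None, :] - a[:, None]).ravel()
    lags = lags[np.abs(lags) <= max_lag]
    counts, _ = np.histogram(lags, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return CorrelogramResult(centers, counts.astype(np.int64), bin_width, max_lag)


def sigmoid_curve(x, x0, delta):
    """Performance-vs-selectivity sigmoid, y = 50 + 50/(1 + exp(-(x-x0)/delta))."""
    return 50.0 + 50.0 / (1.0 + np.exp(-(np.asarray(x, dtype=float) - x0) / delta))


def sigmoid_fit(selectivity_values, performance_values) -> SigmoidFitResult:
    """Nonlinear least-squares fit of the two-parameter sigmoid to
    performance (on the 50-100 scale) against network selectivity."""
    x = np.asarray(selectivity_values, dtype=float)
    y = np.asarray(performance_values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate data: performance is constant")
    p0 = (float(np.median(x)), max(float(np.std(x)) / 2, 1e-3))
    popt, _ = curve_fit(sigmoid_curve, x, y, p0=p0, maxfev=20000)
    resid = y - sigmoid_curve(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean())**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return SigmoidFitResult(float(popt[0]), float(popt[1]), r2)
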