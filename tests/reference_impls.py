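"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (explicit loops, exhaustive search)
and shares no code with the package, so agreement between the two routes is
meaningful evidence of correctness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


# -- CART oracle -----------------------------------------------------------

def _sse(v: np.ndarray) -> float:
    return float(np.sum((v - v.mean()) ** 2)) if v.size else 0.0


def oracle_cart(
    X: np.ndarray,
    y: np.ndarray,
    min_impurity_decrease: float = 0.0,
    min_samples_leaf: int = 1,
    min_samples_split: int = 2,
    max_depth: int | None = None,
) -> dict:
    """Greedy CART by exhaustive double-loop split search.

    Same acceptance rules as the package's fitter: midpoint thresholds,
    weighted impurity decrease gate, leaf-size/split-size/depth limits, ties
    to the lowest feature index then lowest threshold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_total = len(y)
    min_samples_split = max(min_samples_split, 2)

    def grow(idx: np.ndarray, depth: int) -> dict:
        yv = y[idx]
        node = {"n": int(idx.size), "value": float(yv.mean()), "sse": _sse(yv)}
        if (
            idx.size < min_samples_split
            or idx.size < 2 * min_samples_leaf
            or node["sse"] <= 1e-12
            or (max_depth is not None and depth >= max_depth)
        ):
            return node
        best = None  # (gain, j, thr, left_mask)
        # same relative tie tolerance as the package fitter
        eps = 1e-9 * max(node["sse"], 1.0)
        for j in range(X.shape[1]):
            xs = np.unique(X[idx, j])
            for a, b in zip(xs[:-1], xs[1:]):
                thr = (a + b) / 2.0
                lm = X[idx, j] <= thr
                if lm.sum() < min_samples_leaf or (~lm).sum() < min_samples_leaf:
                    continue
                gain = node["sse"] - _sse(yv[lm]) - _sse(yv[~lm])
                if best is None or gain > best[0] + eps:
                    best = (gain, j, thr, lm)
        if best is None or best[0] / n_total < min_impurity_decrease:
            return node
        _, j, thr, lm = best
        node.update(
            feature=j,
            threshold=thr,
            left=grow(idx[lm], depth + 1),
            right=grow(idx[~lm], depth + 1),
        )
        return node

    return grow(np.arange(n_total), 0)


def oracle_signature(node: dict) -> list[tuple]:
    """Pre-order signature comparable to RegressionTreeModel.structure_signature."""
    sig: list[tuple] = []

    def walk(nd: dict) -> None:
        if "feature" in nd:
            sig.append((nd["feature"], round(nd["threshold"], 10), nd["n"]))
            walk(nd["left"])
            walk(nd["right"])
        else:
            sig.append((None, round(nd["value"], 10), nd["n"]))

    walk(node)
    return sig


def oracle_training_mse(node: dict, n_total: int) -> float:
    def leaf_sse(nd: dict) -> float:
        if "feature" in nd:
            return leaf_sse(nd["left"]) + leaf_sse(nd["right"])
        return nd["sse"]

    return leaf_sse(node) / n_total


# -- preprocessing oracle --------------------------------------------------

def oracle_profile(
    samples: pd.DataFrame,
    window_end,
    window_days: int = 30,
    min_days: int = 14,
) -> np.ndarray | None:
    """Loop-based mean-profile reference for one patient.

    Returns the 24-value profile, or None when the patient fails the
    day-sufficiency rule. Mirrors the stated processing order: hourly
    nullification, chronological width-3 smoothing, hour-of-day means.
    """
    end = pd.Timestamp(window_end).normalize()
    start = end - pd.Timedelta(days=window_days)

    # hourly aggregation with the heart-rate quality rule
    hourly: dict[pd.Timestamp, float] = {}
    for _, row in samples.iterrows():
        ts = pd.Timestamp(row["timestamp"])
        key = ts.normalize() + pd.Timedelta(hours=ts.hour)
        hourly.setdefault(key, []).append((row["steps"], row["heart_rate"]))
    grid = pd.date_range(start, end - pd.Timedelta(hours=1), freq="h")
    series = []
    for stamp in grid:
        if stamp not in hourly:
            series.append(np.nan)
            continue
        pairs = hourly[stamp]
        hrs = [h for _, h in pairs if not pd.isna(h)]
        steps = [s for s, _ in pairs if not pd.isna(s)]
        if len(hrs) == 0:  # hourly HR median missing -> hour invalid
            series.append(np.nan)
        else:
            series.append(float(np.sum(steps)) if steps else np.nan)
    series = np.array(series)

    days_with_data = set()
    for stamp, v in zip(grid, series):
        if not np.isnan(v):
            days_with_data.add(stamp.normalize())
    if len(days_with_data) < min_days:
        return None

    smoothed = np.empty_like(series)
    for i in range(len(series)):
        window = [series[j] for j in (i - 1, i, i + 1) if 0 <= j < len(series)]
        window = [v for v in window if not np.isnan(v)]
        smoothed[i] = np.mean(window) if window else np.nan

    profile = np.zeros(24)
    for h in range(24):
        vals = [v for stamp, v in zip(grid, smoothed) if stamp.hour == h and not np.isnan(v)]
        profile[h] = np.mean(vals) if vals else 0.0
    return profile


# -- classification oracle -------------------------------------------------

def oracle_confusion(y_true, y_pred, labels=("A", "B", "C")) -> np.ndarray:
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[labels.index(t), labels.index(p)] += 1
    return cm
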