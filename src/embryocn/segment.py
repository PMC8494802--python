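"""Circular binary segmentation (CBS) of per-bin copy-number profiles.

The copy-number profile of each chromosome is segmented recursively: at each
step the arc of bins whose mean differs most from the complement (the
circular max-|t| statistic) is located; if the split is significant at level
``alpha`` the arc boundaries become change-points and the three resulting
pieces are segmented in turn.  Significance can be assessed either by a
permutation test (exact but costly) or by a conservative Sidak-style bound
over all arcs using the t tail probability (fast, and accurate enough at
deep coverage where genuine steps give enormous statistics).  A final merge
pass re-tests each adjacent pair of segments and removes boundaries that are
no longer significant.

Ties in the max statistic are broken toward the leftmost coordinate, making
the output deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .depth import NormalizedCNMatrix

_EPS = 1e-12


@dataclass(frozen=True)
class CBSParams:
    """Knobs of the change-point search.

    alpha: significance level for accepting a split (and for the merge pass).
    method: "gauss" for the analytic bound, "perm" for a permutation test.
    nperm: permutations when method == "perm".
    min_width: minimum number of bins per segment.
    """

    alpha: float = 0.01
    method: str = "gauss"
    nperm: int = 10_000
    min_width: int = 2
    seed: int = 0


def _max_arc_t(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Max circular two-sample |t| over arcs x[i:j] vs the complement.

    Returns (t, i, j); ties resolved to the smallest (j - i), then smallest i.
    A zero-variance split with distinct means returns t = inf.
    """
    n = x.size
    S = np.concatenate(([0.0], np.cumsum(x)))
    total = S[-1]
    ss_total = float(np.sum((x - total / n) ** 2))
    best_t, best_i, best_j = -1.0, 0, n
    for k in range(min_width, n - min_width + 1):
        sums = S[k:] - S[: n - k + 1]
        m1 = sums / k
        m2 = (total - sums) / (n - k)
        diff = m1 - m2
        # within-group sum of squares via the between-group decomposition
        between = k * (m1 - total / n) ** 2 + (n - k) * (m2 - total / n) ** 2
        within = np.maximum(ss_total - between, 0.0)
        if n > 2:
            var = within / (n - 2)
        else:
            var = np.zeros_like(within)
        denom = np.sqrt(np.maximum(var, 0.0) * (1.0 / k + 1.0 / (n - k)))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(diff) / denom
        t = np.where(denom < _EPS, np.where(np.abs(diff) > 1e-9, np.inf, 0.0), t)
        idx = int(np.argmax(t))
        if t[idx] > best_t:
            best_t, best_i, best_j = float(t[idx]), idx, idx + k
    return best_t, best_i, best_j


def _split_p_value(x: np.ndarray, tmax: float, params: CBSParams,
                   rng: np.random.Generator) -> float:
    n = x.size
    if not np.isfinite(tmax):
        return 0.0
    if tmax <= 0:
        return 1.0
    if params.method == "perm":
        hits = 0
        for _ in range(params.nperm):
            t_b, _, _ = _max_arc_t(rng.permutation(x), params.min_width)
            if t_b >= tmax:
                hits += 1
        return (1 + hits) / (params.nperm + 1)
    if params.method == "gauss":
        # Sidak-style bound over all candidate arcs; conservative but cheap.
        n_tests = n * (n - 1) / 2
        p1 = 2.0 * stats.t.sf(tmax, df=max(n - 2, 1))
        return float(min(1.0, -np.expm1(n_tests * np.log1p(-min(p1, 1.0 - _EPS)))))
    raise ValueError(f"unknown significance method {params.method!r}")


def _recurse(x: np.ndarray, offset: int, params: CBSParams,
             rng: np.random.Generator, breakpoints: list[int]) -> None:
    n = x.size
    if n < 2 * params.min_width:
        return
    tmax, i, j = _max_arc_t(x, params.min_width)
    if tmax <= 0:
        return
    if _split_p_value(x, tmax, params, rng) > params.alpha:
        return
    cuts = [c for c in (i, j) if 0 < c < n]
    for c in cuts:
        breakpoints.append(offset + c)
    edges = [0, *cuts, n]
    for a, b in zip(edges[:-1], edges[1:]):
        _recurse(x[a:b], offset + a, params, rng, breakpoints)


def _merge_pass(x: np.ndarray, breakpoints: list[int], params: CBSParams,
                rng: np.random.Generator) -> list[int]:
    """Drop boundaries whose adjacent segments no longer differ."""
    bps = sorted(breakpoints)
    changed = True
    while changed and bps:
        changed = False
        edges = [0, *bps, x.size]
        worst_p, worst_idx = -1.0, -1
        for idx in range(len(bps)):
            a, b, c = edges[idx], edges[idx + 1], edges[idx + 2]
            left, right = x[a:b], x[b:c]
            if np.ptp(np.concatenate([left, right])) < _EPS:
                p = 1.0
            elif min(left.size, right.size) < 2 or (np.var(left) + np.var(right)) < _EPS:
                p = 0.0 if abs(left.mean() - right.mean()) > 1e-9 else 1.0
            else:
                p = float(stats.ttest_ind(left, right, equal_var=False).pvalue)
            if p > worst_p:
                worst_p, worst_idx = p, idx
        if worst_p > params.alpha:
            del bps[worst_idx]
            changed = True
    return bps


def cbs_breakpoints(x: np.ndarray, params: CBSParams | None = None) -> list[int]:
    """Change-point indices (positions where a new segment starts) of a 1-D
    copy-number vector."""
    params = params or CBSParams()
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return []
    rng = np.random.default_rng(params.seed)
    found: list[int] = []
    _recurse(x, 0, params, rng, found)
    return _merge_pass(x, found, params, rng)


def segment_cn(norm: NormalizedCNMatrix, params: CBSParams | None = None) -> pd.DataFrame:
    """Segment every sample and chromosome of a normalized CN matrix.

    Returns a table of (sample, chrom, start, end, mean_cn, n_bins);
    segments tile the covered extent of each chromosome, with masked or
    missing bins absorbed into the covering segment.
    """
    params = params or CBSParams()
    rows = []
    bins = norm.bins
    for sample in norm.samples:
        y_all = norm.values[sample].to_numpy()
        for chrom in bins["chrom"].unique():
            on_chrom = (bins["chrom"] == chrom).to_numpy()
            ok = on_chrom & ~norm.mask & np.isfinite(y_all)
            if not ok.any():
                warnings.warn(f"no usable bins for {sample} on {chrom}", stacklevel=2)
                continue
            idx = np.flatnonzero(ok)
            y = y_all[idx]
            bps = cbs_breakpoints(y, params)
            edges = [0, *bps, y.size]
            for a, b in zip(edges[:-1], edges[1:]):
                rows.append(
                    {
                        "sample": sample,
                        "chrom": chrom,
                        "start": int(bins["start"].iloc[idx[a]]),
                        "end": int(bins["end"].iloc[idx[b - 1]]),
                        "mean_cn": float(np.mean(y[a:b])),
                        "n_bins": int(b - a),
                    }
                )
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "mean_cn", "n_bins"])


def optimal_rss_breakpoints(x: np.ndarray, n_breakpoints: int) -> list[int]:
    """Exhaustive minimum-RSS placement of a given number of change-points.

    Brute force over all breakpoint sets; intended as an independent oracle
    for small vectors (use only for n <= ~15).
    """
    from itertools import combinations

    x = np.asarray(x, dtype=float)
    n = x.size
    if n_breakpoints == 0:
        return []
    best_rss, best = np.inf, None
    for combo in combinations(range(1, n), n_breakpoints):
        edges = [0, *combo, n]
        rss = sum(
            float(np.sum((x[a:b] - x[a:b].mean()) ** 2))
            for a, b in zip(edges[:-1], edges[1:])
        )
        if rss < best_rss - _EPS:
            best_rss, best = rss, list(combo)
    return best


def export_seg(segments: pd.DataFrame) -> pd.DataFrame:
    """SEG-format view of a segment table (sample, chrom, loc.start, loc.end,
    num.mark, seg.mean)."""
    return pd.DataFrame(
        {
            "sample": segments["sample"],
            "chrom": segments["chrom"],
            "loc.start": segments["start"],
            "loc.end": segments["end"],
            "num.mark": segments["n_bins"],
            "seg.mean": segments["mean_cn"],
        }
    )
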