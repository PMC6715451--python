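"""SAM-style permutation differential expression.

The moderated difference statistic is ``d_i = r_i / (s_i + s0)`` where
``r_i`` is the mean group difference (unpaired) or the mean within-subject
difference (paired), ``s_i`` the corresponding pooled / paired standard
error, and ``s0`` a small positive "fudge" constant chosen from the
percentiles of the ``s_i`` distribution to stabilize features with tiny
variance.  Significance comes from a permutation null pooled across
features: group labels are re-drawn (unpaired) or within-subject signs are
flipped (paired), the statistic is recomputed with the same ``s0``, and

    p_i = (1 + #{permuted |d*| >= |d_i|}) / (1 + N_permuted_values).

Full enumeration of the permutation group is used whenever it is feasible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import ExpressionDataset, LNCRNA, MRNA

log = logging.getLogger(__name__)

FULL_ENUMERATION_LIMIT = 20_000


@dataclass
class SamResult:
    """Per-feature SAM output at a given calling threshold."""

    table: pd.DataFrame        # columns: feature, biotype, d, s, p, called
    s0: float
    threshold: float
    n_permutations: int
    full_enumeration: bool

    def called_features(self) -> list[str]:
        return list(self.table.loc[self.table["called"], "feature"])


# ---------------------------------------------------------------------------
# statistic components
# ---------------------------------------------------------------------------

def _unpaired_components(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r = mean(x1) - mean(x2); s = pooled standard error (SAM definition)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    r = x1.mean(axis=1) - x2.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    a = 1.0 / n1 + 1.0 / n2
    s = np.sqrt(a * ss / (n1 + n2 - 2))
    return r, s


def _paired_components(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r = mean within-subject difference; s = its standard error."""
    n = diffs.shape[1]
    r = diffs.mean(axis=1)
    s = np.sqrt(((diffs - r[:, None]) ** 2).sum(axis=1) / (n * (n - 1)))
    return r, s


def sam_components(ds: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    """(r, s) for the dataset's contrast; paired if pairing is present."""
    if ds.pairing is not None:
        return _paired_components(ds.paired_differences().to_numpy())
    pos, base = ds.contrast
    return _unpaired_components(ds.values_for(pos), ds.values_for(base))


def sam_statistic(ds: ExpressionDataset, s0: float) -> np.ndarray:
    """d_i = r_i / (s_i + s0); errors on zero-variance features when s0 = 0."""
    r, s = sam_components(ds)
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    denom = s + s0
    if np.any(denom == 0):
        raise ValueError("zero-variance feature with s0=0 makes d undefined")
    return r / denom


def choose_s0(r: np.ndarray, s: np.ndarray, n_windows: int = 20) -> float:
    """Fudge-constant selection on the percentile grid 0, 5, ..., 100 of s.

    For each candidate s0, features are split into quantile windows of s and
    the coefficient of variation of mad(d) across windows is evaluated; the
    candidate minimizing it wins (ties -> smallest percentile).
    """
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    if len(s) < 20:
        log.warning("choose_s0 on %d features; >=20 recommended", len(s))
    grid = np.percentile(s, np.arange(0, 101, 5))
    n_windows = max(2, min(n_windows, len(s) // 2))
    edges = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)

    best_cv, best_s0 = np.inf, float(grid[0])
    for candidate in grid:
        d = r / (s + candidate)
        mads = np.array([
            _mad(d[window == w]) for w in range(n_windows) if np.any(window == w)
        ])
        mean = mads.mean()
        cv = 0.0 if mean == 0 else mads.std(ddof=1) / mean if len(mads) > 1 else 0.0
        if cv < best_cv - 1e-15:           # strict improvement; ties keep earlier
            best_cv, best_s0 = cv, float(candidate)
    return best_s0


def _mad(x: np.ndarray) -> float:
    # scaled median absolute deviation (consistent with a normal sd)
    if len(x) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _unpaired_permutations(n1: int, n2: int, n_perm: int, rng: np.random.Generator):
    """Yield boolean case-masks over the pooled columns; full enumeration if small."""
    total = math.comb(n1 + n2, n1)
    if total <= FULL_ENUMERATION_LIMIT:
        masks = np.zeros((total, n1 + n2), dtype=bool)
        for i, idx in enumerate(combinations(range(n1 + n2), n1)):
            masks[i, list(idx)] = True
        return masks, True
    masks = np.zeros((n_perm, n1 + n2), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n1 + n2, size=n1, replace=False)] = True
    return masks, False


def _sign_flips(n: int, n_perm: int, rng: np.random.Generator):
    total = 2**n
    if total <= FULL_ENUMERATION_LIMIT:
        bits = (np.arange(total)[:, None] >> np.arange(n)[None, :]) & 1
        return np.where(bits == 1, -1.0, 1.0), True
    return np.where(rng.random((n_perm, n)) < 0.5, -1.0, 1.0), False


def permutation_pvalues(
    ds: ExpressionDataset,
    d_observed: np.ndarray,
    s0: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, int, bool]:
    """Pooled permutation p-values for |d|.

    Returns (p, number of permutations used, whether fully enumerated).
    The pool contains every feature's statistic under every permutation, so
    the add-one estimator's floor is ``1 / (1 + n_features * n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] = []

    if ds.pairing is not None:
        diffs = ds.paired_differences().to_numpy()
        n = diffs.shape[1]
        if n < 2:
            raise ValueError("paired permutation test needs >= 2 subjects")
        flips, full = _sign_flips(n, n_perm, rng)
        for signs in flips:
            r, s = _paired_components(diffs * signs[None, :])
            pooled.append(np.abs(r / (s + s0)))
        n_used = len(flips)
    else:
        pos, base = ds.contrast
        x = np.hstack([ds.values_for(pos), ds.values_for(base)])
        n1 = len(ds.group_columns(pos))
        n2 = x.shape[1] - n1
        if n1 < 2 or n2 < 2:
            raise ValueError("unpaired permutation test needs >= 2 samples per group")
        masks, full = _unpaired_permutations(n1, n2, n_perm, rng)
        for mask in masks:
            r, s = _unpaired_components(x[:, mask], x[:, ~mask])
            pooled.append(np.abs(r / (s + s0)))
        n_used = len(masks)

    null = np.sort(np.concatenate(pooled))
    total = len(null)
    count_ge = total - np.searchsorted(null, np.abs(d_observed), side="left")
    p = (1.0 + count_ge) / (1.0 + total)
    return p, n_used, full


# ---------------------------------------------------------------------------
# calling and intersection
# ---------------------------------------------------------------------------

def sam_analysis(
    ds: ExpressionDataset,
    threshold: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    s0: float | None = None,
) -> SamResult:
    """Full SAM run: components, s0 selection, permutation p, calls."""
    r, s = sam_components(ds)
    if s0 is None:
        s0 = choose_s0(r, s)
    d = r / (s + s0)
    p, n_used, full = permutation_pvalues(ds, d, s0=s0, n_perm=n_perm, seed=seed)
    table = pd.DataFrame({
        "feature": ds.features,
        "biotype": ds.biotype.values,
        "d": d,
        "s": s,
        "p": p,
        "called": p < threshold,
    }).reset_index(drop=True)
    return SamResult(table=table, s0=s0, threshold=threshold,
                     n_permutations=n_used, full_enumeration=full)


def call_degs(res: SamResult, threshold: float = 0.01) -> dict[str, list[str]]:
    """Features with p strictly below threshold, split by biotype."""
    t = res.table
    called = t[t["p"] < threshold]
    return {
        LNCRNA: sorted(called.loc[called["biotype"] == LNCRNA, "feature"]),
        MRNA: sorted(called.loc[called["biotype"] == MRNA, "feature"]),
    }


def intersect_contrasts(
    degs1: dict[str, list[str]], degs2: dict[str, list[str]]
) -> dict[str, list[str]]:
    """Features called in both contrasts, kept split by biotype."""
    return {
        bt: sorted(set(degs1.get(bt, [])) & set(degs2.get(bt, [])))
        for bt in (LNCRNA, MRNA)
    }


def impute_feature_median(matrix: pd.DataFrame) -> pd.DataFrame:
    """Optional pre-step: replace missing values by the feature median."""
    med = matrix.median(axis=1)
    return matrix.apply(lambda col: col.fillna(med))
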