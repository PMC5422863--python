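"""Statistical comparison machinery for trajectory series.

Two trajectories' series are compared bin by bin with a windowed
Mann-Whitney Z statistic (disjoint 50-snapshot bins by default, matching
the 100-windows-per-10-ns cadence of the source workflow), variances with a
two-sided F-test, and families of tests are controlled with the
Benjamini-Hochberg false-discovery-rate step-up.

These tests treat snapshots within a bin as exchangeable; MD frames are
autocorrelated, so p-values are anticonservative for strongly correlated
series — a documented caveat, not corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .geometry import GeometrySeries


def _values(series) -> np.ndarray:
    if isinstance(series, GeometrySeries):
        return series.values
    return np.asarray(series, dtype=float)


def mann_whitney_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Mann-Whitney U of sample a vs b with tie-corrected normal
    approximation.  Returns (U, Z, two-sided p); an all-tied comparison
    yields Z = 0, p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u = ranks[:n].sum() - n * (n + 1) / 2.0
    mu = n * m / 2.0
    nn = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    var = n * m / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
    if var <= 0:
        return float(u), 0.0, 1.0
    z = (u - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(u), float(z), float(min(p, 1.0))


@dataclass
class WindowedComparison:
    """Per-window Mann-Whitney Z comparison of two aligned series."""

    window: int
    table: pd.DataFrame  # columns: start, u, z, p, all_tied

    def __len__(self) -> int:
        return len(self.table)

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy()

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()


def moving_mwz(series_a, series_b, window: int = 50,
               disjoint: bool = True) -> WindowedComparison:
    """Windowed Mann-Whitney Z between two equal-length series.

    With ``disjoint=True`` (default — the series are compared in "bins")
    windows are consecutive non-overlapping blocks, floor(n/window) of
    them; otherwise a sliding window moves one snapshot at a time.
    """
    a = _values(series_a)
    b = _values(series_b)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    n = a.size
    if not 1 <= window <= n:
        raise ValueError("window must be in [1, series length]")
    starts = range(0, n - window + 1, window if disjoint else 1)
    rows = []
    for s in starts:
        wa = a[s: s + window]
        wb = b[s: s + window]
        all_tied = np.ptp(np.concatenate([wa, wb])) == 0
        u, z, p = mann_whitney_z(wa, wb)
        rows.append({"start": s, "u": u, "z": z, "p": p, "all_tied": all_tied})
    return WindowedComparison(window, pd.DataFrame(rows))


@dataclass
class FTestResult:
    f: float
    dfn: int
    dfd: int
    p: float
    larger: str          # which input had the larger variance ("A" or "B")
    degenerate: bool = False


def f_test_variance(series_a, series_b) -> FTestResult:
    """Two-sided F-test for a variance difference between two series.

    The larger sample variance goes in the numerator (recorded in
    ``larger``); p is the two-sided tail probability.  Zero variance in
    both inputs is an error; in one, p = 0 with the degenerate flag set.
    """
    a = _values(series_a)
    b = _values(series_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each series needs at least 2 values")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both series have zero variance")
    if va == 0 or vb == 0:
        larger = "A" if vb == 0 else "B"
        return FTestResult(np.inf, a.size - 1, b.size - 1, 0.0, larger,
                           degenerate=True)
    if va >= vb:
        f, dfn, dfd, larger = va / vb, a.size - 1, b.size - 1, "A"
    else:
        f, dfn, dfd, larger = vb / va, b.size - 1, a.size - 1, "B"
    p = min(1.0, 2.0 * sps.f.sf(f, dfn, dfd))
    return FTestResult(float(f), dfn, dfd, float(p), larger)


def benjamini_hochberg(p_values, q: float = 0.05
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control at level q.

    Returns (reject flags, adjusted p-values); adjusted values are the
    monotone step-up envelope.  Empty input returns empty arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted


def compare_parameter_family(pairs: dict, q: float = 0.05,
                             test: str = "f") -> pd.DataFrame:
    """Run one test per named series pair and BH-correct the family.

    ``pairs`` maps parameter name -> (series_a, series_b).  The family of
    parameters entering the correction is the caller's declaration.
    Returns a DataFrame with statistic, p, adjusted p and rejection flags.
    """
    names = list(pairs)
    stats_ = []
    ps = []
    for name in names:
        a, b = pairs[name]
        if test == "f":
            r = f_test_variance(a, b)
            stats_.append(r.f)
            ps.append(r.p)
        elif test == "mwz":
            _, z, p = mann_whitney_z(_values(a), _values(b))
            stats_.append(z)
            ps.append(p)
        else:
            raise ValueError(f"unknown test {test!r}")
    reject, adjusted = benjamini_hochberg(np.array(ps), q)
    return pd.DataFrame({"statistic": stats_, "p": ps,
                         "p_adjusted": adjusted, "reject": reject},
                        index=names)
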