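"""Catalytic-geometry tracking and the optimal-attack-geometry census.

The glycosylase reaction is an SN2 displacement at C1' of the everted
lesion: the N-terminal proline nitrogen attacks C1' while the Glu2 carboxyl
protonates the sugar O4'.  The census tracks the two key distances and two
attack angles per snapshot and counts snapshots in which all four are
simultaneously "optimal": N...C1' < 4 A, OE2...O4' < 4.5 A, the
C1'...N...Cdelta angle within 20 degrees of 107 degrees (tetrahedral
nitrogen lone pair), and the O4'...C1'...N angle within 20 degrees of 180
degrees (in-line attack).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometrySeries, angle_series, distance_series


@dataclass
class CatalyticAtoms:
    """Atom indices of the reacting groups."""

    n_pro1: int       # proline backbone nitrogen (nucleophile)
    cd_pro1: int      # proline Cdelta
    oe2_glu2: int     # glutamate carboxyl oxygen (proton donor); for the
                      # protonated GLH variant the choice of OE1/OE2 is the
                      # caller's, default as labeled
    c1p_lesion: int   # lesion C1' (electrophile)
    o4p_lesion: int   # lesion sugar O4' (or carbocyclic isostere)
    n9_lesion: int    # lesion glycosidic nitrogen


@dataclass
class CensusCriteria:
    d1_max: float = 4.0           # N[Pro1]...C1' cutoff, Angstrom
    d2_max: float = 4.5           # OE2[Glu2]...O4' cutoff, Angstrom
    ideal_angle1: float = 107.0   # C1'...N...Cdelta, degrees
    ideal_angle2: float = 180.0   # O4'...C1'...N, degrees
    angle_tolerance: float = 20.0  # symmetric, boundary inclusive

    def __post_init__(self) -> None:
        if self.d1_max <= 0 or self.d2_max <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not 0.0 < self.angle_tolerance < 90.0:
            raise ValueError("angle tolerance must be in (0, 90) degrees")


def catalytic_series(traj, atoms: CatalyticAtoms) -> dict[str, GeometrySeries]:
    """The five aligned series of the attack geometry: d1 (N...C1'),
    d2 (OE2...O4'), angle1 (C1'...N...Cdelta), angle2 (O4'...C1'...N) and
    angle_n9 (N9...C1'...N, reporting the disfavored C1'-N9 attack line)."""
    for field in ("n_pro1", "cd_pro1", "oe2_glu2", "c1p_lesion",
                  "o4p_lesion", "n9_lesion"):
        idx = getattr(atoms, field)
        if not 0 <= idx < traj.topology.n_atoms:
            raise ValueError(f"catalytic atom {field} index {idx} out of range")
    return {
        "d1": distance_series(traj, atoms.n_pro1, atoms.c1p_lesion, name="d1"),
        "d2": distance_series(traj, atoms.oe2_glu2, atoms.o4p_lesion, name="d2"),
        "angle1": angle_series(traj, atoms.c1p_lesion, atoms.n_pro1,
                               atoms.cd_pro1, name="angle1"),
        "angle2": angle_series(traj, atoms.o4p_lesion, atoms.c1p_lesion,
                               atoms.n_pro1, name="angle2"),
        "angle_n9": angle_series(traj, atoms.n9_lesion, atoms.c1p_lesion,
                                 atoms.n_pro1, name="angle_n9"),
    }


def optimal_geometry_census(series: dict[str, GeometrySeries],
                            criteria: CensusCriteria | None = None
                            ) -> tuple[int, float, np.ndarray]:
    """Count snapshots with all four attack-geometry parameters optimal.

    Returns (count, fraction, boolean mask).  The mask is the intersection
    of the four single-criterion masks; invalid (masked) series values fail
    their criterion.
    """
    c = criteria or CensusCriteria()
    lengths = {len(s) for s in series.values()}
    if len(lengths) != 1:
        raise ValueError("series are not aligned")
    ok = (series["d1"].values < c.d1_max) & series["d1"].mask
    ok &= (series["d2"].values < c.d2_max) & series["d2"].mask
    ok &= (np.abs(series["angle1"].values - c.ideal_angle1)
           <= c.angle_tolerance) & series["angle1"].mask
    ok &= (np.abs(series["angle2"].values - c.ideal_angle2)
           <= c.angle_tolerance) & series["angle2"].mask
    count = int(ok.sum())
    return count, count / len(ok), ok


@dataclass
class SeriesSummary:
    """Median, central 90% range, histogram and modality of one series."""

    median: float
    p5: float
    p95: float
    histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin edges)
    peak_count: int

    @property
    def range90(self) -> tuple[float, float]:
        return (self.p5, self.p95)

    def __str__(self) -> str:
        return f"{self.median:.2f} ({self.p5:.2f}-{self.p95:.2f})"


def summarize_series(series: GeometrySeries, min_values: int = 20
                     ) -> SeriesSummary:
    """Median and 5th-95th percentile range plus a histogram peak count.

    Peaks are local maxima of the 3-bin-smoothed Freedman-Diaconis
    histogram exceeding 10% of its global maximum — the count separates
    unimodal from two-basin ("two peaks in the distribution") behavior.
    """
    vals = series.valid_values()
    if vals.size == 0:
        raise ValueError("series has no valid values")
    if vals.size < min_values:
        raise ValueError(f"need >= {min_values} valid values for stable "
                         f"percentiles, got {vals.size}")
    med = float(np.median(vals))
    p5, p95 = (float(v) for v in np.percentile(vals, [5.0, 95.0]))
    if np.ptp(vals) == 0:
        counts = np.array([vals.size], dtype=float)
        edges = np.array([vals[0] - 0.5, vals[0] + 0.5])
        return SeriesSummary(med, p5, p95, (counts, edges), 1)
    counts, edges = np.histogram(vals, bins="fd")
    smoothed = np.convolve(counts.astype(float), np.ones(3) / 3.0, mode="same")
    floor = 0.10 * smoothed.max()
    peaks = 0
    i = 0
    n = len(smoothed)
    while i < n:
        j = i
        while j + 1 < n and smoothed[j + 1] == smoothed[i]:
            j += 1  # plateau
        left = smoothed[i - 1] if i > 0 else -np.inf
        right = smoothed[j + 1] if j + 1 < n else -np.inf
        if smoothed[i] > floor and smoothed[i] > left and smoothed[i] > right:
            peaks += 1
        i = j + 1
    return SeriesSummary(med, p5, p95, (counts, edges), max(peaks, 1))


def census_report(models: dict, criteria: CensusCriteria | None = None):
    """Tabular per-model report: median (90% range) for d1, d2, angle1,
    angle2, and the optimal-geometry snapshot count.

    ``models`` maps model label -> series bundle from
    :func:`catalytic_series`.  Returns a pandas DataFrame.
    """
    import pandas as pd

    c = criteria or CensusCriteria()
    rows = {}
    for label, bundle in models.items():
        count, frac, _ = optimal_geometry_census(bundle, c)
        row = {}
        for key in ("d1", "d2", "angle1", "angle2"):
            s = summarize_series(bundle[key])
            row[key] = str(s)
            row[f"{key}_peaks"] = s.peak_count
        row["optimal_count"] = count
        row["optimal_fraction"] = frac
        rows[label] = row
    return pd.DataFrame(rows).T
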