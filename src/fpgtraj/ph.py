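"""Two-state ionization model for pH-activity profiles.

A single titratable group with acidity constant Ka gives a rising
activity-vs-pH curve with one inflection:

    activity(pH) = B + A / (1 + 10^(pKa - pH))

B is the low-pH baseline, B + A the high-pH plateau, and the curve passes
through B + A/2 exactly at pH = pKa.  The fit is nonlinear least squares
with standard errors from the Jacobian-based covariance; for the enzyme
activity data this model describes, the transition reflects deprotonation
of the catalytic N-terminal proline (reported pKa 6.8 +/- 0.1 under
single-turnover conditions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


def two_state_model(ph, pka, amplitude, baseline):
    """Activity of a single-transition two-state ionization."""
    ph = np.asarray(ph, dtype=float)
    out = baseline + amplitude / (1.0 + 10.0 ** (pka - ph))
    return float(out) if out.ndim == 0 else out


@dataclass
class PhCurve:
    """(pH, activity) data points; activity units are arbitrary."""

    ph: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.ph.shape != self.activity.shape or self.ph.ndim != 1:
            raise ValueError("ph and activity must be aligned 1-d arrays")
        if len(np.unique(self.ph)) != len(self.ph):
            raise ValueError("pH values must be distinct")
        if len(self.ph) < 4:
            raise ValueError("need at least 4 points to fit")

    @classmethod
    def from_text(cls, text: str) -> "PhCurve":
        """Parse delimited text (pH, activity[, replicate]) with optional
        header; replicate columns are averaged per pH."""
        ph, act = [], []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").replace("\t", " ").split()
            try:
                vals = [float(v) for v in parts]
            except ValueError:
                continue  # header line
            ph.append(vals[0])
            act.append(np.mean(vals[1:]))
        return cls(np.array(ph), np.array(act))


class FitConvergenceError(RuntimeError):
    """Raised when the fit fails; carries the best iterate found."""

    def __init__(self, message: str, best_params=None):
        super().__init__(message)
        self.best_params = best_params


@dataclass
class TwoStateFit:
    pka: float
    amplitude: float
    baseline: float
    se_pka: float
    se_amplitude: float
    se_baseline: float
    residuals: np.ndarray
    rss: float

    @property
    def identifiable(self) -> bool:
        """False when the data do not pin down the transition
        (SE(pKa) > 1 pH unit)."""
        return bool(np.isfinite(self.se_pka) and self.se_pka <= 1.0)

    def predict(self, ph):
        return two_state_model(ph, self.pka, self.amplitude, self.baseline)


def _initial_guess(ph: np.ndarray, activity: np.ndarray):
    order = np.argsort(ph)
    phs, act = ph[order], activity[order]
    baseline = float(act.min())
    amplitude = float(act.max() - act.min())
    half = baseline + amplitude / 2.0
    crossing = phs[-1]
    for i in range(len(phs) - 1):
        lo, hi = act[i], act[i + 1]
        if (lo - half) * (hi - half) <= 0 and lo != hi:
            crossing = phs[i] + (half - lo) / (hi - lo) * (phs[i + 1] - phs[i])
            break
    return crossing, max(amplitude, 1e-12), baseline


def fit_two_state(curve: PhCurve, max_restarts: int = 4) -> TwoStateFit:
    """Fit the two-state model by nonlinear least squares.

    Initialization: baseline = min activity, amplitude = range, pKa = pH of
    the half-range crossing by linear interpolation.  On non-convergence
    the fit restarts from pKa offsets of +/-1 and +/-2 units; persistent
    failure raises :class:`FitConvergenceError` carrying the best iterate.
    """
    ph, act = curve.ph, curve.activity
    pka0, a0, b0 = _initial_guess(ph, act)
    best = None
    best_rss = np.inf
    last_error = None
    offsets = [0.0, 1.0, -1.0, 2.0, -2.0][: max_restarts + 1]
    for off in offsets:
        try:
            popt, pcov = curve_fit(
                two_state_model, ph, act, p0=[pka0 + off, a0, b0],
                maxfev=20000)
        except RuntimeError as exc:
            last_error = exc
            continue
        resid = act - two_state_model(ph, *popt)
        rss = float(resid @ resid)
        if rss < best_rss:
            best, best_rss = (popt, pcov, resid), rss
    if best is None:
        raise FitConvergenceError(
            f"two-state fit did not converge: {last_error}",
            best_params=(pka0, a0, b0))
    popt, pcov, resid = best
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) \
        else np.full(3, np.inf)
    return TwoStateFit(
        pka=float(popt[0]), amplitude=float(popt[1]), baseline=float(popt[2]),
        se_pka=float(se[0]), se_amplitude=float(se[1]), se_baseline=float(se[2]),
        residuals=resid, rss=best_rss)
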