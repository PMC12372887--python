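"""Equilibrium binding and dose-response curve models.

Two explicit models with unweighted least-squares fitting:

* one-site total binding, ``Y = Bmax*X/(Kd + X) + NS*X + Background`` —
  specific saturation plus a linear nonspecific term, the standard model
  for spectral-shift / fluorescence binding titrations;
* variable-slope (four-parameter logistic) inhibitor dose-response on
  log10 concentration,
  ``Y = Bottom + (Top - Bottom)/(1 + 10**((log10(IC50) - log10(X)) * Hill))``.

Replicates are fitted jointly; standard errors come from the Jacobian at
the optimum; a fit that fails to converge is returned with
``converged=False`` rather than raising.  A helper builds the serial
dilution design used for titrations (default 1:1 over 16 steps from
250 uM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BindingCurve",
    "BindingModelFit",
    "DoseResponseFit",
    "total_binding_predict",
    "dose_response_predict",
    "fit_total_binding",
    "fit_dose_response",
    "dilution_series",
    "load_curve",
]


@dataclass
class BindingCurve:
    """Concentration-response data; X in uM (an optional single zero allowed)."""

    x: np.ndarray
    y: np.ndarray
    replicate_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if (self.x < 0).any():
            raise ValueError("concentrations must be >= 0")

    def sorted(self) -> "BindingCurve":
        order = np.argsort(self.x)
        reps = None if self.replicate_ids is None else np.asarray(self.replicate_ids)[order]
        return BindingCurve(self.x[order], self.y[order], reps)


def load_curve(source: str | Path, x_col: str = "concentration", y_col: str = "response",
               replicate_col: str = "replicate") -> BindingCurve:
    """Read a concentration-response CSV (optional replicate column)."""
    df = pd.read_csv(source)
    for col in (x_col, y_col):
        if col not in df.columns:
            raise ValueError(f"{source}: missing column {col!r}")
    reps = df[replicate_col].to_numpy() if replicate_col in df.columns else None
    return BindingCurve(df[x_col].to_numpy(float), df[y_col].to_numpy(float), reps)


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def total_binding_predict(
    x: np.ndarray | float, bmax: float, kd: float, ns: float, background: float
) -> np.ndarray | float:
    """One-site total binding: Y = Bmax*X/(Kd + X) + NS*X + Background."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    x = np.asarray(x, dtype=float)
    y = bmax * x / (kd + x) + ns * x + background
    return float(y) if y.ndim == 0 else y


def dose_response_predict(
    x: np.ndarray | float, top: float, bottom: float, ic50: float, hill_slope: float
) -> np.ndarray | float:
    """Variable-slope logistic: the curve passes through (Top+Bottom)/2 at X=IC50."""
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        y = bottom + (top - bottom) / (1.0 + 10.0 ** ((np.log10(ic50) - np.log10(x)) * hill_slope))
    return float(y) if y.ndim == 0 else y


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class BindingModelFit:
    bmax: float
    kd: float
    ns: float
    background: float
    se: dict[str, float]
    rss: float
    converged: bool

    def predict(self, x):
        return total_binding_predict(x, self.bmax, self.kd, self.ns, self.background)


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    ic50: float
    hill_slope: float
    se: dict[str, float]
    rss: float
    converged: bool

    def predict(self, x):
        return dose_response_predict(x, self.top, self.bottom, self.ic50, self.hill_slope)


def _check_curve(curve: BindingCurve, min_distinct: int = 5) -> BindingCurve:
    curve = curve.sorted()
    if len(np.unique(curve.x)) < min_distinct:
        raise ValueError(f"need at least {min_distinct} distinct concentrations")
    return curve


def fit_total_binding(
    curve: BindingCurve,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
    init: Sequence[float] | None = None,
) -> BindingModelFit:
    """Least-squares fit of the one-site total binding model.

    Default initialization: background = min(Y), bmax = max(Y) - min(Y),
    kd = X at the half-rise of Y, ns = terminal slope of the last two
    points.  Default bounds keep bmax >= 0 and kd > 0.
    """
    curve = _check_curve(curve)
    x, y = curve.x, curve.y
    names = ("bmax", "kd", "ns", "background")
    if np.ptp(y) == 0:
        # flat data: every bmax/kd combination with bmax=0 is equivalent
        return BindingModelFit(
            bmax=0.0, kd=float("nan"), ns=0.0, background=float(y[0]),
            se={n: float("nan") for n in names}, rss=0.0, converged=False,
        )
    if init is None:
        background0 = float(np.min(y))
        bmax0 = float(np.ptp(y))
        half = background0 + bmax0 / 2.0
        above = x[y >= half]
        kd0 = float(above[0]) if len(above) and above[0] > 0 else float(np.median(x[x > 0]))
        tail = x > 0
        ns0 = float((y[-1] - y[-2]) / (x[-1] - x[-2])) if x[-1] > x[-2] else 0.0
        init = (bmax0, kd0, max(ns0, 0.0) if ns0 == ns0 else 0.0, background0)
    if bounds is None:
        bounds = ([0.0, 1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf])
    try:
        popt, pcov = curve_fit(
            total_binding_predict, x, y, p0=init, bounds=bounds, maxfev=20000
        )
        converged = np.all(np.isfinite(popt))
    except (RuntimeError, ValueError):
        popt = np.asarray(init, dtype=float)
        pcov = np.full((4, 4), np.nan)
        converged = False
    resid = y - total_binding_predict(x, *popt)
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    return BindingModelFit(
        bmax=float(popt[0]), kd=float(popt[1]), ns=float(popt[2]), background=float(popt[3]),
        se=dict(zip(names, map(float, se))),
        rss=float(np.sum(resid**2)),
        converged=bool(converged),
    )


def fit_dose_response(curve: BindingCurve, init: Sequence[float] | None = None) -> DoseResponseFit:
    """Least-squares fit of the variable-slope logistic dose-response model.

    Zero concentrations cannot sit on a log axis and are dropped with a
    warning.  Initialization from data quartiles: top/bottom from the
    response extremes, IC50 from the concentration nearest the half
    response, hill slope -1 or +1 by the direction of the response.
    """
    curve = _check_curve(curve)
    keep = curve.x > 0
    if not keep.all():
        warnings.warn("dropping zero-concentration points for the logistic fit")
    x, y = curve.x[keep], curve.y[keep]
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct positive concentrations")
    names = ("top", "bottom", "ic50", "hill_slope")
    if np.ptp(y) == 0:
        return DoseResponseFit(
            top=float(y[0]), bottom=float(y[0]), ic50=float("nan"), hill_slope=0.0,
            se={n: float("nan") for n in names}, rss=0.0, converged=False,
        )
    if init is None:
        top0, bottom0 = float(np.max(y)), float(np.min(y))
        half = (top0 + bottom0) / 2.0
        ic50_0 = float(x[np.argmin(np.abs(y - half))])
        falling = y[np.argsort(x)][-1] < y[np.argsort(x)][0]
        hill0 = -1.0 if falling else 1.0
        init = (top0, bottom0, ic50_0, hill0)
    bounds = ([-np.inf, -np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf, np.inf])
    try:
        popt, pcov = curve_fit(dose_response_predict, x, y, p0=init, bounds=bounds, maxfev=20000)
        converged = np.all(np.isfinite(popt))
    except (RuntimeError, ValueError):
        popt = np.asarray(init, dtype=float)
        pcov = np.full((4, 4), np.nan)
        converged = False
    # canonicalize so top >= bottom
    top, bottom, ic50, hill = map(float, popt)
    if top < bottom:
        top, bottom, hill = bottom, top, -hill
        popt = np.array([top, bottom, ic50, hill])
    resid = y - dose_response_predict(x, *popt)
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    return DoseResponseFit(
        top=top, bottom=bottom, ic50=ic50, hill_slope=hill,
        se=dict(zip(names, map(float, se))),
        rss=float(np.sum(resid**2)),
        converged=bool(converged),
    )


def dilution_series(top: float = 250.0, factor: float = 2.0, n_points: int = 16) -> np.ndarray:
    """Descending serial-dilution concentrations [top, top/factor, ...].

    The default emulates a 1:1 dilution titration from 250 uM; note that a
    16-point series bottoms out at top/2**15 (~0.0076 uM) while a 15-point
    series bottoms out at ~0.0153 uM — both designs are expressible via
    ``n_points``.
    """
    if top <= 0:
        raise ValueError("top must be > 0")
    if factor <= 1:
        raise ValueError("factor must be > 1")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    return top / factor ** np.arange(n_points)
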