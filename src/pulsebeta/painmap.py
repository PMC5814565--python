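r"""Normalized stiffness and sigmoid pain mapping.

The stiffness index :math:`\beta` is normalized by its maximum over a
no-stimulation baseline window, giving the change rate
:math:`\beta_n = \beta / \max \beta_{baseline}`.  Two bounded sigmoid
families relate :math:`\beta_n`, the stimulus level and pain scores:

* ``enrs`` — estimated numeric-rating-scale pain from normalized
  stiffness, piecewise:

  .. math:: \mathrm{eNRS} = \begin{cases}
        \dfrac{20}{1 + \exp(a (\beta_n - 1)^{-b})} & \beta_n > 1 \\
        0 & \beta_n \le 1 \end{cases}

  which maps :math:`(1, \infty) \to (0, 10)`, is continuous at
  :math:`\beta_n = 1` and strictly increasing above it.

* ``stimulus`` — a stimulus-response sigmoid
  :math:`10 / (1 + \exp(a S^{-b})) + 1` mapping stimulus level
  :math:`S \ge 0` to :math:`(1, 6)`, with the ``S = 0`` value defined by
  its limit, 1.

Both are fitted by bounded multi-start nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .errors import FitError, NormalizationError
from .io import BaselineWindow

#: Exponent cap to avoid overflow in the sigmoid tails.
_EXP_CAP = 700.0


@dataclass
class StiffnessSeries:
    """Beat-by-beat stiffness with its baseline-normalized form."""

    times: np.ndarray
    beta: np.ndarray
    beta_n: np.ndarray
    baseline: BaselineWindow

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.beta_n = np.asarray(self.beta_n, dtype=float)


@dataclass
class SigmoidMap:
    """Fitted (or specified) sigmoid with its evaluation semantics.

    ``variant`` selects the family: ``"enrs"`` (beta_n -> pain score in
    [0, 10)) or ``"stimulus"`` (level -> value in [1, 6)).
    """

    a: float
    b: float
    variant: str = "enrs"
    r2: float = np.nan
    residuals: np.ndarray | None = field(default=None, repr=False)
    n: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("enrs", "stimulus"):
            raise ValueError(f"unknown sigmoid variant {self.variant!r}")
        if not (self.a > 0 and self.b > 0):
            raise ValueError(
                f"sigmoid parameters must be positive, got a={self.a}, b={self.b}"
            )

    def __call__(self, x):
        if self.variant == "enrs":
            return enrs(x, self)
        return stimulus_sigmoid(x, self)


def normalize_beta(
    times: np.ndarray,
    beta: np.ndarray,
    baseline: BaselineWindow,
) -> StiffnessSeries:
    """Normalize stiffness by its maximum over the baseline window.

    Parameters
    ----------
    times, beta : ndarray
        Beat times (s) and accepted stiffness estimates, equal length.
    baseline : BaselineWindow
        No-stimulation window; at least one beat must fall inside it.

    Raises
    ------
    NormalizationError
        No beat inside the baseline, or non-positive baseline maximum.
    """
    times = np.asarray(times, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if times.shape != beta.shape:
        raise ValueError("times and beta must have equal length")
    in_base = baseline.contains(times)
    if not np.any(in_base):
        raise NormalizationError(
            f"no accepted beat inside baseline window "
            f"[{baseline.start}, {baseline.end}) s"
        )
    ref = float(np.max(beta[in_base]))
    if not ref > 0:
        raise NormalizationError("baseline maximum stiffness is not positive")
    return StiffnessSeries(times=times, beta=beta, beta_n=beta / ref,
                           baseline=baseline)


def series_from_estimates(estimates, fs: float,
                          baseline: BaselineWindow) -> StiffnessSeries:
    """Build a normalized series from accepted beat estimates."""
    acc = [e for e in estimates if e.accepted]
    if not acc:
        raise NormalizationError("no accepted beats to normalize")
    times = np.array([e.beat.t0_sample / fs for e in acc])
    beta = np.array([e.beta for e in acc])
    return normalize_beta(times, beta, baseline)


def enrs(beta_n, map_: SigmoidMap):
    """Estimated NRS pain score from normalized stiffness.

    Zero for ``beta_n <= 1`` (stiffness at or below baseline signals no
    pain); above 1 a bounded sigmoid rising towards, but never reaching,
    10.
    """
    if map_.variant != "enrs":
        raise ValueError("enrs requires a SigmoidMap with variant='enrs'")
    x = np.asarray(beta_n, dtype=float)
    out = np.zeros_like(x)
    pos = x > 1.0
    with np.errstate(over="ignore"):
        expo = np.minimum(map_.a * np.power(x[pos] - 1.0, -map_.b), _EXP_CAP)
        out[pos] = 20.0 / (1.0 + np.exp(expo))
    return float(out) if np.ndim(beta_n) == 0 else out


def stimulus_sigmoid(S, map_: SigmoidMap):
    """Bounded stimulus-response sigmoid 10/(1+exp(a S^-b)) + 1.

    The ``S = 0`` value is defined by the limit, 1; the function is
    strictly increasing and saturates at 6.
    """
    if map_.variant != "stimulus":
        raise ValueError("stimulus_sigmoid requires variant='stimulus'")
    x = np.asarray(S, dtype=float)
    if np.any(x < 0):
        raise ValueError("stimulus level must be non-negative")
    out = np.ones_like(x)
    pos = x > 0.0
    with np.errstate(over="ignore"):
        expo = np.minimum(map_.a * np.power(x[pos], -map_.b), _EXP_CAP)
        out[pos] = 10.0 / (1.0 + np.exp(expo)) + 1.0
    return float(out) if np.ndim(S) == 0 else out


#: Deterministic multi-start grid (a0, b0) for the sigmoid fits.
_STARTS = tuple(product((0.3, 3.0), (0.5, 1.0, 2.0, 4.0)))


def fit_sigmoid(x, y, variant: str = "stimulus",
                starts=_STARTS) -> SigmoidMap:
    """Fit a sigmoid family to data by bounded multi-start NLS.

    Minimizes the sum of squared residuals over ``(a, b)`` with both
    parameters constrained positive, from ``len(starts)`` log-spaced
    deterministic starting points; the best converged fit is returned
    with its determination coefficient.

    Parameters
    ----------
    x, y : array-like
        Predictor (beta_n or stimulus level) and response; at least 3
        distinct x values.
    variant : {'stimulus', 'enrs'}

    Raises
    ------
    FitError
        Every start failed to converge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.unique(x).size < 3:
        raise FitError("need at least 3 distinct predictor values")

    def residuals(theta):
        m = SigmoidMap(a=theta[0], b=theta[1], variant=variant)
        return m(x) - y

    best = None
    failures = []
    for a0, b0 in starts:
        try:
            res = least_squares(residuals, x0=[a0, b0],
                                bounds=([1e-8, 1e-8], [np.inf, np.inf]),
                                xtol=1e-13, ftol=1e-13, gtol=1e-13,
                                max_nfev=2000)
        except Exception as exc:  # pragma: no cover - solver edge cases
            failures.append(f"start ({a0}, {b0}): {exc}")
            continue
        sse = float(2.0 * res.cost)
        # a start that ran out of evaluations may still hold the best
        # finite solution (flat likelihood in a); keep it
        if not np.isfinite(sse):
            failures.append(f"start ({a0}, {b0}): {res.message}")
            continue
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        raise FitError("sigmoid fit failed from every start: "
                       + "; ".join(failures))
    sse, res = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
    return SigmoidMap(a=float(res.x[0]), b=float(res.x[1]), variant=variant,
                      r2=r2, residuals=res.fun.copy(), n=x.size)


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line with diagnostics."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def fit_linear(x, y) -> LinearFit:
    """Fit a first-order linear model y = slope*x + intercept.

    Returns the OLS line, the coefficient of determination and its
    two-sided significance probability (F test; identical to the slope
    t test in simple regression).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct x values for a line")
    res = linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r2=float(res.rvalue) ** 2, p_value=float(res.pvalue),
                     n=x.size)


def mean_beta_n_by_level(series: StiffnessSeries, windows) -> "pd.DataFrame":
    """Aggregate mean beta_n per evaluation window and stimulus level.

    ``windows`` is a list of (start_s, end_s, level) — typically the
    stimulation windows of the protocol, where the stiffness response is
    expressed; beats outside every window are ignored.
    """
    import pandas as pd

    rows = []
    for i, (start, end, level) in enumerate(windows):
        sel = (series.times >= start) & (series.times < end)
        rows.append(dict(trial=i, level=level, n_beats=int(sel.sum()),
                         mean_beta_n=float(np.mean(series.beta_n[sel]))
                         if sel.any() else np.nan))
    return pd.DataFrame(rows)
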