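r"""Log-linearized peripheral arterial viscoelastic forward model.

The peripheral arterial wall is modelled as a second-order mechanical
element whose elastic restoring pressure grows exponentially with strain.
With the strain taken proportional to the photoplethysmogram
:math:`P_l(t)`, blood pressure is

.. math::

    P_b(t) = \mu \ddot P_l(t) + \eta \dot P_l(t)
             + \exp\{\beta P_l(t) + P_{b\beta_0} + P_{b\beta nl}(P_l(t))\},

where :math:`\mu` is the wall inertia (mmHg s\ :sup:`2` per PPG unit),
:math:`\eta` the viscosity (mmHg s per PPG unit) and :math:`\beta` the
stiffness index (per PPG unit).  :math:`P_{b\beta_0}` is a standard-
pressure offset in the exponent, and :math:`P_{b\beta nl}` a venous
pressure component.  The estimation procedure is valid when the venous
term is constant over the samples of one beat, so the simulator treats it
as a constant exponent offset ``p_bnl_const``.

:math:`\beta` rises with sympathetic vasoconstriction and is the
quantity of interest; the remaining parameters are nuisance mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SimulationError

#: Exponent cap; exp(700) is near the double-precision overflow limit.
EXP_CAP = 700.0


@dataclass
class ViscoelasticParams:
    """Parameters of the forward model; simulation ground truth and the
    target of estimation.

    Attributes
    ----------
    mu : float
        Inertia, mmHg s^2 per PPG unit.  >= 0.
    eta : float
        Viscosity, mmHg s per PPG unit.  >= 0.
    beta : float
        Stiffness index, per PPG unit.  > 0 for physiologic simulation.
    p_b0 : float
        Standard-pressure exponent offset (dimensionless exponent).
    p_bnl_const : float
        Constant stand-in for the venous exponent term.
    beta_A : float or None
        Linearized stiffness (mmHg per PPG unit), the step-1 quantity
        ``C1 * exp(p_b0 + p_bnl_const)``; with a constant venous term
        ``C1 == beta``.  Populated by the estimator, derived for truth.
    """

    mu: float
    eta: float
    beta: float
    p_b0: float
    p_bnl_const: float = 0.0
    beta_A: float | None = None

    def __post_init__(self) -> None:
        if self.mu < 0 or self.eta < 0:
            raise SimulationError(
                f"mu and eta must be non-negative, got mu={self.mu}, eta={self.eta}"
            )
        if not self.beta > 0:
            raise SimulationError(f"beta must be positive, got {self.beta}")
        if not np.isfinite(np.exp(min(self.p_b0 + self.p_bnl_const, EXP_CAP))):
            raise SimulationError("exponent offset does not yield a finite pressure")

    @property
    def exp_offset(self) -> float:
        """Total constant exponent offset p_b0 + p_bnl_const."""
        return self.p_b0 + self.p_bnl_const

    @property
    def baseline_pressure(self) -> float:
        """exp(p_b0 + p_bnl_const): elastic pressure at zero strain, mmHg."""
        return float(np.exp(self.exp_offset))

    def true_beta_A(self) -> float:
        """Linearized stiffness implied by the model at zero strain.

        With a constant venous term the Maclaurin slope of the elastic
        pressure at P_l = 0 is ``beta * exp(p_b0 + p_bnl_const)``.
        """
        return self.beta * self.baseline_pressure


def forward_bp(
    ppg: np.ndarray,
    d1: np.ndarray,
    d2: np.ndarray,
    params: ViscoelasticParams,
    exp_cap: float = EXP_CAP,
) -> np.ndarray:
    """Evaluate the forward model elementwise.

    Parameters
    ----------
    ppg, d1, d2 : ndarray
        Photoplethysmogram and its first/second time derivatives
        (PPG units, PPG units/s, PPG units/s^2), equal length.
    params : ViscoelasticParams

    Returns
    -------
    ndarray
        Blood pressure in mmHg.

    Raises
    ------
    SimulationError
        Mismatched lengths, or the exponent exceeds ``exp_cap``.
    """
    ppg = np.asarray(ppg, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if not (ppg.shape == d1.shape == d2.shape):
        raise SimulationError("ppg, d1 and d2 must have identical shapes")
    expo = params.beta * ppg + params.exp_offset
    if expo.size and np.max(expo) > exp_cap:
        raise SimulationError(
            f"elastic exponent {np.max(expo):.3g} exceeds cap {exp_cap:g}"
        )
    return params.mu * d2 + params.eta * d1 + np.exp(expo)


def stiffness_from_stimulus(
    S: float | np.ndarray,
    a: float,
    b: float,
    beta_rest: float,
) -> float | np.ndarray:
    """Stiffness at stimulus level ``S`` through the saturating coupling.

    The normalized stiffness target follows the bounded sigmoid

    .. math:: \\beta_n^{target}(S) = \\frac{10}{1 + \\exp(a S^{-b})} + 1,

    with the ``S = 0`` value defined by its limit, 1 (no stimulation
    leaves stiffness at rest).  As ``S`` grows the target saturates at 6.
    The returned stiffness is ``beta_rest * beta_n_target``.

    Parameters
    ----------
    S : float or ndarray
        Stimulus level in multiples of the standard amplitude, >= 0.
    a, b : float
        Sigmoid shape parameters, > 0.
    beta_rest : float
        Resting stiffness, per PPG unit, > 0.
    """
    if not (a > 0 and b > 0):
        raise ValueError(f"sigmoid shape parameters must be positive, got a={a}, b={b}")
    if not beta_rest > 0:
        raise ValueError(f"beta_rest must be positive, got {beta_rest}")
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValueError("stimulus level must be non-negative")
    target = np.ones_like(S_arr)
    pos = S_arr > 0
    with np.errstate(over="ignore"):
        expo = a * np.power(S_arr[pos], -b)
        target[pos] = 10.0 / (1.0 + np.exp(np.minimum(expo, EXP_CAP))) + 1.0
    out = beta_rest * target
    return float(out) if np.isscalar(S) or np.ndim(S) == 0 else out
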