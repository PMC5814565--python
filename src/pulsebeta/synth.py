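"""Synthetic record generator with known ground truth.

Generates ECG/BP/PPG records that exercise the whole analysis chain:

* PPG: a smooth, exactly periodic two-lobe pulse (systolic + dicrotic),
  one pulse per beat, with analytic first and second derivatives so the
  simulated blood pressure is an exact evaluation of the forward model.
* BP: the viscoelastic forward model applied to the clean PPG, plus
  i.i.d. Gaussian measurement noise.
* ECG: a triangular QRS template at each beat onset.
* Protocol: seven trials of 20 s rest + 24 s electrocutaneous
  stimulation + 20 s evaluation (448 s total), stimulus levels
  1.5/1.0/0.5/0/0.5/1.0/1.5 times a standard amplitude, with stiffness
  coupled to the level through a saturating sigmoid.

Every beat's true parameters are recorded in a ledger so estimates can
be scored by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import SimulationError
from .io import WaveformRecord
from .model import ViscoelasticParams, forward_bp, stiffness_from_stimulus

#: Default stimulus levels, strongest first to blunt anticipation effects.
DEFAULT_LEVELS = (1.5, 1.0, 0.5, 0.0, 0.5, 1.0, 1.5)


@dataclass(frozen=True)
class TrialSpec:
    """One trial: rest, continuous stimulation, then verbal evaluation."""

    rest_s: float = 20.0
    stim_s: float = 24.0
    eval_s: float = 20.0
    level: float = 0.0

    def __post_init__(self) -> None:
        if min(self.rest_s, self.stim_s, self.eval_s) < 0 or self.level < 0:
            raise SimulationError("trial durations and level must be non-negative")

    @property
    def duration(self) -> float:
        return self.rest_s + self.stim_s + self.eval_s


@dataclass(frozen=True)
class ProtocolSchedule:
    """Sequence of trials defining the stimulation protocol."""

    trials: tuple[TrialSpec, ...]

    @classmethod
    def default(cls) -> "ProtocolSchedule":
        return cls(trials=tuple(TrialSpec(level=s) for s in DEFAULT_LEVELS))

    @classmethod
    def constant(cls, level: float, duration_s: float) -> "ProtocolSchedule":
        """A single trial of pure stimulation — convenient for recovery
        studies at a fixed stiffness."""
        return cls(trials=(TrialSpec(rest_s=0.0, stim_s=duration_s,
                                     eval_s=0.0, level=level),))

    @property
    def total_duration(self) -> float:
        return sum(t.duration for t in self.trials)

    def stim_windows(self) -> list[tuple[float, float, float]]:
        """(start_s, end_s, level) of every stimulation interval."""
        out, t = [], 0.0
        for trial in self.trials:
            out.append((t + trial.rest_s, t + trial.rest_s + trial.stim_s,
                        trial.level))
            t += trial.duration
        return out

    def trial_windows(self) -> list[tuple[float, float, float]]:
        """(start_s, end_s, level) of every full trial."""
        out, t = [], 0.0
        for trial in self.trials:
            out.append((t, t + trial.duration, trial.level))
            t += trial.duration
        return out

    def level_at(self, t: float) -> float:
        """Stimulus level at time t (0 outside stimulation intervals)."""
        for start, end, level in self.stim_windows():
            if start <= t < end:
                return level
        return 0.0


@dataclass(frozen=True)
class PulseShape:
    """Shape of the one-beat PPG pulse in phase units (fraction of the
    heart period).  Two periodic von Mises-like lobes: the systolic
    upstroke and the dicrotic wave."""

    systolic_center: float = 0.30
    systolic_width: float = 0.07
    dicrotic_center: float = 0.62
    dicrotic_width: float = 0.12
    dicrotic_frac: float = 0.35

    def __post_init__(self) -> None:
        if self.systolic_width <= 0 or self.dicrotic_width <= 0:
            raise SimulationError("pulse lobe widths must be positive")
        for c in (self.systolic_center, self.dicrotic_center):
            if not 0.0 < c < 1.0:
                raise SimulationError("lobe centers must lie in (0, 1)")
        if self.dicrotic_frac < 0:
            raise SimulationError("dicrotic fraction must be non-negative")


class PPGPulse:
    """Exactly periodic one-beat PPG pulse with analytic derivatives.

    Each lobe is ``exp(kappa * (cos(2 pi (phi - c)) - 1))`` — a periodic
    bump that near its peak matches a Gaussian of width ``w`` in phase
    when ``kappa = 1 / (2 pi w)^2``.  The two-lobe sum is shifted and
    scaled so its minimum is exactly 0 and its maximum exactly
    ``amplitude``; periodicity makes the waveform C-infinity at beat
    junctions.
    """

    def __init__(self, period: float, amplitude: float = 1.0,
                 shape: PulseShape | None = None):
        if not 0.2 <= period <= 3.0:
            raise SimulationError(f"heart period {period} s outside plausible range")
        if amplitude <= 0:
            raise SimulationError("pulse amplitude must be positive")
        self.period = float(period)
        self.amplitude = float(amplitude)
        self.shape = shape or PulseShape()
        s = self.shape
        self._centers = np.array([s.systolic_center, s.dicrotic_center])
        self._kappas = 1.0 / (2.0 * np.pi * np.array(
            [s.systolic_width, s.dicrotic_width])) ** 2
        self._amps = np.array([1.0, s.dicrotic_frac])
        # locate the exact extrema of the raw two-lobe sum once
        grid = np.linspace(0.0, 1.0, 4096, endpoint=False)
        f = self._raw(grid)[0]
        self._peak_phase = self._refine(grid[np.argmax(f)], sign=-1.0)
        trough = self._refine(grid[np.argmin(f)], sign=+1.0)
        self._fmax = float(self._raw(np.array([self._peak_phase]))[0][0])
        self._fmin = float(self._raw(np.array([trough]))[0][0])
        if self._fmax - self._fmin <= 0:
            raise SimulationError("degenerate pulse shape: no dynamic range")
        self._scale = self.amplitude / (self._fmax - self._fmin)

    def _refine(self, phi0: float, sign: float) -> float:
        res = minimize_scalar(
            lambda p: sign * float(self._raw(np.array([p]))[0][0]),
            bounds=(phi0 - 0.01, phi0 + 0.01), method="bounded",
            options={"xatol": 1e-12})
        return float(res.x)

    @property
    def peak_phase(self) -> float:
        """Phase (fraction of the period) at which the pulse peaks."""
        return self._peak_phase % 1.0

    def _raw(self, phi: np.ndarray):
        """Un-normalized two-lobe sum and its phase derivatives."""
        f = np.zeros_like(phi, dtype=float)
        f1 = np.zeros_like(f)
        f2 = np.zeros_like(f)
        two_pi = 2.0 * np.pi
        for a, c, k in zip(self._amps, self._centers, self._kappas):
            th = two_pi * (phi - c)
            e = a * np.exp(k * (np.cos(th) - 1.0))
            f += e
            f1 += e * (-two_pi * k * np.sin(th))
            f2 += e * ((two_pi * k * np.sin(th)) ** 2
                       - two_pi ** 2 * k * np.cos(th))
        return f, f1, f2

    def evaluate(self, t: np.ndarray):
        """Pulse value and its first/second time derivatives at times t
        (seconds, periodic with the heart period)."""
        phi = np.asarray(t, dtype=float) / self.period
        f, f1, f2 = self._raw(phi)
        value = self._scale * (f - self._fmin)
        d1 = self._scale * f1 / self.period
        d2 = self._scale * f2 / self.period ** 2
        return value, d1, d2


class PulseBeat(NamedTuple):
    """Sampled one-beat pulse with analytic derivatives."""

    ppg: np.ndarray
    d1: np.ndarray
    d2: np.ndarray


def make_ppg_pulse(
    period: float,
    fs: float,
    amplitude: float = 1.0,
    shape: PulseShape | None = None,
) -> PulseBeat:
    """Sample one beat of the PPG pulse at rate ``fs``.

    Returns the waveform together with its analytic first and second
    time derivatives (PPG units/s and /s^2).
    """
    pulse = PPGPulse(period=period, amplitude=amplitude, shape=shape)
    n = int(round(period * fs))
    if n < 4:
        raise SimulationError("sampling rate too low for the heart period")
    t = np.arange(n) / fs
    return PulseBeat(*pulse.evaluate(t))


#: Generator defaults: the study conditions for synthetic records.
DEFAULT_PARAMS = dict(mu=0.02, eta=0.3, beta=0.5, p_b0=float(np.log(60.0)))
DEFAULT_COUPLING = dict(a=3.0, b=2.0)


def default_params() -> ViscoelasticParams:
    """Resting-state forward-model parameters used by the simulator.

    Chosen so term magnitudes are physiologic at unit PPG amplitude:
    elastic pressure swings from 60 mmHg at zero strain to ~99 mmHg at
    peak strain (beta = 0.5 per PPG unit), with viscous and inertial
    contributions of a few mmHg each.
    """
    return ViscoelasticParams(**DEFAULT_PARAMS)


def _qrs_template(fs: float, width_s: float = 0.02) -> np.ndarray:
    """Symmetric triangular QRS complex, apex amplitude 1."""
    half = max(1, int(round(width_s * fs / 2)))
    up = np.linspace(0.0, 1.0, half + 1)
    return np.concatenate([up, up[-2::-1]])


def synthesize_record(
    protocol: ProtocolSchedule | None = None,
    fs: float = 1000.0,
    heart_rate_bpm: float = 70.0,
    params: ViscoelasticParams | None = None,
    coupling_a: float = DEFAULT_COUPLING["a"],
    coupling_b: float = DEFAULT_COUPLING["b"],
    sigma_bp: float = 1.0,
    sigma_ppg: float = 0.0,
    ppg_amplitude: float = 1.0,
    ppg_attenuation: float = 0.0,
    shape: PulseShape | None = None,
    params_schedule: Sequence[ViscoelasticParams] | None = None,
    seed: int | None = None,
) -> tuple[WaveformRecord, pd.DataFrame]:
    """Generate a synthetic record under a stimulation protocol.

    Per beat, the stimulus level ``S`` at the beat onset sets the true
    stiffness ``beta = stiffness_from_stimulus(S, a, b, beta_rest)``;
    ``mu``, ``eta`` and the exponent offset stay at their resting values.
    Optionally the PPG amplitude is attenuated with stimulation
    (``ppg_attenuation`` in [0, 1): fractional amplitude loss at the
    strongest level), emulating vasoconstriction of the finger bed; off
    by default because a gain change rescales the strain unit in which
    ``beta`` is expressed.

    Parameters
    ----------
    params_schedule : sequence of ViscoelasticParams, optional
        Explicit per-beat ground truth overriding the protocol coupling;
        its length must equal the number of full beats.
    seed : int
        Seed for the measurement-noise generator; required whenever
        ``sigma_bp`` or ``sigma_ppg`` is nonzero.

    Returns
    -------
    (WaveformRecord, DataFrame)
        The record and a ground-truth ledger with one row per full beat:
        ``beat, t0_s, t0_sample, n_samples, S, mu, eta, beta,
        beta_n_target, amplitude``.
    """
    if protocol is None:
        protocol = ProtocolSchedule.default()
    if params is None:
        params = default_params()
    if not fs >= 250.0:
        raise SimulationError(f"fs must be at least 250 Hz, got {fs}")
    if (sigma_bp > 0 or sigma_ppg > 0) and seed is None:
        raise SimulationError("a seed is required when noise is enabled")
    if not 0.0 <= ppg_attenuation < 1.0:
        raise SimulationError("ppg_attenuation must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    period = 60.0 / heart_rate_bpm
    beat_len = int(round(period * fs))
    n_total = int(round(protocol.total_duration * fs))
    n_beats = n_total // beat_len
    if n_beats < 1:
        raise SimulationError("protocol shorter than one heart period")
    if params_schedule is not None and len(params_schedule) != n_beats:
        raise SimulationError(
            f"params_schedule has {len(params_schedule)} entries but the "
            f"protocol yields {n_beats} beats"
        )
    max_level = max((t.level for t in protocol.trials), default=0.0)

    time = np.arange(n_total) / fs
    ppg = np.zeros(n_total)
    d1 = np.zeros(n_total)
    d2 = np.zeros(n_total)
    bp = np.zeros(n_total)
    ecg = np.zeros(n_total)
    qrs = _qrs_template(fs)
    rows = []

    # iterate full beats plus a possible truncated tail beat
    n_iter = n_beats + (1 if n_total % beat_len else 0)
    for k in range(n_iter):
        start = k * beat_len
        end = min(start + beat_len, n_total)
        t0 = start / fs
        S = protocol.level_at(t0)
        if params_schedule is not None and k < n_beats:
            pk = params_schedule[k]
            beta_k = pk.beta
        else:
            beta_k = stiffness_from_stimulus(S, coupling_a, coupling_b,
                                             params.beta)
            pk = ViscoelasticParams(mu=params.mu, eta=params.eta,
                                    beta=beta_k, p_b0=params.p_b0,
                                    p_bnl_const=params.p_bnl_const)
        amp_k = ppg_amplitude
        if ppg_attenuation > 0 and max_level > 0:
            amp_k *= 1.0 - ppg_attenuation * min(S / max_level, 1.0)
        pulse = PPGPulse(period=period, amplitude=amp_k, shape=shape)
        tau = (np.arange(start, end) - start) / fs
        v, v1, v2 = pulse.evaluate(tau)
        ppg[start:end] = v
        d1[start:end] = v1
        d2[start:end] = v2
        bp[start:end] = forward_bp(v, v1, v2, pk)
        # QRS apex exactly at the beat-onset sample
        apex = len(qrs) // 2
        a = max(0, start - apex)
        b = min(n_total, start - apex + len(qrs))
        ecg[a:b] += qrs[a - (start - apex):b - (start - apex)]
        if k < n_beats:
            rows.append(dict(beat=k, t0_s=t0, t0_sample=start,
                             n_samples=end - start, S=S, mu=pk.mu,
                             eta=pk.eta, beta=beta_k,
                             beta_n_target=beta_k / params.beta,
                             amplitude=amp_k))

    if sigma_bp > 0:
        bp = bp + rng.normal(0.0, sigma_bp, size=n_total)
    if sigma_ppg > 0:
        ppg = ppg + rng.normal(0.0, sigma_ppg, size=n_total)

    record = WaveformRecord(
        time=time, ecg=ecg, bp=bp, ppg=ppg, fs=fs,
        meta=dict(kind="synthetic", heart_rate_bpm=heart_rate_bpm,
                  sigma_bp=sigma_bp, sigma_ppg=sigma_ppg, seed=seed),
    )
    ledger = pd.DataFrame(rows)
    return record, ledger
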