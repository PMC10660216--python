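"""Fixed-period sinusoidal regression and phase-lag estimation.

Seasonal temperature and community-composition cycles are summarized by
the model

    y(x) = A * sin(2*pi*(x + phi)/P) + C,        P fixed (12 months)

fitted by ordinary least squares after linearization:
``y = b1*sin(wx) + b2*cos(wx) + C`` with ``w = 2*pi/P`` is linear in
(b1, b2, C), so the fit is closed-form and deterministic; amplitude and
phase are recovered as ``A = hypot(b1, b2)`` and
``phi = atan2(b2, b1)/w`` normalized into [0, P). The phase lag between
two cycles of common period is the wrapped difference of their phases,
signed so that a positive lag means the first series peaks after the
second — e.g. a community composition cycle trailing the water
temperature it responds to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SineFit", "fit_sine", "phase_lag"]

# Amplitudes below this (relative to data scale) are treated as zero and
# the phase, then unidentifiable, is reported as 0 by convention.
_AMP_TOL = 1e-9


@dataclass(frozen=True)
class SineFit:
    """Canonical-form sinusoid: amplitude >= 0, phase in [0, period)."""

    amplitude: float
    phase: float
    offset: float
    period: float
    rss: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.amplitude * np.sin(2 * np.pi * (x + self.phase) / self.period) + self.offset


def fit_sine(x, y, period: float = 12.0) -> SineFit:
    """Least-squares fit of a fixed-period sinusoid to (x, y) samples.

    Closed form, no iteration, no seed. Requires at least 3 samples whose
    phases are not degenerate (design matrix of full rank 3). The
    (-A, phi + P/2) sign ambiguity is resolved by the canonical form
    amplitude >= 0, phase in [0, P).
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("at least 3 samples are required")
    w = 2 * np.pi / period
    design = np.column_stack([np.sin(w * x), np.cos(w * x), np.ones_like(x)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError(
            "underdetermined design: sample phases do not identify the sinusoid"
        )
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    b1, b2, offset = beta
    amplitude = math.hypot(b1, b2)
    scale = max(1.0, float(np.max(np.abs(y))))
    if amplitude <= _AMP_TOL * scale:
        amplitude, phase = 0.0, 0.0
    else:
        phase = math.atan2(b2, b1) / w % period
        if phase >= period:  # float modulo can land exactly on the period
            phase -= period
    fit = SineFit(amplitude=amplitude, phase=phase, offset=float(offset),
                  period=float(period), rss=0.0)
    rss = float(np.sum((y - fit.predict(x)) ** 2))
    return SineFit(amplitude=amplitude, phase=phase, offset=float(offset),
                   period=float(period), rss=rss)


def phase_lag(fit_a: SineFit, fit_b: SineFit) -> float:
    """Smallest-magnitude signed lag (in x units) between two fitted cycles.

    Returns lambda in (-P/2, P/2] such that cycle ``a`` peaks ``lambda``
    after cycle ``b``; positive = a lags b. Computed as phase_b - phase_a
    wrapped into (-P/2, P/2].
    """
    if fit_a.period != fit_b.period:
        raise ValueError(
            f"periods differ: {fit_a.period} vs {fit_b.period}; lag undefined"
        )
    period = fit_a.period
    lag = (fit_b.phase - fit_a.phase) % period
    if lag > period / 2:
        lag -= period
    return lag
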