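"""Analytic linear ballistic accumulator (LBA) race model.

Each response option accrues evidence linearly from a start point drawn
uniformly on [0, A] at a rate drawn once per trial from N(v_i, s). The
first accumulator to reach the threshold b = k + A determines the choice;
the observed response time is the winning finish time plus the
nondecision time t0. Response caution is b - A/2, the average evidence
that must be accrued before a response.

Densities are left unnormalized with respect to never-terminating races
(all drifts negative); the sampler conditions on termination by
resampling, a discrepancy bounded by prod_i Phi(-v_i / s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate
from scipy.special import ndtr

__all__ = [
    "LBAParams",
    "ChoiceData",
    "PointStartError",
    "accumulator_cdf",
    "accumulator_pdf",
    "point_start_cdf",
    "point_start_pdf",
    "defective_pdf",
    "defective_cdf",
    "choice_probability",
    "termination_probability",
    "sample_race",
    "caution",
]

_Z_CLIP = 38.0
_DENSITY_FLOOR = 1e-290
_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _npdf(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * np.square(z)) / _SQRT_2PI


def _clip(z: np.ndarray) -> np.ndarray:
    return np.clip(z, -_Z_CLIP, _Z_CLIP)


class PointStartError(ValueError):
    """Raised when the uniform-start formulas are evaluated at A = 0.

    Use :func:`point_start_cdf` / :func:`point_start_pdf` (the A -> 0
    limit) instead; :func:`defective_pdf` dispatches automatically.
    """


@dataclass(frozen=True)
class LBAParams:
    """One parameterization of the race.

    Parameters
    ----------
    v : sequence of float
        Mean drift rate per response option (evidence units / s).
    A : float
        Upper bound of the uniform start-point distribution.
    k : float
        Relative threshold; the threshold is ``b = k + A``.
    t0 : float
        Nondecision time in seconds.
    s : float
        Between-trial drift SD, fixed to 1 by convention.
    """

    v: tuple[float, ...]
    A: float
    k: float
    t0: float
    s: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "v", tuple(float(x) for x in self.v))
        if len(self.v) < 2:
            raise ValueError("need at least 2 response options")
        if self.A < 0:
            raise ValueError("A must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if self.s <= 0:
            raise ValueError("s must be > 0")

    @property
    def b(self) -> float:
        return self.k + self.A

    @property
    def caution(self) -> float:
        return self.b - self.A / 2.0

    @property
    def n_options(self) -> int:
        return len(self.v)


@dataclass
class ChoiceData:
    """Observed (choice, RT) pairs with optional condition labels."""

    choices: np.ndarray
    rts: np.ndarray
    subject: str | None = None
    zone: str | None = None

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=int)
        self.rts = np.asarray(self.rts, dtype=float)
        if self.choices.shape != self.rts.shape:
            raise ValueError("choices and rts must be the same length")
        if np.any(self.rts <= 0):
            raise ValueError("all rts must be > 0")

    def __len__(self) -> int:
        return self.choices.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "choice": self.choices,
                "rt_s": self.rts,
                "subject": self.subject,
                "zone": self.zone,
            }
        )


def _cdf_terms(t: np.ndarray, v: float, params: LBAParams):
    b, A, s = params.b, params.A, params.s
    ts = t * s
    u = _clip((b - A - t * v) / ts)
    w = _clip((b - t * v) / ts)
    return b, A, s, ts, u, w


def accumulator_cdf(t, i: int, params: LBAParams):
    """P(accumulator i has reached threshold by decision time t), A > 0."""
    if params.A == 0:
        raise PointStartError("A = 0: use point_start_cdf (A -> 0 limit)")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    if scalar:
        t = t[None]
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    v = params.v[i]
    b, A, s, ts, u, w = _cdf_terms(tp, v, params)
    F = (
        1.0
        + ((b - A - tp * v) / A) * ndtr(u)
        - ((b - tp * v) / A) * ndtr(w)
        + (ts / A) * (_npdf(u) - _npdf(w))
    )
    out[pos] = np.clip(F, 0.0, 1.0)
    return float(out[0]) if scalar else out


def accumulator_pdf(t, i: int, params: LBAParams):
    """First-passage density of accumulator i at decision time t, A > 0."""
    if params.A == 0:
        raise PointStartError("A = 0: use point_start_pdf (A -> 0 limit)")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    if scalar:
        t = t[None]
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    v = params.v[i]
    b, A, s, ts, u, w = _cdf_terms(tp, v, params)
    f = (1.0 / A) * (-v * ndtr(u) + s * _npdf(u) + v * ndtr(w) - s * _npdf(w))
    out[pos] = np.maximum(f, 0.0)
    return float(out[0]) if scalar else out


def point_start_cdf(t, i: int, params: LBAParams):
    """A -> 0 limit: all accumulators start at 0 evidence."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    if scalar:
        t = t[None]
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    v, b, s = params.v[i], params.b, params.s
    out[pos] = ndtr(_clip((tp * v - b) / (tp * s)))
    return float(out[0]) if scalar else out


def point_start_pdf(t, i: int, params: LBAParams):
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    if scalar:
        t = t[None]
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    v, b, s = params.v[i], params.b, params.s
    out[pos] = (b / (s * tp**2)) * _npdf(_clip((b / tp - v) / s))
    return float(out[0]) if scalar else out


def _cdf(t, i, params):
    if params.A == 0:
        return point_start_cdf(t, i, params)
    return accumulator_cdf(t, i, params)


def _pdf(t, i, params):
    if params.A == 0:
        return point_start_pdf(t, i, params)
    return accumulator_pdf(t, i, params)


def defective_pdf(rt, choice: int, params: LBAParams):
    """Density of observing (rt, choice): winner density times losers' survival.

    Zero for rt <= t0. Integrates over rt to the probability of that
    choice, not to 1.
    """
    rt = np.asarray(rt, dtype=float)
    scalar = rt.ndim == 0
    if scalar:
        rt = rt[None]
    dt = rt - params.t0
    out = np.zeros_like(rt)
    pos = dt > 0
    d = dt[pos]
    dens = _pdf(d, choice, params)
    for j in range(params.n_options):
        if j != choice:
            dens = dens * (1.0 - _cdf(d, j, params))
    out[pos] = np.maximum(dens, 0.0)
    return float(out[0]) if scalar else out


def defective_cdf(rt, choice: int, params: LBAParams, **quad_kw):
    """Integral of the defective density from t0 to rt (quadrature)."""
    rt = np.atleast_1d(np.asarray(rt, dtype=float))
    out = np.empty_like(rt)
    for n, r in enumerate(rt):
        if r <= params.t0:
            out[n] = 0.0
        else:
            val, _ = integrate.quad(
                lambda u: defective_pdf(u, choice, params),
                params.t0,
                r,
                limit=200,
                **quad_kw,
            )
            out[n] = val
    return out if out.size > 1 else float(out[0])


def termination_probability(params: LBAParams) -> float:
    """P(at least one accumulator has positive drift) = 1 - prod Phi(-v_i/s)."""
    p_none = np.prod([ndtr(-v / params.s) for v in params.v])
    return float(1.0 - p_none)


def choice_probability(choice: int, params: LBAParams, epsabs: float = 1e-10) -> float:
    """P(response = choice), by adaptive quadrature over the defective density."""
    val, err = integrate.quad(
        lambda u: defective_pdf(u + params.t0, choice, params),
        0.0,
        np.inf,
        limit=400,
        epsabs=epsabs,
    )
    if not np.isfinite(val) or err > max(1e-6, 1e-4 * max(val, 1e-12)):
        raise RuntimeError(
            f"quadrature did not converge: value={val}, abserr={err}"
        )
    return float(min(max(val, 0.0), 1.0))


def sample_race(
    params: LBAParams,
    n: int,
    rng: np.random.Generator | int | None = None,
    subject: str | None = None,
    zone: str | None = None,
) -> ChoiceData:
    """Draw n (choice, rt) pairs, conditioning on race termination.

    Trials on which no accumulator has positive drift are resampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    m = params.n_options
    v = np.asarray(params.v)
    choices = np.empty(n, dtype=int)
    rts = np.empty(n, dtype=float)
    todo = np.arange(n)
    while todo.size:
        nt = todo.size
        starts = rng.uniform(0.0, params.A, size=(nt, m)) if params.A > 0 else np.zeros((nt, m))
        drifts = rng.normal(v, params.s, size=(nt, m))
        with np.errstate(divide="ignore"):
            finish = np.where(drifts > 0, (params.b - starts) / drifts, np.inf)
        winner = np.argmin(finish, axis=1)
        tmin = finish[np.arange(nt), winner]
        ok = np.isfinite(tmin)
        idx = todo[ok]
        choices[idx] = winner[ok]
        rts[idx] = tmin[ok] + params.t0
        todo = todo[~ok]
    return ChoiceData(choices=choices, rts=rts, subject=subject, zone=zone)


def caution(params: LBAParams) -> float:
    """Response caution, b - A/2."""
    return params.caution
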