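"""Event-related skin-conductance modelling and decomposition.

The phasic skin-conductance response (SCR) is described by the four-parameter
sigmoid-exponential waveform of Lim et al. (1997),

    f(t) = g * exp(-(t - T_os)/t_d) / (1 + exp(-(t - T_os)/t_r)),

where ``g`` is the gain (amplitude scale, uS), ``T_os`` the onset latency
after the stimulus (s), ``t_r`` the rise time governing the rising slope (s)
and ``t_d`` the exponential decay time constant (s).  A typical event-related
segment additionally rides on the decaying limb of the previous response and
a tonic level, giving the six-parameter model

    y(t) = f(t) + a0 * exp(-t/t_d) + c,

with ``a0`` the previous-response amplitude at stimulus onset and ``c`` the
tonic skin-conductance level (SCL).  Parameters are extracted from averaged
post-stimulus segments by damped (Marquardt-Levenberg) nonlinear least
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import (
    EmptyInputError,
    IncompatibleTracesError,
    InvalidParameterError,
    UnderdeterminedFitError,
)

__all__ = [
    "SCRParams",
    "SCParams",
    "SCTrace",
    "FitResult",
    "scr_waveform",
    "sc_waveform",
    "average_segments",
    "initial_guess",
    "fit_sc_segment",
]

#: floor used when a heuristic guess would violate a strict-positivity bound
_POSITIVE_FLOOR = 1e-6


@dataclass(frozen=True)
class SCRParams:
    """Four-parameter pure SCR: gain, onset time, rise time, decay constant."""

    g: float
    T_os: float
    t_r: float
    t_d: float

    def __post_init__(self) -> None:
        vals = (self.g, self.T_os, self.t_r, self.t_d)
        if not all(np.isfinite(vals)):
            raise InvalidParameterError(f"non-finite SCR parameter in {vals}")
        if self.g < 0 or self.T_os < 0:
            raise InvalidParameterError("g and T_os must be non-negative")
        if self.t_r <= 0 or self.t_d <= 0:
            raise InvalidParameterError("t_r and t_d must be strictly positive")


@dataclass(frozen=True)
class SCParams:
    """Six-parameter event-related SC model: SCR + previous-response tail + SCL."""

    scr: SCRParams
    a0: float
    c: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a0) and np.isfinite(self.c)):
            raise InvalidParameterError("non-finite a0 or c")
        if self.a0 < 0 or self.c < 0:
            raise InvalidParameterError("a0 and c must be non-negative")

    def as_array(self) -> np.ndarray:
        s = self.scr
        return np.array([s.g, s.T_os, s.t_r, s.t_d, self.a0, self.c])

    @classmethod
    def from_array(cls, arr) -> "SCParams":
        g, T_os, t_r, t_d, a0, c = (float(v) for v in arr)
        return cls(scr=SCRParams(g, T_os, t_r, t_d), a0=a0, c=c)


@dataclass(frozen=True)
class SCTrace:
    """Uniformly sampled conductance segment starting at stimulus onset."""

    times: np.ndarray
    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise IncompatibleTracesError("times and values must be equal-length 1-D arrays")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise IncompatibleTracesError("times must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > 1e-9 * max(abs(dt[0]), 1.0)):
                raise IncompatibleTracesError("times must be uniformly spaced")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_values(cls, values, sampling_rate: float, t0: float = 0.0) -> "SCTrace":
        values = np.asarray(values, dtype=float)
        times = t0 + np.arange(len(values)) / float(sampling_rate)
        return cls(times=times, values=values, sampling_rate=float(sampling_rate))


@dataclass(frozen=True)
class FitResult:
    """Outcome of one Marquardt-Levenberg segment fit."""

    params: SCParams
    sse: float
    iterations: int
    converged: bool


def scr_waveform(params: SCRParams, times) -> np.ndarray:
    """Evaluate the pure four-parameter SCR waveform at ``times`` (seconds).

    Computed in log space so the sigmoid denominator never overflows for
    times far before the onset.
    """
    if not isinstance(params, SCRParams):
        params = SCRParams(*params)
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidParameterError("times must be finite")
    tau = t - params.T_os
    # log f = log g - tau/t_d - log(1 + exp(-tau/t_r)); clamped so extreme
    # (t_d << t_r) trial parameters during fitting yield large finite values
    log_shape = -tau / params.t_d - np.logaddexp(0.0, -tau / params.t_r)
    return params.g * np.exp(np.minimum(log_shape, 700.0))


def sc_waveform(params: SCParams, times) -> np.ndarray:
    """Evaluate the six-parameter SC model: SCR + a0-tail + tonic level.

    The previous-response tail decays with the same time constant ``t_d`` as
    the SCR, keeping the model at six free parameters.
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidParameterError("times must be finite")
    tail = params.a0 * np.exp(-t / params.scr.t_d)
    return scr_waveform(params.scr, t) + tail + params.c


def average_segments(traces: list[SCTrace]) -> SCTrace:
    """Pointwise mean of equally sampled segments (across-subject averaging)."""
    if len(traces) == 0:
        raise EmptyInputError("cannot average an empty list of traces")
    first = traces[0]
    for tr in traces[1:]:
        if len(tr) != len(first):
            raise IncompatibleTracesError(
                f"trace lengths differ: {len(tr)} vs {len(first)}"
            )
        if abs(tr.sampling_rate - first.sampling_rate) > 1e-9 * first.sampling_rate:
            raise IncompatibleTracesError("sampling rates differ")
    mean_values = np.mean([tr.values for tr in traces], axis=0)
    return SCTrace(times=first.times.copy(), values=mean_values,
                   sampling_rate=first.sampling_rate)


def initial_guess(trace: SCTrace) -> SCParams:
    """Heuristic six-parameter starting point for the iterative fit.

    The base heuristics are: c the segment minimum, a0 the onset value
    above c, g the tail-corrected range, T_os the time of steepest
    (tail-corrected) rise, with generic t_r = 0.5 s and t_d = 3 s.  Because
    the sigmoid-exponential SCR carries substantial pre-onset mass and can
    ride on a previous-response limb steep enough to keep the raw trace
    monotone, those heuristics alone can fall outside the fit's basin of
    attraction; the guess is therefore refined over a small grid of
    (T_os, t_r, t_d) candidates, solving the amplitudes (g, a0, c) — in
    which the model is linear — by least squares at each node and keeping
    the lowest-SSE candidate.  Never fails: degenerate (flat, single-point)
    traces get safe defaults.
    """
    if len(trace) == 0:
        raise EmptyInputError("cannot guess parameters from an empty trace")
    t, v = trace.times, trace.values
    c = float(np.min(v))
    a0 = max(float(v[0] - c), 0.0)
    t_d0 = 3.0
    resid = v - a0 * np.exp(-t / t_d0) - c
    g = max(float(np.max(resid) - np.min(resid)), 0.0)
    if len(trace) > 1:
        T_slope = max(float(t[int(np.argmax(np.diff(resid)))]), 0.0)
    else:
        T_slope = 0.0
    base = SCParams(scr=SCRParams(g=g, T_os=T_slope, t_r=0.5, t_d=t_d0),
                    a0=a0, c=c)
    if len(trace) < 7:
        return base

    duration = float(t[-1] - t[0])
    tos_cands = sorted({T_slope} | {x for x in (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)
                                    if x <= duration})
    best, best_sse = base, np.inf
    for T_os in tos_cands:
        for t_r in (0.3, 0.7):
            for t_d in (1.5, 3.0, 6.0):
                shape = scr_waveform(SCRParams(1.0, T_os, t_r, t_d), t)
                B = np.column_stack([shape, np.exp(-t / t_d), np.ones_like(t)])
                amp, *_ = np.linalg.lstsq(B, v, rcond=None)
                amp = np.clip(amp, 0.0, None)
                sse = float(np.sum((B @ amp - v) ** 2))
                if sse < best_sse:
                    best_sse = sse
                    best = SCParams(
                        scr=SCRParams(g=float(amp[0]), T_os=T_os,
                                      t_r=t_r, t_d=t_d),
                        a0=float(amp[1]), c=float(amp[2]))
    return best


# --- Marquardt-Levenberg fitting -------------------------------------------
#
# Internal coordinates: t_r and t_d are optimized as logs (strict positivity);
# g, T_os, a0, c are optimized raw and clipped at zero when decoded.

_LOG_IDX = (2, 3)   # t_r, t_d within the 6-vector
_CLIP_IDX = (0, 1, 4, 5)


def _encode(params: SCParams) -> np.ndarray:
    z = params.as_array()
    z[list(_LOG_IDX)] = np.log(z[list(_LOG_IDX)])
    return z


def _decode(z: np.ndarray) -> SCParams:
    p = z.copy()
    p[list(_LOG_IDX)] = np.clip(np.exp(p[list(_LOG_IDX)]),
                                _POSITIVE_FLOOR, 1e12)
    p[list(_CLIP_IDX)] = np.clip(p[list(_CLIP_IDX)], 0.0, None)
    return SCParams.from_array(p)


def _residuals(z: np.ndarray, trace: SCTrace) -> np.ndarray:
    return sc_waveform(_decode(z), trace.times) - trace.values


def _jacobian(z: np.ndarray, trace: SCTrace, r0: np.ndarray) -> np.ndarray:
    J = np.empty((len(trace), len(z)))
    for j in range(len(z)):
        h = 1e-6 * (1.0 + abs(z[j]))
        zj = z.copy()
        zj[j] += h
        J[:, j] = (_residuals(zj, trace) - r0) / h
    return J


def fit_sc_segment(
    trace: SCTrace,
    init: SCParams | None = None,
    max_iterations: int = 20,
    tol: float = 1e-8,
) -> FitResult:
    """Fit the six-parameter SC model to a segment by Marquardt-Levenberg.

    Parameters
    ----------
    trace
        Post-stimulus segment; must have at least 7 samples (more points
        than the six parameters).
    init
        Starting parameters; defaults to :func:`initial_guess`.
    max_iterations
        Cap on accepted damped-Newton steps (the classical setting for this
        pipeline is 20).
    tol
        Relative SSE decrease below which the fit is declared converged.

    Returns
    -------
    FitResult
        Final parameters, residual sum of squares, number of accepted
        iterations and the convergence flag.  The returned SSE is never
        larger than the SSE at ``init`` (monotone acceptance).
    """
    if len(trace) < 7:
        raise UnderdeterminedFitError(
            f"need at least 7 samples to fit 6 parameters, got {len(trace)}"
        )
    if max_iterations < 1:
        raise InvalidParameterError("max_iterations must be >= 1")
    if init is None:
        init = initial_guess(trace)
    # strict-positivity floor so the log-transform is defined
    scr = init.scr
    if scr.t_r < _POSITIVE_FLOOR or scr.t_d < _POSITIVE_FLOOR:
        scr = replace(scr, t_r=max(scr.t_r, _POSITIVE_FLOOR),
                      t_d=max(scr.t_d, _POSITIVE_FLOOR))
        init = replace(init, scr=scr)

    z = _encode(init)
    r = _residuals(z, trace)
    sse = float(r @ r)
    lam = 1e-3
    iterations = 0
    converged = False

    for _ in range(max_iterations):
        J = _jacobian(z, trace, r)
        JtJ = J.T @ J
        g_vec = J.T @ r
        diag = np.diag(JtJ).copy()
        diag[diag < 1e-12] = 1e-12
        accepted = False
        for _inner in range(50):
            try:
                dz = np.linalg.solve(JtJ + lam * np.diag(diag), -g_vec)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            z_new = z + dz
            r_new = _residuals(z_new, trace)
            sse_new = float(r_new @ r_new)
            if sse_new <= sse:
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            # no downhill step found: stationary to working precision
            converged = True
            break
        iterations += 1
        rel_drop = (sse - sse_new) / max(sse, 1e-300)
        z, r, sse = z_new, r_new, sse_new
        lam = max(lam / 10.0, 1e-12)
        if rel_drop < tol:
            converged = True
            break

    return FitResult(params=_decode(z), sse=sse, iterations=iterations,
                     converged=converged)
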