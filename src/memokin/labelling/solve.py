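"""Forward solution of the BrdU x Ki67 model under a feeding protocol.

The state dynamics are linear with piecewise-constant coefficients: rates of
division, death and Ki67 stage advance never change, but the *outcome* of a
division (daughter BrdU class) depends on whether label is being fed, and
the BrdU class of source arrivals switches from labelled to unlabelled a
delay ``tau`` after feeding ends.  Each phase is therefore an affine system
``dx/dt = A x + s`` which is propagated exactly with the matrix exponential
of the augmented matrix ``[[A, s], [0, 0]]``.  A conventional stiff
integrator (``method="ivp"``) is kept as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from ..exceptions import MemokinError
from .spec import KineticModelSpec, StateSpace, resolve_steady_state

__all__ = ["LabellingProtocol", "LabellingPrediction", "solve_labelling"]


@dataclass(frozen=True)
class LabellingProtocol:
    """A pulse-chase design: ``feed_days`` of label, samples at
    ``sample_times`` (days since the start of feeding)."""

    feed_days: float
    sample_times: tuple

    def __post_init__(self) -> None:
        if self.feed_days <= 0:
            raise ValueError("feed_days must be positive")
        times = np.asarray(self.sample_times, dtype=float)
        if times.size and times.min() < 0:
            raise ValueError("sample times must be nonnegative")
        object.__setattr__(self, "sample_times", tuple(np.sort(times)))


@dataclass
class LabellingPrediction:
    """Predicted labelled fractions over a protocol."""

    times: np.ndarray
    frac_brdu_in_ki67high: np.ndarray
    frac_brdu_in_ki67low: np.ndarray
    kappa_model: np.ndarray
    states: np.ndarray  # (n_times, n_states) occupancy


def _transition_matrix(space: StateSpace, feeding: bool) -> np.ndarray:
    spec = space.spec
    n = space.n_states
    u = spec.khat * spec.beta
    A = np.zeros((n, n))
    for p, sp in enumerate(space.subpops):
        for g in range(spec.khat + 1):
            death = sp.delta_lo if g == 0 else sp.delta_hi
            adv = u if g >= 1 else 0.0
            for d in range(spec.bhat + 1):
                i = space.index(p, g, d)
                A[i, i] -= sp.alpha + death + adv
                if 1 <= g < spec.khat:
                    A[space.index(p, g + 1, d), i] += u
                elif g == spec.khat:
                    A[space.index(p, 0, d), i] += u
                diluted = space.index(p, 1, space.dilute(d))
                if feeding:
                    A[space.index(p, 1, 1), i] += 2.0 * sp.alpha * spec.epsilon
                    A[diluted, i] += 2.0 * sp.alpha * (1.0 - spec.epsilon)
                else:
                    A[diluted, i] += 2.0 * sp.alpha
    return A


def _source_vector(space: StateSpace, labelled: bool) -> np.ndarray:
    s = np.zeros(space.n_states)
    for p, sp in enumerate(space.subpops):
        s[space.index(p, 1, 1 if labelled else 0)] = sp.S_p
    return s


def _phases(space: StateSpace, protocol: LabellingProtocol):
    spec = space.spec
    F = float(protocol.feed_days)
    A_feed = _transition_matrix(space, feeding=True)
    A_chase = _transition_matrix(space, feeding=False)
    s_lab = _source_vector(space, labelled=True)
    s_unl = _source_vector(space, labelled=False)
    phases = [(0.0, F, A_feed, s_lab)]
    if spec.tau > 0:
        phases.append((F, F + spec.tau, A_chase, s_lab))
    phases.append((F + spec.tau, np.inf, A_chase, s_unl))
    return phases


def _propagate_expm(space, protocol, times):
    n = space.n_states
    x = space.equilibrium()
    out = np.empty((times.size, n))
    t_now = 0.0
    k = 0
    for start, end, A, s in _phases(space, protocol):
        aug = np.zeros((n + 1, n + 1))
        aug[:n, :n] = A
        aug[:n, n] = s
        stop = min(end, times[-1] if times.size else 0.0)
        # emit samples inside this phase, then advance to the phase boundary
        while k < times.size and times[k] <= stop + 1e-12:
            dt = times[k] - t_now
            if dt > 0:
                v = expm(aug * dt) @ np.append(x, 1.0)
                x = v[:n]
                t_now = times[k]
            out[k] = x
            k += 1
        if k >= times.size:
            break
        if np.isfinite(end) and end > t_now:
            v = expm(aug * (end - t_now)) @ np.append(x, 1.0)
            x = v[:n]
            t_now = end
    return out


def _propagate_ivp(space, protocol, times, rtol, atol):
    n = space.n_states
    x = space.equilibrium()
    out = np.empty((times.size, n))
    t_now = 0.0
    k = 0
    for start, end, A, s in _phases(space, protocol):
        stop = min(end, times[-1]) if times.size else 0.0
        t_eval = [t for t in times[k:] if t <= stop + 1e-12]
        t_stop = max(stop, t_now)
        if t_stop > t_now:
            sol = solve_ivp(
                lambda t, y: A @ y + s,
                (t_now, t_stop),
                x,
                method="BDF",
                jac=lambda t, y: A,
                t_eval=sorted(set(t_eval) | {t_stop}),
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise MemokinError(f"stiff integration failed: {sol.message}")
            for t in t_eval:
                out[k] = sol.y[:, list(sol.t).index(t)]
                k += 1
            x = sol.y[:, -1]
            t_now = t_stop
        else:
            while k < times.size and times[k] <= t_now + 1e-12:
                out[k] = x
                k += 1
        if k >= times.size:
            break
    return out


def solve_labelling(
    model: KineticModelSpec | StateSpace,
    protocol: LabellingProtocol,
    method: str = "expm",
    rtol: float = 1e-8,
) -> LabellingPrediction:
    """Predict BrdU+ fractions within the Ki67-high and Ki67-low gates.

    ``model`` may be an unresolved :class:`KineticModelSpec` (resolved here)
    or an already-resolved :class:`StateSpace`.  The initial condition is
    the unlabelled equilibrium, so both fractions are exactly zero at t=0.
    """
    space = model if isinstance(model, StateSpace) else resolve_steady_state(model)
    times = np.asarray(protocol.sample_times, dtype=float)
    if method == "expm":
        states = _propagate_expm(space, protocol, times)
    elif method == "ivp":
        atol = 1e-10 * space.spec.N
        states = _propagate_ivp(space, protocol, times, rtol, atol)
    else:
        raise ValueError("method must be 'expm' or 'ivp'")

    floor = -1e-9 * space.spec.N
    if states.min() < floor * 10:
        raise MemokinError(
            f"negative occupancy {states.min():.3e} beyond solver tolerance"
        )
    states = np.clip(states, 0.0, None)
    hi = space.ki67_high_mask()
    pos = space.brdu_pos_mask()
    H = states[:, hi].sum(axis=1)
    L = states[:, ~hi].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_hi = np.where(H > 0, states[:, hi & pos].sum(axis=1) / H, 0.0)
        frac_lo = np.where(L > 0, states[:, ~hi & pos].sum(axis=1) / L, 0.0)
    return LabellingPrediction(
        times=times,
        frac_brdu_in_ki67high=frac_hi,
        frac_brdu_in_ki67low=frac_lo,
        kappa_model=H / (H + L),
        states=states,
    )
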