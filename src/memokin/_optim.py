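"""Shared optimisation helpers: Latin-hypercube multistarts around bounded
trust-region least squares."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .exceptions import ConvergenceError

__all__ = ["latin_hypercube_starts", "multistart_least_squares"]


def latin_hypercube_starts(
    lo: Sequence[float],
    hi: Sequence[float],
    n_starts: int,
    seed: int | None,
) -> np.ndarray:
    """Draw ``n_starts`` points from a Latin hypercube over the box [lo, hi]."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    sampler = qmc.LatinHypercube(d=lo.size, seed=seed)
    unit = sampler.random(n=n_starts)
    return lo + unit * (hi - lo)


def multistart_least_squares(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    bounds: tuple[Sequence[float], Sequence[float]],
    n_starts: int,
    seed: int | None,
    x0: np.ndarray | None = None,
    rss_tol: float | None = None,
    **ls_kwargs,
):
    """Run bounded trust-region least squares from multiple starting points.

    Parameters
    ----------
    residual_fn
        Vector residual function.
    bounds
        ``(lo, hi)`` box constraints.
    n_starts
        Number of Latin-hypercube starting points (in addition to ``x0``).
    x0
        Optional extra starting point tried first (warm start).
    rss_tol
        If given, stop multistarting as soon as a solution with
        ``RSS < rss_tol`` is found (useful on noiseless data where the
        optimum is a near-perfect fit).

    Returns
    -------
    The best :class:`scipy.optimize.OptimizeResult`.

    Raises
    ------
    ConvergenceError
        If no start converges.
    """
    lo, hi = bounds
    starts = []
    if x0 is not None:
        starts.append(np.clip(np.asarray(x0, dtype=float), lo, hi))
    if n_starts > 0:
        starts.extend(latin_hypercube_starts(lo, hi, n_starts, seed))
    best = None
    failures: list[str] = []
    for start in starts:
        try:
            res = least_squares(
                residual_fn, start, bounds=(lo, hi), method="trf", **ls_kwargs
            )
        except Exception as exc:  # noqa: BLE001 - collected into the trace
            failures.append(f"start {start}: {exc!r}")
            continue
        if not np.isfinite(res.cost):
            failures.append(f"start {start}: non-finite cost")
            continue
        if best is None or res.cost < best.cost:
            best = res
        if rss_tol is not None and 2.0 * best.cost < rss_tol:
            break
    if best is None:
        raise ConvergenceError(
            "no multistart converged; trace:\n" + "\n".join(failures)
        )
    return best
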