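"""Replacement kinetics of memory subsets in busulfan chimeras.

The memory pool ``M`` (host + donor + incumbent) receives cells from a
source population ``S(t)`` at per-source-cell rate ``gamma(t) = gamma0 *
exp(-phi t)`` and loses displaceable cells at net rate ``lam`` (which may be
negative, i.e. net growth).  An incumbent population ``M_inc`` is resistant
to displacement and self-renewing.  With normalised chimerism ``rho_M``
(donor fraction relative to DP1 thymocytes) the dynamics are

    dM/dt     = gamma(t) S(t) - lam (M - M_inc)
    drho_M/dt = gamma(t) S(t) / M * (rho_S(t) - rho_M) - lam M_inc / M * rho_M

Two sub-models explain the observed capping of memory chimerism:
"resistant" (``phi = 0``, ``M_inc`` free) and "declining" recruitment
(``M_inc = 0``, ``phi`` free); "combined" frees both.

The fraction of the pool replaced by immigrants over a horizon ``t`` has the
closed form (with ``psi = R + phi - lam``)

    f_replace(t) = Y(t) / (X(t) + Y(t) + M_inc),
    Y(t) = gamma0 S0 exp(-lam t) (1 - exp(-psi t)) / psi,
    X(t) = (M0 - M_inc) exp(-lam t),

which this module evaluates with a series branch at ``psi ~ 0`` and verifies
against direct integration of ``dY/dt = gamma(t) S(t) - lam Y``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._optim import multistart_least_squares
from .exceptions import ModelDomainError, SchemaError
from .source import (
    SourceDescriptor,
    SourceResults,
    T_REF_DEFAULT,
    eval_source_chimerism,
    eval_source_size,
    validate_timecourse,
)

__all__ = [
    "ChimeraModelSpec",
    "ReplacementSummary",
    "simulate_chimera",
    "replacement_fraction",
    "quick_influx_estimate",
    "ChimeraReplacementModel",
    "ChimeraResults",
    "compare_chimera_models",
    "project_replacement_with_age",
]

VARIANTS = ("resistant", "declining", "combined")


@dataclass
class ChimeraModelSpec:
    """Influx/loss/incumbent/decline parameters of the replacement model.

    ``variant`` fixes which extension is active: ``"resistant"`` forces
    ``phi = 0``; ``"declining"`` forces ``M_inc = 0``; ``"combined"`` frees
    both.
    """

    gamma0: float
    lam: float
    M_inc: float = 0.0
    phi: float = 0.0
    variant: str = "combined"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.gamma0 < 0 or self.M_inc < 0 or self.phi < 0:
            raise ValueError("gamma0, M_inc and phi must be nonnegative")
        if self.variant == "resistant" and self.phi != 0.0:
            raise ValueError("resistant variant requires phi = 0")
        if self.variant == "declining" and self.M_inc != 0.0:
            raise ValueError("declining variant requires M_inc = 0")

    def gamma(self, t):
        return self.gamma0 * np.exp(-self.phi * np.asarray(t, dtype=float))


def simulate_chimera(
    spec: ChimeraModelSpec,
    source: SourceDescriptor,
    M0: float,
    rho_M0: float,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float | None = None,
) -> pd.DataFrame:
    """Integrate the coupled (M, rho_M) system over ``t_grid`` (days since
    the descriptor clock origin).

    Returns a DataFrame with columns ``t, M, rho_M``.  Aborts with
    :class:`ModelDomainError` if the pool falls to the incumbent size, where
    the chimerism equation degenerates.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array")
    if M0 <= spec.M_inc:
        raise ModelDomainError("M0 must exceed the incumbent pool size")

    def rhs(t, y):
        M, rho = y
        influx = spec.gamma(t) * eval_source_size(source, t)
        dM = influx - spec.lam * (M - spec.M_inc)
        drho = influx / M * (eval_source_chimerism(source, t) - rho) \
            - spec.lam * spec.M_inc / M * rho
        return [dM, drho]

    # The valid region is M >= M_inc (nonnegative displaceable pool); an
    # asymptotic approach to M_inc from above is legitimate, so only abort
    # once M undershoots it by a numerically meaningful margin.
    def hit_incumbent(t, y):
        return y[0] - spec.M_inc * (1.0 - 1e-9) + 1e-9 * M0

    hit_incumbent.terminal = True

    t0 = min(0.0, t_grid[0])
    sol = solve_ivp(
        rhs,
        (t0, t_grid[-1]),
        [float(M0), float(rho_M0)],
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol if atol is not None else [1e-6 * M0, 1e-10],
        events=hit_incumbent,
    )
    if sol.status == 1:
        raise ModelDomainError(
            f"memory pool reached the incumbent size at t={sol.t_events[0][0]:.3f} d; "
            "the chimerism equation is undefined there"
        )
    if not sol.success:
        raise ModelDomainError(f"integration failed: {sol.message}")
    return pd.DataFrame({"t": sol.t, "M": sol.y[0], "rho_M": sol.y[1]})


def _expm1_over_x(x):
    """(exp(x) - 1)/x with a 3-term series for |x| < 1e-6."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    out = np.empty_like(x)
    xs = x[small]
    out[small] = 1.0 + xs / 2.0 + xs * xs / 6.0
    out[~small] = np.expm1(x[~small]) / x[~small]
    return out


@dataclass
class ReplacementSummary:
    """Replacement-fraction summary over a horizon ``t``.

    ``daily_influx_fraction`` is the instantaneous influx at the start of
    the horizon, ``gamma(0) S(0) / M(0)``.  ``X`` is the number of initially
    present displaceable cells surviving to ``t``; ``Y`` the number of cells
    recruited during ``(0, t)`` and surviving.
    """

    t: float
    daily_influx_fraction: float
    f_replace: float
    f_replace_displaceable: float
    psi: float
    X: float
    Y: float
    Y_numeric: float


def replacement_fraction(
    spec: ChimeraModelSpec,
    source: SourceDescriptor,
    M0: float,
    t: float,
    check: bool = True,
) -> ReplacementSummary:
    """Fraction of the pool (and of its displaceable part) replaced by
    immigrants over ``(0, t)``.

    The closed form is cross-checked against numerical integration of
    ``dY/dt = gamma(t) S(t) - lam Y`` when ``check`` is true.
    """
    t = float(t)
    psi = source.R + spec.phi - spec.lam
    gS0 = spec.gamma0 * source.S0
    # Y(t) = gS0 e^{-lam t} (1 - e^{-psi t})/psi, and
    # (1 - e^{-psi t})/psi = t * [(e^x - 1)/x at x = -psi t]
    Y = gS0 * np.exp(-spec.lam * t) * t * float(_expm1_over_x(-psi * t)) \
        if t > 0 else 0.0
    X = (M0 - spec.M_inc) * np.exp(-spec.lam * t)
    denom_total = X + Y + spec.M_inc
    f_total = Y / denom_total if denom_total > 0 else 0.0
    f_disp = Y / (X + Y) if (X + Y) > 0 else 0.0

    Y_num = Y
    if check and t > 0:
        sol = solve_ivp(
            lambda s, y: [spec.gamma(s) * eval_source_size(source, s) - spec.lam * y[0]],
            (0.0, t),
            [0.0],
            method="LSODA",
            rtol=1e-10,
            atol=1e-12 * max(gS0 * t, 1.0),
        )
        Y_num = float(sol.y[0, -1])
        if Y > 0 and not np.isclose(Y, Y_num, rtol=1e-6):
            raise AssertionError(
                f"closed-form Y={Y:.10g} disagrees with ODE Y={Y_num:.10g}"
            )
    daily = spec.gamma0 * source.S0 / M0
    return ReplacementSummary(
        t=t,
        daily_influx_fraction=float(daily),
        f_replace=float(f_total),
        f_replace_displaceable=float(f_disp),
        psi=float(psi),
        X=float(X),
        Y=float(Y),
        Y_numeric=float(Y_num),
    )


def quick_influx_estimate(drho_dt: float, rho_source: float, rho_memory: float) -> float:
    """Slope-ratio estimator of the daily fractional influx.

    When memory chimerism is low and the pool is near-stationary, the influx
    ``gamma S / M`` is approximately ``(drho_M/dt) / (rho_S - rho_M)``.
    """
    if rho_source <= rho_memory:
        raise ValueError(
            "estimator undefined: source chimerism must exceed memory chimerism"
        )
    return float(drho_dt / (rho_source - rho_memory))


# ---------------------------------------------------------------------------
# Fitting


def _data_fingerprint(ages, counts, chim) -> str:
    h = hashlib.sha256()
    for arr in (ages, counts, chim):
        h.update(np.ascontiguousarray(np.asarray(arr, dtype=float)).tobytes())
    return h.hexdigest()[:16]


class ChimeraReplacementModel:
    """Replacement-model fit to one memory subset's timecourses.

    Fits the five free parameters (``gamma0``, ``lam``, one of
    ``M_inc``/``phi`` per variant — both for "combined" — and the initial
    conditions ``M0``, ``rho_M0``) by maximum likelihood with Gaussian
    residuals on log10 counts and on untransformed normalised chimerism,
    each variance profiled out.  The joint log-likelihood is the sum of the
    two timecourse log-likelihoods.

    Parameters
    ----------
    data : DataFrame
        Timecourse table (schema as :mod:`memokin.source`) for the memory
        subset being fitted.
    source : SourceDescriptor or SourceResults
        Fitted source descriptor; passing :class:`SourceResults` lets the
        bootstrap resample source-parameter draws.
    subset : str
        Population label of the memory subset within ``data``.
    variant : str
        ``"resistant"``, ``"declining"`` or ``"combined"``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        source: SourceDescriptor | SourceResults,
        subset: str,
        variant: str = "resistant",
        t_ref: float = T_REF_DEFAULT,
    ):
        validate_timecourse(data)
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.variant = variant
        self.subset = subset
        self.t_ref = float(t_ref)
        self.source_results = source if isinstance(source, SourceResults) else None
        self.source = source.descriptor if isinstance(source, SourceResults) else source
        sub = data[data["population"] == subset]
        if sub.empty:
            raise SchemaError(f"no rows for population {subset!r}")
        size = sub.dropna(subset=["count"])
        chim = sub.dropna(subset=["chimerism_normalized"])
        self._t_size = size["age_days"].to_numpy(float) - self.t_ref
        self._y_log10 = np.log10(size["count"].to_numpy(float))
        self._t_chim = chim["age_days"].to_numpy(float) - self.t_ref
        self._y_chim = chim["chimerism_normalized"].to_numpy(float)
        self.fingerprint = _data_fingerprint(
            np.concatenate([self._t_size, self._t_chim]),
            self._y_log10,
            self._y_chim,
        )
        self._t_all = np.unique(np.concatenate([[0.0], self._t_size, self._t_chim]))

    # parameter vector: [log10 gamma0, lam, (log10 Minc | log10 phi | both), log10 M0, rho_M0]
    def _bounds(self):
        scale = float(np.median(10 ** self._y_log10))
        lo = [-np.log10(scale) - 6.0, -0.05]
        hi = [1.0 - np.log10(self.source.S0 / scale), 0.1]
        names = ["log10_gamma0", "lam"]
        if self.variant in ("resistant", "combined"):
            lo.append(0.0)
            hi.append(np.log10(scale) + 1.0)
            names.append("log10_Minc")
        if self.variant in ("declining", "combined"):
            lo.append(-5.0)
            hi.append(-1.0)
            names.append("log10_phi")
        lo += [np.log10(scale) - 1.5, 1e-6]
        hi += [np.log10(scale) + 1.5, 1.0]
        names += ["log10_M0", "rho_M0"]
        return np.array(lo), np.array(hi), names

    def _unpack(self, x) -> tuple[ChimeraModelSpec, float, float]:
        gamma0 = 10.0 ** x[0]
        lam = x[1]
        i = 2
        M_inc = 0.0
        phi = 0.0
        if self.variant in ("resistant", "combined"):
            M_inc = 10.0 ** x[i]
            i += 1
        if self.variant in ("declining", "combined"):
            phi = 10.0 ** x[i]
            i += 1
        M0 = 10.0 ** x[i]
        rho_M0 = x[i + 1]
        spec = ChimeraModelSpec(gamma0, lam, M_inc, phi, variant=self.variant)
        return spec, M0, rho_M0

    def _curves(self, x, source: SourceDescriptor):
        spec, M0, rho_M0 = self._unpack(x)
        if M0 <= spec.M_inc:
            return None
        try:
            sim = simulate_chimera(spec, source, M0, rho_M0, self._t_all, rtol=1e-7)
        except ModelDomainError:
            return None
        Mi = np.interp(self._t_size, sim["t"], sim["M"])
        rhoi = np.interp(self._t_chim, sim["t"], sim["rho_M"])
        return np.log10(Mi), rhoi

    def _residuals(self, x, weights, source, y_log10, y_chim):
        curves = self._curves(x, source)
        if curves is None:
            return np.full(self._t_size.size + self._t_chim.size, 1e3)
        logM, rho = curves
        w1, w2 = weights
        return np.concatenate([(y_log10 - logM) / w1, (y_chim - rho) / w2])

    def _fit_once(self, source, y_log10, y_chim, seed, n_starts, x0=None):
        lo, hi, _ = self._bounds()
        weights = [1.0, 0.2]  # initial relative scales of the two blocks
        x = x0
        res = None
        for _ in range(6):  # iterate profiling of the two variances
            res = multistart_least_squares(
                lambda p: self._residuals(p, weights, source, y_log10, y_chim),
                (lo, hi),
                n_starts=n_starts if x is None else 0,
                seed=seed,
                x0=x,
                xtol=1e-12,
                ftol=1e-12,
            )
            x = res.x
            logM, rho = self._curves(x, source)
            s1 = float(np.sqrt(np.mean((y_log10 - logM) ** 2)))
            s2 = float(np.sqrt(np.mean((y_chim - rho) ** 2)))
            new_weights = [max(s1, 1e-9), max(s2, 1e-9)]
            if np.allclose(new_weights, weights, rtol=1e-3):
                weights = new_weights
                break
            weights = new_weights
            n_starts = 0  # warm-start subsequent reweighting passes
        return x, weights

    def _loglik(self, x, source, y_log10, y_chim) -> float:
        logM, rho = self._curves(x, source)
        out = 0.0
        for obs, fit in ((y_log10, logM), (y_chim, rho)):
            n = obs.size
            rss = float(np.sum((obs - fit) ** 2))
            out += -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
        return out

    def fit(
        self,
        n_boot: int = 500,
        seed: int | None = None,
        n_starts: int = 20,
    ) -> "ChimeraResults":
        x, _ = self._fit_once(self.source, self._y_log10, self._y_chim, seed, n_starts)
        spec, M0, rho_M0 = self._unpack(x)
        loglik = self._loglik(x, self.source, self._y_log10, self._y_chim)
        n_params = 6 if self.variant == "combined" else 5
        aic = 2 * n_params - 2 * loglik

        # nonparametric residual bootstrap, jointly resampling source draws
        rng = np.random.default_rng(seed)
        logM, rho = self._curves(x, self.source)
        res_log = self._y_log10 - logM
        res_chim = self._y_chim - rho
        _, _, names = self._bounds()
        rows = []
        for _ in range(n_boot):
            yb_log = logM + rng.choice(res_log, res_log.size, replace=True)
            yb_chim = rho + rng.choice(res_chim, res_chim.size, replace=True)
            src = (
                self.source_results.sample_descriptor(rng)
                if self.source_results is not None
                else self.source
            )
            try:
                xb, _ = self._fit_once(src, yb_log, yb_chim, None, 0, x0=x)
            except Exception:  # noqa: BLE001 - replicate failures are dropped
                continue
            specb, M0b, rb = self._unpack(xb)
            rows.append(
                {
                    "gamma0": specb.gamma0,
                    "lam": specb.lam,
                    "M_inc": specb.M_inc,
                    "phi": specb.phi,
                    "M0": M0b,
                    "rho_M0": rb,
                }
            )
        boot = pd.DataFrame(rows, columns=["gamma0", "lam", "M_inc", "phi", "M0", "rho_M0"])
        # flag estimates pinned at the box edge
        lo, hi, _ = self._bounds()
        at_boundary = bool(np.any(np.isclose(x, lo, atol=1e-8) | np.isclose(x, hi, atol=1e-8)))
        return ChimeraResults(
            model=self,
            spec=spec,
            M0=M0,
            rho_M0=rho_M0,
            loglik=loglik,
            aic=aic,
            n_params=n_params,
            bootstrap=boot,
            at_boundary=at_boundary,
        )


@dataclass
class ChimeraResults:
    """Estimates, likelihood, AIC and bootstrap table for one variant."""

    model: ChimeraReplacementModel
    spec: ChimeraModelSpec
    M0: float
    rho_M0: float
    loglik: float
    aic: float
    n_params: int
    bootstrap: pd.DataFrame = field(repr=False)
    at_boundary: bool = False

    @property
    def fingerprint(self) -> str:
        return self.model.fingerprint

    def params(self) -> dict:
        return {
            "gamma0": self.spec.gamma0,
            "lam": self.spec.lam,
            "M_inc": self.spec.M_inc,
            "phi": self.spec.phi,
            "M0": self.M0,
            "rho_M0": self.rho_M0,
        }

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        point = pd.Series(self.params())
        if self.bootstrap.empty:
            return pd.DataFrame({"estimate": point})
        lo = self.bootstrap.quantile(alpha / 2)
        hi = self.bootstrap.quantile(1 - alpha / 2)
        return pd.DataFrame({"estimate": point, "lo": lo, "hi": hi})

    def replacement_summary(self, t: float = 7.0) -> ReplacementSummary:
        return replacement_fraction(self.spec, self.model.source, self.M0, t)

    def project(self, age_grid, horizon: float = 7.0, n_draws: int = 200,
                seed: int | None = None) -> pd.DataFrame:
        return project_replacement_with_age(
            self, self.model.source, age_grid, horizon=horizon,
            n_draws=n_draws, seed=seed,
        )

    def summary(self) -> str:
        rs = self.replacement_summary(7.0)
        ci = self.conf_int()
        lines = [
            f"Replacement model fit: subset={self.model.subset!r}, "
            f"variant={self.model.variant!r}",
            f"  loglik={self.loglik:.3f}  AIC={self.aic:.3f}  k={self.n_params}"
            + ("  [boundary estimate]" if self.at_boundary else ""),
            f"  daily influx {100 * rs.daily_influx_fraction:.2f}% of pool/day; "
            f"replaced per week {100 * rs.f_replace:.2f}% "
            f"(displaceable only {100 * rs.f_replace_displaceable:.2f}%)",
            f"{'param':>8} {'estimate':>12}"
            + (f" {'lo95':>12} {'hi95':>12}" if "lo" in ci else ""),
        ]
        for name, row in ci.iterrows():
            line = f"{name:>8} {row['estimate']:>12.5g}"
            if "lo" in ci:
                line += f" {row['lo']:>12.5g} {row['hi']:>12.5g}"
            lines.append(line)
        return "\n".join(lines)


def compare_chimera_models(fits: list[ChimeraResults]) -> pd.DataFrame:
    """AIC comparison table for fits on identical data.

    ``delta_aic`` is quoted relative to the best (minimum-AIC) model and
    ``rel_prob = exp(-delta_aic / 2)`` is the relative probability that the
    poorer model is nevertheless the one minimising information loss.
    """
    if not fits:
        raise ValueError("no fits to compare")
    prints = {f.fingerprint for f in fits}
    if len(prints) != 1:
        raise ValueError("fits were made on different data (fingerprint mismatch)")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    return pd.DataFrame(
        {
            "subset": [f.model.subset for f in fits],
            "variant": [f.model.variant for f in fits],
            "aic": aics,
            "delta_aic": delta,
            "rel_prob": np.exp(-delta / 2.0),
        }
    )


def project_replacement_with_age(
    fit: ChimeraResults,
    source: SourceDescriptor,
    age_grid,
    horizon: float = 7.0,
    n_draws: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Weekly replacement fractions (total and displaceable-only) over a
    grid of host ages, with bootstrap uncertainty bands.

    At each age the model state is advanced to that age and the closed-form
    replacement fraction is evaluated over the following ``horizon`` days
    with age-shifted source size and recruitment rate.  Rows beyond twice
    the fitted data range are flagged ``extrapolated``.
    """
    age_grid = np.asarray(age_grid, dtype=float)
    t_ref = fit.model.t_ref
    data_span = float(max(fit.model._t_size.max(), fit.model._t_chim.max()))

    def curve(spec: ChimeraModelSpec, src: SourceDescriptor, M0, rho_M0):
        t0s = age_grid - t_ref
        grid = np.unique(np.concatenate([[0.0], t0s[t0s > 0]]))
        sim = simulate_chimera(spec, src, M0, rho_M0, grid) if grid.size > 1 else None
        tot, disp = [], []
        for t0 in t0s:
            Mt = M0 if t0 <= 0 else float(np.interp(t0, sim["t"], sim["M"]))
            shifted = ChimeraModelSpec(
                gamma0=spec.gamma0 * np.exp(-spec.phi * max(t0, 0.0)),
                lam=spec.lam,
                M_inc=spec.M_inc,
                phi=spec.phi,
                variant=spec.variant,
            )
            shifted_src = SourceDescriptor(
                S0=src.S0 * np.exp(-src.R * max(t0, 0.0)),
                R=src.R,
                rho_max=src.rho_max,
                rho_0=src.rho_0,
                r=src.r,
                t_ref=src.t_ref,
            )
            rs = replacement_fraction(shifted, shifted_src, Mt, horizon, check=False)
            tot.append(rs.f_replace)
            disp.append(rs.f_replace_displaceable)
        return np.array(tot), np.array(disp)

    tot, disp = curve(fit.spec, source, fit.M0, fit.rho_M0)
    out = pd.DataFrame(
        {
            "age_days": age_grid,
            "f_replace_week_total": tot,
            "f_replace_week_displaceable": disp,
            "extrapolated": age_grid - t_ref > 2.0 * data_span,
        }
    )
    if not fit.bootstrap.empty and n_draws > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(len(fit.bootstrap), size=min(n_draws, len(fit.bootstrap)))
        draws_tot, draws_disp = [], []
        for i in idx:
            row = fit.bootstrap.iloc[i]
            try:
                spec_i = ChimeraModelSpec(
                    row["gamma0"], row["lam"], row["M_inc"], row["phi"],
                    variant=fit.spec.variant,
                )
                ti, di = curve(spec_i, source, row["M0"], row["rho_M0"])
            except (ModelDomainError, ValueError):
                continue
            draws_tot.append(ti)
            draws_disp.append(di)
        if draws_tot:
            draws_tot = np.array(draws_tot)
            draws_disp = np.array(draws_disp)
            out["total_lo95"] = np.quantile(draws_tot, 0.025, axis=0)
            out["total_hi95"] = np.quantile(draws_tot, 0.975, axis=0)
            out["displaceable_lo95"] = np.quantile(draws_disp, 0.025, axis=0)
            out["displaceable_hi95"] = np.quantile(draws_disp, 0.975, axis=0)
    return out
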