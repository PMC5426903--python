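"""Empirical descriptors of a source population's size and chimerism.

In the busulfan-chimera system, memory subsets are fed by a precursor
("source") population — the naive CD4 pool, or central memory when modelling
effector memory.  Rather than modelling the source mechanistically, its size
and normalised donor chimerism are described by empirical curves fitted to
the timecourse data:

* size: exponential decay, ``S(t) = S0 * exp(-R * t)``;
* chimerism: logistic growth towards a plateau,
  ``rho_S(t) = rho_max / (1 + exp(-r*t) * (rho_max - rho_0) / rho_0)``.

Time ``t`` runs on the descriptor clock: days since the modelling origin
``t_ref`` (host age 98 days, i.e. six weeks after bone-marrow transplant).

Chimerism is "normalised": the donor fraction in the population divided by
the donor fraction among DP1 thymocytes of the same animal, which controls
for the variable degree of stem-cell replacement across mice.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._optim import multistart_least_squares
from .exceptions import ConvergenceError, SchemaError, UnderdeterminedDataError

__all__ = [
    "SourceDescriptor",
    "eval_source_size",
    "eval_source_chimerism",
    "SourceModel",
    "SourceResults",
    "fit_source_descriptor",
    "validate_timecourse",
]

T_REF_DEFAULT = 98.0  # host age (days) at the modelling origin

TIMECOURSE_COLUMNS = [
    "mouse_id",
    "age_days",
    "population",
    "count",
    "chimerism_normalized",
]


@dataclass
class SourceDescriptor:
    """Parameters of the empirical source size / chimerism curves.

    Attributes
    ----------
    S0 : float
        Source size (cells) at ``t = 0`` on the descriptor clock.
    R : float
        Per-day exponential decay rate of the source size.
    rho_max : float
        Asymptotic normalised chimerism (dimensionless).
    rho_0 : float
        Normalised chimerism at ``t = 0``; must satisfy ``0 < rho_0 <= rho_max``.
    r : float
        Per-day growth rate of the chimerism sigmoid.
    t_ref : float
        Host age (days) at which the descriptor clock starts.
    """

    S0: float
    R: float
    rho_max: float
    rho_0: float
    r: float
    t_ref: float = T_REF_DEFAULT

    def __post_init__(self) -> None:
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")
        if self.rho_0 <= 0:
            raise ValueError("rho_0 must be positive (sigmoid undefined at 0)")
        if self.rho_0 > self.rho_max * (1 + 1e-12):
            raise ValueError("rho_0 must not exceed rho_max")
        if self.r < 0:
            raise ValueError("r must be nonnegative")

    def size(self, t):
        return eval_source_size(self, t)

    def chimerism(self, t):
        return eval_source_chimerism(self, t)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, path) -> "SourceDescriptor":
        with open(path) as fh:
            return cls(**json.load(fh))


def eval_source_size(desc: SourceDescriptor, t):
    """Source size ``S0 * exp(-R t)`` at time ``t`` (descriptor clock, days)."""
    t = np.asarray(t, dtype=float)
    return desc.S0 * np.exp(-desc.R * t)


def eval_source_chimerism(desc: SourceDescriptor, t):
    """Normalised source chimerism at time ``t``.

    Logistic form ``rho_max / (1 + exp(-r t) (rho_max - rho_0)/rho_0)``:
    equals ``rho_0`` at ``t = 0`` and saturates at ``rho_max``.
    """
    t = np.asarray(t, dtype=float)
    shape = (desc.rho_max - desc.rho_0) / desc.rho_0
    return desc.rho_max / (1.0 + np.exp(-desc.r * t) * shape)


def validate_timecourse(data: pd.DataFrame) -> pd.DataFrame:
    """Check a population timecourse table against the expected schema."""
    for col in TIMECOURSE_COLUMNS:
        if col not in data.columns:
            raise SchemaError(f"timecourse table is missing column {col!r}")
    if (data["age_days"] <= 0).any():
        raise SchemaError("age_days must be strictly positive")
    counts = data["count"].dropna()
    if (counts < 0).any():
        raise SchemaError("count must be nonnegative")
    chim = data["chimerism_normalized"].dropna()
    if (chim < 0).any():
        raise SchemaError("chimerism_normalized must be nonnegative")
    return data


def _chimerism_residuals(theta, t, obs):
    rho_max, c, r = theta
    rho_0 = c * rho_max
    shape = (rho_max - rho_0) / rho_0
    return rho_max / (1.0 + np.exp(-r * t) * shape) - obs


class SourceModel:
    """Empirical descriptor model for one source population.

    Parameters
    ----------
    data : DataFrame
        Timecourse table with columns ``mouse_id, age_days, population,
        count, chimerism_normalized``.
    population : str
        Which population label to fit (e.g. ``"naive"`` or ``"TCM"``).
    t_ref : float
        Host age (days) of the descriptor clock origin.

    Size is fitted by least squares on log-transformed counts (count noise
    is multiplicative); chimerism on its natural scale.
    """

    def __init__(self, data: pd.DataFrame, population: str, t_ref: float = T_REF_DEFAULT):
        validate_timecourse(data)
        sub = data[data["population"] == population]
        if sub.empty:
            raise SchemaError(f"no rows for population {population!r}")
        self.population = population
        self.t_ref = float(t_ref)
        size = sub.dropna(subset=["count"])
        chim = sub.dropna(subset=["chimerism_normalized"])
        self._t_size = size["age_days"].to_numpy(float) - self.t_ref
        self._y_logsize = np.log(size["count"].to_numpy(float))
        self._t_chim = chim["age_days"].to_numpy(float) - self.t_ref
        self._y_chim = chim["chimerism_normalized"].to_numpy(float)
        if np.unique(self._t_size).size < 2:
            raise UnderdeterminedDataError(
                "size curve has 2 parameters but fewer than 2 distinct ages"
            )
        if np.unique(self._t_chim).size < 3:
            raise UnderdeterminedDataError(
                "chimerism curve has 3 parameters but fewer than 3 distinct ages"
            )

    # -- point fits ---------------------------------------------------------

    def _fit_size(self, y_log: np.ndarray) -> tuple[float, float]:
        # log S(t) = log S0 - R t: ordinary linear least squares
        A = np.column_stack([np.ones_like(self._t_size), -self._t_size])
        coef, *_ = np.linalg.lstsq(A, y_log, rcond=None)
        return float(np.exp(coef[0])), float(coef[1])

    def _fit_chimerism(self, y: np.ndarray) -> tuple[float, float, float]:
        ymax = max(float(np.max(y)), 1e-6)
        y0 = float(np.clip(y[np.argmin(self._t_chim)], 1e-6, None))
        x0 = np.array([min(ymax * 1.05, 1.45), min(y0 / (ymax * 1.05), 1.0), 0.02])
        lo = [1e-6, 1e-9, 1e-6]
        hi = [1.5, 1.0, 1.0]
        res = least_squares(
            _chimerism_residuals,
            np.clip(x0, lo, hi),
            bounds=(lo, hi),
            args=(self._t_chim, y),
            method="trf",
        )
        if res.status <= 0:
            # fall back to multistarts before declaring failure
            res = multistart_least_squares(
                lambda th: _chimerism_residuals(th, self._t_chim, y),
                (lo, hi),
                n_starts=10,
                seed=0,
            )
        rho_max, c, r = res.x
        return float(rho_max), float(c * rho_max), float(r)

    def fit(self, n_boot: int = 1000, seed: int | None = None) -> "SourceResults":
        """Fit both curves; bootstrap residuals for parameter uncertainty."""
        S0, R = self._fit_size(self._y_logsize)
        rho_max, rho_0, r = self._fit_chimerism(self._y_chim)
        desc = SourceDescriptor(S0, R, rho_max, rho_0, r, t_ref=self.t_ref)

        rng = np.random.default_rng(seed)
        fitted_log = np.log(eval_source_size(desc, self._t_size))
        fitted_chim = eval_source_chimerism(desc, self._t_chim)
        res_log = self._y_logsize - fitted_log
        res_chim = self._y_chim - fitted_chim
        rows = []
        for _ in range(n_boot):
            yb_log = fitted_log + rng.choice(res_log, size=res_log.size, replace=True)
            yb_chim = fitted_chim + rng.choice(res_chim, size=res_chim.size, replace=True)
            try:
                S0b, Rb = self._fit_size(yb_log)
                rmx, r0, rb = self._fit_chimerism(yb_chim)
            except ConvergenceError:
                continue
            rows.append({"S0": S0b, "R": Rb, "rho_max": rmx, "rho_0": r0, "r": rb})
        boot = pd.DataFrame(rows, columns=["S0", "R", "rho_max", "rho_0", "r"])
        return SourceResults(self, desc, boot)


@dataclass
class SourceResults:
    """Fitted source descriptor with bootstrap uncertainty."""

    model: SourceModel
    descriptor: SourceDescriptor
    bootstrap: pd.DataFrame = field(repr=False)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        lo = self.bootstrap.quantile(alpha / 2)
        hi = self.bootstrap.quantile(1 - alpha / 2)
        point = pd.Series(
            {k: getattr(self.descriptor, k) for k in ["S0", "R", "rho_max", "rho_0", "r"]}
        )
        return pd.DataFrame({"estimate": point, "lo": lo, "hi": hi})

    def sample_descriptor(self, rng: np.random.Generator) -> SourceDescriptor:
        """Draw one descriptor from the bootstrap distribution."""
        if self.bootstrap.empty:
            return self.descriptor
        row = self.bootstrap.iloc[rng.integers(len(self.bootstrap))]
        rho_max = float(row["rho_max"])
        rho_0 = min(float(row["rho_0"]), rho_max)
        return SourceDescriptor(
            float(row["S0"]), float(row["R"]), rho_max, rho_0, float(row["r"]),
            t_ref=self.descriptor.t_ref,
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Source descriptor fit: population={self.model.population!r}, "
            f"t_ref={self.descriptor.t_ref:g} d",
            f"  n_size={self.model._t_size.size}, "
            f"n_chimerism={self.model._t_chim.size}, "
            f"bootstrap={len(self.bootstrap)}",
            f"{'param':>8} {'estimate':>12} {'lo95':>12} {'hi95':>12}",
        ]
        for name, row in ci.iterrows():
            lines.append(
                f"{name:>8} {row['estimate']:>12.5g} {row['lo']:>12.5g} {row['hi']:>12.5g}"
            )
        return "\n".join(lines)


def fit_source_descriptor(
    data: pd.DataFrame,
    population: str,
    t_ref: float = T_REF_DEFAULT,
    n_boot: int = 1000,
    seed: int | None = None,
) -> SourceResults:
    """Functional wrapper: fit the empirical descriptors for one population."""
    return SourceModel(data, population, t_ref=t_ref).fit(n_boot=n_boot, seed=seed)
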