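"""BrdU x Ki67 compartmental model: parameterisation and steady-state
resolution.

A memory subset of constant size ``N`` is modelled as one (temporal
heterogeneity, TH) or two (kinetic heterogeneity, KH) subpopulations.  Each
cell carries two labels:

* a Ki67 level: low (quiescent) or one of ``khat`` sequential high stages
  traversed at rate ``khat * beta`` each, so the post-mitotic Ki67-high
  residence time is Erlang with mean ``1/beta`` and CV ``1/sqrt(khat)``;
* a BrdU class: unlabelled, or ``j`` divisions since last uptake
  (``j = 0 .. bhat-1``); after ``bhat`` label-free divisions a cell reverts
  to BrdU-negative.

Cells enter division at per-capita rate ``alpha``; a division removes the
mother and produces two daughters in the first Ki67-high stage.  Ki67-low
and Ki67-high cells die at rates ``delta_lo`` and ``delta_hi``.  A source
(new memory from the naive pool) enters the first Ki67-high stage at
``s_week * N / 7`` cells per day, BrdU-positive during feeding and for
``tau`` days afterwards.

Two experimental constraints are imposed at construction ("steady-state
resolution"): every subpopulation is stationary in size, and the model's
equilibrium Ki67-high fraction equals the observed ``kappa_obs``.  These
eliminate the death rates and one division rate, leaving 4 free continuous
parameters for TH and 6 for KH.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from ..exceptions import InfeasibleParameterError

__all__ = [
    "KineticModelSpec",
    "SubpopRates",
    "StateSpace",
    "build_state_space",
    "resolve_steady_state",
    "ki67_residence_summary",
]

_DELTA_LO_BRACKET = 1e-12


@dataclass
class KineticModelSpec:
    """Full parameterisation of the BrdU x Ki67 model.

    For ``structure="TH"`` the subset is a single population with division
    rate ``alpha_fast``; ``q_fast``, ``f_slow``, ``alpha_slow`` and
    ``death_ratio`` are ignored (the TH death rates are resolved freely from
    the stationarity and Ki67 constraints, so the high/low death-rate ratio
    is an outcome, not an input).

    For ``structure="KH"`` the subset splits into a fast fraction ``q_fast``
    and a slow fraction ``1 - q_fast``; the source feeds the slow
    subpopulation with fraction ``f_slow``.  Within each subpopulation
    ``delta_hi = death_ratio * delta_lo`` with ``death_ratio`` fixed (1 for
    the basic model; 0.1 or 10 for the temporal-heterogeneity variants).
    ``alpha_slow=None`` requests resolution from ``kappa_obs``.
    """

    structure: str = "KH"
    khat: int = 12
    bhat: int = 2
    beta: float = 0.3
    epsilon: float = 0.76
    tau: float = 2.5
    s_week: float = 0.07
    kappa_obs: float | None = None
    alpha_fast: float = 0.1
    alpha_slow: float | None = None
    q_fast: float = 0.5
    f_slow: float = 1.0
    death_ratio: float = 1.0
    N: float = 1.0

    def __post_init__(self) -> None:
        if self.structure not in ("TH", "KH"):
            raise ValueError("structure must be 'TH' or 'KH'")
        if self.khat < 1 or self.bhat < 1:
            raise ValueError("khat and bhat must be >= 1")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")
        if self.structure == "KH" and not 0 < self.q_fast < 1:
            raise ValueError("q_fast must be in (0, 1) for KH")
        if not 0 <= self.f_slow <= 1:
            raise ValueError("f_slow must be in [0, 1]")
        if min(self.beta, self.alpha_fast) <= 0 or self.tau < 0 or self.s_week < 0:
            raise ValueError("rates must be positive; tau and s_week nonnegative")

    def to_json(self, path=None) -> str:
        import json
        from dataclasses import asdict

        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, path) -> "KineticModelSpec":
        import json

        with open(path) as fh:
            return cls(**json.load(fh))

    @property
    def n_subpops(self) -> int:
        return 2 if self.structure == "KH" else 1

    @property
    def n_free_params(self) -> int:
        """Free continuous parameters after steady-state resolution."""
        return 6 if self.structure == "KH" else 4


@dataclass
class SubpopRates:
    """Resolved rates and unlabelled equilibrium of one subpopulation."""

    name: str
    alpha: float
    delta_lo: float
    delta_hi: float
    N_p: float
    S_p: float  # cells/day from the source
    kappa: float  # equilibrium Ki67-high fraction
    stages: np.ndarray  # equilibrium occupancy of high stages 1..khat
    low: float  # equilibrium Ki67-low occupancy


@dataclass
class StateSpace:
    """Index map over (subpopulation, Ki67 stage, BrdU class) with resolved
    rates.

    BrdU class index 0 is unlabelled; index ``j + 1`` means ``j`` divisions
    since last uptake (``j = 0`` freshly labelled).  Ki67 stage 0 is low;
    stages ``1..khat`` are the sequential high stages.
    """

    spec: KineticModelSpec
    subpops: list[SubpopRates] = field(default_factory=list)

    @property
    def n_stages(self) -> int:
        return self.spec.khat + 1

    @property
    def n_classes(self) -> int:
        return self.spec.bhat + 1

    @property
    def n_states(self) -> int:
        return self.spec.n_subpops * self.n_stages * self.n_classes

    def index(self, p: int, g: int, d: int) -> int:
        return (p * self.n_stages + g) * self.n_classes + d

    def dilute(self, d: int) -> int:
        """BrdU class of a daughter after a label-free division."""
        if d == 0:
            return 0
        return d + 1 if d < self.spec.bhat else 0

    @property
    def kappa_model(self) -> float:
        if not self.subpops:
            raise ValueError("state space is not resolved")
        return sum(sp.kappa * sp.N_p for sp in self.subpops) / self.spec.N

    def equilibrium(self) -> np.ndarray:
        """Unlabelled stationary state vector (all mass in BrdU class 0)."""
        x = np.zeros(self.n_states)
        for p, sp in enumerate(self.subpops):
            x[self.index(p, 0, 0)] = sp.low
            for g in range(1, self.spec.khat + 1):
                x[self.index(p, g, 0)] = sp.stages[g - 1]
        return x

    def ki67_high_mask(self) -> np.ndarray:
        m = np.zeros(self.n_states, dtype=bool)
        for p in range(self.spec.n_subpops):
            for g in range(1, self.spec.khat + 1):
                for d in range(self.n_classes):
                    m[self.index(p, g, d)] = True
        return m

    def brdu_pos_mask(self) -> np.ndarray:
        m = np.zeros(self.n_states, dtype=bool)
        for p in range(self.spec.n_subpops):
            for g in range(self.n_stages):
                for d in range(1, self.n_classes):
                    m[self.index(p, g, d)] = True
        return m


def build_state_space(spec: KineticModelSpec) -> StateSpace:
    """Index map only (rates unresolved); mostly useful for introspection."""
    return StateSpace(spec=spec)


def ki67_residence_summary(khat: int, beta: float) -> dict:
    """Mean and CV of the Erlang(khat) Ki67-high residence time."""
    if khat < 1 or beta <= 0:
        raise ValueError("khat >= 1 and beta > 0 required")
    return {"mean": 1.0 / beta, "cv": 1.0 / np.sqrt(khat)}


# ---------------------------------------------------------------------------
# Equilibrium closed forms.
#
# Within one subpopulation at its unlabelled equilibrium the high stages form
# a geometric cascade: inflow into stage 1 is 2*alpha*N_p + S_p, each stage
# drains at D = khat*beta + delta_hi + alpha, so h_g = h_1 * a**(g-1) with
# a = khat*beta / D, and the low pool balances khat*beta*h_khat against
# (delta_lo + alpha) * low.


def _chain(alpha, delta_lo, delta_hi, beta, khat, N_p, S_p):
    u = khat * beta
    D = u + delta_hi + alpha
    a = u / D
    h1 = (2.0 * alpha * N_p + S_p) / D
    stages = h1 * a ** np.arange(khat)
    H = float(stages.sum())
    low = u * stages[-1] / (delta_lo + alpha)
    return stages, H, low


def _solve_delta_lo(alpha, beta, khat, N_p, S_p, ratio):
    """Death rate making the subpopulation stationary at size N_p."""

    def excess(delta_lo):
        _, H, low = _chain(alpha, delta_lo, ratio * delta_lo, beta, khat, N_p, S_p)
        return H + low - N_p

    lo = _DELTA_LO_BRACKET
    shortfall = excess(lo)
    if shortfall < 0:
        raise InfeasibleParameterError(
            "population shrinks even with vanishing death rate",
            violation=-shortfall / N_p,
        )
    hi = max(alpha, beta, S_p / N_p if N_p > 0 else 1.0, 1.0)
    for _ in range(60):
        if excess(hi) < 0:
            break
        hi *= 2.0
    else:
        raise InfeasibleParameterError("no stationary death rate found")
    return brentq(excess, lo, hi, xtol=1e-14, rtol=1e-13)


def _subpop_from_alpha(name, alpha, beta, khat, N_p, S_p, ratio) -> SubpopRates:
    delta_lo = _solve_delta_lo(alpha, beta, khat, N_p, S_p, ratio)
    delta_hi = ratio * delta_lo
    stages, H, low = _chain(alpha, delta_lo, delta_hi, beta, khat, N_p, S_p)
    return SubpopRates(
        name=name,
        alpha=alpha,
        delta_lo=delta_lo,
        delta_hi=delta_hi,
        N_p=N_p,
        S_p=S_p,
        kappa=H / N_p,
        stages=stages,
        low=low,
    )


def _solve_alpha_for_kappa(target, beta, khat, N_p, S_p, ratio):
    """Division rate whose stationary equilibrium has Ki67-high fraction
    ``target``."""
    if not 0 < target < 1:
        raise InfeasibleParameterError(
            f"required subpopulation Ki67-high fraction {target:.4g} not in (0,1)",
            violation=max(-target, target - 1.0),
        )

    def kappa_of(alpha):
        return _subpop_from_alpha("", alpha, beta, khat, N_p, S_p, ratio).kappa

    lo = 1e-8
    floor = kappa_of(lo)
    if floor > target:
        raise InfeasibleParameterError(
            "source influx alone exceeds the required Ki67-high fraction",
            violation=floor - target,
        )
    hi = 1.0
    for _ in range(30):
        if kappa_of(hi) > target:
            break
        hi *= 2.0
    else:
        raise InfeasibleParameterError("no division rate achieves the Ki67 target")
    return brentq(lambda a: kappa_of(a) - target, lo, hi, xtol=1e-14, rtol=1e-13)


def _resolve_th(spec: KineticModelSpec) -> SubpopRates:
    """TH resolution: both death rates solved from the two constraints."""
    kappa = spec.kappa_obs
    if kappa is None or not 0 < kappa < 1:
        raise InfeasibleParameterError("TH resolution requires kappa_obs in (0,1)")
    alpha, beta, khat, N = spec.alpha_fast, spec.beta, spec.khat, spec.N
    S = spec.s_week * N / 7.0
    u = khat * beta
    inflow = 2.0 * alpha * N + S
    target_H = kappa * N

    def H_of(delta_hi):
        a = u / (u + delta_hi + alpha)
        # sum h1 a^{g-1} = inflow (1-a^khat) / (D (1-a)) and D(1-a) = delta_hi+alpha
        return inflow * (1.0 - a**khat) / (delta_hi + alpha)

    H_floorless = H_of(_DELTA_LO_BRACKET)
    if H_floorless < target_H:
        raise InfeasibleParameterError(
            "division rate too low to sustain the observed Ki67-high fraction",
            violation=(target_H - H_floorless) / N,
        )
    hi = 1.0
    for _ in range(60):
        if H_of(hi) < target_H:
            break
        hi *= 2.0
    else:
        raise InfeasibleParameterError("no Ki67-high death rate matches kappa_obs")
    delta_hi = brentq(lambda d: H_of(d) - target_H, _DELTA_LO_BRACKET, hi,
                      xtol=1e-14, rtol=1e-13)
    D = u + delta_hi + alpha
    a = u / D
    h1 = inflow / D
    stages = h1 * a ** np.arange(khat)
    low = (1.0 - kappa) * N
    delta_lo = u * stages[-1] / low - alpha
    if delta_lo <= 0:
        raise InfeasibleParameterError(
            "Ki67-low balance requires a negative death rate",
            violation=-delta_lo,
        )
    return SubpopRates(
        name="single",
        alpha=alpha,
        delta_lo=delta_lo,
        delta_hi=delta_hi,
        N_p=N,
        S_p=S,
        kappa=kappa,
        stages=stages,
        low=low,
    )


def canonicalize_kh(space: StateSpace) -> StateSpace:
    """Relabel a resolved KH model so that "fast" is the faster-dividing
    subpopulation (the two-subpopulation likelihood is symmetric under
    label exchange)."""
    spec = space.spec
    if spec.structure != "KH" or len(space.subpops) != 2:
        return space
    fast, slow = space.subpops
    if fast.alpha >= slow.alpha:
        return space
    fast, slow = slow, fast
    fast = replace(fast, name="fast")
    slow = replace(slow, name="slow")
    S_total = spec.s_week * spec.N / 7.0
    new_spec = replace(
        spec,
        alpha_fast=fast.alpha,
        alpha_slow=slow.alpha,
        q_fast=fast.N_p / spec.N,
        f_slow=slow.S_p / S_total if S_total > 0 else 1.0 - spec.f_slow,
    )
    return StateSpace(spec=new_spec, subpops=[fast, slow])


def resolve_steady_state(spec: KineticModelSpec) -> StateSpace:
    """Resolve death rates (and ``alpha_slow`` when unset) so the model is
    stationary with the observed Ki67-high fraction.

    Raises :class:`InfeasibleParameterError` when no admissible rates exist;
    the fitters treat that as a rejected parameter point.
    """
    space = StateSpace(spec=spec)
    S_total = spec.s_week * spec.N / 7.0
    if spec.structure == "TH":
        space.subpops = [_resolve_th(spec)]
        return space

    N_f = spec.q_fast * spec.N
    N_s = (1.0 - spec.q_fast) * spec.N
    S_f = (1.0 - spec.f_slow) * S_total
    S_s = spec.f_slow * S_total
    fast = _subpop_from_alpha(
        "fast", spec.alpha_fast, spec.beta, spec.khat, N_f, S_f, spec.death_ratio
    )
    if spec.alpha_slow is not None:
        slow = _subpop_from_alpha(
            "slow", spec.alpha_slow, spec.beta, spec.khat, N_s, S_s, spec.death_ratio
        )
        if spec.kappa_obs is None:
            # truth-construction path: kappa_obs is an outcome
            spec = replace(spec, kappa_obs=(fast.kappa * N_f + slow.kappa * N_s) / spec.N)
            space.spec = spec
    else:
        if spec.kappa_obs is None:
            raise InfeasibleParameterError(
                "KH resolution needs kappa_obs (or an explicit alpha_slow)"
            )
        target_slow = (spec.kappa_obs * spec.N - fast.kappa * N_f) / N_s
        alpha_s = _solve_alpha_for_kappa(
            target_slow, spec.beta, spec.khat, N_s, S_s, spec.death_ratio
        )
        slow = _subpop_from_alpha(
            "slow", alpha_s, spec.beta, spec.khat, N_s, S_s, spec.death_ratio
        )
        space.spec = replace(spec, alpha_slow=alpha_s)
    space.subpops = [fast, slow]
    return space
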