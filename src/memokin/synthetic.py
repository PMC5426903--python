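"""Synthetic data generators and the stochastic agent-level oracle.

Two table types are emulated:

* chimera timecourses (per-mouse age, population, count, normalised
  chimerism) generated from the replacement ODEs with lognormal count noise
  and Gaussian chimerism noise;
* BrdU x Ki67 timecourses (per-mouse protocol, sample time, BrdU+ fraction
  per Ki67 gate) generated from the deterministic labelling model with
  Gaussian noise on the arcsine-square-root scale.

``simulate_agents`` realises the labelling model's rules as an exact
event-driven stochastic simulation of independent cells; because the model
is linear, per-cell exponential clocks are equivalent to a Gillespie
simulation of the whole population.  It is the correctness oracle for the
ODE solver.

The bundled parameter presets ("tem", "tcm") are point estimates for murine
CD4 effector and central memory under the two-subpopulation model; the
chimera presets are generator-chosen values of realistic magnitude for
young adult mice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chimera import ChimeraModelSpec, simulate_chimera
from .labelling.solve import LabellingProtocol, solve_labelling
from .labelling.spec import KineticModelSpec, StateSpace, resolve_steady_state
from .source import SourceDescriptor

__all__ = [
    "ChimeraTruth",
    "LabellingTruth",
    "generate_chimera_dataset",
    "generate_labelling_dataset",
    "simulate_agents",
    "agent_labelling_curves",
    "simulate_ki67_residence",
    "chimera_truth_preset",
    "labelling_spec_preset",
    "default_protocols",
]


# ---------------------------------------------------------------------------
# Presets


def labelling_spec_preset(subset: str = "tem") -> KineticModelSpec:
    """Reference KH parameter sets for CD4 T_EM / T_CM (loss-ratio-1)."""
    if subset.lower() == "tem":
        return KineticModelSpec(
            structure="KH", khat=12, bhat=2,
            beta=1.0 / 3.28, epsilon=0.76, tau=2.5, s_week=0.07,
            alpha_fast=1.0 / 5.7, alpha_slow=1.0 / 138.0,
            q_fast=0.38, f_slow=1.0, death_ratio=1.0,
        )
    if subset.lower() == "tcm":
        return KineticModelSpec(
            structure="KH", khat=12, bhat=2,
            beta=1.0 / 3.59, epsilon=0.77, tau=0.085, s_week=0.106,
            alpha_fast=1.0 / 3.4, alpha_slow=1.0 / 167.0,
            q_fast=0.49, f_slow=0.69, death_ratio=1.0,
        )
    raise ValueError("subset must be 'tem' or 'tcm'")


def default_protocols() -> list[LabellingProtocol]:
    """4/7/21-day feeds, each with a chase of up to 14 days."""
    return [
        LabellingProtocol(4.0, (0.0, 1, 2, 3, 4, 5, 7, 9, 11, 14, 18)),
        LabellingProtocol(7.0, (1, 2, 4, 7, 8, 10, 12, 15, 18, 21)),
        LabellingProtocol(21.0, (2, 5, 9, 14, 21, 22, 24, 27, 30, 35)),
    ]


def chimera_truth_preset(subset: str = "tem") -> "ChimeraTruth":
    source = SourceDescriptor(
        S0=1.8e7, R=0.0025, rho_max=0.92, rho_0=0.35, r=0.03, t_ref=98.0
    )
    ages = np.arange(98.0, 421.0, 28.0)
    if subset.lower() == "tem":
        M0 = 1.3e6
        spec = ChimeraModelSpec(
            gamma0=0.010 * M0 / source.S0, lam=0.01, M_inc=0.6e6,
            phi=0.0, variant="resistant",
        )
        return ChimeraTruth(source, spec, M0=M0, rho_M0=0.05,
                            ages=ages, population="TEM")
    if subset.lower() == "tcm":
        M0 = 1.5e6
        spec = ChimeraModelSpec(
            gamma0=0.015 * M0 / source.S0, lam=0.02, M_inc=0.25e6,
            phi=0.0, variant="resistant",
        )
        return ChimeraTruth(source, spec, M0=M0, rho_M0=0.10,
                            ages=ages, population="TCM")
    raise ValueError("subset must be 'tem' or 'tcm'")


# ---------------------------------------------------------------------------
# Chimera dataset


@dataclass
class ChimeraTruth:
    """Ground truth for a synthetic chimera experiment."""

    source: SourceDescriptor
    spec: ChimeraModelSpec
    M0: float
    rho_M0: float
    ages: np.ndarray
    population: str = "TEM"
    source_population: str = "naive"
    mice_per_age: int = 4
    sigma_logcount: float = 0.15  # sd on log10 counts
    sigma_chimerism: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_logcount < 0 or self.sigma_chimerism < 0:
            raise ValueError("noise sigmas must be nonnegative")


def generate_chimera_dataset(truth: ChimeraTruth, seed: int | None) -> pd.DataFrame:
    """Sample a per-mouse chimera timecourse table (source + memory rows).

    Counts receive lognormal noise (Gaussian on log10), chimerism additive
    Gaussian noise truncated at zero.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    ages = np.asarray(truth.ages, dtype=float)
    t = ages - truth.source.t_ref
    sim = simulate_chimera(truth.spec, truth.source, truth.M0, truth.rho_M0, t)
    mem_M = np.interp(t, sim["t"], sim["M"])
    mem_rho = np.interp(t, sim["t"], sim["rho_M"])
    src_S = truth.source.size(t)
    src_rho = truth.source.chimerism(t)

    rows = []
    mouse = 0
    for i, age in enumerate(ages):
        for _ in range(truth.mice_per_age):
            mouse += 1
            mid = f"m{mouse:04d}"
            for pop, count, rho in (
                (truth.source_population, src_S[i], src_rho[i]),
                (truth.population, mem_M[i], mem_rho[i]),
            ):
                c = 10 ** (np.log10(count) + rng.normal(0.0, truth.sigma_logcount)) \
                    if truth.sigma_logcount > 0 else count
                x = rho + rng.normal(0.0, truth.sigma_chimerism) \
                    if truth.sigma_chimerism > 0 else rho
                rows.append(
                    {
                        "mouse_id": mid,
                        "age_days": age,
                        "population": pop,
                        "count": c,
                        "chimerism_normalized": max(x, 0.0),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Labelling dataset


@dataclass
class LabellingTruth:
    """Ground truth for a synthetic BrdU x Ki67 experiment."""

    spec: KineticModelSpec
    protocols: list = field(default_factory=default_protocols)
    mice_per_timepoint: int = 5
    sigma: float = 0.05  # sd on the arcsine-sqrt scale

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def generate_labelling_dataset(truth: LabellingTruth, seed: int | None) -> pd.DataFrame:
    """Sample a per-mouse labelling table from the deterministic model."""
    rng = np.random.default_rng(seed)
    space = resolve_steady_state(truth.spec)
    rows = []
    mouse = 0
    for protocol in truth.protocols:
        pred = solve_labelling(space, protocol)
        for j, t in enumerate(pred.times):
            for _ in range(truth.mice_per_timepoint):
                mouse += 1
                mid = f"b{mouse:04d}"
                for gate, f in (
                    ("high", pred.frac_brdu_in_ki67high[j]),
                    ("low", pred.frac_brdu_in_ki67low[j]),
                ):
                    z = np.arcsin(np.sqrt(np.clip(f, 0.0, 1.0)))
                    if truth.sigma > 0:
                        z = z + rng.normal(0.0, truth.sigma)
                    rows.append(
                        {
                            "mouse_id": mid,
                            "feed_days": protocol.feed_days,
                            "time_days": float(t),
                            "ki67_gate": gate,
                            "frac_brdu_pos": float(
                                np.sin(np.clip(z, 0.0, np.pi / 2)) ** 2
                            ),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Agent-level stochastic oracle


def simulate_agents(
    spec: KineticModelSpec | StateSpace,
    n_cells: int,
    protocol: LabellingProtocol,
    seed: int | None,
) -> tuple[np.ndarray, np.ndarray, StateSpace]:
    """Exact stochastic simulation of the labelling model's rules.

    Every cell carries (subpopulation, Ki67 stage, BrdU class) and draws
    exponential waiting times for stage advance (rate ``khat * beta``),
    division (``alpha``) and death (``delta``); these rates are
    phase-independent, so only event *outcomes* (daughter BrdU classes,
    source label) consult the protocol clock.  Source arrivals are a
    Poisson process.  Returns ``(sample_times, counts, space)`` where
    ``counts[k, i]`` is the number of cells in state ``i`` at sample ``k``.
    """
    if n_cells < 1000:
        raise ValueError("n_cells >= 1000 required for a meaningful oracle run")
    space = spec if isinstance(spec, StateSpace) else resolve_steady_state(spec)
    mspec = space.spec
    rng = np.random.default_rng(seed)
    samples = np.asarray(protocol.sample_times, dtype=float)
    T_end = float(samples.max()) if samples.size else 0.0
    F = float(protocol.feed_days)
    label_until = F + mspec.tau
    scale = n_cells / mspec.N
    u_adv = mspec.khat * mspec.beta
    khat, bhat = mspec.khat, mspec.bhat
    n_states = space.n_states
    counts = np.zeros((samples.size, n_states), dtype=np.int64)

    # initial cells from the unlabelled equilibrium
    probs = space.equilibrium() / mspec.N
    init = rng.multinomial(n_cells, probs)
    state = np.repeat(np.arange(n_states), init)
    t0 = np.zeros(state.size)

    # pre-draw source arrivals (independent Poisson streams per subpop)
    for p, sp in enumerate(space.subpops):
        lam_src = sp.S_p * scale
        if lam_src <= 0 or T_end <= 0:
            continue
        n_arr = rng.poisson(lam_src * T_end)
        t_arr = np.sort(rng.uniform(0.0, T_end, n_arr))
        d_arr = np.where(t_arr <= label_until, 1, 0)
        state = np.concatenate(
            [state, np.array([space.index(p, 1, d) for d in d_arr], dtype=int)]
        )
        t0 = np.concatenate([t0, t_arr])

    n_cls = bhat + 1
    n_stg = khat + 1

    def decode(s):
        d = s % n_cls
        g = (s // n_cls) % n_stg
        p = s // (n_cls * n_stg)
        return p, g, d

    alpha_p = np.array([sp.alpha for sp in space.subpops])
    dlo_p = np.array([sp.delta_lo for sp in space.subpops])
    dhi_p = np.array([sp.delta_hi for sp in space.subpops])

    dilute = np.zeros(n_cls, dtype=int)
    for d in range(n_cls):
        dilute[d] = space.dilute(d)

    while state.size:
        p, g, d = decode(state)
        r_adv = np.where(g >= 1, u_adv, 0.0)
        r_die = np.where(g == 0, dlo_p[p], dhi_p[p])
        r_div = alpha_p[p]
        total = r_adv + r_die + r_div
        t1 = t0 + rng.exponential(1.0 / total)

        # snapshot accounting with the pre-event state over [t0, t1)
        for k, T in enumerate(samples):
            live = (t0 <= T) & (T < t1)
            if live.any():
                np.add.at(counts[k], state[live], 1)

        active = t1 <= T_end
        if not active.any():
            break
        p, g, d, t1 = p[active], g[active], d[active], t1[active]
        draw = rng.uniform(size=t1.size) * total[active]
        is_adv = draw < r_adv[active]
        is_die = (~is_adv) & (draw < (r_adv + r_die)[active])
        is_div = ~(is_adv | is_die)

        new_p = [p[is_adv]]
        new_g = [np.where(g[is_adv] == khat, 0, g[is_adv] + 1)]
        new_d = [d[is_adv]]
        new_t = [t1[is_adv]]

        if is_div.any():
            pd_, dd_, td_ = p[is_div], d[is_div], t1[is_div]
            feeding = td_ <= F
            uptake = feeding & (rng.uniform(size=td_.size) < mspec.epsilon)
            child_d = np.where(uptake, 1, dilute[dd_])
            # mother replaced by one daughter, second daughter appended
            for _ in range(2):
                new_p.append(pd_)
                new_g.append(np.ones(td_.size, dtype=int))
                new_d.append(child_d)
                new_t.append(td_)

        p = np.concatenate(new_p)
        g = np.concatenate(new_g)
        d = np.concatenate(new_d)
        t0 = np.concatenate(new_t)
        state = (p * n_stg + g) * n_cls + d

    if counts.sum(axis=1).min() == 0 and samples.size:
        warnings.warn("population extinct before the last sample", stacklevel=2)
    return samples, counts, space


def agent_labelling_curves(
    spec: KineticModelSpec | StateSpace,
    protocol: LabellingProtocol,
    n_cells: int = 100_000,
    n_reps: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Labelled fractions from replicate agent runs, with Monte-Carlo SEs.

    Replicates are independent simulations of ``n_cells / n_reps`` cells;
    the standard error is the across-replicate SD of the fraction divided
    by ``sqrt(n_reps)``, which correctly accounts for within-lineage
    correlation.
    """
    space = spec if isinstance(spec, StateSpace) else resolve_steady_state(spec)
    rng = np.random.default_rng(seed)
    per = max(n_cells // n_reps, 1000)
    hi = space.ki67_high_mask()
    pos = space.brdu_pos_mask()
    fhi, flo = [], []
    for _ in range(n_reps):
        _, counts, _ = simulate_agents(
            space, per, protocol, seed=int(rng.integers(2**31 - 1))
        )
        H = counts[:, hi].sum(axis=1)
        L = counts[:, ~hi].sum(axis=1)
        fhi.append(counts[:, hi & pos].sum(axis=1) / np.maximum(H, 1))
        flo.append(counts[:, ~hi & pos].sum(axis=1) / np.maximum(L, 1))
    fhi = np.array(fhi)
    flo = np.array(flo)
    return pd.DataFrame(
        {
            "time_days": np.asarray(protocol.sample_times, dtype=float),
            "frac_high": fhi.mean(axis=0),
            "se_high": fhi.std(axis=0, ddof=1) / np.sqrt(n_reps),
            "frac_low": flo.mean(axis=0),
            "se_low": flo.std(axis=0, ddof=1) / np.sqrt(n_reps),
        }
    )


def simulate_ki67_residence(
    khat: int, beta: float, n: int, seed: int | None
) -> np.ndarray:
    """Sampled total Ki67-high residence times under the staged-advance
    rule (``khat`` sequential stages at rate ``khat * beta`` each)."""
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / (khat * beta), size=(n, khat)).sum(axis=1)
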