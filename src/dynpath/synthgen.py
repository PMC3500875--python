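"""Synthetic generators with the structure the estimation modules assume.

Two families of scenarios are provided, each emitting the implied
local-independence graph alongside the data so graph-level verdicts
(delta-separation) and data-level estimates can be cross-checked:

* :class:`MediationScenario` — a survival mediation study: a baseline
  binary treatment X, an internal mediator process Z(t) updated on a
  regular measurement grid (Z = theta0 + theta1 X + subject effect +
  fresh measurement noise, carried forward between measurements), and an
  event intensity beta0 + beta1 X + beta2 Z clipped at zero.  Censoring is
  none, independent (constant rate — all processes locally independent of
  the censoring process), or mediator-dependent (rate increasing in Z — the
  classic dependent-censoring violation, used as a negative control).
  The structure emulates a treatment cohort with two coupled processes
  measured at regular visits, irregular follow-up and censoring; events are
  simulated by fine-grid Bernoulli discretization of the intensity so
  time-varying and covariate-dependent intensities are handled uniformly.

* :class:`PanelScenario` — a discrete-time coupled panel: each subject's
  variable increments are a linear function of all variables' lagged
  levels (a coupling matrix, entry (i, j) = effect of variable j's lagged
  level on variable i's increment) plus Gaussian noise, with missingness
  completely at random.  One-way coupling between a driver and a response
  (the "viral load drives immune recovery" pattern) is packaged as a
  helper with a calibrated standardized effect size.

All generators are deterministic under their scenario seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dpa import CountingProcessData
from .errors import ValidationError
from .increments import PanelData
from .ligraph import LocalIndependenceGraph
from .sdeflow import LinearSDEModel, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "MediationScenario",
    "PanelScenario",
    "gen_mediation_survival",
    "gen_coupled_panel",
    "gen_sde_panel",
    "one_way_panel_scenario",
]

RateLike = float | Callable[[float], float]


def _rate_at(r: RateLike, t: np.ndarray | float) -> np.ndarray | float:
    return r(t) if callable(r) else r


@dataclass(frozen=True)
class MediationScenario:
    """Treatment -> mediator -> event scenario (with optional censoring).

    Defaults describe a calibrated cohort: unit time horizon, mediator
    measured on a 0.1-spaced visit grid, constant hazard coefficients
    beta0 = 0.1, beta1 = 0.3, beta2 = 0.5 and mediator effect theta1 = 1.0,
    with the mediator level centered at theta0 = 0.5 and noise small enough
    that negative-intensity clipping stays negligible (< 1%).
    """

    n: int = 500
    p_treat: float = 0.5
    theta0: float = 0.5
    theta1: float = 1.0
    subject_sd: float = 0.15
    within_sd: float = 0.25
    update_step: float = 0.1
    beta0: RateLike = 0.1
    beta1: RateLike = 0.3
    beta2: RateLike = 0.5
    censoring: str = "none"  # none | independent | mediator
    censor_rate: float = 0.1
    censor_mediator_coef: float = 0.0
    end_time: float = 1.0
    sim_step: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_treat <= 1:
            raise ValidationError("p_treat must be in [0, 1]")
        if self.end_time <= 0:
            raise ValidationError("end_time must be > 0")
        if self.update_step <= 0 or self.sim_step <= 0:
            raise ValidationError("update_step and sim_step must be > 0")
        if self.censoring not in ("none", "independent", "mediator"):
            raise ValidationError(
                "censoring must be one of 'none', 'independent', 'mediator'"
            )
        if self.censor_rate < 0:
            raise ValidationError("censor_rate must be >= 0")

    def implied_graph(self) -> LocalIndependenceGraph:
        """Local-independence graph of the data-generating processes.

        X drives Z and Y; Z drives Y; the censoring process C is driven by
        nothing (independent censoring) or by Z (dependent censoring).  All
        processes are locally independent of C itself.
        """
        nodes = ["X", "Z", "Y", "C"]
        roles = {"X": "treatment", "Z": "mediator", "Y": "outcome", "C": "censoring"}
        edges = [("X", "Z"), ("X", "Y"), ("Z", "Y")]
        if self.censoring == "mediator":
            edges.append(("Z", "C"))
        return LocalIndependenceGraph(nodes, edges, roles)

    def to_dict(self) -> dict:
        out = {
            "schema": "dynpath-mediation-scenario/1",
            "kind": "mediation_survival",
        }
        for k in (
            "n", "p_treat", "theta0", "theta1", "subject_sd", "within_sd",
            "update_step", "beta0", "beta1", "beta2", "censoring", "censor_rate",
            "censor_mediator_coef", "end_time", "sim_step", "seed",
        ):
            v = getattr(self, k)
            if callable(v):
                raise ValidationError(f"cannot serialize callable rate {k!r}")
            out[k] = v
        return out

    @classmethod
    def from_dict(cls, obj: Mapping) -> "MediationScenario":
        kwargs = {k: v for k, v in obj.items() if k not in ("schema", "kind")}
        return cls(**kwargs)


def gen_mediation_survival(s: MediationScenario) -> CountingProcessData:
    """Simulate counting-process data from a mediation survival scenario.

    Per subject: draw X ~ Bernoulli(p_treat); at every visit time draw
    Z = theta0 + theta1 X + b_i + eps (b_i persistent, eps fresh), carry Z
    forward between visits; run the event clock on a fine grid with step
    ``sim_step``, each step a Bernoulli draw with probability
    1 - exp(-max(lambda, 0) * dt); apply the censoring law the same way.
    Emits one row per visit interval actually at risk, covariates constant
    on the interval (LOCF), with the fraction of clipped intensity
    evaluations recorded in ``meta['clip_fraction']``.
    """
    rng = np.random.default_rng(s.seed)
    n = s.n
    X = rng.binomial(1, s.p_treat, n).astype(float)
    b = rng.normal(0.0, s.subject_sd, n)

    # All clocks run in integer units of sim_step so interval boundaries,
    # event times and visit times compare exactly.  Visit times are snapped
    # to the simulation grid.
    n_steps = int(round(s.end_time / s.sim_step))
    visit_steps = np.unique(
        np.round(
            np.arange(0.0, s.end_time - 1e-12, s.update_step) / s.sim_step
        ).astype(int)
    )
    n_visits = visit_steps.size
    Z = (
        s.theta0
        + s.theta1 * X[:, None]
        + b[:, None]
        + rng.normal(0.0, s.within_sd, (n, n_visits))
    )
    # visit index active at fine step k (left endpoint)
    visit_idx = np.searchsorted(visit_steps, np.arange(n_steps), side="right") - 1

    event_step = np.full(n, n_steps + 1, dtype=int)  # right endpoint, 1-based
    censor_step = np.full(n, n_steps + 1, dtype=int)
    alive = np.ones(n, dtype=bool)
    clipped = 0
    evaluated = 0
    for k in range(n_steps):
        if not alive.any():
            break
        t = k * s.sim_step
        z_now = Z[alive, visit_idx[k]]
        lam = (
            _rate_at(s.beta0, t)
            + _rate_at(s.beta1, t) * X[alive]
            + _rate_at(s.beta2, t) * z_now
        )
        evaluated += lam.size
        clipped += int(np.count_nonzero(lam < 0))
        lam = np.clip(lam, 0.0, None)
        u = rng.random(lam.size)
        hit = u < -np.expm1(-lam * s.sim_step)

        if s.censoring == "none":
            chit = np.zeros(lam.size, dtype=bool)
        else:
            crate = s.censor_rate
            if s.censoring == "mediator":
                crate = np.clip(crate + s.censor_mediator_coef * z_now, 0.0, None)
            cu = rng.random(lam.size)
            chit = cu < -np.expm1(-crate * s.sim_step)

        idx = np.flatnonzero(alive)
        # event takes precedence over censoring within the same step
        event_step[idx[hit]] = k + 1
        censor_step[idx[chit & ~hit]] = k + 1
        alive[idx[hit | chit]] = False

    clip_fraction = clipped / max(evaluated, 1)
    if clip_fraction > 0.01:
        logger.warning(
            "mediation scenario: %.2f%% of intensity evaluations clipped at zero",
            100 * clip_fraction,
        )

    T_step = np.minimum(np.minimum(event_step, censor_step), n_steps)
    had_event = event_step <= np.minimum(censor_step, n_steps)
    if not had_event.any():
        logger.warning("mediation scenario produced no events (hazard all zero?)")

    # counting-process rows at visit boundaries, last interval truncated at T
    rows_id, rows_start, rows_stop, rows_event, rows_x, rows_z = [], [], [], [], [], []
    for i in range(n):
        t_i = int(T_step[i])
        for v in range(n_visits):
            a = int(visit_steps[v])
            if a >= t_i:
                break
            bnd = int(visit_steps[v + 1]) if v + 1 < n_visits else n_steps
            stop = min(bnd, t_i)
            rows_id.append(i)
            rows_start.append(a * s.sim_step)
            rows_stop.append(stop * s.sim_step)
            rows_event.append(int(had_event[i] and stop == t_i))
            rows_x.append(X[i])
            rows_z.append(Z[i, v])
    table = pd.DataFrame(
        {
            "id": rows_id,
            "start": rows_start,
            "stop": rows_stop,
            "event": rows_event,
            "X": rows_x,
            "Z": rows_z,
        }
    )
    meta = {
        "scenario": "mediation_survival",
        "seed": s.seed,
        "clip_fraction": clip_fraction,
        "n_events": int(had_event.sum()),
        "n_censored": int((censor_step < np.minimum(event_step, n_steps + 1)).sum()),
        "graph": s.implied_graph(),
    }
    return CountingProcessData(table, meta=meta)


@dataclass(frozen=True)
class PanelScenario:
    """Coupled discrete-time panel scenario.

    ``coupling[i, j]`` is the effect of variable j's lagged level on
    variable i's increment:  V(t) = V(t-1) + coupling @ V(t-1) + noise.
    """

    n: int = 200
    times: tuple[float, ...] = tuple(float(t) for t in range(15))
    variables: tuple[str, ...] = ("RNA", "CD4")
    coupling: tuple[tuple[float, ...], ...] = ((0.0, 0.0), (0.0, 0.0))
    noise_sd: tuple[float, ...] = (1.0, 1.0)
    init_mean: tuple[float, ...] = (0.0, 0.0)
    init_sd: tuple[float, ...] = (1.0, 1.0)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        k = len(self.variables)
        C = np.asarray(self.coupling, dtype=float)
        if len(self.times) < 3:
            raise ValidationError("panel scenario needs >= 3 time points")
        if np.any(np.diff(np.asarray(self.times)) <= 0):
            raise ValidationError("times must be strictly increasing")
        if C.shape != (k, k):
            raise ValidationError(f"coupling must be {k}x{k}")
        for name in ("noise_sd", "init_mean", "init_sd"):
            if len(getattr(self, name)) != k:
                raise ValidationError(f"{name} must have one entry per variable")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")

    def coupling_matrix(self) -> np.ndarray:
        return np.asarray(self.coupling, dtype=float)

    def implied_graph(self) -> LocalIndependenceGraph:
        """Edge j -> i iff coupling[i, j] != 0 off the diagonal."""
        C = self.coupling_matrix()
        edges = [
            (self.variables[j], self.variables[i])
            for i in range(C.shape[0])
            for j in range(C.shape[1])
            if i != j and C[i, j] != 0.0
        ]
        return LocalIndependenceGraph(self.variables, edges)

    def to_dict(self) -> dict:
        return {
            "schema": "dynpath-panel-scenario/1",
            "kind": "coupled_panel",
            "n": self.n,
            "times": list(self.times),
            "variables": list(self.variables),
            "coupling": [list(r) for r in self.coupling],
            "noise_sd": list(self.noise_sd),
            "init_mean": list(self.init_mean),
            "init_sd": list(self.init_sd),
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, obj: Mapping) -> "PanelScenario":
        kwargs = {k: v for k, v in obj.items() if k not in ("schema", "kind")}
        for k in ("times", "variables", "noise_sd", "init_mean", "init_sd"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        if "coupling" in kwargs:
            kwargs["coupling"] = tuple(tuple(r) for r in kwargs["coupling"])
        return cls(**kwargs)


def one_way_panel_scenario(
    n: int = 200,
    n_times: int = 15,
    effect: float = 0.5,
    driver_reversion: float = 0.3,
    response_reversion: float = 0.3,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> PanelScenario:
    """One-way coupled two-variable scenario at a given standardized effect.

    The driver (RNA) is a stationary AR process (mean reversion
    ``driver_reversion``); the response (CD4) increments load on the
    driver's lagged level with coefficient chosen so that
    coef * sd(driver) / noise_sd(response) = ``effect`` at stationarity.
    The reverse direction carries no coupling, so a local-dependence test
    from CD4 to RNA probes a true null.
    """
    rho = 1.0 - driver_reversion
    sd_driver = 1.0 / np.sqrt(1.0 - rho**2)
    c = effect / sd_driver
    return PanelScenario(
        n=n,
        times=tuple(float(t) for t in range(n_times)),
        variables=("RNA", "CD4"),
        coupling=((-driver_reversion, 0.0), (c, -response_reversion)),
        noise_sd=(1.0, 1.0),
        init_mean=(0.0, 0.0),
        init_sd=(sd_driver, sd_driver),
        missing_rate=missing_rate,
        seed=seed,
    )


def gen_coupled_panel(s: PanelScenario) -> PanelData:
    """Simulate a coupled panel; missingness completely at random."""
    rng = np.random.default_rng(s.seed)
    k = len(s.variables)
    n_times = len(s.times)
    C = s.coupling_matrix()
    noise_sd = np.asarray(s.noise_sd)
    values = np.empty((s.n, n_times, k))
    values[:, 0, :] = np.asarray(s.init_mean) + rng.standard_normal(
        (s.n, k)
    ) * np.asarray(s.init_sd)
    for t in range(1, n_times):
        prev = values[:, t - 1, :]
        values[:, t, :] = prev + prev @ C.T + rng.standard_normal((s.n, k)) * noise_sd
    if s.missing_rate > 0:
        mask = rng.random((s.n, n_times, k)) < s.missing_rate
        values = values.copy()
        values[mask] = np.nan
    meta = {
        "scenario": "coupled_panel",
        "seed": s.seed,
        "graph": s.implied_graph(),
    }
    return PanelData(range(s.n), s.times, s.variables, values, meta=meta)


def gen_sde_panel(
    model: LinearSDEModel,
    n: int,
    times: Sequence[float],
    x0: Sequence[float] | None = None,
    obs_noise_sd: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> PanelData:
    """Panel of n independent trajectories of a linear SDE model, with
    observation noise and completely-at-random missingness on top."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= missing_rate < 1:
        raise ValidationError("missing_rate must be in [0, 1)")
    if obs_noise_sd < 0:
        raise ValidationError("obs_noise_sd must be >= 0")
    if x0 is None:
        x0 = np.zeros(model.p)
    ens = simulate(model, x0, times, n_paths=n, seed=seed)
    values = ens.states.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    if obs_noise_sd > 0:
        values = values + rng.normal(0.0, obs_noise_sd, values.shape)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan
    meta = {"scenario": "sde_panel", "seed": seed}
    return PanelData(range(n), ens.times, model.labels, values, meta=meta)
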