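"""Dynamic path analysis for event-history data.

The outcome is a counting process N(t) (single-event survival by default)
whose intensity, given the past, follows an additive hazard model

    lambda(t) = beta_0(t) + beta_1(t) X + beta_2(t) Z(t),

with treatment X and an internal, intermittently measured mediator Z(t)
carried forward as a step function.  At every event time the increment of
the cumulative coefficients B(t) = integral of beta is estimated by least
squares of the event-indicator vector on the at-risk design matrix, and the
increments are added up into cumulative regression functions.  In parallel,
the mediator is regressed on its graph parents (intercept, treatment, any
extra covariates) by ordinary least squares over the at-risk set at each
event time, giving time-varying path coefficients theta(t).

The mediation decomposition combines the two layers:

    direct(t)   = cumulative treatment coefficient, full model (X and Z),
    indirect(t) = sum over event times t_k <= t of theta_1(t_k) dB_Z(t_k),
    total(t)    = cumulative treatment coefficient, marginal model (X only).

When no event time is skipped the three curves satisfy
total = direct + indirect *exactly* at every event time: per event time it
is the in-sample nested least-squares identity (the marginal slope equals
the direct slope plus mediator-on-treatment slope times mediator slope on
the shared at-risk sample).  Skipped times (singular designs) break the
shared-sample premise, so the fit then flags the identity as approximate
instead of papering over it with generalized inverses.

At-risk convention: an interval (start, stop] contains t iff
start < t <= stop, and an event is attributed to its stop time.  Tied event
times are processed once with a multi-event indicator vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyFitError, ValidationError

logger = logging.getLogger(__name__)

#: relative eigenvalue threshold under which a per-time design is singular
SINGULAR_RTOL = 1e-10
#: tolerance for per-subject interval contiguity
CONTIGUITY_TOL = 1e-9

INTERCEPT = "intercept"

__all__ = [
    "CountingProcessData",
    "AdditiveHazardFit",
    "MediatorSeries",
    "DynamicPathFit",
    "fit_additive_hazard",
    "fit_mediator_series",
    "fit_dynamic_path",
    "bootstrap_bands",
]


@dataclass(frozen=True)
class CountingProcessData:
    """Start/stop/event rows with interval-constant covariates.

    ``table`` must carry columns id, start, stop, event plus covariates.
    Rows are normalized to (id, start) order; per subject the intervals must
    be non-overlapping, contiguous, and carry an event only on the last one.
    """

    table: pd.DataFrame
    covariates: tuple[str, ...] = ()
    meta: Mapping = field(default_factory=dict, compare=False)

    REQUIRED = ("id", "start", "stop", "event")

    def __init__(self, table: pd.DataFrame, meta: Mapping | None = None) -> None:
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValidationError(f"missing required column(s): {missing}")
        table = table.copy()
        table["start"] = table["start"].astype(float)
        table["stop"] = table["stop"].astype(float)
        table["event"] = table["event"].astype(int)
        if not table["event"].isin((0, 1)).all():
            raise ValidationError("event column must be 0/1")
        table = table.sort_values(["id", "start"], kind="mergesort").reset_index(drop=True)

        starts = table["start"].to_numpy()
        stops = table["stop"].to_numpy()
        events = table["event"].to_numpy()
        ids = table["id"].to_numpy()
        bad = np.flatnonzero(starts >= stops)
        if len(bad):
            raise ValidationError(
                f"start must be < stop; offending row index(es): {list(bad[:10])}"
            )
        if len(table) > 1:
            same = ids[1:] == ids[:-1]
            gap = np.abs(starts[1:] - stops[:-1]) > CONTIGUITY_TOL
            bad = np.flatnonzero(same & gap)
            if len(bad):
                raise ValidationError(
                    f"subject {ids[bad[0]]!r}: intervals must be contiguous and "
                    f"non-overlapping (row index {bad[0] + 1})"
                )
            bad = np.flatnonzero(same & (events[:-1] == 1))
            if len(bad):
                raise ValidationError(
                    f"subject {ids[bad[0]]!r}: event allowed only on the last interval"
                )
        covs = tuple(c for c in table.columns if c not in self.REQUIRED)
        object.__setattr__(self, "table", table)
        object.__setattr__(self, "covariates", covs)
        object.__setattr__(self, "meta", dict(meta or {}))

    @property
    def n_subjects(self) -> int:
        return self.table["id"].nunique()

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())

    def subject_ids(self) -> np.ndarray:
        return self.table["id"].unique()

    def resample_subjects(self, ids: Sequence) -> "CountingProcessData":
        """Bootstrap helper: dataset of the given subjects, drawn with
        replacement, each draw re-keyed to a fresh subject id."""
        pos = self.table.groupby("id", sort=False).indices
        rows = [pos[s] for s in ids]
        counts = [len(r) for r in rows]
        out = self.table.iloc[np.concatenate(rows)].copy()
        out["id"] = np.repeat(np.arange(len(ids)), counts)
        return CountingProcessData(out.reset_index(drop=True))


@dataclass(frozen=True)
class AdditiveHazardFit:
    """Per-event-time least-squares increments and their cumulative curves.

    ``increments[k]`` solves the at-risk least squares at ``event_times[k]``;
    ``cumulative`` is its running sum; ``cov_increments[k]`` the sandwich
    covariance of increment k.  ``skipped_times`` lists event times dropped
    for singular designs, with ``skipped_event_fraction`` the share of
    events occurring at them.
    """

    terms: tuple[str, ...]
    event_times: np.ndarray
    increments: np.ndarray
    cumulative: np.ndarray
    cov_increments: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    skipped_times: tuple[float, ...]
    skipped_event_fraction: float
    residual_increments: tuple = field(default=(), repr=False, compare=False)

    def term_index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise ValidationError(f"unknown term {term!r}; have {self.terms}") from None

    def cumulative_at(self, times: Sequence[float], term: str) -> np.ndarray:
        """Step-function (last value carried forward) evaluation; 0 before
        the first fitted event time."""
        j = self.term_index(term)
        return _locf(self.event_times, self.cumulative[:, j], np.asarray(times, float))

    def variance_cumulative(self) -> np.ndarray:
        """Running sum of per-increment variances (diagonal), per term."""
        return np.cumsum(np.diagonal(self.cov_increments, axis1=1, axis2=2), axis=0)

    def to_frame(self) -> pd.DataFrame:
        var = np.diagonal(self.cov_increments, axis1=1, axis2=2)
        rows = []
        for j, term in enumerate(self.terms):
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.event_times,
                        "term": term,
                        "coefficient": self.increments[:, j],
                        "cumulative": self.cumulative[:, j],
                        "variance": var[:, j],
                        "at_risk": self.at_risk,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class MediatorSeries:
    """Per-event-time OLS of the mediator's current value on its parents."""

    response: str
    terms: tuple[str, ...]
    times: np.ndarray
    coef: np.ndarray
    se: np.ndarray
    at_risk: np.ndarray
    skipped_times: tuple[float, ...]

    def term_index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise ValidationError(f"unknown term {term!r}; have {self.terms}") from None


@dataclass(frozen=True)
class DynamicPathFit:
    """Cumulative direct/indirect/total decomposition at event times.

    ``identity_approximate`` is True when some event time was skipped in one
    underlying fit but not another, in which case total - direct - indirect
    is no longer an algebraic identity; ``identity_gap`` reports it either
    way.
    """

    event_times: np.ndarray
    direct: np.ndarray
    indirect: np.ndarray
    total: np.ndarray
    identity_gap: np.ndarray
    identity_approximate: bool
    theta: MediatorSeries
    full_fit: AdditiveHazardFit
    marginal_fit: AdditiveHazardFit
    treatment: str
    mediator: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "direct": self.direct,
                "indirect": self.indirect,
                "total": self.total,
                "identity_gap": self.identity_gap,
            }
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _locf(step_times: np.ndarray, step_values: np.ndarray, at: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(step_times, at, side="right") - 1
    out = np.zeros(at.shape, dtype=float)
    ok = idx >= 0
    out[ok] = step_values[idx[ok]]
    return out


def _design_columns(
    data: CountingProcessData, regressors: Sequence[str], intercept: bool
) -> tuple[tuple[str, ...], np.ndarray]:
    for r in regressors:
        if r not in data.covariates:
            raise ValidationError(
                f"regressor {r!r} not among covariates {data.covariates}"
            )
    tbl = data.table
    cols = [np.ones(len(tbl))] if intercept else []
    names = [INTERCEPT] if intercept else []
    for r in regressors:
        cols.append(tbl[r].to_numpy(dtype=float))
        names.append(r)
    if not cols:
        raise ValidationError("empty design: no intercept and no regressors")
    return tuple(names), np.column_stack(cols)


def _solve_ls(Z: np.ndarray, y: np.ndarray):
    """Least squares with explicit singularity detection.

    Returns (beta, gram_inverse) or None when the Gram matrix is
    numerically singular (no silent pseudo-inverse).
    """
    G = Z.T @ Z
    w = np.linalg.eigvalsh(G)
    if w[0] <= SINGULAR_RTOL * max(w[-1], 1.0):
        return None
    Ginv = np.linalg.inv(G)
    return Ginv @ (Z.T @ y), Ginv


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fit_additive_hazard(
    data: CountingProcessData,
    regressors: Sequence[str] = (),
    intercept: bool = True,
    keep_residuals: bool = False,
) -> AdditiveHazardFit:
    """Aalen additive hazard fit: least-squares increment at each event time.

    At each distinct event time the increment vector solves the least
    squares of the event indicator on the at-risk design (interval
    (start, stop] contains t iff start < t <= stop); increments accumulate
    into step-function cumulative regression functions.  Covariance
    increments use the standard least-squares sandwich with the event
    indicator as the squared-residual proxy.  Singular designs are skipped
    and logged, never pseudo-inverted.
    """
    if data.n_events == 0:
        raise EmptyFitError("no events in the data; nothing to fit")
    names, X = _design_columns(data, regressors, intercept)
    tbl = data.table
    start = tbl["start"].to_numpy()
    stop = tbl["stop"].to_numpy()
    event = tbl["event"].to_numpy()
    ids = tbl["id"].to_numpy()

    event_times = np.unique(stop[event == 1])
    q = X.shape[1]

    kept, incs, covs, risks, nevents, resids = [], [], [], [], [], []
    skipped: list[float] = []
    skipped_events = 0
    for t in event_times:
        at_risk = (start < t) & (t <= stop)
        Z = X[at_risk]
        dN = (event[at_risk] == 1) & (stop[at_risk] == t)
        dN = dN.astype(float)
        sol = None
        if Z.shape[0] >= q:
            sol = _solve_ls(Z, dN)
        if sol is None:
            skipped.append(float(t))
            skipped_events += int(dN.sum())
            logger.warning(
                "additive hazard: singular design at t=%g (at risk=%d); increment skipped",
                t,
                Z.shape[0],
            )
            continue
        beta, Ginv = sol
        Zd = Z[dN == 1.0]
        cov = Ginv @ (Zd.T @ Zd) @ Ginv
        kept.append(float(t))
        incs.append(beta)
        covs.append(cov)
        risks.append(int(Z.shape[0]))
        nevents.append(int(dN.sum()))
        if keep_residuals:
            resids.append((float(t), ids[at_risk], dN - Z @ beta))

    if not kept:
        raise EmptyFitError("all event times skipped (singular designs throughout)")
    increments = np.vstack(incs)
    return AdditiveHazardFit(
        terms=names,
        event_times=np.asarray(kept),
        increments=increments,
        cumulative=np.cumsum(increments, axis=0),
        cov_increments=np.stack(covs),
        at_risk=np.asarray(risks),
        n_events=np.asarray(nevents),
        skipped_times=tuple(skipped),
        skipped_event_fraction=skipped_events / data.n_events,
        residual_increments=tuple(resids),
    )


def fit_mediator_series(
    data: CountingProcessData,
    mediator: str,
    regressors: Sequence[str] = (),
    at_times: Sequence[float] | None = None,
) -> MediatorSeries:
    """OLS of the mediator's current value on intercept + regressors over
    the at-risk set at each requested time (defaults to the event times)."""
    if mediator not in data.covariates:
        raise ValidationError(f"mediator {mediator!r} not among covariates")
    names, X = _design_columns(data, regressors, intercept=True)
    tbl = data.table
    start = tbl["start"].to_numpy()
    stop = tbl["stop"].to_numpy()
    z = tbl[mediator].to_numpy(dtype=float)
    if at_times is None:
        at_times = np.unique(stop[tbl["event"].to_numpy() == 1])
    at_times = np.asarray(at_times, dtype=float)
    if at_times.size == 0:
        raise ValidationError("at_times must be nonempty")

    q = X.shape[1]
    kept, coefs, ses, risks = [], [], [], []
    skipped: list[float] = []
    for t in at_times:
        at_risk = (start < t) & (t <= stop)
        Z = X[at_risk]
        y = z[at_risk]
        r = Z.shape[0]
        sol = None
        if r >= q:
            sol = _solve_ls(Z, y)
        if sol is None:
            skipped.append(float(t))
            logger.warning(
                "mediator regression at t=%g skipped (at risk=%d, params=%d)", t, r, q
            )
            continue
        beta, Ginv = sol
        resid = y - Z @ beta
        dof = r - q
        sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
        kept.append(float(t))
        coefs.append(beta)
        ses.append(np.sqrt(sigma2 * np.diag(Ginv)))
        risks.append(r)

    if not kept:
        raise EmptyFitError("no time point admitted a mediator regression")
    return MediatorSeries(
        response=mediator,
        terms=names,
        times=np.asarray(kept),
        coef=np.vstack(coefs),
        se=np.vstack(ses),
        at_risk=np.asarray(risks),
        skipped_times=tuple(skipped),
    )


def fit_dynamic_path(
    data: CountingProcessData,
    treatment: str,
    mediator: str,
    extra: Sequence[str] = (),
) -> DynamicPathFit:
    """Full dynamic path analysis with the treatment -> mediator -> outcome
    diagram (plus optional extra parent covariates of both).

    Runs (i) the full additive fit on {intercept, treatment, mediator,
    extra}, (ii) the marginal additive fit on {intercept, treatment, extra},
    (iii) mediator regressions on {intercept, treatment, extra} at the event
    times, and assembles direct/indirect/total cumulative curves.
    """
    extra = tuple(extra)
    full = fit_additive_hazard(data, (treatment, mediator) + extra)
    marginal = fit_additive_hazard(data, (treatment,) + extra)
    theta = fit_mediator_series(data, mediator, (treatment,) + extra)

    all_skips = set(full.skipped_times) | set(marginal.skipped_times) | set(
        theta.skipped_times
    )
    approximate = bool(all_skips)
    if approximate:
        logger.warning(
            "dynamic path fit: %d event time(s) skipped in at least one layer; "
            "total = direct + indirect holds only approximately",
            len(all_skips),
        )

    # event times fitted by all three layers
    common = np.intersect1d(np.intersect1d(full.event_times, marginal.event_times), theta.times)
    if common.size == 0:
        raise EmptyFitError("no event time was fitted by all three regressions")

    jt_full = full.term_index(treatment)
    jm_full = full.term_index(mediator)
    jt_marg = marginal.term_index(treatment)
    jx_theta = theta.term_index(treatment)

    if not approximate:
        # aligned arrays; exact algebra
        direct = full.cumulative[:, jt_full]
        db_med = full.increments[:, jm_full]
        theta1 = theta.coef[:, jx_theta]
        indirect = np.cumsum(theta1 * db_med)
        total = marginal.cumulative[:, jt_marg]
        times = full.event_times
    else:
        times = common
        direct = full.cumulative_at(times, treatment)
        db_med = full.increments[np.isin(full.event_times, times), jm_full]
        theta1 = theta.coef[np.isin(theta.times, times), jx_theta]
        indirect = np.cumsum(theta1 * db_med)
        total = marginal.cumulative_at(times, treatment)

    gap = total - direct - indirect
    return DynamicPathFit(
        event_times=times,
        direct=direct,
        indirect=indirect,
        total=total,
        identity_gap=gap,
        identity_approximate=approximate,
        theta=theta,
        full_fit=full,
        marginal_fit=marginal,
        treatment=treatment,
        mediator=mediator,
    )


def bootstrap_bands(
    data: CountingProcessData,
    treatment: str,
    mediator: str,
    extra: Sequence[str] = (),
    n_boot: int = 200,
    level: float = 0.95,
    seed: int = 0,
    resample_fn=None,
) -> dict:
    """Pointwise percentile bootstrap bands for the decomposition curves.

    Subjects are resampled with replacement; each replicate's curves are
    evaluated at the original fit's event times by last-value-carried-
    forward, and pointwise percentile bands at the given coverage level are
    taken.  Replicates whose resample contains no event are dropped and
    counted.  ``resample_fn(rng, ids) -> ids`` can override the resampling
    rule (used for degenerate-identity checks).
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    base = fit_dynamic_path(data, treatment, mediator, extra)
    times = base.event_times
    ids = data.subject_ids()
    rng = np.random.default_rng(seed)

    curves = {"direct": [], "indirect": [], "total": []}
    dropped = 0
    for _ in range(n_boot):
        if resample_fn is not None:
            sample = resample_fn(rng, ids)
        else:
            sample = rng.choice(ids, size=len(ids), replace=True)
        boot = data.resample_subjects(sample)
        if boot.n_events == 0:
            dropped += 1
            continue
        try:
            fit = fit_dynamic_path(boot, treatment, mediator, extra)
        except EmptyFitError:
            dropped += 1
            continue
        for name, vals in (
            ("direct", fit.direct),
            ("indirect", fit.indirect),
            ("total", fit.total),
        ):
            curves[name].append(_locf(fit.event_times, vals, times))

    if not curves["direct"]:
        raise EmptyFitError("every bootstrap replicate was dropped")
    alpha = (1.0 - level) / 2.0
    out = {"times": times, "n_dropped": dropped, "point": {
        "direct": base.direct, "indirect": base.indirect, "total": base.total}}
    for name, reps in curves.items():
        arr = np.vstack(reps)
        out[name] = (
            np.quantile(arr, alpha, axis=0),
            np.quantile(arr, 1.0 - alpha, axis=0),
        )
    return out
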