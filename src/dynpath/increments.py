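"""Linear increment models for longitudinal panels.

For processes measured at common discrete times, the time-discrete analogue
of a drift is the conditional expectation of an increment given the past.
The linear increment model regresses, at every time point and across
subjects,

    Delta Y(t) = Y(t) - Y(t-1)  on  intercept + X(t - lag) (+ adjusters),

by ordinary least squares on the complete cases at that time.  A nonzero
coefficient series for X means Y is locally dependent on X; the converse
regression probes the opposite direction, so one-way ("Granger-like")
coupling shows up as a significant series in one direction and a null
series in the other.

The per-time coefficient series can be summed into cumulative coefficient
curves (step functions, variances accumulated assuming independence across
times), and aggregated into a formal local-dependence test: the statistic
is the sum over fitted times of the squared standardized coefficients,
referred either to a chi-squared law with one degree of freedom per fitted
time, or to a permutation law obtained by permuting the candidate driver's
whole trajectory across subjects (which preserves each subject's own
trajectory and the response's autocorrelation, and is the safer reference
because the per-time fits share subjects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyFitError, ValidationError

logger = logging.getLogger(__name__)

SINGULAR_RTOL = 1e-10

__all__ = [
    "PanelData",
    "IncrementFitSeries",
    "LocalDependenceTest",
    "fit_increment_series",
    "cumulative_coefficients",
    "test_local_dependence",
]


@dataclass(frozen=True)
class PanelData:
    """Subjects x common discrete times x variables, NaN = missing.

    ``values`` has shape (n_subjects, n_times, n_variables).  Times must be
    strictly increasing with at least 2 points, and each variable must be
    observed for at least one subject at two consecutive times (otherwise
    no increment involving it is ever estimable).
    """

    subjects: tuple
    times: np.ndarray
    variables: tuple[str, ...]
    values: np.ndarray
    meta: Mapping = field(default_factory=dict, compare=False)

    def __init__(
        self,
        subjects: Iterable,
        times: Sequence[float],
        variables: Iterable[str],
        values: np.ndarray,
        meta: Mapping | None = None,
    ) -> None:
        subjects = tuple(subjects)
        times = np.asarray(times, dtype=float)
        variables = tuple(str(v) for v in variables)
        values = np.asarray(values, dtype=float)
        if len(set(subjects)) != len(subjects):
            raise ValidationError("subject ids must be unique")
        if len(set(variables)) != len(variables):
            raise ValidationError("variable names must be unique")
        if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing with >= 2 points")
        if values.shape != (len(subjects), times.size, len(variables)):
            raise ValidationError(
                f"values shape {values.shape} != "
                f"({len(subjects)}, {times.size}, {len(variables)})"
            )
        obs = ~np.isnan(values)
        for j, var in enumerate(variables):
            consec = obs[:, :-1, j] & obs[:, 1:, j]
            if not consec.any():
                raise ValidationError(
                    f"variable {var!r} is never observed at 2 consecutive times"
                )
        object.__setattr__(self, "subjects", subjects)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "variables", variables)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "meta", dict(meta or {}))

    def var_index(self, name: str) -> int:
        try:
            return self.variables.index(str(name))
        except ValueError:
            raise ValidationError(
                f"unknown variable {name!r}; have {self.variables}"
            ) from None

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_frame(self, layout: str = "wide") -> pd.DataFrame:
        n, k, _ = self.values.shape
        wide = pd.DataFrame(
            {
                "id": np.repeat(np.asarray(self.subjects, dtype=object), k),
                "time": np.tile(self.times, n),
            }
        )
        for j, var in enumerate(self.variables):
            wide[var] = self.values[:, :, j].reshape(-1)
        if layout == "wide":
            return wide
        if layout == "long":
            long = wide.melt(
                id_vars=["id", "time"], var_name="variable", value_name="value"
            )
            return long.dropna(subset=["value"]).reset_index(drop=True)
        raise ValidationError(f"layout must be 'wide' or 'long', got {layout!r}")

    @classmethod
    def from_frame(cls, wide: pd.DataFrame, meta: Mapping | None = None) -> "PanelData":
        for c in ("id", "time"):
            if c not in wide.columns:
                raise ValidationError(f"panel frame must have column {c!r}")
        variables = [c for c in wide.columns if c not in ("id", "time")]
        if not variables:
            raise ValidationError("panel frame has no variable columns")
        if wide.duplicated(["id", "time"]).any():
            raise ValidationError("duplicate (id, time) rows in panel frame")
        subjects = list(pd.unique(wide["id"]))
        times = np.sort(wide["time"].unique().astype(float))
        sid_pos = {s: i for i, s in enumerate(subjects)}
        t_pos = {t: i for i, t in enumerate(times)}
        values = np.full((len(subjects), len(times), len(variables)), np.nan)
        si = wide["id"].map(sid_pos).to_numpy()
        ti = wide["time"].astype(float).map(t_pos).to_numpy()
        for j, var in enumerate(variables):
            values[si, ti, j] = wide[var].to_numpy(dtype=float)
        return cls(subjects, times, variables, values, meta=meta)


@dataclass(frozen=True)
class IncrementFitSeries:
    """Per-time OLS of response increments on lagged predictor levels."""

    response: str
    predictors: tuple[str, ...]
    terms: tuple[str, ...]
    times: np.ndarray
    coef: np.ndarray
    se: np.ndarray
    n_complete: np.ndarray
    skipped_times: tuple[float, ...]
    lag: int

    def term_index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise ValidationError(f"unknown term {term!r}; have {self.terms}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, term in enumerate(self.terms):
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "term": term,
                        "coefficient": self.coef[:, j],
                        "se": self.se[:, j],
                        "n": self.n_complete,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class LocalDependenceTest:
    """Direction-specific test of local dependence in a panel.

    ``statistic`` is the sum of squared standardized per-time coefficients
    of the candidate driver; the per-time contributions are retained for
    inspection.
    """

    from_var: str
    to_var: str
    statistic: float
    df: int
    p_value: float
    method: str
    contributions: np.ndarray
    times: np.ndarray
    n_perm: int | None = None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _series_from_arrays(
    times: np.ndarray,
    dY: np.ndarray,
    lagged: np.ndarray,
    response: str,
    predictors: tuple[str, ...],
    lag: int,
    start_k: int,
    quiet: bool = False,
) -> IncrementFitSeries:
    """Shared per-time OLS loop over precomputed increment/lag arrays.

    ``dY[:, k]`` and ``lagged[:, k, :]`` are aligned with time index
    ``start_k + k`` of ``times``.
    """
    q = 1 + lagged.shape[2]
    kept, coefs, ses, ns = [], [], [], []
    skipped: list[float] = []
    n_fit_times = dY.shape[1]
    for k in range(n_fit_times):
        y = dY[:, k]
        X = lagged[:, k, :]
        ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
        n = int(ok.sum())
        t = float(times[start_k + k])
        if n < q:
            skipped.append(t)
            if not quiet:
                logger.warning(
                    "increment fit at t=%g skipped: %d complete cases < %d params",
                    t, n, q,
                )
            continue
        Z = np.column_stack([np.ones(n), X[ok]])
        yk = y[ok]
        G = Z.T @ Z
        w = np.linalg.eigvalsh(G)
        if w[0] <= SINGULAR_RTOL * max(w[-1], 1.0):
            skipped.append(t)
            if not quiet:
                logger.warning("increment fit at t=%g skipped: singular design", t)
            continue
        Ginv = np.linalg.inv(G)
        beta = Ginv @ (Z.T @ yk)
        resid = yk - Z @ beta
        dof = n - q
        sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
        kept.append(t)
        coefs.append(beta)
        ses.append(np.sqrt(sigma2 * np.diag(Ginv)))
        ns.append(n)
    if not kept:
        raise EmptyFitError("no time point admitted an increment regression")
    return IncrementFitSeries(
        response=response,
        predictors=predictors,
        terms=("intercept",) + predictors,
        times=np.asarray(kept),
        coef=np.vstack(coefs),
        se=np.vstack(ses),
        n_complete=np.asarray(ns),
        skipped_times=tuple(skipped),
        lag=lag,
    )


def _increment_arrays(
    panel: PanelData, response: str, predictors: Sequence[str], lag: int
):
    """Increments of the response and lagged predictor levels, aligned.

    The response increment is always the lag-1 difference Y(t_k)-Y(t_{k-1});
    predictors enter at t_{k-lag} (lag in grid steps).  The first fittable
    time index is max(1, lag).
    """
    jr = panel.var_index(response)
    jp = [panel.var_index(p) for p in predictors]
    start_k = max(1, lag)
    k_idx = np.arange(start_k, panel.times.size)
    Y = panel.values[:, :, jr]
    dY = Y[:, k_idx] - Y[:, k_idx - 1]
    lagged = panel.values[:, :, jp][:, k_idx - lag, :]
    return dY, lagged, start_k


def fit_increment_series(
    panel: PanelData,
    response: str,
    predictors: Sequence[str],
    lag: int = 1,
) -> IncrementFitSeries:
    """Per-time OLS of response increments on lagged predictor levels.

    At each time t_k (k >= max(1, lag)) the regression across subjects is

        Y(t_k) - Y(t_{k-1}) ~ intercept + each predictor at t_{k-lag},

    complete cases only (subjects missing any needed value at that time are
    dropped for that time alone).  Times with fewer complete cases than
    parameters, or a singular design, are skipped and logged.
    """
    if lag < 1:
        raise ValidationError("lag must be >= 1 (grid steps)")
    predictors = tuple(str(p) for p in predictors)
    dY, lagged, start_k = _increment_arrays(panel, response, predictors, lag)
    return _series_from_arrays(
        panel.times, dY, lagged, str(response), predictors, lag, start_k
    )


@dataclass(frozen=True)
class CumulativeCurves:
    """Running sums of per-time coefficients with accumulated variances."""

    terms: tuple[str, ...]
    times: np.ndarray
    cumulative: np.ndarray
    variance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, term in enumerate(self.terms):
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "term": term,
                        "cumulative": self.cumulative[:, j],
                        "variance": self.variance[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def cumulative_coefficients(series: IncrementFitSeries) -> CumulativeCurves:
    """Step-function cumulative coefficient curves.

    Variances accumulate as sums of squared per-time standard errors, i.e.
    assuming independence of estimates across times (shared subjects make
    this approximate; see the methods note).
    """
    if series.times.size == 0:
        raise EmptyFitError("empty increment series")
    return CumulativeCurves(
        terms=series.terms,
        times=series.times,
        cumulative=np.cumsum(series.coef, axis=0),
        variance=np.cumsum(series.se**2, axis=0),
    )


def test_local_dependence(
    panel: PanelData,
    from_var: str,
    to_var: str,
    adjust_for: Sequence[str] = (),
    lag: int = 1,
    method: str = "chi2",
    n_perm: int = 999,
    seed: int = 0,
) -> LocalDependenceTest:
    """Test whether ``to_var``'s increments depend on lagged ``from_var``.

    Fits the increment series of ``to_var`` on lagged {from_var} union
    adjust_for and aggregates Q = sum over fitted times of
    (coef_t / SE_t)^2 for the ``from_var`` coefficient.  ``method='chi2'``
    refers Q to a chi-squared law with one degree of freedom per fitted
    time; ``method='permutation'`` permutes ``from_var``'s whole trajectory
    across subjects (each subject's own trajectory kept intact) and
    recomputes Q.  Times with zero standard error are dropped and logged.
    """
    if method not in ("chi2", "permutation"):
        raise ValidationError("method must be 'chi2' or 'permutation'")
    if method == "permutation" and n_perm < 99:
        raise ValidationError("permutation test needs n_perm >= 99")
    predictors = (str(from_var),) + tuple(str(a) for a in adjust_for)

    def statistic_of(series: IncrementFitSeries):
        j = series.term_index(str(from_var))
        coefs = series.coef[:, j]
        ses = series.se[:, j]
        # exact in-sample fits leave SEs at rounding level; treat those as
        # degenerate too, not just literal zeros
        ok = np.isfinite(ses) & (ses > 1e-12 * (np.abs(coefs) + 1.0))
        if not ok.all():
            logger.warning(
                "local-dependence test: dropping %d time(s) with degenerate SE",
                int((~ok).sum()),
            )
        contrib = (coefs[ok] / ses[ok]) ** 2
        return contrib, series.times[ok]

    series = fit_increment_series(panel, to_var, predictors, lag=lag)
    contrib, times = statistic_of(series)
    if contrib.size == 0:
        raise EmptyFitError("no usable time point for the local-dependence test")
    stat = float(contrib.sum())
    df = int(contrib.size)

    if method == "chi2":
        p = float(stats.chi2.sf(stat, df))
        return LocalDependenceTest(
            from_var=str(from_var), to_var=str(to_var), statistic=stat, df=df,
            p_value=p, method=method, contributions=contrib, times=times,
        )

    rng = np.random.default_rng(seed)
    jf = panel.var_index(from_var)
    dY, lagged, start_k = _increment_arrays(panel, to_var, predictors, lag)
    n_subj = len(panel.subjects)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_subj)
        lag_perm = lagged.copy()
        lag_perm[:, :, 0] = lagged[perm, :, 0]  # from_var is first predictor
        try:
            s = _series_from_arrays(
                panel.times, dY, lag_perm, str(to_var), predictors, lag, start_k,
                quiet=True,
            )
        except EmptyFitError:
            continue
        c, _ = statistic_of(s)
        if c.size and float(c.sum()) >= stat:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return LocalDependenceTest(
        from_var=str(from_var), to_var=str(to_var), statistic=stat, df=df,
        p_value=float(p), method=method, contributions=contrib, times=times,
        n_perm=n_perm,
    )
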