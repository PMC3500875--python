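"""Linear (stochastic) dynamic systems and path-specific effects.

The model is the linear system

    dX_t = A X_t dt + u(t) dt + dW_t,

where ``A`` is a constant p x p drift matrix (entry ``A[i, j]`` is the rate
at which the *level* of process j moves the *drift* of process i, units
1/time), ``u`` an optional deterministic input (level/time) and ``W`` a
correlated Brownian disturbance with diffusion matrix ``noise_cov``
(level^2/time).  With zero input the conditional expectation is the matrix
exponential flow  E(X_t | X_0) = exp(A t) X_0.

Two structural readings of ``A`` are provided:

* the local-independence graph — an edge j -> i exactly when ``A[i, j]`` is
  (numerically) nonzero off the diagonal, i.e. when process i's drift
  genuinely involves process j's level;
* path-specific effects — for an acyclic, zero-diagonal source -> target
  sub-system the response of the target to a level perturbation ``delta``
  of the source decomposes over directed paths.  The decomposition is
  computed by *node splitting*: the system is unfolded into the prefix tree
  of all source -> target paths, so each root-to-leaf route is one path and
  each leaf copy of the target receives only the final edge of its path.
  Summing leaf responses recovers the full target response, and each
  leaf response has the closed form (product of path weights) * t^k / k!
  * delta for a path with k edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.linalg import expm

from .errors import (
    NodeLookupError,
    NoPathError,
    UnsupportedConfigurationError,
    UnsupportedStructureError,
    ValidationError,
)
from .ligraph import LocalIndependenceGraph

logger = logging.getLogger(__name__)

#: eigenvalue tolerance below which noise_cov counts as positive semidefinite
PSD_TOL = 1e-10

__all__ = [
    "LinearSDEModel",
    "TrajectoryEnsemble",
    "PathEffect",
    "expected_state",
    "simulate",
    "drift_to_graph",
    "split_paths",
    "path_effects",
    "total_effect",
]


InputFn = Callable[[float], np.ndarray]


@dataclass(frozen=True)
class LinearSDEModel:
    """Constant-coefficient linear stochastic system over named processes."""

    labels: tuple[str, ...]
    drift: np.ndarray
    input: InputFn | None = None
    noise_cov: np.ndarray | None = None

    def __init__(
        self,
        labels: Iterable[str],
        drift: np.ndarray | Sequence[Sequence[float]],
        input: InputFn | Sequence[float] | None = None,
        noise_cov: np.ndarray | Sequence[Sequence[float]] | None = None,
    ) -> None:
        labels = tuple(str(x) for x in labels)
        if len(set(labels)) != len(labels):
            raise ValidationError("process labels must be unique")
        p = len(labels)
        drift = np.asarray(drift, dtype=float)
        if drift.shape != (p, p):
            raise ValidationError(
                f"drift must be {p}x{p} to match {p} labels, got {drift.shape}"
            )
        if input is not None and not callable(input):
            const = np.asarray(input, dtype=float).reshape(-1)
            if const.shape != (p,):
                raise ValidationError("constant input must have one entry per process")
            if np.any(const != 0.0):
                input = _ConstantInput(const)
            else:
                input = None
        if noise_cov is None:
            noise_cov = np.zeros((p, p))
        noise_cov = np.asarray(noise_cov, dtype=float)
        if noise_cov.shape != (p, p):
            raise ValidationError(f"noise_cov must be {p}x{p}, got {noise_cov.shape}")
        if not np.allclose(noise_cov, noise_cov.T, atol=1e-8):
            raise ValidationError("noise_cov must be symmetric")
        eigvals = np.linalg.eigvalsh(0.5 * (noise_cov + noise_cov.T))
        if eigvals.min(initial=0.0) < -PSD_TOL:
            raise ValidationError(
                f"noise_cov must be positive semidefinite "
                f"(min eigenvalue {eigvals.min():.3e} < -{PSD_TOL:g})"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "drift", drift)
        object.__setattr__(self, "input", input)
        object.__setattr__(self, "noise_cov", noise_cov)

    # -- node resolution ---------------------------------------------------

    @property
    def p(self) -> int:
        return len(self.labels)

    def index(self, node: str | int) -> int:
        """Resolve a node given by label or 0-based position."""
        if isinstance(node, (int, np.integer)) and not isinstance(node, bool):
            if 0 <= node < self.p:
                return int(node)
            raise NodeLookupError(f"node position {node} out of range 0..{self.p - 1}")
        node = str(node)
        try:
            return self.labels.index(node)
        except ValueError:
            raise NodeLookupError(f"unknown process label {node!r}") from None

    def has_zero_input(self) -> bool:
        return self.input is None

    # -- JSON schema -------------------------------------------------------

    def to_json_dict(self) -> dict:
        if self.input is None:
            inp = None
        elif isinstance(self.input, _ConstantInput):
            inp = {"constant": self.input.value.tolist()}
        else:
            raise ValidationError("only constant inputs are JSON-serializable")
        return {
            "schema": "dynpath-model/1",
            "labels": list(self.labels),
            "drift": self.drift.tolist(),
            "input": inp,
            "noise_cov": self.noise_cov.tolist(),
        }

    @classmethod
    def from_json_dict(cls, obj: Mapping) -> "LinearSDEModel":
        try:
            labels = obj["labels"]
            drift = obj["drift"]
        except (TypeError, KeyError) as exc:
            raise ValidationError(f"malformed model JSON: {exc}") from exc
        inp = obj.get("input")
        if inp is not None:
            if not isinstance(inp, Mapping) or "constant" not in inp:
                raise ValidationError('model JSON "input" must be null or {"constant": [...]}')
            inp = inp["constant"]
        return cls(labels, drift, input=inp, noise_cov=obj.get("noise_cov"))


class _ConstantInput:
    """Constant deterministic input, comparable and serializable."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)

    def __call__(self, t: float) -> np.ndarray:
        return self.value


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Simulated sample paths on a common time grid.

    ``states`` has shape (n_paths, n_times, p), aligned with ``times`` and
    the model's labels; ``seed`` records the generator seed for provenance.
    """

    times: np.ndarray
    states: np.ndarray
    labels: tuple[str, ...]
    seed: int

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
            raise ValidationError("times must be a strictly increasing 1-d grid")
        if self.states.shape[1] != times.size or self.states.shape[2] != len(self.labels):
            raise ValidationError("states shape inconsistent with times/labels")
        object.__setattr__(self, "times", times)

    def to_frame(self):
        """Long table: path_id, time, one column per process label."""
        import pandas as pd

        n_paths, n_times, p = self.states.shape
        out = {
            "path_id": np.repeat(np.arange(n_paths), n_times),
            "time": np.tile(self.times, n_paths),
        }
        for j, lab in enumerate(self.labels):
            out[lab] = self.states[:, :, j].reshape(-1)
        return pd.DataFrame(out)


@dataclass(frozen=True)
class PathEffect:
    """Effect transmitted along one directed path.

    ``effect`` is the level change of the path's terminal node at horizon t
    caused by a level perturbation of the source at time 0, routed along
    exactly this path.
    """

    path: tuple[str, ...]
    effect: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def expected_state(model: LinearSDEModel, x0: Sequence[float], t: float) -> np.ndarray:
    """Conditional expectation E(X_t | X_0 = x0) = exp(A t) x0.

    Only defined for zero deterministic input; with a nonzero input the
    closed form above no longer holds and the call raises.
    """
    if not model.has_zero_input():
        raise UnsupportedConfigurationError(
            "expected_state requires zero deterministic input; this model has a "
            "nonzero input term (integrate it via simulate with noise_cov=0 instead)"
        )
    if t < 0:
        raise ValidationError("t must be nonnegative")
    x0 = np.asarray(x0, dtype=float).reshape(-1)
    if x0.shape != (model.p,):
        raise ValidationError(f"x0 must have length {model.p}")
    if t == 0:
        return x0.copy()
    return expm(model.drift * t) @ x0


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root with small negative eigenvalues clipped."""
    w, v = np.linalg.eigh(0.5 * (cov + cov.T))
    if w.min(initial=0.0) < -PSD_TOL:
        raise ValidationError("noise_cov must be positive semidefinite")
    return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T


def simulate(
    model: LinearSDEModel,
    x0: Sequence[float],
    times: Sequence[float],
    n_paths: int = 1,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Euler–Maruyama sample paths on the given grid.

    The integration step *is* the grid spacing — accuracy is controlled by
    refining the grid.  With ``noise_cov = 0`` a single path is the Euler
    solution of the ODE; identical seeds yield byte-identical ensembles.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValidationError("times must be a 1-d grid")
    if times[0] != 0.0:
        raise ValidationError("time grid must start at 0")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValidationError("time grid must be strictly increasing")
    if n_paths < 1:
        raise ValidationError("n_paths must be >= 1")
    x0 = np.asarray(x0, dtype=float).reshape(-1)
    if x0.shape != (model.p,):
        raise ValidationError(f"x0 must have length {model.p}")

    p = model.p
    noisy = np.any(model.noise_cov != 0.0)
    L = _psd_sqrt(model.noise_cov) if noisy else None
    rng = np.random.default_rng(seed)

    states = np.empty((n_paths, times.size, p))
    states[:, 0, :] = x0
    A_T = model.drift.T
    for k in range(times.size - 1):
        dt = times[k + 1] - times[k]
        x = states[:, k, :]
        drift_term = x @ A_T
        if model.input is not None:
            drift_term = drift_term + model.input(times[k])
        nxt = x + drift_term * dt
        if noisy:
            dW = rng.standard_normal((n_paths, p)) * np.sqrt(dt)
            nxt = nxt + dW @ L.T
        states[:, k + 1, :] = nxt
    return TrajectoryEnsemble(times=times, states=states, labels=model.labels, seed=int(seed))


def drift_to_graph(model: LinearSDEModel, tol: float = 0.0) -> LocalIndependenceGraph:
    """Local-independence graph read off the drift matrix.

    Edge j -> i is present iff i != j and |A[i, j]| > tol; diagonal entries
    (self-dependence) never produce edges.
    """
    if tol < 0:
        raise ValidationError("tol must be nonnegative")
    edges = []
    A = model.drift
    for i in range(model.p):
        for j in range(model.p):
            if i != j and abs(A[i, j]) > tol:
                edges.append((model.labels[j], model.labels[i]))
    return LocalIndependenceGraph(model.labels, edges)


def _path_graph(model: LinearSDEModel, tol: float = 0.0) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(model.p))
    A = model.drift
    for i in range(model.p):
        for j in range(model.p):
            if i != j and abs(A[i, j]) > tol:
                g.add_edge(j, i)
    return g


def _enumerate_paths(
    model: LinearSDEModel, source: str | int, target: str | int, max_path_len: int | None
) -> tuple[int, int, list[tuple[int, ...]]]:
    """All simple directed source->target paths, validated for splitting.

    Requires the drift graph restricted to the target's ancestry to be
    acyclic and all nodes on source->target paths to have zero diagonal.
    Paths are returned ordered lexicographically by label sequence.
    """
    si = model.index(source)
    ti = model.index(target)
    g = _path_graph(model)
    relevant = nx.ancestors(g, ti) | {ti}
    sub = g.subgraph(relevant)
    if not nx.is_directed_acyclic_graph(sub):
        raise UnsupportedStructureError(
            "path decomposition requires the ancestry of the target to be acyclic; "
            "a feedback cycle was found (use total_effect for cyclic systems)"
        )
    cutoff = max_path_len if max_path_len is not None else None
    paths = [
        tuple(pth)
        for pth in nx.all_simple_paths(g, si, ti, cutoff=cutoff)
    ]
    if not paths:
        raise NoPathError(
            f"no directed path from {model.labels[si]!r} to {model.labels[ti]!r}"
        )
    on_path = {v for pth in paths for v in pth}
    bad = [model.labels[v] for v in sorted(on_path) if model.drift[v, v] != 0.0]
    if bad:
        raise UnsupportedStructureError(
            f"path decomposition requires zero diagonal on nodes along "
            f"source->target paths; nonzero self-rate on {bad}"
        )
    paths.sort(key=lambda pth: tuple(model.labels[v] for v in pth))
    return si, ti, paths


def split_paths(
    model: LinearSDEModel,
    source: str | int,
    target: str | int,
    max_path_len: int | None = None,
) -> tuple[LinearSDEModel, dict[str, tuple[str, ...]]]:
    """Unfold the source->target sub-system into its path prefix tree.

    Each distinct source->target path becomes one root-to-leaf route; shared
    prefixes are shared tree nodes, and a node lying on several diverging
    routes is duplicated once per distinct prefix.  Each leaf is a copy of
    the target fed only by the final edge of its path.  The returned
    registry maps each leaf label to its path (original labels); summing
    the leaf responses recovers the original target response to a source
    perturbation.

    Only the tree edges are retained in the split drift matrix: the split
    system isolates exactly the flow from the source along the enumerated
    paths, which is what the path-effect computation requires.
    """
    si, ti, paths = _enumerate_paths(model, source, target, max_path_len)
    labels_of = model.labels

    def prefix_label(prefix: tuple[int, ...]) -> str:
        if len(prefix) == 1:
            return labels_of[prefix[0]]
        return "/".join(labels_of[v] for v in prefix)

    # collect distinct prefixes (length >= 1) in deterministic order
    prefixes: list[tuple[int, ...]] = [(si,)]
    seen = {(si,)}
    for pth in paths:
        for k in range(2, len(pth) + 1):
            pre = pth[:k]
            if pre not in seen:
                seen.add(pre)
                prefixes.append(pre)

    new_labels = [prefix_label(pre) for pre in prefixes]
    if len(set(new_labels)) != len(new_labels):  # pragma: no cover - defensive
        raise ValidationError("label collision while splitting; rename processes")
    idx = {pre: k for k, pre in enumerate(prefixes)}
    q = len(prefixes)
    A_new = np.zeros((q, q))
    for pre in prefixes:
        if len(pre) == 1:
            continue
        parent = pre[:-1]
        A_new[idx[pre], idx[parent]] = model.drift[pre[-1], pre[-2]]

    registry = {
        prefix_label(pth): tuple(labels_of[v] for v in pth) for pth in paths
    }
    split_model = LinearSDEModel(new_labels, A_new)
    return split_model, registry


def path_effects(
    model: LinearSDEModel,
    source: str | int,
    target: str | int,
    t: float,
    delta: float = 1.0,
    max_path_len: int | None = None,
) -> list[PathEffect]:
    """Path-specific effects of a source perturbation on the target.

    Each effect is the matrix-exponential response, in the split (prefix
    tree) system at horizon ``t``, of that path's leaf copy to an initial
    shift ``delta`` of the source.  The effects sum to
    :func:`total_effect` up to numerical tolerance.
    """
    if not model.has_zero_input():
        raise UnsupportedConfigurationError(
            "path_effects requires zero deterministic input"
        )
    if t < 0:
        raise ValidationError("t must be nonnegative")
    split_model, registry = split_paths(model, source, target, max_path_len)
    x0 = np.zeros(split_model.p)
    x0[0] = delta  # root of the prefix tree is the source
    xt = expected_state(split_model, x0, t)
    out = []
    for leaf_label in sorted(registry, key=lambda k: registry[k]):
        out.append(PathEffect(path=registry[leaf_label], effect=float(xt[split_model.index(leaf_label)])))
    return out


def total_effect(
    model: LinearSDEModel,
    source: str | int,
    target: str | int,
    t: float,
    delta: float = 1.0,
) -> float:
    """Total effect (exp(A t))[target, source] * delta; any drift, cyclic or not."""
    if not model.has_zero_input():
        raise UnsupportedConfigurationError(
            "total_effect requires zero deterministic input"
        )
    if t < 0:
        raise ValidationError("t must be nonnegative")
    si = model.index(source)
    ti = model.index(target)
    return float(expm(model.drift * t)[ti, si] * delta)
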