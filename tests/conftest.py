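"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by a different route from
the implementation: a truncated power series for the matrix exponential, a
closed-form path-weight formula, and an explicit normal-equations solve for
the per-event-time regressions.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from dynpath import CountingProcessData, LinearSDEModel, LocalIndependenceGraph

DATA_DIR = Path(__file__).parent / "data"


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def series_expm(A: np.ndarray, t: float, n_terms: int = 60) -> np.ndarray:
    """Truncated power series for exp(A t), term-by-term.

    With n_terms = 60 and moderate ||A t|| the remainder is far below 1e-12;
    terms are accumulated in order so the computation shares nothing with
    scipy's scaling-and-squaring routine.
    """
    p = A.shape[0]
    out = np.eye(p)
    term = np.eye(p)
    for k in range(1, n_terms):
        term = term @ (A * t) / k
        out = out + term
    return out


def enumerate_path_effects(A: np.ndarray, source: int, target: int, t: float, delta: float):
    """Closed-form oracle for acyclic zero-diagonal drifts.

    A path with k edges and weight product pi contributes pi * t^k / k! *
    delta, because (A^k)[target, source] sums weight products over length-k
    paths.  Returns {path (index tuple): effect}.
    """
    from math import factorial

    p = A.shape[0]
    results = {}

    def walk(node, path, weight):
        if node == target:
            k = len(path) - 1
            results[tuple(path)] = weight * t**k / factorial(k) * delta
            return
        for nxt in range(p):
            if nxt != node and A[nxt, node] != 0.0 and nxt not in path:
                walk(nxt, path + [nxt], weight * A[nxt, node])

    walk(source, [source], 1.0)
    return results


def normal_equations_additive(data: CountingProcessData, regressors, intercept=True):
    """Explicit per-event-time normal-equations solve (reference path).

    Loops over rows with plain Python, builds X'X and X'y by hand, and
    solves with np.linalg.solve.  Returns (times, increments).
    """
    tbl = data.table
    event_times = sorted(tbl.loc[tbl["event"] == 1, "stop"].unique())
    times, incs = [], []
    for t in event_times:
        rows = []
        ys = []
        for _, row in tbl.iterrows():
            if row["start"] < t <= row["stop"]:
                x = ([1.0] if intercept else []) + [row[r] for r in regressors]
                rows.append(x)
                ys.append(1.0 if (row["event"] == 1 and row["stop"] == t) else 0.0)
        X = np.array(rows)
        y = np.array(ys)
        q = X.shape[1]
        XtX = np.zeros((q, q))
        Xty = np.zeros(q)
        for xi, yi in zip(X, y):
            XtX += np.outer(xi, xi)
            Xty += xi * yi
        if np.linalg.matrix_rank(XtX) < q:
            continue
        times.append(t)
        incs.append(np.linalg.solve(XtX, Xty))
    return np.array(times), np.array(incs)


def random_acyclic_model(rng: np.random.Generator, p: int) -> LinearSDEModel:
    """Random strictly-lower-triangular (hence acyclic, zero-diagonal) drift
    in topological order, weights in [-2, 2], ~60% edge density."""
    A = np.zeros((p, p))
    for i in range(p):
        for j in range(i):
            if rng.random() < 0.6:
                A[i, j] = rng.uniform(-2.0, 2.0)
    return LinearSDEModel([f"n{k}" for k in range(p)], A)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def chain3_factory():
    """Three-process chain-plus-shortcut system: 1 -> 2 (a), 2 -> 3 (b),
    1 -> 3 (c), zero diagonal."""

    def make(a=1.0, b=1.0, c=1.0):
        A = np.array([[0.0, 0.0, 0.0], [a, 0.0, 0.0], [c, b, 0.0]])
        return LinearSDEModel(["1", "2", "3"], A)

    return make


@pytest.fixture
def censoring_graph():
    """Treatment X drives outcome Y, censoring C and mediator L; L drives Y.
    The independent-censoring pattern: C is separated from Y by X."""
    return LocalIndependenceGraph(
        ["X", "Y", "C", "L"],
        [("X", "Y"), ("X", "C"), ("X", "L"), ("L", "Y")],
        roles={"X": "treatment", "Y": "outcome", "C": "censoring", "L": "mediator"},
    )


@pytest.fixture
def confounded_diagram():
    """Exposure X -> mediator Z -> outcome dY with unmeasured confounder U
    of Z and dY, and no direct X -> dY edge (the no-direct-effect null)."""
    return LocalIndependenceGraph(
        ["X", "Z", "U", "dY"],
        [("X", "Z"), ("U", "Z"), ("U", "dY"), ("Z", "dY")],
        roles={"X": "treatment", "Z": "mediator", "U": "unobserved", "dY": "outcome"},
    )


@pytest.fixture
def repeated_mediator_diagram():
    """As confounded_diagram but the mediator is measured before and after
    exposure; the confounder acts on the pre-exposure measurement only."""
    return LocalIndependenceGraph(
        ["X", "Z0", "Z1", "U", "dY"],
        [("X", "Z1"), ("Z0", "Z1"), ("U", "Z0"), ("U", "dY"), ("Z1", "dY")],
        roles={"X": "treatment", "Z0": "covariate", "Z1": "mediator",
               "U": "unobserved", "dY": "outcome"},
    )


@pytest.fixture
def hand8():
    """Hand-checkable 8-subject counting-process dataset with tied event
    times, multi-interval subjects and censoring."""
    return CountingProcessData(pd.read_csv(DATA_DIR / "hand8.csv"))
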