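"""uDEAS: univariate dynamic encoding algorithm for searches.

A derivative-free global optimizer over a box.  Each variable is encoded as a
binary row; ``decode`` maps a row of length ``d`` to the midpoint of one of
the ``2**d`` equal cells of its interval.  A *local search* repeats sessions;
a *session* visits each variable once and applies

* a bisectional search (BSS): append one bit, i.e. split the current cell in
  two, evaluate both children, keep the better one (ties keep the lower, "0",
  child); and
* a unidirectional search (UDS): step the row's integer value by +/-1 in the
  direction the BSS winner indicates, at fixed length, accepting steps while
  the cost strictly decreases.

The *global* scheme restarts the local search from random initial matrices
and returns the best local minimum.  Variable visiting order is either the
fixed input order or re-ranked each session by a cost-sensitivity score: the
mean magnitude of the secant slopes |dL/dv| observed for that variable during
its BSS pair and its M accepted UDS steps, divided by M + 1.  High-sensitivity
variables are searched first in the next session.

The best evaluated point is tracked across every cost call, so the reported
best cost is monotone non-increasing within a local search even when a BSS
deepening temporarily lands on a worse cell midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OptimizerConfig",
    "BinaryMatrix",
    "SessionResult",
    "OptimizeResult",
    "decode",
    "decode_row",
    "encode_value",
    "bisectional_search",
    "unidirectional_search",
    "sensitivity",
    "run_session",
    "optimize",
]

CostFn = Callable[[np.ndarray], float]


def decode_row(value: int, length: int, lo: float, hi: float) -> float:
    """Midpoint decoding: cell ``value`` of ``2**length`` equal cells."""
    if length < 1:
        raise ValueError("row length must be >= 1")
    return lo + (hi - lo) * (value + 0.5) / (1 << length)


def decode(row: str, lo: float, hi: float) -> float:
    """Decode a binary string row; strictly inside (lo, hi)."""
    if not row:
        raise ValueError("empty binary row")
    if set(row) - {"0", "1"}:
        raise ValueError(f"non-binary characters in row {row!r}")
    return decode_row(int(row, 2), len(row), lo, hi)


def encode_value(x: float, length: int, lo: float, hi: float) -> int:
    """Index of the depth-``length`` cell containing ``x`` (clipped to box)."""
    n = 1 << length
    idx = int(np.floor((x - lo) / (hi - lo) * n))
    return min(max(idx, 0), n - 1)


@dataclass
class OptimizerConfig:
    """uDEAS settings.

    initial_depth / max_depth bound the binary row lengths; the attainable
    grid at max_depth has spacing (hi-lo)/2**max_depth per variable.
    ordering selects fixed ("sequential") or cost-sensitivity-ranked
    ("sensitivity") variable visiting; seed drives the restart matrices.
    """

    initial_depth: int = 2
    max_depth: int = 12
    restarts: int = 5
    ordering: str = "sensitivity"
    seed: int = 0
    uds_step_cap: int | None = None

    def __post_init__(self):
        if not (1 <= self.initial_depth <= self.max_depth):
            raise ValueError("need 1 <= initial_depth <= max_depth")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.ordering not in ("sequential", "sensitivity"):
            raise ValueError(f"unknown ordering {self.ordering!r}")


@dataclass
class BinaryMatrix:
    """One (value, length) binary row per variable plus decoding bounds."""

    values: list[int]
    lengths: list[int]
    bounds: list[tuple[float, float]]

    def __post_init__(self):
        if not (len(self.values) == len(self.lengths) == len(self.bounds)):
            raise ValueError("values, lengths, bounds must align")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("need lo < hi for every variable")
        for v, ln in zip(self.values, self.lengths):
            if ln < 1 or not 0 <= v < (1 << ln):
                raise ValueError("row value out of range for its length")

    @classmethod
    def random(cls, bounds, depth: int, rng: np.random.Generator):
        vals = [int(rng.integers(0, 1 << depth)) for _ in bounds]
        return cls(vals, [depth] * len(bounds), list(bounds))

    @classmethod
    def from_point(cls, x: Sequence[float], bounds, depth: int):
        vals = [encode_value(xi, depth, lo, hi)
                for xi, (lo, hi) in zip(x, bounds)]
        return cls(vals, [depth] * len(bounds), list(bounds))

    def decode_all(self) -> np.ndarray:
        return np.array([
            decode_row(v, ln, lo, hi)
            for v, ln, (lo, hi) in zip(self.values, self.lengths, self.bounds)
        ])

    def rows(self) -> list[str]:
        return [format(v, f"0{ln}b") for v, ln in zip(self.values, self.lengths)]

    def copy(self) -> "BinaryMatrix":
        return BinaryMatrix(list(self.values), list(self.lengths),
                            list(self.bounds))


@dataclass
class SessionResult:
    """Outcome of one session over all variables."""

    matrix: BinaryMatrix
    best_cost: float
    best_x: np.ndarray
    sensitivities: np.ndarray        # S(v_i) for this session, >= 0
    uds_counts: np.ndarray           # M per variable
    improved: bool
    n_evals: int


@dataclass
class OptimizeResult:
    x: np.ndarray
    cost: float
    n_evals: int
    restart_costs: list[float]
    history: list[list[float]]       # per restart, best cost after each session

    def __iter__(self):  # allow x, cost = optimize(...)
        return iter((self.x, self.cost))


class _Tracker:
    """Evaluates the cost and remembers the best point ever seen."""

    def __init__(self, cost_fn: CostFn):
        self.cost_fn = cost_fn
        self.best_cost = np.inf
        self.best_x: np.ndarray | None = None
        self.n_evals = 0

    def __call__(self, x: np.ndarray) -> float:
        c = float(self.cost_fn(x))
        self.n_evals += 1
        if c < self.best_cost:
            self.best_cost = c
            self.best_x = np.array(x)
        return c


def bisectional_search(
    matrix: BinaryMatrix, var_index: int, cost_fn: CostFn,
    *, max_depth: int | None = None,
):
    """Append one bit to row ``var_index``; keep the better child.

    Returns ``(child_costs, child_values, direction)`` where direction is +1
    when the "1" (upper) child won and -1 otherwise; ties keep the "0" child.
    Returns ``None`` when the row is already at ``max_depth`` (the variable is
    skipped this session).  The matrix is modified in place.
    """
    ln = matrix.lengths[var_index]
    if max_depth is not None and ln >= max_depth:
        return None
    lo, hi = matrix.bounds[var_index]
    base = matrix.decode_all()
    v0, v1 = matrix.values[var_index] << 1, (matrix.values[var_index] << 1) | 1
    x0 = decode_row(v0, ln + 1, lo, hi)
    x1 = decode_row(v1, ln + 1, lo, hi)
    c0 = _eval_at(cost_fn, base, var_index, x0)
    c1 = _eval_at(cost_fn, base, var_index, x1)
    if c1 < c0:
        matrix.values[var_index], direction = v1, +1
    else:
        matrix.values[var_index], direction = v0, -1
    matrix.lengths[var_index] = ln + 1
    return (c0, c1), (x0, x1), direction


def _eval_at(cost_fn, base: np.ndarray, i: int, xi: float) -> float:
    x = base.copy()
    x[i] = xi
    return cost_fn(x)


def unidirectional_search(
    matrix: BinaryMatrix, var_index: int, direction: int, cost_fn: CostFn,
    start_cost: float, *, step_cap: int | None = None,
):
    """Step row ``var_index`` by ``direction`` while the cost strictly drops.

    Stops at the first non-improving step or at the range clamp.  Returns the
    trace of accepted ``(value_real, cost)`` pairs (M = len(trace)).
    """
    ln = matrix.lengths[var_index]
    lo, hi = matrix.bounds[var_index]
    base = matrix.decode_all()
    cap = (1 << ln) - 1 if step_cap is None else step_cap
    best = start_cost
    trace: list[tuple[float, float]] = []
    v = matrix.values[var_index]
    for _ in range(cap):
        nxt = v + direction
        if nxt < 0 or nxt > (1 << ln) - 1:
            break
        xi = decode_row(nxt, ln, lo, hi)
        c = _eval_at(cost_fn, base, var_index, xi)
        if c < best:
            v, best = nxt, c
            trace.append((xi, c))
        else:
            break
    matrix.values[var_index] = v
    return trace, best


def sensitivity(
    bss_costs: tuple[float, float],
    bss_values: tuple[float, float],
    uds_trace: list[tuple[float, float]],
    winner_value: float,
    winner_cost: float,
) -> float:
    """Cost-sensitivity score: mean |secant slope| over BSS pair + UDS steps.

    S = (|L_l - L_r| / |v_l - v_r| + sum_k |L_{k-1} - L_k| / |v_{k-1} - v_k|)
        / (M + 1),
    where step 0 of the UDS chain is the winning BSS child.  Zero-width
    denominators contribute nothing (cannot occur under midpoint decoding).
    """
    (c0, c1), (x0, x1) = bss_costs, bss_values
    total = abs(c0 - c1) / abs(x0 - x1) if x0 != x1 else 0.0
    prev_v, prev_c = winner_value, winner_cost
    for v, c in uds_trace:
        if v != prev_v:
            total += abs(prev_c - c) / abs(prev_v - v)
        prev_v, prev_c = v, c
    return total / (len(uds_trace) + 1)


def run_session(
    matrix: BinaryMatrix,
    order: Sequence[int],
    cost_fn: CostFn,
    config: OptimizerConfig,
    *,
    _tracker: _Tracker | None = None,
) -> SessionResult:
    """One BSS + UDS pass over the variables in ``order``."""
    tr = _tracker if _tracker is not None else _Tracker(cost_fn)
    n = len(matrix.values)
    sens = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    cost_before = tr.best_cost
    if not np.isfinite(cost_before):
        cost_before = tr(matrix.decode_all())
    for i in order:
        res = bisectional_search(matrix, i, tr, max_depth=config.max_depth)
        if res is None:
            # Row at max length: no bit to add, but the session still probes
            # the two same-depth neighbors and runs a UDS in the better
            # direction, so sessions keep improving until none does.
            sens[i], counts[i] = _refine_at_depth(matrix, i, tr, config)
            continue
        (c0, c1), (x0, x1), direction = res
        winner_cost = c1 if direction > 0 else c0
        winner_value = x1 if direction > 0 else x0
        trace, _ = unidirectional_search(
            matrix, i, direction, tr, winner_cost,
            step_cap=config.uds_step_cap,
        )
        sens[i] = sensitivity((c0, c1), (x0, x1), trace,
                              winner_value, winner_cost)
        counts[i] = len(trace)
    return SessionResult(
        matrix=matrix,
        best_cost=tr.best_cost,
        best_x=tr.best_x,
        sensitivities=sens,
        uds_counts=counts,
        improved=tr.best_cost < cost_before,
        n_evals=tr.n_evals,
    )


def _refine_at_depth(matrix, i, tracker, config) -> tuple[float, int]:
    """Same-depth neighbor probe + UDS for a row at maximum length.

    Evaluates the integer neighbors v-1 and v+1, moves to the better one if
    it beats the current point, then walks in that direction while the cost
    strictly drops.  Returns (sensitivity, M).
    """
    ln = matrix.lengths[i]
    lo, hi = matrix.bounds[i]
    base = matrix.decode_all()
    v = matrix.values[i]
    c_cur = tracker(base)
    probes = []
    for cand in (v - 1, v + 1):
        if 0 <= cand <= (1 << ln) - 1:
            xi = decode_row(cand, ln, lo, hi)
            probes.append((cand, xi, _eval_at(tracker, base, i, xi)))
    if not probes:
        return 0.0, 0
    cand, xi, c_cand = min(probes, key=lambda p: p[2])
    slope = 0.0
    if len(probes) == 2:
        (_, xa, ca), (_, xb, cb) = probes
        slope = abs(ca - cb) / abs(xa - xb)
    else:
        x_cur = base[i]
        slope = abs(c_cur - c_cand) / abs(x_cur - xi) if x_cur != xi else 0.0
    if c_cand >= c_cur:
        return slope, 0
    matrix.values[i] = cand
    direction = 1 if cand > v else -1
    trace, _ = unidirectional_search(
        matrix, i, direction, tracker, c_cand, step_cap=config.uds_step_cap
    )
    s = sensitivity((c_cur, c_cand), (base[i], xi), trace, xi, c_cand)
    return max(s, slope / (len(trace) + 1)), len(trace) + 1


def _local_search(matrix, cost_fn, config) -> tuple[_Tracker, list[float]]:
    tr = _Tracker(cost_fn)
    tr(matrix.decode_all())
    n = len(matrix.values)
    order = list(range(n))  # first session is sequential
    costs = []
    while True:
        res = run_session(matrix, order, cost_fn, config, _tracker=tr)
        costs.append(res.best_cost)
        if config.ordering == "sensitivity":
            # descending S; ties broken by variable index for determinism
            order = sorted(range(n), key=lambda i: (-res.sensitivities[i], i))
        all_deep = all(ln >= config.max_depth for ln in matrix.lengths)
        if all_deep and not res.improved:
            break
    return tr, costs


def optimize(
    cost_fn: CostFn,
    bounds: Sequence[tuple[float, float]],
    config: OptimizerConfig | None = None,
    *,
    warm_start: Sequence[float] | None = None,
    warm_depth: int | None = None,
) -> OptimizeResult:
    """Multistart uDEAS over a box; deterministic given config.seed.

    ``warm_start`` seeds the first restart's matrix at ``warm_depth``
    (default ``max(initial_depth, max_depth - 4)``), encoding the given point
    into its grid cell; the remaining restarts draw random matrices at
    ``initial_depth``.
    """
    if config is None:
        config = OptimizerConfig()
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    for lo, hi in bounds:
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("bounds must be finite with lo < hi")
    rng = np.random.default_rng(config.seed)
    best_x, best_cost, total_evals = None, np.inf, 0
    restart_costs, history = [], []
    for r in range(config.restarts):
        if r == 0 and warm_start is not None:
            depth = warm_depth if warm_depth is not None else max(
                config.initial_depth, config.max_depth - 4)
            matrix = BinaryMatrix.from_point(warm_start, bounds, depth)
        else:
            matrix = BinaryMatrix.random(bounds, config.initial_depth, rng)
        tr, costs = _local_search(matrix, cost_fn, config)
        restart_costs.append(tr.best_cost)
        history.append(costs)
        total_evals += tr.n_evals
        if tr.best_cost < best_cost:
            best_cost, best_x = tr.best_cost, tr.best_x
    return OptimizeResult(
        x=best_x, cost=best_cost, n_evals=total_evals,
        restart_costs=restart_costs, history=history,
    )
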