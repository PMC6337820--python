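"""Missing-data strategies for short biomarker time series.

Three strategies are provided for the sparse visit-grid biomarker series:

* **omit** — keep only the observed entries (the mixed models and the
  counting-process Cox machinery tolerate unbalanced sampling);
* **LOCF** — last observation carried forward along the visit grid;
* **OCS** — fuzzy short-time-series clustering (FSTS) combined with the
  optimal completion strategy: missing entries are free variables of the
  clustering objective and are imputed during the alternating optimization.

FSTS is fuzzy c-means under a distance on segment *slopes*: each series is
read as a piecewise-linear function on the visit grid and two series are
compared through the slopes of corresponding segments, making the distance
invariant to vertical shifts.  Because of that invariance the prototype
linear system is rank-deficient by one; prototypes are level-anchored so
their membership-weighted mean level matches the data's (see
`fsts_cluster`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryMatrix",
    "FuzzyPartition",
    "sts_distance",
    "fsts_cluster",
    "ocs_impute",
    "locf_impute",
]


@dataclass
class TrajectoryMatrix:
    """Patients x visit-grid matrix of (log) biomarker values.

    ``values`` holds NaN at unobserved cells; ``mask`` is True where
    observed.  Every row must retain at least one observed entry.
    """

    ids: np.ndarray
    times: np.ndarray
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.times.size < 2 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing with length >= 2")
        if not self.mask.any(axis=1).all():
            raise ValueError("every row needs at least one observed entry")

    @classmethod
    def from_long(
        cls, long_data: pd.DataFrame, schedule: np.ndarray
    ) -> "TrajectoryMatrix":
        schedule = np.asarray(schedule, dtype=float)
        ids = np.asarray(sorted(long_data["id"].unique()))
        values = np.full((ids.size, schedule.size), np.nan)
        pos = {round(t, 10): j for j, t in enumerate(schedule)}
        idx = {pid: i for i, pid in enumerate(ids)}
        for pid, t, y in long_data[["id", "t", "y"]].itertuples(index=False):
            j = pos.get(round(float(t), 10))
            if j is not None:
                values[idx[pid], j] = y
        return cls(ids=ids, times=schedule, values=values, mask=~np.isnan(values))

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, pid in enumerate(self.ids):
            for j, t in enumerate(self.times):
                if self.mask[i, j]:
                    rows.append((pid, t, self.values[i, j]))
        return pd.DataFrame(rows, columns=["id", "t", "y"])

    def write_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=[f"m{t:g}" for t in self.times])
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "TrajectoryMatrix":
        df = pd.read_csv(path)
        times = np.array([float(c[1:]) for c in df.columns[1:]])
        values = df.iloc[:, 1:].to_numpy(dtype=float)
        return cls(
            ids=df["id"].to_numpy(),
            times=times,
            values=values,
            mask=~np.isnan(values),
        )


@dataclass
class FuzzyPartition:
    """State of an FSTS clustering run."""

    c: int
    m_fuzz: float
    U: np.ndarray  # (c, n) memberships, columns sum to 1
    V: np.ndarray  # (c, T) prototypes on the data's level scale
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    degenerate: bool = False  # all series identical with c > 1


def _slope_operator(times: np.ndarray) -> np.ndarray:
    """(T-1, T) matrix mapping a series to its per-segment slopes."""
    times = np.asarray(times, dtype=float)
    dt = np.diff(times)
    if np.any(dt == 0):
        raise ValueError("duplicate time points give zero-length segments")
    T = times.size
    G = np.zeros((T - 1, T))
    for k in range(T - 1):
        G[k, k] = -1.0 / dt[k]
        G[k, k + 1] = 1.0 / dt[k]
    return G


def sts_distance(x: np.ndarray, v: np.ndarray, times: np.ndarray) -> float:
    """Slope-based distance between two complete series on the same grid.

    d^2 = sum_k (slope_x(k) - slope_v(k))^2 over consecutive segments; a
    Euclidean distance on slope vectors, hence symmetric and triangular,
    and invariant to constant vertical shifts.
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    G = _slope_operator(times)
    return float(np.linalg.norm(G @ x - G @ v))


def _init_prototypes(S: np.ndarray, c: int) -> np.ndarray:
    """Order-invariant farthest-point seeding on slope vectors.

    The first seed is the series with the largest slope norm; each further
    seed maximizes the minimum distance to those already chosen.  Ties break
    on the lexicographic order of the slope vectors so a permutation of the
    rows selects the same series.
    """
    n = S.shape[0]
    keys = [tuple(row) for row in S]

    def argbest(scores: np.ndarray) -> int:
        best = np.flatnonzero(scores == scores.max())
        return int(min(best, key=lambda i: keys[i]))

    chosen = [argbest(np.linalg.norm(S, axis=1))]
    while len(chosen) < c:
        d2 = np.min(
            [np.sum((S - S[j]) ** 2, axis=1) for j in chosen], axis=0
        )
        d2[chosen] = -1.0
        chosen.append(argbest(d2))
    return S[chosen].copy()


def _memberships(d: np.ndarray, m_fuzz: float) -> np.ndarray:
    """Fuzzy c-means membership update from a (c, n) distance matrix.

    Zero distances get a crisp assignment to the first matching cluster
    (standard singularity rule, deterministic tie-break).
    """
    c, n = d.shape
    U = np.zeros((c, n))
    zero = d <= 1e-300
    has_zero = zero.any(axis=0)
    if np.any(has_zero):
        first = np.argmax(zero[:, has_zero], axis=0)
        U[first, np.flatnonzero(has_zero)] = 1.0
    ok = ~has_zero
    if np.any(ok):
        power = 2.0 / (m_fuzz - 1.0)
        with np.errstate(over="ignore"):
            ratio = d[:, ok][:, None, :] / d[:, ok][None, :, :]  # (c, c, n_ok)
            denom = np.sum(ratio**power, axis=1)
        U[:, ok] = 1.0 / denom
    return U


def _objective(Sx: np.ndarray, Sv: np.ndarray, U: np.ndarray, m_fuzz: float) -> float:
    d2 = ((Sx[None, :, :] - Sv[:, None, :]) ** 2).sum(axis=2)  # (c, n)
    return float(np.sum(U**m_fuzz * d2))


def _prototypes_from_slopes(
    Sv: np.ndarray, X: np.ndarray, U: np.ndarray, m_fuzz: float, times: np.ndarray
) -> np.ndarray:
    """Rebuild level-scale prototypes from slope prototypes.

    Integrates the slope vector along the grid and anchors the free level so
    the membership-weighted mean level of the prototype equals that of the
    member series.
    """
    dt = np.diff(times)
    c = Sv.shape[0]
    V = np.zeros((c, times.size))
    Um = U**m_fuzz
    row_mean = X.mean(axis=1)
    for i in range(c):
        path = np.concatenate([[0.0], np.cumsum(Sv[i] * dt)])
        wsum = Um[i].sum()
        target = (Um[i] @ row_mean) / wsum if wsum > 0 else row_mean.mean()
        V[i] = path + (target - path.mean())
    return V


def fsts_cluster(
    M: TrajectoryMatrix,
    c: int = 6,
    m_fuzz: float = 1.3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FuzzyPartition:
    """Fuzzy short-time-series clustering of a complete trajectory matrix.

    Alternates the fuzzy c-means membership update (under the slope
    distance) with exact prototype minimization: the optimal prototype
    slope vector is the membership-weighted mean of the member slope
    vectors, then the level is anchored (see module docstring).  Stops when
    the largest prototype change drops below ``tol``.
    """
    if not M.mask.all():
        raise ValueError("fsts_cluster requires a complete matrix; use ocs_impute")
    X = M.values
    n = X.shape[0]
    if not 1 <= c <= n:
        raise ValueError("need 1 <= c <= n")
    if m_fuzz <= 1:
        raise ValueError("fuzzifier must exceed 1")
    G = _slope_operator(M.times)
    Sx = X @ G.T  # (n, T-1)
    degenerate = bool(c > 1 and np.allclose(Sx, Sx[0]))
    Sv = _init_prototypes(Sx, c)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((Sx[None, :, :] - Sv[:, None, :]) ** 2).sum(axis=2)
        U = _memberships(np.sqrt(d2), m_fuzz)
        Um = U**m_fuzz
        wsum = Um.sum(axis=1, keepdims=True)
        Sv_new = np.where(wsum > 0, (Um @ Sx) / np.maximum(wsum, 1e-300), Sv)
        trace.append(_objective(Sx, Sv_new, U, m_fuzz))
        if np.max(np.abs(Sv_new - Sv)) < tol:
            Sv = Sv_new
            converged = True
            break
        Sv = Sv_new
    V = _prototypes_from_slopes(Sv, X, U, m_fuzz, M.times)
    return FuzzyPartition(
        c=c,
        m_fuzz=m_fuzz,
        U=U,
        V=V,
        objective_trace=trace,
        n_iter=it,
        converged=converged,
        degenerate=degenerate,
    )


def _complete_rows(
    X: np.ndarray, mask: np.ndarray, U: np.ndarray, Sv: np.ndarray,
    G: np.ndarray, m_fuzz: float,
) -> np.ndarray:
    """Exact minimization of the OCS objective over the missing coordinates.

    For row k the objective sum_i u_ik^m ||G x - s_i||^2 is a strictly
    convex quadratic in the missing coordinates (every coordinate enters at
    least one slope segment and at least one entry is pinned), solved by a
    small linear system per row.
    """
    Um = U**m_fuzz
    GtG = G.T @ G
    X = X.copy()
    for k in range(X.shape[0]):
        mis = ~mask[k]
        if not mis.any():
            continue
        Sk = Um[:, k].sum()
        target = (Um[:, k] @ Sv) / max(Sk, 1e-300)  # weighted slope target
        rhs = G.T @ target - GtG[:, mask[k]] @ X[k, mask[k]]
        A = GtG[np.ix_(mis, mis)]
        X[k, mis] = np.linalg.solve(A, rhs[mis])
    return X


def ocs_impute(
    M: TrajectoryMatrix,
    c: int = 6,
    m_fuzz: float = 1.3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[TrajectoryMatrix, FuzzyPartition]:
    """FSTS clustering with optimal completion of missing entries.

    Missing cells are free variables of the clustering objective.  Each
    cycle runs (membership update, prototype update, exact missing-value
    update), every step a coordinate-wise minimization, so the objective is
    non-increasing across cycles.  Observed entries are never altered.
    """
    if not M.mask.any(axis=1).all():
        raise ValueError("a row with all entries missing cannot be completed")
    if M.mask.all():
        part = fsts_cluster(M, c=c, m_fuzz=m_fuzz, seed=seed, tol=tol, max_iter=max_iter)
        return TrajectoryMatrix(M.ids, M.times, M.values.copy(), M.mask | True), part

    times = M.times
    G = _slope_operator(times)
    # start from within-row linear interpolation / edge fill
    X = np.array(
        [
            np.interp(times, times[m], v[m])
            for v, m in zip(M.values, M.mask)
        ]
    )
    Sx = X @ G.T
    Sv = _init_prototypes(Sx, c)
    trace: list[float] = []
    converged = False
    it = 0
    U = np.full((c, X.shape[0]), 1.0 / c)
    for it in range(1, max_iter + 1):
        Sx = X @ G.T
        d2 = ((Sx[None, :, :] - Sv[:, None, :]) ** 2).sum(axis=2)
        U = _memberships(np.sqrt(d2), m_fuzz)
        Um = U**m_fuzz
        wsum = Um.sum(axis=1, keepdims=True)
        Sv_new = np.where(wsum > 0, (Um @ Sx) / np.maximum(wsum, 1e-300), Sv)
        X_new = _complete_rows(X, M.mask, U, Sv_new, G, m_fuzz)
        trace.append(_objective(X_new @ G.T, Sv_new, U, m_fuzz))
        delta = max(np.max(np.abs(Sv_new - Sv)), np.max(np.abs(X_new - X)))
        Sv, X = Sv_new, X_new
        if delta < tol:
            converged = True
            break
    V = _prototypes_from_slopes(Sv, X, U, m_fuzz, times)
    part = FuzzyPartition(
        c=c,
        m_fuzz=m_fuzz,
        U=U,
        V=V,
        objective_trace=trace,
        n_iter=it,
        converged=converged,
    )
    out = TrajectoryMatrix(
        ids=M.ids, times=times, values=X, mask=np.ones_like(M.mask)
    )
    return out, part


def locf_impute(M: TrajectoryMatrix) -> TrajectoryMatrix:
    """Last observation carried forward along the visit grid.

    Leading missing entries (before a patient's first observation) stay
    missing; they are dropped on conversion to long format.
    """
    values = M.values.copy()
    mask = M.mask.copy()
    for j in range(1, values.shape[1]):
        carry = ~mask[:, j] & mask[:, j - 1]
        values[carry, j] = values[carry, j - 1]
        mask[carry, j] = True
    return TrajectoryMatrix(ids=M.ids, times=M.times, values=values, mask=mask)
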