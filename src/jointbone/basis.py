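"""Time bases for longitudinal biomarker trajectories.

Three mean-structure families are supported for the population trajectory of
a (log-scale) biomarker over follow-up time ``t`` in months:

* ``rational``:     (1, (t + delta)^(-eta)), delta > 0, eta > 0
* ``exponential``:  (1, exp(-delta * t)),    delta > 0
* ``spline``:       natural cubic spline with ``k`` interior knots
                    (dimension k + 2, including the intercept)
* ``constant``:     (1,) — degenerate intercept-only basis, useful for
                    random-intercept models and low-dimensional diagnostics.

The same basis row serves as both the fixed-effects and the random-effects
design (the z = x convention), so the random-effect dimension always equals
the basis dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BasisSpec", "natural_cubic_basis", "parametric_basis"]


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a trajectory basis.

    Parameters
    ----------
    kind
        One of ``rational``, ``exponential``, ``spline``, ``constant``.
    delta, eta
        Positive tuning parameters of the parametric families.  ``eta`` is
        only used by the rational family.
    knots
        Interior knot locations (months) for the spline family.
    boundary
        Boundary knots ``(t0, tf)`` for the spline family; the spline is
        linear outside this interval (natural constraints).
    extrapolation_guard
        Evaluating a spline further than this many months outside the
        boundary triggers a warning (the value is still the linear
        extension).
    """

    kind: str
    delta: float | None = None
    eta: float | None = None
    knots: tuple[float, ...] = ()
    boundary: tuple[float, float] = (0.0, 12.0)
    extrapolation_guard: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in {"rational", "exponential", "spline", "constant"}:
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind in {"rational", "exponential"}:
            if self.delta is None or self.delta <= 0:
                raise ValueError("delta must be > 0 for parametric bases")
        if self.kind == "rational":
            if self.eta is None or self.eta <= 0:
                raise ValueError("eta must be > 0 for the rational basis")
        if self.kind == "spline":
            k = np.asarray(self.knots, dtype=float)
            t0, tf = self.boundary
            if k.size and (np.any(np.diff(k) <= 0) or k[0] <= t0 or k[-1] >= tf):
                raise ValueError(
                    "interior knots must be strictly increasing and strictly "
                    "inside the boundary"
                )

    @property
    def dim(self) -> int:
        if self.kind == "constant":
            return 1
        if self.kind in {"rational", "exponential"}:
            return 2
        return len(self.knots) + 2

    def design(self, t: np.ndarray | float) -> np.ndarray:
        """Design matrix (len(t), dim) at times ``t`` (months)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.kind == "constant":
            return np.ones((t.size, 1))
        if self.kind in {"rational", "exponential"}:
            return parametric_basis(t, self)
        return natural_cubic_basis(t, self)


def parametric_basis(t: np.ndarray | float, spec: BasisSpec) -> np.ndarray:
    """Two-column design (intercept + decay term) of the parametric families."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if spec.kind == "rational":
        col = (t + spec.delta) ** (-spec.eta)
    elif spec.kind == "exponential":
        col = np.exp(-spec.delta * t)
    else:
        raise ValueError(f"{spec.kind!r} is not a parametric basis")
    return np.column_stack([np.ones_like(t), col])


def natural_cubic_basis(t: np.ndarray | float, spec: BasisSpec) -> np.ndarray:
    """Natural cubic spline design matrix.

    Uses the standard reduced basis {1, t, N_1, ..., N_k} built from
    truncated cubes, where each N_j is constrained to be linear beyond the
    boundary knots (zero second and third derivative outside [t0, tf]).
    With ``k`` interior knots the dimension is ``k + 2``.
    """
    if spec.kind != "spline":
        raise ValueError("natural_cubic_basis requires a spline spec")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    t0, tf = spec.boundary
    guard = spec.extrapolation_guard
    if np.any(t < t0 - guard) or np.any(t > tf + guard):
        warnings.warn(
            "evaluating natural cubic basis far outside the boundary knots; "
            "values are the linear extension",
            RuntimeWarning,
            stacklevel=2,
        )
    xi = np.concatenate([[t0], np.asarray(spec.knots, dtype=float), [tf]])
    K = xi.size  # total knots; basis dimension is K

    def d(j: int) -> np.ndarray:
        num = np.maximum(t - xi[j], 0.0) ** 3 - np.maximum(t - xi[K - 1], 0.0) ** 3
        return num / (xi[K - 1] - xi[j])

    cols = [np.ones_like(t), t]
    d_last = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - d_last)
    return np.column_stack(cols)


def default_spline_spec(times: np.ndarray, n_interior: int = 2) -> BasisSpec:
    """Spline spec with interior knots at evenly spaced quantiles of ``times``.

    With two interior knots these are the 33rd and 67th percentiles of the
    observed measurement times; boundary knots sit at the min and max.
    """
    times = np.asarray(times, dtype=float)
    t0, tf = float(times.min()), float(times.max())
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    knots = np.quantile(times, qs)
    # keep knots strictly interior even on degenerate inputs
    eps = 1e-8 * max(tf - t0, 1.0)
    knots = np.clip(knots, t0 + eps, tf - eps)
    knots = tuple(float(k) for k in np.unique(knots))
    return BasisSpec(kind="spline", knots=knots, boundary=(t0, tf))
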