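"""Shared-parameter joint model for a longitudinal biomarker and survival.

Model.  For patient ``i`` with baseline covariates ``w_i`` and random
effects ``b_i ~ N(0, D)``:

    y_ij = m_i(t_ij) + eps_ij,          m_i(t) = x(t)'(beta + b_i)
    h_i(t | b_i) = h0(t) exp{gamma' w_i + alpha * m_i(t)}

with ``eps ~ N(0, sigma^2)`` and a piecewise-constant baseline hazard
``h0``.  The association parameter ``alpha`` links the *current true*
biomarker level to the hazard.

Likelihood.  The marginal likelihood integrates the random effects out of
the product of the longitudinal density, the event density / survival
probability, and the random-effects prior:

    L_i = ∫ [prod_j N(y_ij; m_i, sigma^2)] h_i(T_i)^{d_i} exp(-H_i(T_i))
          N(b; 0, D) db.

The outer integral uses *adaptive* Gauss-Hermite quadrature: per patient
the integrand is re-centred at its mode and re-scaled by its curvature
(both found by a damped Newton search), which keeps few nodes accurate even
for concentrated posteriors.  The inner cumulative hazard uses fixed
Gauss-Legendre quadrature within each hazard piece.

Estimation is direct quasi-Newton (L-BFGS) on transformed parameters
(Cholesky factor of D with log diagonal, log sigma, log hazard heights)
with an analytic gradient obtained from the posterior-expectation identity
d log L_i / d theta = E[d log g / d theta | data].  Standard errors come
from a central-difference Hessian of that gradient at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm

from .basis import BasisSpec
from .longitudinal import LMEFit, fit_lme

logger = logging.getLogger(__name__)

__all__ = [
    "JointModelSpec",
    "JointModelFit",
    "piecewise_cumhaz",
    "joint_loglik",
    "fit_joint_model",
    "wald_table",
    "event_quantile_breaks",
]

_LOG2PI = np.log(2.0 * np.pi)


def piecewise_cumhaz(
    t: np.ndarray | float, heights: np.ndarray, breaks: np.ndarray
) -> np.ndarray:
    """Cumulative baseline hazard of a piecewise-constant h0.

    ``breaks`` are the Q+1 interval bounds starting at 0; ``heights`` the Q
    per-interval hazards.  Beyond the last break the last height is
    extrapolated (logged once per call).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    heights = np.asarray(heights, dtype=float)
    breaks = np.asarray(breaks, dtype=float)
    if breaks[0] != 0 or np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must start at 0 and increase strictly")
    if np.any(t > breaks[-1]):
        logger.debug("times beyond the last hazard break: extrapolating last height")
    lo = breaks[:-1]
    hi = breaks[1:]
    overlap = np.clip(t[:, None], lo[None, :], hi[None, :]) - lo[None, :]
    H = overlap @ heights
    H += np.maximum(t - breaks[-1], 0.0) * heights[-1]
    return H


def event_quantile_breaks(
    time_obs: np.ndarray, status: np.ndarray, n_pieces: int = 6
) -> np.ndarray:
    """Hazard breaks at event-time quantiles (equal events per piece)."""
    ev = np.asarray(time_obs, dtype=float)[np.asarray(status) == 1]
    if ev.size == 0:
        raise ValueError("no events; cannot place hazard breaks")
    qs = np.linspace(0, 1, n_pieces + 1)[1:-1]
    inner = np.quantile(ev, qs)
    top = float(np.max(time_obs)) + 1e-9
    breaks = np.concatenate([[0.0], np.unique(inner), [top]])
    return breaks


@dataclass
class JointModelSpec:
    """Structural settings of the joint model."""

    basis: BasisSpec
    hazard_breaks: np.ndarray | None = None  # None -> event sextiles at fit time
    n_hazard_pieces: int = 6
    n_quad: int | None = None  # Gauss-Hermite nodes per dimension
    n_gl: int = 15  # Gauss-Legendre nodes per hazard piece
    max_iter: int = 200
    rel_tol: float = 1e-7

    def gh_nodes(self, dim: int) -> int:
        if self.n_quad is not None:
            return self.n_quad
        return 9 if dim <= 2 else 5


@dataclass
class JointModelFit:
    spec: JointModelSpec
    covariate_names: list[str]
    beta: np.ndarray
    D: np.ndarray
    sigma2: float
    gamma: np.ndarray
    alpha: float
    hazard_breaks: np.ndarray
    h0_heights: np.ndarray
    se: dict = field(default_factory=dict)
    wald_p: dict = field(default_factory=dict)
    loglik: float = np.nan
    converged: bool = False
    n_iter: int = 0
    n_patients: int = 0
    n_events: int = 0
    params: np.ndarray = None
    param_names: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        """JSON-serializable fit summary (all parameters, se, p, loglik)."""
        return {
            "beta": np.asarray(self.beta).tolist(),
            "D": np.asarray(self.D).tolist(),
            "sigma2": float(self.sigma2),
            "gamma": dict(zip(self.covariate_names, np.asarray(self.gamma).tolist())),
            "alpha": float(self.alpha),
            "hazard_breaks": np.asarray(self.hazard_breaks).tolist(),
            "h0_heights": np.asarray(self.h0_heights).tolist(),
            "se": self.se,
            "wald_p": self.wald_p,
            "loglik": float(self.loglik),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_patients": self.n_patients,
            "n_events": self.n_events,
        }


class _JointLikelihood:
    """Vectorized joint log-likelihood with analytic gradient."""

    def __init__(
        self,
        baseline: pd.DataFrame,
        longitudinal: pd.DataFrame,
        covariates: list[str],
        spec: JointModelSpec,
    ):
        self.spec = spec
        basis = spec.basis
        self.p = basis.dim
        self.covariates = covariates
        base = baseline.sort_values("id").reset_index(drop=True)
        self.ids = base["id"].to_numpy()
        n = len(base)
        self.n = n
        # covariates are centred and scaled internally (and the biomarker is
        # centred inside the hazard) so the optimizer sees comparably
        # curved directions; pack/unpack translate to the natural scale.
        W_raw = base[covariates].to_numpy(dtype=float)
        self.w_mean = W_raw.mean(axis=0)
        sd = W_raw.std(axis=0)
        self.w_scale = np.where(sd > 1e-12, sd, 1.0)
        self.W = (W_raw - self.w_mean) / self.w_scale
        self.pw = self.W.shape[1]
        self.y_center = (
            float(longitudinal["y"].mean()) if len(longitudinal) else 0.0
        )
        self.T = base["time_obs"].to_numpy(dtype=float)
        self.delta = base["status"].to_numpy(dtype=float)
        self.n_events = int(self.delta.sum())

        if spec.hazard_breaks is None:
            self.breaks = event_quantile_breaks(
                self.T, self.delta, spec.n_hazard_pieces
            )
        else:
            self.breaks = np.asarray(spec.hazard_breaks, dtype=float)
        self.Q = self.breaks.size - 1

        # longitudinal layout, padded (n, Jmax)
        obs = {pid: g for pid, g in longitudinal.groupby("id")}
        Jmax = max((len(g) for g in obs.values()), default=1)
        Jmax = max(Jmax, 1)
        self.yobs = np.zeros((n, Jmax))
        self.omask = np.zeros((n, Jmax))
        self.Xobs = np.zeros((n, Jmax, self.p))
        for i, pid in enumerate(self.ids):
            g = obs.get(pid)
            if g is None or len(g) == 0:
                continue
            tt = g["t"].to_numpy(dtype=float)
            yy = g["y"].to_numpy(dtype=float)
            self.yobs[i, : tt.size] = yy
            self.omask[i, : tt.size] = 1.0
            self.Xobs[i, : tt.size] = basis.design(tt)
        self.nobs_i = self.omask.sum(axis=1)
        # X'X per patient for Newton curvature
        Xm = self.Xobs * self.omask[:, :, None]
        self.XtX = np.einsum("njp,njq->npq", Xm, self.Xobs)

        # survival design
        self.XT = basis.design(self.T)
        self.pieceT = np.clip(
            np.searchsorted(self.breaks, self.T, side="right") - 1, 0, self.Q - 1
        )

        # Gauss-Legendre layout over (0, T_i) per hazard piece, padded to
        # Q * n_gl columns; weights are zero where a piece has no overlap.
        gl_x, gl_w = np.polynomial.legendre.leggauss(spec.n_gl)
        lo = np.minimum(self.T[:, None], self.breaks[:-1][None, :])  # (n,Q)
        hi_edge = np.append(self.breaks[1:-1], np.inf)
        hi = np.minimum(self.T[:, None], hi_edge[None, :])
        length = np.maximum(hi - lo, 0.0)
        mid, half = 0.5 * (lo + hi), 0.5 * length
        Sq = mid[:, :, None] + half[:, :, None] * gl_x[None, None, :]  # (n,Q,ngl)
        Wq = half[:, :, None] * gl_w[None, None, :]
        self.Sq = Sq.reshape(n, -1)
        self.wq = Wq.reshape(n, -1)
        self.piece_idx = np.repeat(np.arange(self.Q), spec.n_gl)
        self.Xq = basis.design(self.Sq.ravel()).reshape(n, -1, self.p)

        # Gauss-Hermite tensor grid
        m_nodes = spec.gh_nodes(self.p)
        z1, w1 = np.polynomial.hermite.hermgauss(m_nodes)
        grids = np.meshgrid(*([z1] * self.p), indexing="ij")
        self.Z = np.column_stack([g.ravel() for g in grids])  # (B, p)
        wg = np.meshgrid(*([w1] * self.p), indexing="ij")
        logw = np.sum(np.log(np.column_stack([g.ravel() for g in wg])), axis=1)
        self.logw_plus_z2 = logw + np.sum(self.Z**2, axis=1)  # (B,)
        self.B = self.Z.shape[0]

        self._mode_cache = np.zeros((n, self.p))
        self.n_params = (
            self.p + self.p * (self.p + 1) // 2 + 1 + self.pw + 1 + self.Q
        )
        self.param_names = (
            [f"beta{j}" for j in range(self.p)]
            + [
                f"chol_D_{r}{c}" for r in range(self.p) for c in range(r + 1)
            ]
            + ["log_sigma"]
            + list(covariates)
            + ["alpha"]
            + [f"log_h0_{q}" for q in range(self.Q)]
        )

    # -- parameter packing ---------------------------------------------------
    # The packed vector holds the *internal* parameterization: gamma on the
    # standardized-covariate scale and hazard heights absorbing
    # exp(gamma' w_mean + alpha * y_center).  pack/unpack translate from/to
    # the natural scale; _split reads the internal values directly.

    def pack(self, beta, L, sigma, gamma, alpha, heights) -> np.ndarray:
        p = self.p
        gamma = np.asarray(gamma, dtype=float)
        heights = np.asarray(heights, dtype=float)
        gamma_int = gamma * self.w_scale
        log_h_int = (
            np.log(heights) + float(gamma @ self.w_mean) + alpha * self.y_center
        )
        lvals = []
        for r in range(p):
            for c in range(r + 1):
                lvals.append(np.log(max(L[r, c], 1e-8)) if r == c else L[r, c])
        return np.concatenate(
            [
                np.asarray(beta, dtype=float),
                lvals,
                [np.log(sigma)],
                gamma_int,
                [alpha],
                log_h_int,
            ]
        )

    def _split(self, params: np.ndarray):
        """Internal-scale parameters from the packed vector."""
        p, pw, Q = self.p, self.pw, self.Q
        k = 0
        beta = params[k : k + p]
        k += p
        L = np.zeros((p, p))
        for r in range(p):
            for c in range(r + 1):
                L[r, c] = np.exp(params[k]) if r == c else params[k]
                k += 1
        sigma = np.exp(params[k])
        k += 1
        gamma = params[k : k + pw]
        k += pw
        alpha = params[k]
        k += 1
        heights = np.exp(params[k : k + Q])
        return beta, L, sigma, gamma, alpha, heights

    def unpack(self, params: np.ndarray):
        """Natural-scale parameters from the packed vector."""
        beta, L, sigma, gamma_int, alpha, heights_int = self._split(params)
        gamma = gamma_int / self.w_scale
        heights = heights_int * np.exp(
            -float(gamma @ self.w_mean) - alpha * self.y_center
        )
        return beta, L, sigma, gamma, alpha, heights

    # -- core computations ---------------------------------------------------

    def _parts(self, beta, alpha, gamma, heights, sigma):
        """Parameter-dependent but b-independent pieces.

        ``base_q`` and ``base_T`` (hazard side) are centred by the mean
        observed biomarker; the heights are on the matching internal scale.
        """
        eta_w = self.W @ gamma  # (n,)
        base_obs = np.einsum("njp,p->nj", self.Xobs, beta)
        base_q = np.einsum("nqp,p->nq", self.Xq, beta) - self.y_center
        base_T = self.XT @ beta - self.y_center
        hq = self.wq * heights[self.piece_idx][None, :]  # (n,Qtot)
        return eta_w, base_obs, base_q, base_T, hq

    def _log_g_terms(self, b, parts, L, sigma, alpha):
        """log g(b) pieces for b of shape (n, B, p) -> (n, B) each."""
        eta_w, base_obs, base_q, base_T, hq = parts
        m_obs = base_obs[:, None, :] + b @ self.Xobs.transpose(0, 2, 1)
        r = (self.yobs[:, None, :] - m_obs) * self.omask[:, None, :]
        ll_y = -0.5 * (
            self.nobs_i[:, None] * (_LOG2PI + 2.0 * np.log(sigma))
            + np.sum(r**2, axis=2) / sigma**2
        )
        m_q = base_q[:, None, :] + b @ self.Xq.transpose(0, 2, 1)
        Hq = hq[:, None, :] * np.exp(alpha * m_q)  # (n,B,Qtot)
        H = np.exp(eta_w)[:, None] * np.sum(Hq, axis=2)
        m_T = base_T[:, None] + np.einsum("np,nbp->nb", self.XT, b)
        log_h = (
            np.log(np.maximum(self._heights[self.pieceT], 1e-300))[:, None]
            + eta_w[:, None]
            + alpha * m_T
        )
        ll_T = self.delta[:, None] * log_h - H
        u = b @ np.linalg.inv(L).T
        ll_b = (
            -0.5 * self.p * _LOG2PI
            - np.sum(np.log(np.diag(L)))
            - 0.5 * np.sum(u**2, axis=2)
        )
        return ll_y, ll_T, ll_b, m_obs, r, m_q, Hq, H, m_T, u

    def _find_modes(self, parts, L, Dinv, sigma, alpha, heights):
        """Damped Newton search for per-patient posterior modes (n, p)."""
        eta_w, base_obs, base_q, base_T, hq = parts
        b = self._mode_cache.copy()
        n, p = self.n, self.p

        def logg(bm):
            out = self._log_g_terms(bm[:, None, :], parts, L, sigma, alpha)
            return (out[0] + out[1] + out[2])[:, 0]

        cur = logg(b)
        for _ in range(30):
            m_obs = base_obs + (self.Xobs @ b[:, :, None])[:, :, 0]
            r = (self.yobs - m_obs) * self.omask
            g_y = (r[:, None, :] @ self.Xobs)[:, 0, :] / sigma**2
            m_q = base_q + (self.Xq @ b[:, :, None])[:, :, 0]
            hrow = hq * np.exp(alpha * m_q) * np.exp(eta_w)[:, None]
            g_T = alpha * (
                self.delta[:, None] * self.XT
                - (hrow[:, None, :] @ self.Xq)[:, 0, :]
            )
            g_b = -b @ Dinv.T
            grad = g_y + g_T + g_b
            Hs = (
                -self.XtX / sigma**2
                - alpha**2 * (self.Xq.transpose(0, 2, 1) * hrow[:, None, :]) @ self.Xq
                - Dinv[None, :, :]
            )
            step = np.linalg.solve(-Hs, grad[:, :, None])[:, :, 0]
            new_b = b + step
            new = logg(new_b)
            worse = new < cur - 1e-12
            halvings = 0
            while np.any(worse) and halvings < 8:
                step = np.where(worse[:, None], 0.5 * step, step)
                new_b = b + step
                new_w = logg(new_b)
                new = np.where(worse, new_w, new)
                worse = new < cur - 1e-12
                halvings += 1
            b = np.where((new >= cur - 1e-12)[:, None], new_b, b)
            moved = np.max(np.abs(step))
            cur = np.maximum(new, cur)
            if moved < 1e-9 or np.max(np.abs(grad)) < 1e-8:
                break
        # final curvature at the mode
        m_q = base_q + (self.Xq @ b[:, :, None])[:, :, 0]
        hrow = hq * np.exp(alpha * m_q) * np.exp(eta_w)[:, None]
        Hs = (
            -self.XtX / sigma**2
            - alpha**2 * (self.Xq.transpose(0, 2, 1) * hrow[:, None, :]) @ self.Xq
            - Dinv[None, :, :]
        )
        self._mode_cache = b
        return b, -Hs  # mode, precision A = -Hessian

    def value_and_grad(self, params: np.ndarray, want_grad: bool = True):
        beta, L, sigma, gamma, alpha, heights = self._split(params)
        self._heights = heights
        D = L @ L.T
        try:
            Dinv = np.linalg.inv(D)
            invL = np.linalg.inv(L)
        except np.linalg.LinAlgError:
            return -1e12, np.zeros(self.n_params)
        parts = self._parts(beta, alpha, gamma, heights, sigma)
        mode, A = self._find_modes(parts, L, Dinv, sigma, alpha, heights)
        M = np.linalg.cholesky(A)  # (n,p,p)
        invM = np.linalg.inv(M)
        # b nodes: mu + sqrt(2) * M^{-T} z
        offs = np.sqrt(2.0) * np.einsum("npq,bp->nbq", invM, self.Z)
        Bn = mode[:, None, :] + offs  # (n,B,p)
        ll_y, ll_T, ll_b, m_obs, r, m_q, Hq, H, m_T, u = self._log_g_terms(
            Bn, parts, L, sigma, alpha
        )
        logg = ll_y + ll_T + ll_b  # (n,B)
        log_norm = (
            0.5 * self.p * np.log(2.0)
            - np.sum(np.log(np.diagonal(M, axis1=1, axis2=2)), axis=1)
        )
        per = self.logw_plus_z2[None, :] + logg
        Li = log_norm + logsumexp(per, axis=1)
        total = float(np.sum(Li))
        if not want_grad:
            return total, None
        # posterior weights over nodes
        P = np.exp(per - logsumexp(per, axis=1, keepdims=True))  # (n,B)
        eta_w = parts[0]
        sigma2 = sigma**2

        # d beta
        d_beta_y = (r @ self.Xobs) / sigma2
        EHqX = Hq @ self.Xq
        d_beta_T = alpha * (
            self.delta[:, None, None] * self.XT[:, None, :]
            - np.exp(eta_w)[:, None, None] * EHqX
        )
        g_beta = np.einsum("nb,nbp->p", P, d_beta_y + d_beta_T)
        # d log sigma
        d_ls = np.sum(r**2, axis=2) / sigma2 - self.nobs_i[:, None]
        g_ls = float(np.einsum("nb,nb->", P, d_ls))
        # d gamma
        d_g = (self.delta[:, None] - H)[:, :, None] * self.W[:, None, :]
        g_gamma = np.einsum("nb,nbw->w", P, d_g)
        # d alpha
        d_a = self.delta[:, None] * m_T - np.exp(eta_w)[:, None] * np.einsum(
            "nbq,nbq->nb", Hq, m_q
        )
        g_alpha = float(np.einsum("nb,nb->", P, d_a))
        # d log h0 per piece
        Hq_piece = Hq.reshape(self.n, self.B, self.Q, self.spec.n_gl).sum(axis=3)
        d_h = -np.exp(eta_w)[:, None, None] * Hq_piece  # (n,B,Q)
        g_h = np.einsum("nb,nbq->q", P, d_h)
        ev_piece = np.zeros((self.n, self.Q))
        ev_piece[np.arange(self.n), self.pieceT] = self.delta
        g_h += ev_piece.sum(axis=0)
        # d chol(D): dlogphi/dL = L^{-T} (u u' - I)
        Euu = np.einsum("nb,nbp,nbq->pq", P, u, u)
        S = invL.T @ (Euu - float(self.n) * np.eye(self.p))
        g_L = []
        for rr in range(self.p):
            for cc in range(rr + 1):
                val = S[rr, cc]
                if rr == cc:
                    val *= L[rr, cc]  # chain rule through log-diagonal
                g_L.append(val)
        grad = np.concatenate(
            [g_beta, np.asarray(g_L), [g_ls], g_gamma, [g_alpha], g_h]
        )
        return total, grad

    def loglik(self, params: np.ndarray) -> float:
        return self.value_and_grad(params, want_grad=False)[0]


def joint_loglik(
    params: dict,
    baseline: pd.DataFrame,
    longitudinal: pd.DataFrame,
    covariates: list[str],
    spec: JointModelSpec,
) -> float:
    """Joint log-likelihood at explicit parameter values.

    ``params`` needs keys beta, D, sigma2, gamma, alpha, h0_heights (and the
    spec must carry explicit hazard_breaks).
    """
    lik = _JointLikelihood(baseline, longitudinal, covariates, spec)
    D = np.asarray(params["D"], dtype=float)
    L = np.linalg.cholesky(D)
    packed = lik.pack(
        params["beta"],
        L,
        float(np.sqrt(params["sigma2"])),
        params["gamma"],
        float(params["alpha"]),
        params["h0_heights"],
    )
    return lik.loglik(packed)


def _init_survival(
    baseline: pd.DataFrame, covariates: list[str], breaks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-exponential initial values: Cox gamma + occurrence/exposure."""
    from .survival import fit_cox

    try:
        cf = fit_cox(baseline, covariates)
        gamma = cf.gamma.to_numpy()
    except Exception:  # degenerate designs fall back to zero
        gamma = np.zeros(len(covariates))
    W = baseline[covariates].to_numpy(dtype=float)
    T = baseline["time_obs"].to_numpy(dtype=float)
    d = baseline["status"].to_numpy(dtype=float)
    risk = np.exp(W @ gamma)
    lo, hi = breaks[:-1], np.append(breaks[1:-1], np.inf)
    expo = np.clip(np.minimum(T[:, None], hi[None, :]) - lo[None, :], 0.0, None)
    Q = breaks.size - 1
    piece = np.clip(np.searchsorted(breaks, T, side="right") - 1, 0, Q - 1)
    dcount = np.zeros(Q)
    np.add.at(dcount, piece, d)
    denom = (expo * risk[:, None]).sum(axis=0)
    heights = np.maximum(dcount, 0.5) / np.maximum(denom, 1e-10)
    return gamma, heights


def fit_joint_model(
    baseline: pd.DataFrame,
    longitudinal: pd.DataFrame,
    covariates: list[str],
    spec: JointModelSpec,
    init: dict | None = None,
    compute_se: bool = True,
    constrain_alpha: float | None = None,
) -> JointModelFit:
    """Maximum-likelihood joint model fit.

    Initialized from a separate LME fit and a piecewise-exponential survival
    fit with alpha = 0, then maximized by L-BFGS with the analytic gradient.
    ``constrain_alpha`` pins the association (used for likelihood-ratio and
    separability checks).
    """
    lik = _JointLikelihood(baseline, longitudinal, covariates, spec)
    if init is None:
        lme = fit_lme(longitudinal, spec.basis)
        D0 = lme.D + 1e-4 * np.trace(lme.D) / lik.p * np.eye(lik.p)
        gamma0, h0 = _init_survival(baseline, covariates, lik.breaks)
        init = {
            "beta": lme.beta,
            "D": D0,
            "sigma2": max(lme.sigma2, 1e-4),
            "gamma": gamma0,
            "alpha": 0.0,
            "h0_heights": h0,
        }
    L0 = np.linalg.cholesky(np.asarray(init["D"], dtype=float))
    x0 = lik.pack(
        init["beta"],
        L0,
        float(np.sqrt(init["sigma2"])),
        init["gamma"],
        float(init["alpha"]),
        init["h0_heights"],
    )

    alpha_pos = lik.p + lik.p * (lik.p + 1) // 2 + 1 + lik.pw

    def neg(params: np.ndarray):
        if constrain_alpha is not None:
            params = params.copy()
            params[alpha_pos] = constrain_alpha
        val, grad = lik.value_and_grad(params)
        if constrain_alpha is not None:
            grad = grad.copy()
            grad[alpha_pos] = 0.0
        return -val, -grad

    # keep variance components out of degenerate corners where the
    # likelihood is flat and the numeric Hessian uninformative
    bounds = []
    for name in lik.param_names:
        if name.startswith("chol_D_") and name[-2] == name[-1]:
            bounds.append((np.log(1e-5), None))
        elif name == "log_sigma":
            bounds.append((np.log(1e-4), None))
        elif name.startswith("log_h0_"):
            bounds.append((-30.0, 5.0))
        else:
            bounds.append((None, None))

    res = optimize.minimize(
        neg,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": spec.max_iter,
            "ftol": spec.rel_tol,
            "gtol": 1e-6,
            "maxcor": 20,
        },
    )
    xhat = res.x
    if constrain_alpha is not None:
        xhat[alpha_pos] = constrain_alpha
    beta, L, sigma, gamma, alpha, heights = lik.unpack(xhat)
    ll = lik.loglik(xhat)

    se: dict = {}
    wald: dict = {}
    if compute_se:
        se, wald = _wald_from_hessian(lik, xhat, covariates)
    fit = JointModelFit(
        spec=spec,
        covariate_names=covariates,
        beta=beta,
        D=L @ L.T,
        sigma2=float(sigma**2),
        gamma=gamma,
        alpha=float(alpha),
        hazard_breaks=lik.breaks,
        h0_heights=heights,
        se=se,
        wald_p=wald,
        loglik=float(ll),
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_patients=lik.n,
        n_events=lik.n_events,
        params=xhat,
        param_names=lik.param_names,
    )
    if not res.success:
        logger.warning("joint model optimizer did not report convergence: %s", res.message)
    return fit


def _wald_from_hessian(
    lik: _JointLikelihood, xhat: np.ndarray, covariates: list[str], step: float = 1e-4
) -> tuple[dict, dict]:
    """SEs from a central-difference Hessian of the analytic gradient."""
    k = xhat.size
    H = np.zeros((k, k))
    for j in range(k):
        xp = xhat.copy()
        xm = xhat.copy()
        xp[j] += step
        xm[j] -= step
        _, gp = lik.value_and_grad(xp)
        _, gm = lik.value_and_grad(xm)
        H[:, j] = (gp - gm) / (2 * step)
    H = 0.5 * (H + H.T)
    se: dict = {}
    wald: dict = {}
    try:
        cov = np.linalg.inv(-H)
        dvar = np.diag(cov).copy()
        # near-flat directions (typically collapsed variance components)
        # produce unusable curvature for *those* parameters only; the
        # coefficient block is still informative
        dvar[dvar <= 0] = np.nan
        sevec = np.sqrt(dvar)
        # gamma entries sit on the standardized-covariate scale internally;
        # estimates and SEs rescale linearly back to the natural scale.
        gamma_lo = lik.p + lik.p * (lik.p + 1) // 2 + 1
        scale = np.ones(xhat.size)
        scale[gamma_lo : gamma_lo + lik.pw] = lik.w_scale
        for j, name in enumerate(lik.param_names):
            if name.startswith("log_h0_"):
                continue  # heights are reported without SEs
            s = sevec[j] / scale[j]
            est = xhat[j] / scale[j]
            se[name] = float(s)
            wald[name] = (
                float(2.0 * norm.sf(abs(est) / s)) if np.isfinite(s) and s > 0 else np.nan
            )
    except np.linalg.LinAlgError:
        logger.warning("singular Hessian: standard errors unavailable")
    return se, wald


def wald_table(fit: JointModelFit) -> pd.DataFrame:
    """Coefficient table (estimate, se, p, significance at 5%).

    Rows cover the survival coefficients (one per baseline covariate), the
    association alpha, and the longitudinal fixed effects.
    """
    if not fit.se:
        raise ValueError("fit has no standard errors")
    rows = []
    est = {name: g for name, g in zip(fit.covariate_names, fit.gamma)}
    est["alpha"] = fit.alpha
    est.update({f"beta{j}": v for j, v in enumerate(fit.beta)})
    order = (
        list(fit.covariate_names)
        + ["alpha"]
        + [f"beta{j}" for j in range(fit.beta.size)]
    )
    for name in order:
        s = fit.se.get(name, np.nan)
        p = fit.wald_p.get(name, np.nan)
        rows.append(
            {
                "parameter": name,
                "estimate": est[name],
                "se": s,
                "p": p,
                "significant_5pct": bool(p < 0.05) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)
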