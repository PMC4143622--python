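"""Group-based trajectory modelling: finite mixtures of polynomial growth curves.

The model assumes a population composed of ``k`` latent subgroups. Within
subgroup ``j`` an individual's trait at time ``t`` is

    y_it = sum_d beta_jd * t^d + gamma' x_it + e_it,   e_it ~ N(0, sigma^2)

with a polynomial mean trajectory of subgroup-specific order, optional
covariate effects, and a residual standard deviation shared across
subgroups. Visits are conditionally independent given subgroup, so an
individual's density is the pi-weighted product over observed visits.
Estimation is by EM with weighted-least-squares M-steps; the posterior
subgroup membership probabilities (one row per individual, columns summing
to one) are the Bayesian posterior probabilities (BPPs) used downstream as
a derived phenotype.

Model selection follows a two-run protocol: a first run with cubic
trajectories in every subgroup, after which each subgroup's polynomial
order is cut back to the highest-order term still significant (Wald test)
at a chosen level; a second, final run with the pruned orders (covariates,
when requested, enter only in this final run). The number of subgroups is
chosen by the Bayesian information criterion in the form
``loglik - (p/2) * ln(N)`` (higher is better), with ties broken toward
fewer subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm


def _logsumexp(a: np.ndarray, axis: int = -1, keepdims: bool = False) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return out if keepdims else np.squeeze(out, axis=axis)

from .longdata import LongitudinalData

__all__ = [
    "TrajectoryModelSpec",
    "GroupTrajectoryModel",
    "GroupTrajectoryResults",
    "count_params",
    "fit_mixture",
    "prune_orders",
    "prune_rule",
    "select_model",
]

MAX_ORDER = 3


class ConvergenceError(RuntimeError):
    """Raised when no EM restart converges where a converged fit is required."""


@dataclass
class TrajectoryModelSpec:
    """Structural description of one mixture fit.

    Attributes
    ----------
    k : int
        Number of latent trajectory subgroups (>= 1).
    orders : list of int
        Polynomial order of each subgroup's mean trajectory, each in 0..3.
    use_covariates : bool
        Whether covariate effects enter the subgroup means.
    covariate_sharing : {"group-specific", "shared"}
        Whether each subgroup has its own covariate coefficients or one
        common vector is shared by all subgroups.
    """

    k: int
    orders: list[int] = field(default_factory=list)
    use_covariates: bool = False
    covariate_sharing: str = "group-specific"

    def __post_init__(self) -> None:
        if not self.orders:
            self.orders = [MAX_ORDER] * self.k
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.orders) != self.k:
            raise ValueError("orders must have length k")
        if any(o < 0 or o > MAX_ORDER for o in self.orders):
            raise ValueError(f"orders must lie in 0..{MAX_ORDER}")
        if self.covariate_sharing not in ("group-specific", "shared"):
            raise ValueError("covariate_sharing must be 'group-specific' or 'shared'")


def count_params(spec: TrajectoryModelSpec, n_covariates: int = 0) -> int:
    """Number of free parameters p of a mixture fit.

    Polynomial coefficients (order_j + 1 per subgroup), k-1 free mixing
    proportions, one shared residual SD, and the covariate coefficients
    (n_covariates if shared across subgroups, k * n_covariates otherwise).
    """
    p = sum(o + 1 for o in spec.orders) + (spec.k - 1) + 1
    if spec.use_covariates and n_covariates:
        p += n_covariates if spec.covariate_sharing == "shared" else spec.k * n_covariates
    return p


class GroupTrajectoryModel:
    """Finite mixture of polynomial trajectories for longitudinal data.

    Parameters
    ----------
    data : LongitudinalData
        The repeated measurements.
    spec : TrajectoryModelSpec
        Subgroup count, polynomial orders and covariate handling.
    sigma_shared : bool
        Residual SD shared across subgroups (the conventional choice);
        set False for subgroup-specific SDs.
    bic_sample_size : {"individuals", "observations"}
        N used in the BIC penalty.
    """

    def __init__(
        self,
        data: LongitudinalData,
        spec: TrajectoryModelSpec,
        sigma_shared: bool = True,
        bic_sample_size: str = "individuals",
    ):
        if spec.k > data.n_individuals:
            raise ValueError(
                f"k={spec.k} exceeds the number of individuals ({data.n_individuals})"
            )
        self.data = data
        self.spec = spec
        self.sigma_shared = sigma_shared
        self.bic_sample_size = bic_sample_size

        self._y = data.values
        self._t = data.times
        self._m = data.mask.astype(float)
        self._n, self._T = self._y.shape
        # polynomial design per subgroup: (N, T, order_j + 1)
        self._Xp = [
            np.stack([self._t**d for d in range(o + 1)], axis=2) for o in spec.orders
        ]
        if spec.use_covariates:
            self._Xc = data.covariate_matrix()
        else:
            self._Xc = np.zeros((self._n, self._T, 0))
        self._nc = self._Xc.shape[2]
        obs = self._y[data.mask]
        self._sigma_floor = max(1e-6 * float(np.std(obs)), 1e-12)

    # ------------------------------------------------------------------
    @property
    def n_params(self) -> int:
        return count_params(self.spec, self._nc)

    def _mu(self, beta: list[np.ndarray], gamma: np.ndarray) -> np.ndarray:
        """Subgroup means, shape (N, T, k)."""
        k = self.spec.k
        mu = np.empty((self._n, self._T, k))
        for j in range(k):
            mu[:, :, j] = self._Xp[j] @ beta[j]
            if self._nc:
                gj = gamma if gamma.ndim == 1 else gamma[j]
                mu[:, :, j] += self._Xc @ gj
        return mu

    def _logdens(self, mu: np.ndarray, sigma) -> np.ndarray:
        """Per-individual per-subgroup log density over observed visits, (N, k)."""
        sig = np.broadcast_to(np.atleast_1d(sigma), (self.spec.k,))
        r = self._y[:, :, None] - mu
        ll = -0.5 * np.log(2 * np.pi * sig**2)[None, None, :] - r**2 / (
            2 * sig**2
        )[None, None, :]
        return np.einsum("ntk,nt->nk", ll, self._m)

    def loglik(self, params: dict) -> float:
        ld = self._logdens(self._mu(params["beta"], params["gamma"]), params["sigma"])
        return float(np.sum(_logsumexp(np.log(params["pi"])[None, :] + ld, axis=1)))

    # -- EM ------------------------------------------------------------
    def _m_step(self, resp: np.ndarray) -> dict:
        k = self.spec.k
        w = resp[:, None, :] * self._m[:, :, None]  # (N, T, k)
        group_specific = self.spec.covariate_sharing == "group-specific" or self._nc == 0
        beta: list[np.ndarray] = [None] * k  # type: ignore[list-item]
        if group_specific:
            gamma = np.zeros((k, self._nc))
            for j in range(k):
                D = (
                    np.concatenate([self._Xp[j], self._Xc], axis=2)
                    if self._nc
                    else self._Xp[j]
                )
                Df = D.reshape(-1, D.shape[2])
                wf = w[:, :, j].ravel()
                yf = np.where(self._m.ravel() > 0, self._y.ravel(), 0.0)
                A = Df.T @ (Df * wf[:, None])
                b = Df.T @ (wf * yf)
                A[np.diag_indices_from(A)] += 1e-10
                coef = np.linalg.solve(A, b)
                pj = self.spec.orders[j] + 1
                beta[j] = coef[:pj]
                if self._nc:
                    gamma[j] = coef[pj:]
            if self._nc == 0:
                gamma = np.zeros(0)
        else:  # shared covariate coefficients: one joint WLS across subgroups
            pj = [o + 1 for o in self.spec.orders]
            P = sum(pj) + self._nc
            A = np.zeros((P, P))
            b = np.zeros(P)
            offs = np.concatenate([[0], np.cumsum(pj)])
            yf = np.where(self._m > 0, self._y, 0.0).ravel()
            Xcf = self._Xc.reshape(-1, self._nc)
            for j in range(k):
                Xj = self._Xp[j].reshape(-1, pj[j])
                wf = w[:, :, j].ravel()
                s = slice(offs[j], offs[j + 1])
                A[s, s] += Xj.T @ (Xj * wf[:, None])
                A[s, -self._nc:] += Xj.T @ (Xcf * wf[:, None])
                A[-self._nc:, s] += (Xcf * wf[:, None]).T @ Xj
                A[-self._nc:, -self._nc:] += Xcf.T @ (Xcf * wf[:, None])
                b[s] += Xj.T @ (wf * yf)
                b[-self._nc:] += Xcf.T @ (wf * yf)
            A[np.diag_indices_from(A)] += 1e-10
            coef = np.linalg.solve(A, b)
            beta = [coef[offs[j] : offs[j + 1]] for j in range(k)]
            gamma = coef[-self._nc:]

        mu = self._mu(beta, gamma)
        r2 = (self._y[:, :, None] - mu) ** 2
        if self.sigma_shared:
            sigma = float(np.sqrt(np.sum(w * r2) / max(np.sum(w), 1e-300)))
            sigma = max(sigma, self._sigma_floor)
        else:
            num = np.einsum("ntk,ntk->k", w, r2)
            den = np.maximum(np.sum(w, axis=(0, 1)), 1e-300)
            sigma = np.maximum(np.sqrt(num / den), self._sigma_floor)
        pi = np.maximum(resp.mean(axis=0), 1e-12)
        pi = pi / pi.sum()
        return {"beta": beta, "gamma": gamma, "pi": pi, "sigma": sigma}

    def _e_step(self, params: dict) -> tuple[np.ndarray, float]:
        ld = self._logdens(self._mu(params["beta"], params["gamma"]), params["sigma"])
        lw = np.log(params["pi"])[None, :] + ld
        norm_ = _logsumexp(lw, axis=1)
        resp = np.exp(lw - norm_[:, None])
        return resp, float(norm_.sum())

    def _init_resp(self, rng: np.random.Generator, restart: int) -> np.ndarray:
        """Hard assignment from a quantile split of individual means, jittered."""
        k = self.spec.k
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            means = np.nansum(np.where(self._m > 0, self._y, 0), axis=1) / np.maximum(
                self._m.sum(axis=1), 1
            )
        order = np.argsort(means, kind="stable")
        groups = np.empty(self._n, dtype=int)
        for j, chunk in enumerate(np.array_split(order, k)):
            groups[chunk] = j
        if restart > 0:
            flip = rng.random(self._n) < 0.3
            groups[flip] = rng.integers(0, k, size=flip.sum())
        resp = np.zeros((self._n, k))
        resp[np.arange(self._n), groups] = 1.0
        # small smoothing so no subgroup starts empty
        resp = 0.95 * resp + 0.05 / k
        return resp

    def fit(
        self,
        n_restarts: int = 10,
        seed: int | None = None,
        max_iter: int = 500,
        tol: float = 1e-8,
        compute_se: bool = True,
    ) -> "GroupTrajectoryResults":
        """Run EM from several initializations; keep the best converged fit.

        Returns the restart with the highest log-likelihood among those that
        converged; if none converged, the best non-converged fit is returned
        with ``converged=False``.
        """
        if n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        rng = np.random.default_rng(seed)
        best = None
        best_ll = -np.inf
        best_conv = False
        n_used = 0
        for r in range(n_restarts):
            n_used += 1
            resp = self._init_resp(rng, r)
            params = self._m_step(resp)
            ll_prev = -np.inf
            converged = False
            trace = []
            for _ in range(max_iter):
                resp, ll = self._e_step(params)
                trace.append(ll)
                if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol:
                    converged = True
                    break
                ll_prev = ll
                params = self._m_step(resp)
            resp, ll = self._e_step(params)
            better = (converged and not best_conv) or (
                converged == best_conv and ll > best_ll
            )
            if best is None or better:
                best = (params, resp, ll, converged, list(trace))
                best_ll = ll
                best_conv = converged
        params, resp, ll, converged, trace = best  # type: ignore[misc]
        res = GroupTrajectoryResults(
            model=self,
            spec=self.spec,
            beta=params["beta"],
            gamma=params["gamma"],
            pi=params["pi"],
            sigma=params["sigma"],
            loglik=ll,
            bpp=resp,
            converged=converged,
            n_restarts_used=n_used,
            em_trace=trace,
        )
        if compute_se:
            res._compute_wald()
        return res

    # -- packed parameter vector (for observed information) -------------
    def _pack(self, params: dict) -> np.ndarray:
        theta = [np.concatenate(params["beta"])]
        if self._nc:
            theta.append(np.ravel(params["gamma"]))
        pi = params["pi"]
        if self.spec.k > 1:
            theta.append(np.log(pi[:-1] / pi[-1]))
        sig = np.atleast_1d(params["sigma"])
        theta.append(np.log(sig if not self.sigma_shared else sig[:1]))
        return np.concatenate(theta)

    def _loglik_batch(self, thetas: np.ndarray) -> np.ndarray:
        """Log-likelihood for a batch of packed parameter vectors, (B,)."""
        k = self.spec.k
        B = thetas.shape[0]
        pj = [o + 1 for o in self.spec.orders]
        offs = np.concatenate([[0], np.cumsum(pj)])
        pos = offs[-1]
        mu = np.zeros((B, self._n, self._T, k))
        for j in range(k):
            bj = thetas[:, offs[j] : offs[j + 1]]
            mu[:, :, :, j] = np.einsum("ntp,bp->bnt", self._Xp[j], bj)
        if self._nc:
            if self.spec.covariate_sharing == "shared":
                g = thetas[:, pos : pos + self._nc]
                pos += self._nc
                mu += np.einsum("ntc,bc->bnt", self._Xc, g)[:, :, :, None]
            else:
                for j in range(k):
                    g = thetas[:, pos : pos + self._nc]
                    pos += self._nc
                    mu[:, :, :, j] += np.einsum("ntc,bc->bnt", self._Xc, g)
        if k > 1:
            alpha = thetas[:, pos : pos + k - 1]
            pos += k - 1
            a = np.concatenate([alpha, np.zeros((B, 1))], axis=1)
            logpi = a - _logsumexp(a, axis=1, keepdims=True)
        else:
            logpi = np.zeros((B, 1))
        nsig = 1 if self.sigma_shared else k
        sig = np.exp(thetas[:, pos : pos + nsig])
        sig = np.broadcast_to(sig, (B, k)) if nsig == 1 else sig
        r = self._y[None, :, :, None] - mu
        s2 = sig[:, None, None, :] ** 2
        ll = -0.5 * np.log(2 * np.pi * s2) - r**2 / (2 * s2)
        ld = np.einsum("bntk,nt->bnk", ll, self._m)
        return _logsumexp(logpi[:, None, :] + ld, axis=2).sum(axis=1)

    def _unpack(self, theta: np.ndarray) -> dict:
        """Inverse of :meth:`_pack`."""
        k = self.spec.k
        pj = [o + 1 for o in self.spec.orders]
        offs = np.concatenate([[0], np.cumsum(pj)])
        beta = [theta[offs[j] : offs[j + 1]] for j in range(k)]
        pos = offs[-1]
        if self._nc:
            if self.spec.covariate_sharing == "shared":
                gamma = theta[pos : pos + self._nc]
                pos += self._nc
            else:
                gamma = theta[pos : pos + k * self._nc].reshape(k, self._nc)
                pos += k * self._nc
        else:
            gamma = np.zeros((k, self._nc))
        if k > 1:
            a = np.concatenate([theta[pos : pos + k - 1], [0.0]])
            pi = np.exp(a - _logsumexp(a))
            pos += k - 1
        else:
            pi = np.ones(1)
        nsig = 1 if self.sigma_shared else k
        sig = np.exp(theta[pos : pos + nsig])
        sigma = float(sig[0]) if self.sigma_shared else sig
        return {"beta": beta, "gamma": gamma, "pi": pi, "sigma": sigma}

    def _score(self, theta: np.ndarray) -> np.ndarray:
        """Analytic gradient of the log-likelihood in the packed parameters.

        Uses the mixture identity: the score is the responsibility-weighted
        sum of component-wise complete-data scores.
        """
        k = self.spec.k
        p = self._unpack(theta)
        mu = self._mu(p["beta"], p["gamma"])
        ld = self._logdens(mu, p["sigma"])
        lw = np.log(p["pi"])[None, :] + ld
        w = np.exp(lw - _logsumexp(lw, axis=1, keepdims=True))  # (N, k)
        sig = np.broadcast_to(np.atleast_1d(p["sigma"]), (k,))
        rm = (self._y[:, :, None] - mu) * self._m[:, :, None]  # (N, T, k)

        parts = []
        for j in range(k):
            parts.append(
                np.einsum("n,nt,ntp->p", w[:, j], rm[:, :, j], self._Xp[j])
                / sig[j] ** 2
            )
        if self._nc:
            gj = [
                np.einsum("n,nt,ntc->c", w[:, j], rm[:, :, j], self._Xc) / sig[j] ** 2
                for j in range(k)
            ]
            if self.spec.covariate_sharing == "shared":
                parts.append(np.sum(gj, axis=0))
            else:
                parts.extend(gj)
        if k > 1:
            parts.append(w[:, :-1].sum(axis=0) - self._n * p["pi"][:-1])
        nobs = self._m.sum(axis=1)
        ss = np.einsum("ntk,nt->nk", (self._y[:, :, None] - mu) ** 2, self._m)
        if self.sigma_shared:
            parts.append(
                np.array([np.sum(w * (ss / sig[0] ** 2 - nobs[:, None]))])
            )
        else:
            parts.append(
                np.einsum("nk,nk->k", w, ss / sig[None, :] ** 2 - nobs[:, None])
            )
        return np.concatenate(parts)


@dataclass
class GroupTrajectoryResults:
    """Fitted trajectory mixture: estimates, uncertainty and posteriors.

    Attributes
    ----------
    beta : list of ndarray
        Polynomial coefficients per subgroup (constant term first).
    gamma : ndarray
        Covariate coefficients, (k, C) when subgroup-specific or (C,).
    pi : ndarray
        Subgroup membership probabilities (sums to 1).
    sigma : float or ndarray
        Residual SD (shared scalar by default).
    loglik, n_params, bic : float, int, float
        Maximized log-likelihood; free-parameter count p;
        BIC = loglik - (p/2) ln(N), higher is better.
    bpp : ndarray, shape (N, k)
        Bayesian posterior probabilities of subgroup membership.
    coef_pvalues : list of ndarray
        Two-sided Wald p-values for each subgroup's polynomial coefficients.
    """

    model: GroupTrajectoryModel
    spec: TrajectoryModelSpec
    beta: list[np.ndarray]
    gamma: np.ndarray
    pi: np.ndarray
    sigma: float | np.ndarray
    loglik: float
    bpp: np.ndarray
    converged: bool
    n_restarts_used: int
    em_trace: list[float] = field(default_factory=list)
    coef_se: list[np.ndarray] = field(default_factory=list)
    coef_pvalues: list[np.ndarray] = field(default_factory=list)
    gamma_se: np.ndarray | None = None
    gamma_pvalues: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def bic(self) -> float:
        if self.model.bic_sample_size == "observations":
            n = int(self.model.data.mask.sum())
        else:
            n = self.model.data.n_individuals
        return self.loglik - (self.n_params / 2.0) * np.log(n)

    @property
    def assigned_group(self) -> np.ndarray:
        """Modal subgroup per individual (0-based)."""
        return np.argmax(self.bpp, axis=1)

    def predict_trajectory(self, group: int, t) -> np.ndarray:
        """Fitted polynomial mean of one subgroup at times ``t``.

        Covariate terms are excluded (reference level zero).
        """
        t = np.asarray(t, dtype=float)
        b = self.beta[group]
        return sum(b[d] * t**d for d in range(len(b)))

    # ------------------------------------------------------------------
    def _compute_wald(self) -> None:
        """Wald SEs/p-values from the numerical observed information.

        Central-difference Hessian of the log-likelihood in the packed free
        parameters (beta, gamma, mixing logits, log sigma), inverted to get
        the coefficient covariance; p-values from the standard normal.
        """
        m = self.model
        params = {"beta": self.beta, "gamma": self.gamma, "pi": self.pi, "sigma": self.sigma}
        theta = m._pack(params)
        p = len(theta)
        h = 1e-5 * np.maximum(1.0, np.abs(theta))
        H = np.empty((p, p))
        for a in range(p):
            step = h[a] * _e(p, a)
            H[:, a] = (m._score(theta + step) - m._score(theta - step)) / (2 * h[a])
        H = (H + H.T) / 2.0
        info = -H
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        var = np.diag(cov).copy()
        var[var < 0] = np.nan  # information not PD at a boundary
        se = np.sqrt(var)
        offs = np.concatenate([[0], np.cumsum([o + 1 for o in self.spec.orders])])
        self.coef_se = [se[offs[j] : offs[j + 1]] for j in range(self.spec.k)]
        with np.errstate(invalid="ignore"):
            self.coef_pvalues = [
                2 * norm.sf(np.abs(self.beta[j] / self.coef_se[j]))
                for j in range(self.spec.k)
            ]
        nc = m._nc
        if nc:
            pos = offs[-1]
            ng = nc if self.spec.covariate_sharing == "shared" else self.spec.k * nc
            gse = se[pos : pos + ng]
            gflat = np.ravel(self.gamma)
            self.gamma_se = gse.reshape(np.shape(self.gamma))
            with np.errstate(invalid="ignore"):
                self.gamma_pvalues = (
                    2 * norm.sf(np.abs(gflat / gse))
                ).reshape(np.shape(self.gamma))

    def summary(self) -> str:
        lines = [
            "Group-based trajectory model",
            "=" * 64,
            f"subgroups (k):      {self.spec.k}",
            f"polynomial orders:  {self.spec.orders}",
            f"individuals:        {self.model.data.n_individuals}",
            f"log-likelihood:     {self.loglik:.4f}",
            f"free parameters:    {self.n_params}",
            f"BIC (higher=best):  {self.bic:.4f}",
            f"converged:          {self.converged} ({self.n_restarts_used} restarts)",
            f"sigma:              {np.round(self.sigma, 4)}",
            "-" * 64,
        ]
        for j in range(self.spec.k):
            lines.append(f"subgroup {j + 1}: pi = {self.pi[j]:.4f}")
            for d, b in enumerate(self.beta[j]):
                se = self.coef_se[j][d] if self.coef_se else np.nan
                pv = self.coef_pvalues[j][d] if self.coef_pvalues else np.nan
                lines.append(
                    f"    t^{d}: {b:12.4f}   se {se:10.4f}   p {pv:10.3g}"
                )
        if self.model._nc:
            lines.append("covariates:")
            g = np.atleast_2d(self.gamma)
            names = self.model.data.covariate_names
            for j in range(g.shape[0]):
                tag = "" if g.shape[0] == 1 else f" (subgroup {j + 1})"
                for c, name in enumerate(names):
                    lines.append(f"    {name}{tag}: {g[j, c]:.4f}")
        return "\n".join(lines)


def _e(p: int, i: int) -> np.ndarray:
    v = np.zeros(p)
    v[i] = 1.0
    return v


# ---------------------------------------------------------------------------
# Functional interface
# ---------------------------------------------------------------------------

def fit_mixture(
    data: LongitudinalData,
    spec: TrajectoryModelSpec,
    n_restarts: int = 10,
    seed: int | None = None,
    **kwargs,
) -> GroupTrajectoryResults:
    """Fit one mixture specification; best converged restart wins."""
    return GroupTrajectoryModel(data, spec, **kwargs).fit(
        n_restarts=n_restarts, seed=seed
    )


def prune_orders(
    data: LongitudinalData,
    k: int,
    alpha: float = 0.05,
    seed: int | None = None,
    n_restarts: int = 10,
) -> TrajectoryModelSpec:
    """First-run order pruning: all-cubic fit, then keep the highest
    significant order per subgroup.

    Each subgroup's final order is the largest d in {1, 2, 3} whose
    coefficient Wald p-value is below ``alpha``, or 0 when no non-constant
    term is significant; the constant term is never removed.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    # a degree-d polynomial needs d+1 distinct time points to be identified,
    # so the first run caps the order at n_visits - 1
    init_order = min(MAX_ORDER, data.n_visits - 1)
    first = fit_mixture(
        data,
        TrajectoryModelSpec(k=k, orders=[init_order] * k),
        n_restarts=n_restarts,
        seed=seed,
    )
    if not first.converged:
        raise ConvergenceError(
            f"first-run all-cubic fit (k={k}) did not converge after "
            f"{first.n_restarts_used} restarts; loglik={first.loglik:.3f}"
        )
    orders = [prune_rule(first.coef_pvalues[j], alpha) for j in range(k)]
    return TrajectoryModelSpec(k=k, orders=orders)


def prune_rule(pvalues, alpha: float) -> int:
    """Largest polynomial order whose coefficient is significant.

    ``pvalues`` are the Wald p-values for orders 0..3 of one subgroup; the
    result is the largest d >= 1 with p_d < alpha, or 0 when no
    non-constant term qualifies. The intercept is never removed.
    """
    sig = [
        d
        for d in range(1, len(pvalues))
        if np.isfinite(pvalues[d]) and pvalues[d] < alpha
    ]
    return max(sig) if sig else 0


def select_model(
    data: LongitudinalData,
    k_max: int = 6,
    use_covariates: bool = False,
    alpha: float = 0.05,
    n_restarts: int = 10,
    seed: int | None = None,
    covariate_sharing: str = "group-specific",
) -> GroupTrajectoryResults:
    """Two-run fits for k = 1..k_max; return the highest-BIC model.

    For each k the all-cubic first run determines pruned polynomial orders;
    the final run refits with those orders, introducing covariates (when
    requested) only at this final stage. Ties in BIC go to the smaller k.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    rng = np.random.default_rng(seed)
    best: GroupTrajectoryResults | None = None
    failures = []
    for k in range(1, k_max + 1):
        sub = int(rng.integers(0, 2**31 - 1))
        try:
            spec = prune_orders(data, k, alpha=alpha, seed=sub, n_restarts=n_restarts)
        except (ConvergenceError, ValueError) as exc:
            failures.append((k, str(exc)))
            continue
        spec = TrajectoryModelSpec(
            k=k,
            orders=spec.orders,
            use_covariates=use_covariates,
            covariate_sharing=covariate_sharing,
        )
        fit = fit_mixture(data, spec, n_restarts=n_restarts, seed=sub + 1)
        if not fit.converged:
            failures.append((k, "final fit not converged"))
            continue
        if best is None or fit.bic > best.bic:  # strict: ties keep smaller k
            best = fit
    if best is None:
        raise ConvergenceError(f"no k in 1..{k_max} produced a converged fit: {failures}")
    return best
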