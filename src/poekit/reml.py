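"""Restricted maximum likelihood for linear mixed models with dense covariances.

Fits y = X b + sum_i u_i + e with u_i ~ N(0, sigma_i^2 A_i) for an arbitrary
list of relationship matrices A_i plus an iid residual.  Estimation is
average-information (AI) REML with expectation-maximisation fallback steps
when an AI proposal leaves the parameter space, step-halving to keep the
restricted log-likelihood non-decreasing, and truncation of negative variance
updates at the zero boundary.  This is the algorithm used by the standard
GREML tools for exactly this class of model.

The restricted log-likelihood is reported without the (n - p) log(2 pi) / 2
constant:  l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ].

Also provides the one-sided Wald test for a variance component and the
boundary-corrected one-sided likelihood-ratio test (the 1/2 chi^2_0 : 1/2
chi^2_1 mixture, appropriate because the null value sigma^2 = 0 lies on the
boundary of the parameter space).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, lapack

__all__ = ["VCFit", "reml_fit", "wald_onesided", "lrt_onesided", "reml_loglik"]


@dataclass
class VCFit:
    """Variance-component estimates from one REML fit.

    ``names`` always ends with ``"residual"``; ``proportions`` are the
    per-component shares of the total phenotypic variance (summing to 1),
    i.e. the h^2 / e^2 quantities reported for each relationship matrix.
    ``boundary`` flags components pinned at the zero boundary (their standard
    errors are still reported but are not trustworthy there).
    """

    names: list[str]
    variances: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    boundary: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.boundary is None:
            self.boundary = np.zeros(len(self.names), dtype=bool)

    @property
    def proportions(self) -> np.ndarray:
        total = self.variances.sum()
        if total <= 0:
            return np.full_like(self.variances, np.nan)
        return self.variances / total

    def variance(self, name: str) -> float:
        return float(self.variances[self.names.index(name)])

    def proportion(self, name: str) -> float:
        return float(self.proportions[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])


def _as_design(X, n: int) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _chol_inv_logdet(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of an SPD matrix via Cholesky (LAPACK potri)."""
    c, info = lapack.dpotrf(V, lower=1, overwrite_a=0)
    if info != 0:
        raise np.linalg.LinAlgError("V is not positive definite")
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv, info = lapack.dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("inversion failed")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv, logdet


def _reml_state(y: np.ndarray, X: np.ndarray, A: list[np.ndarray],
                theta: np.ndarray) -> dict:
    """Log-likelihood, scores and average-information matrix at theta."""
    n = len(y)
    k = len(A)
    V = np.zeros((n, n))
    for t, a in zip(theta, A):
        V += t * a
    Vinv, logdetV = _chol_inv_logdet(V)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular fixed-effect design")
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    Py = P @ y
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    # scores and AI matrix
    W = np.column_stack([a @ Py for a in A])          # A_i P y
    q = Py @ W                                        # y' P A_i P y
    tr = np.array([np.vdot(P, a) for a in A])         # tr(P A_i), A symmetric
    score = 0.5 * (q - tr)
    PW = P @ W
    AI = 0.5 * (W.T @ PW)
    return {"ll": ll, "score": score, "AI": AI, "q": q, "tr": tr, "theta": theta,
            "Vinv": Vinv, "P": P, "Py": Py, "VinvX": VinvX, "XtVinvX": XtVinvX}


def reml_loglik(y, X, matrices, variances) -> float:
    """Restricted log-likelihood at fixed variance values (no constant term)."""
    y = np.asarray(y, dtype=float)
    X = _as_design(X, len(y))
    A = [np.asarray(m, dtype=float) for m in matrices] + [np.eye(len(y))]
    return _reml_state(y, X, A, np.asarray(variances, dtype=float))["ll"]


def reml_fit(y, X=None, matrices=(), names=None, *, max_iter: int = 100,
             tol_loglik: float = 1e-6, tol_param: float = 1e-8,
             start: np.ndarray | None = None) -> VCFit:
    """AI-REML fit of variance components for one phenotype.

    Parameters
    ----------
    y:
        Phenotype vector.
    X:
        Fixed-effect design (an intercept column is used when ``None``).
    matrices:
        Relationship matrices (``RelationshipMatrix`` or ndarray); the iid
        residual component is always appended implicitly.
    names:
        Component names; defaults to matrix ``kind`` attributes where
        available.
    start:
        Optional starting variances (including residual, last); the default
        splits the phenotypic variance equally across all components.

    Non-convergence within ``max_iter`` is reported through the ``converged``
    flag, not raised.  Negative updates are truncated at the zero boundary.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = _as_design(X, n)
    p = np.linalg.matrix_rank(X)
    if p < X.shape[1]:
        raise np.linalg.LinAlgError("singular fixed-effect design")
    mats = []
    auto_names = []
    for m in matrices:
        kind = getattr(m, "kind", None)
        vals = getattr(m, "values", m)
        mats.append(np.asarray(vals, dtype=float))
        auto_names.append(kind if kind is not None else f"vc{len(auto_names)}")
    if names is None:
        names = auto_names
    names = list(names) + ["residual"]
    k = len(mats) + 1
    if n < X.shape[1] + k:
        raise ValueError("more parameters than observations")

    # Closed form for the iid-only model.
    if not mats:
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        s2 = float(resid @ resid) / (n - X.shape[1])
        ll = reml_loglik(y, X, [], [s2]) if s2 > 0 else np.inf
        se = np.array([s2 * np.sqrt(2.0 / (n - X.shape[1]))])
        return VCFit(names, np.array([s2]), se, ll, True, 0)

    A = mats + [np.eye(n)]
    var_y = float(np.var(y, ddof=1))
    if var_y <= 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-10 * var_y
    theta = (np.full(k, var_y / k) if start is None
             else np.clip(np.asarray(start, dtype=float), floor, None))

    state = _reml_state(y, X, A, theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # active-set handling of the sigma^2 >= 0 boundary: components sitting
        # at the floor whose score pushes them negative are pinned there and
        # excluded from the update; the residual is never pinned.
        pinned = (theta <= 2 * floor) & (state["score"] < 0)
        pinned[-1] = False
        free = ~pinned
        prop = theta.copy()
        prop[pinned] = floor
        if it == 1 or not free.any():
            prop[free] = _em_update(theta, state, n)[free]
        else:
            # AI step; components the step drives negative are truncated at
            # the boundary and the system re-solved for the remainder.
            for _ in range(k):
                try:
                    delta = np.linalg.solve(state["AI"][np.ix_(free, free)],
                                            state["score"][free])
                except np.linalg.LinAlgError:
                    prop[free] = _em_update(theta, state, n)[free]
                    break
                prop[free] = theta[free] + delta
                neg = free & (prop < 0)
                neg[-1] = False
                if not neg.any():
                    break
                prop[neg] = floor
                free = free & ~neg
                if not free.any():
                    break
            if prop[-1] < 0:  # residual forced negative: fall back to EM
                prop = _em_update(theta, state, n)
                prop[pinned] = floor
        prop = np.clip(prop, floor, None)
        new_state = _try_state(y, X, A, prop)
        halvings = 0
        while (new_state is None or new_state["ll"] < state["ll"] - 1e-10) \
                and halvings < 20:
            prop = np.clip(0.5 * (prop + theta), floor, None)
            new_state = _try_state(y, X, A, prop)
            halvings += 1
        if new_state is None:  # numerically stuck; report current point
            break
        d_ll = new_state["ll"] - state["ll"]
        d_par = float(np.max(np.abs(prop - theta)))
        theta, state = prop, new_state
        if abs(d_ll) < tol_loglik and d_par < tol_param * max(1.0, var_y):
            converged = True
            break

    boundary = theta <= 2 * floor
    variances = np.where(boundary, 0.0, theta)
    try:
        cov = np.linalg.inv(state["AI"])
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(state["AI"])
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return VCFit(names, variances, se, state["ll"], converged, it, boundary)


def _try_state(y, X, A, theta):
    try:
        return _reml_state(y, X, A, theta)
    except np.linalg.LinAlgError:
        return None


def _em_update(theta: np.ndarray, state: dict, n: int) -> np.ndarray:
    """EM-REML step: always admissible (up to truncation), slow but safe."""
    return theta + theta ** 2 * (state["q"] - state["tr"]) / n


def blup(y, X, matrices, fit: VCFit) -> tuple[np.ndarray, np.ndarray]:
    """GLS fixed effects and summed BLUP of the random effects at a fit.

    Returns ``(beta_hat, u_total)`` with ``u_total = sum_i sigma_i^2 A_i
    V^-1 (y - X beta_hat)``.
    """
    y = np.asarray(y, dtype=float)
    X = _as_design(X, len(y))
    A = [np.asarray(getattr(m, "values", m), dtype=float) for m in matrices]
    theta = fit.variances
    V = theta[-1] * np.eye(len(y))
    for t, a in zip(theta[:-1], A):
        V += t * a
    c = cho_factor(V, lower=True)
    VinvX = cho_solve(c, X)
    beta = np.linalg.solve(X.T @ VinvX, VinvX.T @ y)
    r = y - X @ beta
    Vinv_r = cho_solve(c, r)
    u = np.zeros(len(y))
    for t, a in zip(theta[:-1], A):
        u += t * (a @ Vinv_r)
    return beta, u


# ---------------------------------------------------------------------------
# Tests for variance components
# ---------------------------------------------------------------------------

def wald_onesided(estimate: float, se: float) -> float:
    """One-sided Wald p-value for H1: sigma^2 > 0;  p = 1 - Phi(est / se)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(stats.norm.sf(estimate / se))


def lrt_onesided(loglik_null: float, loglik_alt: float) -> tuple[float, float]:
    """One-sided LRT (df = 1) for adding one variance component.

    The statistic 2 (l_alt - l_null) is floored at zero; because the null
    pins the extra variance at the boundary, the reference distribution is
    the equal mixture of a point mass at 0 and chi^2_1, so
    p = 0.5 P(chi^2_1 >= statistic) for a positive statistic and 0.5 at 0.
    """
    statistic = max(0.0, 2.0 * (loglik_alt - loglik_null))
    p = 0.5 * float(stats.chi2.sf(statistic, df=1)) if statistic > 0 else 0.5
    return statistic, p
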