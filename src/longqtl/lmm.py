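"""REML engine for the longitudinal kinship mixed model.

Model for observation (mouse i, day j):

    y_ij = x_ij' alpha + b0_i + b1_i * d_j + e_ij,
    (b0, b1) ~ N(0, Sigma_G (x) K  +  Sigma_E (x) I_n),   e ~ N(0, sigma^2 I),

where K is the (mouse-expanded) genetic relatedness matrix, Sigma_G the 2x2
kinship intercept/slope covariance block (sigma1^2, sigma3^2, sigma5^2) and
Sigma_E the individual block (sigma2^2, sigma4^2, sigma6^2).

For balanced designs (every mouse observed on the same day vector) the
observation covariance factorizes as V = K (x) A + I (x) B with A, B rank-2
updates of the identity, so after one eigendecomposition of K every REML
evaluation reduces to n independent 2x2 Woodbury problems. Unbalanced data
fall back to a dense-covariance evaluation. Variance parameters are
optimized on an unconstrained scale (Cholesky factors of the two 2x2 blocks,
log residual variance) by multi-start L-BFGS-B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

_LOG2PI = np.log(2.0 * np.pi)

VARCOMP_NAMES = (
    "sigma1_sq",  # kinship intercept variance
    "sigma2_sq",  # individual intercept variance
    "sigma3_sq",  # kinship slope variance
    "sigma4_sq",  # individual slope variance
    "sigma5_sq",  # kinship intercept-slope covariance
    "sigma6_sq",  # individual intercept-slope covariance
    "sigma_sq",  # residual variance
)


def _unpack_theta(theta: np.ndarray, include_genetic: bool):
    """theta -> (Sigma_G, Sigma_E, sigma^2) via Cholesky parameterization."""
    theta = np.asarray(theta, dtype=float)
    if include_genetic:
        a, b, c = theta[0:3]
        Sg = np.array([[a * a, a * b], [a * b, b * b + c * c]])
        d, e, f = theta[3:6]
        s2 = np.exp(theta[6])
    else:
        Sg = np.zeros((2, 2))
        d, e, f = theta[0:3]
        s2 = np.exp(theta[3])
    Se = np.array([[d * d, d * e], [d * e, e * e + f * f]])
    return Sg, Se, s2


def _pack_components(components, include_genetic: bool = True) -> np.ndarray:
    """Inverse of _unpack_theta for a (s1,s2,s3,s4,s5,s6,resid) tuple."""
    s1, s2i, s3, s4, s5, s6, resid = [float(v) for v in components]

    def chol2(v0, v1, c):
        M = np.array([[v0, c], [c, v1]])
        w, V = np.linalg.eigh(M)
        L = np.linalg.cholesky(
            (V * np.clip(w, 0.0, None)) @ V.T + 1e-12 * np.eye(2)
        )
        return L[0, 0], L[1, 0], L[1, 1]

    ge = chol2(s2i, s4, s6)
    if include_genetic:
        gg = chol2(s1, s3, s5)
        return np.array([*gg, *ge, np.log(max(resid, 1e-12))])
    return np.array([*ge, np.log(max(resid, 1e-12))])


def components_from_theta(theta: np.ndarray, include_genetic: bool) -> tuple:
    Sg, Se, s2 = _unpack_theta(theta, include_genetic)
    return (Sg[0, 0], Se[0, 0], Sg[1, 1], Se[1, 1], Sg[0, 1], Se[0, 1], s2)


class _KronEngine:
    """Balanced-design engine: eigenrotation + per-eigencomponent 2x2 Woodbury."""

    def __init__(self, Y: np.ndarray, X: np.ndarray, day: np.ndarray, K: np.ndarray | None):
        # Y: (n_mice, T); X: (n_mice, T, p); day: (T,)
        self.Y = Y
        self.X = X
        self.day = day
        n, T, p = X.shape
        self.n, self.T, self.p = n, T, p
        self.N = n * T
        if K is None:
            self.U = None
            self.s = np.ones(n)
            Yt, Xt = Y, X
        else:
            w, U = np.linalg.eigh(K)
            self.U = U
            self.s = np.clip(w, 0.0, None)
            Yt = U.T @ Y
            Xt = np.einsum("nm,mtp->ntp", U.T, X, optimize=True)
        self.Yt, self.Xt = Yt, Xt
        F = np.column_stack([np.ones(T), day])  # (T, 2)
        self.F = F
        self.FtF = F.T @ F
        self.FtY = Yt @ F  # (n, 2)
        self.FtX = np.matmul(F.T[None], Xt)  # (n, 2, p)
        self.yy = (Yt**2).sum(axis=1)  # (n,)
        self.Xy = np.matmul(Xt.transpose(0, 2, 1), Yt[:, :, None])[:, :, 0]  # (n, p)
        self.XX = np.matmul(Xt.transpose(0, 2, 1), Xt)  # (n, p, p)
        self.ysum = Yt.sum(axis=1)  # (n,)
        self.Xsum = Xt.sum(axis=1)  # (n, p)
        self.XtT = self.FtX.transpose(0, 2, 1).copy()  # (n, p, 2)
        self.yy_tot = float(self.yy.sum())
        self.Xy_tot = self.Xy.sum(axis=0)
        self.XX_tot = self.XX.sum(axis=0)

    def _blocks(self, Sg, Se, s2):
        P = self.s[:, None, None] * Sg[None] + Se[None]  # (n, 2, 2)
        D = s2 * np.eye(2)[None] + np.matmul(self.FtF[None], P)
        detD = D[:, 0, 0] * D[:, 1, 1] - D[:, 0, 1] * D[:, 1, 0]
        Dinv = np.empty_like(D)
        Dinv[:, 0, 0] = D[:, 1, 1]
        Dinv[:, 1, 1] = D[:, 0, 0]
        Dinv[:, 0, 1] = -D[:, 0, 1]
        Dinv[:, 1, 0] = -D[:, 1, 0]
        Dinv /= detD[:, None, None]
        Q = np.matmul(P, Dinv)  # symmetric
        return Q, detD

    def _gls(self, Sg, Se, s2):
        Q, detD = self._blocks(Sg, Se, s2)
        if np.any(detD <= 0.0):
            return None
        logdetV = self.n * (self.T - 2) * np.log(s2) + np.log(detD).sum()
        QFtY = np.matmul(Q, self.FtY[:, :, None])  # (n, 2, 1)
        yVy = (self.yy_tot - float((self.FtY * QFtY[:, :, 0]).sum())) / s2
        XVy = (
            self.Xy_tot - np.matmul(self.XtT, QFtY)[:, :, 0].sum(axis=0)
        ) / s2
        XVX = (
            self.XX_tot
            - np.matmul(self.XtT, np.matmul(Q, self.FtX)).sum(axis=0)
        ) / s2
        return logdetV, yVy, XVy, XVX, Q

    def reml_loglik(self, theta: np.ndarray, include_genetic: bool) -> float:
        Sg, Se, s2 = _unpack_theta(theta, include_genetic)
        out = self._gls(Sg, Se, s2)
        if out is None:
            return -np.inf
        logdetV, yVy, XVy, XVX, _ = out
        sign, logdetXVX = np.linalg.slogdet(XVX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XVX, XVy)
        quad = yVy - XVy @ beta
        return -0.5 * (logdetV + logdetXVX + quad + (self.N - self.p) * _LOG2PI)

    def beta_cov(self, theta: np.ndarray, include_genetic: bool):
        Sg, Se, s2 = _unpack_theta(theta, include_genetic)
        logdetV, yVy, XVy, XVX, _ = self._gls(Sg, Se, s2)
        cov = np.linalg.inv(XVX)
        return cov @ XVy, cov


class _DenseEngine:
    """General (unbalanced) engine with an explicitly assembled covariance."""

    def __init__(self, y, X, day, mouse_idx, K):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.N, self.p = self.X.shape
        n = int(mouse_idx.max()) + 1
        Z0 = np.zeros((self.N, n))
        Z0[np.arange(self.N), mouse_idx] = 1.0
        self.Z0 = Z0
        self.Z1 = Z0 * np.asarray(day, float)[:, None]
        self.K = np.eye(n) if K is None else np.asarray(K, float)

    def _V(self, Sg, Se, s2):
        n = self.K.shape[0]
        A0 = Sg[0, 0] * self.K + Se[0, 0] * np.eye(n)
        A1 = Sg[1, 1] * self.K + Se[1, 1] * np.eye(n)
        C = Sg[0, 1] * self.K + Se[0, 1] * np.eye(n)
        V = (
            self.Z0 @ A0 @ self.Z0.T
            + self.Z1 @ A1 @ self.Z1.T
            + self.Z0 @ C @ self.Z1.T
            + self.Z1 @ C @ self.Z0.T
            + s2 * np.eye(self.N)
        )
        return V

    def reml_loglik(self, theta, include_genetic):
        Sg, Se, s2 = _unpack_theta(theta, include_genetic)
        V = self._V(Sg, Se, s2)
        try:
            cf = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
        Vy = cho_solve(cf, self.y)
        VX = cho_solve(cf, self.X)
        XVX = self.X.T @ VX
        XVy = self.X.T @ Vy
        sign, logdetXVX = np.linalg.slogdet(XVX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XVX, XVy)
        quad = self.y @ Vy - XVy @ beta
        return -0.5 * (logdetV + logdetXVX + quad + (self.N - self.p) * _LOG2PI)

    def beta_cov(self, theta, include_genetic):
        Sg, Se, s2 = _unpack_theta(theta, include_genetic)
        V = self._V(Sg, Se, s2)
        cf = cho_factor(V, lower=True)
        VX = cho_solve(cf, self.X)
        XVX = self.X.T @ VX
        cov = np.linalg.inv(XVX)
        return cov @ (VX.T @ self.y), cov


@dataclass
class LmmFit:
    """REML fit of the longitudinal kinship mixed model."""

    varcomp: dict
    fixef: np.ndarray
    fixef_names: list
    fixef_cov: np.ndarray
    reml_loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    df_method: str = "satterthwaite"
    include_genetic: bool = True
    theta: np.ndarray = field(default=None, repr=False)
    engine: object = field(default=None, repr=False)

    @property
    def components(self) -> tuple:
        return tuple(self.varcomp[k] for k in VARCOMP_NAMES)

    def reml_at_components(self, components) -> float:
        """Restricted log-likelihood at an arbitrary variance-component vector."""
        theta = _pack_components(components, self.include_genetic)
        return self.engine.reml_loglik(theta, self.include_genetic)

    def satterthwaite_df(self, index: int) -> float:
        """Satterthwaite-type df for the fixed effect at ``index``.

        df = 2 g^2 / Var(g) with g = Var(beta_hat_index) and Var(g) obtained
        by the delta method from the numeric gradient of g w.r.t. the
        variance parameters and the inverse observed REML information.
        """
        theta0 = self.theta

        def gfun(th):
            _, cov = self.engine.beta_cov(th, self.include_genetic)
            return cov[index, index]

        h = 1e-4 * np.maximum(np.abs(theta0), 1.0)
        grad = np.empty_like(theta0)
        for k in range(len(theta0)):
            tp, tm = theta0.copy(), theta0.copy()
            tp[k] += h[k]
            tm[k] -= h[k]
            grad[k] = (gfun(tp) - gfun(tm)) / (2.0 * h[k])
        H = _numeric_hessian(
            lambda th: -self.engine.reml_loglik(th, self.include_genetic), theta0
        )
        cov_theta = np.linalg.pinv(H)
        var_g = float(grad @ cov_theta @ grad)
        g0 = gfun(theta0)
        if var_g <= 0:
            return float(self.n_obs - len(self.fixef))
        return float(2.0 * g0 * g0 / var_g)


def _numeric_hessian(f, x0, rel_h=1e-3):
    k = len(x0)
    h = rel_h * np.maximum(np.abs(x0), 1.0)
    H = np.empty((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
            xpp[[i, j]] += h[[i, j]]
            xmm[[i, j]] -= h[[i, j]]
            if i == j:
                H[i, i] = (f(xpp) - 2.0 * f0 + f(xmm)) / (h[i] * h[i])
            else:
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * h[i] * h[j])
    return H


def _is_balanced(day: np.ndarray, mouse_idx: np.ndarray):
    """If every mouse has the same ordered day vector, return it, else None."""
    df = pd.DataFrame({"m": mouse_idx, "d": day})
    first = None
    for _, grp in df.groupby("m", sort=True):
        d = grp["d"].to_numpy()
        if first is None:
            first = d
        elif len(d) != len(first) or not np.array_equal(d, first):
            return None
    return first


def fit_longitudinal_lmm(
    y: np.ndarray,
    X: np.ndarray,
    day: np.ndarray,
    mouse: np.ndarray,
    K: np.ndarray | None = None,
    include_genetic: bool = True,
    fixef_names: list | None = None,
    n_starts: int = 3,
    tol: float = 1e-8,
    theta0: np.ndarray | None = None,
) -> LmmFit:
    """REML fit of the longitudinal model.

    Parameters
    ----------
    y, X, day : observation-level response, design matrix and day covariate.
    mouse : observation-level mouse labels; ``K`` (if given) must be the
        mouse-level kinship aligned to the order of first appearance.
    include_genetic : fit the kinship blocks; with False the model reduces to
        an i.i.d. random-intercept+slope model (the no-genetics time-course
        model).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    day = np.asarray(day, float)
    mouse_idx, uniq = pd.factorize(mouse)
    n_mice = len(uniq)
    if n_mice < 2:
        raise ValueError("need at least two mice to fit random intercepts and slopes")
    if K is not None and K.shape[0] != n_mice:
        raise ValueError("kinship matrix must be mouse-level and aligned with the data")
    if K is not None and np.linalg.eigvalsh(K).min() < -1e-8:
        raise ValueError("kinship matrix must be positive semidefinite")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, fixef_names)
        raise ValueError(f"rank-deficient fixed-effect design; collinear columns: {bad}")

    order = np.lexsort((day, mouse_idx))
    y_o, X_o, day_o, mi_o = y[order], X[order], day[order], mouse_idx[order]
    dvec = _is_balanced(day_o, mi_o)
    if dvec is not None:
        n, T, p = n_mice, len(dvec), X.shape[1]
        engine = _KronEngine(
            y_o.reshape(n, T), X_o.reshape(n, T, p), dvec, K
        )
    else:
        engine = _DenseEngine(y_o, X_o, day_o, mi_o, K)

    vy = max(float(np.var(y)), 1e-8)
    dbar2 = max(float(np.mean(day**2)), 1.0)

    def start(fg, fe, fr):
        g = [np.sqrt(fg * vy), 0.0, np.sqrt(fg * vy / dbar2)]
        e = [np.sqrt(fe * vy), 0.0, np.sqrt(fe * vy / dbar2)]
        if include_genetic:
            return np.array([*g, *e, np.log(fr * vy)])
        return np.array([*e, np.log(fr * vy)])

    if theta0 is not None:
        starts = [np.asarray(theta0, dtype=float)]
    else:
        starts = [start(0.2, 0.2, 0.5), start(0.02, 0.4, 0.5), start(0.45, 0.05, 0.3)][:n_starts]

    best = None
    n_iter = 0
    for x0 in starts:
        res = optimize.minimize(
            lambda th: -engine.reml_loglik(th, include_genetic),
            x0,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": tol * 1e-4, "gtol": 1e-7},
        )
        n_iter += res.nit
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    theta = best.x
    beta, cov = engine.beta_cov(theta, include_genetic)
    comps = components_from_theta(theta, include_genetic)
    fit = LmmFit(
        varcomp=dict(zip(VARCOMP_NAMES, [float(c) for c in comps])),
        fixef=beta,
        fixef_names=fixef_names or [f"x{i}" for i in range(X.shape[1])],
        fixef_cov=cov,
        reml_loglik=float(-best.fun),
        converged=bool(best.success),
        n_iter=int(n_iter),
        n_obs=len(y),
        include_genetic=include_genetic,
        theta=theta,
        engine=engine,
    )
    return fit


def _collinear_columns(X: np.ndarray, names: list | None) -> list:
    """Name columns involved in rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(X, pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    dropped = piv[np.sum(diag > tol):]
    names = names or [f"x{i}" for i in range(X.shape[1])]
    return [names[i] for i in sorted(dropped)]
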