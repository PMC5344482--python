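"""Linear mixed models for breeding-value prediction and REML estimation.

The animal model is ``y = Xb + Zu + e`` with ``u ~ N(0, K sigma_a^2)`` and
``e ~ N(0, I sigma_e^2)``, where K is either the pedigree numerator
relationship matrix (pedigree BLUP) or the genomic relationship matrix
(GBLUP). Henderson's mixed-model equations give BLUEs/BLUPs and, through
the inverse coefficient matrix, prediction error variances and the
theoretical accuracy ``r = sqrt(1 - PEV / sigma_a^2)``.

Variance components are estimated by average-information REML with an
EM-REML fallback step whenever an AI update proposes a negative component
or a likelihood decrease (the EM step is guaranteed ascent and positivity).
The bivariate version estimates 2x2 genetic and residual covariance
matrices under ``u ~ N(0, V_g (x) K)`` using AI updates with step halving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def full_rank_columns(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ModelError("design matrix must be 2-D with >= 1 column")
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * diag.max()).sum()) if diag.size else 0
    return np.sort(piv[:rank])


def design_matrix(df: pd.DataFrame, factors=("sex", "hatch")):
    """Intercept + treatment-coded dummies for the given factors.

    Aliased (e.g. all-zero) columns are dropped; returns (X, names).
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in factors:
        d = pd.get_dummies(df[f].astype(str), prefix=f, drop_first=True)
        for c in d.columns:
            cols.append(d[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    keep = full_rank_columns(X)
    if len(keep) < X.shape[1]:
        X = X[:, keep]
        names = [names[k] for k in keep]
    return X, names


def incidence_matrix(record_ids, all_ids) -> np.ndarray:
    """Z mapping records to random-effect levels; individuals without
    records simply get zero columns-worth of rows."""
    pos = {i: k for k, i in enumerate(all_ids)}
    Z = np.zeros((len(record_ids), len(all_ids)))
    for r, i in enumerate(record_ids):
        Z[r, pos[i]] = 1.0
    return Z


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------

@dataclass
class MMEComponents:
    """Assembled coefficient matrix and right-hand side."""

    C: np.ndarray = field(repr=False)
    rhs: np.ndarray = field(repr=False)
    n_fixed: int = 0
    sigma_a2: float = 1.0
    sigma_e2: float = 1.0
    random_ids: list[str] = field(default_factory=list)
    k_diag: np.ndarray | None = None
    fixed_names: list[str] = field(default_factory=list)


@dataclass
class MMESolution:
    """Solutions, prediction error variances and theoretical accuracies."""

    fixed_effects: pd.Series
    u: pd.Series                     # (G)EBV for every random-effect level
    pev: pd.Series
    r_theo: pd.Series
    sigma_a2: float
    sigma_e2: float
    n_pev_clamped: int = 0


def build_mme(y, X, Z, K, sigma_a2: float, sigma_e2: float,
              K_inv: np.ndarray | None = None,
              random_ids=None, fixed_names=None) -> MMEComponents:
    """Assemble Henderson's equations C [b; u] = rhs.

    ``C = [[X'X, X'Z], [Z'X, Z'Z + K^-1 lambda]]`` with
    ``lambda = sigma_e^2 / sigma_a^2``. K must be factorizable (apply
    ``kinship.stabilize`` first if needed); a precomputed ``K_inv`` avoids
    refactorizing across folds.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    K = np.asarray(K, dtype=float)
    n = y.shape[0]
    if X.shape[0] != n or Z.shape[0] != n:
        raise ModelError("X/Z row counts do not match y")
    q = Z.shape[1]
    if K.shape != (q, q):
        raise ModelError("K dimension does not match Z columns")
    if sigma_a2 <= 0 or sigma_e2 <= 0:
        raise ModelError("variance components must be positive")
    if K_inv is None:
        try:
            cf = linalg.cho_factor(K)
        except linalg.LinAlgError as exc:
            raise ModelError("K is not factorizable; stabilize it first") from exc
        K_inv = linalg.cho_solve(cf, np.eye(q))
    lam = sigma_e2 / sigma_a2
    p = X.shape[1]
    C = np.empty((p + q, p + q))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T @ Z
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Z.T @ Z + K_inv * lam
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    if random_ids is None:
        random_ids = [f"u{k}" for k in range(q)]
    if fixed_names is None:
        fixed_names = [f"b{k}" for k in range(p)]
    return MMEComponents(C=C, rhs=rhs, n_fixed=p, sigma_a2=sigma_a2,
                         sigma_e2=sigma_e2, random_ids=list(random_ids),
                         k_diag=np.diag(K).copy(),
                         fixed_names=list(fixed_names))


def solve_mme(mme: MMEComponents) -> MMESolution:
    """Dense symmetric solve; PEV from the inverse coefficient matrix.

    ``PEV_i = (C^-1)_{u_i u_i} * sigma_e^2``, clamped to [0, sigma_a^2]
    (clamps counted), and ``r_theo = sqrt(1 - PEV / sigma_a^2)``.
    """
    p = mme.n_fixed
    # C is symmetric positive definite in exact arithmetic (X full rank,
    # K^-1 PD); try Cholesky first, fall back to LU when a strongly ridged
    # K^-1 leaves C numerically semi-definite
    try:
        cf = linalg.cho_factor(mme.C, check_finite=False)
        C_inv = linalg.cho_solve(cf, np.eye(mme.C.shape[0]),
                                 check_finite=False)
    except linalg.LinAlgError:
        import warnings as _w
        try:
            with _w.catch_warnings():
                _w.simplefilter("ignore", linalg.LinAlgWarning)
                C_inv = linalg.inv(mme.C, check_finite=False)
        except linalg.LinAlgError as exc:
            raise ModelError("singular coefficient matrix (aliased fixed "
                             "effects not removed?)") from exc
    sol = C_inv @ mme.rhs
    pev_raw = np.diag(C_inv)[p:] * mme.sigma_e2
    pev = np.clip(pev_raw, 0.0, mme.sigma_a2)
    n_clamped = int(np.sum(pev != pev_raw))
    r_theo = np.sqrt(1.0 - pev / mme.sigma_a2)
    return MMESolution(
        fixed_effects=pd.Series(sol[:p], index=mme.fixed_names),
        u=pd.Series(sol[p:], index=mme.random_ids),
        pev=pd.Series(pev, index=mme.random_ids),
        r_theo=pd.Series(r_theo, index=mme.random_ids),
        sigma_a2=mme.sigma_a2, sigma_e2=mme.sigma_e2,
        n_pev_clamped=n_clamped)


# ---------------------------------------------------------------------------
# univariate AIREML
# ---------------------------------------------------------------------------

@dataclass
class VarComp:
    """Univariate variance components and heritability."""

    sigma_a2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def lambda_(self) -> float:
        return self.sigma_e2 / self.sigma_a2


def _reml_pieces(V: np.ndarray, X: np.ndarray, y: np.ndarray):
    """P matrix, Py and restricted log-likelihood for fixed V."""
    n = V.shape[0]
    cf = linalg.cho_factor(V, check_finite=False)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    V_inv = linalg.cho_solve(cf, np.eye(n), check_finite=False)
    B = V_inv @ X
    XtVX = X.T @ B
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise ModelError("X'V^-1X not positive definite (aliased columns?)")
    P = V_inv - B @ np.linalg.solve(XtVX, B.T)
    Py = P @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return P, Py, ll


def aireml(y, X, Z, K, init=None, tol: float = 1e-8, max_iter: int = 200,
           verbose: bool = False) -> VarComp:
    """AI-REML for the two-component animal model.

    Maximizes the restricted likelihood over (sigma_a^2, sigma_e^2) with
    average-information updates, substituting an EM-REML step whenever the
    AI proposal leaves the parameter space or decreases the likelihood.
    Components pinned at a small positive floor when the boundary attracts
    them. Standard error of h^2 by the delta method from the inverse AI
    matrix at the optimum.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    K = np.asarray(K, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ModelError("need more records than fixed effects + 1")
    q = K.shape[0]
    G_r = Z @ K @ Z.T
    vary = float(np.var(y, ddof=1))
    floor = max(vary, 1e-12) * 1e-6
    theta = np.array(init, dtype=float) if init is not None else np.array(
        [vary / 2.0, vary / 2.0])
    theta = np.maximum(theta, floor)

    eye = np.eye(n)
    ll_trace: list[float] = []
    converged = False
    it = 0
    P, Py, ll = _reml_pieces(theta[0] * G_r + theta[1] * eye, X, y)
    for it in range(1, max_iter + 1):
        tr_pg = float(np.sum(P * G_r))       # tr(P G_r), both symmetric
        tr_p = float(np.trace(P))
        GPy = G_r @ Py
        score = 0.5 * np.array([float(Py @ GPy) - tr_pg,
                                float(Py @ Py) - tr_p])
        PGPy = P @ GPy
        PPy = P @ Py
        AI = 0.5 * np.array([
            [float(GPy @ PGPy), float(GPy @ PPy)],
            [float(GPy @ PPy), float(Py @ PPy)],
        ])
        used_em = False
        try:
            delta = np.linalg.solve(AI, score)
            proposal = theta + delta
        except np.linalg.LinAlgError:
            proposal = np.array([-1.0, -1.0])
        if np.any(proposal <= 0):
            # truncate a negative proposal to a tenth of the current value:
            # geometric decay toward the boundary, ascent checked below
            proposal = np.where(proposal <= 0,
                                np.maximum(theta * 0.1, floor), proposal)
        try:
            P_new, Py_new, ll_new = _reml_pieces(
                proposal[0] * G_r + proposal[1] * eye, X, y)
        except (linalg.LinAlgError, ModelError):
            used_em = True
        else:
            if ll_new + 1e-10 < ll:
                used_em = True
        if used_em:
            # EM-REML (P-form): guaranteed ascent and positivity
            proposal = np.array([
                theta[0] + theta[0] ** 2 * (float(Py @ GPy) - tr_pg) / q,
                theta[1] + theta[1] ** 2 * (float(Py @ Py) - tr_p) / n,
            ])
            proposal = np.maximum(proposal, floor)
            P_new, Py_new, ll_new = _reml_pieces(
                proposal[0] * G_r + proposal[1] * eye, X, y)
        rel_change = np.max(np.abs(proposal - theta) / (np.abs(theta) + floor))
        theta, P, Py, ll = proposal, P_new, Py_new, ll_new
        ll_trace.append(ll)
        if verbose:
            print(f"iter {it}: theta={theta}, logL={ll:.6f}, em={used_em}")
        if rel_change < tol:
            converged = True
            break
        # boundary pinning: tiny component with downhill gradient
        if theta[0] <= floor * 10 and score[0] < 0:
            theta[0] = floor
            converged = True
            break

    # SE of h2 by delta method from the inverse AI at the optimum
    GPy = G_r @ Py
    PGPy = P @ GPy
    PPy = P @ Py
    AI = 0.5 * np.array([
        [float(GPy @ PGPy), float(GPy @ PPy)],
        [float(GPy @ PPy), float(Py @ PPy)],
    ])
    tot = theta.sum()
    h2 = float(theta[0] / tot)
    grad = np.array([theta[1], -theta[0]]) / tot ** 2
    try:
        cov_theta = np.linalg.inv(AI)
        se_h2 = float(np.sqrt(max(0.0, grad @ cov_theta @ grad)))
    except np.linalg.LinAlgError:
        se_h2 = float("nan")
    if not converged:
        warnings.warn(f"AIREML did not converge in {max_iter} iterations",
                      stacklevel=2)
    return VarComp(sigma_a2=float(theta[0]), sigma_e2=float(theta[1]),
                   h2=h2, se_h2=se_h2, loglik=float(ll), n_iter=it,
                   converged=converged, loglik_trace=ll_trace)


# ---------------------------------------------------------------------------
# bivariate AIREML
# ---------------------------------------------------------------------------

@dataclass
class CovComp:
    """Bivariate genetic/residual covariance matrices and the genetic
    correlation with its delta-method standard error."""

    genetic_cov: np.ndarray
    residual_cov: np.ndarray
    r_g: float
    se_rg: float
    loglik: float
    n_iter: int
    converged: bool


def _biv_V(theta, K11, K22, K12, O12, n1, n2):
    g11, g12, g22, r11, r12, r22 = theta
    V = np.empty((n1 + n2, n1 + n2))
    V[:n1, :n1] = g11 * K11 + r11 * np.eye(n1)
    V[n1:, n1:] = g22 * K22 + r22 * np.eye(n2)
    V[:n1, n1:] = g12 * K12 + r12 * O12
    V[n1:, :n1] = V[:n1, n1:].T
    return V


def _theta_valid(theta, floor):
    g11, g12, g22, r11, r12, r22 = theta
    if min(g11, g22, r11, r22) <= floor:
        return False
    if g12 ** 2 >= g11 * g22 * (1 - 1e-8):
        return False
    if r12 ** 2 >= r11 * r22 * (1 - 1e-8):
        return False
    return True


def aireml_bivariate(y1, y2, X1, X2, Z1, Z2, K, init=None, tol: float = 1e-6,
                     max_iter: int = 200) -> CovComp:
    """AI-REML for two traits sharing the relationship matrix K.

    Records for each trait may cover different (overlapping) individuals;
    residual covariance applies only to records of the same individual.
    AI updates use step halving whenever a proposal leaves the positive-
    definite region or decreases the restricted likelihood.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if np.var(y1) == 0 or np.var(y2) == 0:
        raise ModelError("both traits need non-zero variance")
    X1, X2 = np.asarray(X1, float), np.asarray(X2, float)
    Z1, Z2 = np.asarray(Z1, float), np.asarray(Z2, float)
    K = np.asarray(K, float)
    n1, n2 = y1.size, y2.size
    K11 = Z1 @ K @ Z1.T
    K22 = Z2 @ K @ Z2.T
    K12 = Z1 @ K @ Z2.T
    O12 = Z1 @ Z2.T                # same-individual indicator
    y = np.concatenate([y1, y2])
    X = linalg.block_diag(X1, X2)

    v1, v2 = np.var(y1, ddof=1), np.var(y2, ddof=1)
    floor = 1e-8 * min(v1, v2)
    if init is None:
        c = float(np.corrcoef(y1[:min(n1, n2)], y2[:min(n1, n2)])[0, 1]) \
            if n1 == n2 else 0.0
        init = np.array([v1 / 2, 0.5 * c * np.sqrt(v1 * v2) / 2, v2 / 2,
                         v1 / 2, 0.5 * c * np.sqrt(v1 * v2) / 2, v2 / 2])
    theta = np.array(init, dtype=float)
    if not _theta_valid(theta, floor):
        theta = np.array([v1 / 2, 0.0, v2 / 2, v1 / 2, 0.0, v2 / 2])

    def derivative_times(vec, i):
        """V_i @ vec for the six structure matrices."""
        a, b = vec[:n1], vec[n1:]
        out = np.zeros_like(vec)
        if i == 0:
            out[:n1] = K11 @ a
        elif i == 1:
            out[:n1] = K12 @ b
            out[n1:] = K12.T @ a
        elif i == 2:
            out[n1:] = K22 @ b
        elif i == 3:
            out[:n1] = a
        elif i == 4:
            out[:n1] = O12 @ b
            out[n1:] = O12.T @ a
        elif i == 5:
            out[n1:] = b
        return out

    def traces(P):
        """tr(P V_i) for the six structure matrices."""
        P11, P22, P12 = P[:n1, :n1], P[n1:, n1:], P[:n1, n1:]
        return np.array([
            float(np.sum(P11 * K11)),
            2.0 * float(np.sum(P12 * K12)),
            float(np.sum(P22 * K22)),
            float(np.trace(P11)),
            2.0 * float(np.sum(P12 * O12)),
            float(np.trace(P22)),
        ])

    P, Py, ll = _reml_pieces(_biv_V(theta, K11, K22, K12, O12, n1, n2), X, y)
    converged = False
    it = 0
    AI = np.eye(6)
    for it in range(1, max_iter + 1):
        W = [derivative_times(Py, i) for i in range(6)]
        tr = traces(P)
        yPVPy = np.array([float(Py @ w) for w in W])
        score = 0.5 * (yPVPy - tr)
        PW = [P @ w for w in W]
        AI = 0.5 * np.array([[float(W[i] @ PW[j]) for j in range(6)]
                             for i in range(6)])
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(6) * np.trace(AI),
                                    score)
        except np.linalg.LinAlgError:
            delta = score / (np.abs(np.diag(AI)) + 1.0)
        if not np.all(np.isfinite(delta)):
            delta = score / (np.abs(np.diag(AI)) + 1.0)
        # trust region: a near-singular AI (degenerate data) can propose an
        # astronomically long Newton step; cap the relative move instead
        scale = np.abs(theta) + np.sqrt(v1 * v2) * 1e-3
        stretch = np.max(np.abs(delta) / scale)
        if stretch > 5.0:
            delta = delta * (5.0 / stretch)
        def try_direction(direction):
            step = 1.0
            for _ in range(25):
                cand = theta + step * direction
                if _theta_valid(cand, floor):
                    try:
                        pieces = _reml_pieces(
                            _biv_V(cand, K11, K22, K12, O12, n1, n2), X, y)
                    except (linalg.LinAlgError, ModelError):
                        step /= 2.0
                        continue
                    if pieces[2] + 1e-10 >= ll:
                        return cand, pieces
                step /= 2.0
            return None, None

        proposal, pieces = try_direction(delta)
        if proposal is None:
            # boundary stall: a blocked joint step may hide an uphill
            # block-coordinate move (genetic-only, then residual-only)
            for mask in (np.r_[np.ones(3), np.zeros(3)],
                         np.r_[np.zeros(3), np.ones(3)]):
                proposal, pieces = try_direction(delta * mask)
                if proposal is not None:
                    break
        if proposal is None:
            converged = True  # no uphill step found: at a (near) optimum
            break
        P_new, Py_new, ll_new = pieces
        rel = np.max(np.abs(proposal - theta)
                     / (np.abs(theta) + np.sqrt(v1 * v2) * 1e-8))
        theta, P, Py, ll = proposal, P_new, Py_new, ll_new
        if rel < tol:
            converged = True
            break
    else:
        warnings.warn(f"bivariate AIREML did not converge in {max_iter} "
                      "iterations", stacklevel=2)

    g11, g12, g22, r11, r12, r22 = theta
    r_g = float(g12 / np.sqrt(g11 * g22))
    grad = np.zeros(6)
    grad[0] = -0.5 * r_g / g11
    grad[1] = 1.0 / np.sqrt(g11 * g22)
    grad[2] = -0.5 * r_g / g22
    try:
        cov_theta = np.linalg.inv(AI + 1e-12 * np.eye(6) * np.trace(AI))
        se_rg = float(np.sqrt(max(0.0, grad @ cov_theta @ grad)))
    except np.linalg.LinAlgError:
        se_rg = float("nan")
    return CovComp(
        genetic_cov=np.array([[g11, g12], [g12, g22]]),
        residual_cov=np.array([[r11, r12], [r12, r22]]),
        r_g=r_g, se_rg=se_rg, loglik=float(ll), n_iter=it,
        converged=converged)
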