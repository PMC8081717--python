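"""Generic linear mixed model machinery: REML, Henderson's mixed model
equations, and prediction-error variances of estimable/predictable functions.

The model is

    y = X beta + Z u + e,   u ~ N(0, G(theta)),   e ~ N(0, R),

where ``R`` is either a *known* positive-definite matrix (the forwarded
variance-covariance matrix of stage-I adjusted means) or ``sigma2_e * I``
with the plot residual variance estimated alongside the other components.

``G`` is block diagonal over a list of :class:`RandomTerm` objects.  Each
term carries one of four covariance structures:

``scalar``
    homogeneous ``sigma2 * I`` (one parameter);
``groups``
    group-heterogeneous ``(+)_g sigma2_g * I`` -- the direct sum over e.g.
    agro-ecological zones, with a group index per column (one parameter per
    group);
``us3``
    an unstructured symmetric PSD 3x3 matrix shared i.i.d. across subjects
    (random-coefficient intercept/linear/quadratic triplets; 6 parameters,
    log-Cholesky parameterised so any parameter vector yields a PSD matrix);
``diag3``
    the diagonal restriction of ``us3`` (3 parameters).  Provided because a
    diagonal coefficient covariance loses invariance under covariate
    translation, which is worth demonstrating.

Scalar variances are parameterised as ``sigma2 = s2_y * exp(t)`` with
``t`` box-bounded in ``[-30, 10]``; the lower bound is an effective zero
(boundary REML estimates are floored there and flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as sla
from scipy import optimize

__all__ = [
    "RandomTerm",
    "MixedModel",
    "FitResult",
    "ConvergenceError",
    "EstimabilityError",
    "reml_deviance",
    "reml_deviance_and_grad",
    "fit_reml",
    "solve_mme",
    "pev",
]

_LOWER = -30.0
_UPPER = 10.0
_BOUNDARY_TOL = 2.0  # transformed-scale distance from the floor that flags a boundary


class ConvergenceError(RuntimeError):
    """REML iteration failed to converge; carries the optimiser trace."""


class EstimabilityError(ValueError):
    """A requested fixed-effect function is not estimable from the data."""


@dataclass
class RandomTerm:
    """One random term of the model with its covariance structure.

    For ``us3``/``diag3`` the ``Z`` columns must be ordered subject-major:
    for each subject the three columns hold the intercept, linear and
    quadratic covariate loadings (values ``1, x, x^2`` on the subject's
    rows).
    """

    name: str
    Z: np.ndarray
    labels: list[tuple]
    structure: str = "scalar"
    col_group: np.ndarray | None = None   # 'groups': group index per column
    group_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.structure not in ("scalar", "groups", "us3", "diag3"):
            raise ValueError(f"unknown covariance structure {self.structure!r}")
        if self.structure == "groups":
            if self.col_group is None:
                raise ValueError("'groups' structure requires col_group")
            self.col_group = np.asarray(self.col_group)
            if not self.group_names:
                self.group_names = sorted(set(self.col_group.tolist()))
        if self.structure in ("us3", "diag3") and self.Z.shape[1] % 3:
            raise ValueError("us3/diag3 terms need 3 columns per subject")
        if len(self.labels) != self.Z.shape[1]:
            raise ValueError("labels must match Z columns")

    @property
    def n_params(self) -> int:
        return {"scalar": 1, "groups": len(self.group_names),
                "us3": 6, "diag3": 3}[self.structure]

    @property
    def n_subjects(self) -> int:
        return self.Z.shape[1] // 3


def _chol_from_params(t: np.ndarray) -> np.ndarray:
    """Lower-triangular factor from the 6-vector (log d1, log d2, log d3,
    l21, l31, l32)."""
    L = np.zeros((3, 3))
    L[0, 0], L[1, 1], L[2, 2] = np.exp(t[0] / 2), np.exp(t[1] / 2), np.exp(t[2] / 2)
    L[1, 0], L[2, 0], L[2, 1] = t[3], t[4], t[5]
    return L


class MixedModel:
    """Design matrices plus caches used by the REML deviance.

    Parameters
    ----------
    y : response vector.
    X : fixed-effects design (may be rank deficient; a generalised inverse
        is used and only estimable functions are reported).
    terms : random terms, columns grouped contiguously by term.
    R : known residual covariance matrix, or ``None`` to estimate a
        homogeneous plot residual ``sigma2_e * I``.
    """

    def __init__(self, y, X, terms: Sequence[RandomTerm],
                 R: np.ndarray | None = None,
                 fixed_labels: list[tuple] | None = None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError("X rows must match y")
        self.terms = list(terms)
        self.R = None if R is None else np.asarray(R, dtype=float)
        if self.R is not None and self.R.shape != (n, n):
            raise ValueError("R must be n x n")
        self.fixed_labels = fixed_labels or [("x", j) for j in range(self.X.shape[1])]
        self.estimate_residual = self.R is None

    # -- caches ---------------------------------------------------------
    @property
    def n(self) -> int:
        return self.y.size

    @property
    def Z(self) -> np.ndarray:
        if not self.terms:
            return np.zeros((self.n, 0))
        return np.hstack([t.Z for t in self.terms])

    @property
    def random_labels(self) -> list[tuple]:
        out: list[tuple] = []
        for t in self.terms:
            out.extend((t.name,) + lab for lab in t.labels)
        return out

    def _build_caches(self) -> None:
        """Precompute per-component Gram matrices so each deviance
        evaluation is a weighted sum of fixed n x n matrices."""
        if hasattr(self, "_grams"):
            return
        self._s2y = float(np.var(self.y)) or 1.0
        grams: list[list[np.ndarray]] = []
        for t in self.terms:
            if t.structure == "scalar":
                grams.append([t.Z @ t.Z.T])
            elif t.structure == "groups":
                gs = []
                for g in t.group_names:
                    Zg = t.Z[:, np.asarray(t.col_group) == g]
                    gs.append(Zg @ Zg.T)
                grams.append(gs)
            else:  # us3 / diag3: cross Grams of the power columns
                B = [t.Z[:, r::3] for r in range(3)]
                gs = [[B[r] @ B[s].T for s in range(3)] for r in range(3)]
                grams.append(gs)
        self._grams = grams
        # orthonormal basis of col(X) for the REML profile terms
        u, s, _ = np.linalg.svd(self.X, full_matrices=False)
        self._Xr = u[:, s > s[0] * 1e-10] if s.size and s[0] > 0 else u[:, :0]

    # -- parameter packing ---------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(t.n_params for t in self.terms) + int(self.estimate_residual)

    def split_params(self, theta: np.ndarray) -> tuple[list[np.ndarray], float | None]:
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError("theta has wrong length")
        parts, k = [], 0
        for t in self.terms:
            parts.append(theta[k:k + t.n_params])
            k += t.n_params
        resid = float(theta[k]) if self.estimate_residual else None
        return parts, resid

    def term_cov(self, term: RandomTerm, t: np.ndarray) -> np.ndarray:
        """Covariance parameter(s) of one term on the variance scale:
        a vector of variances (scalar/groups/diag3) or a 3x3 matrix (us3)."""
        s2 = getattr(self, "_s2y", None) or float(np.var(self.y)) or 1.0
        if term.structure == "scalar":
            return np.array([s2 * np.exp(t[0])])
        if term.structure == "groups":
            return s2 * np.exp(t)
        if term.structure == "diag3":
            return s2 * np.exp(t)
        L = _chol_from_params(t)
        return s2 * (L @ L.T)

    def build_V(self, theta: np.ndarray) -> np.ndarray:
        self._build_caches()
        parts, resid = self.split_params(theta)
        n = self.n
        V = np.array(self.R, dtype=float) if self.R is not None else np.zeros((n, n))
        if self.estimate_residual:
            V[np.diag_indices(n)] += self._s2y * np.exp(resid)
        for term, t, grams in zip(self.terms, parts, self._grams):
            cov = self.term_cov(term, t)
            if term.structure in ("scalar", "groups"):
                for v, S in zip(np.atleast_1d(cov), grams):
                    V += v * S
            elif term.structure == "diag3":
                for r in range(3):
                    V += cov[r] * grams[r][r]
            else:  # us3
                A = cov
                for r in range(3):
                    for s in range(3):
                        if A[r, s] != 0.0:
                            V += A[r, s] * grams[r][s]
        return V

    def build_G(self, theta: np.ndarray) -> np.ndarray:
        """Materialise the full (q x q) block-diagonal G."""
        parts, _ = self.split_params(theta)
        blocks = []
        for term, t in zip(self.terms, parts):
            cov = self.term_cov(term, t)
            q = term.Z.shape[1]
            if term.structure == "scalar":
                blocks.append(np.full(q, cov[0]))
            elif term.structure == "groups":
                v = np.empty(q)
                for g, vg in zip(term.group_names, cov):
                    v[np.asarray(term.col_group) == g] = vg
                blocks.append(v)
            elif term.structure == "diag3":
                blocks.append(np.tile(cov, term.n_subjects))
            else:
                A = cov
                blocks.append(sla.block_diag(*([A] * term.n_subjects)))
        mats = [np.diag(b) if b.ndim == 1 else b for b in blocks]
        if not mats:
            return np.zeros((0, 0))
        return sla.block_diag(*mats)


def _chol(V: np.ndarray):
    try:
        return sla.cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        cond = np.linalg.cond(V)
        raise np.linalg.LinAlgError(
            f"V numerically singular (condition number {cond:.3g})") from exc


def reml_deviance(theta: np.ndarray, model: MixedModel) -> float:
    """Minus twice the restricted log-likelihood, constant terms dropped:

        log|V| + log|X' V^-1 X| + y' P y,

    with ``X`` replaced by an orthonormal basis of its column space so the
    value is invariant to the fixed-effect parameterisation.
    """
    model._build_caches()
    V = model.build_V(theta)
    c = _chol(V)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    Xr = model._Xr
    ViX = sla.cho_solve(c, Xr, check_finite=False)
    Viy = sla.cho_solve(c, model.y, check_finite=False)
    A = Xr.T @ ViX
    cA = sla.cho_factor(A, lower=True, check_finite=False)
    logdetA = 2.0 * float(np.sum(np.log(np.diag(cA[0]))))
    Xty = Xr.T @ Viy
    yPy = float(model.y @ Viy - Xty @ sla.cho_solve(cA, Xty, check_finite=False))
    return logdetV + logdetA + yPy


def _dL_dt(t: np.ndarray, j: int) -> np.ndarray:
    """Derivative of the lower-triangular factor w.r.t. its j-th parameter."""
    E = np.zeros((3, 3))
    if j < 3:
        E[j, j] = 0.5 * np.exp(t[j] / 2)
    else:
        (r, c) = [(1, 0), (2, 0), (2, 1)][j - 3]
        E[r, c] = 1.0
    return E


def reml_deviance_and_grad(theta: np.ndarray, model: MixedModel):
    """Deviance plus its analytic gradient on the transformed scale.

    Uses the standard restricted-likelihood derivative
    ``tr(P dV/dt) - y'P (dV/dt) P y`` with ``P`` the REML projection
    matrix; per-term traces reduce to cheap products with the cached
    component Gram factors."""
    model._build_caches()
    V = model.build_V(theta)
    c = _chol(V)
    n = model.n
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    Vi = sla.cho_solve(c, np.eye(n), check_finite=False)
    Xr = model._Xr
    ViX = Vi @ Xr
    A = Xr.T @ ViX
    cA = sla.cho_factor(A, lower=True, check_finite=False)
    logdetA = 2.0 * float(np.sum(np.log(np.diag(cA[0]))))
    P = Vi - ViX @ sla.cho_solve(cA, ViX.T, check_finite=False)
    Py = P @ model.y
    dev = logdetV + logdetA + float(model.y @ Py)

    parts, resid = model.split_params(theta)
    grad = np.empty(model.n_params)
    k = 0
    s2y = model._s2y
    for term, t, grams in zip(model.terms, parts, model._grams):
        if term.structure == "scalar":
            v = s2y * np.exp(t[0])
            PZ = P @ term.Z
            grad[k] = v * (float(np.sum(term.Z * PZ))
                           - float(np.sum((term.Z.T @ Py) ** 2)))
            k += 1
        elif term.structure == "groups":
            for gi, g in enumerate(term.group_names):
                Zg = term.Z[:, np.asarray(term.col_group) == g]
                v = s2y * np.exp(t[gi])
                grad[k] = v * (float(np.sum(Zg * (P @ Zg)))
                               - float(np.sum((Zg.T @ Py) ** 2)))
                k += 1
        else:
            B = [term.Z[:, r::3] for r in range(3)]
            PB = [P @ b for b in B]
            T = np.array([[float(np.sum(B[s] * PB[r])) for s in range(3)]
                          for r in range(3)])
            u = [b.T @ Py for b in B]
            Q = np.array([[float(u[r] @ u[s]) for s in range(3)]
                          for r in range(3)])
            D = T - Q
            if term.structure == "diag3":
                for r in range(3):
                    grad[k] = s2y * np.exp(t[r]) * D[r, r]
                    k += 1
            else:
                L = _chol_from_params(t)
                for j in range(6):
                    E = _dL_dt(t, j)
                    dA = s2y * (E @ L.T + L @ E.T)
                    grad[k] = float(np.sum(dA * D))
                    k += 1
    if model.estimate_residual:
        v = s2y * np.exp(resid)
        grad[k] = v * (float(np.trace(P)) - float(Py @ Py))
    return dev, grad


def _dV_list(model: MixedModel, theta: np.ndarray) -> list[np.ndarray]:
    """Derivatives of V w.r.t. each transformed parameter."""
    model._build_caches()
    parts, resid = model.split_params(theta)
    s2y = model._s2y
    out: list[np.ndarray] = []
    for term, t, grams in zip(model.terms, parts, model._grams):
        if term.structure == "scalar":
            out.append(s2y * np.exp(t[0]) * grams[0])
        elif term.structure == "groups":
            for gi, S in enumerate(grams):
                out.append(s2y * np.exp(t[gi]) * S)
        elif term.structure == "diag3":
            for r in range(3):
                out.append(s2y * np.exp(t[r]) * grams[r][r])
        else:
            L = _chol_from_params(t)
            for j in range(6):
                E = _dL_dt(t, j)
                dA = s2y * (E @ L.T + L @ E.T)
                dV = np.zeros((model.n, model.n))
                for r in range(3):
                    for s in range(3):
                        if dA[r, s] != 0.0:
                            dV += dA[r, s] * grams[r][s]
                out.append(dV)
    if model.estimate_residual:
        out.append(s2y * np.exp(resid) * np.eye(model.n))
    return out


def _ai_refine(model: MixedModel, theta: np.ndarray,
               max_steps: int = 50, tol: float = 1e-10):
    """Average-information Newton refinement of a REML solution.

    Quasi-Newton progress stalls in the nearly flat, curved valleys that
    random-coefficient covariances produce; damped AI steps (the
    average-information approximation to the Hessian of the deviance)
    restore quadratic convergence near the optimum.  Steps are accepted
    only when the deviance decreases; parameters stay inside the bounds.
    """
    lo = np.array([b[0] if b[0] is not None else -np.inf for b in _bounds(model)])
    hi = np.array([b[1] if b[1] is not None else np.inf for b in _bounds(model)])
    theta = np.clip(np.asarray(theta, float), lo, hi)
    dev, grad = reml_deviance_and_grad(theta, model)
    lam = 1e-6
    for _ in range(max_steps):
        V = model.build_V(theta)
        c = _chol(V)
        Vi = sla.cho_solve(c, np.eye(model.n), check_finite=False)
        Xr = model._Xr
        ViX = Vi @ Xr
        A = Xr.T @ ViX
        cA = sla.cho_factor(A, lower=True, check_finite=False)
        P = Vi - ViX @ sla.cho_solve(cA, ViX.T, check_finite=False)
        Py = P @ model.y
        W = np.column_stack([dV @ Py for dV in _dV_list(model, theta)])
        H = W.T @ P @ W
        improved = False
        for _ in range(12):
            try:
                step = np.linalg.solve(H + lam * np.diag(np.maximum(np.diag(H), 1.0)),
                                       -grad)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            cand = np.clip(theta + step, lo, hi)
            try:
                dev_c, grad_c = reml_deviance_and_grad(cand, model)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            if dev_c <= dev + 1e-12:
                gain = dev - dev_c
                theta, dev, grad = cand, dev_c, grad_c
                lam = max(lam / 10, 1e-8)
                improved = True
                break
            lam *= 10
        if not improved or gain < tol:
            break
    return theta, dev, grad


@dataclass
class FitResult:
    """REML estimates plus the generalised inverse of the MME coefficient
    matrix, partitioned as C11 = var(beta_hat), C12 = cov(beta_hat, u_hat - u),
    C22 = var(u_hat - u)."""

    model: MixedModel
    theta: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    C11: np.ndarray
    C12: np.ndarray
    C22: np.ndarray
    deviance: float
    converged: bool
    n_iter: int
    boundary: list[str]
    grad_norm: float
    sigma2_e: float | None = None

    def __post_init__(self) -> None:
        self._fixed_index = {lab: i for i, lab in enumerate(self.model.fixed_labels)}
        self._random_index = {lab: i for i, lab in enumerate(self.model.random_labels)}
        A = self.model.X.T @ self._Vi @ self.model.X
        self._XtViX = A

    @property
    def _Vi(self) -> np.ndarray:
        if not hasattr(self, "_Vi_cache"):
            V = self.model.build_V(self.theta)
            c = _chol(V)
            self._Vi_cache = sla.cho_solve(c, np.eye(self.model.n), check_finite=False)
        return self._Vi_cache

    def fixed_index(self, label: tuple) -> int:
        return self._fixed_index[label]

    def random_index(self, label: tuple) -> int:
        return self._random_index[label]

    @property
    def p(self) -> int:
        return self.model.X.shape[1]

    @property
    def q(self) -> int:
        return sum(t.Z.shape[1] for t in self.model.terms)

    def term_params(self) -> dict[str, np.ndarray]:
        """Estimated covariance parameters per random term on the variance
        scale (vector of variances, or a 3x3 matrix for us3 terms)."""
        parts, resid = self.model.split_params(self.theta)
        out = {t.name: self.model.term_cov(t, p) for t, p in zip(self.model.terms, parts)}
        if resid is not None:
            out["residual"] = np.array([self.model._s2y * np.exp(resid)])
        return out

    def variance(self, term_name: str, group=None) -> float:
        """Scalar variance component of a term; ``group`` selects the zone
        for group-heterogeneous structures."""
        for t in self.model.terms:
            if t.name == term_name:
                cov = self.term_params()[term_name]
                if t.structure == "groups":
                    if group is None:
                        raise ValueError(f"term {term_name!r} is group-heterogeneous")
                    return float(cov[t.group_names.index(group)])
                if t.structure == "scalar":
                    return float(cov[0])
                raise ValueError(f"term {term_name!r} has matrix-valued covariance")
        raise KeyError(term_name)

    def K_vector(self, entries: dict[tuple, float]) -> np.ndarray:
        K = np.zeros(self.p)
        for lab, v in entries.items():
            K[self.fixed_index(lab)] = v
        return K

    def M_vector(self, entries: dict[tuple, float]) -> np.ndarray:
        M = np.zeros(self.q)
        for lab, v in entries.items():
            M[self.random_index(lab)] = v
        return M


def solve_mme(X, Z, G, R, y, fixed_labels=None):
    """Solve Henderson's mixed model equations for given (G, R).

    Returns ``(beta, u, C)`` where ``C`` is the (p+q) x (p+q) generalised
    inverse of the MME coefficient matrix, computed through V-based
    identities that remain valid when ``G`` is singular.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.atleast_2d(np.asarray(Z, float))
    G = np.atleast_2d(np.asarray(G, float))
    R = np.atleast_2d(np.asarray(R, float))
    y = np.asarray(y, float).ravel()
    n = y.size
    V = Z @ G @ Z.T + R
    c = _chol(V)
    Vi = sla.cho_solve(c, np.eye(n), check_finite=False)
    A = X.T @ Vi @ X
    C11 = np.linalg.pinv(A, hermitian=True)
    beta = C11 @ X.T @ Vi @ y
    P = Vi - Vi @ X @ C11 @ X.T @ Vi
    u = G @ Z.T @ Vi @ (y - X @ beta)
    C12 = -C11 @ X.T @ Vi @ Z @ G
    C22 = G - G @ Z.T @ P @ Z @ G
    C = np.block([[C11, C12], [C12.T, C22]])
    return beta, u, C


def _default_start(model: MixedModel) -> np.ndarray:
    x0 = []
    k = 1 + len(model.terms) + int(model.estimate_residual)
    base = np.log(1.0 / k)
    for t in model.terms:
        if t.structure == "scalar":
            x0.append([base])
        elif t.structure == "groups":
            x0.append([base] * len(t.group_names))
        elif t.structure == "diag3":
            x0.append([base] * 3)
        else:
            x0.append([base, base, base, 0.0, 0.0, 0.0])
    if model.estimate_residual:
        x0.append([base])
    return np.concatenate([np.asarray(v, float) for v in x0]) if x0 else np.zeros(0)


def _bounds(model: MixedModel) -> list[tuple]:
    b: list[tuple] = []
    for t in model.terms:
        if t.structure == "us3":
            b += [(_LOWER, _UPPER)] * 3 + [(None, None)] * 3
        else:
            b += [(_LOWER, _UPPER)] * t.n_params
    if model.estimate_residual:
        b.append((_LOWER, _UPPER))
    return b


def _param_names(model: MixedModel) -> list[str]:
    names = []
    for t in model.terms:
        if t.structure == "scalar":
            names.append(t.name)
        elif t.structure == "groups":
            names += [f"{t.name}[{g}]" for g in t.group_names]
        elif t.structure == "diag3":
            names += [f"{t.name}.d{r}" for r in range(3)]
        else:
            names += [f"{t.name}.L{i}" for i in range(6)]
    if model.estimate_residual:
        names.append("residual")
    return names


def fit_reml(model: MixedModel, x0: np.ndarray | None = None,
             max_iter: int = 500, n_restarts: int = 3,
             seed: int = 0) -> FitResult:
    """Estimate variance parameters by REML and solve the MME at the optimum.

    Quasi-Newton (L-BFGS-B) on the transformed deviance with analytic
    gradients, followed by a damped average-information Newton refinement
    (:func:`_ai_refine`); on non-convergence up to ``n_restarts`` jittered
    restarts are attempted and the best converged solution kept.
    """
    if model.n < 2:
        raise ValueError("need at least 2 observations to fit a mixed model")
    model._build_caches()
    start = _default_start(model) if x0 is None else np.asarray(x0, float)
    bounds = _bounds(model)

    def _solve_from(s):
        """L-BFGS-B phase followed by AI-Newton refinement."""
        res = optimize.minimize(
            reml_deviance_and_grad, s, args=(model,), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-5})
        theta, dev, grad = _ai_refine(model, res.x)
        # projected gradient: ignore components pinned at an active bound
        proj = grad.copy()
        for j, (lo, _) in enumerate(bounds):
            if lo is not None and theta[j] <= lo + 1e-9 and grad[j] > 0:
                proj[j] = 0.0
        ok = float(np.max(np.abs(proj), initial=0.0)) < 1e-3 * max(1.0, abs(dev))
        return theta, dev, grad, ok, int(res.nit)

    best, trace = None, []
    rng = np.random.default_rng(seed)
    if start.size == 0:
        best = (start, reml_deviance(start, model), np.zeros(0), True, 0)
    else:
        for attempt in range(1 + n_restarts):
            s = start if attempt == 0 else start + rng.normal(0, 0.5 + attempt, start.size)
            cand = _solve_from(s)
            trace.append((attempt, float(cand[1]), bool(cand[3])))
            if best is None or cand[1] < best[1] - 1e-10:
                best = cand
            if best[3]:
                break
        if not best[3]:
            raise ConvergenceError(
                f"REML failed to converge after {len(trace)} starts; trace={trace}")

    theta, best_dev, best_grad, best_ok, best_nit = best
    names = _param_names(model)
    boundary = [nm for nm, b, t in zip(names, bounds, theta)
                if b[0] is not None and t < b[0] + _BOUNDARY_TOL]
    G = model.build_G(theta)
    R = model.R
    sigma2_e = None
    if model.estimate_residual:
        _, resid = model.split_params(theta)
        sigma2_e = model._s2y * np.exp(resid)
        R = sigma2_e * np.eye(model.n)
    Z = model.Z
    beta, u, C = solve_mme(model.X, Z, G, R, model.y, model.fixed_labels)
    p = model.X.shape[1]
    fit = FitResult(
        model=model, theta=theta, beta=beta, u=u,
        C11=C[:p, :p], C12=C[:p, p:], C22=C[p:, p:],
        deviance=float(best_dev), converged=bool(best_ok),
        n_iter=best_nit, boundary=boundary,
        grad_norm=float(np.linalg.norm(best_grad)), sigma2_e=sigma2_e)
    return fit


def pev(fit: FitResult, K: np.ndarray | None = None,
        M: np.ndarray | None = None, check: bool = True) -> float:
    """Prediction-error variance of ``K' beta_hat + M' u_hat`` as a
    predictor of ``K' beta + M' u``:  [K' M'] C^- [K; M].

    Raises :class:`EstimabilityError` when ``K`` is not in the row space of
    ``X`` (through the data)."""
    K = np.zeros(fit.p) if K is None else np.asarray(K, float).ravel()
    M = np.zeros(fit.q) if M is None else np.asarray(M, float).ravel()
    if K.size != fit.p or M.size != fit.q:
        raise ValueError("K/M have wrong length")
    if check and K.any():
        # estimable iff K lies in range(X' V^-1 X) = row space of X
        proj = fit._XtViX @ (fit.C11 @ K)
        if np.linalg.norm(proj - K) > 1e-6 * (1.0 + np.linalg.norm(K)):
            raise EstimabilityError("K is not estimable from the fitted design")
    val = float(K @ fit.C11 @ K + 2.0 * K @ fit.C12 @ M + M @ fit.C22 @ M)
    return max(val, 0.0)
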