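"""Random regression mixed model for longitudinal traits.

The model decomposes a repeatedly measured trait ``y`` of individual ``k``
at age ``t`` as

    y_tk = F_i + f(t) + r_a(t; k) + r_pe(t; k) + e_tk

where ``F_i`` are time-constant fixed factor effects, ``f(t)`` is a fixed
population-mean curve, and ``r_a`` / ``r_pe`` are additive-genetic and
permanent-environment curves with random Legendre coefficients ``a_k`` and
``p_k``.  In matrix form  ``y = X1 f + X2 b + Z1 a + Z2 p + e``  with

    Var(a) = A (x) D,   Var(p) = I (x) P,   Var(e) = I sigma2_e,

A the pedigree numerator relationship matrix, D and P the coefficient
covariance matrices, and (x) the Kronecker product.  Variance components are
estimated by average-information REML; fixed effects and BLUPs solve
Henderson's mixed model equations

    [ W'W + blkdiag(0, s2e A^-1 (x) D^-1, s2e I (x) P^-1) ] sol = W'y.

Balanced designs (every individual measured at the same ages) are rotated by
the eigendecomposition of A into independent per-individual blocks, which
makes each REML iteration O(n); unbalanced data uses a single dense block.

The public surface is statsmodels-like: build a
:class:`RandomRegressionModel`, call :meth:`~RandomRegressionModel.fit`, and
work with the returned :class:`RandomRegressionResults` (variance
components, solutions, ``summary()``, and the genome scan).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .basis import LegendreBasis, design_matrix
from .pedigree import Pedigree, RelationshipMatrix, build_A, build_A_inverse

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "MmeSystem",
    "MmeSolution",
    "RandomRegressionModel",
    "RandomRegressionResults",
    "build_design",
    "solve_mme",
    "select_orders",
]


class IdentifiabilityError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory


# ---------------------------------------------------------------------------
# specification containers


@dataclass(frozen=True)
class ModelSpec:
    """Model configuration: fixed effects and basis orders.

    ``order_fixed``/``order_additive``/``order_pe`` are the Legendre degrees
    of the population-mean, additive-genetic and permanent-environment
    curves (each contributes degree+1 coefficients).  Orders are capped at
    ``n_distinct_ages - 1``; a curve with more coefficients than distinct
    measurement ages is not identifiable.
    """

    order_fixed: int = 2
    order_additive: int = 1
    order_pe: int = 1
    factors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    basis: LegendreBasis | None = None

    def resolve_basis(self, ages: np.ndarray) -> LegendreBasis:
        if self.basis is not None:
            return self.basis
        lo, hi = float(np.min(ages)), float(np.max(ages))
        if lo == hi:  # single measurement age: any 1-point interval works
            lo, hi = lo - 1.0, hi + 1.0
        return LegendreBasis(order=0, t_min=lo, t_max=hi)


@dataclass
class VarianceComponents:
    """(D, P, sigma2_e): coefficient covariances and residual variance."""

    D: np.ndarray
    P: np.ndarray
    sigma2_e: float

    def __post_init__(self) -> None:
        self.D = np.atleast_2d(np.asarray(self.D, float))
        self.P = np.atleast_2d(np.asarray(self.P, float))
        for name, m in (("D", self.D), ("P", self.P)):
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-8 * max(1.0, np.abs(m).max()):
                raise ValueError(f"{name} must be positive semidefinite")
        if self.sigma2_e < 0:
            raise ValueError("sigma2_e must be >= 0")

    @property
    def n_params(self) -> int:
        qa, qp = self.D.shape[0], self.P.shape[0]
        return qa * (qa + 1) // 2 + qp * (qp + 1) // 2 + 1

    def genetic_variance(self, phi_rows: np.ndarray) -> np.ndarray:
        return np.einsum("ti,ij,tj->t", phi_rows, self.D, phi_rows)

    def pe_variance(self, phi_rows: np.ndarray) -> np.ndarray:
        return np.einsum("ti,ij,tj->t", phi_rows, self.P, phi_rows)


# ---------------------------------------------------------------------------
# design / MME


@dataclass
class MmeSystem:
    """Design matrices and bookkeeping for Henderson's equations."""

    y: np.ndarray
    X1: np.ndarray            # factor dummies (N x p1, may have 0 columns)
    X2: np.ndarray            # mean-curve Legendre covariates + constant covariates
    Z1: np.ndarray            # N x (n_ped * (order_additive+1))
    Z2: np.ndarray            # N x (n_pheno * (order_pe+1))
    ped_ids: list[str]        # ordering of the additive coefficient blocks
    pheno_ids: list[str]      # phenotyped individuals (permanent-env blocks)
    record_individual: np.ndarray  # index of each record into pheno_ids
    ages: np.ndarray
    basis_fixed: LegendreBasis
    basis_additive: LegendreBasis
    basis_pe: LegendreBasis
    x_labels: list[str] = field(default_factory=list)

    @property
    def X(self) -> np.ndarray:
        return np.hstack([self.X1, self.X2])

    @property
    def n_records(self) -> int:
        return self.y.size


@dataclass
class MmeSolution:
    fixed_factors: np.ndarray
    fixed_regression: np.ndarray
    additive: np.ndarray       # n_ped x (order_additive+1)
    permanent_env: np.ndarray  # n_pheno x (order_pe+1)
    fitted: np.ndarray


def _factor_dummies(df: pd.DataFrame, factors) -> tuple[np.ndarray, list[str]]:
    if not factors:
        return np.empty((len(df), 0)), []
    dummies = pd.get_dummies(df[list(factors)].astype(str), drop_first=True, dtype=float)
    return dummies.to_numpy(), list(dummies.columns)


def build_design(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    ped_ids: list[str] | None = None,
    trait: str = "weight",
    age_col: str = "age_months",
    id_col: str = "id",
) -> MmeSystem:
    """Assemble y, X1, X2, Z1, Z2 from a long-format phenotype table.

    ``ped_ids`` fixes the ordering of additive-coefficient blocks and may
    contain non-phenotyped ancestors (they simply get no Z1 rows); defaults
    to the phenotyped individuals in order of first appearance.
    """
    for col in (trait, age_col, id_col, *spec.factors, *spec.covariates):
        if col not in pheno.columns:
            raise KeyError(f"phenotype table lacks column {col!r}")
    df = pheno.reset_index(drop=True)
    y = df[trait].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite trait values")
    ages = df[age_col].to_numpy(dtype=float)

    distinct = np.unique(ages)
    cap = len(distinct) - 1
    for name, order in (
        ("order_fixed", spec.order_fixed),
        ("order_additive", spec.order_additive),
        ("order_pe", spec.order_pe),
    ):
        if order > cap:
            raise IdentifiabilityError(
                f"{name}={order} needs {order + 1} coefficients but only "
                f"{len(distinct)} distinct ages are observed"
            )

    base = spec.resolve_basis(ages)
    basis_fixed = base.with_order(spec.order_fixed)
    basis_additive = base.with_order(spec.order_additive)
    basis_pe = base.with_order(spec.order_pe)

    ids = df[id_col].astype(str).tolist()
    pheno_ids = list(dict.fromkeys(ids))
    if ped_ids is None:
        ped_ids = pheno_ids
    ped_pos = {i: k for k, i in enumerate(ped_ids)}
    missing = [i for i in pheno_ids if i not in ped_pos]
    if missing:
        raise KeyError(f"phenotyped individuals absent from pedigree ordering: {missing[:5]}")
    pheno_pos = {i: k for k, i in enumerate(pheno_ids)}
    rec_ind = np.array([pheno_pos[i] for i in ids])

    X1, x1_labels = _factor_dummies(df, spec.factors)
    phi_f = design_matrix(ages, basis_fixed)
    cov = df[list(spec.covariates)].to_numpy(dtype=float) if spec.covariates else np.empty((len(df), 0))
    X2 = np.hstack([phi_f, cov])
    x_labels = (
        x1_labels
        + [f"mean_phi{l}" for l in range(basis_fixed.n_coef)]
        + list(spec.covariates)
    )

    X = np.hstack([X1, X2])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in the deficiency via QR pivoting
        _, _, piv = sla.qr(X, pivoting=True, mode="economic")
        confounded = [x_labels[j] for j in piv[rank:]]
        raise IdentifiabilityError(
            f"fixed-effect design is rank deficient; confounded columns: {confounded}"
        )

    qa, qp = basis_additive.n_coef, basis_pe.n_coef
    phi_a = design_matrix(ages, basis_additive)
    phi_p = design_matrix(ages, basis_pe)
    N = len(df)
    Z1 = np.zeros((N, len(ped_ids) * qa))
    Z2 = np.zeros((N, len(pheno_ids) * qp))
    rows = np.arange(N)
    ped_block = np.array([ped_pos[i] for i in ids])
    for l in range(qa):
        Z1[rows, ped_block * qa + l] = phi_a[:, l]
    for l in range(qp):
        Z2[rows, rec_ind * qp + l] = phi_p[:, l]

    return MmeSystem(
        y=y, X1=X1, X2=X2, Z1=Z1, Z2=Z2,
        ped_ids=list(ped_ids), pheno_ids=pheno_ids, record_individual=rec_ind,
        ages=ages, basis_fixed=basis_fixed, basis_additive=basis_additive,
        basis_pe=basis_pe, x_labels=x_labels,
    )


def _mme_coefficient(sys: MmeSystem, A_inv: np.ndarray, vc: VarianceComponents):
    if not vc.sigma2_e > 0:
        raise ValueError("mixed model equations require sigma2_e > 0")
    W = np.hstack([sys.X1, sys.X2, sys.Z1, sys.Z2])
    C = W.T @ W
    p = sys.X1.shape[1] + sys.X2.shape[1]
    qa = sys.basis_additive.n_coef
    qp = sys.basis_pe.n_coef
    na, npe = len(sys.ped_ids), len(sys.pheno_ids)
    Dinv = np.linalg.inv(vc.D)
    Pinv = np.linalg.inv(vc.P)
    ia = slice(p, p + na * qa)
    ip = slice(p + na * qa, p + na * qa + npe * qp)
    C[ia, ia] += vc.sigma2_e * np.kron(A_inv, Dinv)
    C[ip, ip] += vc.sigma2_e * np.kron(np.eye(npe), Pinv)
    return W, C, p, qa, qp, na, npe


def solve_mme(
    sys: MmeSystem, A_inv: np.ndarray, vc: VarianceComponents
) -> MmeSolution:
    """Direct solve of Henderson's mixed model equations."""
    W, C, p, qa, qp, na, npe = _mme_coefficient(sys, A_inv, vc)
    rhs = W.T @ sys.y
    try:
        cf = sla.cho_factor(C)
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise np.linalg.LinAlgError(f"singular MME coefficient matrix: {e}") from e
    sol = sla.cho_solve(cf, rhs)
    p1 = sys.X1.shape[1]
    return MmeSolution(
        fixed_factors=sol[:p1],
        fixed_regression=sol[p1:p],
        additive=sol[p : p + na * qa].reshape(na, qa),
        permanent_env=sol[p + na * qa :].reshape(npe, qp),
        fitted=W @ sol,
    )


# ---------------------------------------------------------------------------
# REML engine: AI updates on a block-diagonal representation of V


def _vech_indices(q: int):
    return [(i, j) for i in range(q) for j in range(i, q)]


def _pack(D, P, s2e):
    qa, qp = D.shape[0], P.shape[0]
    return np.array(
        [D[i, j] for i, j in _vech_indices(qa)]
        + [P[i, j] for i, j in _vech_indices(qp)]
        + [s2e]
    )


def _unpack(theta, qa, qp):
    D = np.zeros((qa, qa))
    P = np.zeros((qp, qp))
    k = 0
    for i, j in _vech_indices(qa):
        D[i, j] = D[j, i] = theta[k]
        k += 1
    for i, j in _vech_indices(qp):
        P[i, j] = P[j, i] = theta[k]
        k += 1
    return D, P, float(theta[k])


def _project_psd(M: np.ndarray, floor: float) -> np.ndarray:
    w, v = np.linalg.eigh(M)
    w = np.maximum(w, floor)
    return (v * w) @ v.T


class _REMLBlocks:
    """Per-block data for a variance model linear in its parameters.

    Each block ``b`` carries (y_b, X_b) and matrices C_bt with
    ``V_b(theta) = sum_t theta_t C_bt``.
    """

    def __init__(self, ys, Xs, Cs):
        self.ys = ys
        self.Xs = Xs
        self.Cs = Cs  # list over blocks of list over params of matrices
        self.n_params = len(Cs[0])
        self.n_fixed = Xs[0].shape[1]
        self.n_records = sum(y.size for y in ys)

    def loglike(self, theta, want_derivs: bool = False):
        p = self.n_fixed
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        logdet = 0.0
        per_block = []
        for y, X, Cs in zip(self.ys, self.Xs, self.Cs):
            V = sum(t * C for t, C in zip(theta, Cs))
            try:
                cf = sla.cho_factor(V, lower=True)
            except (np.linalg.LinAlgError, ValueError):
                return (-np.inf, None) if want_derivs else -np.inf
            logdet += 2.0 * np.log(np.diag(cf[0])).sum()
            Vi_y = sla.cho_solve(cf, y)
            Vi_X = sla.cho_solve(cf, X)
            XtVX += X.T @ Vi_X
            XtVy += X.T @ Vi_y
            ytVy += y @ Vi_y
            per_block.append((cf, Vi_y, Vi_X))
        sign, ld_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return (-np.inf, None) if want_derivs else -np.inf
        beta = np.linalg.solve(XtVX, XtVy)
        ypy = ytVy - XtVy @ beta
        ll = -0.5 * (logdet + ld_xvx + ypy)
        if not want_derivs:
            return ll
        # score and average-information matrix
        T = self.n_params
        XtVX_inv = np.linalg.inv(XtVX)
        tr_term = np.zeros(T)
        quad = np.zeros(T)
        # accumulators for AI: across blocks
        ut_Vi_us = np.zeros((T, T))
        Xt_Vi_u = np.zeros((p, T))
        for (y, X, Cs), (cf, Vi_y, Vi_X) in zip(
            zip(self.ys, self.Xs, self.Cs), per_block
        ):
            r = Vi_y - Vi_X @ beta  # P y restricted to this block
            us = np.column_stack([C @ r for C in Cs])
            Vi_us = sla.cho_solve(cf, us)
            ut_Vi_us += us.T @ Vi_us
            Xt_Vi_u += X.T @ Vi_us
            for t, C in enumerate(Cs):
                Vi_C = sla.cho_solve(cf, C)
                tr_term[t] += np.trace(Vi_C)
                tr_term[t] -= np.einsum("ij,ji->", XtVX_inv, Vi_X.T @ C @ Vi_X)
                quad[t] += r @ C @ r
        score = -0.5 * (tr_term - quad)
        AI = 0.5 * (ut_Vi_us - Xt_Vi_u.T @ XtVX_inv @ Xt_Vi_u)
        return ll, (score, AI, beta)


def _build_blocks(sys: MmeSystem, A_sub: np.ndarray):
    """Rotate a balanced design into per-individual blocks, or fall back to
    one dense block.  Returns (_REMLBlocks, param names)."""
    qa, qp = sys.basis_additive.n_coef, sys.basis_pe.n_coef
    names = (
        [f"D[{i},{j}]" for i, j in _vech_indices(qa)]
        + [f"P[{i},{j}]" for i, j in _vech_indices(qp)]
        + ["sigma2_e"]
    )
    n = len(sys.pheno_ids)
    # balanced iff every individual has one record at each of the same ages
    order = np.lexsort((sys.ages, sys.record_individual))
    ages_sorted = sys.ages[order]
    rec_sorted = sys.record_individual[order]
    counts = np.bincount(rec_sorted, minlength=n)
    balanced = False
    if counts.min() == counts.max() and sys.n_records == n * counts[0]:
        T = counts[0]
        age_mat = ages_sorted.reshape(n, T)
        balanced = bool(
            np.all(age_mat == age_mat[0]) and len(np.unique(age_mat[0])) == T
        )
    def sym(q, i, j):
        E = np.zeros((q, q))
        E[i, j] = E[j, i] = 1.0
        return E

    if balanced:
        T = counts[0]
        ages0 = age_mat[0]
        Phi_a = design_matrix(ages0, sys.basis_additive)
        Phi_p = design_matrix(ages0, sys.basis_pe)
        s, U = np.linalg.eigh(A_sub)
        Y = sys.y[order].reshape(n, T)
        Xall = sys.X[order].reshape(n, T, -1)
        Ytil = U.T @ Y
        Xtil = np.einsum("ab,btp->atp", U.T, Xall)
        D_bases = [Phi_a @ sym(qa, i, j) @ Phi_a.T for i, j in _vech_indices(qa)]
        P_bases = [Phi_p @ sym(qp, i, j) @ Phi_p.T for i, j in _vech_indices(qp)]
        eye = np.eye(T)
        ys, Xs, Cs = [], [], []
        for b in range(n):
            ys.append(Ytil[b])
            Xs.append(Xtil[b])
            Cs.append([s[b] * M for M in D_bases] + list(P_bases) + [eye])
        return _REMLBlocks(ys, Xs, Cs), names

    # general path: one dense block over all records
    N = sys.n_records
    phi_a_rec = design_matrix(sys.ages, sys.basis_additive)
    phi_p_rec = design_matrix(sys.ages, sys.basis_pe)
    A_by_rec = A_sub[np.ix_(sys.record_individual, sys.record_individual)]
    same_ind = (sys.record_individual[:, None] == sys.record_individual[None, :]).astype(float)
    Cs_one = []
    for i, j in _vech_indices(qa):
        E = sym(qa, i, j)
        Cs_one.append(A_by_rec * (phi_a_rec @ E @ phi_a_rec.T))
    for i, j in _vech_indices(qp):
        E = sym(qp, i, j)
        Cs_one.append(same_ind * (phi_p_rec @ E @ phi_p_rec.T))
    Cs_one.append(np.eye(N))
    return _REMLBlocks([sys.y], [sys.X], [Cs_one]), names


# ---------------------------------------------------------------------------
# model / results


class RandomRegressionModel:
    """Legendre random-regression mixed model for a longitudinal trait.

    Parameters
    ----------
    pheno
        Long-format table: one row per measurement, with individual ID,
        age, trait value and any factor/covariate columns.
    relationship
        A :class:`~rrgwas.pedigree.Pedigree` (A and its sparse-rule inverse
        are built from it) or a ready :class:`RelationshipMatrix`; ``None``
        means unrelated individuals (A = I).
    spec
        A :class:`ModelSpec`; keyword shortcuts ``order_fixed`` etc. are
        accepted instead.
    """

    def __init__(
        self,
        pheno: pd.DataFrame,
        relationship: Pedigree | RelationshipMatrix | None = None,
        spec: ModelSpec | None = None,
        trait: str = "weight",
        age_col: str = "age_months",
        id_col: str = "id",
        **spec_kwargs,
    ):
        if spec is None:
            spec = ModelSpec(**spec_kwargs)
        elif spec_kwargs:
            spec = replace(spec, **spec_kwargs)
        self.spec = spec
        self.pheno = pheno
        self.trait, self.age_col, self.id_col = trait, age_col, id_col

        pheno_ids = list(dict.fromkeys(pheno[id_col].astype(str)))
        if relationship is None:
            self.A = RelationshipMatrix(ids=pheno_ids, values=np.eye(len(pheno_ids)))
            self._A_inv_values = np.eye(len(pheno_ids))
        elif isinstance(relationship, Pedigree):
            self.A = build_A(relationship)
            self._A_inv_values = build_A_inverse(relationship).values
        else:
            self.A = relationship
            self._A_inv_values = np.linalg.inv(relationship.values)

        self.sys = build_design(
            pheno, spec, ped_ids=self.A.ids, trait=trait, age_col=age_col, id_col=id_col
        )
        self.A_sub = self.A.submatrix(self.sys.pheno_ids)
        self._blocks, self.vc_names = _build_blocks(self.sys, self.A_sub)

    # -- fitting ------------------------------------------------------------

    def start_values(self) -> VarianceComponents:
        s2y = float(np.var(self.sys.y, ddof=1))
        qa, qp = self.sys.basis_additive.n_coef, self.sys.basis_pe.n_coef
        return VarianceComponents(
            D=0.3 * s2y * np.eye(qa) / qa,
            P=0.3 * s2y * np.eye(qp) / qp,
            sigma2_e=0.4 * s2y,
        )

    def loglike_restricted(self, vc: VarianceComponents) -> float:
        theta = _pack(vc.D, vc.P, vc.sigma2_e)
        return self._blocks.loglike(theta)

    def fit(
        self,
        start: VarianceComponents | None = None,
        maxiter: int = 200,
        tol_loglike: float = 1e-8,
        tol_params: float = 1e-6,
    ) -> "RandomRegressionResults":
        """Estimate (D, P, sigma2_e) by AI-REML and solve the MME.

        Average-information Newton steps with step halving; D and P are
        projected to the nearest PSD matrix after every update.  Stops when
        the restricted log-likelihood or the parameters stabilize.
        """
        qa, qp = self.sys.basis_additive.n_coef, self.sys.basis_pe.n_coef
        vc0 = start or self.start_values()
        s2y = float(np.var(self.sys.y, ddof=1))
        floor = 1e-8 * max(s2y, 1.0)

        def proj(theta):
            D, P, s2e = _unpack(theta, qa, qp)
            D = _project_psd(D, floor)
            P = _project_psd(P, floor)
            s2e = max(s2e, floor)
            return _pack(D, P, s2e)

        theta = proj(_pack(vc0.D, vc0.P, vc0.sigma2_e))
        ll, derivs = self._blocks.loglike(theta, want_derivs=True)
        if not np.isfinite(ll):
            raise ConvergenceError("restricted likelihood undefined at start values")
        trajectory = [ll]
        converged = False
        for it in range(maxiter):
            score, AI, _ = derivs
            try:
                delta = np.linalg.solve(AI + 1e-12 * np.eye(len(score)), score)
            except np.linalg.LinAlgError:
                delta = score / max(np.abs(score).max(), 1.0)
            step = 1.0
            improved = False
            for _ in range(25):
                theta_try = proj(theta + step * delta)
                ll_try = self._blocks.loglike(theta_try)
                if np.isfinite(ll_try) and ll_try >= ll - 1e-12:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                # likelihood cannot be improved along the AI direction:
                # treat as converged at a boundary
                converged = True
                break
            dpar = np.max(np.abs(theta_try - theta) / np.maximum(np.abs(theta), floor))
            dll = ll_try - ll
            theta, ll = theta_try, ll_try
            trajectory.append(ll)
            ll, derivs = self._blocks.loglike(theta, want_derivs=True)
            if abs(dll) < tol_loglike or dpar < tol_params:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"AI-REML did not converge in {maxiter} iterations "
                f"(last delta logRL {dll:.3e})",
                trajectory=trajectory,
            )
        D, P, s2e = _unpack(theta, qa, qp)
        vc = VarianceComponents(D=D, P=P, sigma2_e=s2e)
        return self._results(vc, ll, trajectory, converged=True)

    def fit_fixed_vc(self, vc: VarianceComponents) -> "RandomRegressionResults":
        """Solve the MME at user-supplied variance components (no REML)."""
        ll = self.loglike_restricted(vc)
        return self._results(vc, ll, [ll], converged=True)

    def _results(self, vc, ll, trajectory, converged):
        sol = solve_mme(self.sys, self._A_inv_values, vc)
        n_vc = vc.n_params
        aic = -2.0 * ll + 2.0 * n_vc
        bic = -2.0 * ll + n_vc * np.log(self.sys.n_records)
        return RandomRegressionResults(
            model=self, vc=vc, solution=sol,
            loglike=ll, aic=aic, bic=bic,
            converged=converged, n_iter=len(trajectory) - 1, trajectory=trajectory,
        )


@dataclass
class RandomRegressionResults:
    """Fitted null model: variance components, solutions, diagnostics."""

    model: RandomRegressionModel
    vc: VarianceComponents
    solution: MmeSolution
    loglike: float
    aic: float
    bic: float
    converged: bool
    n_iter: int
    trajectory: list[float]

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    def heritability(self, ages) -> np.ndarray:
        """h2(t) = var_a(t) / (var_a(t) + var_pe(t) + sigma2_e)."""
        sys = self.model.sys
        phi_a = design_matrix(np.asarray(ages, float), sys.basis_additive)
        phi_p = design_matrix(np.asarray(ages, float), sys.basis_pe)
        va = self.vc.genetic_variance(phi_a)
        vp = self.vc.pe_variance(phi_p)
        return va / (va + vp + self.vc.sigma2_e)

    def mean_curve(self, ages) -> np.ndarray:
        sys = self.model.sys
        phi = design_matrix(np.asarray(ages, float), sys.basis_fixed)
        return phi @ self.solution.fixed_regression[: sys.basis_fixed.n_coef]

    def breeding_value_curves(self, ages) -> pd.DataFrame:
        """Additive-genetic curves (EBV over age) per pedigree individual."""
        sys = self.model.sys
        phi = design_matrix(np.asarray(ages, float), sys.basis_additive)
        vals = self.solution.additive @ phi.T
        return pd.DataFrame(vals, index=sys.ped_ids, columns=list(np.asarray(ages)))

    def scan(self, genotypes, snp_order: int | None = None, method: str = "wald"):
        from .scan import run_scan

        return run_scan(genotypes, self, snp_order=snp_order, method=method)

    def summary(self) -> str:
        sys = self.model.sys
        lines = []
        lines.append("Random Regression Mixed Model (REML)")
        lines.append("=" * 60)
        lines.append(
            f"records: {sys.n_records}   individuals: {len(sys.pheno_ids)}   "
            f"pedigree size: {len(sys.ped_ids)}"
        )
        lines.append(
            f"orders (mean/additive/perm-env): {self.spec.order_fixed}/"
            f"{self.spec.order_additive}/{self.spec.order_pe}   "
            f"age range: [{sys.basis_fixed.t_min:g}, {sys.basis_fixed.t_max:g}] months"
        )
        lines.append(
            f"logRL: {self.loglike:.4f}   AIC: {self.aic:.2f}   BIC: {self.bic:.2f}   "
            f"iterations: {self.n_iter}   converged: {self.converged}"
        )
        lines.append("-" * 60)
        lines.append("additive coefficient covariance D:")
        for row in self.vc.D:
            lines.append("  " + "  ".join(f"{v:10.4f}" for v in row))
        lines.append("permanent-environment coefficient covariance P:")
        for row in self.vc.P:
            lines.append("  " + "  ".join(f"{v:10.4f}" for v in row))
        lines.append(f"residual variance sigma2_e: {self.vc.sigma2_e:.4f}")
        ages = np.unique(sys.ages)
        h2 = self.heritability(ages)
        lines.append("-" * 60)
        lines.append("age (months):  " + "  ".join(f"{a:8g}" for a in ages))
        lines.append("h2(t):         " + "  ".join(f"{v:8.3f}" for v in h2))
        lines.append("mean curve:    " + "  ".join(f"{v:8.2f}" for v in self.mean_curve(ages)))
        lines.append("=" * 60)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "loglike_restricted": self.loglike,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "D": self.vc.D.tolist(),
            "P": self.vc.P.tolist(),
            "sigma2_e": self.vc.sigma2_e,
            "orders": [self.spec.order_fixed, self.spec.order_additive, self.spec.order_pe],
            "basis": {
                "t_min": self.model.sys.basis_fixed.t_min,
                "t_max": self.model.sys.basis_fixed.t_max,
            },
        }


def select_orders(
    pheno: pd.DataFrame,
    relationship,
    candidates: list[tuple[int, int, int]],
    criterion: str = "bic",
    **model_kwargs,
) -> tuple[RandomRegressionResults, pd.DataFrame]:
    """Fit every (order_fixed, order_additive, order_pe) candidate and pick
    the best by BIC (AIC reported alongside)."""
    if not candidates:
        raise ValueError("no candidate order triples supplied")
    rows = []
    fits = []
    for mf, ma, mp in candidates:
        model = RandomRegressionModel(
            pheno, relationship,
            order_fixed=mf, order_additive=ma, order_pe=mp, **model_kwargs,
        )
        res = model.fit()
        fits.append(res)
        rows.append(
            {
                "order_fixed": mf, "order_additive": ma, "order_pe": mp,
                "loglike": res.loglike, "aic": res.aic, "bic": res.bic,
            }
        )
    table = pd.DataFrame(rows)
    best = int(table[criterion].idxmin())
    return fits[best], table
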