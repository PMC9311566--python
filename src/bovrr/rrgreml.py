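"""Random-regression REML with genomic additive and dominance structures.

The model for a trait record of cow ``i`` at intended calving age ``t`` is

    y_it = x_it' b + phi(t)' a_i + phi(t)' d_i [+ phi(t)' pe_i] + e_it

with ``phi`` the normalized Legendre basis on standardized age, additive
coefficient vectors ``a`` with covariance ``K_a (x) G``, dominance
coefficients ``d`` with ``K_d (x) D``, an optional permanent-environment
term with identity relationship, and iid residuals.  Variance components
are estimated by REML: EM steps (monotone in the restricted
log-likelihood) accelerated with average-information (AI) steps whenever
the AI proposal is admissible and does not decrease the likelihood.  All
per-iteration quantities come from one Cholesky factorization of the
mixed-model-equation (MME) coefficient matrix.

Random-effect coefficients are ordered coefficient-major: the vector for
a factor is ``[u_coef0 (n animals); u_coef1; ...]`` so its covariance is
``K (x) REL`` with n x n blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .basis import basis_at_age

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelSpec:
    """What to fit: trait, fixed effects, basis, variance structure."""

    trait: str = "CW"
    order: int = 1  # Legendre basis order (1 = intercept + slope)
    age_min: float = 2.0
    age_max: float = 8.0
    include_pe: bool = False
    include_dominance: bool = True
    use_calf_sex: bool | None = None  # default: WtW only
    tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("basis order must be >= 0")
        if self.use_calf_sex is None:
            self.use_calf_sex = self.trait == "WtW"


@dataclass
class Designs:
    """Assembled design matrices for one trait."""

    y: np.ndarray  # (N,)
    X: np.ndarray  # (N, p) full column rank
    Phi: np.ndarray  # (N, k+1) basis values per record
    cow_idx: np.ndarray  # (N,) index into animal_ids
    animal_ids: np.ndarray  # (n,)
    fixed_names: list[str]

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def order(self) -> int:
        return self.Phi.shape[1] - 1

    def Z(self) -> sp.csr_matrix:
        """Sparse random-regression incidence, coefficient-major columns."""
        N, kk = self.Phi.shape
        n = self.n_animals
        rows = np.tile(np.arange(N), kk)
        cols = np.concatenate([c * n + self.cow_idx for c in range(kk)])
        data = self.Phi.T.ravel()
        return sp.csr_matrix((data, (rows, cols)), shape=(N, kk * n))


def build_design(
    records: pd.DataFrame, spec: ModelSpec, animal_ids: np.ndarray
) -> Designs:
    """Design matrices from trait records.

    Fixed effects: intercept, opportunity group (factor), intended calving
    age (factor over 0.5-yr classes) and, for WtW, the cumulative calf-sex
    covariate.  Redundant factor columns are dropped by pivoted QR so X has
    full column rank (dropped levels are logged).
    """
    sub = records.loc[records["trait"] == spec.trait] if "trait" in records else records
    if sub.empty:
        raise ValueError(f"no records for trait {spec.trait}")
    ages = sub["age_yr"].to_numpy(dtype=float)
    if ages.min() < spec.age_min - 1e-9 or ages.max() > spec.age_max + 1e-9:
        raise ValueError("record age outside standardization bounds")

    id_index = {a: i for i, a in enumerate(animal_ids)}
    try:
        cow_idx = np.array([id_index[c] for c in sub["cow_id"]], dtype=int)
    except KeyError as exc:
        raise ValueError(f"cow {exc.args[0]} missing from relationship matrix") from exc

    blocks = [np.ones((len(sub), 1))]
    names = ["intercept"]
    for col, tag in (("opp_group", "grp"), ("age_yr", "age")):
        d = pd.get_dummies(sub[col].astype(str), prefix=tag, dtype=float)
        d = d.iloc[:, 1:]  # reference level absorbed by the intercept
        blocks.append(d.to_numpy())
        names.extend(d.columns.tolist())
    if spec.use_calf_sex and "cum_calf_sex" in sub:
        blocks.append(sub["cum_calf_sex"].to_numpy(dtype=float)[:, None])
        names.append("cum_calf_sex")
    X = np.column_stack(blocks)

    # drop linearly dependent columns (pivoted QR on the Gram matrix scale)
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > max(X.shape) * np.finfo(float).eps * diag[0]).sum())
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        dropped = [names[j] for j in piv[rank:]]
        logger.info("dropping %d redundant fixed columns: %s", len(dropped), dropped)
        X = X[:, keep]
        names = [names[j] for j in keep]

    Phi = basis_at_age(ages, spec.age_min, spec.age_max, spec.order)
    return Designs(
        y=sub["value_kg"].to_numpy(dtype=float),
        X=X,
        Phi=Phi,
        cow_idx=cow_idx,
        animal_ids=np.asarray(animal_ids),
        fixed_names=names,
    )


@dataclass
class RRFit:
    """REML estimates and BLUPs for one trait."""

    spec: ModelSpec
    animal_ids: np.ndarray
    K_a: np.ndarray
    K_d: np.ndarray | None
    K_pe: np.ndarray | None
    sigma2_e: float
    loglik: float
    loglik_trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    beta: np.ndarray | None = None
    fixed_names: list[str] | None = None
    coef_a: np.ndarray | None = None  # (n, k+1) additive coefficient BLUPs
    coef_d: np.ndarray | None = None
    coef_pe: np.ndarray | None = None

    def variance_components(self) -> dict:
        out = {"K_a": self.K_a.tolist(), "sigma2_e": self.sigma2_e}
        if self.K_d is not None:
            out["K_d"] = self.K_d.tolist()
        if self.K_pe is not None:
            out["K_pe"] = self.K_pe.tolist()
        return out


# ---------------------------------------------------------------------------
# internals


def _psd_ridge_cholesky(A: np.ndarray, label: str) -> tuple[np.ndarray, float]:
    """Condition a relationship matrix for inversion.

    Genomic relationship matrices are rank deficient whenever variants do
    not outnumber animals, so the smallest eigenvalue is pinned to
    1e-4 x mean diagonal (no-op for well-conditioned inputs); the applied
    ridge is logged.
    """
    mean_diag = float(np.mean(np.diag(A)))
    lam_min = float(np.linalg.eigvalsh(A)[0])
    ridge = max(0.0, 1e-4 * mean_diag - lam_min)
    if ridge:
        logger.info("added ridge %.3g to %s", ridge, label)
        A = A + ridge * np.eye(A.shape[0])
    return A, ridge


def _floor_psd(K: np.ndarray, floor: float) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone with an eigenvalue floor."""
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    return (U * np.clip(w, floor, None)) @ U.T


class _Factor:
    """One random-regression factor (additive, dominance, or PE)."""

    def __init__(self, label: str, rel: np.ndarray | None, n: int, kk: int):
        self.label = label
        self.kk = kk
        self.n = n
        if rel is None:
            self.rel = np.eye(n)
            self.rel_inv = np.eye(n)
            self.logdet_rel = 0.0
        else:
            rel, _ = _psd_ridge_cholesky(np.asarray(rel, dtype=float), label)
            L = sla.cholesky(rel, lower=True)
            self.rel = rel
            self.logdet_rel = 2.0 * float(np.sum(np.log(np.diag(L))))
            self.rel_inv = sla.cho_solve((L, True), np.eye(n))
        self.K = np.eye(kk)

    def set_K(self, K: np.ndarray, floor: float) -> None:
        self.K = _floor_psd(K, floor)

    def K_inv_logdet(self) -> tuple[np.ndarray, float]:
        w, U = np.linalg.eigh(self.K)
        return (U / w) @ U.T, float(np.sum(np.log(w)))

    def n_params(self) -> int:
        return self.kk * (self.kk + 1) // 2

    def param_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i in range(self.kk) for j in range(i, self.kk)]


class _MME:
    """Mixed-model-equation workspace shared across iterations."""

    def __init__(self, designs: Designs, factors: list[_Factor]):
        self.designs = designs
        self.factors = factors
        X = designs.X
        Z = designs.Z()
        self.Z = Z
        self.p = X.shape[1]
        self.q0 = Z.shape[1]  # columns per factor (all share Z)
        self.n_fac = len(factors)
        y = designs.y
        self.N = len(y)
        self.yty = float(y @ y)
        XtX = X.T @ X
        XtZ = X.T @ Z
        ZtZ = (Z.T @ Z).toarray()
        Xty = X.T @ y
        Zty = Z.T @ y
        dim = self.p + self.n_fac * self.q0
        self.dim = dim
        base = np.empty((dim, dim))
        base[: self.p, : self.p] = XtX
        for f in range(self.n_fac):
            o = self.p + f * self.q0
            base[: self.p, o : o + self.q0] = XtZ
            base[o : o + self.q0, : self.p] = XtZ.T
            for g in range(self.n_fac):
                og = self.p + g * self.q0
                base[o : o + self.q0, og : og + self.q0] = ZtZ
        self.base = base
        self.rhs_raw = np.concatenate([Xty] + [Zty] * self.n_fac)

    def assemble(self, sigma2_e: float, out: np.ndarray | None = None) -> np.ndarray:
        C = self.base / sigma2_e if out is None else np.divide(self.base, sigma2_e, out=out)
        n = self.factors[0].n
        for f, fac in enumerate(self.factors):
            Kinv, _ = fac.K_inv_logdet()
            o = self.p + f * self.q0
            for i in range(fac.kk):
                for j in range(fac.kk):
                    C[o + i * n : o + (i + 1) * n, o + j * n : o + (j + 1) * n] += (
                        Kinv[i, j] * fac.rel_inv
                    )
        return C

    def log_gamma_det(self) -> float:
        total = 0.0
        for fac in self.factors:
            _, logdetK = fac.K_inv_logdet()
            total += fac.n * logdetK + fac.kk * fac.logdet_rel
        return total

    def loglik_and_factor(self, sigma2_e: float):
        """Restricted logL plus the Cholesky factor and the solution."""
        C = self.assemble(sigma2_e)
        cho = sla.cho_factor(C, lower=True, overwrite_a=True, check_finite=False)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        s = sla.cho_solve(cho, self.rhs_raw / sigma2_e, check_finite=False)
        yPy = (self.yty - float(s @ self.rhs_raw)) / sigma2_e
        ll = -0.5 * (
            self.N * np.log(sigma2_e)
            + self.log_gamma_det()
            + logdet_C
            + yPy
            + (self.N - self.p) * LOG2PI
        )
        return ll, cho, s

    def apply_W(self, s: np.ndarray) -> np.ndarray:
        out = self.designs.X @ s[: self.p]
        for f in range(self.n_fac):
            o = self.p + f * self.q0
            out += self.Z @ s[o : o + self.q0]
        return out

    def Wt(self, v: np.ndarray) -> np.ndarray:
        Ztv = self.Z.T @ v
        return np.concatenate([self.designs.X.T @ v] + [Ztv] * self.n_fac)

    def derivatives(self, sigma2_e: float, cho, s: np.ndarray):
        """Gradient, average-information matrix and EM update at the
        current parameters, from one MME factorization.

        Parameter order: upper-triangle elements of each factor's K in
        factor order, then sigma2_e.
        """
        designs = self.designs
        kk = self.factors[0].kk
        n = self.factors[0].n
        e_hat = designs.y - self.apply_W(s)
        Py = e_hat / sigma2_e
        t = self.Z.T @ Py
        T = t.reshape(kk, n)

        # AI working vectors: dV/dtheta @ Py for each parameter
        workers = []
        for fac in self.factors:
            RT = (fac.rel @ T.T).T
            for i, j in fac.param_pairs():
                vec = np.zeros((kk, n))
                vec[i] += RT[j]
                if i != j:
                    vec[j] += RT[i]
                workers.append(self.Z @ vec.ravel())
        workers.append(Py)
        Wmat = np.column_stack(workers)
        sol_w = sla.cho_solve(cho, self.Wt(Wmat) / sigma2_e, check_finite=False)
        PW = (Wmat - _apply_W_multi(self, sol_w)) / sigma2_e
        AI = 0.5 * (Wmat.T @ PW)
        AI = (AI + AI.T) / 2.0

        Cinv_low = _invert_from_cholesky(cho)  # lower triangle only

        def inv_block(oi: int, oj: int) -> np.ndarray:
            """n x n block of the symmetric inverse from its lower triangle."""
            if oi > oj:
                return Cinv_low[oi : oi + n, oj : oj + n]
            if oi < oj:
                return Cinv_low[oj : oj + n, oi : oi + n].T
            blk = Cinv_low[oi : oi + n, oj : oj + n]
            low = np.tril(blk)
            return low + np.tril(blk, -1).T

        grad = []
        em_theta = []
        tr_gamma_cinv = 0.0
        for f, fac in enumerate(self.factors):
            o = self.p + f * self.q0
            Q = np.empty((kk, kk))
            Tr = np.empty((kk, kk))
            u = [s[o + c * n : o + (c + 1) * n] for c in range(kk)]
            relinv_u = [fac.rel_inv @ uc for uc in u]
            for i in range(kk):
                for j in range(kk):
                    Q[i, j] = u[i] @ relinv_u[j]
                    blk = inv_block(o + i * n, o + j * n)
                    Tr[i, j] = float(np.sum(fac.rel_inv * blk.T))
            Kinv, _ = fac.K_inv_logdet()
            tr_gamma_cinv += float(np.sum(Kinv * Tr.T))
            em_K = (Q + Tr) / n
            for i, j in fac.param_pairs():
                E = np.zeros((kk, kk))
                E[i, j] = E[j, i] = 1.0
                S = Kinv @ E @ Kinv
                grad.append(
                    -0.5
                    * (
                        n * float(np.trace(Kinv @ E))
                        - float(np.sum(S * Tr.T))
                        - float(np.sum(S * Q))
                    )
                )
                em_theta.append(em_K[i, j])
        q_tot = self.n_fac * self.q0
        trP = (self.N - self.p - q_tot + tr_gamma_cinv) / sigma2_e
        grad.append(-0.5 * (trP - float(e_hat @ e_hat) / sigma2_e**2))
        em_theta.append((self.yty - float(s @ self.rhs_raw)) / (self.N - self.p))
        return np.array(grad), AI, np.array(em_theta)


def _get_params(factors: list[_Factor], sigma2_e: float) -> np.ndarray:
    vals = []
    for fac in factors:
        for i, j in fac.param_pairs():
            vals.append(fac.K[i, j])
    vals.append(sigma2_e)
    return np.array(vals)


def _set_params(factors: list[_Factor], theta: np.ndarray, floor: float):
    pos = 0
    for fac in factors:
        K = np.zeros((fac.kk, fac.kk))
        for i, j in fac.param_pairs():
            K[i, j] = K[j, i] = theta[pos]
            pos += 1
        fac.set_K(K, floor)
    return float(theta[pos])


def reml_fit(
    y_or_designs,
    G: np.ndarray,
    D: np.ndarray | None = None,
    spec: ModelSpec | None = None,
    records: pd.DataFrame | None = None,
    animal_ids: np.ndarray | None = None,
    tol: float | None = None,
    max_iter: int | None = None,
) -> RRFit:
    """Estimate variance components by EM/AI-REML and return BLUPs.

    Accepts either a prebuilt :class:`Designs` object or a record table
    (with ``records``/``animal_ids``).  ``D`` may be omitted for an
    additive-only model; a permanent-environment term is added when
    ``spec.include_pe`` is set.
    """
    spec = spec or ModelSpec()
    if isinstance(y_or_designs, Designs):
        designs = y_or_designs
    else:
        if records is None:
            raise ValueError("pass a Designs object or records + animal_ids")
        designs = build_design(records, spec, animal_ids)
    tol = spec.tol if tol is None else tol
    max_iter = spec.max_iter if max_iter is None else max_iter

    n = designs.n_animals
    kk = designs.order + 1
    factors = [_Factor("G", G, n, kk)]
    if spec.include_dominance and D is not None:
        factors.append(_Factor("D", D, n, kk))
    if spec.include_pe:
        factors.append(_Factor("PE", None, n, kk))

    mme = _MME(designs, factors)
    if mme.N - mme.p <= len(_get_params(factors, 1.0)):
        raise ValueError("too few records for the number of variance parameters")

    # starting values: spread an OLS-residual variance over the components
    beta0, *_ = np.linalg.lstsq(designs.X, designs.y, rcond=None)
    var_y = float(np.var(designs.y - designs.X @ beta0, ddof=mme.p))
    # PSD floor for K eigenvalues: large enough to keep the MME well
    # conditioned when a component collapses, negligible next to var(y)
    floor = 1e-6 * var_y
    phi_bar = float(np.mean(np.sum(designs.Phi**2, axis=1)))
    for fac in factors:
        fac.set_K((0.5 * var_y / len(factors) / phi_bar) * np.eye(kk), floor)
    sigma2_e = 0.5 * var_y

    trace: list[float] = []
    ll, cho, s = mme.loglik_and_factor(sigma2_e)
    trace.append(ll)
    converged = False
    ai_cooldown = 0  # skip AI trials for a few iterations after failures
    for it in range(max_iter):
        grad, AI, em_theta = mme.derivatives(sigma2_e, cho, s)
        theta = _get_params(factors, sigma2_e)

        accepted = None  # (ll, cho, s, sigma2_e)

        def try_candidate(cand: np.ndarray):
            if cand[-1] <= 0:
                return None
            sig_c = _set_params(factors, cand, floor)
            try:
                cand_ll, cand_cho, cand_s = mme.loglik_and_factor(sig_c)
            except (sla.LinAlgError, np.linalg.LinAlgError):
                return None
            if np.isfinite(cand_ll) and cand_ll > ll:
                return cand_ll, cand_cho, cand_s, sig_c
            return None

        if ai_cooldown == 0:
            try:
                delta = np.linalg.solve(AI, grad)
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                for step in (1.0, 0.25):
                    accepted = try_candidate(theta + step * delta)
                    if accepted:
                        break
            if accepted is None:
                ai_cooldown = 3  # AI unhelpful here; rely on (extrapolated) EM
        else:
            ai_cooldown -= 1

        if accepted is None:
            direction = em_theta - theta
            for alpha in (4.0, 2.0):
                accepted = try_candidate(theta + alpha * direction)
                if accepted:
                    break
        if accepted is None:
            # plain EM step: monotone up to PSD-floor round-off
            sigma2_e = _set_params(factors, em_theta, floor)
            try:
                new_ll, cho, s = mme.loglik_and_factor(sigma2_e)
            except (sla.LinAlgError, np.linalg.LinAlgError):
                # numerically stuck against the PSD boundary: keep the
                # previous iterate and stop
                sigma2_e = _set_params(factors, theta, max(floor, 1e-8 * var_y))
                new_ll, cho, s = mme.loglik_and_factor(sigma2_e)
                trace.append(new_ll)
                converged = True
                ll = new_ll
                break
        else:
            new_ll, cho, s, sigma2_e = accepted

        trace.append(new_ll)
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged:
        logger.warning("REML did not converge in %d iterations", max_iter)

    # final solve for BLUPs at the converged components
    beta = s[: mme.p]
    coefs: dict[str, np.ndarray] = {}
    for f, fac in enumerate(factors):
        o = mme.p + f * mme.q0
        coefs[fac.label] = s[o : o + mme.q0].reshape(kk, n).T

    return RRFit(
        spec=spec,
        animal_ids=designs.animal_ids,
        K_a=factors[0].K.copy(),
        K_d=next((f.K.copy() for f in factors if f.label == "D"), None),
        K_pe=next((f.K.copy() for f in factors if f.label == "PE"), None),
        sigma2_e=sigma2_e,
        loglik=ll,
        loglik_trace=trace,
        converged=converged,
        n_iter=len(trace) - 1,
        beta=beta,
        fixed_names=designs.fixed_names,
        coef_a=coefs.get("G"),
        coef_d=coefs.get("D"),
        coef_pe=coefs.get("PE"),
    )


def _apply_W_multi(mme: _MME, S: np.ndarray) -> np.ndarray:
    out = mme.designs.X @ S[: mme.p]
    for f in range(mme.n_fac):
        o = mme.p + f * mme.q0
        out += mme.Z @ S[o : o + mme.q0]
    return out


def _invert_from_cholesky(cho) -> np.ndarray:
    """Inverse from a lower Cholesky factor; only the lower triangle of
    the result is valid (the upper holds factorization remnants)."""
    L, lower = cho
    inv, info = sla.lapack.dpotri(L, lower=lower)
    if info != 0:
        raise np.linalg.LinAlgError("dpotri failed")
    return inv


def blup_effects(
    fit: RRFit, designs: Designs, G: np.ndarray, D: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Solve the MME at the fitted variance components.

    Returns coefficient BLUPs per factor (``a``, and ``d``/``pe`` when in
    the model), each of shape (n_animals, k+1); animals without records
    but connected through G receive predictions.
    """
    n = designs.n_animals
    kk = designs.order + 1
    factors = [_Factor("G", G, n, kk)]
    factors[0].set_K(fit.K_a, 0.0)
    if fit.K_d is not None and D is not None:
        fd = _Factor("D", D, n, kk)
        fd.set_K(fit.K_d, 0.0)
        factors.append(fd)
    if fit.K_pe is not None:
        fp = _Factor("PE", None, n, kk)
        fp.set_K(fit.K_pe, 0.0)
        factors.append(fp)
    mme = _MME(designs, factors)
    _, _, s = mme.loglik_and_factor(fit.sigma2_e)
    out: dict[str, np.ndarray] = {"beta": s[: mme.p]}
    labels = {"G": "a", "D": "d", "PE": "pe"}
    for f, fac in enumerate(factors):
        o = mme.p + f * mme.q0
        out[labels[fac.label]] = s[o : o + mme.q0].reshape(kk, n).T
    return out


def project_to_age(
    coef_a: np.ndarray,
    coef_d: np.ndarray | None,
    spec: ModelSpec,
    age: float = 8.0,
    animal_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Project coefficient BLUPs to a target age: u(t) = phi(t)' coeffs."""
    phi = basis_at_age(age, spec.age_min, spec.age_max, spec.order)[0]
    u_a = np.asarray(coef_a) @ phi
    u_d = (np.asarray(coef_d) @ phi) if coef_d is not None else np.zeros_like(u_a)
    out = pd.DataFrame({"u_a": u_a, "u_d": u_d, "total": u_a + u_d})
    if animal_ids is not None:
        out.insert(0, "animal_id", animal_ids)
    return out


def heritability_curve(fit: RRFit, ages) -> pd.DataFrame:
    """Additive and dominance variance fractions along the age range."""
    spec = fit.spec
    rows = []
    for age in np.atleast_1d(ages):
        phi = basis_at_age(age, spec.age_min, spec.age_max, spec.order)[0]
        v_a = float(phi @ fit.K_a @ phi)
        v_d = float(phi @ fit.K_d @ phi) if fit.K_d is not None else 0.0
        v_pe = float(phi @ fit.K_pe @ phi) if fit.K_pe is not None else 0.0
        tot = v_a + v_d + v_pe + fit.sigma2_e
        rows.append(
            dict(age=float(age), v_a=v_a, v_d=v_d, v_pe=v_pe,
                 sigma2_e=fit.sigma2_e, h2_a=v_a / tot, h2_d=v_d / tot)
        )
    return pd.DataFrame(rows)
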