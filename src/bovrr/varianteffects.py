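"""Back-solved per-variant effects with permutation significance.

Projected animal effects are distributed over variants with the
minimum-norm back-solve ``alpha = M' (M M')^{-1} u`` (and the analogous
``d = H' (H H')^{-1} u_d`` for dominance), using the identity
``M M' = c * GRM`` so the already-built relationship matrix serves as the
Gram matrix.  Effects are standardized to z-scores over the variant
vector; significance comes from the standard error of each variant's
z-score across random permutations of the animal-effect vector, referred
to the standard normal, with Bonferroni correction.  Variants pruned for
redundancy inherit the result of their retained representative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.stats import norm

from .simdata import rng_from_seed

__all__ = [
    "backsolve",
    "zscore",
    "permutation_pvalues",
    "bonferroni_select",
    "propagate_redundant",
    "variant_effect_table",
]


def _gram_solver(gram: np.ndarray, scale: float, coeff: np.ndarray | None = None):
    """Cholesky solver for (gram * scale), ridged if necessary.

    When ``coeff`` is given, checks the contract gram * scale = coeff coeff'.
    """
    A = np.asarray(gram, dtype=float) * scale
    if coeff is not None:
        ref = coeff @ coeff.T
        err = np.max(np.abs(A - ref)) / max(1.0, np.max(np.abs(ref)))
        if err > 1e-6:
            raise ValueError(
                f"gram*scale does not match coeff@coeff' (rel err {err:.2e})"
            )
    ridge = 0.0
    mean_diag = float(np.mean(np.diag(A)))
    while True:
        try:
            L = sla.cholesky(A + ridge * np.eye(A.shape[0]), lower=True)
            break
        except sla.LinAlgError:
            ridge = max(ridge * 10.0, 1e-8 * mean_diag)
            if ridge > mean_diag:
                raise np.linalg.LinAlgError("gram matrix singular even with ridge")
    return lambda v: sla.cho_solve((L, True), v, check_finite=False)


def backsolve(
    coeff_matrix: np.ndarray,
    u: np.ndarray,
    gram: np.ndarray,
    scale: float,
    check: bool = True,
) -> np.ndarray:
    """Minimum-norm variant effects: coeff' (gram*scale)^{-1} u."""
    coeff = np.asarray(coeff_matrix, dtype=float)
    u = np.asarray(u, dtype=float)
    if coeff.shape[0] != len(u):
        raise ValueError("coeff rows must match length of u")
    solver = _gram_solver(gram, scale, coeff if check else None)
    return coeff.T @ solver(u)


def zscore(effects: np.ndarray) -> np.ndarray:
    """Standardize an effect vector: (e - mean) / SD, SD with ddof=1."""
    effects = np.asarray(effects, dtype=float)
    if effects.size < 2:
        raise ValueError("need at least two effects to standardize")
    sd = effects.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread; z-scores undefined")
    return (effects - effects.mean()) / sd


def permutation_pvalues(
    coeff_matrix: np.ndarray,
    gram: np.ndarray,
    scale: float,
    u: np.ndarray,
    B: int = 5000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation SE of per-variant z-scores and approximate p-values.

    For each of ``B`` random permutations of the entries of ``u``, the
    effects are re-solved and standardized; the SE of each variant's
    permuted z-scores calibrates its observed z, with two-sided
    standard-normal tails giving p.  Returns ``(se, p, flagged)`` where
    ``flagged`` marks variants whose permutation SE was zero (p set to 1).
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    u = np.asarray(u, dtype=float)
    coeff = np.asarray(coeff_matrix, dtype=float)
    solver = _gram_solver(gram, scale, coeff)
    z_obs = zscore(coeff.T @ solver(u))

    rng = rng_from_seed(seed)
    n = len(u)
    # solve for all permutations at once: columns of U are permuted u's
    U = np.empty((n, B))
    for b in range(B):
        U[:, b] = u[rng.permutation(n)]
    E = coeff.T @ solver(U)  # m x B permuted effect vectors
    E = (E - E.mean(axis=0)) / E.std(axis=0, ddof=1)
    se = E.std(axis=1, ddof=1)

    # z-scores are O(1); anything this small is degenerate (identical
    # permutations), not a real spread
    flagged = se <= 1e-8
    ratio = np.where(flagged, 0.0, np.abs(z_obs) / np.where(flagged, 1.0, se))
    p = 2.0 * norm.sf(ratio)
    p = np.where(flagged, 1.0, np.minimum(p, 1.0))
    return se, p, flagged


def bonferroni_select(p: np.ndarray, alpha: float = 0.05, m_tests: int | None = None) -> np.ndarray:
    """Bonferroni flags: p * m_tests < alpha."""
    p = np.asarray(p, dtype=float)
    if m_tests is None:
        m_tests = len(p)
    if m_tests < len(p):
        raise ValueError("m_tests smaller than number of p-values")
    return p * m_tests < alpha


def propagate_redundant(
    table: pd.DataFrame,
    redundancy_map: dict[int, int],
    pruned_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Extend results to pruned variants.

    ``table`` is indexed by variant index (positions in the pre-pruning
    variant list) and carries effect/z/p/significance columns; each pruned
    variant inherits its retained representative's statistics, plus a
    ``representative`` column pointing at it.  ``pruned_meta`` (indexed by
    pruned variant index) can supply the pruned variants' own chrom/pos.
    """
    out = table.copy()
    out["representative"] = out.index
    rows = []
    for pruned, rep in redundancy_map.items():
        if rep not in table.index:
            raise KeyError(f"redundancy map target {rep} not among tested variants")
        row = table.loc[rep].copy()
        row["representative"] = rep
        if pruned_meta is not None and pruned in pruned_meta.index:
            for col in pruned_meta.columns:
                if col in row.index:
                    row[col] = pruned_meta.loc[pruned, col]
        row.name = pruned
        rows.append(row)
    if rows:
        out = pd.concat([out, pd.DataFrame(rows)])
        out = out.sort_index()
    return out


def variant_effect_table(
    variants: pd.DataFrame,
    M: np.ndarray,
    H: np.ndarray,
    G: np.ndarray,
    D: np.ndarray,
    c_a: float,
    c_d: float,
    u_a: np.ndarray,
    u_d: np.ndarray,
    B: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    redundancy_map: dict[int, int] | None = None,
    pruned_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full per-variant table for one trait: effects, z, p, flags.

    ``variants`` provides chrom/pos for the retained variants (its index
    should hold pre-pruning variant positions when a redundancy map is
    supplied); the Bonferroni family size is the number of tested
    (retained) variants.
    """
    alpha_hat = backsolve(M, u_a, G, c_a)
    d_hat = backsolve(H, u_d, D, c_d)
    z_a = zscore(alpha_hat)
    z_d = zscore(d_hat)
    _, p_a, _ = permutation_pvalues(M, G, c_a, u_a, B=B, seed=seed)
    _, p_d, _ = permutation_pvalues(H, D, c_d, u_d, B=B, seed=seed + 1)
    m = len(alpha_hat)
    table = pd.DataFrame(
        index=variants.index,
        data={
            "chrom": variants["chrom"].to_numpy(),
            "pos": variants["pos"].to_numpy(),
            "alpha_kg": alpha_hat,
            "d_kg": d_hat,
            "z_a": z_a,
            "z_d": z_d,
            "p_a": p_a,
            "p_d": p_d,
            "sig_a": bonferroni_select(p_a, alpha=alpha, m_tests=m),
            "sig_d": bonferroni_select(p_d, alpha=alpha, m_tests=m),
        }
    )
    if redundancy_map:
        table = propagate_redundant(table, redundancy_map, pruned_meta=pruned_meta)
    return table
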