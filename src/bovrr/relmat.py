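"""Genotype QC and genomic relationship matrices.

Builds the additive GRM **G** (VanRaden method 1: centered allele counts,
scaled by ``2*sum(p_j*(1-p_j))``) and the dominance GRM **D** (genotypic
dominance-deviation coding, scaled by ``sum((2*p_j*q_j)^2)``), together
with their coefficient matrices **M** and **H** used later to back-solve
per-variant effects.  Genomic inbreeding is the G diagonal minus 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # internal missing-call code


@dataclass
class GenotypeMatrix:
    """Animals x variants call matrix with variant metadata.

    ``calls`` holds alternate-allele counts in {0, 1, 2} with -1 for a
    missing call.  ``variants`` is a DataFrame with at least columns
    ``chrom``, ``pos`` (1-based bp) and optionally ``annotation``.
    """

    animal_ids: np.ndarray
    variants: pd.DataFrame
    calls: np.ndarray  # int8, shape (n_animals, n_variants)

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.animal_ids), len(self.variants)):
            raise ValueError("calls shape does not match ids/variants")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per variant from non-missing calls."""
        obs = self.calls >= 0
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n_obs)
        return np.where(n_obs > 0, p, np.nan)

    def variant_call_rate(self) -> np.ndarray:
        return (self.calls >= 0).mean(axis=0)

    def animal_call_rate(self) -> np.ndarray:
        return (self.calls >= 0).mean(axis=1)

    def subset(self, animal_mask=None, variant_mask=None) -> "GenotypeMatrix":
        a = np.arange(self.n_animals) if animal_mask is None else np.flatnonzero(animal_mask)
        v = np.arange(self.n_variants) if variant_mask is None else np.flatnonzero(variant_mask)
        return GenotypeMatrix(
            animal_ids=self.animal_ids[a],
            variants=self.variants.iloc[v].reset_index(drop=True),
            calls=self.calls[np.ix_(a, v)],
        )


@dataclass
class RelationshipPair:
    """Additive and dominance GRMs with their coefficient matrices."""

    animal_ids: np.ndarray
    G: np.ndarray
    D: np.ndarray
    M: np.ndarray  # centered additive coefficients, n x m
    H: np.ndarray  # centered dominance coefficients, n x m
    c_a: float  # 2 * sum p_j q_j
    c_d: float  # sum (2 p_j q_j)^2
    freqs: np.ndarray
    redundancy_map: dict = field(default_factory=dict)


def qc_filter(
    genotypes: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.005,
) -> GenotypeMatrix:
    """Filter variants and animals by call rate and variants by MAF.

    Order: variant call rate, then animal call rate, then MAF (strict
    ``maf > min_maf``); MAF is recomputed on the retained animals.
    """
    if not (0 < min_call_rate <= 1):
        raise ValueError("min_call_rate must be in (0, 1]")
    g = genotypes
    v_keep = g.variant_call_rate() >= min_call_rate
    g = g.subset(variant_mask=v_keep)
    a_keep = g.animal_call_rate() >= min_call_rate
    g = g.subset(animal_mask=a_keep)
    p = g.allele_frequencies()
    maf = np.minimum(p, 1 - p)
    m_keep = maf > min_maf
    g2 = g.subset(variant_mask=m_keep)
    logger.info(
        "qc_filter: removed %d variants (call rate), %d animals, %d variants (MAF)",
        int((~v_keep).sum()), int((~a_keep).sum()), int((~m_keep).sum()),
    )
    if g2.n_variants == 0:
        raise ValueError("all variants removed by QC")
    if g2.n_animals == 0:
        raise ValueError("all animals removed by QC")
    return g2


def ld_prune(
    genotypes: GenotypeMatrix,
    window_bp: int = 50_000,
    r_thresh: float = 0.98,
) -> tuple[GenotypeMatrix, dict[int, int]]:
    """Remove close, nearly redundant variants.

    Scans each chromosome left to right; a variant is dropped and mapped to
    the earlier retained variant when they are within ``window_bp`` and the
    absolute Pearson correlation of their call vectors (over animals
    non-missing at both) exceeds ``r_thresh``.  Returns the pruned matrix
    and a map from each dropped variant index to its retained
    representative (indices into the *input* variant table).
    """
    calls = genotypes.calls
    chrom = genotypes.variants["chrom"].to_numpy()
    pos = genotypes.variants["pos"].to_numpy()
    n_var = genotypes.n_variants
    keep = np.ones(n_var, dtype=bool)
    redundancy: dict[int, int] = {}
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if np.any(np.diff(pos[idx]) < 0):
            raise ValueError(f"positions not sorted on chromosome {c}")
        retained: list[int] = []
        for j in idx:
            dropped = False
            for i in reversed(retained):
                if pos[j] - pos[i] > window_bp:
                    break
                r = _pairwise_r(calls[:, i], calls[:, j])
                if r is not None and abs(r) > r_thresh:
                    keep[j] = False
                    redundancy[int(j)] = int(i)
                    dropped = True
                    break
            if not dropped:
                retained.append(j)
    return genotypes.subset(variant_mask=keep), redundancy


def _pairwise_r(a: np.ndarray, b: np.ndarray):
    """Pearson r of two call vectors over jointly non-missing animals.

    Returns None when either vector has zero variance (r undefined, so the
    pair is treated as not prunable).
    """
    ok = (a >= 0) & (b >= 0)
    if ok.sum() < 2:
        return None
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return None
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _imputed_calls(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Float calls with per-variant mean imputation of missing entries."""
    calls = genotypes.calls.astype(float)
    p = genotypes.allele_frequencies()
    miss = genotypes.calls < 0
    n_miss = int(miss.sum())
    if n_miss:
        logger.info("mean-imputing %d missing calls", n_miss)
        fill = np.broadcast_to(2.0 * p, calls.shape)
        calls = np.where(miss, fill, calls)
    return calls, p


def additive_grm(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Additive GRM: G = M M' / (2 sum p_j q_j), M = calls - 2p."""
    calls, p = _imputed_calls(genotypes)
    q = 1.0 - p
    c_a = float(2.0 * np.sum(p * q))
    if c_a == 0:
        raise ValueError("all variants monomorphic; additive scaling is zero")
    M = calls - 2.0 * p
    G = (M @ M.T) / c_a
    return G, M, c_a


def dominance_grm(
    genotypes: GenotypeMatrix, coding: str = "deviation"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Dominance GRM from genotypic dominance-deviation coding.

    Per variant with alternate frequency p and q = 1 - p, the coded values
    are: call 0 -> -2p^2, call 1 -> 2pq, call 2 -> -2q^2, and
    D = H H' / sum((2 p_j q_j)^2).  ``coding="indicator"`` instead centers
    the raw 0/1 heterozygosity indicator (call==1 minus its frequency
    expectation 2pq) with the same scaling, for sensitivity analyses.
    """
    calls, p = _imputed_calls(genotypes)
    q = 1.0 - p
    c_d = float(np.sum((2.0 * p * q) ** 2))
    if c_d == 0:
        raise ValueError("no heterozygosity; dominance scaling is zero")
    if coding == "deviation":
        H = np.select(
            [np.isclose(calls, 0), np.isclose(calls, 1), np.isclose(calls, 2)],
            [
                np.broadcast_to(-2.0 * p**2, calls.shape),
                np.broadcast_to(2.0 * p * q, calls.shape),
                np.broadcast_to(-2.0 * q**2, calls.shape),
            ],
            # mean-imputed (fractional) calls carry no dominance information
            default=0.0,
        )
    elif coding == "indicator":
        het = np.isclose(calls, 1).astype(float)
        H = het - 2.0 * p * q
    else:
        raise ValueError(f"unknown dominance coding: {coding!r}")
    D = (H @ H.T) / c_d
    return D, H, c_d


def genomic_inbreeding(G: np.ndarray) -> np.ndarray:
    """Genomic inbreeding per animal: diagonal of G minus 1."""
    return np.diag(G) - 1.0


def build_relationships(
    genotypes: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.005,
    window_bp: int = 50_000,
    r_thresh: float = 0.98,
    dominance_coding: str = "deviation",
    prune: bool = True,
) -> tuple[RelationshipPair, GenotypeMatrix]:
    """QC-filter, LD-prune, and build both GRMs in one call."""
    g = qc_filter(genotypes, min_call_rate=min_call_rate, min_maf=min_maf)
    if prune:
        g, redundancy = ld_prune(g, window_bp=window_bp, r_thresh=r_thresh)
    else:
        redundancy = {}
    G, M, c_a = additive_grm(g)
    D, H, c_d = dominance_grm(g, coding=dominance_coding)
    pair = RelationshipPair(
        animal_ids=g.animal_ids,
        G=G,
        D=D,
        M=M,
        H=H,
        c_a=c_a,
        c_d=c_d,
        freqs=g.allele_frequencies(),
        redundancy_map=redundancy,
    )
    return pair, g
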