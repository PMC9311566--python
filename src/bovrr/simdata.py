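"""Synthetic multibreed beef herds with known genetic parameters.

Emulates the structure a crossbred-cow genomic analysis assumes: several
divergent breeds, crossbred pedigrees with tracked breed composition,
linked genotypes produced by gene dropping (so runs of homozygosity can
arise), and longitudinal cow-weight / weight-weaned event data generated
under a seasonal breeding and two-strikes culling regime.

Breed divergence follows the Balding–Nichols model: each breed's
alternate-allele frequency at a variant is Beta-distributed around a
shared ancestral frequency ``p0`` with spread controlled by a single
``F_ST`` parameter.  Meioses recombine under the Haldane (no
interference) model.  All randomness flows through an explicit seed via
the counter-based Philox generator, so results are reproducible across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import basis_at_age
from .relmat import GenotypeMatrix, additive_grm, dominance_grm

__all__ = [
    "BreedPanel",
    "Pedigree",
    "TrueParams",
    "Mating",
    "CrossingPlan",
    "COMPOSITE_BREEDS",
    "decompose_composition",
    "simulate_breed_panel",
    "simulate_pedigree",
    "drop_genotypes",
    "simulate_events",
    "make_true_params",
    "default_plan",
    "simulate_herd",
]

EVENT_COLUMNS = [
    "cow_id", "age", "pregnant", "weaned",
    "calf_sex", "weaning_weight", "cow_weight",
]

#: Composite-breed decompositions to base breeds.  Stabilized composites
#: are expanded to their component purebred fractions before any
#: heterozygosity bookkeeping.
COMPOSITE_BREEDS: dict[str, dict[str, float]] = {
    "Brangus": {"Brahman": 0.375, "Angus": 0.625},
    "Santa Gertrudis": {"Brahman": 0.375, "Shorthorn": 0.625},
    "Beefmaster": {"Brahman": 0.5, "Hereford": 0.25, "Shorthorn": 0.25},
    "MARC II": {"Angus": 0.25, "Hereford": 0.25, "Gelbvieh": 0.25, "Simmental": 0.25},
    "MARC III": {"Angus": 0.25, "Hereford": 0.25, "Red Poll": 0.25, "Pinzgauer": 0.25},
    "ChiAngus": {"Angus": 0.8, "Chianina": 0.2},
}


def rng_from_seed(seed: int) -> np.random.Generator:
    """Counter-based generator; identical streams on every platform."""
    return np.random.Generator(np.random.Philox(seed))


def decompose_composition(comp: dict[str, float]) -> dict[str, float]:
    """Expand composite breeds into base-breed fractions."""
    out: dict[str, float] = {}
    for breed, frac in comp.items():
        if breed in COMPOSITE_BREEDS:
            for b, f in COMPOSITE_BREEDS[breed].items():
                out[b] = out.get(b, 0.0) + frac * f
        else:
            out[breed] = out.get(breed, 0.0) + frac
    return out


@dataclass
class BreedPanel:
    """Per-breed allele frequencies over a shared variant map."""

    breeds: list[str]
    freqs: dict[str, np.ndarray]  # breed -> alt-allele frequency per variant
    variants: pd.DataFrame  # chrom, pos (1-based bp)
    chrom_lengths: dict  # chrom -> length in bp
    fst: float

    def __post_init__(self) -> None:
        m = len(self.variants)
        for b in self.breeds:
            f = np.asarray(self.freqs[b], dtype=float)
            if f.shape != (m,):
                raise ValueError(f"frequency vector for {b} has wrong length")
            if np.any(f < 0) or np.any(f > 1):
                raise ValueError(f"frequencies for {b} outside [0, 1]")
            self.freqs[b] = f
        for c, sub in self.variants.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def _unique_positions(rng: np.random.Generator, length: int, k: int) -> np.ndarray:
    """k distinct sorted positions in 1..length without materializing the range."""
    if k > length:
        raise ValueError("more variants than base pairs")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=k))
    while len(pos) < k:
        extra = rng.integers(1, length + 1, size=k - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def simulate_breed_panel(
    n_breeds: int,
    n_variants: int,
    n_chromosomes: int = 5,
    chrom_length: int = 100_000_000,
    fst: float = 0.1,
    seed: int = 0,
    breed_names: list[str] | None = None,
) -> BreedPanel:
    """Balding–Nichols breed panel around ancestral Uniform(0.05, 0.95) p0.

    ``fst = 0`` returns identical frequency vectors for every breed.
    """
    if n_breeds < 1 or n_variants < 1 or n_chromosomes < 1:
        raise ValueError("counts must be positive")
    if not (0 <= fst < 1):
        raise ValueError("fst must be in [0, 1)")
    rng = rng_from_seed(seed)
    if breed_names is None:
        breed_names = [f"B{i + 1}" for i in range(n_breeds)]
    if len(breed_names) != n_breeds:
        raise ValueError("breed_names length mismatch")

    # spread variants over chromosomes, unique sorted positions per chrom
    counts = np.full(n_chromosomes, n_variants // n_chromosomes)
    counts[: n_variants % n_chromosomes] += 1
    chroms, positions = [], []
    for c in range(n_chromosomes):
        k = int(counts[c])
        if k == 0:
            continue
        pos = _unique_positions(rng, chrom_length, k)
        chroms.extend([str(c + 1)] * k)
        positions.extend(pos.tolist())
    variants = pd.DataFrame({"chrom": chroms, "pos": positions})

    p0 = rng.uniform(0.05, 0.95, size=n_variants)
    freqs: dict[str, np.ndarray] = {}
    for b in breed_names:
        if fst == 0:
            freqs[b] = p0.copy()
        else:
            a = p0 * (1 - fst) / fst
            bb = (1 - p0) * (1 - fst) / fst
            freqs[b] = rng.beta(a, bb)
    return BreedPanel(
        breeds=list(breed_names),
        freqs=freqs,
        variants=variants,
        chrom_lengths={str(c + 1): chrom_length for c in range(n_chromosomes)},
        fst=fst,
    )


@dataclass
class Pedigree:
    """Pedigree table plus per-animal breed compositions.

    ``table`` columns: animal_id, sire_id, dam_id (empty string for
    unknown), sex ('M'/'F'), birth_season (int half-year index), cohort.
    Rows are ordered so parents precede offspring.
    """

    table: pd.DataFrame
    composition: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.table.itertuples(index=False):
            for parent in (row.sire_id, row.dam_id):
                if parent and parent not in seen:
                    raise ValueError(f"parent {parent} after offspring {row.animal_id}")
            seen.add(row.animal_id)
        for aid, comp in self.composition.items():
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition of {aid} sums to {total}")

    @property
    def animal_ids(self) -> np.ndarray:
        return self.table["animal_id"].to_numpy()

    def females(self) -> np.ndarray:
        t = self.table
        return t.loc[t["sex"] == "F", "animal_id"].to_numpy()


@dataclass
class Mating:
    name: str  # cohort name for the offspring
    sire_cohort: str
    dam_cohort: str
    n_offspring: int


@dataclass
class CrossingPlan:
    """Founder cohorts (name -> breed composition) and staged matings."""

    founder_cohorts: dict[str, dict[str, float]]
    generations: list[list[Mating]] = field(default_factory=list)


def default_plan(
    breeds: list[str],
    offspring_per_mating: int = 60,
    n_generations: int = 2,
) -> CrossingPlan:
    """Purebred lines, F1 crosses of adjacent breeds, then backcrosses and
    three/four-breed crosses — a compact stand-in for a continuous
    multibreed sampling herd."""
    founders = {b: {b: 1.0} for b in breeds}
    gen1: list[Mating] = []
    for b in breeds:
        gen1.append(Mating(f"{b}_pure", b, b, offspring_per_mating))
    for i in range(len(breeds)):
        a, b = breeds[i], breeds[(i + 1) % len(breeds)]
        gen1.append(Mating(f"F1_{a}x{b}", a, b, offspring_per_mating))
    generations = [gen1]
    if n_generations >= 2:
        gen2: list[Mating] = []
        for i in range(len(breeds)):
            a, b = breeds[i], breeds[(i + 1) % len(breeds)]
            c = breeds[(i + 2) % len(breeds)]
            gen2.append(Mating(f"{a}_pure2", f"{a}_pure", f"{a}_pure", offspring_per_mating))
            gen2.append(Mating(f"BC_{a}x{a}{b}", f"{a}_pure", f"F1_{a}x{b}", offspring_per_mating))
            gen2.append(
                Mating(f"X3_{c}x{a}{b}", f"{c}_pure", f"F1_{a}x{b}", offspring_per_mating)
            )
        generations.append(gen2)
    return CrossingPlan(founder_cohorts=founders, generations=generations)


def simulate_pedigree(
    plan: CrossingPlan,
    n_founders_per_breed: int = 20,
    seed: int = 0,
) -> Pedigree:
    """Realize a pedigree from a crossbreeding plan.

    Founders of each cohort get that cohort's (decomposed) composition;
    every non-founder's composition is the parental average.
    """
    if n_founders_per_breed < 1:
        raise ValueError("need at least one founder per cohort")
    rng = rng_from_seed(seed)
    rows: list[dict] = []
    composition: dict[str, dict[str, float]] = {}
    cohort_members: dict[str, list[tuple[str, str]]] = {}

    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"A{counter:06d}"

    for cohort, comp in plan.founder_cohorts.items():
        comp = decompose_composition(comp)
        members = []
        for i in range(n_founders_per_breed):
            aid = new_id()
            sex = "M" if i % 2 == 0 else "F"
            rows.append(
                dict(animal_id=aid, sire_id="", dam_id="", sex=sex,
                     birth_season=0, cohort=cohort)
            )
            composition[aid] = dict(comp)
            members.append((aid, sex))
        cohort_members[cohort] = members

    for g, matings in enumerate(plan.generations, start=1):
        new_members: dict[str, list[tuple[str, str]]] = {}
        for mating in matings:
            sires = [a for a, s in cohort_members.get(mating.sire_cohort, []) if s == "M"]
            dams = [a for a, s in cohort_members.get(mating.dam_cohort, []) if s == "F"]
            if not sires or not dams:
                raise ValueError(
                    f"plan references cohort without available parents: "
                    f"{mating.sire_cohort} x {mating.dam_cohort}"
                )
            members = new_members.setdefault(mating.name, [])
            for off in range(mating.n_offspring):
                sire = sires[rng.integers(len(sires))]
                dam = dams[rng.integers(len(dams))]
                aid = new_id()
                # alternate sexes so every cohort can parent the next stage
                sex = "M" if off % 2 == 0 else "F"
                rows.append(
                    dict(animal_id=aid, sire_id=sire, dam_id=dam, sex=sex,
                         birth_season=2 * g, cohort=mating.name)
                )
                comp: dict[str, float] = {}
                for b, f in composition[sire].items():
                    comp[b] = comp.get(b, 0.0) + 0.5 * f
                for b, f in composition[dam].items():
                    comp[b] = comp.get(b, 0.0) + 0.5 * f
                composition[aid] = comp
                members.append((aid, sex))
        cohort_members.update(new_members)

    return Pedigree(table=pd.DataFrame(rows), composition=composition)


def _meiosis(
    parent_haps: np.ndarray,
    morgan_pos: np.ndarray,
    chrom_morgans: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete under Haldane recombination (Poisson crossovers)."""
    n_xo = rng.poisson(chrom_morgans)
    start = int(rng.integers(2))
    if n_xo == 0:
        return parent_haps[start]
    xo = np.sort(rng.uniform(0.0, chrom_morgans, size=n_xo))
    segment = np.searchsorted(xo, morgan_pos, side="right")
    choice = (start + segment) % 2
    return np.where(choice == 0, parent_haps[0], parent_haps[1])


def drop_genotypes(
    pedigree: Pedigree,
    panel: BreedPanel,
    map_cm_per_mb: float = 1.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop linked genotypes through the pedigree.

    Founder haplotypes are drawn per chromosome from breed allele
    frequencies, with each founder haplotype's breed label sampled from the
    founder's composition.  Meioses recombine under the Haldane model, so
    inbred lines accumulate long homozygous stretches.
    """
    if map_cm_per_mb <= 0:
        raise ValueError("map_cm_per_mb must be positive")
    for aid in pedigree.animal_ids:
        comp = pedigree.composition[aid]
        for b in comp:
            if b not in panel.breeds:
                raise ValueError(f"breed {b} not in panel")

    rng = rng_from_seed(seed)
    variants = panel.variants
    chrom_codes = variants["chrom"].to_numpy()
    chrom_list = list(dict.fromkeys(chrom_codes))
    chrom_slices: dict[str, slice] = {}
    morgan_pos: dict[str, np.ndarray] = {}
    chrom_morgans: dict[str, float] = {}
    for c in chrom_list:
        idx = np.flatnonzero(chrom_codes == c)
        chrom_slices[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        pos = variants["pos"].to_numpy()[idx].astype(float)
        morgan_pos[c] = pos / 1e6 * map_cm_per_mb / 100.0
        chrom_morgans[c] = panel.chrom_lengths[c] / 1e6 * map_cm_per_mb / 100.0

    m = panel.n_variants
    haplotypes: dict[str, np.ndarray] = {}
    table = pedigree.table
    for row in table.itertuples(index=False):
        haps = np.empty((2, m), dtype=np.int8)
        if not row.sire_id:  # founder
            comp = pedigree.composition[row.animal_id]
            breeds = list(comp)
            probs = np.array([comp[b] for b in breeds])
            for h in range(2):
                for c in chrom_list:
                    sl = chrom_slices[c]
                    b = breeds[rng.choice(len(breeds), p=probs)]
                    f = panel.freqs[b][sl]
                    haps[h, sl] = (rng.random(f.shape[0]) < f).astype(np.int8)
        else:
            for h, parent in enumerate((row.sire_id, row.dam_id)):
                ph = haplotypes[parent]
                for c in chrom_list:
                    sl = chrom_slices[c]
                    haps[h, sl] = _meiosis(
                        ph[:, sl], morgan_pos[c], chrom_morgans[c], rng
                    )
        haplotypes[row.animal_id] = haps

    ids = pedigree.animal_ids
    calls = np.empty((len(ids), m), dtype=np.int8)
    for i, aid in enumerate(ids):
        calls[i] = haplotypes[aid].sum(axis=0)
    var_meta = variants.copy()
    var_meta["annotation"] = "simulated"
    return GenotypeMatrix(animal_ids=ids, variants=var_meta, calls=calls)


@dataclass
class TrueParams:
    """Generating parameters for the longitudinal traits.

    ``K_a``/``K_d``/``K_pe`` are coefficient covariance matrices (kg^2) on
    the normalized-Legendre basis over standardized age; ``sigma2_e`` is
    the residual variance (kg^2).  The conception model is logistic with a
    baseline probability and a shift proportional to the cow's
    (standardized) dominance value, which is how heterosis raises
    productivity in the simulated herd.
    """

    K_a: np.ndarray
    K_d: np.ndarray
    sigma2_e: float
    K_pe: np.ndarray | None = None
    dominance_mean: float = 0.0  # kg per heterozygous locus (variant-effects mode)
    #: fraction of dominance variance carried by the heterozygosity-linked
    #: (directional) component in variant-effects mode; this is what makes
    #: dominance behave as heterosis
    directional_dominance: float = 0.0
    conception_base: float = 0.75
    conception_heterosis: float = 0.0  # logit shift per SD of dominance value
    age_min: float = 2.0
    age_max: float = 8.0
    cw_mature: float = 650.0  # kg, asymptotic cow weight
    cw_growth_rate: float = 0.55  # 1/yr approach to maturity
    cw_age2: float = 430.0  # kg at first breeding outcome
    calf_base: float = 230.0  # kg weaning weight baseline
    calf_sex_effect: float = 12.0  # kg, added for males, subtracted for females
    calf_noise_sd: float = 25.0  # kg
    calf_genetic_scale: float = 0.35  # cow age-8 genetic value -> per-calf kg
    weaning_prob: float = 0.95
    group_effect_sd: float = 15.0  # kg, opportunity-group effects

    def __post_init__(self) -> None:
        for name in ("K_a", "K_d"):
            K = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if not np.allclose(K, K.T):
                raise ValueError(f"{name} not symmetric")
            if np.min(np.linalg.eigvalsh(K)) < -1e-8 * max(1.0, np.trace(K)):
                raise ValueError(f"{name} not positive semidefinite")
            setattr(self, name, K)
        if self.K_pe is not None:
            self.K_pe = np.atleast_2d(np.asarray(self.K_pe, dtype=float))
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")

    @property
    def order(self) -> int:
        return self.K_a.shape[0] - 1

    def mean_weight(self, age: float) -> float:
        """Asymptotic mean cow-weight growth curve."""
        return self.cw_mature - (self.cw_mature - self.cw_age2) * np.exp(
            -self.cw_growth_rate * (age - self.age_min)
        )


def make_true_params(
    ratio_a8: float,
    ratio_d8: float,
    total_var_age8: float = 2500.0,
    order: int = 1,
    ratio_pe8: float = 0.0,
    **kwargs,
) -> TrueParams:
    """Build coefficient covariances hitting target age-8 variance ratios.

    The shape of each coefficient covariance is fixed (intercept-dominant
    with a positive intercept-slope covariance) and scaled so that
    phi(age_max)' K phi(age_max) equals the requested share of
    ``total_var_age8``; the residual picks up the remainder.
    """
    if ratio_a8 + ratio_d8 + ratio_pe8 >= 1.0:
        raise ValueError("variance ratios must sum to less than 1")
    if order == 0:
        shape = np.array([[1.0]])
    else:
        shape = np.eye(order + 1)
        shape[0, 0] = 1.0
        for j in range(1, order + 1):
            shape[j, j] = 0.5 / j
            shape[0, j] = shape[j, 0] = 0.25 / j
    phi = basis_at_age(
        kwargs.get("age_max", 8.0),
        kwargs.get("age_min", 2.0),
        kwargs.get("age_max", 8.0),
        order,
    )[0]
    denom = float(phi @ shape @ phi)

    def scaled(ratio: float) -> np.ndarray:
        return (ratio * total_var_age8 / denom) * shape

    K_pe = scaled(ratio_pe8) if ratio_pe8 > 0 else None
    sigma2_e = (1.0 - ratio_a8 - ratio_d8 - ratio_pe8) * total_var_age8
    return TrueParams(
        K_a=scaled(ratio_a8), K_d=scaled(ratio_d8), K_pe=K_pe,
        sigma2_e=sigma2_e, **kwargs,
    )


def _psd_factor(A: np.ndarray) -> np.ndarray:
    """Factor L with L L' = A for a (numerically) PSD matrix."""
    w, U = np.linalg.eigh(np.asarray(A, dtype=float))
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def _sample_coefficients(
    K: np.ndarray, L_rel: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw an n x (k+1) coefficient matrix with vec-covariance K (x) REL,
    where ``L_rel`` factors the n x n relationship matrix."""
    n = L_rel.shape[0]
    Z = rng.standard_normal((n, K.shape[0]))
    return L_rel @ Z @ _psd_factor(K).T


def simulate_events(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    params: TrueParams,
    mode: str = "coefficient-sampling",
    seed: int = 0,
    causal_fraction: float = 0.1,
    cow_ids: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate breeding exposures, pregnancy tests, calves and weights.

    Returns ``(events, truth)``.  ``events`` has one row per breeding
    exposure with columns ``cow_id, age, pregnant, weaned, calf_sex,
    weaning_weight, cow_weight``; intended calving ages start at 2 and
    advance 1.0 yr after a pregnancy, 0.5 yr after an open (non-pregnant)
    diagnosis, and a cow is culled after her second consecutive open test.
    ``truth`` holds per-animal true additive/dominance coefficients, their
    age-8 projections, and the conception logit shift.

    ``mode="coefficient-sampling"`` draws animal coefficient vectors with
    covariance K_a (x) G and K_d (x) D (records then follow the
    random-regression model exactly); ``mode="variant-effects"`` builds
    animal values from per-variant effects (additive Normal; dominance
    Normal with positive mean on the heterozygosity coding, giving
    directional dominance).
    """
    if mode not in ("coefficient-sampling", "variant-effects"):
        raise ValueError(f"unknown mode: {mode!r}")
    rng = rng_from_seed(seed)
    ids = genotypes.animal_ids
    n = len(ids)
    k = params.order

    if mode == "coefficient-sampling":
        G, _, _ = additive_grm(genotypes)
        a_coef = _sample_coefficients(params.K_a, _psd_factor(G), rng)
        if np.any(params.K_d):
            D, _, _ = dominance_grm(genotypes)
            d_coef = _sample_coefficients(params.K_d, _psd_factor(D), rng)
        else:
            d_coef = np.zeros((n, k + 1))
    else:
        _, M, c_a = additive_grm(genotypes)
        _, H, c_d = dominance_grm(genotypes)
        m = M.shape[1]
        n_causal = max(1, int(round(causal_fraction * m)))
        causal = rng.choice(m, size=n_causal, replace=False)
        p = genotypes.allele_frequencies()[causal]
        ca_c = 2.0 * np.sum(p * (1 - p))
        cd_c = np.sum((2.0 * p * (1 - p)) ** 2)
        La = _psd_factor(params.K_a / max(ca_c, 1e-12))
        alpha = rng.standard_normal((n_causal, k + 1)) @ La.T
        a_coef = M[:, causal] @ alpha
        f_dir = params.directional_dominance
        if not (0 <= f_dir < 1):
            raise ValueError("directional_dominance must be in [0, 1)")
        Ld = _psd_factor((1.0 - f_dir) * params.K_d / max(cd_c, 1e-12))
        delta = rng.standard_normal((n_causal, k + 1)) @ Ld.T
        delta[:, 0] += params.dominance_mean
        d_coef = H[:, causal] @ delta
        if f_dir > 0:
            # heterozygosity-linked intercept component, scaled to carry
            # f_dir of the target intercept dominance variance
            hsum = H[:, causal].sum(axis=1)
            sd_h = hsum.std()
            if sd_h > 0:
                d_coef[:, 0] += np.sqrt(f_dir * params.K_d[0, 0]) * (
                    (hsum - hsum.mean()) / sd_h
                )

    pe_coef = (
        _sample_coefficients(params.K_pe, np.eye(n), rng)
        if params.K_pe is not None
        else np.zeros((n, k + 1))
    )

    phi8 = basis_at_age(params.age_max, params.age_min, params.age_max, k)[0]
    a8 = a_coef @ phi8
    d8 = d_coef @ phi8
    d_sd = d8.std()
    het_shift = params.conception_heterosis * (
        (d8 - d8.mean()) / d_sd if d_sd > 0 else np.zeros(n)
    )

    truth = pd.DataFrame({"animal_id": ids})
    for j in range(k + 1):
        truth[f"a{j}"] = a_coef[:, j]
        truth[f"d{j}"] = d_coef[:, j]
    truth["a8"] = a8
    truth["d8"] = d8
    truth["conception_shift"] = het_shift

    if cow_ids is None:
        females = set(pedigree.females())
        cow_ids = np.array([a for a in ids if a in females])
    idx_of = {a: i for i, a in enumerate(ids)}

    base_logit = np.log(params.conception_base / (1 - params.conception_base))
    group_effects: dict[int, float] = {}
    table = pedigree.table.set_index("animal_id")

    ages = np.arange(params.age_min, params.age_max + 0.25, 0.5)
    phi_by_age = {a: basis_at_age(a, params.age_min, params.age_max, k)[0] for a in ages}

    rows: list[dict] = []
    sigma_e = np.sqrt(params.sigma2_e)
    for cow in cow_ids:
        i = idx_of[cow]
        season = int(table.loc[cow, "birth_season"])
        if season not in group_effects:
            group_effects[season] = rng.normal(0.0, params.group_effect_sd)
        g_eff = group_effects[season]
        age = params.age_min
        consec_open = 0
        while age <= params.age_max + 1e-9:
            p_conc = 1.0 / (1.0 + np.exp(-(base_logit + het_shift[i])))
            pregnant = bool(rng.random() < p_conc)
            phi = phi_by_age[round(age * 2) / 2]
            cw = (
                params.mean_weight(age)
                + g_eff
                + phi @ (a_coef[i] + d_coef[i] + pe_coef[i])
                + rng.normal(0.0, sigma_e)
            )
            weaned = False
            calf_sex = ""
            ww = 0.0
            if pregnant:
                weaned = bool(rng.random() < params.weaning_prob)
                if weaned:
                    calf_sex = "M" if rng.random() < 0.5 else "F"
                    ww = (
                        params.calf_base
                        + (params.calf_sex_effect if calf_sex == "M" else -params.calf_sex_effect)
                        + params.calf_genetic_scale * (a8[i] + d8[i])
                        + rng.normal(0.0, params.calf_noise_sd)
                    )
                    ww = max(ww, 0.0)
            rows.append(
                dict(cow_id=cow, age=round(age * 2) / 2, pregnant=pregnant,
                     weaned=weaned, calf_sex=calf_sex,
                     weaning_weight=ww, cow_weight=cw)
            )
            if pregnant:
                consec_open = 0
                age += 1.0
            else:
                consec_open += 1
                if consec_open >= 2:
                    break  # culled after second consecutive open diagnosis
                age += 0.5
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return events, truth


def simulate_herd(
    n_cows: int,
    n_variants: int,
    ratio_a8: float = 0.5,
    ratio_d8: float = 0.05,
    seed: int = 0,
    n_breeds: int = 4,
    n_chromosomes: int = 5,
    chrom_length: int = 100_000_000,
    fst: float = 0.15,
    mode: str = "coefficient-sampling",
    total_var_age8: float = 2500.0,
    order: int = 1,
    n_founders_per_breed: int = 20,
    causal_fraction: float = 0.1,
    **param_kwargs,
) -> dict:
    """One-call study herd: panel, pedigree, cow genotypes, events, truth.

    Builds a crossbreeding plan sized so the offspring generations contain
    at least ``n_cows`` females, gene-drops genotypes, keeps the first
    ``n_cows`` offspring females as the phenotyped cow set (genotypes are
    subset to those cows), and simulates their longitudinal records with
    the requested age-8 additive/dominance variance ratios.
    """
    panel = simulate_breed_panel(
        n_breeds, n_variants, n_chromosomes, chrom_length, fst=fst, seed=seed
    )
    # default_plan yields 5*n_breeds matings over two generations;
    # ~half of offspring are female, so size matings with ~20% margin
    per_mating = max(4, int(np.ceil(2.4 * n_cows / (5 * n_breeds))))
    plan = default_plan(panel.breeds, offspring_per_mating=per_mating)
    pedigree = simulate_pedigree(plan, n_founders_per_breed=n_founders_per_breed, seed=seed + 1)
    genotypes = drop_genotypes(pedigree, panel, seed=seed + 2)

    tab = pedigree.table
    offspring_females = tab.loc[
        (tab["sex"] == "F") & (tab["sire_id"] != ""), "animal_id"
    ].to_numpy()
    if len(offspring_females) < n_cows:
        raise ValueError(
            f"plan produced only {len(offspring_females)} cows, need {n_cows}"
        )
    cows = offspring_females[:n_cows]
    cow_geno = genotypes.subset(
        animal_mask=np.isin(genotypes.animal_ids, cows)
    )
    params = make_true_params(
        ratio_a8, ratio_d8, total_var_age8=total_var_age8, order=order, **param_kwargs
    )
    events, truth = simulate_events(
        pedigree, cow_geno, params, mode=mode, seed=seed + 3,
        causal_fraction=causal_fraction, cow_ids=cows,
    )
    return dict(
        panel=panel,
        pedigree=pedigree,
        genotypes=cow_geno,
        all_genotypes=genotypes,
        params=params,
        events=events,
        truth=truth,
        cows=cows,
    )
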