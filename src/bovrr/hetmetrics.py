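"""Pedigree and genomic heterosis indicators and merit-group summaries.

Covers expected retained heterozygosity from breed compositions
(``pHet = 1 - sum_b sire_b * dam_b`` over base breeds, composites
decomposed and Angus/Red Angus merged), genomic heterozygosity (fraction
of heterozygous calls), genomic inbreeding (G diagonal minus 1, from
``relmat``), and consecutive-scan detection of runs of homozygosity
(ROH, minimum span 1 Mb) and heterozygosity-rich regions (HRR, minimum
span 100 kb).  Cows are grouped into halves and quadrants by projected
total merit, and the indicators are regressed on / summarized by group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .relmat import GenotypeMatrix
from .simdata import decompose_composition

__all__ = [
    "pedigree_retained_heterozygosity",
    "genomic_heterozygosity",
    "detect_roh",
    "detect_hrr",
    "group_cows",
    "regress_metrics",
    "summarize_groups",
    "segments_to_bed",
    "heterosis_profile",
]

#: breeds treated as one population for retained-heterozygosity purposes
MERGED_BREEDS = {"Red Angus": "Angus"}


def _base_composition(comp: dict[str, float]) -> dict[str, float]:
    out: dict[str, float] = {}
    for breed, frac in decompose_composition(comp).items():
        b = MERGED_BREEDS.get(breed, breed)
        out[b] = out.get(b, 0.0) + frac
    return out


def pedigree_retained_heterozygosity(
    sire_comp: dict[str, float], dam_comp: dict[str, float]
) -> float:
    """Expected fraction of F1 heterozygosity: 1 - sum_b s_b * d_b.

    Compositions are decomposed to base breeds first; a purebred x same
    purebred mating gives 0, disjoint purebreds give 1.
    """
    s = _base_composition(sire_comp)
    d = _base_composition(dam_comp)
    for label, comp in (("sire", s), ("dam", d)):
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{label} composition sums to {total}")
    shared = set(s) & set(d)
    return 1.0 - sum(s[b] * d[b] for b in shared)


def genomic_heterozygosity(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-animal fraction of heterozygous calls among non-missing calls."""
    calls = genotypes.calls
    n_obs = (calls >= 0).sum(axis=1)
    if np.any(n_obs == 0):
        raise ValueError("animal with zero non-missing calls")
    return (calls == 1).sum(axis=1) / n_obs


@dataclass
class RunParams:
    """Consecutive-scan run parameters (shared by ROH and HRR)."""

    min_length_bp: int
    min_snp: int
    max_gap_bp: int = 1_000_000
    max_opposite: int = 0  # interrupting calls of the opposite state
    max_miss: int = 1


ROH_DEFAULTS = RunParams(min_length_bp=1_000_000, min_snp=15)
HRR_DEFAULTS = RunParams(min_length_bp=100_000, min_snp=3, max_opposite=0, max_miss=1)

SEGMENT_COLUMNS = ["animal_id", "chrom", "start", "end", "n_snp"]


def _scan_runs(
    calls_row: np.ndarray, pos: np.ndarray, in_state, params: RunParams
) -> list[tuple[int, int, int]]:
    """Maximal qualifying runs of ``in_state`` calls along one chromosome.

    A run extends over consecutive variants while calls are in-state,
    tolerating up to ``max_opposite`` opposite-state calls and
    ``max_miss`` missing calls, with inter-variant gaps at most
    ``max_gap_bp``.  Runs are trimmed to start and end on in-state calls
    and emitted when span (end - start) >= min_length_bp and the in-state
    count >= min_snp.
    """
    segments: list[tuple[int, int, int]] = []
    m = len(pos)
    i = 0
    while i < m:
        if not in_state(calls_row[i]):
            i += 1
            continue
        # start a candidate run at i
        n_opp = 0
        n_miss = 0
        last_in = i
        count_in = 1
        j = i + 1
        while j < m:
            if pos[j] - pos[j - 1] > params.max_gap_bp:
                break
            c = calls_row[j]
            if in_state(c):
                count_in += 1
                last_in = j
            elif c < 0:
                n_miss += 1
                if n_miss > params.max_miss:
                    break
            else:
                n_opp += 1
                if n_opp > params.max_opposite:
                    break
            j += 1
        span = int(pos[last_in] - pos[i])
        if span >= params.min_length_bp and count_in >= params.min_snp:
            segments.append((int(pos[i]), int(pos[last_in]), count_in))
        i = last_in + 1
    return segments


def _detect_runs(
    genotypes: GenotypeMatrix, in_state, params: RunParams
) -> tuple[pd.DataFrame, np.ndarray]:
    chrom = genotypes.variants["chrom"].to_numpy()
    pos = genotypes.variants["pos"].to_numpy()
    chrom_list = list(dict.fromkeys(chrom))
    slices = {}
    for c in chrom_list:
        idx = np.flatnonzero(chrom == c)
        if np.any(np.diff(pos[idx]) < 0):
            raise ValueError(f"positions not sorted on chromosome {c}")
        slices[c] = idx
    rows = []
    totals = np.zeros(genotypes.n_animals, dtype=np.int64)
    for i, aid in enumerate(genotypes.animal_ids):
        for c in chrom_list:
            idx = slices[c]
            for start, end, n_snp in _scan_runs(
                genotypes.calls[i, idx], pos[idx], in_state, params
            ):
                rows.append(dict(animal_id=aid, chrom=c, start=start, end=end, n_snp=n_snp))
                totals[i] += end - start
    segs = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return segs, totals


def detect_roh(
    genotypes: GenotypeMatrix,
    min_length_bp: int = 1_000_000,
    min_snp: int = 15,
    max_gap_bp: int = 1_000_000,
    max_het: int = 0,
    max_miss: int = 1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Runs of homozygosity by the consecutive method.

    Returns (segments, per-animal total bases); span is end - start over
    1-based variant positions.
    """
    params = RunParams(min_length_bp, min_snp, max_gap_bp, max_het, max_miss)
    return _detect_runs(genotypes, lambda c: c == 0 or c == 2, params)


def detect_hrr(
    genotypes: GenotypeMatrix,
    min_length_bp: int = 100_000,
    min_snp: int = 3,
    max_gap_bp: int = 1_000_000,
    max_hom: int = 0,
    max_miss: int = 1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Heterozygosity-rich regions: the same scan with het as run state."""
    params = RunParams(min_length_bp, min_snp, max_gap_bp, max_hom, max_miss)
    return _detect_runs(genotypes, lambda c: c == 1, params)


def segments_to_bed(segments: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based inclusive segments to BED (0-based, half-open)."""
    bed = segments[["chrom", "start", "end", "animal_id"]].copy()
    bed["start"] = bed["start"] - 1  # BED start is 0-based
    return bed


def heterosis_profile(
    genotypes: GenotypeMatrix,
    Fg: np.ndarray,
    pedigree=None,
    roh_params: dict | None = None,
    hrr_params: dict | None = None,
) -> pd.DataFrame:
    """Per-animal pHet (if pedigree given), gHet, Fg, HRR and ROH bases."""
    ghet = genomic_heterozygosity(genotypes)
    _, roh = detect_roh(genotypes, **(roh_params or {}))
    _, hrr = detect_hrr(genotypes, **(hrr_params or {}))
    out = pd.DataFrame(
        {
            "animal_id": genotypes.animal_ids,
            "gHet": ghet,
            "Fg": np.asarray(Fg, dtype=float),
            "HRR_bases": hrr,
            "ROH_bases": roh,
        }
    )
    if pedigree is not None:
        table = pedigree.table.set_index("animal_id")
        phet = []
        for aid in genotypes.animal_ids:
            sire = table.loc[aid, "sire_id"]
            dam = table.loc[aid, "dam_id"]
            if sire and dam:
                phet.append(
                    pedigree_retained_heterozygosity(
                        pedigree.composition[sire], pedigree.composition[dam]
                    )
                )
            else:
                phet.append(np.nan)
        out.insert(1, "pHet", phet)
    return out


def group_cows(proj_cw: pd.DataFrame, proj_wtw: pd.DataFrame) -> pd.DataFrame:
    """Halves and quadrants by mean total merit for each trait.

    Quadrants follow low/high CW x low/high WtW: LL, LH (low CW, high
    WtW), HH, HL.  Ties at a mean go to the Low half.
    """
    cw = proj_cw.set_index("animal_id")["total"]
    wtw = proj_wtw.set_index("animal_id")["total"]
    common = cw.index.intersection(wtw.index)
    if len(common) == 0:
        raise ValueError("no cows shared between the two projections")
    cw = cw.loc[common]
    wtw = wtw.loc[common]
    high_cw = cw > cw.mean()
    high_wtw = wtw > wtw.mean()
    quad = np.where(
        high_cw, np.where(high_wtw, "HH", "HL"), np.where(high_wtw, "LH", "LL")
    )
    return pd.DataFrame(
        {
            "animal_id": common,
            "cw_half": np.where(high_cw, "High", "Low"),
            "wtw_half": np.where(high_wtw, "High", "Low"),
            "quadrant": quad,
        }
    )


def regress_metrics(
    projections: dict[str, pd.DataFrame],
    profile: pd.DataFrame,
    metrics: tuple[str, ...] = ("pHet", "gHet", "Fg", "HRR_bases", "ROH_bases"),
) -> pd.DataFrame:
    """R^2 x 100 of dominance and total projected effects on each metric.

    ``projections`` maps trait tag -> per-animal projection frame with
    columns u_d and total.  Zero-variance metrics yield missing R^2.
    """
    prof = profile.set_index("animal_id")
    rows = []
    for trait, proj in projections.items():
        p = proj.set_index("animal_id")
        common = prof.index.intersection(p.index)
        if len(common) < 3:
            raise ValueError("need at least 3 cows for regression")
        for effect, col in (("dominance", "u_d"), ("total", "total")):
            yv = p.loc[common, col].to_numpy(dtype=float)
            for metric in metrics:
                if metric not in prof.columns:
                    continue
                xv = prof.loc[common, metric].to_numpy(dtype=float)
                ok = ~np.isnan(xv)
                if xv[ok].std() == 0:
                    r2 = np.nan
                else:
                    res = stats.linregress(xv[ok], yv[ok])
                    r2 = 100.0 * res.rvalue**2
                rows.append(dict(trait=trait, effect=effect, metric=metric, r2_pct=r2))
    return pd.DataFrame(rows)


def summarize_groups(
    profile: pd.DataFrame,
    groups: pd.DataFrame,
    metrics: tuple[str, ...] = ("pHet", "gHet", "Fg", "HRR_bases", "ROH_bases"),
) -> pd.DataFrame:
    """Mean (SE = SD/sqrt(n)) of each indicator for All/halves/quadrants."""
    merged = groups.merge(profile, on="animal_id", how="inner")
    if merged.empty:
        raise ValueError("no overlap between groups and profile")

    def labels(row):
        yield "All"
        yield f"{row.cw_half} CW"
        yield f"{row.wtw_half} WtW"
        yield row.quadrant

    group_order = ["All", "Low CW", "High CW", "Low WtW", "High WtW", "LL", "LH", "HH", "HL"]
    rows = []
    for gname in group_order:
        if gname == "All":
            sub = merged
        elif gname.endswith("CW"):
            sub = merged[merged["cw_half"] == gname.split()[0]]
        elif gname.endswith("WtW"):
            sub = merged[merged["wtw_half"] == gname.split()[0]]
        else:
            sub = merged[merged["quadrant"] == gname]
        if sub.empty:
            continue
        row = {"group": gname, "n": len(sub)}
        for metric in metrics:
            if metric not in sub.columns:
                continue
            vals = sub[metric].dropna().to_numpy(dtype=float)
            row[f"{metric}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{metric}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
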