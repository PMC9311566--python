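"""Heterosis indicators: retained heterozygosity, genomic heterozygosity,
ROH/HRR detection (with an exhaustive-window oracle), merit groups,
regressions and summaries."""

import numpy as np
import pandas as pd
import pytest

from bovrr import hetmetrics as hm
from tests.conftest import genotypes_from_calls


class TestRetainedHeterozygosity:
    def test_f1_of_disjoint_purebreds(self):
        assert hm.pedigree_retained_heterozygosity(
            {"Angus": 1.0}, {"Hereford": 1.0}
        ) == pytest.approx(1.0)

    def test_purebred_mating(self):
        assert hm.pedigree_retained_heterozygosity(
            {"Angus": 1.0}, {"Angus": 1.0}
        ) == pytest.approx(0.0)

    def test_brangus_by_brangus(self):
        brangus = {"Brahman": 0.375, "Angus": 0.625}
        assert hm.pedigree_retained_heterozygosity(brangus, brangus) == pytest.approx(
            0.46875
        )

    def test_composite_labels_are_decomposed(self):
        assert hm.pedigree_retained_heterozygosity(
            {"Brangus": 1.0}, {"Brangus": 1.0}
        ) == pytest.approx(0.46875)

    def test_red_angus_merged_with_angus(self):
        assert hm.pedigree_retained_heterozygosity(
            {"Angus": 1.0}, {"Red Angus": 1.0}
        ) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        breeds = ["A", "B", "C", "D"]
        s = rng.dirichlet(np.ones(4))
        d = rng.dirichlet(np.ones(4))
        sc = dict(zip(breeds, s))
        dc = dict(zip(breeds, d))
        ab = hm.pedigree_retained_heterozygosity(sc, dc)
        ba = hm.pedigree_retained_heterozygosity(dc, sc)
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab <= 1.0

    def test_bad_composition_rejected(self):
        with pytest.raises(ValueError):
            hm.pedigree_retained_heterozygosity({"A": 0.7}, {"A": 1.0})


class TestGenomicHeterozygosity:
    def test_simple_count(self):
        g = genotypes_from_calls([[0, 1, 1, 2]])
        assert hm.genomic_heterozygosity(g)[0] == pytest.approx(0.5)

    def test_all_homozygous(self):
        g = genotypes_from_calls([[0, 2, 0, 2]])
        assert hm.genomic_heterozygosity(g)[0] == 0.0

    def test_missing_excluded_from_denominator(self):
        g = genotypes_from_calls([[1, -1, 1]])
        assert hm.genomic_heterozygosity(g)[0] == pytest.approx(1.0)

    def test_het_plus_hom_fraction_is_one_without_missing(self, small_herd):
        g = small_herd["genotypes"]
        ghet = hm.genomic_heterozygosity(g)
        hom = ((g.calls == 0) | (g.calls == 2)).mean(axis=1)
        np.testing.assert_allclose(ghet + hom, 1.0)


class TestROH:
    def test_twenty_variant_run_span(self):
        pos = 1_000_000 + 100_000 * np.arange(20)
        g = genotypes_from_calls([np.full(20, 2)], positions=pos)
        segs, total = hm.detect_roh(g)
        assert len(segs) == 1
        seg = segs.iloc[0]
        assert seg["start"] == 1_000_000 and seg["end"] == 2_900_000
        assert seg["n_snp"] == 20
        assert total[0] == 1_900_000

    def test_heterozygous_animal_has_no_roh(self):
        pos = 1_000_000 + 100_000 * np.arange(20)
        g = genotypes_from_calls([np.ones(20)], positions=pos)
        _, total = hm.detect_roh(g)
        assert total[0] == 0

    def test_run_below_one_megabase_rejected(self):
        pos = 1_000_000 + 40_000 * np.arange(21)  # span 0.8 Mb
        g = genotypes_from_calls([np.full(21, 0)], positions=pos)
        segs, total = hm.detect_roh(g)
        assert segs.empty and total[0] == 0


class TestHRR:
    def test_five_het_variants_spanning_150kb(self):
        pos = 1_000_000 + 37_500 * np.arange(5)  # span exactly 150 kb
        g = genotypes_from_calls([np.ones(5)], positions=pos)
        segs, total = hm.detect_hrr(g)
        assert len(segs) == 1
        assert total[0] == 150_000

    def test_all_homozygous_has_no_hrr(self):
        pos = 1_000_000 + 50_000 * np.arange(5)
        g = genotypes_from_calls([np.full(5, 2)], positions=pos)
        _, total = hm.detect_hrr(g)
        assert total[0] == 0

    def test_span_below_100kb_rejected(self):
        pos = 1_000_000 + 30_000 * np.arange(4)  # span 90 kb
        g = genotypes_from_calls([np.ones(4)], positions=pos)
        segs, total = hm.detect_hrr(g)
        assert segs.empty and total[0] == 0


def enumerate_runs_oracle(calls, pos, in_state, min_length, min_snp, max_gap,
                          max_opposite, max_miss):
    """Exhaustive-window oracle for the consecutive method.

    A window [i, j] qualifies when: both endpoints are in-state, every
    inter-variant gap inside is <= max_gap, and the counts of
    opposite-state / missing calls inside are within their limits.  For
    each admissible start (scanned left to right, resuming after the
    previous candidate's end) the maximal such window is found by brute
    force, and emitted if span and count minima hold.
    """

    def window_valid(i, j):
        if not (in_state(calls[i]) and in_state(calls[j])):
            return False
        n_opp = n_miss = 0
        for k in range(i, j + 1):
            if k > i and pos[k] - pos[k - 1] > max_gap:
                return False
            c = calls[k]
            if in_state(c):
                continue
            if c < 0:
                n_miss += 1
            else:
                n_opp += 1
        return n_opp <= max_opposite and n_miss <= max_miss

    out = []
    m = len(pos)
    i = 0
    while i < m:
        if not in_state(calls[i]):
            i += 1
            continue
        best_j = max(
            (j for j in range(i, m) if window_valid(i, j)), default=None
        )
        count = sum(1 for k in range(i, best_j + 1) if in_state(calls[k]))
        span = pos[best_j] - pos[i]
        if span >= min_length and count >= min_snp:
            out.append((int(pos[i]), int(pos[best_j]), count))
        i = best_j + 1
    return out


class TestRunOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_roh_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m = 50
        pos = np.sort(rng.choice(np.arange(1, 8_000_000, 1000), m, replace=False))
        calls = rng.choice([0, 1, 2, -1], size=m, p=[0.42, 0.12, 0.42, 0.04])
        g = genotypes_from_calls([calls], positions=pos)
        kw = dict(min_length_bp=500_000, min_snp=5, max_gap_bp=1_000_000, max_miss=1)
        segs, _ = hm.detect_roh(g, max_het=0, **kw)
        oracle = enumerate_runs_oracle(
            calls, pos, lambda c: c == 0 or c == 2,
            kw["min_length_bp"], kw["min_snp"], kw["max_gap_bp"], 0, kw["max_miss"],
        )
        got = [tuple(r) for r in segs[["start", "end", "n_snp"]].to_numpy()]
        assert got == oracle

    @pytest.mark.parametrize("seed", range(6))
    def test_hrr_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = 40
        pos = np.sort(rng.choice(np.arange(1, 3_000_000, 500), m, replace=False))
        calls = rng.choice([0, 1, 2, -1], size=m, p=[0.25, 0.45, 0.25, 0.05])
        g = genotypes_from_calls([calls], positions=pos)
        kw = dict(min_length_bp=100_000, min_snp=3, max_gap_bp=1_000_000, max_miss=1)
        segs, _ = hm.detect_hrr(g, max_hom=0, **kw)
        oracle = enumerate_runs_oracle(
            calls, pos, lambda c: c == 1,
            kw["min_length_bp"], kw["min_snp"], kw["max_gap_bp"], 0, kw["max_miss"],
        )
        got = [tuple(r) for r in segs[["start", "end", "n_snp"]].to_numpy()]
        assert got == oracle

    def test_segments_never_overlap(self, small_herd):
        segs, _ = hm.detect_roh(small_herd["genotypes"], min_length_bp=200_000, min_snp=4)
        for (_, _), sub in segs.groupby(["animal_id", "chrom"]):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] > sub["end"].to_numpy()[:-1]).all()


class TestMeritGroups:
    def _proj(self, ids, totals):
        return pd.DataFrame({"animal_id": ids, "total": totals})

    def test_quadrant_labels(self):
        ids = ["a", "b", "c", "d"]
        cw = self._proj(ids, [10.0, 10.0, -10.0, -10.0])
        wtw = self._proj(ids, [10.0, -10.0, 10.0, -10.0])
        groups = hm.group_cows(cw, wtw).set_index("animal_id")
        assert groups.loc["a", "quadrant"] == "HH"
        assert groups.loc["b", "quadrant"] == "HL"
        assert groups.loc["c", "quadrant"] == "LH"
        assert groups.loc["d", "quadrant"] == "LL"

    def test_ties_go_to_low_half(self):
        ids = ["a", "b"]
        groups = hm.group_cows(
            self._proj(ids, [5.0, 5.0]), self._proj(ids, [1.0, 1.0])
        )
        assert (groups["cw_half"] == "Low").all()
        assert (groups["quadrant"] == "LL").all()

    def test_symmetric_pair_split(self):
        ids = ["a", "b"]
        groups = hm.group_cows(
            self._proj(ids, [3.0, -3.0]), self._proj(ids, [0.0, 0.0])
        ).set_index("animal_id")
        assert groups.loc["a", "cw_half"] == "High"
        assert groups.loc["b", "cw_half"] == "Low"


class TestRegressMetrics:
    def _profile(self, ids, metric):
        return pd.DataFrame({"animal_id": ids, "pHet": metric})

    def test_perfect_fit_gives_r2_100(self):
        ids = [f"c{i}" for i in range(10)]
        vals = np.linspace(0, 1, 10)
        proj = pd.DataFrame({"animal_id": ids, "u_d": vals, "total": vals})
        out = hm.regress_metrics({"CW": proj}, self._profile(ids, vals), metrics=("pHet",))
        assert np.allclose(out["r2_pct"], 100.0)

    def test_independent_noise_gives_near_zero_r2(self):
        rng = np.random.default_rng(4)
        ids = [f"c{i}" for i in range(2000)]
        proj = pd.DataFrame(
            {"animal_id": ids, "u_d": rng.standard_normal(2000),
             "total": rng.standard_normal(2000)}
        )
        out = hm.regress_metrics(
            {"CW": proj}, self._profile(ids, rng.standard_normal(2000)), metrics=("pHet",)
        )
        assert (out["r2_pct"] < 1.0).all()

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        ids = [f"c{i}" for i in range(50)]
        metric = rng.standard_normal(50)
        y = 2 * metric + rng.standard_normal(50)
        proj = pd.DataFrame({"animal_id": ids, "u_d": y, "total": y})
        r1 = hm.regress_metrics({"CW": proj}, self._profile(ids, metric), metrics=("pHet",))
        r2 = hm.regress_metrics(
            {"CW": proj}, self._profile(ids, 100.0 * metric - 7.0), metrics=("pHet",)
        )
        np.testing.assert_allclose(r1["r2_pct"], r2["r2_pct"], atol=1e-9)

    def test_zero_variance_metric_reported_missing(self):
        ids = [f"c{i}" for i in range(5)]
        proj = pd.DataFrame(
            {"animal_id": ids, "u_d": np.arange(5.0), "total": np.arange(5.0)}
        )
        out = hm.regress_metrics({"CW": proj}, self._profile(ids, np.ones(5)), metrics=("pHet",))
        assert out["r2_pct"].isna().all()


class TestSummaries:
    def _setup(self):
        ids = [f"c{i}" for i in range(8)]
        rng = np.random.default_rng(6)
        profile = pd.DataFrame(
            {"animal_id": ids, "pHet": rng.uniform(0, 1, 8),
             "gHet": rng.uniform(0.2, 0.4, 8)}
        )
        cw = pd.DataFrame({"animal_id": ids, "total": rng.standard_normal(8)})
        wtw = pd.DataFrame({"animal_id": ids, "total": rng.standard_normal(8)})
        groups = hm.group_cows(cw, wtw)
        return profile, groups

    def test_all_group_mean_is_weighted_half_mean(self):
        profile, groups = self._setup()
        summ = hm.summarize_groups(profile, groups, metrics=("pHet",)).set_index("group")
        lo = summ.loc["Low CW"]
        hi = summ.loc["High CW"]
        weighted = (lo["pHet_mean"] * lo["n"] + hi["pHet_mean"] * hi["n"]) / (
            lo["n"] + hi["n"]
        )
        assert summ.loc["All", "pHet_mean"] == pytest.approx(weighted)

    def test_singleton_group_se_missing(self):
        profile = pd.DataFrame({"animal_id": ["a", "b"], "pHet": [0.1, 0.9]})
        groups = pd.DataFrame(
            {"animal_id": ["a", "b"], "cw_half": ["Low", "High"],
             "wtw_half": ["Low", "High"], "quadrant": ["LL", "HH"]}
        )
        summ = hm.summarize_groups(profile, groups, metrics=("pHet",)).set_index("group")
        assert np.isnan(summ.loc["LL", "pHet_se"])
        assert not np.isnan(summ.loc["All", "pHet_se"])
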