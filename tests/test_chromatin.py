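"""RiP normalisation, correlation, and the KS-gated rank testing scheme."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ernascope.chromatin import (
    correlate_changes,
    differential_features,
    peak_union,
    rip_factors,
    stratified_tests,
)
from ernascope.diffexp import SizeFactors

from conftest import random_peaks


def _frags(rows):
    return pd.DataFrame(
        [{"chrom": c, "start": s, "end": e, "name": ".", "mapq": 60, "strand": "."}
         for c, s, e in rows]
    )


class TestPeakUnion:
    def test_single_set_is_merged_self(self):
        df = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 50], "end": [100, 150]})
        out = peak_union([df])
        assert out.values.tolist() == [["chr1", 0, 150]]

    def test_union_across_replicates_and_conditions(self, rng):
        sets = [random_peaks(rng, 50, max_pos=3000) for _ in range(4)]
        out = peak_union(sets)
        covered = set()
        for df in sets:
            for _, r in df.iterrows():
                covered.update((r["chrom"], p) for p in range(r["start"], r["end"]))
        got = set()
        for _, r in out.iterrows():
            got.update((r["chrom"], p) for p in range(r["start"], r["end"]))
        assert got == covered


UNION = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [2000]})


class TestRiPFactors:
    def test_identical_samples_unit_factors(self):
        f = _frags([("chr1", 1100, 1300)] * 5 + [("chr2", 0, 200)] * 5)
        rf = rip_factors({"a": f, "b": f.copy()}, UNION)
        assert (rf.size_factor == 1.0).all()

    def test_stated_arithmetic_rule(self):
        """rip (0.10, 0.20) -> scaled (1, 2) -> size factors (1, 0.5)."""
        a = _frags([("chr1", 1100, 1300)] * 1 + [("chr2", 0, 200)] * 9)
        b = _frags([("chr1", 1100, 1300)] * 2 + [("chr2", 0, 200)] * 8)
        rf = rip_factors({"a": a, "b": b}, UNION)
        assert rf.rip.tolist() == [0.1, 0.2]
        assert rf.scaled_rip.tolist() == [1.0, 2.0]
        assert rf.size_factor.tolist() == [1.0, 0.5]
        assert rf.size_factor[rf.rip.idxmin()] == 1.0
        assert (rf.size_factor <= 1.0).all()

    def test_background_downsampling_raises_rip_lowers_factor(self):
        base = [("chr1", 1100, 1300)] * 4
        noisy = _frags(base + [("chr2", 0, 200)] * 16)     # rip 0.2
        cleaned = _frags(base + [("chr2", 0, 200)] * 6)    # rip 0.4
        other = _frags(base + [("chr2", 0, 200)] * 36)     # rip 0.1 (anchor)
        rf_noisy = rip_factors({"x": noisy, "ref": other}, UNION)
        rf_clean = rip_factors({"x": cleaned, "ref": other}, UNION)
        assert rf_clean.rip["x"] > rf_noisy.rip["x"]
        assert rf_clean.size_factor["x"] < rf_noisy.size_factor["x"]

    def test_invariance_under_proportional_library_growth(self):
        """Scaling every sample's fragments (in and out of union) by a common
        factor leaves the RiP ratios, hence all size factors, unchanged."""
        a = _frags([("chr1", 1100, 1300)] * 2 + [("chr2", 0, 200)] * 8)
        b = _frags([("chr1", 1100, 1300)] * 4 + [("chr2", 0, 200)] * 6)
        before = rip_factors({"a": a, "b": b}, UNION)
        a3 = pd.concat([a] * 3, ignore_index=True)
        b3 = pd.concat([b] * 3, ignore_index=True)
        after = rip_factors({"a": a3, "b": b3}, UNION)
        pd.testing.assert_series_equal(before.size_factor, after.size_factor)

    def test_equal_proportion_in_union_addition_preserves_anchor(self):
        """Adding in-union fragments worth the same fraction of each library
        moves every RiP by the same monotone map, so the sample anchoring the
        scaling (the minimum) and the factor ordering are preserved."""
        a = _frags([("chr1", 1100, 1300)] * 2 + [("chr2", 0, 200)] * 18)  # rip 0.1
        b = _frags([("chr1", 1100, 1300)] * 8 + [("chr2", 0, 200)] * 12)  # rip 0.4
        before = rip_factors({"a": a, "b": b}, UNION)
        # +25% of each library, all inside the union
        a2 = pd.concat([a, _frags([("chr1", 1100, 1300)] * 5)], ignore_index=True)
        b2 = pd.concat([b, _frags([("chr1", 1100, 1300)] * 5)], ignore_index=True)
        after = rip_factors({"a": a2, "b": b2}, UNION)
        for rf in (before, after):
            assert rf.rip.idxmin() == "a"
            assert rf.size_factor["a"] == 1.0
        assert np.allclose(after.rip, (before.rip + 0.25) / 1.25)

    def test_zero_reads_in_peaks_rejected(self):
        f = _frags([("chr2", 0, 200)] * 5)
        with pytest.raises(ValueError, match="zero reads in peaks"):
            rip_factors({"a": f}, UNION)


class TestCorrelateChanges:
    def test_identity_and_monotone_transforms(self):
        x = np.linspace(-2, 2, 50)
        table = pd.DataFrame({"a_log2fc": x, "b_log2fc": x, "c_log2fc": -(x ** 3)})
        out = correlate_changes(table)
        assert out.loc["a_log2fc", "b_log2fc"] == pytest.approx(1.0)
        assert out.loc["a_log2fc", "c_log2fc"] == pytest.approx(-1.0)
        assert np.allclose(out, out.T, equal_nan=True)
        assert np.allclose(np.diag(out), 1.0)

    def test_constant_column_yields_nan(self):
        table = pd.DataFrame({"a_log2fc": [1.0, 2.0, 3.0], "b_log2fc": [5.0, 5.0, 5.0]})
        out = correlate_changes(table)
        assert np.isnan(out.loc["a_log2fc", "b_log2fc"])
        assert np.isnan(out.loc["b_log2fc", "b_log2fc"])

    def test_matches_rank_then_pearson_oracle_with_ties(self, rng):
        x = rng.integers(0, 10, 50).astype(float)  # heavy ties
        y = rng.integers(0, 10, 50).astype(float)
        table = pd.DataFrame({"x_log2fc": x, "y_log2fc": y})
        out = correlate_changes(table)

        def avg_rank(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            sv = v[order]
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        expected = np.corrcoef(avg_rank(x), avg_rank(y))[0, 1]
        assert out.loc["x_log2fc", "y_log2fc"] == pytest.approx(expected)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            correlate_changes(pd.DataFrame({"a_log2fc": [1.0, 2.0]}))


class TestStratifiedTests:
    def _table(self, induced, unchanged, repressed=()):
        rows = [{"erna_group": "induced", "X_log2fc": v} for v in induced]
        rows += [{"erna_group": "unchanged", "X_log2fc": v} for v in unchanged]
        rows += [{"erna_group": "repressed", "X_log2fc": v} for v in repressed]
        return pd.DataFrame(rows)

    def test_identical_groups_keep_gate_closed(self):
        vals = list(np.linspace(0, 1, 40))
        out = stratified_tests(self._table(vals, vals))
        row = out.iloc[0]
        assert not row["gate_open"]
        assert np.isnan(row["wmw_pvalue"])

    def test_shifted_group_opens_gate_strongly(self):
        rng = np.random.default_rng(3)
        unchanged = rng.normal(0, 1, 50)
        induced = rng.normal(2, 1, 50)  # +2 sigma shift
        out = stratified_tests(self._table(induced, unchanged))
        row = out[out["group"] == "induced"].iloc[0]
        assert row["gate_open"]
        assert row["wmw_pvalue"] < 1e-3
        assert row["stars"] in ("**", "***")

    def test_wmw_matches_exhaustive_enumeration(self):
        """3-vs-3 toy, no ties: p equals the exact permutation null of U."""
        induced = [1.0, 4.0, 6.0]
        unchanged = [2.0, 3.0, 5.0]
        out = stratified_tests(self._table(induced, unchanged), gate_alpha=1.1)
        got = out.iloc[0]["wmw_pvalue"]
        pooled = induced + unchanged
        u_obs = sum(1 for a in induced for b in unchanged if a > b)
        m = len(induced)
        us = []
        for combo in itertools.combinations(range(6), m):
            grp = [pooled[i] for i in combo]
            rest = [pooled[i] for i in range(6) if i not in combo]
            us.append(sum(1 for a in grp for b in rest if a > b))
        exact = np.mean([abs(u - 4.5) >= abs(u_obs - 4.5) for u in us])
        exact_test = stats.mannwhitneyu(induced, unchanged, alternative="two-sided",
                                        method="exact").pvalue
        assert exact == pytest.approx(exact_test)
        # small tie-free groups use the exact null, so equality holds
        assert got == pytest.approx(exact)

    def test_small_group_reports_nan(self):
        out = stratified_tests(self._table([1.0], np.linspace(0, 1, 10)))
        assert np.isnan(out.iloc[0]["ks_pvalue"])


class TestDifferentialFeatures:
    def test_requires_two_replicates_per_condition(self, rng):
        counts = pd.DataFrame(rng.integers(10, 100, (5, 3)),
                              index=[f"s{i}" for i in range(5)],
                              columns=["c1", "c2", "t1"])
        with pytest.raises(ValueError, match="fewer than 2 replicates"):
            differential_features(
                {"X": counts},
                {"X": SizeFactors(pd.Series(1.0, index=counts.columns))},
                {"X": ["control", "control", "treated"]},
                pd.Series("unchanged", index=counts.index),
            )

    def test_recovers_feature_lfc_structure(self, default_experiment):
        """Assays simulated at high eRNA coupling recover correlated LFCs."""
        exp = default_experiment
        sites = exp.truth.sites.set_index("site_id")
        rep_a = sites[sites["reproducible_A"] & sites["tissues"].str.contains("A")]
        groups = rep_a.loc[rep_a["true_erna_A"], "reg_class"].replace({"none": None})
        counts = exp.counts["ATAC"]
        truth_rip = exp.truth.rip.query("assay == 'ATAC'").set_index("sample_id")
        factors = SizeFactors(truth_rip["true_size_factor"], "rip_reciprocal")
        table = differential_features(
            {"ATAC": counts}, {"ATAC": factors},
            {"ATAC": ["treated" if "treated" in c else "control" for c in counts.columns]},
            groups,
        )
        joined = table.join(rep_a["true_lfc_ATAC"])
        diff = joined[joined["erna_group"].isin(["induced", "repressed"])]
        rho = stats.spearmanr(diff["ATAC_log2fc"], diff["true_lfc_ATAC"]).statistic
        assert rho > 0.7
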