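import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmscreen.read_deconvolution import CountsMatrix
from dmscreen.selection_scoring import (
    SampleSheet,
    ScoringParams,
    call_hits,
    compute_fractions,
    filter_low_t0,
    nearest_rank_threshold,
    score_screen,
    survival_lfc,
    z_scores,
)


def counts_matrix(variant_counts: dict[str, dict[str, int]], wt: dict[str, int]):
    """Build a CountsMatrix from {sample: {variant: count}} plus WT counts."""
    variants = sorted({v for d in variant_counts.values() for v in d})
    mat = CountsMatrix.empty(variants, sorted(variant_counts))
    for s, d in variant_counts.items():
        for v, c in d.items():
            mat.counts.loc[v, s] = c
        mat.counts.loc["WT", s] = wt[s]
    return CountsMatrix(mat.counts, mat.counts.sum(axis=0))


def basic_sheet(conditions=("T0", "DMSO", "DNMDP100"), replicates=2):
    rows = [
        {"sample_id": f"{c}_r{r}", "condition": c, "replicate": r}
        for c in conditions
        for r in range(1, replicates + 1)
    ]
    return SampleSheet(pd.DataFrame(rows))


class TestFractions:
    def test_stated_formula(self):
        mat = counts_matrix({"s1": {"v": 10}}, wt={"s1": 990})
        f = compute_fractions(mat, pseudocount=0)
        assert f.loc["v", "s1"] == pytest.approx(0.01)

    def test_pseudocount_rescues_zero_counts(self):
        mat = counts_matrix({"s1": {"v": 0, "w": 1000}}, wt={"s1": 0})
        f = compute_fractions(mat, pseudocount=0.5)
        assert f.loc["v", "s1"] == pytest.approx(0.5 / 1000.5)

    def test_scale_invariance_without_pseudocount(self):
        raw = {"s1": {"v1": 10, "v2": 40}}
        a = compute_fractions(counts_matrix(raw, wt={"s1": 50}), pseudocount=0)
        scaled = {"s1": {"v1": 30, "v2": 120}}
        b = compute_fractions(counts_matrix(scaled, wt={"s1": 150}), pseudocount=0)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_assigned_reads_is_an_error(self):
        mat = counts_matrix({"s1": {"v": 0}}, wt={"s1": 0})
        with pytest.raises(ValueError, match="zero assigned"):
            compute_fractions(mat, pseudocount=0.5)


class TestLowT0Filter:
    def test_distinct_values_flag_exactly_nearest_rank_count(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.permutation(np.arange(1, 101, dtype=float)))
        flags = filter_low_t0(vals, ScoringParams(t0_percentile=8))
        assert flags.sum() == 8
        assert set(vals[flags]) == set(range(1, 9))

    def test_fifty_distinct_values_flag_four(self):
        vals = pd.Series(np.linspace(0.001, 0.05, 50))
        flags = filter_low_t0(vals, ScoringParams(t0_percentile=8))
        assert flags.sum() == 4

    def test_all_ties_flag_everything(self):
        vals = pd.Series([0.01] * 20)
        flags = filter_low_t0(vals, ScoringParams(t0_percentile=8))
        assert flags.all()

    @given(st.integers(1, 500), st.integers(0, 2**31 - 1))
    def test_nearest_rank_law_for_distinct_values(self, n, seed):
        rng = np.random.default_rng(seed)
        vals = pd.Series(rng.permutation(np.arange(n, dtype=float)))
        flags = filter_low_t0(vals, ScoringParams(t0_percentile=8))
        assert flags.sum() == int(np.ceil(0.08 * n))

    def test_threshold_is_smallest_value_covering_percentile(self):
        assert nearest_rank_threshold(pd.Series([5.0, 1.0, 3.0]), 50) == 3.0
        assert nearest_rank_threshold(pd.Series([5.0, 1.0, 3.0]), 34) == 3.0
        assert nearest_rank_threshold(pd.Series([5.0, 1.0, 3.0]), 33) == 1.0


class TestSurvivalLfc:
    def _fractions(self, data, samples):
        return pd.DataFrame(data, index=["v"], columns=samples)

    def test_doubling_under_treatment_gives_lfc_one(self):
        sheet = basic_sheet()
        fr = self._fractions(
            [[0.1, 0.1, 0.1, 0.1, 0.2, 0.2]],
            ["T0_r1", "T0_r2", "DMSO_r1", "DMSO_r2", "DNMDP100_r1", "DNMDP100_r2"],
        )
        lfc = survival_lfc(fr, sheet, "DNMDP100", "DMSO")
        assert lfc["v"] == pytest.approx(1.0)

    def test_everything_identical_to_t0_gives_zero(self):
        sheet = basic_sheet()
        fr = self._fractions(
            [[0.1] * 6],
            ["T0_r1", "T0_r2", "DMSO_r1", "DMSO_r2", "DNMDP100_r1", "DNMDP100_r2"],
        )
        assert survival_lfc(fr, sheet, "DNMDP100", "DMSO")["v"] == pytest.approx(0.0)

    def test_replicates_averaged_before_ratio(self):
        sheet = basic_sheet()
        fr = self._fractions(
            [[0.1, 0.1, 0.1, 0.1, 0.2, 0.4]],
            ["T0_r1", "T0_r2", "DMSO_r1", "DMSO_r2", "DNMDP100_r1", "DNMDP100_r2"],
        )
        # norms (2, 4) vs (1, 1): log2(3/1)
        lfc = survival_lfc(fr, sheet, "DNMDP100", "DMSO")
        assert lfc["v"] == pytest.approx(np.log2(3), abs=1e-12)

    def test_missing_condition_raises(self):
        sheet = basic_sheet(conditions=("T0", "DMSO"))
        fr = self._fractions([[0.1] * 4], ["T0_r1", "T0_r2", "DMSO_r1", "DMSO_r2"])
        with pytest.raises(ValueError, match="DNMDP100"):
            survival_lfc(fr, sheet, "DNMDP100", "DMSO")


class TestZScores:
    def test_unit_example(self):
        z = z_scores(pd.Series([-1.0, 0.0, 1.0]))
        assert list(z) == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_sd_is_an_error(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            z_scores(pd.Series([2.0, 2.0, 2.0]))

    @given(st.integers(0, 2**31 - 1), st.integers(2, 400))
    def test_standardization_moments(self, seed, n):
        rng = np.random.default_rng(seed)
        vals = pd.Series(rng.normal(size=n) * 3 + 1)
        if vals.std(ddof=1) == 0:
            return
        z = z_scores(vals)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestCallHits:
    def test_standard_normal_tail_fraction(self):
        rng = np.random.default_rng(123)
        lfc = pd.Series(rng.normal(size=10_000))
        hits = call_hits(lfc, ScoringParams())
        # mass above mean + 1 SD for a standard normal is ~0.159
        assert hits.mean() == pytest.approx(0.159, abs=0.02)

    def test_constant_vector_has_no_hits(self):
        assert not call_hits(pd.Series([0.5] * 10)).any()

    def test_hits_require_positive_lfc(self):
        # shift the whole distribution far negative: >1 SD but never >0
        rng = np.random.default_rng(1)
        lfc = pd.Series(rng.normal(loc=-10, scale=0.1, size=1000))
        assert not call_hits(lfc).any()


class TestScoreScreen:
    def _screen(self, rng, n_var=200, depth=100_000, lof_frac=0.1, scale=1):
        """Synthetic counts with a known enriched subset."""
        ids = [f"v{i}" for i in range(n_var)]
        lof = set(ids[: int(lof_frac * n_var)])
        t0 = rng.lognormal(0, 0.5, n_var)
        t0 /= t0.sum()
        post = np.where([i in lof for i in ids], t0, t0 * 0.05)
        post /= post.sum()
        samples, rows = {}, []
        for cond, p in (("T0", t0), ("DMSO", t0), ("DNMDP100", post)):
            for r in (1, 2):
                sid = f"{cond}_r{r}"
                samples[sid] = rng.multinomial(depth, p) * scale
                rows.append({"sample_id": sid, "condition": cond, "replicate": r})
        mat = CountsMatrix.empty(ids, list(samples))
        for sid, cnt in samples.items():
            mat.counts.loc[ids, sid] = cnt
        return (
            CountsMatrix(mat.counts, mat.counts.sum(axis=0)),
            SampleSheet(pd.DataFrame(rows)),
            lof,
        )

    def test_low_confidence_variants_carry_no_scores(self):
        rng = np.random.default_rng(7)
        mat, sheet, _ = self._screen(rng)
        table = score_screen(mat, sheet)
        low = table[table["low_confidence"]]
        assert len(low) > 0
        assert low["lfc_dnmdp100_vs_dmso"].isna().all()
        assert low["z"].isna().all()
        assert low["resistance_hit"].isna().all()

    def test_z_moments_over_retained_variants(self):
        rng = np.random.default_rng(8)
        mat, sheet, _ = self._screen(rng)
        table = score_screen(mat, sheet)
        z = table.loc[~table["low_confidence"], "z"]
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_enriched_subset_recovered_as_hits(self):
        rng = np.random.default_rng(9)
        mat, sheet, lof = self._screen(rng)
        table = score_screen(mat, sheet)
        called = set(table[table["resistance_hit"].fillna(False).astype(bool)].index)
        retained_lof = lof - set(table[table["low_confidence"]].index)
        assert len(called & retained_lof) / len(retained_lof) >= 0.9

    def test_scale_invariance_of_all_scores(self):
        rng = np.random.default_rng(10)
        mat, sheet, _ = self._screen(rng)
        params = ScoringParams(pseudocount=0.0)
        base = score_screen(mat, sheet, params)
        scaled_counts = mat.counts.copy()
        scaled_counts["DNMDP100_r1"] *= 7  # rescale one sample's depth
        mat2 = CountsMatrix(scaled_counts, scaled_counts.sum(axis=0))
        rescored = score_screen(mat2, sheet, params)
        pd.testing.assert_frame_equal(base, rescored)

    def test_identical_treatment_and_control_yield_no_hits(self):
        rng = np.random.default_rng(11)
        ids = [f"v{i}" for i in range(50)]
        t0 = rng.integers(50, 500, size=50)
        samples, rows = {}, []
        for cond in ("T0", "DMSO", "DNMDP100"):
            for r in (1, 2):
                sid = f"{cond}_r{r}"
                samples[sid] = t0  # same counts everywhere
                rows.append({"sample_id": sid, "condition": cond, "replicate": r})
        mat = CountsMatrix.empty(ids, list(samples))
        for sid, cnt in samples.items():
            mat.counts.loc[ids, sid] = cnt
        mat = CountsMatrix(mat.counts, mat.counts.sum(axis=0))
        table = score_screen(mat, SampleSheet(pd.DataFrame(rows)))
        retained = table[~table["low_confidence"]]
        assert retained["lfc_dnmdp100_vs_dmso"].abs().max() == pytest.approx(0.0)
        assert not retained["resistance_hit"].astype(bool).any()

    def test_monotonicity_in_own_treatment_count(self):
        rng = np.random.default_rng(12)
        mat, sheet, _ = self._screen(rng, n_var=50)
        base = score_screen(mat, sheet)
        bumped = mat.counts.copy()
        target = "v25"
        bumped.loc[target, ["DNMDP100_r1", "DNMDP100_r2"]] += 500
        mat2 = CountsMatrix(bumped, bumped.sum(axis=0))
        rescored = score_screen(mat2, sheet)
        if not base.loc[target, "low_confidence"]:
            assert (
                rescored.loc[target, "lfc_dnmdp100_vs_dmso"]
                >= base.loc[target, "lfc_dnmdp100_vs_dmso"]
            )

    def test_excluded_variants_never_become_hits(self):
        rng = np.random.default_rng(13)
        mat, sheet, lof = self._screen(rng)
        some_lof = sorted(lof)[:5]
        table = score_screen(mat, sheet, excluded_variants=set(some_lof))
        assert not table.loc[some_lof, "resistance_hit"].fillna(False).any()


class TestSampleSheet:
    def test_requires_t0_and_unique_ids(self):
        with pytest.raises(ValueError, match="T0"):
            SampleSheet(
                pd.DataFrame(
                    [{"sample_id": "a", "condition": "DMSO", "replicate": 1}]
                )
            )
        with pytest.raises(ValueError, match="duplicate"):
            SampleSheet(
                pd.DataFrame(
                    [
                        {"sample_id": "a", "condition": "T0", "replicate": 1},
                        {"sample_id": "a", "condition": "T0", "replicate": 2},
                    ]
                )
            )

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SampleSheet(
                pd.DataFrame(
                    [{"sample_id": "a", "condition": "DRUGX", "replicate": 1}]
                )
            )
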