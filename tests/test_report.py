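"""Panel filtering, mutation loads, association tests, motif mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from uvhotspots.core import GenomicInterval
from uvhotspots.report import (
    PanelCall,
    SampleLoad,
    association_tests,
    compute_loads,
    filter_panel_calls,
    map_snvs_to_motif,
    regress_loads,
    sample_exclusion,
    test_expression_by_mutation as expression_by_mutation,
)

from conftest import make_cohort


def call(depths_afs, whitelisted=True, sample="s1", pos=100):
    return PanelCall(sample, "1", pos, "C", "T", tuple(depths_afs), in_whitelist=whitelisted)


class TestFilterPanelCalls:
    def test_duplicate_deep_whitelisted_retained(self):
        assert filter_panel_calls([call([(60, 0.05), (60, 0.2)])])

    def test_single_replicate_low_af_dropped(self):
        assert filter_panel_calls([call([(60, 0.05)])]) == []

    def test_single_replicate_high_af_kept(self):
        assert filter_panel_calls([call([(60, 0.2)])])

    def test_truth_table_oracle(self):
        """All combinations of the three predicates match direct evaluation."""
        depths = (40, 51, 200)
        afs = (0.05, 0.1, 0.3)
        for d1, a1, wl in itertools.product(depths, afs, (True, False)):
            # single-replicate calls
            c = call([(d1, a1)], whitelisted=wl)
            expected = wl and d1 > 50 and a1 > 0.1
            assert bool(filter_panel_calls([c])) == expected
            # duplicate calls: AF clause waived, both depths must pass
            for d2 in depths:
                c2 = call([(d1, a1), (d2, 0.5)], whitelisted=wl)
                expected2 = wl and d1 > 50 and d2 > 50
                assert bool(filter_panel_calls([c2])) == expected2

    def test_monotone_in_thresholds(self):
        calls = [call([(d, a)]) for d in (40, 60, 80) for a in (0.05, 0.15, 0.4)]
        strict = {id(c) for c in filter_panel_calls(calls, min_depth=70, min_af=0.2)}
        lax = {id(c) for c in filter_panel_calls(calls, min_depth=50, min_af=0.1)}
        assert strict <= lax


class TestSampleExclusion:
    def _table(self, low1, low2_shared, n_amplicons=77):
        """low1 amplicons <100 in rep1 only; low2_shared low in both reps."""
        rows = []
        for i in range(n_amplicons):
            r1 = 50 if i < low1 + low2_shared else 500
            r2 = 50 if i < low2_shared else 500
            rows.append(("s", f"amp{i}", r1, r2))
        return pd.DataFrame(rows, columns=["sample", "amplicon", "reads_rep1", "reads_rep2"])

    def test_thirty_one_low_in_one_replicate_dropped(self):
        assert sample_exclusion(self._table(31, 0)) == []

    def test_twenty_one_low_in_both_dropped(self):
        assert sample_exclusion(self._table(0, 21)) == []

    def test_boundary_cases_kept(self):
        assert sample_exclusion(self._table(30, 0)) == ["s"]
        assert sample_exclusion(self._table(10, 20)) == ["s"]

    def test_all_covered_kept(self):
        assert sample_exclusion(self._table(0, 0)) == ["s"]

    def test_truth_table_oracle(self):
        for low1, shared in itertools.product((0, 10, 20, 21, 30, 31), repeat=2):
            if low1 + shared > 77:
                continue
            table = self._table(low1, shared)
            n1, n2 = low1 + shared, shared
            expected = not (n1 > 30 or n2 > 30 or (n1 > 20 and n2 > 20))
            assert (sample_exclusion(table) == ["s"]) == expected


class TestComputeLoads:
    def test_counts_and_zero_fill(self):
        calls = [call([(60, 0.3)], sample="a", pos=p) for p in range(100, 105)]
        cov = pd.DataFrame({"sample": ["a", "b"], "gender": ["m", "f"]})
        loads = {l.sample_id: l for l in compute_loads(calls, cov)}
        assert loads["a"].promoter_mutation_load == 5
        assert loads["b"].promoter_mutation_load == 0
        assert loads["b"].covariates["gender"] == "f"


class TestAssociationTests:
    def _loads(self, values, covs, name="grade"):
        return [
            SampleLoad(f"s{i}", v, covariates={name: c})
            for i, (v, c) in enumerate(zip(values, covs))
        ]

    def test_two_groups_use_mann_whitney(self, rng):
        loads = self._loads(rng.poisson(5, 40), ["a"] * 20 + ["b"] * 20)
        res = association_tests(loads, "grade")
        assert res.test == "mann_whitney" and res.group_sizes == {"a": 20, "b": 20}

    def test_many_groups_use_kruskal(self, rng):
        loads = self._loads(rng.poisson(5, 40), list("abcd") * 10)
        assert association_tests(loads, "grade").test == "kruskal_wallis"

    def test_numeric_uses_spearman(self, rng):
        loads = self._loads(rng.poisson(5, 40), rng.normal(size=40))
        res = association_tests(loads, "grade", numeric=True)
        assert res.test == "spearman" and res.estimate is not None

    def test_constant_loads_flag_no_variance(self):
        loads = self._loads([3] * 20, ["a", "b"] * 10)
        assert association_tests(loads, "grade").test == "no_variance"

    def test_missing_covariate_excluded_pairwise(self, rng):
        loads = self._loads(rng.poisson(5, 30), ["a"] * 15 + ["b"] * 14 + [np.nan])
        assert association_tests(loads, "grade").group_sizes == {"a": 15, "b": 14}

    def test_permutation_null_calibration(self, rng):
        """Permuted group labels give approximately uniform p-values."""
        values = rng.poisson(5, 60)
        ps = []
        for _ in range(200):
            labels = rng.permutation(["a"] * 30 + ["b"] * 30)
            ps.append(association_tests(self._loads(values, labels), "grade").p_value)
        assert kstest(ps, "uniform").statistic < 0.1

    def test_power_at_ordered_grades(self, rng):
        """Loads shifted by one unit per grade are detected at n=30/group."""
        values, grades = [], []
        for g in range(4):
            values.extend(rng.poisson(5 + 2 * g, 30))
            grades.extend([g] * 30)
        res = association_tests(self._loads(values, grades), "grade")
        assert res.test == "kruskal_wallis" and res.p_value < 0.05


class TestRegressLoads:
    def _loads(self, x, y):
        return [
            SampleLoad(f"s{i}", int(yi), nonsynonymous_load=int(xi))
            for i, (xi, yi) in enumerate(zip(x, y))
        ]

    def test_collinear_r2_one(self):
        x = np.arange(10)
        res = regress_loads(self._loads(x, 3 * x + 2))
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)

    def test_independent_noise_r2_small(self, rng):
        hits = 0
        for _ in range(40):
            x = rng.poisson(100, 40)
            y = rng.poisson(30, 40)
            if regress_loads(self._loads(x, y)).r_squared < 0.2:
                hits += 1
        assert hits >= 38  # >= 95% of replicates

    def test_known_slope_recovered_within_3se(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0, 400, 60)
        y = 0.05 * x + rng.normal(0, 2, 60)
        res = regress_loads(self._loads(x, np.maximum(0, np.round(y))))
        fit = sm.OLS(np.maximum(0, np.round(y)), sm.add_constant(x)).fit()
        assert abs(res.slope - 0.05) < 3 * fit.bse[1] + 0.01


class TestExpressionByMutation:
    def _tables(self, rng, n_samples=40, n_genes=50, shift_gene=None, shift=0.0):
        samples = [f"s{i}" for i in range(n_samples)]
        genes = [f"g{j}" for j in range(n_genes)]
        expr = pd.DataFrame(
            rng.normal(size=(n_samples, n_genes)), index=samples, columns=genes
        )
        status = pd.DataFrame(
            rng.random((n_samples, n_genes)) < 0.3, index=samples, columns=genes
        )
        if shift_gene is not None:
            expr.loc[status[shift_gene], shift_gene] += shift
        return expr, status

    def test_planted_shift_attains_minimum_q(self, rng):
        expr, status = self._tables(rng, shift_gene="g7", shift=3.0)
        result, _ = expression_by_mutation(expr, status)
        assert result.loc[result["q_value"].idxmin(), "gene"] == "g7"
        assert result["q_value"].min() < 0.05

    def test_null_fdr_control(self, rng):
        false_hits, n_tests = 0, 0
        for _ in range(25):
            expr, status = self._tables(rng, n_genes=40)
            result, _ = expression_by_mutation(expr, status)
            false_hits += int((result["q_value"] < 0.05).sum())
            n_tests += 1
        assert false_hits / n_tests < 1.0  # well under one false gene per cohort

    def test_all_mutated_gene_excluded(self, rng):
        expr, status = self._tables(rng, n_genes=5)
        status["g2"] = True
        result, excluded = expression_by_mutation(expr, status)
        assert "g2" in excluded
        assert "g2" not in set(result["gene"])


class TestMapSnvsToMotif:
    def test_plus_strand_position(self):
        c = make_cohort([("s", "1", 105, "G", "A")])
        occ = [GenomicInterval("1", 100, 110, strand="+")]
        out = map_snvs_to_motif(c, occ, motif_length=10)
        assert out.to_dict("records") == [
            {"position": 5, "ref": "G", "alt": "A", "count": 1}
        ]

    def test_minus_strand_reverses_and_complements(self):
        c = make_cohort([("s", "1", 105, "G", "A")])
        occ = [GenomicInterval("1", 100, 110, strand="-")]
        out = map_snvs_to_motif(c, occ, motif_length=10)
        assert out.to_dict("records") == [
            {"position": 6, "ref": "C", "alt": "T", "count": 1}
        ]

    def test_width_mismatch_errors(self):
        c = make_cohort([("s", "1", 105, "G", "A")])
        with pytest.raises(ValueError, match="width"):
            map_snvs_to_motif(c, [GenomicInterval("1", 100, 111, strand="+")], 10)

    def test_double_strand_flip_is_involution(self, rng):
        events = [
            (f"s{i}", "1", int(p), "G", "A")
            for i, p in enumerate(rng.integers(101, 111, size=30))
        ]
        c = make_cohort(events)
        plus = [GenomicInterval("1", 100, 110, strand="+")]
        minus = [GenomicInterval("1", 100, 110, strand="-")]
        once = map_snvs_to_motif(c, minus, 10)
        direct = map_snvs_to_motif(c, plus, 10)
        # flipping the minus-strand table back reproduces the plus-strand table
        flipped = once.assign(
            position=11 - once["position"],
            ref=once["ref"].map({"A": "T", "C": "G", "G": "C", "T": "A"}),
            alt=once["alt"].map({"A": "T", "C": "G", "G": "C", "T": "A"}),
        ).sort_values(["position", "ref", "alt"]).reset_index(drop=True)
        assert flipped.equals(direct.sort_values(["position", "ref", "alt"]).reset_index(drop=True))
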