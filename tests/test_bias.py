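"""Bias statistics: log(max/EC50), Δlog/ΔΔlog chains, t-based calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gpcrbias import (PathwayAgonism, log_max_ec50, delta_log, ddelta_log,
                      ktau_bias, bias_from_agonism, paired_compare)
from gpcrbias.calibration import ddlog_from_profiles


def _pa(value, ligand="L", pathway="p1", assay="a1", metric="log_max_ec50"):
    return PathwayAgonism(ligand=ligand, pathway=pathway, assay_id=assay,
                          metric=metric, value=value)


class TestLogMaxEc50:
    def test_full_agonist_glucagon_profile(self):
        assert log_max_ec50(100.0, 6.7) == pytest.approx(8.70, abs=1e-10)

    def test_partial_agonist_profile(self):
        assert log_max_ec50(54.0, 6.7) == pytest.approx(8.432, abs=5e-4)

    def test_unit_scale(self):
        assert log_max_ec50(100.0, 0.0) == pytest.approx(2.0)

    def test_nonpositive_emax_rejected(self):
        with pytest.raises(ValueError):
            log_max_ec50(0.0, 6.0)


class TestDeltaLog:
    def test_self_comparison_is_zero(self):
        a = _pa(8.7)
        assert delta_log(a, a) == 0.0

    def test_glucagon_aib2_mini_gs(self):
        d = delta_log(_pa(log_max_ec50(54, 6.7)), _pa(log_max_ec50(100, 6.7)))
        assert d == pytest.approx(-0.268, abs=5e-4)

    def test_glucagon_aib2_arrestin(self):
        d = delta_log(_pa(log_max_ec50(25, 6.2)), _pa(log_max_ec50(100, 6.1)))
        assert d == pytest.approx(-0.502, abs=5e-4)

    def test_mismatches_rejected(self):
        with pytest.raises(ValueError, match="pathway"):
            delta_log(_pa(1.0, pathway="p1"), _pa(1.0, pathway="p2"))
        with pytest.raises(ValueError, match="assay"):
            delta_log(_pa(1.0, assay="a1"), _pa(1.0, assay="a2"))


class TestDdeltaLog:
    def test_identical_dlog_vectors_unbiased(self):
        v = [0.1, -0.2, 0.05, 0.0]
        est = ddelta_log(v, v)
        assert est.mean == 0.0
        assert est.biased is False

    def test_profile_table_bias_factor(self):
        dd = ddlog_from_profiles("GCG-AIB2", "GCG", "GCGR",
                                 ("mini-Gs", "barr2"))
        assert dd == pytest.approx(0.234, abs=5e-4)
        assert dd > 0  # toward the G-protein pathway

    @given(st.lists(st.floats(-2, 2), min_size=2, max_size=8),
           st.lists(st.floats(-2, 2), min_size=2, max_size=8))
    def test_antisymmetry_exact(self, d1, d2):
        n = min(len(d1), len(d2))
        a = ddelta_log(d1[:n], d2[:n])
        b = ddelta_log(d2[:n], d1[:n])
        assert a.per_assay_dd == tuple(-v for v in b.per_assay_dd)
        assert a.mean == -b.mean

    def test_single_assay_gives_undetermined_call(self):
        est = ddelta_log([0.3], [0.1])
        assert est.ci95 is None and est.biased is None
        assert est.mean == pytest.approx(0.2)

    def test_ci_uses_student_t(self):
        from scipy import stats
        dd = np.array([0.30, 0.21, 0.26, 0.35])
        est = ddelta_log(dd, np.zeros_like(dd))
        sem = dd.std(ddof=1) / 2.0
        tcrit = stats.t.ppf(0.975, 3)
        assert est.ci95[0] == pytest.approx(dd.mean() - tcrit * sem)
        assert est.ci95[1] == pytest.approx(dd.mean() + tcrit * sem)
        assert est.biased is True  # CI excludes zero

    def test_transitivity_of_means(self):
        rng = np.random.default_rng(5)
        rows = []
        for lig, base in (("A", 0.3), ("B", -0.1), ("C", 0.0)):
            for pathway, shift in (("p1", 0.2), ("p2", -0.4)):
                for assay in range(4):
                    rows.append(dict(ligand=lig, pathway=pathway,
                                     assay_id=f"a{assay}",
                                     metric="log_max_ec50",
                                     value=base + shift + rng.normal(0, .1)))
        table = pd.DataFrame(rows)
        dd = {pair: bias_from_agonism(table, *pair, ("p1", "p2"),
                                      "log_max_ec50").mean
              for pair in (("A", "C"), ("A", "B"), ("B", "C"))}
        assert dd[("A", "C")] == pytest.approx(
            dd[("A", "B")] + dd[("B", "C")], abs=1e-12)

    def test_additive_agonism_shift_cancels(self):
        # rescaling the Emax axis shifts log(max/EC50) by a constant
        rng = np.random.default_rng(9)
        rows = []
        for lig in ("A", "B"):
            for pathway in ("p1", "p2"):
                for assay in range(5):
                    rows.append(dict(ligand=lig, pathway=pathway,
                                     assay_id=f"a{assay}",
                                     metric="log_max_ec50",
                                     value=rng.normal()))
        table = pd.DataFrame(rows)
        shifted = table.assign(value=table.value + np.log10(3.7))
        a = bias_from_agonism(table, "A", "B", ("p1", "p2"), "log_max_ec50")
        b = bias_from_agonism(shifted, "A", "B", ("p1", "p2"),
                              "log_max_ec50")
        assert a.per_assay_dd == pytest.approx(b.per_assay_dd, abs=1e-12)


class TestKtauBias:
    def _table(self, scale_p1=1.0, scale_p2=1.0, n=5):
        rows = []
        for assay in range(n):
            for pathway, base, scale in (("p1", 0.17, scale_p1),
                                         ("p2", 1.05, scale_p2)):
                rows.append(dict(ligand="REF", pathway=pathway,
                                 assay_id=f"a{assay}", ktau=base))
                rows.append(dict(ligand="TEST", pathway=pathway,
                                 assay_id=f"a{assay}", ktau=base * scale))
        return pd.DataFrame(rows)

    def test_identical_ligands_unbiased(self):
        est = ktau_bias(self._table(), "TEST", "REF", ("p1", "p2"))
        assert est.mean == pytest.approx(0.0, abs=1e-12)
        assert est.biased is False

    def test_partial_agonist_without_bias(self):
        # both pathways halved: partial agonism, ΔΔlog ktau stays zero
        est = ktau_bias(self._table(0.5, 0.5), "TEST", "REF", ("p1", "p2"))
        assert est.mean == pytest.approx(0.0, abs=1e-12)
        table = self._table(0.5, 0.5)
        p1 = table[(table.pathway == "p1")]
        dlog = np.log10(
            p1[p1.ligand == "TEST"].ktau.to_numpy()
            / p1[p1.ligand == "REF"].ktau.to_numpy())
        assert dlog == pytest.approx(np.log10(0.5), abs=1e-12)

    def test_biased_agonist_construction(self):
        est = ktau_bias(self._table(1.0, 0.25), "TEST", "REF", ("p1", "p2"))
        assert est.mean == pytest.approx(0.602, abs=5e-4)

    def test_nonpositive_ktau_excluded_with_warning(self):
        table = self._table()
        table.loc[0, "ktau"] = -0.01
        with pytest.warns(UserWarning, match="non-positive"):
            est = ktau_bias(table, "TEST", "REF", ("p1", "p2"))
        assert est.n == 4  # the broken assay drops out of the pairing


class TestPairedCompare:
    def test_identical_vectors(self):
        res = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_constant_shift_degenerate(self):
        res = paired_compare([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
        assert res.p == 0.0 and np.isinf(res.t) and res.degenerate

    def test_matches_scipy_on_generic_data(self):
        from scipy import stats
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 8))
        res = paired_compare(a, b)
        ref = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df == 7

    def test_requires_pairs(self):
        with pytest.raises(ValueError):
            paired_compare([1.0], [2.0])
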