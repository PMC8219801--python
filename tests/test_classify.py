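"""Tests for UV-response, kinetics, dependency and partition classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from uvrecover import (DataError, call_dependency, call_kinetics,
                       call_uv_response, classify_recovery_ratio,
                       mean_response_curve, partition_genes,
                       summarize_dependency)


def wide_from(early, late, recovery=None, genes=None):
    genes = genes or [f"g{i}" for i in range(len(early))]
    data = {0.5: early, 2.5: late}
    if recovery is not None:
        data[24.5] = recovery
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


class TestCallUvResponse:
    @pytest.mark.parametrize("early,late,expected", [
        (1.0, 0.40, "repressed"),
        (2.5, 1.00, "induced"),
        (0.9, 0.50, "repressed"),   # inclusive boundary: exactly 2-fold down
        (2.0, 1.00, "induced"),     # inclusive boundary: exactly 2-fold up
        (1.0, 0.51, "unchanged"),
        (1.99, 0.51, "unchanged"),
    ])
    def test_calls(self, early, late, expected):
        out = call_uv_response(wide_from([early], [late]))
        assert out.iloc[0]["response"] == expected

    def test_conflict_excluded(self):
        out = call_uv_response(wide_from([2.5], [0.4]))
        assert out.iloc[0]["response"] == "excluded"
        assert out.iloc[0]["reason"] == "conflict"

    def test_missing_timepoint_raises(self):
        wide = pd.DataFrame({0.5: [1.0]}, index=["g0"])
        with pytest.raises(DataError, match="2.5"):
            call_uv_response(wide)

    def test_classes_partition_input(self):
        rng = np.random.default_rng(3)
        wide = wide_from(rng.uniform(0, 3, 500), rng.uniform(0, 3, 500))
        out = call_uv_response(wide)
        assert out["response"].isin(["repressed", "induced", "unchanged",
                                     "excluded"]).all()
        assert len(out) == 500

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, scale):
        """Ratios are scale-free: multiplying a gene's raw values through
        leaves classification unchanged (ratios are unchanged by construction;
        classification depends only on ratios)."""
        wide = wide_from([0.4, 2.1, 1.0], [0.3, 1.0, 0.9])
        assert (call_uv_response(wide)["response"]
                == call_uv_response(wide * scale / scale)["response"]).all()


class TestCallKinetics:
    def test_fast_slow_boundary(self):
        wide = wide_from([0.40, 0.80, 0.50], [0.30, 0.45, 0.45])
        resp = call_uv_response(wide)
        kin = call_kinetics(resp, wide)
        assert kin.tolist() == ["fast", "slow", "fast"]  # 0.5 exactly -> fast

    def test_error_on_non_repressed(self):
        wide = wide_from([1.0], [0.9])
        resp = call_uv_response(wide)
        with pytest.raises(DataError, match="non-repressed"):
            call_kinetics(resp, wide, genes=["g0"])

    def test_fast_union_slow_equals_repressed(self):
        rng = np.random.default_rng(11)
        wide = wide_from(rng.uniform(0, 2, 300), rng.uniform(0, 2, 300))
        resp = call_uv_response(wide)
        kin = call_kinetics(resp, wide)
        assert set(kin.index) == set(resp.index[resp["response"] == "repressed"])
        assert kin.isin(["fast", "slow"]).all()


class TestDependency:
    @pytest.mark.parametrize("rc,rk,expected", [
        (1.0, 0.5, "stimulated"),
        (0.8, 0.8, "independent"),
        (0.5, 0.6, "inhibited"),
    ])
    def test_examples(self, rc, rk, expected):
        ctrl = wide_from([1.0], [0.4], [rc])
        kd = wide_from([1.0], [0.4], [rk])
        out = call_dependency(ctrl, kd, ["g0"])
        assert out.iloc[0]["dependency"] == expected
        assert out.iloc[0]["relative_recovery"] == pytest.approx(rk / rc)

    def test_boundaries(self):
        assert classify_recovery_ratio(0.90) == "stimulated"
        assert classify_recovery_ratio(1.10) == "inhibited"
        assert classify_recovery_ratio(0.9000001) == "independent"
        assert classify_recovery_ratio(1.0999999) == "independent"

    def test_bands_tile_positive_axis(self):
        rng = np.random.default_rng(5)
        ratios = np.exp(rng.uniform(-8, 8, 10_000))
        classes = classify_recovery_ratio(ratios)
        assert set(np.unique(classes)) <= {"stimulated", "independent", "inhibited"}
        # every ratio maps to exactly one class (vector output, no NaN slots)
        assert len(classes) == 10_000

    def test_control_recovery_zero_excluded(self):
        ctrl = wide_from([1.0], [0.4], [0.0])
        kd = wide_from([1.0], [0.4], [0.5])
        out = call_dependency(ctrl, kd, ["g0"])
        assert out.iloc[0]["dependency"] == "excluded"
        assert out.iloc[0]["reason"] == "control_recovery_zero"

    def test_missing_in_knockdown_excluded(self):
        ctrl = wide_from([1.0], [0.4], [0.9])
        kd = wide_from([1.0], [0.4], [0.9]).drop(index=["g0"])
        out = call_dependency(ctrl, kd, ["g0"])
        assert out.iloc[0]["dependency"] == "excluded"
        assert out.iloc[0]["reason"] == "missing_ratio"


class TestPartitions:
    def test_median_split(self):
        lengths = pd.Series({"a": 2000, "b": 4000, "c": 6000, "d": 8000})
        rpkm = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        out = partition_genes(lengths, rpkm)
        assert out.loc[["a", "b"], "length_class"].tolist() == ["short", "short"]
        assert out.loc[["c", "d"], "length_class"].tolist() == ["long", "long"]
        assert out.attrs["length_median_bp"] == 5000

    def test_median_tie_goes_short(self):
        lengths = pd.Series({"a": 1000, "b": 5000, "c": 9000})
        rpkm = pd.Series(1.0, index=lengths.index)
        out = partition_genes(lengths, rpkm)
        assert out.loc["b", "length_class"] == "short"  # exactly the median

    def test_quartiles_deterministic_under_ties(self):
        lengths = pd.Series({f"g{i}": 1000 for i in range(8)})
        rpkm = pd.Series(1.0, index=lengths.index)
        out = partition_genes(lengths, rpkm)
        # ties broken by gene_id: g0,g1 -> q1 ... g6,g7 -> q4
        assert out["length_quartile"].tolist() == [1, 1, 2, 2, 3, 3, 4, 4]
        assert (out["length_quartile"].value_counts() == 2).all()

    def test_quartile_one_is_shortest(self):
        rng = np.random.default_rng(1)
        lengths = pd.Series(rng.integers(500, 100_000, 101),
                            index=[f"g{i}" for i in range(101)])
        rpkm = pd.Series(rng.random(101), index=lengths.index)
        out = partition_genes(lengths, rpkm)
        q1_max = lengths[out["length_quartile"] == 1].max()
        q4_min = lengths[out["length_quartile"] == 4].min()
        assert q1_max <= q4_min

    def test_empty_set_raises(self):
        with pytest.raises(DataError, match="empty"):
            partition_genes(pd.Series(dtype=float), pd.Series(dtype=float))

    def test_biotype_classes(self):
        lengths = pd.Series({"a": 1, "b": 2})
        bt = pd.Series({"a": "protein_coding", "b": "lincRNA"})
        out = partition_genes(lengths, pd.Series(1.0, index=lengths.index), bt)
        assert out["biotype_class"].tolist() == ["coding", "noncoding"]


class TestSummaries:
    def _dep(self, classes):
        return pd.DataFrame({"dependency": classes},
                            index=[f"g{i}" for i in range(len(classes))])

    def test_all_stimulated(self):
        s = summarize_dependency(self._dep(["stimulated"] * 4))
        assert s["fractions"] == {"stimulated": 1.0, "independent": 0.0,
                                  "inhibited": 0.0}

    def test_half_half(self):
        s = summarize_dependency(self._dep(["stimulated", "independent"]))
        assert s["fractions"]["stimulated"] == 0.5
        assert s["fractions"]["inhibited"] == 0.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        classes = rng.choice(["stimulated", "independent", "inhibited", "excluded"],
                             size=200)
        s = summarize_dependency(self._dep(list(classes)))
        assert abs(sum(s["fractions"].values()) - 1.0) < 1e-12
        assert s["n"] + s["n_excluded"] == 200

    def test_mean_curve_single_gene(self):
        wide = wide_from([0.4], [0.3], [0.9])
        curve = mean_response_curve(wide, ["g0"])
        assert curve.loc[0.5, "mean"] == 0.4
        assert (curve["sd"] == 0).all()
        assert (curve["n"] == 1).all()

    def test_mean_curve_matches_brute_force(self):
        rng = np.random.default_rng(9)
        wide = wide_from(rng.random(40), rng.random(40), rng.random(40))
        genes = list(wide.index[:17])
        curve = mean_response_curve(wide, genes)
        for tp in (0.5, 2.5, 24.5):
            vals = [wide.loc[g, tp] for g in genes]
            mean = sum(vals) / len(vals)
            sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            assert curve.loc[tp, "mean"] == pytest.approx(mean, rel=1e-12)
            assert curve.loc[tp, "sd"] == pytest.approx(sd, rel=1e-12)

    def test_two_genes_mean(self):
        wide = wide_from([0.4, 0.6], [0.3, 0.3])
        assert mean_response_curve(wide, wide.index).loc[0.5, "mean"] == pytest.approx(0.5)
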