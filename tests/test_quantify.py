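"""Unit and property tests for RPKM quantification and scaling normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from uvrecover import (DataError, ExpressionMatrix, ScalingFactorTable,
                       apply_scaling, compute_rpkm, filter_complete_cases,
                       relative_to_baseline)
from uvrecover.quantify import parse_timepoint

from conftest import make_matrix


def _counts_matrix(counts, library_size=1_000_000, genes=None):
    return make_matrix(
        {"s1": counts},
        [{"sample_id": "s1", "condition": "control", "timepoint_h": 0,
          "replicate": 1, "library_size": library_size}],
        genes=genes)


class TestComputeRpkm:
    @pytest.mark.parametrize("counts,length,lib,expected", [
        (10, 1000, 1_000_000, 10.0),          # unit definition
        (0, 48_667, 50_000_000, 0.0),         # zero counts
        (250, 48_667, 50_000_000, 250 / (48.667 * 50)),  # realistic scale
    ])
    def test_examples(self, counts, length, lib, expected):
        m = _counts_matrix([counts], library_size=lib)
        out = compute_rpkm(m, pd.Series({"g0": length}))
        assert out.state == "rpkm"
        assert out.values.iloc[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_median_length_gene_at_typical_depth(self):
        """250 reads on a median-length gene at 50M depth ~ 0.102739 RPKM."""
        m = _counts_matrix([250], library_size=50_000_000)
        out = compute_rpkm(m, pd.Series({"g0": 48_667}))
        assert out.values.iloc[0, 0] == pytest.approx(0.102739, abs=5e-7)

    def test_missing_length_names_gene(self):
        m = _counts_matrix([1, 2], genes=["gA", "gB"])
        with pytest.raises(DataError, match="gB"):
            compute_rpkm(m, pd.Series({"gA": 1000}))

    def test_zero_library_size_rejected(self):
        m = _counts_matrix([1], library_size=0)
        with pytest.raises(DataError, match="library_size"):
            compute_rpkm(m, pd.Series({"g0": 1000}))

    @given(counts=st.integers(0, 10_000), k=st.floats(0.1, 50))
    @settings(max_examples=50, deadline=None)
    def test_depth_invariance(self, counts, k):
        """Scaling counts and library size together leaves RPKM unchanged."""
        a = compute_rpkm(_counts_matrix([counts]), pd.Series({"g0": 1234}))
        b = compute_rpkm(_counts_matrix([counts * k], library_size=1_000_000 * k),
                         pd.Series({"g0": 1234}))
        assert b.values.iloc[0, 0] == pytest.approx(a.values.iloc[0, 0], rel=1e-9)


class TestApplyScaling:
    def _rpkm(self, cols, tps):
        samples = [{"sample_id": s, "condition": "control", "timepoint_h": t,
                    "replicate": 1, "library_size": 1e6}
                   for s, t in zip(cols, tps)]
        return make_matrix({s: [0.28, 2.0, 1.3] for s in cols}, samples,
                           state="rpkm")

    def test_unit_factors_identity_bitwise(self):
        m = self._rpkm(["a", "b"], [0.0, 2.5])
        out = apply_scaling(m, ScalingFactorTable({("control", 2.5): 1.0}))
        assert (out.values.to_numpy() == m.values.to_numpy()).all()
        assert out.state == "scaled_rpkm"

    @pytest.mark.parametrize("rpkm,factor,expected", [
        (2.0, 0.5, 1.0),
        (0.28, 0.37, 0.1036),
    ])
    def test_arithmetic(self, rpkm, factor, expected):
        m = make_matrix({"s": [rpkm]},
                        [{"sample_id": "s", "condition": "control",
                          "timepoint_h": 2.5, "replicate": 1, "library_size": 1e6}],
                        state="rpkm")
        out = apply_scaling(m, ScalingFactorTable({("control", 2.5): factor}))
        assert out.values.iloc[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_missing_factor_names_pair(self):
        m = self._rpkm(["a", "b"], [0.0, 24.5])
        with pytest.raises(DataError, match=r"control.*24\.5"):
            apply_scaling(m, ScalingFactorTable({("control", 2.5): 0.5}))

    def test_baseline_factor_must_be_one(self):
        with pytest.raises(DataError, match="baseline"):
            ScalingFactorTable({("control", 0.0): 0.9})

    def test_commutes_with_gene_subsetting(self):
        m = self._rpkm(["a", "b"], [0.0, 2.5])
        factors = ScalingFactorTable({("control", 2.5): 0.37})
        sub_then_scale = apply_scaling(m.subset_genes(["g0", "g2"]), factors)
        scale_then_sub = apply_scaling(m, factors).subset_genes(["g0", "g2"])
        pd.testing.assert_frame_equal(sub_then_scale.values, scale_then_sub.values)


class TestRelativeToBaseline:
    def _scaled(self, baseline, post, tp=24.5):
        return make_matrix(
            {"b": baseline, "p": post},
            [{"sample_id": "b", "condition": "control", "timepoint_h": 0,
              "replicate": 1, "library_size": 1e6},
             {"sample_id": "p", "condition": "control", "timepoint_h": tp,
              "replicate": 1, "library_size": 1e6}],
            state="scaled_rpkm")

    def test_ratio_values(self):
        rt = relative_to_baseline(self._scaled([4.0, 0.28], [2.0, 0.28]))
        wide = rt.wide("control")
        assert wide.loc["g0", 24.5] == pytest.approx(0.5)
        assert wide.loc["g1", 24.5] == pytest.approx(1.0)  # full recovery

    def test_baseline_zero_excluded(self):
        rt = relative_to_baseline(self._scaled([0.0, 1.0], [2.0, 0.5]))
        assert rt.excluded_genes("control") == {"g0"}
        assert rt.excluded.iloc[0]["reason"] == "baseline_zero"
        assert "g0" not in rt.wide("control").index

    def test_excluded_plus_retained_partition_input(self):
        rng = np.random.default_rng(7)
        base = rng.random(30)
        base[rng.random(30) < 0.3] = 0.0
        m = self._scaled(list(base), list(rng.random(30)))
        rt = relative_to_baseline(m)
        retained = set(rt.wide("control").index)
        excluded = rt.excluded_genes("control")
        assert retained | excluded == set(m.genes)
        assert retained & excluded == set()

    def test_replicate_mean_averages(self):
        samples = []
        values = {}
        for rep, post in [(1, 2.0), (2, 4.0)]:
            for tp, v in [(0.0, 4.0), (24.5, post)]:
                sid = f"r{rep}_{tp}"
                values[sid] = [v]
                samples.append({"sample_id": sid, "condition": "control",
                                "timepoint_h": tp, "replicate": rep,
                                "library_size": 1e6})
        m = make_matrix(values, samples, state="scaled_rpkm")
        mean_rt = relative_to_baseline(m, mode="replicate_mean")
        assert mean_rt.wide("control").loc["g0", 24.5] == pytest.approx((0.5 + 1.0) / 2)
        per_rt = relative_to_baseline(m, mode="per_replicate")
        assert per_rt.wide("control", replicate=2).loc["g0", 24.5] == pytest.approx(1.0)


class TestFilterCompleteCases:
    def _m(self):
        return make_matrix(
            {"c0": [1.0, 1.0], "c1": [1.0, 0.0], "k0": [1.0, 1.0], "k1": [2.0, 3.0]},
            [{"sample_id": "c0", "condition": "control", "timepoint_h": 0,
              "replicate": 1, "library_size": 1e6},
             {"sample_id": "c1", "condition": "control", "timepoint_h": 24.5,
              "replicate": 1, "library_size": 1e6},
             {"sample_id": "k0", "condition": "knockdown_A", "timepoint_h": 0,
              "replicate": 1, "library_size": 1e6},
             {"sample_id": "k1", "condition": "knockdown_A", "timepoint_h": 24.5,
              "replicate": 1, "library_size": 1e6}],
            state="scaled_rpkm")

    def test_zero_anywhere_drops_gene(self):
        kept = filter_complete_cases(self._m(), ["control", "knockdown_A"])
        assert list(kept) == ["g0"]

    def test_empty_condition_list_is_vacuous(self):
        assert list(filter_complete_cases(self._m(), [])) == ["g0", "g1"]


def test_timepoint_aliases():
    assert parse_timepoint("2h30") == 2.5
    assert parse_timepoint("24h30") == 24.5
    assert parse_timepoint("30min") == 0.5
    assert parse_timepoint(6.5) == 6.5
    with pytest.raises(DataError):
        parse_timepoint("tomorrow")
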