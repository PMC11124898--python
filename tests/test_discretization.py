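"""Class-overlap discretizer vs a linear-scan endpoint-sweep oracle."""

import json

import numpy as np
import pandas as pd
import pytest

from enoserot.discretization import (
    ClassRange,
    DiscretizationModel,
    fit_discretizer,
    transform,
    one_hot_encode,
    overlap_fraction,
)


def sweep_oracle_tag(value, class_ranges):
    """Assign a tag by linearly scanning sorted interior endpoints."""
    lo = min(r.lo for r in class_ranges)
    hi = max(r.hi for r in class_ranges)
    ends = sorted({e for r in class_ranges for e in (r.lo, r.hi) if lo < e < hi})
    tag = 1
    for e in ends:
        if value >= e:
            tag += 1
    return min(max(tag, 1), len(ends) + 1)


def _frame(values_by_class):
    rows = []
    for label, vals in values_by_class.items():
        rows += [{"label": label, "F": v} for v in vals]
    return pd.DataFrame(rows)


class TestFit:
    def test_disjoint_class_ranges_give_five_segments(self):
        # [0,1], [2,3], [4,5]: 3 pure regions + 2 gaps
        t = _frame({"a": [0.0, 1.0], "b": [2.0, 3.0], "c": [4.0, 5.0]})
        model = fit_discretizer(t)
        assert model.widths["F"] == 5
        # class-interior values carry the three distinct pure-region tags
        # (exact upper endpoints roll into the gap by the half-open rule)
        interior = transform(model, _frame({"a": [0.5], "b": [2.5], "c": [4.5]}))
        assert list(interior["F"]) == [1, 3, 5]

    def test_identical_ranges_give_single_segment(self):
        t = _frame({"a": [0.0, 1.0], "b": [0.0, 1.0]})
        model = fit_discretizer(t)
        assert model.widths["F"] == 1
        assert (transform(model, t)["F"] == 1).all()

    def test_partial_overlap_gives_three_segments(self):
        # [0,2] and [1,3]: pure-A, overlap, pure-B
        t = _frame({"a": [0.0, 2.0], "b": [1.0, 3.0]})
        model = fit_discretizer(t)
        assert model.widths["F"] == 3
        tags = transform(model, _frame({"a": [0.5, 1.5], "b": [2.5]}))
        assert list(tags["F"]) == [1, 2, 3]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fit_discretizer(pd.DataFrame({"label": [], "F": []}))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_discretizer(_frame({"a": [0.0, 1.0]}))


class TestTransform:
    def test_breakpoint_value_joins_right_segment_by_half_open_rule(self):
        t = _frame({"a": [0.0, 2.0], "b": [1.0, 3.0]})
        model = fit_discretizer(t)
        # breakpoints are 1.0 and 2.0; [b_k, b_{k+1}) convention
        out = transform(model, _frame({"a": [1.0, 2.0]}))
        assert list(out["F"]) == [2, 3]

    def test_values_outside_fitted_range_clip_to_end_segments(self):
        t = _frame({"a": [0.0, 2.0], "b": [1.0, 3.0]})
        model = fit_discretizer(t)
        out = transform(model, _frame({"a": [-100.0, 100.0]}))
        assert list(out["F"]) == [1, 3]

    @pytest.mark.parametrize("seed", range(40))
    def test_random_instances_match_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 4)
        classes = {}
        for c in range(k):
            vals = rng.normal(loc=rng.uniform(-2, 2), size=rng.integers(3, 10))
            classes[f"c{c}"] = list(vals)
        t = _frame(classes)
        model = fit_discretizer(t)
        ranges = model.class_ranges["F"]
        queries = rng.uniform(-5, 5, size=25)
        got = transform(model, _frame({"c0": list(queries)}))["F"].to_numpy()
        expected = [sweep_oracle_tag(v, ranges) for v in queries]
        assert list(got) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_tagging_is_monotone_in_the_value(self, seed):
        rng = np.random.default_rng(500 + seed)
        t = _frame({"a": list(rng.normal(size=8)), "b": list(rng.normal(1.0, 1, 8))})
        model = fit_discretizer(t)
        v = np.sort(rng.uniform(-4, 4, 50))
        tags = transform(model, _frame({"a": list(v)}))["F"].to_numpy()
        assert np.all(np.diff(tags) >= 0)

    def test_feature_name_mismatch_rejected(self):
        model = fit_discretizer(_frame({"a": [0.0, 2.0], "b": [1.0, 3.0]}))
        with pytest.raises(ValueError):
            transform(model, pd.DataFrame({"label": ["a"], "G": [1.0]}))


class TestOneHot:
    @pytest.fixture()
    def fitted(self):
        t = _frame({"a": [0.0, 2.0], "b": [1.0, 3.0]})
        return fit_discretizer(t), t

    def test_tag_two_of_three_encodes_middle_position(self, fitted):
        model, t = fitted
        enc = one_hot_encode(transform(model, _frame({"a": [1.5]})), model)
        assert list(enc[["F_seg1", "F_seg2", "F_seg3"]].iloc[0]) == [0, 1, 0]

    def test_every_row_sums_to_feature_count(self, fitted):
        model, t = fitted
        t2 = t.copy()
        t2["G"] = [0.0, 5.0, 2.0, 7.0]
        model2 = fit_discretizer(t2)
        enc = one_hot_encode(transform(model2, t2), model2)
        cols = [c for c in enc.columns if c != "label"]
        assert (enc[cols].sum(axis=1) == 2).all()

    def test_argmax_round_trip_recovers_tags(self, fitted):
        model, t = fitted
        tags = transform(model, t)
        enc = one_hot_encode(tags, model)
        k = model.widths["F"]
        recovered = enc[[f"F_seg{j}" for j in range(1, k + 1)]].to_numpy().argmax(1) + 1
        np.testing.assert_array_equal(recovered, tags["F"].to_numpy())

    def test_out_of_range_tag_rejected(self, fitted):
        model, t = fitted
        bad = transform(model, t)
        bad.loc[bad.index[0], "F"] = 99
        with pytest.raises(ValueError):
            one_hot_encode(bad, model)


class TestOverlapAndSerialization:
    def test_overlap_fraction_extremes(self):
        disjoint = fit_discretizer(_frame({"a": [0.0, 1.0], "b": [2.0, 3.0]}))
        nested = fit_discretizer(_frame({"a": [0.0, 3.0], "b": [0.0, 3.0]}))
        assert overlap_fraction(disjoint)["F"] == 0.0
        assert overlap_fraction(nested)["F"] == 1.0

    def test_partial_overlap_fraction_is_overlap_length_over_span(self):
        model = fit_discretizer(_frame({"a": [0.0, 2.0], "b": [1.0, 3.0]}))
        assert overlap_fraction(model)["F"] == pytest.approx(1.0 / 3.0)

    def test_json_round_trip(self):
        model = fit_discretizer(_frame({"a": [0.0, 2.0], "b": [1.0, 3.0]}))
        clone = DiscretizationModel.from_json(model.to_json())
        assert clone.widths == model.widths
        np.testing.assert_allclose(clone.breakpoints["F"], model.breakpoints["F"])
        t = _frame({"a": [0.5, 1.5, 2.5]})
        pd.testing.assert_frame_equal(transform(model, t), transform(clone, t))


def test_storage_mode_has_larger_mean_overlap_than_laboratory():
    """Ambient interference widens inter-class feature-range overlap."""
    import enoserot as er
    from enoserot.synthdata import default_environment, simulate_dataset

    fractions = {}
    for envname in ("laboratory", "storage"):
        vals = []
        for seed in range(5):
            recs = simulate_dataset(15, default_environment(envname), seed=40 + seed)
            table = er.extract_features([er.baseline_correct(r) for r in recs])
            sub = table.drop(columns=["sample_id", "environment"])
            vals.append(overlap_fraction(fit_discretizer(sub)).mean())
        fractions[envname] = np.mean(vals)
    assert fractions["storage"] > fractions["laboratory"]
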