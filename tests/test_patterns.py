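from itertools import permutations

import numpy as np
import pytest

from urodmas import (
    CaptureRegion,
    DMASMatrix,
    ValidationError,
    build_windows,
    classify,
    mine_patterns,
    normalize_scores,
    observed_ordering,
    score_samples,
)
from urodmas import io as uio


class TestObservedOrdering:
    def test_worked_example(self):
        # DMAS(w2) > DMAS(w1) > DMAS(w3)  =>  ascending order w3 < w1 < w2
        assert observed_ordering([0.5, 0.9, 0.1]) == (2, 0, 1)

    def test_all_ties_fall_back_to_genomic_order(self):
        assert observed_ordering([0.0, 0.0, 0.0]) == (0, 1, 2)

    def test_partial_tie_uses_stable_order(self):
        assert observed_ordering([0.2, 0.2, 0.1]) == (2, 0, 1)

    def test_matches_stable_sort_oracle_on_random_values(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            k = int(rng.integers(2, 5))
            vals = rng.integers(0, 4, size=k) / 4.0  # force ties often
            expected = tuple(
                sorted(range(k), key=lambda i: (vals[i], i))
            )
            assert observed_ordering(vals) == expected


def oracle_mine(values, labels_list, region_cols, k, delta_min):
    """Exhaustive enumeration oracle over all tuples and permutations.

    Returns {(region, start_offset, perm): (freq_h, freq_c)} for entries
    whose absolute contrast reaches delta_min.
    """
    out = {}
    for region, cols in region_cols.items():
        for i in range(len(cols) - k + 1):
            tup = cols[i : i + k]
            for perm in permutations(range(k)):
                n_h = n_c = f_h = f_c = 0
                for row, lab in enumerate(labels_list):
                    v = values[row, tup]
                    observed = tuple(sorted(range(k), key=lambda j: (v[j], j)))
                    if lab == "healthy":
                        n_h += 1
                        f_h += observed == perm
                    else:
                        n_c += 1
                        f_c += observed == perm
                fh, fc = f_h / n_h, f_c / n_c
                if abs(fh - fc) >= delta_min:
                    out[(region, i, perm)] = (fh, fc)
    return out


def _random_instance(rng):
    n_regions = int(rng.integers(1, 3))
    regions, window_ids, region_cols = [], [], {}
    col = 0
    for r in range(n_regions):
        n_win = int(rng.integers(1, 6))
        rid = f"r{r}"
        regions.append(CaptureRegion("chr1", col * 1000, col * 1000 + 10 * n_win, rid))
        region_cols[rid] = list(range(col, col + n_win))
        window_ids += [f"{rid}.{i}" for i in range(n_win)]
        col += n_win
    catalog = build_windows(regions, 10)
    assert catalog.window_ids == window_ids
    n_h = int(rng.integers(2, 7))
    n_c = int(rng.integers(2, 7))
    sample_ids = [f"h{i}" for i in range(n_h)] + [f"c{i}" for i in range(n_c)]
    labels = {s: ("healthy" if s[0] == "h" else "cancer") for s in sample_ids}
    # low-cardinality values so ties and repeated orderings are common
    values = rng.integers(0, 4, size=(n_h + n_c, col)) / 3.0
    dmas = DMASMatrix(sample_ids, window_ids, values)
    return dmas, labels, catalog, region_cols


class TestMinePatterns:
    def test_perfect_separation_gives_weight_one_patterns(self, separating_fixture, tiny_catalog):
        dmas, labels = separating_fixture
        model = mine_patterns(dmas, labels, tiny_catalog, k=3, delta_min=0.5)
        healthy = {(p.feature.region_id, p.permutation): p.weight for p in model.healthy_patterns}
        cancer = {(p.feature.region_id, p.permutation): p.weight for p in model.cancer_patterns}
        assert healthy == {("rB", (2, 0, 1)): 1.0}
        assert cancer == {("rB", (1, 0, 2)): 1.0}

    def test_identical_classes_give_empty_model(self, tiny_catalog, caplog):
        values = np.tile(np.array([0.3, 0.1, 0.5, 0.9, 0.2]), (4, 1))
        dmas = DMASMatrix(["h0", "h1", "c0", "c1"], tiny_catalog.window_ids, values)
        labels = {"h0": "healthy", "h1": "healthy", "c0": "cancer", "c1": "cancer"}
        with caplog.at_level("WARNING"):
            model = mine_patterns(dmas, labels, tiny_catalog, delta_min=0.1)
        assert model.n_patterns == 0

    def test_partial_frequency_contrast_weight(self, separating_fixture, tiny_catalog):
        dmas, labels = separating_fixture
        values = dmas.values.copy()
        values[0, 2:] = [0.5, 0.1, 0.9]  # one healthy sample defects to the cancer ordering
        noisy = DMASMatrix(dmas.sample_ids, dmas.window_ids, values)
        model = mine_patterns(noisy, labels, tiny_catalog, k=3, delta_min=0.5)
        healthy = {p.permutation: p.weight for p in model.healthy_patterns}
        assert healthy[(2, 0, 1)] == pytest.approx(2 / 3)

    def test_class_with_zero_samples_is_an_error(self, separating_fixture, tiny_catalog):
        dmas, _ = separating_fixture
        labels = {s: "healthy" for s in dmas.sample_ids}
        with pytest.raises(ValidationError, match="both classes"):
            mine_patterns(dmas, labels, tiny_catalog)

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            dmas, labels, catalog, region_cols = _random_instance(rng)
            delta_min = float(rng.choice([0.3, 0.5, 0.8]))
            model = mine_patterns(dmas, labels, catalog, k=3, delta_min=delta_min,
                                  max_patterns_per_class=10**6)
            expected = oracle_mine(
                dmas.values,
                [labels[s] for s in dmas.sample_ids],
                region_cols,
                k=3,
                delta_min=delta_min,
            )
            got = {}
            for p in model.healthy_patterns + model.cancer_patterns:
                key = (p.feature.region_id, p.feature.start_index, p.permutation)
                got[key] = (p.freq_healthy, p.freq_cancer)
                assert p.weight == pytest.approx(
                    abs(p.freq_healthy - p.freq_cancer)
                )
            assert got.keys() == expected.keys()
            for key in expected:
                assert got[key] == pytest.approx(expected[key])

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(23)
        dmas, labels, catalog, _ = _random_instance(rng)
        swapped = {
            s: ("cancer" if c == "healthy" else "healthy") for s, c in labels.items()
        }
        m1 = mine_patterns(dmas, labels, catalog, delta_min=0.3)
        m2 = mine_patterns(dmas, swapped, catalog, delta_min=0.3)

        def key(p):
            return (p.feature.region_id, p.feature.start_index, p.permutation, p.weight)

        assert sorted(map(key, m1.healthy_patterns)) == sorted(map(key, m2.cancer_patterns))
        assert sorted(map(key, m1.cancer_patterns)) == sorted(map(key, m2.healthy_patterns))
        s1 = score_samples(m1, dmas)["d_score"].to_numpy()
        s2 = score_samples(m2, dmas)["d_score"].to_numpy()
        np.testing.assert_allclose(s1, -s2, atol=1e-12)

    def test_permutation_frequencies_sum_to_one_per_class(self):
        rng = np.random.default_rng(29)
        dmas, labels, catalog, region_cols = _random_instance(rng)
        expected = oracle_mine(
            dmas.values, [labels[s] for s in dmas.sample_ids], region_cols, 3, 0.0
        )
        by_tuple_h: dict = {}
        for (region, i, _perm), (fh, _fc) in expected.items():
            by_tuple_h[(region, i)] = by_tuple_h.get((region, i), 0.0) + fh
        for total in by_tuple_h.values():
            assert total == pytest.approx(1.0)

    def test_serialization_is_deterministic(self, tmp_path, separating_fixture, tiny_catalog):
        dmas, labels = separating_fixture
        paths = []
        for i in range(2):
            model = mine_patterns(dmas, labels, tiny_catalog, k=3, delta_min=0.5)
            p = tmp_path / f"m{i}.json"
            uio.save_model(p, model)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_max_patterns_truncates_by_weight(self, separating_fixture, tiny_catalog):
        dmas, labels = separating_fixture
        model = mine_patterns(dmas, labels, tiny_catalog, delta_min=0.1,
                              max_patterns_per_class=1)
        assert len(model.healthy_patterns) <= 1
        assert len(model.cancer_patterns) <= 1


class TestScoring:
    def test_derived_seventh_sample_scores(self, separating_model, separating_fixture):
        dmas, _ = separating_fixture
        extra = DMASMatrix(
            ["x"], dmas.window_ids, np.array([[0.3, 0.3, 0.5, 0.9, 0.1]])
        )
        scored = score_samples(separating_model, extra)
        assert scored.loc[0, "h_score"] == pytest.approx(1.0)
        assert scored.loc[0, "c_score"] == pytest.approx(0.0)
        assert scored.loc[0, "d_score"] == pytest.approx(1.0)

    def test_empty_model_scores_zero(self, separating_fixture, tiny_catalog):
        from urodmas import PatternModel

        dmas, _ = separating_fixture
        scored = score_samples(PatternModel(3, 0.5, 2000), dmas)
        assert (scored[["h_score", "c_score", "d_score"]] == 0).all().all()

    def test_d_is_h_minus_c_exactly(self, separating_model, separating_fixture):
        dmas, _ = separating_fixture
        scored = score_samples(separating_model, dmas)
        np.testing.assert_array_equal(
            scored["d_score"], scored["h_score"] - scored["c_score"]
        )

    def test_missing_window_is_an_error_naming_it(self, separating_model, separating_fixture):
        dmas, _ = separating_fixture
        truncated = DMASMatrix(
            dmas.sample_ids, dmas.window_ids[:-1], dmas.values[:, :-1]
        )
        with pytest.raises(ValidationError, match="rB.2"):
            score_samples(separating_model, truncated)

    def test_extra_healthy_match_never_decreases_h_or_d(self, separating_fixture, tiny_catalog):
        dmas, labels = separating_fixture
        model = mine_patterns(dmas, labels, tiny_catalog, delta_min=0.3)
        assert len(model.healthy_patterns) >= 1
        target = model.healthy_patterns[0]
        cols = [dmas.window_ids.index(w) for w in target.feature.window_ids]
        # sample currently NOT matching the healthy pattern: a cancer row
        base = score_samples(model, dmas)
        row = dmas.sample_ids.index("c0")
        values = dmas.values.copy()
        # impose the healthy-specific ordering on the target tuple
        values[row, cols] = np.argsort(target.permutation) / 10.0
        bumped = score_samples(
            model, DMASMatrix(dmas.sample_ids, dmas.window_ids, values)
        )
        assert bumped.loc[row, "h_score"] >= base.loc[row, "h_score"]


class TestNormalizeAndClassify:
    def test_unit_variance_example(self, separating_fixture):
        import pandas as pd

        scores = pd.DataFrame(
            {"sample_id": list("abc"), "h_score": 0.0, "c_score": 0.0,
             "d_score": [1.0, 2.0, 3.0], "z": np.nan}
        )
        z = normalize_scores(scores)["z"].to_numpy()
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])

    def test_degenerate_batch_maps_to_zero(self):
        import pandas as pd

        scores = pd.DataFrame(
            {"sample_id": ["a", "b"], "h_score": 0.0, "c_score": 0.0,
             "d_score": [5.0, 5.0], "z": np.nan}
        )
        np.testing.assert_array_equal(normalize_scores(scores)["z"], [0.0, 0.0])

    def test_two_sample_standardization(self):
        import pandas as pd

        scores = pd.DataFrame(
            {"sample_id": ["a", "b"], "h_score": 0.0, "c_score": 0.0,
             "d_score": [0.0, 4.0], "z": np.nan}
        )
        z = normalize_scores(scores)["z"].to_numpy()
        np.testing.assert_allclose(z, [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_single_sample_batch_rejected(self):
        import pandas as pd

        scores = pd.DataFrame(
            {"sample_id": ["a"], "h_score": 0.0, "c_score": 0.0,
             "d_score": [1.0], "z": np.nan}
        )
        with pytest.raises(ValidationError):
            normalize_scores(scores)

    @pytest.mark.parametrize(
        "z,cutoff,expected",
        [(0.3, 0.0, "healthy"), (0.0, 0.0, "cancer"), (-2.0, 0.0, "cancer"),
         (1.1, 1.1, "cancer"), (1.2, 1.1, "healthy")],
    )
    def test_classify_boundary_goes_to_risk_class(self, z, cutoff, expected):
        assert classify(z, cutoff) == expected
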