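"""Sweep accounting, contribution metrics, verdicts and metric properties."""

import dataclasses
import json

import numpy as np
import pytest

from modcontrib import (
    DegenerateReportError,
    DistanceAccumulator,
    EngineConfig,
    EngineError,
    FixtureSpec,
    ModalityDescriptor,
    MultimodalSample,
    build_report,
    class_resolved_importance,
    classify_collapse,
    is_degenerate,
    make_fixture,
    modality_contribution,
    overall_patch_contribution,
    patch_importance,
    per_sample_contribution,
    run_sweep,
)
from modcontrib.reference import naive_contribution


def two_modality_inputs():
    """One sample, tabular h=2 + text h=3."""
    descs = [
        ModalityDescriptor(
            "tab", "tabular", mask_strategy="zero",
            feature_kinds=("continuous", "continuous"),
        ),
        ModalityDescriptor("txt", "text", mask_strategy="remove"),
    ]
    sample = MultimodalSample(
        "s0", {"tab": np.array([1.0, 2.0]), "txt": ["a", "b", "c"]}
    )
    return descs, [sample]


class CountingPredictor:
    def __init__(self, fn):
        self.fn = fn
        self.n_calls = 0

    def __call__(self, sample):
        self.n_calls += 1
        return self.fn(sample)


def test_sweep_makes_exactly_one_plain_and_one_masked_call_per_part():
    descs, dataset = two_modality_inputs()
    predictor = CountingPredictor(
        lambda s: np.array([s.parts["tab"].sum() + len(s.parts["txt"])])
    )
    run_sweep(predictor, dataset, descs)
    assert predictor.n_calls == 1 + (2 + 3)


def test_ignored_modality_accumulates_exactly_zero():
    descs, dataset = two_modality_inputs()
    predictor = lambda s: np.array([s.parts["tab"].sum()])  # ignores text
    acc = run_sweep(predictor, dataset, descs)
    assert acc.part_class_sums["txt"].sum() == 0.0
    m = modality_contribution(acc)
    np.testing.assert_array_equal(m, [1.0, 0.0])


def manual_accumulator(totals_per_modality):
    """Accumulator with one part per modality and given class-summed totals."""
    names = [f"m{i}" for i in range(len(totals_per_modality))]
    acc = DistanceAccumulator(names, n_classes=1)
    acc.add_sample("s0", {n: np.array([[t]]) for n, t in zip(names, totals_per_modality)})
    return acc


def test_contribution_arithmetic_matches_direct_normalization():
    acc = manual_accumulator([0.3, 0.1])
    np.testing.assert_allclose(modality_contribution(acc), [0.75, 0.25], atol=1e-6)


def test_all_zero_distances_flagged_degenerate_not_uniform():
    acc = manual_accumulator([0.0, 0.0, 0.0])
    m = modality_contribution(acc)
    np.testing.assert_array_equal(m, np.zeros(3))
    assert is_degenerate(acc)
    report = build_report(acc)
    assert report.degenerate and report.verdict.label == "degenerate"
    with pytest.raises(DegenerateReportError):
        overall_patch_contribution(report)


def test_single_nonzero_modality_takes_all_contribution():
    acc = manual_accumulator([0.7, 0.0, 0.0])
    np.testing.assert_allclose(modality_contribution(acc), [1.0, 0.0, 0.0])


def test_patch_importance_single_part_and_symmetry():
    acc = DistanceAccumulator(["m"], n_classes=1)
    acc.add_sample("s0", {"m": np.full((7, 1), 0.2)})
    np.testing.assert_allclose(patch_importance(acc, "m"), np.full(7, 1 / 7))
    single = DistanceAccumulator(["m"], n_classes=2)
    single.add_sample("s0", {"m": np.array([[0.1, 0.4]])})
    np.testing.assert_allclose(patch_importance(single, "m"), [1.0])


def test_per_sample_contribution_and_global_average():
    acc = DistanceAccumulator(["a", "b"], n_classes=1)
    acc.add_sample("s0", {"a": np.array([[1.0]]), "b": np.array([[0.0]])})
    acc.add_sample("s1", {"a": np.array([[0.0]]), "b": np.array([[1.0]])})
    np.testing.assert_array_equal(per_sample_contribution(acc, 0), [1.0, 0.0])
    np.testing.assert_array_equal(per_sample_contribution(acc, 1), [0.0, 1.0])
    np.testing.assert_allclose(modality_contribution(acc), [0.5, 0.5])


def test_single_sample_dataset_per_sample_equals_global(additive_fixture):
    spec = dataclasses.replace(additive_fixture.spec, n_samples=1)
    fx = make_fixture(spec)
    acc = run_sweep(fx.predictor, fx.samples, fx.descs, fx.stats)
    np.testing.assert_allclose(
        per_sample_contribution(acc, 0), modality_contribution(acc), atol=1e-15
    )


@pytest.mark.parametrize(
    "m, expected_label, expected_dominant",
    [
        ([0.00, 1.00], "collapse", "b"),
        ([0.92, 0.08], "tendency", "a"),
        ([0.5, 0.5], "balanced", "a"),
        ([0.96, 0.04], "collapse", "a"),
        ([0.89, 0.11], "balanced", "a"),
    ],
)
def test_collapse_classification_thresholds(m, expected_label, expected_dominant):
    verdict = classify_collapse(np.array(m), ["a", "b"])
    assert verdict.label == expected_label
    assert verdict.dominant == expected_dominant


def test_collapse_thresholds_configurable_and_validated():
    cfg = EngineConfig(collapse_threshold=0.99, tendency_threshold=0.85)
    assert classify_collapse(np.array([0.98, 0.02]), config=cfg).label == "tendency"
    with pytest.raises(ValueError):
        EngineConfig(collapse_threshold=0.9, tendency_threshold=0.95)
    with pytest.raises(ValueError):
        EngineConfig(epsilon=0.0)


def test_class_resolved_importance_modes():
    acc = DistanceAccumulator(["m"], n_classes=2)
    acc.add_sample("s0", {"m": np.array([[1.0, 0.0], [0.0, 3.0]])})
    np.testing.assert_allclose(class_resolved_importance(acc, "m", "mean"), [0.25, 0.75])
    np.testing.assert_allclose(class_resolved_importance(acc, "m", "max"), [0.25, 0.75])
    np.testing.assert_allclose(class_resolved_importance(acc, "m", 0), [1.0, 0.0])
    np.testing.assert_allclose(class_resolved_importance(acc, "m", "class:1"), [0.0, 1.0])
    with pytest.raises(ValueError):
        class_resolved_importance(acc, "m", 2)


def test_single_class_output_makes_all_modes_agree():
    acc = DistanceAccumulator(["m"], n_classes=1)
    acc.add_sample("s0", {"m": np.array([[0.2], [0.6]])})
    for mode in ("mean", "max", 0):
        np.testing.assert_allclose(
            class_resolved_importance(acc, "m", mode), [0.25, 0.75]
        )


def test_two_class_separable_maps_concentrate_per_class():
    fx = make_fixture(FixtureSpec(seed=5, n_samples=4, family="two_class_separable"))
    acc = run_sweep(fx.predictor, fx.samples, fx.descs, fx.stats)
    class0 = class_resolved_importance(acc, "image", 0)
    class1 = class_resolved_importance(acc, "image", 1)
    assert class0[0] == pytest.approx(1.0) and class0[1] == pytest.approx(0.0)
    assert class1[1] == pytest.approx(1.0) and class1[0] == pytest.approx(0.0)


# -- predictor-contract violations ------------------------------------------


def test_wrong_length_output_aborts_naming_the_sample():
    descs, dataset = two_modality_inputs()

    calls = {"n": 0}

    def flaky(sample):
        calls["n"] += 1
        return np.zeros(1 if calls["n"] == 1 else 2)

    with pytest.raises(EngineError, match="s0"):
        run_sweep(flaky, dataset, descs)


def test_non_finite_output_aborts():
    descs, dataset = two_modality_inputs()
    with pytest.raises(EngineError, match="non-finite"):
        run_sweep(lambda s: np.array([np.nan]), dataset, descs)


def test_empty_dataset_rejected():
    descs, _ = two_modality_inputs()
    with pytest.raises(EngineError):
        run_sweep(lambda s: np.zeros(1), [], descs)


# -- metric properties -------------------------------------------------------


def sweep_report(fx, config=None, scale=1.0, order=None):
    samples = fx.samples if order is None else [fx.samples[i] for i in order]
    predictor = (
        fx.predictor if scale == 1.0 else (lambda s, p=fx.predictor: scale * p(s))
    )
    acc = run_sweep(predictor, samples, fx.descs, fx.stats, config)
    return build_report(acc, fx.descs, config)


def test_scale_invariance_of_contributions_and_verdict(additive_fixture):
    base = sweep_report(additive_fixture)
    scaled = sweep_report(additive_fixture, scale=3.7)
    np.testing.assert_allclose(scaled.m, base.m, atol=1e-9)
    for name in base.modalities:
        np.testing.assert_allclose(scaled.mp[name], base.mp[name], atol=1e-9)
    assert scaled.verdict.label == base.verdict.label


def test_sample_permutation_invariance(additive_fixture):
    base = sweep_report(additive_fixture)
    n = len(additive_fixture.samples)
    permuted = sweep_report(additive_fixture, order=list(reversed(range(n))))
    # accumulation order differs, so agreement is to float addition accuracy
    np.testing.assert_allclose(permuted.m, base.m, rtol=0, atol=1e-12)
    for name in base.modalities:
        np.testing.assert_allclose(permuted.mp[name], base.mp[name], rtol=0, atol=1e-12)


def test_batch_size_independence(additive_fixture):
    base = sweep_report(additive_fixture, EngineConfig(batch_size=1))
    for batch in (2, 3, 64):
        other = sweep_report(additive_fixture, EngineConfig(batch_size=batch))
        np.testing.assert_array_equal(other.m, base.m)
        for name in base.modalities:
            np.testing.assert_array_equal(other.mp[name], base.mp[name])


def test_repeated_runs_are_bit_identical(additive_fixture):
    first = sweep_report(additive_fixture).to_json()
    second = sweep_report(additive_fixture).to_json()
    assert first == second


def test_normalization_identities(additive_fixture):
    report = sweep_report(additive_fixture)
    assert report.m.sum() == pytest.approx(1.0, abs=1e-9)
    for name in report.modalities:
        assert report.mp[name].sum() == pytest.approx(1.0, abs=1e-9)
    total = sum(w.sum() for w in report.weighted.values())
    assert total == pytest.approx(1.0, abs=1e-9)
    assert overall_patch_contribution(report).keys() == report.mp.keys()


def test_engine_matches_naive_oracle_and_closed_form(additive_fixture):
    fx = additive_fixture
    acc = run_sweep(fx.predictor, fx.samples, fx.descs, fx.stats)
    report = build_report(acc, fx.descs)
    m_naive, mp_naive = naive_contribution(fx.predictor, fx.samples, fx.descs, fx.stats)
    np.testing.assert_allclose(report.m, m_naive, rtol=0, atol=1e-12)
    for name in report.modalities:
        np.testing.assert_allclose(report.mp[name], mp_naive[name], rtol=0, atol=1e-12)
    np.testing.assert_allclose(report.m, fx.predictor.expected_m, atol=1e-9)
    for name in report.modalities:
        np.testing.assert_allclose(
            report.mp[name], fx.predictor.expected_mp[name], atol=1e-9
        )


def test_report_json_round_trip_carries_key_fields(additive_fixture):
    report = sweep_report(additive_fixture)
    doc = json.loads(report.to_json())
    assert doc["modalities"] == report.modalities
    np.testing.assert_allclose(doc["m"], report.m)
    assert doc["verdict"]["label"] == report.verdict.label
    assert set(doc["h"]) == set(report.modalities)
    rows = report.csv_rows()
    assert len(rows) == sum(report.h.values())
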