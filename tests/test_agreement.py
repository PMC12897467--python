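"""Unmeasured-ion classification, Cohen's kappa and the agreement report."""

import numpy as np
import pandas as pd
import pytest

from acidbase.agreement import (
    CATEGORIES,
    ReferenceBands,
    agreement_report,
    classify_ui_status,
    cohen_kappa,
)


def brute_force_kappa(table):
    """Independent p_o/p_e arithmetic, element by element."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    po = sum(table[i, i] for i in range(3)) / n
    pe = 0.0
    for i in range(3):
        row = sum(table[i, j] for j in range(3))
        col = sum(table[j, i] for j in range(3))
        pe += (row / n) * (col / n)
    return (po - pe) / (1 - pe)


@pytest.mark.parametrize(
    "value, index, expected",
    [
        (14.0, "agc", "normal"),
        (20.0, "agc", "UA_acidosis"),
        (5.0, "agc", "UC_alkalosis"),
        (0.0, "sig", "normal"),
        (3.0, "sig", "UA_acidosis"),
        (-3.0, "sig", "UC_alkalosis"),
        (-16.0, "begap", "UA_acidosis"),
        (3.0, "begap", "UC_alkalosis"),
        (1.0, "begap", "normal"),
    ],
)
def test_classification_rules(value, index, expected):
    assert classify_ui_status(value, index) == expected


def test_sig_center_is_normal_for_any_tolerance():
    for tol in (0.0, 0.5, 5.0):
        assert classify_ui_status(0.0, "sig", ReferenceBands(tolerance=tol)) == "normal"


def test_unknown_index_rejected():
    with pytest.raises(ValueError, match="unknown index"):
        classify_ui_status(1.0, "ag")


def test_every_value_gets_exactly_one_category():
    values = np.linspace(-30, 30, 501)
    for index in ("agc", "sig", "begap"):
        labels = classify_ui_status(values, index)
        assert set(labels) <= set(CATEGORIES)
        assert len(labels) == len(values)


def test_kappa_perfect_and_chance_agreement():
    assert cohen_kappa(np.diag([10, 20, 30])) == pytest.approx(1.0)
    margins_a, margins_b = np.array([0.5, 0.3, 0.2]), np.array([0.2, 0.5, 0.3])
    independent = 1000 * np.outer(margins_a, margins_b)
    assert cohen_kappa(independent) == pytest.approx(0.0, abs=1e-12)


def test_kappa_matches_brute_force_oracle():
    table = [[20, 5, 0], [10, 50, 5], [0, 5, 5]]
    assert cohen_kappa(table) == pytest.approx(brute_force_kappa(table), abs=1e-12)
    rng = np.random.default_rng(12345)
    for _ in range(100):
        random_table = rng.integers(0, 40, size=(3, 3))
        if random_table.sum() == 0:
            continue
        assert cohen_kappa(random_table) == pytest.approx(
            brute_force_kappa(random_table), abs=1e-12
        )


def test_kappa_degenerate_and_invalid_tables():
    single_category = np.zeros((3, 3))
    single_category[0, 0] = 42
    assert cohen_kappa(single_category) == 0.0
    with pytest.raises(ValueError):
        cohen_kappa(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        cohen_kappa([[1, 2], [3, 4], [5, 6]])


def test_kappa_invariant_under_simultaneous_permutation():
    rng = np.random.default_rng(7)
    table = rng.integers(1, 30, size=(3, 3))
    perm = [2, 0, 1]
    assert cohen_kappa(table[np.ix_(perm, perm)]) == pytest.approx(cohen_kappa(table))


def _panel_frame(agc, sig, begap):
    return pd.DataFrame({"agc": agc, "sig": sig, "begap": begap})


def test_report_linear_indices_and_identical_labels():
    rng = np.random.default_rng(0)
    sig = rng.normal(0, 4, 400)
    panels = _panel_frame(agc=12 + sig, sig=sig, begap=-sig)
    report = agreement_report(panels)
    assert report.pearson.loc["sig", "begap"] == pytest.approx(-1.0)
    # sig and begap carry identical information and the same band half-width,
    # with mirrored sign conventions: identical classifications, kappa 1
    assert report.kappa[("sig", "begap")] == pytest.approx(1.0)
    for tab in report.crosstabs.values():
        assert tab.values.sum() == 400


def test_report_constant_column_reported_missing():
    panels = _panel_frame(agc=np.full(50, 12.0), sig=np.linspace(-3, 3, 50),
                          begap=np.linspace(3, -3, 50))
    with pytest.warns(UserWarning, match="constant column"):
        report = agreement_report(panels)
    assert np.isnan(report.pearson.loc["agc", "sig"])


def test_report_requires_two_patients():
    with pytest.raises(ValueError):
        agreement_report(_panel_frame([1.0], [1.0], [1.0]))


def test_correlation_agreement_dissociation():
    """Shifted centers: |r| stays 1 while kappa collapses — the clinical point."""
    rng = np.random.default_rng(3)
    x = rng.normal(0, 5, 1000)
    panels = _panel_frame(agc=12 + x, sig=x, begap=-x + 6.0)
    report = agreement_report(panels)
    assert abs(report.pearson.loc["sig", "begap"]) > 0.99
    assert report.kappa[("sig", "begap")] < 0.5


def test_reclassification_counts_conditioned_on_normal_agc(default_panels):
    report = agreement_report(default_panels)
    n_agc_normal = int(
        ((default_panels["agc"] >= 7) & (default_panels["agc"] <= 17)).sum()
    )
    for other in ("sig", "begap"):
        assert sum(report.reclass_counts[other].values()) == n_agc_normal


def test_synthetic_cohort_reproduces_published_sign_pattern(default_panels):
    report = agreement_report(default_panels)
    assert report.pearson.loc["agc", "begap"] < 0
    assert report.pearson.loc["sig", "begap"] < 0
    assert report.pearson.loc["agc", "sig"] > 0


def test_bands_validation():
    with pytest.raises(ValueError):
        ReferenceBands(agc_normal=(17.0, 7.0))
    with pytest.raises(ValueError):
        ReferenceBands(tolerance=-1.0)
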