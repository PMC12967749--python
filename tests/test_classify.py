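"""Limitation taxonomy: decision rules, roll-up, cohort summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import colimstat.classify as cl
from colimstat import (
    Thresholds,
    biomass_from_frame,
    classify_combination,
    classify_stream,
    compute_all_ratios,
    rr_to_percent,
    summarize_cohort,
)
from colimstat.synthetic import SyntheticScenario, SyntheticCohort, generate_biomass, mean_surface
from colimstat.design import design_for_year
from conftest import make_biomass_frame


# ---------------------------------------------------------------------------
# independent decision-table oracle: a literal, flat re-statement of the rules
# ---------------------------------------------------------------------------

def oracle_category(rr_a, rr_b, rr_ab, th):
    stim_a = rr_a > th
    stim_b = rr_b > th
    if stim_a and stim_b:
        return "independent_colimitation"
    if stim_a and not stim_b:
        if rr_ab - rr_a > th:
            return "serial_limitation"
        return "single_limitation"
    if stim_b and not stim_a:
        if rr_ab - rr_b > th:
            return "serial_limitation"
        return "single_limitation"
    if rr_ab > th:
        return "simultaneous_colimitation"
    if rr_a < -th or rr_b < -th or rr_ab < -th:
        return "negative_response"
    return "no_response"


def oracle_interaction(irr, th_i):
    if irr is None or (isinstance(irr, float) and math.isnan(irr)):
        return "not_applicable"
    if irr > th_i:
        return "super_additive"
    if irr < -th_i:
        return "sub_additive"
    return "additive"


def test_decision_table_agrees_with_oracle_on_dense_grid(thresholds):
    rng = np.random.default_rng(2024)
    n = 20_000
    rr_a = rng.uniform(-1.5, 1.5, n)
    rr_b = rng.uniform(-1.5, 1.5, n)
    rr_ab = rng.uniform(-1.5, 2.5, n)
    irr = rng.uniform(-1.5, 1.5, n)
    irr[rng.random(n) < 0.05] = np.nan
    for i in range(n):
        got = classify_combination(rr_a[i], rr_b[i], rr_ab[i], float(irr[i]), thresholds)
        assert got.category == oracle_category(rr_a[i], rr_b[i], rr_ab[i], thresholds.theta_single)
        assert got.interaction_class == oracle_interaction(float(irr[i]), thresholds.theta_interaction)


def test_every_category_is_reachable(thresholds):
    cases = {
        (0.9, 0.9, 1.8): "independent_colimitation",
        (0.9, 0.1, 1.0): "single_limitation",
        (0.5, 0.1, 0.95): "serial_limitation",
        (0.05, 0.02, 0.8): "simultaneous_colimitation",
        (-0.5, 0.1, 0.0): "negative_response",
        (0.1, 0.1, 0.1): "no_response",
    }
    seen = set()
    for (a, b, ab), expected in cases.items():
        got = classify_combination(a, b, ab, 0.0, thresholds)
        assert got.category == expected
        seen.add(got.category)
    assert seen == set(cl.CATEGORIES)


def test_spec_branch_examples(thresholds):
    lab = classify_combination(0.9, 0.1, 1.0, 0.05, thresholds, a_elements=("N",), b_elements=("P",))
    assert lab.category == cl.SINGLE_LIMITATION
    assert lab.elements == ("N",)
    assert lab.interaction_class == cl.ADDITIVE

    lab = classify_combination(0.05, 0.02, 0.8, 0.8, thresholds)
    assert lab.category == cl.SIMULTANEOUS_COLIMITATION
    assert lab.interaction_class == cl.SUPER_ADDITIVE

    lab = classify_combination(0.5, 0.1, 0.95, 0.0, thresholds, a_elements=("A",), b_elements=("B",))
    assert lab.category == cl.SERIAL_LIMITATION
    assert lab.primary == ("A",) and lab.secondary == "B"


def test_strict_inequality_at_threshold(thresholds):
    lab = classify_combination(0.326, 0.0, 0.326, 0.0, thresholds)
    assert lab.category == cl.NO_RESPONSE
    lab = classify_combination(0.385, 0.385, 0.77, 0.385, thresholds)
    assert lab.category == cl.INDEPENDENT_COLIMITATION
    assert lab.interaction_class == cl.ADDITIVE


@given(
    st.lists(st.floats(min_value=-1.2, max_value=1.2), min_size=3, max_size=3),
    st.floats(min_value=0.05, max_value=0.5),
    st.floats(min_value=0.05, max_value=1.0),
)
@settings(max_examples=200)
def test_threshold_monotonicity_of_stimulation_driven_labels(rrs, theta_lo, delta):
    """Raising theta_single never adds elements limited through their own
    stimulation (single, serial-primary, independent).

    The simultaneous branch is excluded by design: a combined-only response
    is reclassified from single to simultaneous when the responding single
    drops below a raised threshold, so full-label monotonicity cannot hold.
    """
    rr_a, rr_b, rr_ab = rrs
    lo = classify_combination(rr_a, rr_b, rr_ab, 0.0, Thresholds(theta_lo, 0.385))
    hi = classify_combination(rr_a, rr_b, rr_ab, 0.0, Thresholds(theta_lo + delta, 0.385))

    def limited(lab):
        if lab.category in (cl.SINGLE_LIMITATION, cl.INDEPENDENT_COLIMITATION):
            return set(lab.elements)
        if lab.category == cl.SERIAL_LIMITATION:
            return set(lab.primary)
        return set()

    assert limited(hi) <= limited(lo)


def _classify_scenario(scenario, year=2022, stream="S1"):
    design = design_for_year(year)
    cohort = SyntheticCohort([(stream, scenario)], design, seed=0)
    table = generate_biomass(cohort)
    rs = compute_all_ratios(table)[(stream, "chl_a")]
    return classify_stream(rs, design=design)


def test_independent_n_fe_rolls_up_both_elements():
    sc = SyntheticScenario(cl.INDEPENDENT_COLIMITATION, ("N", "Fe"), sigma_log=0.0)
    c = _classify_scenario(sc)
    assert c.element_status["N"] == cl.LIMITED
    assert c.element_status["Fe"] == cl.LIMITED
    assert c.element_status["Zn"] == cl.NONE


def test_simultaneous_only_signal_counts_both_elements(thresholds, design2022):
    """RR_NP above threshold with both singles below -> both N and P limited."""
    means = {t.label: 2.0 for t in design2022.treatments}
    means["N+P"] = 2.0 * math.exp(0.9)
    means["N+P+Fe"] = means["N+P"]
    table = biomass_from_frame(make_biomass_frame(means), design2022)
    rs = compute_all_ratios(table)[("S1", "chl_a")]
    c = classify_stream(rs, thresholds, design2022)
    assert c.element_status["N"] == cl.LIMITED
    assert c.element_status["P"] == cl.LIMITED
    labels = {lab.contrast: lab.category for lab in c.labels}
    assert labels["NxP"] == cl.SIMULTANEOUS_COLIMITATION


def test_all_ratios_below_threshold_all_none(flat_table_2022, design2022):
    rs = compute_all_ratios(flat_table_2022)[("S1", "chl_a")]
    c = classify_stream(rs, design=design2022)
    assert all(v == cl.NONE for v in c.element_status.values())
    assert not c.any_limited


def test_serial_secondary_never_counted_limited():
    sc = SyntheticScenario(cl.SERIAL_LIMITATION, ("N", "Fe"), sigma_log=0.0)
    c = _classify_scenario(sc)
    assert c.element_status["N"] == cl.LIMITED
    assert c.element_status["Fe"] == cl.SERIAL_SECONDARY
    # the serial combination never appears among co-limitation combos
    assert all("Fe" not in combo or "N" not in combo for combo in c.colimitation_combos)


def test_negative_response_does_not_erase_limitation(design2022, thresholds):
    """An element can respond negatively alone yet be co-limited elsewhere."""
    means = {t.label: 2.0 for t in design2022.treatments}
    means["N"] = 2.0 * math.exp(-0.6)  # negative single response
    means["N+P"] = 2.0 * math.exp(0.9)  # simultaneous N-P signal
    means["N+P+Fe"] = means["N+P"]
    table = biomass_from_frame(make_biomass_frame(means), design2022)
    c = classify_stream(compute_all_ratios(table)[("S1", "chl_a")], thresholds, design2022)
    assert c.element_status["N"] == cl.LIMITED


def test_rollup_purity():
    sc = SyntheticScenario(cl.SERIAL_LIMITATION, ("N", "Fe"), sigma_log=0.0)
    c = _classify_scenario(sc)
    recomputed = cl.roll_up_status(
        c.labels, c.added, c.single_rrs, c.thresholds, c.element_status.keys()
    )
    assert recomputed == c.element_status


def test_added_element_colimitation_requires_base_response(design2022, thresholds):
    means = {t.label: 2.0 for t in design2022.treatments}
    means["P+Fe+Mo"] = 2.0 * math.exp(0.6)  # Mo adds growth, but P+Fe itself flat
    table = biomass_from_frame(make_biomass_frame(means), design2022)
    c = classify_stream(compute_all_ratios(table)[("S1", "chl_a")], thresholds, design2022)
    assert c.element_status["Mo"] == cl.NONE

    means["P+Fe"] = 2.0 * math.exp(0.9)
    means["P+Fe+Mo"] = means["P+Fe"] * math.exp(0.6)
    table = biomass_from_frame(make_biomass_frame(means), design2022)
    c = classify_stream(compute_all_ratios(table)[("S1", "chl_a")], thresholds, design2022)
    assert c.element_status["Mo"] == cl.LIMITED
    assert ("P", "Fe", "Mo") in c.colimitation_combos


@pytest.mark.parametrize(
    "rr,expected,places",
    [(0.326, 38.5, 1), (0.0, 0.0, 6), (-math.log(2), -50.0, 6)],
)
def test_rr_to_percent(rr, expected, places):
    assert round(rr_to_percent(rr), places) == pytest.approx(expected)


def test_rr_to_percent_median_n_response():
    # median N-limited RR of 0.89 prints as +144%
    assert round(rr_to_percent(0.89)) == 144


def _cohort_of(n_limited, n_total, year=2022):
    """Cohort with `n_limited` single-N streams and the rest unresponsive."""
    design = design_for_year(year)
    streams = []
    for i in range(n_total):
        if i < n_limited:
            sc = SyntheticScenario(cl.SINGLE_LIMITATION, ("N",), sigma_log=0.0)
        else:
            sc = SyntheticScenario(cl.NO_RESPONSE, sigma_log=0.0)
        streams.append((f"S{i:03d}", sc))
    cohort = SyntheticCohort(streams, design, seed=0)
    table = generate_biomass(cohort)
    ratio_sets = compute_all_ratios(table)
    return [classify_stream(rs, design=design) for rs in ratio_sets.values()]


def test_cohort_percent_arithmetic():
    summary = summarize_cohort(_cohort_of(30, 40))
    row = summary.element_summary.set_index("element").loc["N"]
    assert row["n_limited"] == 30
    assert row["pct_limited"] == pytest.approx(75.0)
    assert row["n_single_stimulated"] == 30
    assert summary.pct_any_response == pytest.approx(75.0)


def test_cohort_median_rr_matches_sort_oracle():
    cls = _cohort_of(7, 10)
    summary = summarize_cohort(cls)
    rrs = sorted(
        c.single_rrs["N"] for c in cls if c.element_status["N"] == cl.LIMITED
    )
    expected = rrs[len(rrs) // 2] if len(rrs) % 2 else 0.5 * (rrs[len(rrs) // 2 - 1] + rrs[len(rrs) // 2])
    row = summary.element_summary.set_index("element").loc["N"]
    assert row["median_rr"] == pytest.approx(expected, abs=1e-12)


def test_interaction_class_distribution_all_super():
    design = design_for_year(2022)
    streams = [
        (f"S{i}", SyntheticScenario(cl.SIMULTANEOUS_COLIMITATION, ("N", "P"), sigma_log=0.0))
        for i in range(5)
    ]
    table = generate_biomass(SyntheticCohort(streams, design, seed=0))
    cls = [classify_stream(rs, design=design) for rs in compute_all_ratios(table).values()]
    dist = summarize_cohort(cls).interaction_class_distribution.set_index("interaction_class")
    # joint effect e^0.89 over a flat additive expectation is super-additive
    assert dist.loc[cl.SUPER_ADDITIVE, "fraction"] == pytest.approx(1.0)


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        summarize_cohort([])
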