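"""Regeneration score: formula anchors, invariances, cohort aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselastica import (CohortSpec, MissingBaselineError, ValidationError,
                          ZeroBaselineError, cohort_rs, generate_cohort,
                          regeneration_score)

positive = st.floats(0.1, 1e3)


def test_matched_moduli_score_100_percent():
    assert regeneration_score(1.0, 1.0, 7.3, 1.0) == 100.0
    assert regeneration_score(55.0, 55.0, 400.0, 50.0) == 100.0


def test_baseline_scores_zero_percent():
    assert regeneration_score(7.3, 1.0, 7.3, 1.0) == 0.0
    assert regeneration_score(365.0, 50.0, 365.0, 50.0) == 0.0


def test_partial_regeneration_value():
    # gap shrank from 6.3 to 0.63: nine tenths of the way to native stiffness
    assert regeneration_score(1.63, 1.0, 7.3, 1.0) == pytest.approx(90.0)


def test_growing_gap_goes_negative_unclamped():
    assert regeneration_score(20.0, 1.0, 7.3, 1.0) < 0.0


def test_zero_baseline_difference_is_undefined():
    with pytest.raises(ZeroBaselineError):
        regeneration_score(2.0, 1.0, 5.0, 5.0)


def test_nonpositive_modulus_rejected():
    with pytest.raises(ValidationError, match="e_n0"):
        regeneration_score(1.0, 1.0, 2.0, -1.0)


@settings(deadline=None, max_examples=80, derandomize=True)
@given(e_t=positive, e_n=positive, e_t0=positive, e_n0=positive,
       c=st.floats(1e-2, 1e2))
def test_rs_invariant_under_common_rescaling(e_t, e_n, e_t0, e_n0, c):
    if abs(e_t0 - e_n0) < 1e-6:
        e_t0 = e_n0 + 1.0
    rs = regeneration_score(e_t, e_n, e_t0, e_n0)
    rs_scaled = regeneration_score(c * e_t, c * e_n, c * e_t0, c * e_n0)
    assert rs_scaled == pytest.approx(rs, rel=1e-9, abs=1e-7)


def test_rs_monotone_in_current_gap():
    gaps = np.linspace(0.0, 10.0, 25)
    scores = [regeneration_score(1.0 + g, 1.0, 7.3, 1.0) for g in gaps]
    assert np.all(np.diff(scores) < 0)


def _zero_noise_cohort(**kwargs):
    spec = CohortSpec(between_animal_cv=0.0, measurement_cv=0.0, seed=0, **kwargs)
    return generate_cohort(spec)


def test_cohort_rs_zero_noise_has_zero_sem():
    records, summary = cohort_rs(_zero_noise_cohort())
    assert (summary["sem"] == 0.0).all()
    assert (summary["n"] == 7).all()


def test_cohort_rs_cardinality():
    records, summary = cohort_rs(_zero_noise_cohort())
    post = records[records["timepoint_months"] > 0]
    assert post.groupby("timepoint_months").size().eq(7).all()


def test_cohort_rs_unity_ratio_scores_100():
    table = _zero_noise_cohort(timepoints=(0.0, 6.0, 12.0),
                               modulus_ratio_means=(7.3, 1.0, 1.0))
    _, summary = cohort_rs(table)
    later = summary[summary["timepoint_months"] > 0]
    np.testing.assert_allclose(later["mean"], 100.0, atol=1e-9)


def test_cohort_rs_missing_baseline_names_the_animal():
    table = _zero_noise_cohort()
    table = table[~((table["animal_id"] == "animal_03")
                    & (table["timepoint_months"] == 0.0))]
    with pytest.raises(MissingBaselineError, match="animal_03"):
        cohort_rs(table)


def test_per_animal_rs_differs_from_group_mean_plugin():
    """Mean per-animal RS is not the RS of the group-mean moduli under noise.

    With between-animal spread, averaging the nonlinear score over animals
    and plugging group means into the formula give different numbers — the
    reason group-level modulus ratios and group-level scores are not
    mutually derivable. In the zero-variance limit they coincide.
    """
    spec = CohortSpec(between_animal_cv=0.3, measurement_cv=0.2, seed=21)
    table = generate_cohort(spec)
    _, summary = cohort_rs(table)

    wide = table.pivot_table(index=["animal_id", "timepoint_months"],
                             columns="tissue", values="modulus")
    means = wide.groupby("timepoint_months").mean()
    plug = {
        tp: regeneration_score(means.loc[tp, "itev"], means.loc[tp, "native"],
                               means.loc[0.0, "itev"], means.loc[0.0, "native"])
        for tp in means.index if tp > 0
    }
    per_animal = summary.set_index("timepoint_months")["mean"]
    diffs = [abs(per_animal[tp] - plug[tp]) for tp in plug]
    assert max(diffs) > 0.5  # clearly distinct under this noise level

    # zero-variance cohort: the two routes agree exactly
    table0 = _zero_noise_cohort()
    _, summary0 = cohort_rs(table0)
    wide0 = table0.pivot_table(index=["animal_id", "timepoint_months"],
                               columns="tissue", values="modulus")
    means0 = wide0.groupby("timepoint_months").mean()
    for tp in means0.index:
        if tp == 0:
            continue
        plug0 = regeneration_score(means0.loc[tp, "itev"], means0.loc[tp, "native"],
                                   means0.loc[0.0, "itev"], means0.loc[0.0, "native"])
        assert plug0 == pytest.approx(
            summary0.set_index("timepoint_months")["mean"][tp], abs=1e-9)


def test_signed_and_absolute_scores_agree_when_itev_stiffer():
    # engineered vessel stiffer than native at both times: same score either way
    assert regeneration_score(3.0, 1.0, 7.3, 1.0, signed=True) == \
        regeneration_score(3.0, 1.0, 7.3, 1.0, signed=False)
    # crossing below native flips the signed numerator
    assert regeneration_score(0.5, 1.0, 7.3, 1.0, signed=True) != \
        regeneration_score(0.5, 1.0, 7.3, 1.0, signed=False)
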