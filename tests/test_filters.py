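"""Acceptance criteria, boost ratio, and the intensity notch."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from motifboost._rng import substream
from motifboost.filters import (
    INTENSITY_PREFIX,
    ChannelDesign,
    FilterCriteria,
    SiteQuantRecord,
    apply_acceptance_criteria,
    attrition_counts,
    boost_ratio,
    boost_ratio_column,
    ck2_design,
    count_valid_channels,
    enrichment_specificity,
    intensity_notch_threshold,
    py_design,
    records_to_frame,
)


def _record(intensities, loc=0.9, key=("P1", 10, "S")):
    return SiteQuantRecord(
        site_key=key, window="A" * 7 + "S" + "A" * 7,
        localization_probability=loc, intensities=intensities,
    )


def test_channel_design_validation():
    with pytest.raises(ValueError):
        ChannelDesign(("126", "127"), {"126": "boost", "127": "boost"}, ())
    with pytest.raises(ValueError):  # duplicate sets must partition samples
        ChannelDesign(
            ("126", "127", "128"),
            {"126": "sample:a", "127": "sample:a", "128": "boost"},
            (("126",),),
        )
    d = ck2_design()
    assert d.sample_channels == ("126", "127", "129", "130")
    assert d.boost_channels == ("128", "131")
    assert d.conditions == ("DMSO", "CKi")
    assert d.replicate_pairs("DMSO") == [("126", "128"), ("129", "131")]


def test_boost_ratio_printed_formula():
    """131 signal over the average of 127 and 129 (pY design)."""
    design = py_design()
    rec = _record({"131": 2000.0, "127": 10.0, "129": 30.0})
    assert boost_ratio(rec, design) == pytest.approx(100.0)
    assert not (boost_ratio(rec, design) < FilterCriteria().boost_ratio_max)


def test_boost_ratio_symmetry_and_undefined():
    design = ck2_design()
    equal = _record({ch: 7.0 for ch in design.channels})
    assert boost_ratio(equal, design) == pytest.approx(1.0)
    zeros = _record({"128": 5.0, "131": 5.0})
    assert boost_ratio(zeros, design) is None


def test_count_valid_channels_rules():
    rec = _record({"126": 0.0, "127": 5.0})
    assert count_valid_channels(rec, ["126", "127", "129"]) == 1
    assert count_valid_channels(rec, []) == 0
    rng = substream(3, "valid")
    design = ck2_design()
    for _ in range(100):
        intens = {ch: float(x) for ch, x in zip(design.channels, rng.integers(0, 3, 6))}
        rec = _record(intens)
        brute = sum(1 for ch in design.sample_channels if intens.get(ch, 0) > 0)
        assert count_valid_channels(rec, design.sample_channels) == brute


def _random_frame(n, seed, design):
    rng = substream(seed, "records")
    rows = {
        "protein_id": [f"P{i}" for i in range(n)],
        "position": rng.integers(1, 500, n),
        "residue": rng.choice(list("STY"), n),
        "window": "A" * 7 + "S" + "A" * 7,
        "localization_prob": rng.uniform(0, 1, n),
        "is_phosphopeptide": rng.uniform(size=n) < 0.91,
    }
    frame = pd.DataFrame(rows)
    for ch in design.channels:
        vals = np.exp2(rng.uniform(30, 50, n))
        vals[rng.uniform(size=n) < 0.25] = 0.0  # missing values
        frame[INTENSITY_PREFIX + ch] = vals
    return frame


def _naive_flags(frame, design, criteria):
    """Independent per-record reimplementation of the acceptance criteria."""
    out = []
    for _, row in frame.iterrows():
        intens = {ch: row[INTENSITY_PREFIX + ch] for ch in design.channels}
        boost = np.mean([intens[ch] for ch in design.boost_channels])
        denom = np.mean([intens[ch] for ch in design.ratio_denominator_channels()])
        pass_ratio = denom > 0 and (boost / denom) < criteria.boost_ratio_max
        total = sum(intens[ch] for ch in design.sample_channels)
        pass_intensity = total > 0 and np.log2(total) > criteria.log2_total_sample_intensity_min
        if criteria.require_valid_in_one_duplicate_set:
            pass_valid = any(
                sum(1 for ch in dset if intens[ch] > 0) >= criteria.min_valid_channels
                for dset in design.duplicate_sets
            )
        else:
            pass_valid = sum(1 for ch in design.sample_channels if intens[ch] > 0) >= criteria.min_valid_channels
        pass_loc = (not criteria.require_class1) or row["localization_prob"] > criteria.class1_min_localization
        out.append((pass_ratio, pass_intensity, pass_valid, pass_loc,
                    pass_ratio and pass_intensity and pass_valid and pass_loc))
    return pd.DataFrame(
        out, columns=["pass_boost_ratio", "pass_intensity", "pass_valid_channels", "pass_localization", "pass_all"]
    )


@pytest.mark.parametrize("per_duplicate_set", [True, False])
def test_vectorized_criteria_agree_with_naive_oracle(per_duplicate_set):
    design = ck2_design()
    criteria = FilterCriteria(require_valid_in_one_duplicate_set=per_duplicate_set)
    frame = _random_frame(500, seed=17, design=design)
    flagged = apply_acceptance_criteria(frame, design, criteria)
    naive = _naive_flags(frame, design, criteria)
    for col in naive.columns:
        assert (flagged[col].to_numpy() == naive[col].to_numpy()).all(), col


def test_strict_intensity_boundary():
    """A record at exactly 2^40 total sample intensity fails the strict '>40'."""
    design = ck2_design()
    base = {"128": 10.0, "131": 10.0}
    exact = {**base, "126": 2.0**40 / 2, "129": 2.0**40 / 2, "127": 0.0, "130": 0.0}
    above = {**base, "126": 2.0**40, "129": 2.0**40, "127": 0.0, "130": 0.0}
    frame = records_to_frame([_record(exact), _record(above)], design)
    flagged = apply_acceptance_criteria(frame, design, FilterCriteria(require_valid_in_one_duplicate_set=False))
    assert not flagged["pass_intensity"].iloc[0]
    assert flagged["pass_intensity"].iloc[1]


def test_one_valid_channel_per_duplicate_set_fails():
    design = ck2_design()
    rec = _record({"126": 5.0, "127": 0.0, "129": 5.0, "130": 0.0, "128": 10.0, "131": 10.0})
    frame = records_to_frame([rec], design)
    flagged = apply_acceptance_criteria(frame, design)
    assert not flagged["pass_valid_channels"].iloc[0]


def test_passing_record_passes_all():
    design = ck2_design()
    rec = _record(
        {"126": 2.0**40, "127": 2.0**40, "129": 2.0**39, "130": 0.0,
         "128": 2.0**42, "131": 2.0**42},
        loc=0.9,
    )
    frame = records_to_frame([rec], design)
    flagged = apply_acceptance_criteria(frame, design)
    assert flagged["pass_all"].iloc[0]
    assert flagged["boost_ratio"].iloc[0] < 100


def test_filter_idempotence_and_monotonicity():
    design = ck2_design()
    frame = _random_frame(400, seed=23, design=design)
    criteria = FilterCriteria()
    once = apply_acceptance_criteria(frame, design, criteria)
    passing = once[once["pass_all"]].drop(columns=[c for c in once.columns if c.startswith("pass_") or c in ("boost_ratio", "log2_total_sample_intensity")])
    again = apply_acceptance_criteria(passing, design, criteria)
    assert again["pass_all"].all()
    # relaxing any single threshold never decreases the passing count
    n0 = int(once["pass_all"].sum())
    for relaxed in (
        dataclasses.replace(criteria, boost_ratio_max=1e6),
        dataclasses.replace(criteria, log2_total_sample_intensity_min=1.0),
        dataclasses.replace(criteria, min_valid_channels=1),
        dataclasses.replace(criteria, require_class1=False),
    ):
        assert int(apply_acceptance_criteria(frame, design, relaxed)["pass_all"].sum()) >= n0


def test_attrition_counts_are_consistent():
    design = ck2_design()
    flagged = apply_acceptance_criteria(_random_frame(300, seed=29, design=design), design)
    att = attrition_counts(flagged)
    assert att["input"] == 300
    assert att["pass_all"] == int(flagged["pass_all"].sum())
    assert att["pass_all"] <= att["input"] - max(
        att["fail_boost_ratio"], att["fail_intensity"], att["fail_valid_channels"], att["fail_localization"]
    )


def test_enrichment_specificity_definition():
    frame = pd.DataFrame({"is_phosphopeptide": [True] * 91 + [False] * 9})
    assert enrichment_specificity(frame) == pytest.approx(0.91)
    assert enrichment_specificity(pd.DataFrame({"is_phosphopeptide": [True] * 5})) == 1.0
    assert enrichment_specificity(pd.DataFrame({"is_phosphopeptide": [False] * 5})) == 0.0
    assert np.isnan(enrichment_specificity(pd.DataFrame({"is_phosphopeptide": []})))


def test_boost_ratio_column_matches_record_level():
    design = ck2_design()
    frame = _random_frame(200, seed=31, design=design)
    col = boost_ratio_column(frame, design)
    for i in range(len(frame)):
        rec = _record({ch: frame[INTENSITY_PREFIX + ch].iloc[i] for ch in design.channels})
        expected = boost_ratio(rec, design)
        if expected is None:
            assert np.isnan(col.iloc[i])
        else:
            assert col.iloc[i] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# notch threshold


def _analytic_crossing(w1, mu1, sd1, w2, mu2, sd2):
    def diff(x):
        return w1 * stats.norm.pdf(x, mu1, sd1) - w2 * stats.norm.pdf(x, mu2, sd2)

    return optimize.brentq(diff, mu1, mu2)


def test_notch_threshold_matches_mixture_crossing_oracle():
    rng = substream(41, "mixture")
    n = 5000
    w1 = 0.45
    n1 = int(n * w1)
    values = np.concatenate([rng.normal(35, 1.0, n1), rng.normal(43, 1.5, n - n1)])
    found = intensity_notch_threshold(values)
    expected = _analytic_crossing(w1, 35, 1.0, 1 - w1, 43, 1.5)
    assert found is not None
    assert abs(found - expected) < 1.0


def test_notch_threshold_unimodal_returns_none():
    rng = substream(43, "unimodal")
    assert intensity_notch_threshold(rng.normal(40, 1.0, 5000)) is None


def test_notch_threshold_translation_equivariance():
    rng = substream(47, "shift")
    values = np.concatenate([rng.normal(35, 1.0, 2000), rng.normal(43, 1.5, 3000)])
    t0 = intensity_notch_threshold(values)
    t5 = intensity_notch_threshold(values + 5.0)
    assert abs((t5 - 5.0) - t0) < 0.1
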