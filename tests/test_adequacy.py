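"""EAR cut-point prevalences and the stratified adequacy report."""

import numpy as np
import pandas as pd
import pytest

import saltfort as sf
from saltfort.adequacy import EmptyStratumError

from conftest import toy_participants


def test_counting_prevalences():
    assert sf.prevalence_inadequate([5, 6, 7], 4.0) == 0.0
    assert sf.prevalence_inadequate([1, 2, 3, 9], 4.0) == 75.0
    assert sf.prevalence_excess([1, 2, 3], 10.0) == 0.0
    assert sf.prevalence_excess([1] * 19 + [99], 10.0) == 5.0


def test_ties_count_as_adequate_and_not_excess():
    """Strict inequalities at the cutoffs."""
    assert sf.prevalence_inadequate([4.0, 4.0], 4.0) == 0.0
    assert sf.prevalence_excess([10.0, 10.0], 10.0) == 0.0


def test_empty_stratum_is_an_error_not_zero():
    with pytest.raises(EmptyStratumError):
        sf.prevalence_inadequate([], 4.0)
    with pytest.raises(EmptyStratumError):
        sf.prevalence_excess([], 4.0)


@pytest.mark.parametrize("mu, sigma, cutoff", [
    (np.log(6.9), 0.5, 9.9),
    (np.log(2.5), 0.5, 3.6),
    (np.log(159.0), 0.7, 320.0),
])
def test_cutpoint_matches_lognormal_closed_form(mu, sigma, cutoff):
    """Empirical cut-point vs the normal-CDF oracle, +-1 pp at n=50000."""
    rng = np.random.default_rng(42)
    draws = np.exp(mu + sigma * rng.standard_normal(50_000))
    expected = sf.prevalence_below_lognormal(mu, sigma, cutoff)
    assert sf.prevalence_inadequate(draws, cutoff) == pytest.approx(
        expected, abs=1.0
    )
    # excess side: tail above the cutoff
    assert sf.prevalence_excess(draws, cutoff) == pytest.approx(
        100.0 - expected, abs=1.0
    )


def fortified_fixture():
    """Two scenarios over the toy participants, with hand-set intakes."""
    df = toy_participants(n_adults=4, n_children=2)
    usual = pd.concat([
        pd.DataFrame({
            "participant_id": df.participant_id,
            "nutrient": "zinc",
            # women EAR 9.9: a0,a1 below; children EAR 3.6: both below
            "usual_intake": [8.0, 9.0, 12.0, 15.0, 2.0, 3.0],
        }),
        pd.DataFrame({
            "participant_id": df.participant_id,
            "nutrient": "folate",
            "usual_intake": [200.0, 400.0, 500.0, 600.0, 100.0, 140.0],
        }),
    ], ignore_index=True)
    scenario = sf.build_scenario(df, "recommended")
    spec = sf.FortificationSpec(zinc_mg_per_g=0.8, folic_acid_ug_per_g=30.0)
    fortified = pd.concat(
        [sf.baseline_rows(usual), sf.apply_fortification(usual, scenario, spec)],
        ignore_index=True,
    )
    return df, fortified


def test_summarize_baseline_has_zero_pp_reduction(refs):
    df, fortified = fortified_fixture()
    report = sf.summarize(fortified, df, refs, by=["life_stage"])
    base = report[report.scenario == "baseline"]
    assert (base["pp_reduction"] == 0).all()
    # counting check: women zinc baseline 2/4 below EAR 9.9
    women = base[(base.life_stage == "woman_15_49y") & (base.nutrient == "zinc")]
    assert women["pct_inadequate"].iloc[0] == 50.0


def test_summarize_identical_tables_give_identical_rows(refs):
    df, fortified = fortified_fixture()
    clone = fortified.copy()
    clone.loc[clone.scenario == "recommended", "scenario"] = "calculated"
    report = sf.summarize(pd.concat([fortified, clone]), df, refs,
                          by=["life_stage"])
    rec = report[report.scenario == "recommended"].drop(columns="scenario")
    calc = report[report.scenario == "calculated"].drop(columns="scenario")
    pd.testing.assert_frame_equal(rec.reset_index(drop=True),
                                  calc.reset_index(drop=True))


def test_report_invariant_to_row_order(refs):
    df, fortified = fortified_fixture()
    shuffled = fortified.sample(frac=1.0, random_state=3)
    a = sf.summarize(fortified, df, refs, by=["life_stage"])
    b = sf.summarize(shuffled, df, refs, by=["life_stage"])
    pd.testing.assert_frame_equal(a, b)


def test_partition_sums_to_one_hundred(refs, small_population):
    """% below EAR + % in [EAR, UL] + % above UL = 100 per stratum (zinc)."""
    usual, _ = sf.estimate_population_usual(small_population, refs, min_n=2)
    scenario = sf.build_scenario(small_population, "recommended")
    spec = sf.FortificationSpec(zinc_mg_per_g=0.8, folic_acid_ug_per_g=30.0)
    fortified = sf.apply_fortification(usual, scenario, spec)
    attrs = small_population.set_index("participant_id")
    sub = fortified[fortified.nutrient == "zinc"].copy()
    for col in ("region", "life_stage", "status"):
        sub[col] = sub["participant_id"].map(attrs[col])
    from saltfort.adequacy import per_person_reference
    ear = per_person_reference(sub, refs, "zinc", "ear")
    ul = per_person_reference(sub, refs, "zinc", "ul")
    for (_, _), grp in sub.assign(_e=ear, _u=ul).groupby(
        ["region", "life_stage"]
    ):
        below = sf.prevalence_inadequate(grp["fortified_usual"], grp["_e"])
        above = sf.prevalence_excess(grp["fortified_usual"], grp["_u"])
        middle = 100.0 * np.mean(
            (grp["fortified_usual"] >= grp["_e"])
            & (grp["fortified_usual"] <= grp["_u"])
        )
        assert below + middle + above == pytest.approx(100.0)


def test_table_shaped_report_covers_all_group_region_strata(refs,
                                                            full_population):
    usual, _ = sf.estimate_population_usual(full_population, refs)
    scenario = sf.build_scenario(full_population, "recommended")
    spec = sf.FortificationSpec(zinc_mg_per_g=0.8, folic_acid_ug_per_g=30.0)
    fortified = pd.concat(
        [sf.baseline_rows(usual),
         sf.apply_fortification(usual, scenario, spec)],
        ignore_index=True,
    )
    report = sf.summarize(fortified, full_population, refs,
                          by=["region", "life_stage"])
    strata = set(map(tuple, report[["region", "life_stage"]].to_numpy()))
    assert strata == {
        (r, s)
        for r in ("AddisAbaba", "Somali")
        for s in ("child_1_3y", "woman_15_49y", "man_19_45y")
    }
    rendered = sf.render(report)
    assert rendered["pct_inadequate"].between(0, 100).all()
    assert rendered["pct_excess"].between(0, 100).all()


def test_unknown_stratifier_errors(refs):
    df, fortified = fortified_fixture()
    with pytest.raises(KeyError):
        sf.summarize(fortified, df, refs, by=["flavour"])
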