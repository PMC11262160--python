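"""Constrained grid search over fortificant addition rates."""

import numpy as np
import pandas as pd
import pytest

import saltfort as sf
from saltfort.adequacy import per_person_reference

from conftest import scaled_config


@pytest.fixture(scope="module")
def small_problem(refs):
    """~200-person synthetic population with usual intakes and a scenario."""
    pop = sf.generate_population(scaled_config(0.09, seed=17))
    usual, _ = sf.estimate_population_usual(pop, refs, min_n=2)
    scenario = sf.build_scenario(pop, "recommended")
    return pop, usual, scenario


def brute_force_best(pop, usual, scenario, nutrient, grid, refs,
                     threshold=5.0):
    """Independent exhaustive evaluation, written from first principles."""
    sub = usual[usual.nutrient == nutrient].merge(
        scenario.salt[["participant_id", "discretionary_salt_g_d"]],
        on="participant_id",
    ).merge(
        pop[["participant_id", "region", "life_stage", "status"]],
        on="participant_id",
    )
    ear = per_person_reference(sub, refs, nutrient, "ear").to_numpy()
    ul = per_person_reference(sub, refs, nutrient, "ul").to_numpy()
    base = sub["usual_intake"].to_numpy()
    salt = sub["discretionary_salt_g_d"].to_numpy()
    strata = list(zip(sub["region"], sub["life_stage"]))
    labels = sorted(set(strata))
    masks = {s: np.array([x == s for x in strata]) for s in labels}

    best_rate, best_obj = None, -np.inf
    trace = []
    for rate in grid:
        total = base + salt * rate
        delivered = salt * rate
        excess_basis = total if nutrient == "zinc" else delivered
        objs, ws, exc = [], [], []
        for s in labels:
            m = masks[s]
            objs.append(100 * (np.mean(base[m] < ear[m])
                               - np.mean(total[m] < ear[m])))
            ws.append(m.sum())
            exc.append(100 * np.mean(excess_basis[m] > ul[m]))
        obj = float(np.average(objs, weights=ws))
        feasible = max(exc) < threshold
        trace.append((rate, obj, max(exc), feasible))
        if feasible and obj > best_obj:
            best_rate, best_obj = rate, obj
    return best_rate, best_obj, trace


@pytest.mark.parametrize("nutrient, grid", [
    ("zinc", np.linspace(0.0, 2.0, 11)),
    ("folate", np.linspace(0.0, 120.0, 11)),
])
def test_optimizer_matches_brute_force(small_problem, refs, nutrient, grid):
    """Grid search equals an independent exhaustive evaluation."""
    pop, usual, scenario = small_problem
    res = sf.optimize_rate(usual, pop, scenario, nutrient, grid, refs)
    bf_rate, bf_obj, bf_trace = brute_force_best(
        pop, usual, scenario, nutrient, grid, refs
    )
    assert res.feasible
    assert res.chosen_rate == pytest.approx(bf_rate)
    assert res.objective == pytest.approx(bf_obj)
    assert res.constraint_margin < 5.0
    for (rate, obj, mex, feas), row in zip(bf_trace,
                                           res.grid_trace.itertuples()):
        assert row.rate == pytest.approx(rate)
        assert row.objective == pytest.approx(obj)
        assert row.max_excess == pytest.approx(mex)
        assert row.feasible == feas


def test_objective_at_rate_zero_is_zero(small_problem, refs):
    pop, usual, scenario = small_problem
    res = sf.optimize_rate(usual, pop, scenario, "zinc", [0.0], refs)
    assert res.chosen_rate == 0.0
    assert res.objective == 0.0


def test_infinite_ul_never_binds(small_problem, refs, tmp_path):
    """With the UL out of reach the maximum grid rate is chosen."""
    pop, usual, scenario = small_problem
    refs.write(tmp_path / "e.csv", tmp_path / "v.csv")
    table = pd.read_csv(tmp_path / "e.csv")
    table["ul"] = 1e12
    table.to_csv(tmp_path / "e.csv", index=False)
    loose = sf.NutrientReferences.from_files(tmp_path / "e.csv",
                                             tmp_path / "v.csv")
    grid = np.linspace(0.0, 2.0, 11)
    res = sf.optimize_rate(usual, pop, scenario, "zinc", grid, loose)
    assert res.chosen_rate == pytest.approx(grid[-1])


def test_no_feasible_rate_returns_trace_not_exception(small_problem, refs,
                                                      tmp_path):
    pop, usual, scenario = small_problem
    refs.write(tmp_path / "e.csv", tmp_path / "v.csv")
    table = pd.read_csv(tmp_path / "e.csv")
    # UL just above EAR: essentially everyone is in excess at any rate
    table["ul"] = table["ear"] * 1.0001
    table.to_csv(tmp_path / "e.csv", index=False)
    tight = sf.NutrientReferences.from_files(tmp_path / "e.csv",
                                             tmp_path / "v.csv")
    res = sf.optimize_rate(usual, pop, scenario, "zinc",
                           np.linspace(0.5, 2.0, 4), tight)
    assert not res.feasible
    assert res.chosen_rate is None
    assert len(res.grid_trace) == 4


def test_feasible_set_is_prefix_and_refinement_helps(small_problem, refs):
    """Excess is monotone in rate, so feasibility is a grid prefix; a finer
    grid can only improve the attained objective."""
    pop, usual, scenario = small_problem
    coarse = np.linspace(0.0, 2.0, 6)
    fine = np.linspace(0.0, 2.0, 21)
    res_c = sf.optimize_rate(usual, pop, scenario, "zinc", coarse, refs)
    res_f = sf.optimize_rate(usual, pop, scenario, "zinc", fine, refs)
    feas = res_f.grid_trace["feasible"].to_numpy()
    assert not np.any(~feas[:-1] & feas[1:])  # no re-entry after infeasible
    assert res_f.objective >= res_c.objective - 1e-12


def test_invalid_grids_rejected(small_problem, refs):
    pop, usual, scenario = small_problem
    with pytest.raises(ValueError):
        sf.optimize_rate(usual, pop, scenario, "zinc", [], refs)
    with pytest.raises(ValueError):
        sf.optimize_rate(usual, pop, scenario, "zinc", [0.5, 0.1], refs)
    with pytest.raises(ValueError):
        sf.optimize_rate(usual, pop, scenario, "zinc", [-0.1, 0.5], refs)
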