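"""Per-person discretionary salt under the two modelled scenarios.

``calculated``: adult discretionary salt is a fixed fraction (default 90%)
of urinary-sodium-derived total salt; children, who have no urinary data,
receive the region-mean adult discretionary salt scaled by their energy
intake relative to the region-mean adult energy.

``recommended``: every adult consumes the WHO limit (5 g/d); each child
receives 5 g/d scaled by the same energy ratio.

Full precision propagates internally; rounding to one decimal happens only
in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import (
    DISCRETIONARY_FRACTION,
    RECOMMENDED_ADULT_SALT_G_D,
    SODIUM_TO_SALT_FACTOR,
)

SCENARIO_NAMES = ("calculated", "recommended")


@dataclass
class SaltScenarioParams:
    discretionary_fraction: float = DISCRETIONARY_FRACTION
    adult_recommended_g_d: float = RECOMMENDED_ADULT_SALT_G_D
    #: grouping used for the child scaling base under "calculated"
    child_base_cols: tuple = ("region",)

    def __post_init__(self):
        if not 0.0 <= self.discretionary_fraction <= 1.0:
            raise ValueError("discretionary fraction must be in [0, 1]")
        if self.adult_recommended_g_d < 0:
            raise ValueError("recommended salt must be >= 0")


@dataclass
class SaltScenario:
    """Named scenario with its per-person discretionary salt table."""

    name: str
    salt: pd.DataFrame  # participant_id, scenario, discretionary_salt_g_d
    params: SaltScenarioParams = field(default_factory=SaltScenarioParams)


def sodium_to_salt(sodium_mg_day, factor: float = SODIUM_TO_SALT_FACTOR):
    """Urinary sodium (mg/d) -> salt (g/d); 2000 mg Na equates to 5 g salt."""
    sodium = np.asarray(sodium_mg_day, dtype=float)
    if (sodium < 0).any():
        raise ValueError("sodium must be >= 0")
    out = sodium * factor
    return float(out) if np.isscalar(sodium_mg_day) else out


def discretionary_salt_adult(total_salt_g_day, fraction: float = DISCRETIONARY_FRACTION):
    """Discretionary share of adult total salt."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    total = np.asarray(total_salt_g_day, dtype=float)
    if (total < 0).any():
        raise ValueError("total salt must be >= 0")
    out = total * fraction
    return float(out) if np.isscalar(total_salt_g_day) else out


def child_salt_from_energy(adult_salt_g_day, child_energy_kcal, adult_energy_kcal):
    """Scale an adult salt amount by the child:adult energy ratio."""
    adult_energy = np.asarray(adult_energy_kcal, dtype=float)
    if (adult_energy <= 0).any():
        raise ValueError("adult energy must be > 0")
    return np.asarray(adult_salt_g_day, dtype=float) * (
        np.asarray(child_energy_kcal, dtype=float) / adult_energy
    )


def build_scenario(
    participants: pd.DataFrame,
    name: str,
    params: SaltScenarioParams | None = None,
) -> SaltScenario:
    """Per-person discretionary salt for one scenario.

    ``participants`` needs ``participant_id``, ``life_stage``,
    ``energy_kcal_d`` and (for the calculated scenario, adults)
    ``total_salt_g_d``; the input frame is never mutated.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; expected {SCENARIO_NAMES}")
    params = params or SaltScenarioParams()
    is_child = participants["life_stage"] == "child_1_3y"
    adults = participants[~is_child]
    children = participants[is_child]

    problems = []
    if name == "calculated" and adults["total_salt_g_d"].isna().any():
        problems.append(
            "adults missing total_salt_g_d: "
            + ", ".join(adults.loc[adults["total_salt_g_d"].isna(), "participant_id"])
        )
    if children["energy_kcal_d"].isna().any():
        problems.append(
            "children missing energy_kcal_d: "
            + ", ".join(children.loc[children["energy_kcal_d"].isna(), "participant_id"])
        )
    if problems:
        raise ValueError("; ".join(problems))

    salt = pd.Series(np.nan, index=participants.index)
    base_cols = list(params.child_base_cols)
    if name == "calculated":
        salt[~is_child] = adults["total_salt_g_d"] * params.discretionary_fraction
        if len(children):
            # children inherit the group-mean adult discretionary salt,
            # scaled by their energy relative to group-mean adult energy
            adult_disc = adults.assign(_disc=salt[~is_child])
            base = adult_disc.groupby(base_cols)[["_disc", "energy_kcal_d"]].mean()
            key = children[base_cols].apply(tuple, axis=1) if len(base_cols) > 1 \
                else children[base_cols[0]]
            base_salt = key.map(base["_disc"] if len(base_cols) == 1 else
                                {k: v for k, v in base["_disc"].items()})
            base_energy = key.map(base["energy_kcal_d"] if len(base_cols) == 1 else
                                  {k: v for k, v in base["energy_kcal_d"].items()})
            if base_salt.isna().any():
                missing = sorted(set(key[base_salt.isna()]))
                raise ValueError(f"no adults to anchor child salt in strata {missing}")
            salt[is_child] = child_salt_from_energy(
                base_salt.to_numpy(), children["energy_kcal_d"].to_numpy(),
                base_energy.to_numpy(),
            )
    else:  # recommended
        salt[~is_child] = params.adult_recommended_g_d
        if len(children):
            mean_adult_energy = adults["energy_kcal_d"].mean()
            if not np.isfinite(mean_adult_energy) or mean_adult_energy <= 0:
                raise ValueError("no adult energy to anchor child salt scaling")
            salt[is_child] = child_salt_from_energy(
                params.adult_recommended_g_d,
                children["energy_kcal_d"].to_numpy(),
                mean_adult_energy,
            )

    table = pd.DataFrame(
        {
            "participant_id": participants["participant_id"].to_numpy(),
            "scenario": name,
            "discretionary_salt_g_d": salt.to_numpy(),
        }
    )
    return SaltScenario(name=name, salt=table, params=params)
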