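"""Adequacy and excess of usual intake: the EAR cut-point machinery.

Prevalence of inadequate intake is the share of the usual-intake
distribution below the group's estimated average requirement (EAR
cut-point method); prevalence of excess is the share above the tolerable
upper intake level (UL).  Both are applied to the *empirical* distribution
of per-person usual-intake estimates; a parametric lognormal variant is
provided because, when the usual-intake distribution is exactly lognormal,
the cut-point prevalence has the closed form ``Phi((ln c - mu) / sigma)``
— useful as an analytic cross-check.

Per nutrient, the excess check uses a different intake basis:

* zinc — total usual intake vs the zinc UL;
* folate — fortificant-delivered folic acid vs the folic-acid UL
  (the UL applies to the synthetic form only).

Ties at exactly the EAR or UL count as adequate / not excess (strict
inequalities).  Percentages are rounded to integers only in rendered
reports; machine-readable output keeps full precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .reference import DemographicGroup, NutrientReferences

#: intake basis for the >UL check, per nutrient
EXCESS_BASIS = {"zinc": "fortified_usual", "folate": "delivered"}


class EmptyStratumError(ValueError):
    """Prevalence over an empty stratum is undefined, not zero."""


def prevalence_inadequate(usual_intakes, ear_per_person) -> float:
    """% of persons with usual intake strictly below their EAR."""
    intakes = np.asarray(usual_intakes, dtype=float)
    ears = np.broadcast_to(np.asarray(ear_per_person, dtype=float), intakes.shape)
    if intakes.size == 0:
        raise EmptyStratumError("no participants in stratum")
    return 100.0 * float(np.mean(intakes < ears))


def prevalence_excess(intake_basis, ul_per_person) -> float:
    """% of persons with intake (on the nutrient's basis) strictly above UL."""
    intakes = np.asarray(intake_basis, dtype=float)
    uls = np.broadcast_to(np.asarray(ul_per_person, dtype=float), intakes.shape)
    if intakes.size == 0:
        raise EmptyStratumError("no participants in stratum")
    return 100.0 * float(np.mean(intakes > uls))


def prevalence_below_lognormal(mu: float, sigma: float, cutoff: float) -> float:
    """Closed-form % below a cutoff for a lognormal(mu, sigma) distribution."""
    if cutoff <= 0:
        return 0.0
    return 100.0 * float(norm.cdf((np.log(cutoff) - mu) / sigma))


def per_person_reference(
    participants: pd.DataFrame, references: NutrientReferences, nutrient: str,
    which: str = "ear",
) -> pd.Series:
    """EAR or UL per participant, respecting physiological status."""
    lookup = references.ear if which == "ear" else references.ul
    pairs = participants[["life_stage", "status"]].drop_duplicates()
    table = {
        (ls, st): lookup(nutrient, DemographicGroup(ls, st))
        for ls, st in pairs.itertuples(index=False)
    }
    keys = list(zip(participants["life_stage"], participants["status"]))
    return pd.Series([table[k] for k in keys], index=participants.index)


def summarize(
    fortified: pd.DataFrame,
    participants: pd.DataFrame,
    references: NutrientReferences,
    by=("region", "life_stage"),
    baseline_scenario: str = "baseline",
    subset: pd.Series | None = None,
) -> pd.DataFrame:
    """One report row per stratum x nutrient x scenario.

    ``fortified`` is the long table from :mod:`saltfort.fortify` (include
    the ``baseline`` rows to get pp_reduction anchored); ``participants``
    carries the stratifiers.  ``subset`` optionally restricts participants
    (e.g. adults only, urban only) before stratification.

    Columns: stratifiers, ``nutrient``, ``scenario``, ``n``,
    ``median_intake`` (full precision), ``pct_inadequate``, ``pct_excess``,
    ``pp_reduction`` (baseline minus scenario inadequacy).
    """
    by = list(by)
    unknown = set(by) - set(participants.columns)
    if unknown:
        raise KeyError(f"unknown stratifiers: {sorted(unknown)}")
    attrs = participants if subset is None else participants[subset]
    attrs = attrs.set_index("participant_id")

    df = fortified[fortified["participant_id"].isin(attrs.index)].copy()
    for col in by + ["life_stage", "status"]:
        df[col] = df["participant_id"].map(attrs[col])

    rows = []
    for (nutrient, scenario), chunk in df.groupby(["nutrient", "scenario"], sort=True):
        ear = per_person_reference(chunk, references, nutrient, "ear")
        ul = per_person_reference(chunk, references, nutrient, "ul")
        chunk = chunk.assign(_ear=ear, _ul=ul, _basis=chunk[EXCESS_BASIS[nutrient]])
        for stratum, grp in chunk.groupby(by, sort=True):
            stratum = stratum if isinstance(stratum, tuple) else (stratum,)
            rows.append(
                dict(zip(by, stratum))
                | {
                    "nutrient": nutrient,
                    "scenario": scenario,
                    "n": len(grp),
                    "median_intake": float(grp["fortified_usual"].median()),
                    "pct_inadequate": prevalence_inadequate(
                        grp["fortified_usual"], grp["_ear"]
                    ),
                    "pct_excess": prevalence_excess(grp["_basis"], grp["_ul"]),
                }
            )
    report = pd.DataFrame(rows)
    base = (
        report[report["scenario"] == baseline_scenario]
        .set_index(by + ["nutrient"])["pct_inadequate"]
    )
    anchor = report.set_index(by + ["nutrient"]).index
    report["pp_reduction"] = (base.reindex(anchor).to_numpy()
                              - report["pct_inadequate"].to_numpy())
    return report.sort_values(by + ["nutrient", "scenario"], ignore_index=True)


def render(report: pd.DataFrame) -> pd.DataFrame:
    """Rounded presentation copy: integer percentages, 1-decimal medians."""
    out = report.copy()
    out["median_intake"] = out["median_intake"].round(1)
    for col in ("pct_inadequate", "pct_excess", "pp_reduction"):
        out[col] = out[col].round(0).astype(int)
    return out
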