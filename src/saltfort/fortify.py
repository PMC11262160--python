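"""Nutrient delivery from fortified salt.

Delivered amount = discretionary salt (g/d) x addition rate (per g).  Zinc
is added at mg/g; folic acid at ug/g, expressed in dietary folate
equivalents via ``dfe_factor``.  The default ``dfe_factor`` is 1.0 — i.e.
1 ug folic acid counted as 1 ug DFE — matching the reference design
arithmetic (e.g. 6.7 g/d x 22 ug/g = 147 ug DFE); the conventional 1.7
factor for fortificant folic acid is available by configuration.

The fortificant-only delivery is kept as its own column because the
excess-intake check uses different bases per nutrient: total usual intake
for zinc, fortificant-delivered folic acid for folate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FortificationSpec:
    """Addition rates per gram of salt."""

    zinc_mg_per_g: float = 0.0
    folic_acid_ug_per_g: float = 0.0
    dfe_factor: float = 1.0

    def __post_init__(self):
        if self.zinc_mg_per_g < 0 or self.folic_acid_ug_per_g < 0:
            raise ValueError("addition rates must be >= 0")
        if self.dfe_factor <= 0:
            raise ValueError("dfe_factor must be > 0")

    def rate(self, nutrient: str) -> float:
        """Delivered amount per gram of salt, in intake units (DFE for folate)."""
        if nutrient == "zinc":
            return self.zinc_mg_per_g
        if nutrient in ("folate", "folic_acid"):
            return self.folic_acid_ug_per_g * self.dfe_factor
        raise KeyError(f"unknown nutrient {nutrient!r}")


def nutrient_from_salt(salt_g_day, spec: FortificationSpec) -> dict:
    """Delivered nutrients for a salt intake: {'zinc': mg/d, 'folate': ug DFE/d}."""
    salt = np.asarray(salt_g_day, dtype=float)
    if (salt < 0).any():
        raise ValueError("salt must be >= 0")
    out = {n: salt * spec.rate(n) for n in ("zinc", "folate")}
    if np.isscalar(salt_g_day):
        out = {n: float(v) for n, v in out.items()}
    return out


def apply_fortification(
    usual_estimates: pd.DataFrame,
    scenario,
    spec: FortificationSpec,
) -> pd.DataFrame:
    """Add fortificant delivery to baseline usual intakes.

    Parameters
    ----------
    usual_estimates
        Long table: ``participant_id``, ``nutrient``, ``usual_intake``.
    scenario
        A :class:`~saltfort.salt.SaltScenario` (or its ``salt`` table).

    Returns a long table with ``baseline_usual``, ``delivered``,
    ``fortified_usual``, ``scenario`` and ``rate`` per person and nutrient.
    The baseline column is carried through untouched; additivity
    (fortified - baseline == delivered) holds exactly.
    """
    salt_table = getattr(scenario, "salt", scenario)
    name = salt_table["scenario"].iloc[0] if len(salt_table) else ""
    merged = usual_estimates.merge(
        salt_table[["participant_id", "discretionary_salt_g_d"]],
        on="participant_id",
        how="left",
        validate="many_to_one",
    )
    if merged["discretionary_salt_g_d"].isna().any():
        missing = sorted(
            merged.loc[merged["discretionary_salt_g_d"].isna(), "participant_id"]
            .unique()
        )
        raise ValueError(f"scenario missing participants: {missing}")
    rates = merged["nutrient"].map({n: spec.rate(n) for n in ("zinc", "folate")})
    delivered = merged["discretionary_salt_g_d"] * rates
    return pd.DataFrame(
        {
            "participant_id": merged["participant_id"],
            "nutrient": merged["nutrient"],
            "scenario": name,
            "rate": rates,
            "baseline_usual": merged["usual_intake"],
            "delivered": delivered,
            "fortified_usual": merged["usual_intake"] + delivered,
        }
    )


def baseline_rows(usual_estimates: pd.DataFrame) -> pd.DataFrame:
    """The unfortified counterpart table (scenario='baseline', zero delivery)."""
    return pd.DataFrame(
        {
            "participant_id": usual_estimates["participant_id"],
            "nutrient": usual_estimates["nutrient"],
            "scenario": "baseline",
            "rate": 0.0,
            "baseline_usual": usual_estimates["usual_intake"],
            "delivered": 0.0,
            "fortified_usual": usual_estimates["usual_intake"],
        }
    )
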