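"""Item-level 24-h recall records -> per-person one-day nutrient intakes.

A recall table (participant_id, food_code, amount_g) is joined against a
food composition table (FCT) giving energy, zinc and folate per 100 g, and
summed per participant.  Because no single FCT carries every nutrient for
every food (folate in particular is typically borrowed from neighbouring
countries' tables), :func:`merge_fct_sources` composes an FCT from an
ordered list of sources with first-non-missing precedence and a provenance
record of which source supplied each value.
"""

from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger(__name__)

NUTRIENT_COLUMNS = {
    "energy_kcal_100g": "energy_kcal_d",
    "zinc_mg_100g": "zinc_mg_d",
    "folate_ug_dfe_100g": "folate_ug_dfe_d",
}


class MissingFoodCodeError(KeyError):
    """Recall items reference food codes absent from the FCT (strict mode)."""

    def __init__(self, codes):
        self.codes = sorted(codes)
        super().__init__(f"food codes missing from FCT: {self.codes}")


def compute_day_intake(
    items: pd.DataFrame,
    fct: pd.DataFrame,
    mode: str = "strict",
    participant_ids=None,
) -> pd.DataFrame:
    """Sum ``amount_g x composition_per_100g / 100`` per participant.

    Parameters
    ----------
    items
        Columns ``participant_id``, ``food_code``, ``amount_g`` (grams).
    fct
        Columns ``food_code`` plus the per-100 g nutrient columns.
    mode
        ``"strict"`` raises :class:`MissingFoodCodeError` listing every
        unmatched code; ``"lenient"`` drops unmatched items with a logged
        count.  Silent nutrient undercounting is the classic failure mode
        here, so strict is the default.
    participant_ids
        Optional full roster; participants with no items get all-zero rows.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    if (items["amount_g"] < 0).any():
        bad = items.loc[items["amount_g"] < 0, "participant_id"].tolist()
        raise ValueError(f"negative amount_g for participants {bad}")

    known = set(fct["food_code"])
    unmatched = set(items["food_code"]) - known
    if unmatched:
        if mode == "strict":
            raise MissingFoodCodeError(unmatched)
        n_dropped = items["food_code"].isin(unmatched).sum()
        log.warning(
            "dropping %d recall items with %d unmatched food codes: %s",
            n_dropped, len(unmatched), sorted(unmatched),
        )
        items = items[~items["food_code"].isin(unmatched)]

    merged = items.merge(fct, on="food_code", how="left", validate="many_to_one")
    for per100, out in NUTRIENT_COLUMNS.items():
        merged[out] = merged["amount_g"] * merged[per100] / 100.0
    totals = (
        merged.groupby("participant_id")[list(NUTRIENT_COLUMNS.values())]
        .sum()
        .reset_index()
    )
    if participant_ids is not None:
        totals = (
            totals.set_index("participant_id")
            .reindex(pd.Index(participant_ids, name="participant_id"), fill_value=0.0)
            .reset_index()
        )
    return totals


def merge_fct_sources(
    primary: pd.DataFrame,
    fallbacks,
    source_names=None,
) -> pd.DataFrame:
    """Compose an FCT: per food and nutrient, first non-missing source wins.

    ``fallbacks`` is an ordered list tried after ``primary``.  For every
    nutrient column a sibling ``<column>_source`` records the winning
    source name, so borrowed values stay auditable.
    """
    sources = [primary, *fallbacks]
    if source_names is None:
        source_names = ["primary"] + [f"fallback_{i}" for i in range(len(fallbacks))]
    if len(source_names) != len(sources):
        raise ValueError("source_names must match the number of tables")

    nutrient_cols = [c for c in primary.columns if c != "food_code"]
    all_codes = pd.Index(
        pd.concat([t["food_code"] for t in sources]).unique(), name="food_code"
    )
    indexed = [t.set_index("food_code").reindex(all_codes) for t in sources]

    out = pd.DataFrame(index=all_codes)
    for col in nutrient_cols:
        value = pd.Series(float("nan"), index=all_codes)
        origin = pd.Series(pd.NA, index=all_codes, dtype="object")
        for name, table in zip(source_names, indexed):
            if col not in table.columns:
                continue
            take = value.isna() & table[col].notna()
            value[take] = table.loc[take, col]
            origin[take] = name
        out[col] = value
        out[col + "_source"] = origin
    return out.reset_index()
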