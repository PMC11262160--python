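"""Usual-intake estimation from a single 24-h recall per person.

A single recall day confounds within-person (day-to-day) and between-person
variation, so the within-person component cannot be estimated from the
survey itself.  Following the standard external-variance workflow, the
within:between variance ratio ``r`` is imputed from an external nutrient
variance database, and per-person usual intakes are obtained by shrinking
transformed observed intakes toward the stratum mean:

    t_usual_i = mu_t + sqrt(1 / (1 + r)) * (t_obs_i - mu_t)

On the transformed (default natural-log) scale, with observed variance
``var_obs``, the decomposition is ``var_between = var_obs / (1 + r)`` and
``var_within = var_obs * r / (1 + r)``; the shrinkage factor
``sqrt(var_between / var_obs) = sqrt(1/(1+r))`` removes exactly the
within-person share of the variance, so
``Var(t_usual) = shrinkage^2 * var_obs = var_between``.

Nuisance recall-day covariates (weekend, sickness, unusual consumption) are
removed by OLS on the transformed scale before shrinkage; stratifiers (age,
sex, region, SES, residence) are retained for stratification, never removed.
Back-transform of the per-person point estimates is plain ``exp()``: the
outputs of interest — medians and cut-point prevalences — are invariant to
any monotone mean correction, which is therefore not applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

#: Recall-day nuisance covariates removed before shrinkage.
NUISANCE_COVARIATES = ("weekend", "sick", "unusual")

NUTRIENT_COLUMNS = {"zinc": "zinc_mg_d", "folate": "folate_ug_dfe_d"}


class StratumTooSmallError(ValueError):
    """Stratum below the size floor; pool strata (e.g. collapse regions)."""


@dataclass
class UsualIntakeModel:
    """Fitted transformation + variance decomposition for one stratum."""

    nutrient: str
    stratum: str
    transform: str
    mu_t: float
    var_obs_t: float
    var_between_t: float
    var_within_t: float
    shrinkage: float
    n: int
    variance_ratio: float
    covariate_coefficients: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def handle_zeros(intakes: np.ndarray) -> np.ndarray:
    """Replace zero intakes with half the smallest positive value.

    A single recall can legitimately record zero intake (folate especially);
    the log transform needs positive values.  The replacement count is
    logged.  All-zero strata cannot be salvaged and raise.
    """
    intakes = np.asarray(intakes, dtype=float)
    if (intakes < 0).any():
        raise ValueError("negative intakes are invalid")
    zeros = intakes == 0
    if not zeros.any():
        return intakes
    positive = intakes[~zeros]
    if positive.size == 0:
        raise ValueError("all intakes zero; cannot fit on the log scale")
    out = intakes.copy()
    out[zeros] = positive.min() / 2.0
    log.info("replaced %d zero intakes with %.4g", zeros.sum(), positive.min() / 2.0)
    return out


def adjust_covariates(
    transformed: np.ndarray,
    covariates: pd.DataFrame,
    nuisance=NUISANCE_COVARIATES,
    mode: str = "reference",
):
    """Remove nuisance recall-day effects on the transformed scale.

    Fits OLS of the transformed intake on the nuisance indicators and
    re-expresses each observation as prediction-at-reference + residual.
    ``mode="reference"`` predicts at all-nuisance-flags-false (a typical
    weekday, well, usual-consumption day); ``mode="mean"`` predicts at the
    sample mean of the flags (averaging over them).  Constant (aliased)
    columns are dropped with a logged warning.

    Returns ``(adjusted, coefficients)``.
    """
    if mode not in ("reference", "mean"):
        raise ValueError(f"mode must be 'reference' or 'mean', got {mode!r}")
    y = np.asarray(transformed, dtype=float)
    cols = [c for c in nuisance if c in covariates.columns]
    if not cols:
        return y.copy(), {}
    X = covariates[cols].astype(float).to_numpy()
    keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
    dropped = [cols[i] for i in range(len(cols)) if i not in keep]
    if dropped:
        log.warning("dropping aliased/constant covariates: %s", dropped)
    if not keep:
        return y.copy(), {}
    X = X[:, keep]
    names = [cols[i] for i in keep]
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design).fit()
    beta = fit.params[1:]
    reference = np.zeros(X.shape[1]) if mode == "reference" else X.mean(axis=0)
    adjusted = y - (X - reference) @ beta
    return adjusted, dict(zip(names, beta))


def fit_usual_model(
    day_intakes: np.ndarray,
    variance_ratio: float,
    transform: str = "log",
    nutrient: str = "",
    stratum: str = "",
    min_n: int = 30,
    covariates: pd.DataFrame | None = None,
    covariate_mode: str = "reference",
) -> tuple[UsualIntakeModel, np.ndarray]:
    """Fit the variance decomposition for one stratum.

    Returns the fitted model plus the covariate-adjusted transformed
    intakes (needed by :func:`estimate_usual` so adjustment and shrinkage
    share one code path).
    """
    if transform != "log":
        raise NotImplementedError("only the log transform is implemented")
    if variance_ratio < 0:
        raise ValueError("variance ratio must be >= 0")
    intakes = handle_zeros(day_intakes)
    n = intakes.size
    if n < min_n:
        raise StratumTooSmallError(
            f"stratum {stratum!r} has n={n} < {min_n}; pool strata "
            "(e.g. collapse regions) before fitting"
        )
    t = np.log(intakes)
    coefs: dict = {}
    if covariates is not None:
        t, coefs = adjust_covariates(t, covariates, mode=covariate_mode)
    var_obs = float(np.var(t, ddof=1))
    r = float(variance_ratio)
    var_between = var_obs / (1.0 + r)
    var_within = var_obs * r / (1.0 + r)
    model = UsualIntakeModel(
        nutrient=nutrient,
        stratum=stratum,
        transform="log",
        mu_t=float(np.mean(t)),
        var_obs_t=var_obs,
        var_between_t=var_between,
        var_within_t=var_within,
        shrinkage=float(np.sqrt(1.0 / (1.0 + r))),
        n=n,
        variance_ratio=r,
        covariate_coefficients=coefs,
    )
    return model, t


def estimate_usual(transformed: np.ndarray, model: UsualIntakeModel) -> np.ndarray:
    """Shrink transformed intakes toward the stratum mean; back-transform."""
    t = np.asarray(transformed, dtype=float)
    t_usual = model.mu_t + model.shrinkage * (t - model.mu_t)
    return np.exp(t_usual)


def estimate_population_usual(
    survey: pd.DataFrame,
    references,
    nutrients=("zinc", "folate"),
    stratum_cols=("region", "life_stage"),
    min_n: int = 30,
    adjust: bool = True,
    covariate_mode: str = "reference",
):
    """Per-stratum usual-intake estimation for a whole survey.

    Strata below ``min_n`` fall back to a region-collapsed (pooled) model,
    logged.  Returns a long table (participant_id, nutrient, usual_intake)
    and the dict of fitted models keyed by (nutrient, stratum label).
    """
    stratum_cols = list(stratum_cols)
    pieces, models = [], {}
    for nutrient in nutrients:
        col = NUTRIENT_COLUMNS[nutrient]
        small = []
        for label, idx in survey.groupby(stratum_cols, sort=True).groups.items():
            sub = survey.loc[idx]
            if len(sub) < min_n:
                small.append((label, idx))
                continue
            pieces.append(
                _fit_stratum(sub, nutrient, col, "|".join(map(str, np.atleast_1d(
                    np.asarray(label, dtype=object)))), references, min_n,
                    adjust, covariate_mode, models)
            )
        if small:
            # pool undersized strata across regions within life stage
            pooled_idx = np.concatenate([np.asarray(i) for _, i in small])
            pooled_labels = [lab for lab, _ in small]
            for stage, idx in (
                survey.loc[pooled_idx].groupby("life_stage", sort=True).groups.items()
            ):
                sub = pd.concat([
                    survey[(survey["life_stage"] == stage)],
                ])
                log.warning(
                    "strata %s below n=%d for %s; fitting region-pooled model "
                    "for life_stage=%s (n=%d)",
                    pooled_labels, min_n, nutrient, stage, len(sub),
                )
                model, t = _fit_raw(
                    sub, nutrient, col, f"pooled|{stage}", references, min_n,
                    adjust, covariate_mode,
                )
                models[(nutrient, f"pooled|{stage}")] = model
                usual = estimate_usual(t, model)
                keep = sub["participant_id"].isin(
                    survey.loc[idx, "participant_id"]
                ).to_numpy()
                pieces.append(pd.DataFrame({
                    "participant_id": sub.loc[keep, "participant_id"].to_numpy(),
                    "nutrient": nutrient,
                    "usual_intake": usual[keep],
                }))
    long = pd.concat(pieces, ignore_index=True).sort_values(
        ["nutrient", "participant_id"], ignore_index=True
    )
    return long, models


def _age_class(stage: str) -> str:
    return "child" if stage == "child_1_3y" else "adult"


def _fit_raw(sub, nutrient, col, label, references, min_n, adjust, covariate_mode):
    ratio = references.variance_ratio(nutrient, _age_class(sub["life_stage"].iloc[0]))
    cov = sub[list(NUISANCE_COVARIATES)] if adjust and set(
        NUISANCE_COVARIATES
    ) <= set(sub.columns) else None
    return fit_usual_model(
        sub[col].to_numpy(), ratio, nutrient=nutrient, stratum=label,
        min_n=min_n, covariates=cov, covariate_mode=covariate_mode,
    )


def _fit_stratum(sub, nutrient, col, label, references, min_n, adjust,
                 covariate_mode, models):
    model, t = _fit_raw(sub, nutrient, col, label, references, min_n, adjust,
                        covariate_mode)
    models[(nutrient, label)] = model
    return pd.DataFrame({
        "participant_id": sub["participant_id"].to_numpy(),
        "nutrient": nutrient,
        "usual_intake": estimate_usual(t, model),
    })
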