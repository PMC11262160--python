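"""Synthetic dietary-survey generator with known ground truth.

The restricted national consumption-survey microdata behind this analysis is
not redistributable, so every downstream stage is exercised on synthetic
surveys that emulate its structure: one 24-h recall per participant, strata
by region (Addis Ababa, Somali) x demographic group (children 1-3 y, women
15-49 y, men 19-45 y), urban/rural residence, SES quintiles, and pregnancy/
lactation status for women.

Per stratum, each person's *true usual intake* of a nutrient is drawn
lognormal around a configured median with a configured between-person
geometric SD; the single observed recall day multiplies it by lognormal
within-person noise whose log-scale variance is ``ratio x between-person
log-variance``, where ``ratio`` is the externally imputed within:between
variance ratio (0.47/0.61 zinc child/adult, 0.72/0.89 folate child/adult).
Because the ground truth is retained, shrinkage estimators and prevalence
methods can be validated against it directly.

Adults carry a total (urinary-sodium-derived) salt intake; children never
do — their salt is always derived downstream from energy intake.

Randomness: one root seed; each stratum gets an independent substream keyed
by a stable hash of its label, so adding or resizing one stratum never
perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .reference import LIFE_STAGES, STATUSES

SES_LEVELS = ("lowest", "lower_middle", "middle", "upper_middle", "highest")

#: Survey-table columns, in output order.
SURVEY_COLUMNS = [
    "participant_id",
    "region",
    "life_stage",
    "status",
    "residence",
    "ses_quintile",
    "energy_kcal_d",
    "total_salt_g_d",
    "weekend",
    "sick",
    "unusual",
    "zinc_mg_d",
    "folate_ug_dfe_d",
]
TRUTH_COLUMNS = ["participant_id", "true_zinc_mg_d", "true_folate_ug_dfe_d"]


class ConfigError(ValueError):
    """Invalid population configuration."""


@dataclass
class PopulationConfig:
    """Everything needed to simulate one survey.

    Nested dicts are keyed by plain strings so the config round-trips
    through YAML.  ``usual_intake_params[nutrient][region][life_stage]``
    holds ``{"median": natural-scale median, "gsd": geometric SD}``;
    ``within_variance_ratios[nutrient][age_class]`` the imputed ratios;
    ``salt_offsets_g_d[region][life_stage]`` additive shifts applied to the
    base adult total-salt mean so group means can differ by region and sex.
    """

    n_per_stratum: dict
    urban_fraction: dict
    ses_distribution: dict
    status_distribution: dict
    usual_intake_params: dict
    within_variance_ratios: dict
    adult_total_salt_mean_g_d: float = 8.3
    adult_total_salt_sd_g_d: float = 2.0
    salt_offsets_g_d: dict = field(default_factory=dict)
    adult_energy_kcal: tuple = (2200.0, 450.0)
    child_energy_ratio: float = 0.45
    child_energy_sd_kcal: float = 220.0
    covariate_rates: dict = field(
        default_factory=lambda: {"weekend": 2 / 7, "sick": 0.05, "unusual": 0.05}
    )
    covariate_effects: dict = field(
        default_factory=lambda: {"weekend": 0.0, "sick": 0.0, "unusual": 0.0}
    )
    seed: int = 0

    def validate(self) -> None:
        for region, by_stage in self.n_per_stratum.items():
            for stage, n in by_stage.items():
                if stage not in LIFE_STAGES:
                    raise ConfigError(f"unknown life stage {stage!r}")
                if n < 0:
                    raise ConfigError(f"negative stratum size for {region}/{stage}")
        for region, probs in self.ses_distribution.items():
            p = np.asarray([probs[k] for k in SES_LEVELS], dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(f"SES probabilities for {region} must sum to 1")
        for region, probs in self.status_distribution.items():
            p = np.asarray([probs[k] for k in STATUSES], dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(f"status probabilities for {region} must sum to 1")
        for region, frac in self.urban_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"urban fraction for {region} outside [0, 1]")
            if region == "AddisAbaba" and frac != 1.0:
                raise ConfigError("Addis Ababa strata are urban-only")
        for nutrient, by_region in self.usual_intake_params.items():
            for region, by_stage in by_region.items():
                for stage, p in by_stage.items():
                    if p["median"] <= 0 or p["gsd"] <= 1.0:
                        raise ConfigError(
                            f"median must be > 0 and gsd > 1 for "
                            f"{nutrient}/{region}/{stage}"
                        )
        for nutrient, by_class in self.within_variance_ratios.items():
            for age_class, r in by_class.items():
                if r < 0:
                    raise ConfigError(
                        f"variance ratio < 0 for {nutrient}/{age_class}"
                    )
        if self.adult_total_salt_mean_g_d <= 0 or self.adult_total_salt_sd_g_d <= 0:
            raise ConfigError("salt mean and SD must be > 0")
        if self.adult_energy_kcal[0] <= 0 or self.adult_energy_kcal[1] <= 0:
            raise ConfigError("energy mean and SD must be > 0")
        if self.child_energy_ratio <= 0:
            raise ConfigError("child energy ratio must be > 0")
        for name, rate in self.covariate_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"covariate rate {name} outside [0, 1]")

    # -- YAML round-trip --------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["adult_energy_kcal"] = list(self.adult_energy_kcal)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["adult_energy_kcal"] = tuple(d["adult_energy_kcal"])
        return cls(**d)


def default_config(seed: int = 0) -> PopulationConfig:
    """The default study conditions.

    Stratum sizes mirror the 2013 Ethiopian National Food Consumption
    Survey subsample for Addis Ababa and Somali (2271 participants), intake
    medians match the baseline usual-intake medians reported for those
    strata, adult total salt centres on the 8.3 g/d national estimate with
    region x sex offsets chosen so group-mean discretionary salt (90% of
    total) reproduces the reference design values (8.5/6.7 g/d men/women in
    Addis Ababa, 6.8/5.3 in Somali).
    """
    medians = {
        "zinc": {
            "AddisAbaba": {"child_1_3y": 2.5, "woman_15_49y": 6.9, "man_19_45y": 9.2},
            "Somali": {"child_1_3y": 1.8, "woman_15_49y": 4.2, "man_19_45y": 5.4},
        },
        "folate": {
            "AddisAbaba": {
                "child_1_3y": 126.0,
                "woman_15_49y": 457.0,
                "man_19_45y": 552.0,
            },
            "Somali": {
                "child_1_3y": 62.0,
                "woman_15_49y": 159.0,
                "man_19_45y": 207.0,
            },
        },
    }
    gsd = float(np.exp(0.5))  # between-person log-SD 0.5
    usual = {
        nutrient: {
            region: {
                stage: {"median": m, "gsd": gsd} for stage, m in by_stage.items()
            }
            for region, by_stage in by_region.items()
        }
        for nutrient, by_region in medians.items()
    }
    base = 8.3
    disc = {  # discretionary targets from the reference design table
        "AddisAbaba": {"man_19_45y": 8.5, "woman_15_49y": 6.7},
        "Somali": {"man_19_45y": 6.8, "woman_15_49y": 5.3},
    }
    offsets = {
        region: {stage: round(d / 0.9 - base, 3) for stage, d in by_stage.items()}
        for region, by_stage in disc.items()
    }
    return PopulationConfig(
        n_per_stratum={
            "AddisAbaba": {"child_1_3y": 422, "woman_15_49y": 722, "man_19_45y": 86},
            "Somali": {"child_1_3y": 414, "woman_15_49y": 603, "man_19_45y": 24},
        },
        urban_fraction={"AddisAbaba": 1.0, "Somali": 177 / 1041},
        ses_distribution={
            "AddisAbaba": {
                "lowest": 0.0,
                "lower_middle": 0.0,
                "middle": 0.0,
                "upper_middle": 119 / 1230,
                "highest": 1111 / 1230,
            },
            "Somali": {
                "lowest": 226 / 1041,
                "lower_middle": 271 / 1041,
                "middle": 286 / 1041,
                "upper_middle": 161 / 1041,
                "highest": 97 / 1041,
            },
        },
        status_distribution={
            "AddisAbaba": {
                "none": 467 / 722,
                "pregnant": 22 / 722,
                "lactating": 233 / 722,
            },
            "Somali": {
                "none": 224 / 603,
                "pregnant": 69 / 603,
                "lactating": 310 / 603,
            },
        },
        usual_intake_params=usual,
        within_variance_ratios={
            "zinc": {"child": 0.47, "adult": 0.61},
            "folate": {"child": 0.72, "adult": 0.89},
        },
        adult_total_salt_mean_g_d=base,
        salt_offsets_g_d=offsets,
        seed=seed,
    )


def _stratum_rng(seed: int, label: str) -> np.random.Generator:
    """Independent substream per stratum, stable under stratum additions."""
    digest = hashlib.sha256(label.encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), sub]))


def _truncnorm(rng, mean, sd, size):
    """Normal truncated at zero (no negative salt or energy)."""
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Simulate one survey; deterministic given ``config.seed``.

    Returns one row per participant with observed one-day intakes, the
    ground-truth usual intakes (``true_*`` columns), demographics, energy,
    adult total salt (NaN for children) and recall-day covariate flags.
    """
    config.validate()
    frames = []
    for region in sorted(config.n_per_stratum):
        for stage in LIFE_STAGES:
            n = int(config.n_per_stratum[region].get(stage, 0))
            if n == 0:
                continue
            frames.append(_generate_stratum(config, region, stage, n))
    if not frames:
        df = pd.DataFrame(columns=SURVEY_COLUMNS + TRUTH_COLUMNS[1:])
        return df
    out = pd.concat(frames, ignore_index=True)
    return out[SURVEY_COLUMNS + TRUTH_COLUMNS[1:]]


def _generate_stratum(config, region, stage, n) -> pd.DataFrame:
    rng = _stratum_rng(config.seed, f"{region}|{stage}")
    age_class = "child" if stage == "child_1_3y" else "adult"

    residence = np.where(
        rng.random(n) < config.urban_fraction[region], "urban", "rural"
    )
    ses_p = [config.ses_distribution[region][k] for k in SES_LEVELS]
    ses = rng.choice(np.arange(1, 6), size=n, p=np.asarray(ses_p) / sum(ses_p))
    if stage == "woman_15_49y":
        st_p = [config.status_distribution[region][k] for k in STATUSES]
        status = rng.choice(list(STATUSES), size=n, p=np.asarray(st_p) / sum(st_p))
    else:
        status = np.full(n, "none", dtype=object)

    adult_mean, adult_sd = config.adult_energy_kcal
    if age_class == "child":
        energy = _truncnorm(
            rng, adult_mean * config.child_energy_ratio, config.child_energy_sd_kcal, n
        )
        salt = np.full(n, np.nan)
    else:
        energy = _truncnorm(rng, adult_mean, adult_sd, n)
        offset = config.salt_offsets_g_d.get(region, {}).get(stage, 0.0)
        salt = _truncnorm(
            rng,
            config.adult_total_salt_mean_g_d + offset,
            config.adult_total_salt_sd_g_d,
            n,
        )

    cov = {
        name: rng.random(n) < config.covariate_rates.get(name, 0.0)
        for name in ("weekend", "sick", "unusual")
    }
    cov_shift = sum(
        config.covariate_effects.get(name, 0.0) * cov[name].astype(float)
        for name in cov
    )

    data = {
        "participant_id": [f"{region}-{stage}-{i:05d}" for i in range(n)],
        "region": region,
        "life_stage": stage,
        "status": status,
        "residence": residence,
        "ses_quintile": ses,
        "energy_kcal_d": energy,
        "total_salt_g_d": salt,
        **cov,
    }
    for nutrient, by_region in config.usual_intake_params.items():
        params = by_region[region][stage]
        sigma_b = np.log(params["gsd"])
        mu = np.log(params["median"])
        true = np.exp(mu + sigma_b * rng.standard_normal(n))
        ratio = config.within_variance_ratios[nutrient][age_class]
        sigma_w = np.sqrt(ratio) * sigma_b
        observed = true * np.exp(sigma_w * rng.standard_normal(n) + cov_shift)
        col = "zinc_mg_d" if nutrient == "zinc" else "folate_ug_dfe_d"
        data[col] = observed
        data["true_" + col] = true
    return pd.DataFrame(data)


def split_ground_truth(survey: pd.DataFrame):
    """Split a generated table into the survey proper and the truth table."""
    truth = survey[TRUTH_COLUMNS].copy()
    return survey[SURVEY_COLUMNS].copy(), truth
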