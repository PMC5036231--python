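"""Synthetic Labrador-cohort generator with known ground truth.

No public data accompany the limber-tail analysis, so every downstream
stage is exercised against simulated tables whose generating process is
fully known: a single-generation sire/dam pedigree with
Dirichlet-multinomial offspring allocation (one concentration knob
spans uniform to popular-sire-dominated contribution patterns), owner
covariates matched to the published control marginals (swimming
prevalence 68/86, purpose mix dominated by household pets), a logistic
disease model with swimming, working-status and latitude effects plus a
sire-level normal random effect, owner free-text illness reports drawn
from template classes (keyword-bearing, keyword-free "tail" phrasings,
and non-tail distractors), and tail questionnaires with configurable
sign-reporting and misattribution rates and correlated pain /
quality-of-life scores.

All generators take an explicit integer seed and are deterministic
given (seed, config); there is no global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CovariateConfig",
    "RiskModelParams",
    "TemplateConfig",
    "ResponseConfig",
    "CaseSimulation",
    "generate_pedigree",
    "generate_cohort",
    "simulate_case_status",
    "render_free_text_reports",
    "generate_questionnaires",
    "write_synthetic_tables",
]

PURPOSES = ("household_pet", "working", "gundog_and_pet", "other")


@dataclass(frozen=True)
class CovariateConfig:
    """Marginal distributions for owner-reported covariates.

    Defaults track the published control group: swimming prevalence
    68/86, purpose mix overwhelmingly household pets with a few working
    dogs, and household latitudes spread over mainland Britain.
    """

    p_swim: float = 68 / 86
    purpose_probs: tuple[float, float, float, float] = (0.95, 0.035, 0.005, 0.01)
    latitude_mean: float = 52.8
    latitude_sd: float = 1.8
    latitude_range: tuple[float, float] = (49.0, 61.0)
    longitude_mean: float = -1.8
    longitude_sd: float = 1.5
    p_female: float = 0.5
    p_neutered: float = 0.55
    p_smoker_household: float = 0.15
    household_types: tuple[str, ...] = ("family", "couple", "single", "retired")
    household_probs: tuple[float, ...] = (0.45, 0.3, 0.1, 0.15)
    coats: tuple[str, ...] = ("black", "yellow", "chocolate")
    coat_probs: tuple[float, ...] = (0.45, 0.35, 0.2)
    birth_year_range: tuple[int, int] = (2010, 2014)

    def validate(self) -> None:
        if not 0 <= self.p_swim <= 1:
            raise ValueError("p_swim must be a probability")
        for name, probs in (
            ("purpose_probs", self.purpose_probs),
            ("household_probs", self.household_probs),
            ("coat_probs", self.coat_probs),
        ):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if self.latitude_range[0] >= self.latitude_range[1]:
            raise ValueError("latitude_range must be increasing")


@dataclass(frozen=True)
class RiskModelParams:
    """Logistic disease model on the log-odds scale.

    logit P(affected) = intercept + beta_swim*swims + beta_work*working
    + beta_lat*(latitude - latitude_ref) + u_sire,
    u_sire ~ Normal(0, sire_sd^2).  "Working" includes gundog-and-pet
    dogs.  Defaults use the published effect sizes (swimming OR 4.7,
    working OR 5.1, latitude OR 1.47/degree), a moderate familial
    effect, and an intercept solved numerically so the marginal
    incidence under the default covariates is the observed 9.7%.
    """

    intercept: float = -4.14
    beta_swim: float = math.log(4.7)
    beta_work: float = math.log(5.1)
    beta_lat: float = math.log(1.47)
    sire_sd: float = 0.9
    latitude_ref: float = 52.8

    def validate(self) -> None:
        if self.sire_sd < 0:
            raise ValueError("sire_sd must be >= 0")
        for name in ("intercept", "beta_swim", "beta_work", "beta_lat"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def generate_pedigree(
    n_dogs: int, n_sires: int, n_dams: int, concentration: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Single-generation pedigree with Dirichlet-multinomial allocation.

    Offspring are allocated to sires (and independently to dams) by a
    multinomial draw over Dirichlet(concentration) weights: a small
    concentration lets a few popular parents dominate, a large one
    approaches uniform contributions.  Parents are not themselves
    cohort members.  Returns columns dog_id, sire_id, dam_id.
    """
    if min(n_dogs, n_sires, n_dams) < 1:
        raise ValueError("n_dogs, n_sires and n_dams must all be >= 1")
    if n_sires > n_dogs or n_dams > n_dogs:
        raise ValueError("cannot have more sires or dams than dogs")
    if not concentration > 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)

    def allocate(n_parents: int) -> np.ndarray:
        w = rng.dirichlet(np.full(n_parents, concentration))
        counts = rng.multinomial(n_dogs, w)
        assignment = np.repeat(np.arange(n_parents), counts)
        return rng.permuted(assignment)

    sires = allocate(n_sires)
    dams = allocate(n_dams)
    return pd.DataFrame(
        {
            "dog_id": [f"D{i:05d}" for i in range(n_dogs)],
            "sire_id": [f"S{i:04d}" for i in sires],
            "dam_id": [f"M{i:04d}" for i in dams],
        }
    )


def generate_cohort(
    pedigree: pd.DataFrame, config: CovariateConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """One DogRecord row per pedigree entry with covariates drawn i.i.d."""
    if pedigree.empty:
        raise ValueError("pedigree must be non-empty")
    cfg = config or CovariateConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    lat = rng.normal(cfg.latitude_mean, cfg.latitude_sd, n)
    lat = np.clip(lat, *cfg.latitude_range)
    y0, y1 = cfg.birth_year_range
    birth = pd.to_datetime(
        {
            "year": rng.integers(y0, y1 + 1, n),
            "month": rng.integers(1, 13, n),
            "day": rng.integers(1, 29, n),
        }
    )
    df = pd.DataFrame(
        {
            "dog_id": pedigree["dog_id"].to_numpy(),
            "sire_id": pedigree["sire_id"].to_numpy(),
            "dam_id": pedigree["dam_id"].to_numpy(),
            "sex": np.where(rng.random(n) < cfg.p_female, "F", "M"),
            "birth_date": birth.dt.strftime("%Y-%m-%d"),
            "purpose": rng.choice(PURPOSES, n, p=cfg.purpose_probs),
            "swims": rng.random(n) < cfg.p_swim,
            "latitude": np.round(lat, 4),
            "longitude": np.round(rng.normal(cfg.longitude_mean, cfg.longitude_sd, n), 4),
            "household_type": rng.choice(cfg.household_types, n, p=cfg.household_probs),
            "smoker_household": rng.random(n) < cfg.p_smoker_household,
            "coat": rng.choice(cfg.coats, n, p=cfg.coat_probs),
            "neutered": rng.random(n) < cfg.p_neutered,
        }
    )
    return df


@dataclass
class CaseSimulation:
    """Disease-status draw plus the latent quantities tests introspect."""

    affected: pd.Series  # bool, indexed by dog_id
    sire_effects: pd.Series  # latent u_sire, indexed by sire_id
    linear_predictor: pd.Series  # logit-scale risk per dog


def simulate_case_status(
    cohort: pd.DataFrame, params: RiskModelParams | None = None, seed: int = 0
) -> CaseSimulation:
    """Draw affected/unaffected per dog from the logistic risk model."""
    p = params or RiskModelParams()
    p.validate()
    if cohort["sire_id"].isna().any() or (cohort["sire_id"] == "").any():
        raise ValueError("every dog needs a known sire for the risk model")
    rng = np.random.default_rng(seed)
    sires = pd.Index(sorted(cohort["sire_id"].unique()))
    u = pd.Series(rng.normal(0.0, p.sire_sd, len(sires)), index=sires)
    working = cohort["purpose"].isin(["working", "gundog_and_pet"]).to_numpy()
    eta = (
        p.intercept
        + p.beta_swim * cohort["swims"].to_numpy().astype(float)
        + p.beta_work * working.astype(float)
        + p.beta_lat * (cohort["latitude"].to_numpy() - p.latitude_ref)
        + u.loc[cohort["sire_id"]].to_numpy()
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    affected = rng.random(len(cohort)) < prob
    idx = pd.Index(cohort["dog_id"])
    return CaseSimulation(
        affected=pd.Series(affected, index=idx, name="affected"),
        sire_effects=u,
        linear_predictor=pd.Series(eta, index=idx, name="eta"),
    )


# Owner phrasing templates.  Keyword templates contain "tail" plus at
# least one screening keyword; tail-only templates contain "tail" but no
# keyword (the manual-review channel); distractors never mention the tail.
_KEYWORD_TEMPLATES = (
    "Limber tail after a swim in the lake",
    "His tail went completely limp overnight",
    "Swimmer's tail - hanging down since the morning",
    "Cold water swim then a dead tail the next day",
    "Tail stiff at the base and droopy at the tip",
    "Frozen tail, wouldn't lift it after working in the cold",
    "Her tail just drops straight down, very unusual",
    "Limp tail for a couple of days after a long walk",
    "Tail like a broken rudder, very sorry for himself",
    "Staved tail after jumping into the river",
)
_TAIL_ONLY_TEMPLATES = (
    "She had a problem with her tail, she couldn't wag it for 5 days",
    "His tail was hanging down and he seemed very unhappy",
    "Tail not wagging as usual, held low near the body",
    "Something wrong with her tail, very sore near the base",
)
_DISTRACTOR_TEMPLATES = (
    "Diarrhoea for two days",
    "Limping on the front left leg after a run",
    "Ear infection, seen by the vet",
    "Vomited twice overnight but fine now",
    "Cut pad on a walk, healed quickly",
)


@dataclass(frozen=True)
class TemplateConfig:
    """Free-text rendering: template classes and emission rates.

    ``extra_report_rate`` is the Poisson mean of additional reports per
    affected dog (observed incident multiplicity was 53 incidents over
    43 dogs); ``vet_visit_rate`` the per-incident probability of a vet
    visit (11 of 53 incidents).
    """

    keyword_templates: tuple[str, ...] = _KEYWORD_TEMPLATES
    tail_only_templates: tuple[str, ...] = _TAIL_ONLY_TEMPLATES
    distractor_templates: tuple[str, ...] = _DISTRACTOR_TEMPLATES
    p_tail_only: float = 0.1
    extra_report_rate: float = 53 / 43 - 1
    vet_visit_rate: float = 11 / 53
    distractor_vet_rate: float = 0.5

    def validate(self) -> None:
        for name in ("keyword_templates", "tail_only_templates", "distractor_templates"):
            if not getattr(self, name):
                raise ValueError(f"template class {name} is empty")
        for name in ("p_tail_only", "vet_visit_rate", "distractor_vet_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.extra_report_rate < 0:
            raise ValueError("extra_report_rate must be >= 0")


def render_free_text_reports(
    cohort: pd.DataFrame,
    statuses: pd.Series,
    template_config: TemplateConfig | None = None,
    distractor_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit owner illness reports with ground-truth template labels.

    Every affected dog emits at least one tail report (keyword-bearing,
    or keyword-free with probability ``p_tail_only``); unaffected dogs
    emit a non-tail distractor with probability ``distractor_rate``.
    The ``template_class`` column is ground truth for screening
    evaluation and belongs in the sidecar, not the reports CSV.
    """
    if not 0 <= distractor_rate <= 1:
        raise ValueError("distractor_rate must be in [0, 1]")
    cfg = template_config or TemplateConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    rows = []
    birth = pd.to_datetime(cohort.set_index("dog_id")["birth_date"])
    for dog_id in cohort["dog_id"]:
        affected = bool(statuses.loc[dog_id])
        n_reports = 0
        classes: list[str] = []
        if affected:
            n_reports = 1 + rng.poisson(cfg.extra_report_rate)
            for _ in range(n_reports):
                classes.append(
                    "tail_no_keyword" if rng.random() < cfg.p_tail_only else "keyword"
                )
        if rng.random() < distractor_rate:
            classes.append("distractor")
        for cls in classes:
            if cls == "keyword":
                text = cfg.keyword_templates[rng.integers(len(cfg.keyword_templates))]
                vet = rng.random() < cfg.vet_visit_rate
            elif cls == "tail_no_keyword":
                text = cfg.tail_only_templates[rng.integers(len(cfg.tail_only_templates))]
                vet = rng.random() < cfg.vet_visit_rate
            else:
                text = cfg.distractor_templates[rng.integers(len(cfg.distractor_templates))]
                vet = rng.random() < cfg.distractor_vet_rate
            date = birth.loc[dog_id] + pd.Timedelta(days=int(rng.integers(240, 1400)))
            rows.append(
                {
                    "dog_id": dog_id,
                    "report_date": date.strftime("%Y-%m-%d"),
                    "text": text,
                    "vet_visit": vet,
                    "template_class": cls,
                }
            )
    cols = ["dog_id", "report_date", "text", "vet_visit", "template_class"]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class ResponseConfig:
    """Questionnaire behaviour of owners, by true status.

    Sign-reporting probabilities apply to affected dogs;
    ``misattribution_rate`` is the chance an affected owner blames an
    alternative cause (injury / anal glands), which downstream
    classification must veto.  ``control_sign_rate`` gives unaffected
    dogs a tail-sign profile exercising the classifier's exclusion
    paths, split between anal-gland attributions (3 of the 5 published
    non-promoted sign-bearing controls) and sign patterns lacking
    limpness (the other 2); promotable limpness among provisional
    controls arises upstream, from truly affected dogs whose reports
    the keyword screen missed.  Affected dogs lack limpness signs with
    probability (1-p_limp_end)(1-p_limp_length) ~ 7.5%, feeding the
    provisional-case exclusion path (2 of 31 published).  Pain and
    quality-of-life scores are drawn on 0-10 with the configured
    Pearson correlation (0.72 published).
    """

    p_limp_end: float = 0.85
    p_limp_length: float = 0.5
    p_stiff_base: float = 0.5
    p_hair_on_end: float = 0.15
    p_painful: float = 0.7
    p_unsure: float = 0.05  # chance a negative sign answer is "unsure" instead of "no"
    misattribution_rate: float = 0.05
    control_sign_rate: float = 5 / 93
    control_anal_gland_share: float = 0.6
    pain_mean: float = 6.0
    pain_sd: float = 2.4
    qol_mean: float = 4.1
    qol_sd: float = 2.8
    pain_qol_corr: float = 0.72
    p_pain_reported_yes: float = 0.6
    p_pain_reported_no: float = 0.3
    duration_categories: tuple[str, ...] = (
        "a few hours",
        "1 day",
        "2 days",
        "a few days",
        "a week or more",
    )
    duration_probs: tuple[float, ...] = (0.07, 0.13, 0.15, 0.40, 0.25)
    extra_episode_rate: float = 53 / 43 - 1

    def validate(self) -> None:
        for name in (
            "p_limp_end", "p_limp_length", "p_stiff_base", "p_hair_on_end",
            "p_painful", "p_unsure", "misattribution_rate", "control_sign_rate",
            "control_anal_gland_share",
            "p_pain_reported_yes", "p_pain_reported_no",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not -1 <= self.pain_qol_corr <= 1:
            raise ValueError("pain_qol_corr must be in [-1, 1]")
        if abs(sum(self.duration_probs) - 1) > 1e-9:
            raise ValueError("duration_probs must sum to 1")


def _latent_corr(target: float, sd1: float, sd2: float) -> float:
    # rounding scores to integers adds ~1/12 variance per axis, which
    # attenuates the sample correlation; inflate the latent one to match
    a1 = sd1**2 / (sd1**2 + 1 / 12)
    a2 = sd2**2 / (sd2**2 + 1 / 12)
    return float(np.clip(target / math.sqrt(a1 * a2), -0.999, 0.999))


def _draw_scores(rng, n, cfg: ResponseConfig) -> tuple[np.ndarray, np.ndarray]:
    rho = _latent_corr(cfg.pain_qol_corr, cfg.pain_sd, cfg.qol_sd)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    pain = np.clip(np.rint(cfg.pain_mean + cfg.pain_sd * z[:, 0]), 0, 10).astype(int)
    qol = np.clip(np.rint(cfg.qol_mean + cfg.qol_sd * z[:, 1]), 0, 10).astype(int)
    return pain, qol


def generate_questionnaires(
    cohort: pd.DataFrame,
    statuses: pd.Series,
    response_config: ResponseConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One tail questionnaire per cohort dog (repeat submissions collapsed)."""
    cfg = response_config or ResponseConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = len(cohort)
    pain, qol = _draw_scores(rng, n, cfg)

    def yn(p_yes: float) -> str:
        if rng.random() < p_yes:
            return "yes"
        return "unsure" if rng.random() < cfg.p_unsure else "no"

    rows = []
    for i, row in enumerate(cohort.itertuples(index=False)):
        affected = bool(statuses.loc[row.dog_id])
        if affected:
            signs = {
                "sign_limp_end": yn(cfg.p_limp_end),
                "sign_limp_length": yn(cfg.p_limp_length),
                "sign_stiff_base": yn(cfg.p_stiff_base),
                "sign_hair_on_end": yn(cfg.p_hair_on_end),
                "sign_painful": yn(cfg.p_painful),
            }
            attribution = "none"
            if rng.random() < cfg.misattribution_rate:
                attribution = "injury" if rng.random() < 0.5 else "anal_glands"
            precursors = {
                "precursor_swimming": yn(29 / 38),
                "precursor_cold_weather": yn(19 / 38),
                "precursor_vigorous_exercise": yn(18 / 38),
                "precursor_wet_weather": yn(11 / 38),
                "precursor_confinement": yn(6 / 38),
            }
            pain_reported = rng.choice(
                ["yes", "no", "unsure"],
                p=[cfg.p_pain_reported_yes, cfg.p_pain_reported_no,
                   1 - cfg.p_pain_reported_yes - cfg.p_pain_reported_no],
            )
            pain_score, qol_score = int(pain[i]), int(qol[i])
            n_episodes = 1 + int(rng.poisson(cfg.extra_episode_rate))
            duration = str(rng.choice(cfg.duration_categories, p=cfg.duration_probs))
        else:
            signs = {k: "no" for k in (
                "sign_limp_end", "sign_limp_length", "sign_stiff_base",
                "sign_hair_on_end", "sign_painful")}
            attribution = "none"
            if rng.random() < cfg.control_sign_rate:
                if rng.random() < cfg.control_anal_gland_share:
                    # anal-gland attribution: stiff base and/or limp length
                    signs["sign_stiff_base"] = "yes"
                    if rng.random() < 0.5:
                        signs["sign_limp_length"] = "yes"
                    attribution = "anal_glands"
                else:
                    # signs without limpness: not promotable
                    signs["sign_stiff_base"] = "yes"
                    if rng.random() < 0.5:
                        signs["sign_hair_on_end"] = "yes"
            precursors = {k: "no" for k in (
                "precursor_swimming", "precursor_cold_weather",
                "precursor_vigorous_exercise", "precursor_wet_weather",
                "precursor_confinement")}
            pain_reported = "no"
            pain_score = qol_score = 0
            n_episodes = 0
            duration = ""
        rows.append(
            {
                "dog_id": row.dog_id,
                **signs,
                "attribution": attribution,
                "attribution_text": "" if attribution == "none" else f"suspected {attribution.replace('_', ' ')}",
                **precursors,
                "pain_reported": pain_reported,
                "pain_score": pain_score,
                "qol_score": qol_score,
                "n_episodes": n_episodes,
                "duration_category": duration,
                "swims_ever": bool(row.swims),
            }
        )
    return pd.DataFrame(rows)


def write_synthetic_tables(
    out_dir: str | Path,
    dogs: pd.DataFrame,
    reports: pd.DataFrame,
    questionnaires: pd.DataFrame,
    simulation: CaseSimulation | None = None,
) -> dict[str, Path]:
    """Write dogs.csv / reports.csv / questionnaires.csv (+ truth sidecar).

    The reports CSV drops the ground-truth ``template_class`` column;
    truth (statuses, latent sire effects, template labels) goes to
    ``ground_truth.json`` for tests only.  Unknown parents are written
    as empty fields; dates are ISO-8601; encoding UTF-8.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dogs": out / "dogs.csv",
        "reports": out / "reports.csv",
        "questionnaires": out / "questionnaires.csv",
    }
    dogs.to_csv(paths["dogs"], index=False)
    reports.drop(columns=["template_class"], errors="ignore").to_csv(
        paths["reports"], index=False
    )
    questionnaires.to_csv(paths["questionnaires"], index=False)
    if simulation is not None:
        truth = {
            "affected": {k: bool(v) for k, v in simulation.affected.items()},
            "sire_effects": {k: float(v) for k, v in simulation.sire_effects.items()},
            "template_classes": reports["template_class"].tolist()
            if "template_class" in reports
            else [],
        }
        paths["ground_truth"] = out / "ground_truth.json"
        paths["ground_truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
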