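"""End-to-end orchestration: simulate -> screen -> classify -> analyse -> permtest.

One declarative config (YAML or :class:`RunConfig`) drives the whole
run; every stage writes plain CSV/JSON outputs, every output file is
hashed into a manifest, and a rerun with the same config reproduces the
manifest byte for byte.  Stage-level logging records the record counts
at each filter so the provisional -> final flow is auditable.

The analysis stage also recomputes the worked-example estimates from
the published counts of the UK Labrador Retriever cohort study of
limber tail (the swimming and working-dog exposure tables and the
incidence numerators/denominators).  Those counts are fixed inputs, so
this block is independent of the synthetic cohort and gives a stable
reference output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import epi, permutation, screening, synthetic

log = logging.getLogger("limbertail")

__all__ = [
    "WORKED_EXAMPLE",
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "validate_inputs",
]

# Published counts used as fixed worked-example inputs (exposure given
# as (case exposed, case unexposed, control exposed, control unexposed)).
WORKED_EXAMPLE: dict[str, Any] = {
    "swimming_table": (36, 2, 68, 18),
    "working_dog_table": (6, 32, 3, 83),
    "incidence_provisional_controls": (9, 93),
    "incidence_nonresponder_bound": (9, 127),
    "incidence_whole_cohort": (43, 6000),
    "vet_visit_missed": (32, 43),
}


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "limbertail_run"
    # synthetic cohort
    n_dogs: int = 2000
    n_sires: int = 300
    n_dams: int = 400
    concentration: float = 1.0
    distractor_rate: float = 0.05
    # screening / classification
    keywords: tuple[str, ...] = screening.DEFAULT_KEYWORDS
    controls_per_case: int = 3
    # inference
    level: float = 0.95
    ci_method: str = "minlike"
    # permutation
    n_perm: int = 10_000
    weighting: str = "offspring_weighted"
    parent_axis: str = "sire"
    include_reference_tables: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "keywords" in raw:
            raw["keywords"] = tuple(raw["keywords"])
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0 (0 skips the permutation stage)")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


@dataclass
class RunReport:
    config: RunConfig
    results: dict[str, Any]
    paths: dict[str, str]
    manifest: dict[str, str]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _or_block(table, level, method) -> dict[str, Any]:
    est = epi.exact_or_estimate(epi.ContingencyTable2x2(*table), level=level, method=method)
    return {
        "table": list(table),
        "or": est.or_point,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "p_two_sided": est.p_value,
        "method": est.method,
    }


def _incidence_block(k, n, level, n_nonresponders=0) -> dict[str, Any]:
    inc = epi.cumulative_incidence(k, n, level, n_nonresponders)
    out = {
        "k": k, "n": n,
        "percent": 100 * inc.primary.point,
        "ci_low_percent": 100 * inc.primary.ci_low,
        "ci_high_percent": 100 * inc.primary.ci_high,
    }
    if inc.sensitivity is not None:
        out["sensitivity_percent"] = 100 * inc.sensitivity.point
    return out


def reference_estimates(level: float = 0.95, method: str = "minlike") -> dict[str, Any]:
    """Worked-example estimates recomputed from the published counts."""
    w = WORKED_EXAMPLE
    miss_k, miss_n = w["vet_visit_missed"]
    return {
        "swimming": _or_block(w["swimming_table"], level, method),
        "working_dog": _or_block(w["working_dog_table"], level, method),
        "incidence_provisional_controls": _incidence_block(
            *w["incidence_provisional_controls"], level
        ),
        "incidence_nonresponder_bound": _incidence_block(
            *w["incidence_nonresponder_bound"], level
        ),
        "incidence_whole_cohort": _incidence_block(*w["incidence_whole_cohort"], level),
        "missed_by_vet_percent": _incidence_block(miss_k, miss_n, level),
    }


def validate_inputs(paths: dict[str, str | Path]) -> list[str]:
    """Schema and referential-integrity check of the three input CSVs.

    Returns a list of violations (empty when valid).
    """
    required = {
        "dogs": ["dog_id", "sire_id", "dam_id", "sex", "birth_date", "purpose",
                 "swims", "latitude", "longitude"],
        "reports": ["dog_id", "report_date", "text", "vet_visit"],
        "questionnaires": ["dog_id", *_classify.SIGN_FIELDS, "attribution",
                           "pain_score", "qol_score", "duration_category",
                           "n_episodes", "swims_ever"],
    }
    violations: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    for name, cols in required.items():
        p = Path(paths.get(name, ""))
        if not p.is_file():
            violations.append(f"{name}: file not found ({p})")
            continue
        df = pd.read_csv(p, dtype={"dog_id": str})
        tables[name] = df
        for c in cols:
            if c not in df.columns:
                violations.append(f"{name}: missing required column {c!r}")
    dogs = tables.get("dogs")
    if dogs is not None and "dog_id" in dogs:
        if dogs["dog_id"].duplicated().any():
            violations.append("dogs: duplicate dog_id values")
        if "latitude" in dogs:
            lat = pd.to_numeric(dogs["latitude"], errors="coerce")
            bad = lat.isna() | (lat < 49) | (lat > 61)
            if bad.any():
                violations.append(f"dogs: {int(bad.sum())} latitude values outside [49, 61]")
        if "purpose" in dogs:
            bad = ~dogs["purpose"].isin(synthetic.PURPOSES)
            if bad.any():
                violations.append(f"dogs: {int(bad.sum())} invalid purpose values")
        known = set(dogs["dog_id"])
        for name in ("reports", "questionnaires"):
            t = tables.get(name)
            if t is not None and "dog_id" in t:
                orphans = set(t["dog_id"]) - known
                if orphans:
                    violations.append(
                        f"{name}: {len(orphans)} dog_id values absent from dogs.csv "
                        f"(e.g. {sorted(orphans)[:3]})"
                    )
    for name, col in (("dogs", "birth_date"), ("reports", "report_date")):
        t = tables.get(name)
        if t is not None and col in t:
            parsed = pd.to_datetime(t[col], format="%Y-%m-%d", errors="coerce")
            if parsed.isna().any():
                violations.append(f"{name}: {int(parsed.isna().sum())} unparseable {col} values")
    for f in _classify.SIGN_FIELDS:
        t = tables.get("questionnaires")
        if t is not None and f in t:
            bad = ~t[f].astype(str).str.lower().isin(["yes", "no", "unsure"])
            if bad.any():
                violations.append(f"questionnaires: {int(bad.sum())} invalid {f} values")
    return violations


def _markdown_report(results: dict[str, Any], config: RunConfig) -> str:
    def fmt_or(b):
        return (f"{b['or']:.1f} (95% CI {b['ci_low']:.1f} to {b['ci_high']:.1f}), "
                f"p={b['p_two_sided']:.2f}")

    def fmt_inc(b):
        return (f"{b['percent']:.1f}% ({b['k']}/{b['n']}; 95% CI "
                f"{b['ci_low_percent']:.1f} to {b['ci_high_percent']:.1f}%)")

    lines = [
        "# Limber-tail pipeline report",
        "",
        f"Seed {config.seed}; cohort of {config.n_dogs} dogs "
        f"({config.n_sires} sires, {config.n_dams} dams).",
        "",
        "## Screening and classification",
        "",
        f"- candidate dogs after keyword screening: {results['screening']['n_candidates']}"
        f" ({results['screening']['n_incidents']} incidents)",
        f"- awaiting manual review (tail without keyword): "
        f"{results['screening']['n_needs_review_reports']} reports",
        f"- final cases {results['classification']['n_cases_final']}, "
        f"controls {results['classification']['n_controls_final']}, "
        f"excluded {results['classification']['n_excluded']}",
        "",
        "## Cohort estimates",
        "",
        f"- cumulative incidence among provisional controls: "
        f"{fmt_inc(results['analysis']['incidence_provisional_controls'])}",
        f"- swimming odds ratio: {fmt_or(results['analysis']['swimming'])}",
        f"- working-dog odds ratio: {fmt_or(results['analysis']['working_dog'])}",
    ]
    lat = results["analysis"].get("latitude_fit")
    if lat is not None:
        lines.append(
            f"- latitude odds ratio per degree: {lat['or']:.2f} "
            f"(95% CI {lat['ci_low']:.2f} to {lat['ci_high']:.2f})"
        )
    dur = results["analysis"].get("duration_days")
    if dur and dur.get("mean") is not None:
        lines.append(f"- mean first-episode duration: {dur['mean']:.1f} days")
    pq = results["analysis"].get("pain_qol_correlation")
    if pq is not None:
        lines.append(f"- pain / quality-of-life Pearson r: {pq:.2f}")
    perm = results.get("permutation")
    lines += ["", "## Pedigree permutation test", ""]
    if perm is None:
        lines.append("- skipped (n_perm=0)")
    else:
        verdict = "beyond" if perm["significant_clustering"] else "within"
        lines += [
            f"- observed {config.parent_axis} contribution statistic "
            f"{perm['observed_statistic']:.3f} ({verdict} the null 97.5th centile "
            f"{perm['pct_97_5']:.3f})",
            f"- upper-tail p = {perm['p_value']:.4g} ({perm['n_perm']} permutations)",
        ]
    if "reference" in results:
        ref = results["reference"]
        lines += [
            "",
            "## Worked example (published counts)",
            "",
            f"- swimming OR: {fmt_or(ref['swimming'])}",
            f"- working-dog OR: {fmt_or(ref['working_dog'])}",
            f"- incidence 9/93: {fmt_inc(ref['incidence_provisional_controls'])}",
            f"- incidence bound 9/127: {fmt_inc(ref['incidence_nonresponder_bound'])}",
            f"- whole-cohort incidence 43/6000: {fmt_inc(ref['incidence_whole_cohort'])}",
            f"- dogs missed by practice records 32/43: "
            f"{fmt_inc(ref['missed_by_vet_percent'])}",
        ]
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages under one seed and write a hashed manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    results: dict[str, Any] = {}
    stage = "simulate"
    try:
        # --- simulate ------------------------------------------------
        seeds = np.random.SeedSequence(config.seed).spawn(6)
        sub = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
        pedigree = synthetic.generate_pedigree(
            config.n_dogs, config.n_sires, config.n_dams, config.concentration, sub[0]
        )
        cohort = synthetic.generate_cohort(pedigree, seed=sub[1])
        sim = synthetic.simulate_case_status(cohort, seed=sub[2])
        reports = synthetic.render_free_text_reports(
            cohort, sim.affected, distractor_rate=config.distractor_rate, seed=sub[3]
        )
        quest = synthetic.generate_questionnaires(cohort, sim.affected, seed=sub[4])
        paths.update(synthetic.write_synthetic_tables(out, cohort, reports, quest, sim))
        log.info("simulate: %d dogs, %d reports, %.1f%% affected",
                 len(cohort), len(reports), 100 * sim.affected.mean())

        # --- screen --------------------------------------------------
        stage = "screen"
        screen = screening.screen_cohort(reports, config.keywords, level=config.level)
        screen.results.to_csv(out / "screen_results.csv", index=False)
        screen.needs_review.to_csv(out / "needs_review.csv", index=False)
        paths["screen_results"] = out / "screen_results.csv"
        paths["needs_review"] = out / "needs_review.csv"
        results["screening"] = {
            "n_candidates": len(screen.candidates),
            "n_incidents": screen.n_incidents,
            "multiplicity": screen.multiplicity,
            "n_needs_review_reports": int(len(screen.needs_review)),
            "n_dogs_vet_visit": screen.n_dogs_vet_visit,
            "missed_by_vet_percent": (
                None if screen.missed_by_vet is None
                else 100 * screen.missed_by_vet.point
            ),
        }
        log.info("screen: %d candidate dogs, %d incidents",
                 len(screen.candidates), screen.n_incidents)

        # --- provisional status & classify ---------------------------
        stage = "classify"
        rng = np.random.default_rng(sub[5])
        candidates = list(screen.candidates)
        non_candidates = sorted(set(cohort["dog_id"]) - set(candidates))
        n_controls = min(len(non_candidates), config.controls_per_case * max(len(candidates), 1))
        provisional_controls = sorted(
            rng.choice(non_candidates, size=n_controls, replace=False)
        )
        provisional = {d: "case" for d in candidates}
        provisional.update({d: "control" for d in provisional_controls})
        pd.DataFrame(
            sorted(provisional.items()), columns=["dog_id", "provisional"]
        ).to_csv(out / "provisional_status.csv", index=False)
        paths["provisional_status"] = out / "provisional_status.csv"

        responses = quest[quest["dog_id"].isin(provisional)].reset_index(drop=True)
        status_table, transitions = _classify.reclassify_cohort(responses, provisional)
        status_table.to_csv(out / "final_status.csv", index=False)
        _write_json(out / "transitions.json", transitions)
        paths["final_status"] = out / "final_status.csv"
        paths["transitions"] = out / "transitions.json"
        results["classification"] = transitions
        log.info("classify: %(n_cases_final)d cases, %(n_controls_final)d controls, "
                 "%(n_excluded)d excluded", transitions)

        # --- analyse -------------------------------------------------
        stage = "analyse"
        cases = status_table.loc[status_table["final"] == "case", "dog_id"]
        controls = status_table.loc[status_table["final"] == "control", "dog_id"]
        arms = pd.concat([cases, controls])
        dog_info = cohort.set_index("dog_id")
        q_info = quest.set_index("dog_id")
        case_mask = q_info.loc[arms].index.isin(set(cases))
        swims = q_info.loc[arms, "swims_ever"].astype(bool).to_numpy()
        working = dog_info.loc[arms, "purpose"].isin(["working", "gundog_and_pet"]).to_numpy()

        analysis: dict[str, Any] = {}
        analysis["incidence_provisional_controls"] = _incidence_block(
            transitions["controls_promoted"], transitions["n_provisional_controls"],
            config.level,
        )
        analysis["incidence_whole_cohort_conservative"] = _incidence_block(
            len(candidates), len(cohort), config.level
        )
        analysis["swimming"] = _or_block(
            dataclasses.astuple(epi.table_from_masks(case_mask, swims)),
            config.level, config.ci_method,
        )
        analysis["working_dog"] = _or_block(
            dataclasses.astuple(epi.table_from_masks(case_mask, working)),
            config.level, config.ci_method,
        )
        outcome = case_mask.astype(float)
        for pred, key in (("latitude", "latitude_fit"), ("longitude", "longitude_fit")):
            try:
                fit = epi.fit_logistic(
                    outcome,
                    dog_info.loc[arms, [pred]].astype(float),
                    level=config.level,
                )
                analysis[key] = {
                    "or": fit.or_scale[pred],
                    "ci_low": fit.or_ci[pred][0],
                    "ci_high": fit.or_ci[pred][1],
                    "p": fit.p_values[pred],
                    "converged": fit.converged,
                    "separation": fit.separation,
                }
            except ValueError as exc:
                analysis[key] = {"error": str(exc)}

        case_q = q_info.loc[cases]
        durations = [
            _classify.recode_duration(d)
            for d in case_q["duration_category"].astype(str)
            if str(d).strip()
        ]
        if len(durations) >= 2:
            s = epi.summarise_numeric(durations, config.level)
            analysis["duration_days"] = {
                "mean": s.mean, "ci_low": s.ci_low, "ci_high": s.ci_high, "n": s.n,
            }
        pain = case_q["pain_score"].astype(float)
        qol = case_q["qol_score"].astype(float)
        if len(case_q) >= 2:
            sp = epi.summarise_numeric(pain, config.level)
            sq = epi.summarise_numeric(qol, config.level)
            analysis["pain_score"] = {"mean": sp.mean, "ci_low": sp.ci_low,
                                      "ci_high": sp.ci_high, "n": sp.n}
            analysis["qol_score"] = {"mean": sq.mean, "ci_low": sq.ci_low,
                                     "ci_high": sq.ci_high, "n": sq.n}
        try:
            analysis["pain_qol_correlation"] = epi.pearson_correlation(pain, qol)
        except ValueError:
            analysis["pain_qol_correlation"] = None
        # pain-question inconsistencies are reported, never corrected
        inconsistent = int(
            ((case_q["pain_reported"].isin(["no", "unsure"]))
             & (case_q["pain_score"].astype(float) > 0)).sum()
        )
        analysis["pain_answer_inconsistencies"] = inconsistent
        analysis["mixed_effects_models"] = "not implemented"
        results["analysis"] = analysis

        # --- permtest ------------------------------------------------
        stage = "permtest"
        if config.n_perm > 0 and len(cases) > 0:
            perm = permutation.permutation_test(
                case_ids=list(cases),
                cohort_ids=list(cohort["dog_id"]),
                pedigree=pedigree,
                parent_axis=config.parent_axis,
                n_perm=config.n_perm,
                seed=config.seed,
                weighting=config.weighting,
            )
            other = permutation.contribution_statistic(
                [d for d in cases if d in set(cohort["dog_id"])], pedigree,
                config.parent_axis,
                "plain_mean" if config.weighting == "offspring_weighted"
                else "offspring_weighted",
            )
            results["permutation"] = {
                "parent_axis": config.parent_axis,
                "weighting": config.weighting,
                "observed_statistic": perm.observed.statistic,
                "observed_statistic_alt_weighting": other.statistic,
                "n_parents": perm.observed.n_parents,
                "n_dogs": perm.observed.n_dogs,
                "pct_2_5": perm.pct_2_5,
                "pct_97_5": perm.pct_97_5,
                "p_value": perm.p_value,
                "n_perm": perm.n_perm,
                "seed": perm.seed,
                "significant_clustering": perm.significant_clustering,
            }
            _write_json(out / "permutation.json", results["permutation"])
            pd.DataFrame({"statistic": perm.null_values}).to_csv(
                out / "null_distribution.csv", index=False
            )
            paths["permutation"] = out / "permutation.json"
            paths["null_distribution"] = out / "null_distribution.csv"
        else:
            results["permutation"] = None
            log.info("permtest: skipped (n_perm=0)")

        if config.include_reference_tables:
            results["reference"] = reference_estimates(config.level, config.ci_method)

        # --- report & manifest --------------------------------------
        stage = "report"
        _write_json(out / "results.json", results)
        paths["results"] = out / "results.json"
        (out / "report.md").write_text(_markdown_report(results, config))
        paths["report"] = out / "report.md"
        manifest = {
            name: _sha256(p) for name, p in sorted(paths.items()) if p.is_file()
        }
        _write_json(out / "manifest.json", manifest)
        paths["manifest"] = out / "manifest.json"
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for p in paths.values():
            if Path(p).is_file():
                Path(p).rename(failed / Path(p).name)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return RunReport(
        config=config,
        results=_jsonable(results),
        paths={k: str(v) for k, v in paths.items()},
        manifest=manifest,
    )
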