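"""End-to-end orchestration: simulate -> kinetics -> GLM -> behaviour -> QC -> PLS.

``run_pipeline`` executes the whole multimodal analysis from a single
config, either on ready-made paired ROI matrices ("matrices" level) or
from raw synthetic signals ("raw" level: TAC fitting and GLM contrast
extraction are actually run).  One global seed fans out into per-stage
seeds via stable hashing of stage names, so each stage is independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import cohort as syn
from . import fmri, kinetics, pls

logger = logging.getLogger("synlink")

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "derive_seed", "write_report"]


def derive_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 from a global seed and a stage name."""
    return (int(base_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Single configuration for the full pipeline."""

    cohort: syn.CohortSpec = field(default_factory=syn.CohortSpec)
    task: str = "switching"
    level: str = "matrices"  # "matrices" or "raw"
    seed: int | None = None  # overrides cohort.seed via per-stage derivation
    # QC thresholds (study defaults)
    performance_sd: float = 2.5
    motion_threshold_mm: float = 0.5
    motion_consecutive: int = 30
    # PLS settings
    n_components: int = 2
    n_permutations: int = 1000
    # raw-level nuisance magnitudes
    bold_noise_sd: float = 0.1
    frame_noise_scale: float = 0.02

    def __post_init__(self):
        if self.task not in ("switching", "nback"):
            raise ValueError("task must be 'switching' or 'nback'")
        if self.level not in ("matrices", "raw"):
            raise ValueError("level must be 'matrices' or 'raw'")
        for name in ("performance_sd", "motion_threshold_mm", "motion_consecutive",
                     "n_components", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and not isinstance(d["cohort"], syn.CohortSpec):
            d["cohort"] = syn.CohortSpec.from_dict(d["cohort"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class AnalysisReport:
    """Everything the analysis produced, with seeds; the JSON/CSV source of truth."""

    config: dict
    seeds: dict
    pet: pd.DataFrame  # included subjects x ROIs (DVRcs or latent units)
    fmri_pe: pd.DataFrame  # included subjects x ROIs (contrast PE)
    behaviour: pd.DataFrame
    exclusions: pd.DataFrame
    plsca: dict
    plsr: dict
    exploratory: pd.DataFrame
    variability: pd.DataFrame
    truth: syn.GroundTruth | None = None


def _raw_pet_matrix(spec, X, config, rng_seed):
    """TAC simulation + 1TC fitting + DVR normalisation -> subjects x ROI DVRcs."""
    base_dvr, dvr_scale = 3.0, 0.1
    col_sd = X.std(axis=0, ddof=1).replace(0, 1.0)
    targets = base_dvr + dvr_scale * (X / col_sd)
    aif = syn.default_aif()
    tacs, truth_kin = syn.generate_subject_tacs(
        spec,
        aif=aif,
        frame_noise_scale=config.frame_noise_scale,
        dvr_targets=targets,
        seed=rng_seed,
    )
    rows = {}
    for subj, roi_tacs in tacs.items():
        vt = {}
        for roi, tac in roi_tacs.items():
            fit = kinetics.fit_1tc(tac, aif)
            if not fit.converged:
                raise RuntimeError(f"kinetics stage failed for {subj}/{roi}")
            vt[roi] = fit.vt
        dvr = kinetics.compute_dvr(vt, syn.PET_REFERENCE_LABEL)
        rows[subj] = dvr["dvr_cs"].drop(syn.PET_REFERENCE_LABEL)
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(X.index), list(X.columns)]


def _raw_fmri_matrix(spec, Y, config, design, rng_seed):
    """BOLD forward simulation + GLM + contrast -> subjects x ROI PE matrix."""
    pe_scale, baseline_beta = 0.2, 0.5
    col_sd = Y.std(axis=0, ddof=1).replace(0, 1.0)
    target_pe = pe_scale * (Y / col_sd)
    if design.task_name == "switching":
        tr_s, n_vol, contrast = fmri.SWITCH_TR_S, fmri.SWITCH_N_VOLUMES, "switch"
        betas_of = lambda pe: {"no_switch": np.full(len(pe), baseline_beta),
                               "switch": baseline_beta + pe}
    else:
        tr_s, n_vol, contrast = fmri.NBACK_TR_S, fmri.NBACK_N_VOLUMES, "wm_load"
        betas_of = lambda pe: {"0back": np.full(len(pe), baseline_beta),
                               "1back": baseline_beta + pe,
                               "2back": baseline_beta + pe}
    dm = fmri.build_design_matrix(design, tr_s, n_vol)
    drift = {"periods_s": [400.0, 250.0], "amplitudes": [0.3, 0.2]}
    rows = {}
    for i, subj in enumerate(Y.index):
        pe = target_pe.loc[subj].to_numpy()
        run = syn.generate_bold_run(
            design, betas_of(pe), noise_sd=config.bold_noise_sd, drift=drift,
            tr_s=tr_s, n_volumes=n_vol, seed=derive_seed(rng_seed, f"bold:{subj}"),
        )
        res = fmri.fit_glm(run, dm)
        rows[subj] = pd.Series(
            fmri.compute_contrast(res, contrast).pe, index=Y.columns
        )
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(Y.index), list(Y.columns)]


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the full multimodal analysis described by ``config``."""
    spec = config.cohort
    if config.seed is not None:
        spec = syn.CohortSpec.from_dict(
            {**spec.to_dict(), "seed": derive_seed(config.seed, "cohort")}
        )
    seeds = {
        "cohort": spec.seed,
        "behaviour": derive_seed(spec.seed, "behaviour"),
        "trials": derive_seed(spec.seed, "trials"),
        "pet_raw": derive_seed(spec.seed, "pet_raw"),
        "fmri_raw": derive_seed(spec.seed, "fmri_raw"),
        "permutation_ca": derive_seed(spec.seed, "permutation_ca"),
        "permutation_r": derive_seed(spec.seed, "permutation_r"),
    }
    logger.info("cohort stage: n=%d seed=%d", spec.n_subjects, spec.seed)
    X, Y, truth = syn.generate_paired_matrices(spec)

    design = (
        fmri.switching_design(seed=spec.seed)
        if config.task == "switching"
        else fmri.nback_design(seed=spec.seed)
    )
    behaviour_spec = spec.behaviour
    if config.task == "nback" and behaviour_spec.outcome_name == "switch_cost_s":
        behaviour_spec = syn.BehaviourSpec.nback_default()

    # behavioural outcomes: trial records at raw level, direct draws otherwise
    perf_scores = {}
    outcome = {}
    if config.level == "raw":
        for i, subj in enumerate(X.index):
            rec = syn.generate_trial_records(
                design,
                truth.pet_scores[i, behaviour_spec.component_index],
                behaviour_spec,
                seed=derive_seed(seeds["trials"], subj),
            )
            stats = fmri.behavioural_stats(rec, config.task)
            if config.task == "switching":
                outcome[subj] = stats["switch_cost_s"]
                perf_scores[subj] = 100.0 * rec["correct"].mean()
            else:
                outcome[subj] = stats["mean_12back_accuracy"]
                perf_scores[subj] = stats["mean_12back_accuracy"]
        outcome = pd.Series(outcome, name=behaviour_spec.outcome_name)
    else:
        outcome = syn.generate_behaviour_outcomes(
            truth, behaviour_spec, seed=seeds["behaviour"], subject_ids=list(X.index)
        )
        perf_scores = {s: 100.0 for s in X.index}  # no trial data: nobody excludable

    # modality matrices
    if config.level == "raw":
        logger.info("kinetics stage (raw TAC fitting)")
        pet = _raw_pet_matrix(spec, X, config, seeds["pet_raw"])
        logger.info("GLM stage (raw BOLD fitting)")
        fmri_pe = _raw_fmri_matrix(spec, Y, config, design, seeds["fmri_raw"])
    else:
        pet, fmri_pe = X.copy(), Y.copy()

    # inter-stage validation
    if list(pet.index) != list(fmri_pe.index):
        bad = sorted(set(pet.index) ^ set(fmri_pe.index))
        raise ValueError(f"modality subject mismatch: {bad}")

    exclusions = fmri.qc_exclusions(
        perf_scores,
        performance_sd=config.performance_sd,
        motion_threshold_mm=config.motion_threshold_mm,
        motion_consecutive=config.motion_consecutive,
    )
    included = [s for s in pet.index if exclusions.loc[s, "included"]]
    logger.info("QC: %d/%d subjects retained", len(included), len(pet.index))
    pet_in = pet.loc[included]
    fmri_in = fmri_pe.loc[included]
    outcome_in = outcome.loc[included]

    variability = kinetics.variability_stats(pet_in)

    ca = pls.pls_canonical_fit(pet_in, fmri_in, n_components=config.n_components)
    ca_perm = pls.permutation_test_pls_ca(
        pet_in, fmri_in, n_components=config.n_components,
        n_permutations=config.n_permutations, seed=seeds["permutation_ca"],
    )
    plsr_fit = pls.pls_regression(pet_in, outcome_in, n_components=config.n_components)
    plsr_perm = pls.permutation_test_plsr(
        pet_in, outcome_in, n_components=config.n_components,
        n_permutations=config.n_permutations, seed=seeds["permutation_r"],
    )

    rows = []
    for roi in pet_in.columns:
        rr = pls.pearson_with_p(pet_in[roi], fmri_in[roi])
        rows.append({"roi": roi, "pair": "pet_vs_fmri",
                     "r": rr["r"], "p_uncorrected": rr["p_two_sided"]})
        rb = pls.pearson_with_p(pet_in[roi], outcome_in)
        rows.append({"roi": roi, "pair": f"pet_vs_{outcome.name}",
                     "r": rb["r"], "p_uncorrected": rb["p_two_sided"]})
    exploratory = pd.DataFrame(rows)

    plsca_table = {
        "components": [
            {
                "component": i + 1,
                "r": float(ca.correlations[i]),
                "cov": float(ca.covariances[i]),
                "p": float(ca_perm.p_values[i]),
                "pet_weights": dict(zip(pet_in.columns, ca.x_weights[:, i].tolist())),
                "fmri_weights": dict(zip(fmri_in.columns, ca.y_weights[:, i].tolist())),
            }
            for i in range(config.n_components)
        ],
        "n_permutations": config.n_permutations,
        "seed": seeds["permutation_ca"],
    }
    plsr_table = {
        "r_squared": plsr_fit.r_squared,
        "rmse": plsr_fit.rmse,
        "p": float(plsr_perm.p_values[0]),
        "outcome": str(outcome.name),
        "pet_weights": [
            dict(zip(pet_in.columns, plsr_fit.x_weights[:, i].tolist()))
            for i in range(config.n_components)
        ],
        "n_permutations": config.n_permutations,
        "seed": seeds["permutation_r"],
    }

    return AnalysisReport(
        config=config.to_dict(),
        seeds=seeds,
        pet=pet_in,
        fmri_pe=fmri_in,
        behaviour=outcome_in.to_frame(),
        exclusions=exclusions,
        plsca=plsca_table,
        plsr=plsr_table,
        exploratory=exploratory,
        variability=variability,
        truth=truth,
    )


def write_report(report: AnalysisReport, outdir) -> Path:
    """Serialise a report: results.json plus tidy CSV tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.pet.rename_axis("subject").to_csv(out / "pet_dvr.csv")
    report.fmri_pe.rename_axis("subject").to_csv(out / "fmri_pe.csv")
    report.behaviour.rename_axis("subject").to_csv(out / "behaviour.csv")
    report.exclusions.rename_axis("subject").to_csv(out / "exclusions.csv")
    report.exploratory.to_csv(out / "exploratory_correlations.csv", index=False)
    report.variability.rename_axis("roi").to_csv(out / "variability.csv")
    payload = {
        "config": report.config,
        "seeds": report.seeds,
        "pls_ca": report.plsca,
        "pls_r": report.plsr,
        "n_subjects_included": int(report.pet.shape[0]),
        "excluded": {
            str(s): list(report.exclusions.loc[s, "reasons"])
            for s in report.exclusions.index
            if not report.exclusions.loc[s, "included"]
        },
    }
    (out / "results.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    if report.truth is not None:
        report.truth.to_json(out / "truth.json")
    return out
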