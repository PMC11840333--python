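"""Seeded synthetic cohorts with planted cross-modal latent structure.

The study design being emulated pairs, for each subject, (a) a regional
PET distribution-volume-ratio profile (synaptic terminal density proxy)
and (b) a regional task-fMRI contrast-estimate profile, plus behavioural
summaries (switch cost, N-back accuracy).  No subject data are public, so
everything downstream is exercised on cohorts generated here, at every
level of rawness:

* ready-made paired subjects x ROI matrices whose cross-block structure
  is planted: X = sum_j t_j p_j' + E_x and Y = sum_j u_j q_j' + E_y, with
  per-component latent score pairs (t_j, u_j) bivariate standard normal
  at a configurable correlation rho_j (drawn via the Cholesky factor of
  the 2x2 correlation matrix), components mutually independent, and
  i.i.d. Gaussian feature noise;
* regional time-activity curves from the 1TC forward model with a shared
  input function and duration-scaled frame noise, with known kinetic
  ground truth;
* ROI-level BOLD runs from the GLM forward model (HRF-convolved design
  times planted amplitudes, plus slow cosine drift and white noise);
* trial-level behavioural records whose subject-level outcome is
  linearly coupled to a PET latent score with residual variance chosen
  to hit a target population R^2.

Identical ``CohortSpec`` (including seed) reproduces every byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fmri import BOLDRun, TaskDesign, _convolved_regressors, nback_design, switching_design
from .kinetics import (
    DEFAULT_VB,
    FrameSchedule,
    InputFunction,
    OneTCParams,
    TissueTAC,
    simulate_tac,
    write_tac_table,
)

__all__ = [
    "LatentComponentSpec",
    "BehaviourSpec",
    "CohortSpec",
    "GroundTruth",
    "SWITCHING_ROIS",
    "PET_REFERENCE_LABEL",
    "default_aif",
    "default_kinetic_ranges",
    "generate_paired_matrices",
    "generate_behaviour_outcomes",
    "generate_subject_tacs",
    "generate_bold_run",
    "generate_trial_records",
    "write_cohort_bundle",
    "load_cohort_bundle",
]

# the six task-switching ROIs used for the paired matrices; the PET
# reference region (centrum semiovale) additionally appears in TACs only
SWITCHING_ROIS = (
    "dlpfc",
    "posterior_frontal",
    "insula",
    "acc",
    "parietal_precuneus",
    "thalamus_putamen",
)
PET_REFERENCE_LABEL = "centrum_semiovale"


@dataclass(frozen=True)
class LatentComponentSpec:
    """One planted cross-modal component.

    Either explicit per-ROI loading vectors or just their norms may be
    given; unspecified directions are drawn as seeded random orthonormal
    vectors and scaled to the requested norms.
    """

    latent_correlation: float
    pet_norm: float = 1.0
    fmri_norm: float = 1.0
    pet_loadings: tuple[float, ...] | None = None
    fmri_loadings: tuple[float, ...] | None = None

    def __post_init__(self):
        if not -1.0 <= self.latent_correlation <= 1.0:
            raise ValueError("latent correlation must lie in [-1, 1]")
        for name in ("pet", "fmri"):
            vec = getattr(self, f"{name}_loadings")
            if vec is not None:
                v = tuple(float(x) for x in vec)
                object.__setattr__(self, f"{name}_loadings", v)
                norm = float(np.linalg.norm(v))
                if norm == 0:
                    raise ValueError(f"{name} loading vector must be nonzero")
                object.__setattr__(self, f"{name}_norm", norm)
            elif getattr(self, f"{name}_norm") <= 0:
                raise ValueError(f"{name} loading norm must be positive")

    @property
    def norm_product(self) -> float:
        return self.pet_norm * self.fmri_norm


@dataclass(frozen=True)
class BehaviourSpec:
    """Linear coupling of a behavioural outcome to a PET latent score.

    outcome = intercept + scale * t_j + e, with Var(scale*t_j)/Var(outcome)
    equal to ``target_r_squared`` (t_j is standard normal).  When the
    coupling is switched off (scale = 0 or target R^2 = 0) the residual
    SD must be supplied via ``residual_sd``.
    """

    outcome_name: str = "switch_cost_s"
    target_r_squared: float = 0.45
    intercept: float = 0.100
    scale: float = 0.055
    component_index: int = 0
    residual_sd: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.target_r_squared < 1.0:
            raise ValueError("target R^2 must lie in [0, 1)")
        if self.outcome_name not in ("switch_cost_s", "mean_12back_accuracy"):
            raise ValueError(f"unknown outcome {self.outcome_name!r}")

    def residual_sd_value(self) -> float:
        """Residual SD implied by the target R^2 (or the explicit override)."""
        if self.residual_sd is not None:
            return float(self.residual_sd)
        if self.scale != 0 and self.target_r_squared > 0:
            r2 = self.target_r_squared
            return abs(self.scale) * float(np.sqrt((1.0 - r2) / r2))
        return 1.0  # decoupled outcome with no stated noise: unit SD

    @classmethod
    def nback_default(cls) -> "BehaviourSpec":
        # accuracy in percent: ~90% mean, ~3 points per latent SD
        return cls("mean_12back_accuracy", 0.45, 90.0, 3.0)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort (seed included)."""

    n_subjects: int = 25
    roi_labels: tuple[str, ...] = SWITCHING_ROIS
    components: tuple[LatentComponentSpec, ...] = (
        # defaults mirror the two estimated cross-modal components of the
        # study cohort: a dominant weakly-correlated component and a
        # smaller strongly-correlated one
        LatentComponentSpec(0.28, pet_norm=2.0, fmri_norm=2.0),
        LatentComponentSpec(0.63, pet_norm=1.0, fmri_norm=1.0),
    )
    feature_noise_sd: float = 0.5
    behaviour: BehaviourSpec = field(default_factory=BehaviourSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        if self.feature_noise_sd < 0:
            raise ValueError("feature noise SD must be non-negative")
        comps = tuple(self.components)
        if len(comps) > len(self.roi_labels) - 1:
            raise ValueError("component count exceeds the ROI rank budget")
        order = sorted(range(len(comps)), key=lambda j: -comps[j].norm_product)
        object.__setattr__(self, "components", tuple(comps[j] for j in order))
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def subject_ids(self) -> list[str]:
        return [f"sub-{i + 1:03d}" for i in range(self.n_subjects)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        if "components" in d:
            d["components"] = tuple(
                c if isinstance(c, LatentComponentSpec) else LatentComponentSpec(**c)
                for c in d["components"]
            )
        if "behaviour" in d and not isinstance(d["behaviour"], BehaviourSpec):
            d["behaviour"] = BehaviourSpec(**d["behaviour"])
        if "roi_labels" in d:
            d["roi_labels"] = tuple(d["roi_labels"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Book-keeping for recovery tests: every latent draw and coefficient."""

    pet_scores: np.ndarray  # n x k (t_j)
    fmri_scores: np.ndarray  # n x k (u_j)
    latent_correlations: np.ndarray
    pet_loadings: np.ndarray  # n_rois x k
    fmri_loadings: np.ndarray
    seed: int
    behaviour_coefficients: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "pet_scores": self.pet_scores.tolist(),
            "fmri_scores": self.fmri_scores.tolist(),
            "latent_correlations": self.latent_correlations.tolist(),
            "pet_loadings": self.pet_loadings.tolist(),
            "fmri_loadings": self.fmri_loadings.tolist(),
            "seed": self.seed,
            "behaviour_coefficients": self.behaviour_coefficients,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            pet_scores=np.asarray(d["pet_scores"]),
            fmri_scores=np.asarray(d["fmri_scores"]),
            latent_correlations=np.asarray(d["latent_correlations"]),
            pet_loadings=np.asarray(d["pet_loadings"]),
            fmri_loadings=np.asarray(d["fmri_loadings"]),
            seed=d["seed"],
            behaviour_coefficients=d.get("behaviour_coefficients", {}),
        )


def _draw_loadings(
    components: Sequence[LatentComponentSpec],
    n_rois: int,
    which: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Loading matrix (n_rois x k): explicit vectors, or seeded
    variance-balanced orthogonal directions scaled to the requested norms.

    Default directions keep every feature's planted variance equal across
    the block (flat-magnitude entries): the first is uniform, the second
    a seeded balanced +/- pattern, further ones QR-orthonormal (no longer
    flat).  Equal column variances make the downstream column
    standardisation a uniform rescaling, so the planted geometry — and
    hence the planted canonical correlations — survive it; mutual
    orthogonality keeps components from leaking into each other.
    """
    k = len(components)
    out = np.empty((n_rois, k))
    free = [j for j, c in enumerate(components) if getattr(c, f"{which}_loadings") is None]
    if free:
        dirs = np.zeros((n_rois, len(free)))
        flat = 1.0 / np.sqrt(n_rois)
        n_flat = 0
        if len(free) >= 1:
            dirs[:, 0] = flat * (1.0 if rng.random() < 0.5 else -1.0)
            n_flat = 1
        if len(free) >= 2 and n_rois % 2 == 0:
            signs = np.concatenate(
                [np.ones(n_rois // 2), -np.ones(n_rois // 2)]
            )
            rng.shuffle(signs)
            dirs[:, 1] = flat * signs
            n_flat = 2
        if len(free) > n_flat:
            raw = rng.standard_normal((n_rois, len(free) - n_flat))
            raw -= dirs[:, :n_flat] @ (dirs[:, :n_flat].T @ raw)
            q, r = np.linalg.qr(raw)
            dirs[:, n_flat:] = q * np.sign(np.diag(r))
        for col, j in enumerate(free):
            out[:, j] = dirs[:, col] * getattr(components[j], f"{which}_norm")
    for j, c in enumerate(components):
        vec = getattr(c, f"{which}_loadings")
        if vec is not None:
            v = np.asarray(vec, dtype=float)
            if v.size != n_rois:
                raise ValueError(
                    f"{which} loading vector length {v.size} != {n_rois} ROIs"
                )
            out[:, j] = v
    return out


def generate_paired_matrices(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Subjects x ROI matrices for both modalities with planted components.

    Returns (pet_matrix, fmri_matrix, truth); matrices are DataFrames
    indexed by subject id with the spec's ROI columns.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, len(spec.roi_labels)
    k = spec.n_components
    P = _draw_loadings(spec.components, p, "pet", rng)
    Q = _draw_loadings(spec.components, p, "fmri", rng)
    T = np.empty((n, k))
    U = np.empty((n, k))
    rhos = np.array([c.latent_correlation for c in spec.components])
    for j, rho in enumerate(rhos):
        z = rng.standard_normal((n, 2))
        T[:, j] = z[:, 0]
        U[:, j] = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    X = T @ P.T + spec.feature_noise_sd * rng.standard_normal((n, p))
    Y = U @ Q.T + spec.feature_noise_sd * rng.standard_normal((n, p))
    subjects = spec.subject_ids
    truth = GroundTruth(
        pet_scores=T, fmri_scores=U, latent_correlations=rhos,
        pet_loadings=P, fmri_loadings=Q, seed=spec.seed,
    )
    return (
        pd.DataFrame(X, index=subjects, columns=spec.roi_labels),
        pd.DataFrame(Y, index=subjects, columns=spec.roi_labels),
        truth,
    )


def generate_behaviour_outcomes(
    truth: GroundTruth,
    behaviour: BehaviourSpec,
    seed: int | None = None,
    subject_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Subject-level behavioural outcomes coupled to a PET latent score."""
    rng = np.random.default_rng(truth.seed + 104729 if seed is None else seed)
    t = truth.pet_scores[:, behaviour.component_index]
    sd_e = behaviour.residual_sd_value()
    coupled = behaviour.scale if behaviour.target_r_squared > 0 else 0.0
    y = behaviour.intercept + coupled * t + sd_e * rng.standard_normal(t.size)
    truth.behaviour_coefficients = {
        "outcome_name": behaviour.outcome_name,
        "intercept": behaviour.intercept,
        "scale": float(coupled),
        "residual_sd": float(sd_e),
        "component_index": behaviour.component_index,
        "population_r_squared": behaviour.target_r_squared,
    }
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(t.size)]
    return pd.Series(y, index=list(subject_ids), name=behaviour.outcome_name)


def default_aif(peak_kbq_ml: float = 120.0, p2wb_ratio: float = 1.3) -> InputFunction:
    """Synthetic arterial input: fast gamma-variate peak with biexponential tail.

    Shaped like a metabolite-corrected plasma curve after a 20-s bolus:
    sharp peak near 1 min, washout over 90 min.  Sampled densely early
    (2 s) and progressively sparser late; piecewise-linear between
    samples, matching the forward model's interpolation.
    """
    t_s = np.unique(
        np.concatenate(
            [
                np.arange(0.0, 120.0, 2.0),
                np.arange(120.0, 600.0, 10.0),
                np.arange(600.0, 1800.0, 30.0),
                np.arange(1800.0, 5401.0, 60.0),
            ]
        )
    )
    t = t_s / 60.0  # minutes
    peak = t * np.exp(-t / 0.7)
    tail = (0.15 * np.exp(-t / 8.0) + 0.075 * np.exp(-t / 70.0)) * (
        1.0 - np.exp(-((t / 0.7) ** 2))
    )
    curve = peak / np.max(peak) + tail
    curve = curve * (peak_kbq_ml / np.max(curve))
    return InputFunction(t_s, curve, p2wb_ratio)


def default_kinetic_ranges(roi_labels: Sequence[str] = SWITCHING_ROIS) -> dict:
    """Per-ROI (K1, k2) uniform draw intervals (per-minute units).

    Grey-matter ROIs get V_T in roughly 10-27 mL/cm^3; the centrum
    semiovale entry sits at the low-V_T end (~3-6), as expected for a
    region with minimal specific binding.
    """
    ranges = {roi: {"k1": (0.25, 0.40), "k2": (0.015, 0.025)} for roi in roi_labels}
    ranges[PET_REFERENCE_LABEL] = {"k1": (0.12, 0.18), "k2": (0.028, 0.040)}
    return ranges


def generate_subject_tacs(
    spec: CohortSpec,
    kinetic_ranges: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    aif: InputFunction | None = None,
    schedule: FrameSchedule | None = None,
    frame_noise_scale: float = 0.05,
    dvr_targets: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[dict[str, dict[str, TissueTAC]], pd.DataFrame]:
    """Per-subject regional TACs from the 1TC forward model, truth recorded.

    Frame noise is multiplicative zero-mean Gaussian with SD scaled by
    1/sqrt(frame duration) (60-s reference frame), mimicking count
    statistics.  When ``dvr_targets`` (subjects x ROIs) is given, each
    grey-matter region's k2 is set so that its true DVRcs equals the
    target, tying the PET matrices to the planted latent structure.

    Returns ``(tacs, truth)`` where ``tacs[subject][roi]`` is a
    TissueTAC and ``truth`` is a tidy frame of the drawn K1/k2/V_T.
    """
    if aif is None:
        aif = default_aif()
    if schedule is None:
        schedule = FrameSchedule.default()
    if kinetic_ranges is None:
        kinetic_ranges = default_kinetic_ranges(spec.roi_labels)
    for roi, rr in kinetic_ranges.items():
        for par in ("k1", "k2"):
            lo, hi = rr[par]
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid {par} range for {roi!r}")
    rng = np.random.default_rng(spec.seed + 15485863 if seed is None else seed)
    rois = [PET_REFERENCE_LABEL] + [r for r in kinetic_ranges if r != PET_REFERENCE_LABEL]
    tacs: dict[str, dict[str, TissueTAC]] = {}
    rows = []
    for subj in spec.subject_ids:
        tacs[subj] = {}
        vt_cs = None
        for roi in rois:
            rr = kinetic_ranges[roi]
            k1 = rng.uniform(*rr["k1"])
            if roi != PET_REFERENCE_LABEL and dvr_targets is not None:
                dvr = float(dvr_targets.loc[subj, roi])
                if dvr <= 0:
                    raise ValueError(f"DVR target must be positive ({subj}, {roi})")
                k2 = k1 / (dvr * vt_cs)
            else:
                k2 = rng.uniform(*rr["k2"])
            if roi == PET_REFERENCE_LABEL:
                vt_cs = k1 / k2
            params = OneTCParams(k1, k2, DEFAULT_VB)
            tac = simulate_tac(params, aif, schedule)
            act = tac.activity
            if frame_noise_scale > 0:
                eps = rng.standard_normal(act.size)
                act = act * (
                    1.0
                    + frame_noise_scale
                    * np.sqrt(60.0 / schedule.durations_s)
                    * eps
                )
            tacs[subj][roi] = TissueTAC(schedule, act, roi_label=roi)
            rows.append(
                {"subject": subj, "roi": roi, "k1": k1, "k2": k2, "vt": k1 / k2}
            )
    return tacs, pd.DataFrame(rows)


def generate_bold_run(
    design: TaskDesign,
    betas: Mapping[str, float | Sequence[float]],
    noise_sd: float = 0.0,
    drift: Mapping[str, Sequence[float]] | None = None,
    tr_s: float = 3.0,
    n_volumes: int = 180,
    seed: int | None = None,
    baseline: float = 0.0,
) -> BOLDRun:
    """ROI-level BOLD run from the GLM forward model.

    signal = sum_c beta_c * (HRF-convolved regressor of condition c)
           + baseline + slow cosine drift + i.i.d. Gaussian noise.

    ``betas`` maps each design condition to a scalar or per-series
    vector.  ``drift`` is {"periods_s": [...], "amplitudes": [...]}
    (optionally "phases"); periods longer than the high-pass cut-off make
    the drift removable by construction.
    """
    if n_volumes * tr_s + 1e-9 < design.total_duration_s:
        raise ValueError("design longer than the run")
    missing = set(design.conditions) - set(betas)
    if missing:
        raise ValueError(f"betas missing for conditions {sorted(missing)}")
    regs, _ = _convolved_regressors(design, tr_s, n_volumes)
    amp = np.atleast_2d(
        np.column_stack([np.atleast_1d(np.asarray(betas[c], float)) for c in design.conditions])
    )
    n_series = amp.shape[0]
    R = regs[[c for c in design.conditions]].to_numpy()  # n_vol x n_cond
    signal = R @ amp.T + baseline
    if drift is not None:
        # drift as DCT-II cosines (zero-slope at run boundaries): each
        # requested period is snapped to the nearest basis frequency, so a
        # high-pass with a shorter cut-off removes the drift exactly
        periods = np.asarray(drift["periods_s"], dtype=float)
        amps = np.asarray(drift["amplitudes"], dtype=float)
        i = np.arange(n_volumes)
        d = np.zeros(n_volumes)
        for per, a in zip(periods, amps):
            k = max(int(round(2.0 * n_volumes * tr_s / per)), 1)
            d += a * np.cos(np.pi * k * (i + 0.5) / n_volumes)
        signal = signal + d[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + noise_sd * rng.standard_normal((n_volumes, n_series))
    return BOLDRun(signal, tr_s)


def generate_trial_records(
    design: TaskDesign,
    latent_score: float,
    behaviour: BehaviourSpec,
    seed: int | None = None,
    base_rt_s: float = 0.65,
    rt_sd_s: float = 0.15,
    lapse_rate: float = 0.04,
) -> pd.DataFrame:
    """Trial-level behavioural record realising the planted coupling.

    Switching: the subject's expected switch cost is
    intercept + scale * latent + e, with Var(e) reduced by the sampling
    variance of the trial-mean difference so the realised cohort-level
    outcome keeps the target population R^2.  N-back: per-trial
    correctness is Bernoulli with the block accuracy coupled likewise
    (accuracy in percent).
    """
    if behaviour.target_r_squared >= 1.0:
        raise ValueError("target R^2 must be < 1")
    rng = np.random.default_rng(seed)
    ev = design.events.copy()
    if design.task_name == "switching":
        n_sw = int((ev["condition"] == "switch").sum())
        n_ns = int((ev["condition"] == "no_switch").sum())
        trial_var = rt_sd_s**2 * (1.0 / n_sw + 1.0 / n_ns)
        subj_var = max(behaviour.residual_sd_value() ** 2 - trial_var, 0.0)
        mu_cost = (
            behaviour.intercept
            + behaviour.scale * latent_score
            + np.sqrt(subj_var) * rng.standard_normal()
        )
        rt = base_rt_s + rt_sd_s * rng.standard_normal(len(ev))
        rt = rt + np.where(ev["condition"] == "switch", mu_cost, 0.0)
        ev["response_time_s"] = np.clip(rt, 0.15, None)
        ev["correct"] = rng.random(len(ev)) > lapse_rate
    elif design.task_name == "nback":
        n_trials_per_cond = int((ev["condition"] == "1back").sum())
        # accuracy in percent; sampling variance of the mean of the 1- and
        # 2-back condition accuracies
        trial_p = min(max(behaviour.intercept / 100.0, 0.05), 0.99)
        trial_var = 100.0**2 * trial_p * (1 - trial_p) / (2.0 * n_trials_per_cond)
        subj_var = max(behaviour.residual_sd_value() ** 2 - trial_var, 0.0)
        acc = (
            behaviour.intercept
            + behaviour.scale * latent_score
            + np.sqrt(subj_var) * rng.standard_normal()
        )
        p_correct = min(max(acc / 100.0, 0.02), 1.0)
        ev["response_time_s"] = np.clip(
            0.6 + 0.1 * rng.standard_normal(len(ev)), 0.15, 1.9
        )
        ev["correct"] = rng.random(len(ev)) < p_correct
    else:
        raise ValueError(f"design has no trial_type rule for task {design.task_name!r}")
    return ev


def write_cohort_bundle(
    outdir,
    pet: pd.DataFrame,
    fmri: pd.DataFrame,
    behaviour: pd.Series | pd.DataFrame,
    truth: GroundTruth,
    tacs: Mapping[str, Mapping[str, TissueTAC]] | None = None,
    events: Mapping[str, pd.DataFrame] | None = None,
    aif: InputFunction | None = None,
) -> Path:
    """Write a cohort directory: pet_dvr.csv, fmri_pe.csv, behaviour.csv,
    truth.json, plus optional per-subject TAC and events TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pet.rename_axis("subject").to_csv(out / "pet_dvr.csv")
    fmri.rename_axis("subject").to_csv(out / "fmri_pe.csv")
    beh = behaviour.to_frame() if isinstance(behaviour, pd.Series) else behaviour
    beh.rename_axis("subject").to_csv(out / "behaviour.csv")
    truth.to_json(out / "truth.json")
    if aif is not None:
        aif.to_tsv(out / "aif.tsv")
    if tacs is not None:
        tdir = out / "tacs"
        tdir.mkdir(exist_ok=True)
        for subj, roi_tacs in tacs.items():
            sched = next(iter(roi_tacs.values())).schedule
            write_tac_table(
                tdir / f"{subj}_tacs.tsv",
                sched,
                {roi: t.activity for roi, t in roi_tacs.items()},
            )
    if events is not None:
        edir = out / "events"
        edir.mkdir(exist_ok=True)
        for subj, ev in events.items():
            cols = ["onset_s", "duration_s", "condition"]
            extra = [c for c in ("response_time_s", "correct") if c in ev.columns]
            ev[cols + extra].rename(
                columns={
                    "onset_s": "onset",
                    "duration_s": "duration",
                    "condition": "trial_type",
                    "response_time_s": "response_time",
                }
            ).to_csv(edir / f"{subj}_events.tsv", sep="\t", index=False)
    return out


def load_cohort_bundle(bundle_dir) -> dict:
    """Load the tabular core of a cohort bundle written by write_cohort_bundle."""
    d = Path(bundle_dir)
    out = {
        "pet": pd.read_csv(d / "pet_dvr.csv", index_col="subject"),
        "fmri": pd.read_csv(d / "fmri_pe.csv", index_col="subject"),
        "behaviour": pd.read_csv(d / "behaviour.csv", index_col="subject"),
    }
    if (d / "truth.json").exists():
        out["truth"] = GroundTruth.from_json(d / "truth.json")
    if (d / "aif.tsv").exists():
        out["aif"] = InputFunction.from_tsv(d / "aif.tsv")
    return out
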