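"""Task designs, first-level GLM with a gamma HRF, contrasts, behaviour and QC.

Implements the first-level analysis chain for two in-scanner executive
tasks:

* an N-back working-memory block design (0/1/2-back; 6 blocks per
  condition, each 20 s of ten 2-s trials followed by 10 s rest; 9 min
  total, acquired as 270 volumes at TR = 2 s), and
* an event-related task-switching design (150 trials; the cue colour
  changes on 42 trials — "switch" — and repeats on 108 — "no-switch";
  180 volumes at TR = 3 s).

Task regressors are boxcars convolved with a gamma HRF (mean lag 6 s,
SD 3 s, unit area), with finite-difference temporal derivatives.  The
high-pass filter (100 s cut-off) is an exact projection onto the
orthogonal complement of a low-frequency discrete-cosine basis, applied
identically to data and model.  Behavioural summaries are block accuracy
(percent correct of responded trials) and switch cost (mean RT on switch
minus no-switch trials).  QC mirrors the study rules: task performance
below group mean − 2.5 SD, or mean relative RMS displacement above
0.5 mm persisting for more than 30 consecutive volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gamma as gamma_dist

__all__ = [
    "TaskDesign",
    "BOLDRun",
    "DesignMatrix",
    "ContrastResult",
    "GLMResult",
    "nback_design",
    "switching_design",
    "gamma_hrf",
    "dct_highpass_basis",
    "high_pass_filter",
    "build_design_matrix",
    "fit_glm",
    "compute_contrast",
    "extract_roi_pe",
    "behavioural_stats",
    "qc_exclusions",
    "smooth_volume",
    "NBACK_TR_S",
    "NBACK_N_VOLUMES",
    "SWITCH_TR_S",
    "SWITCH_N_VOLUMES",
]

HRF_MEAN_S = 6.0
HRF_SD_S = 3.0
NBACK_TR_S = 2.0
NBACK_N_VOLUMES = 270
SWITCH_TR_S = 3.0
SWITCH_N_VOLUMES = 180

CONTRASTS = {
    # "1&2-back>0-back": working-memory load
    "wm_load": {"0back": -1.0, "1back": 0.5, "2back": 0.5},
    # "switch>no-switch": set shifting
    "switch": {"no_switch": -1.0, "switch": 1.0},
}
CONTRAST_ALIASES = {"1&2-back>0-back": "wm_load", "switch>no-switch": "switch"}


@dataclass(frozen=True)
class TaskDesign:
    """Trial-level task timing; events has onset_s, duration_s, condition."""

    events: pd.DataFrame
    task_name: str
    total_duration_s: float

    def __post_init__(self):
        ev = self.events
        required = {"onset_s", "duration_s", "condition"}
        if not required.issubset(ev.columns):
            raise ValueError(f"events must have columns {sorted(required)}")
        if not ev["onset_s"].is_monotonic_increasing:
            raise ValueError("event onsets must be nondecreasing")
        if float((ev["onset_s"] + ev["duration_s"]).max()) > self.total_duration_s + 1e-9:
            raise ValueError("events extend beyond the stated task duration")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.events["condition"].unique())

    @property
    def n_trials(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class BOLDRun:
    """BOLD time series, volumes x series (voxels or ROIs)."""

    data: np.ndarray
    tr_s: float

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.data, dtype=float))
        if d.shape[0] == 1 and np.asarray(self.data).ndim == 1:
            d = d.T
        object.__setattr__(self, "data", d)
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class DesignMatrix:
    """Named GLM regressors sampled at volume midpoints."""

    frame: pd.DataFrame
    tr_s: float
    task_columns: tuple[str, ...]
    hp_cutoff_s: float | None

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


@dataclass(frozen=True)
class GLMResult:
    betas: pd.DataFrame  # regressors x series
    residual_var: np.ndarray
    dof: int
    design: DesignMatrix


@dataclass(frozen=True)
class ContrastResult:
    contrast_name: str
    pe: np.ndarray  # one value per series
    weights: dict[str, float]
    t: np.ndarray | None = None
    p_two_sided: np.ndarray | None = None


def nback_design(seed: int = 0) -> TaskDesign:
    """Default N-back block design: 3 conditions x 6 blocks, 540 s, 180 trials.

    Block order is a seeded pseudorandom permutation of the 18 blocks.
    Each block holds ten contiguous 2-s trials then 10 s rest.
    """
    rng = np.random.default_rng(seed)
    blocks = np.array(["0back", "1back", "2back"] * 6)
    rng.shuffle(blocks)
    rows = []
    for b, cond in enumerate(blocks):
        block_onset = 30.0 * b
        for tr in range(10):
            rows.append(
                {
                    "onset_s": block_onset + 2.0 * tr,
                    "duration_s": 2.0,
                    "condition": cond,
                    "block": b,
                }
            )
    return TaskDesign(pd.DataFrame(rows), "nback", total_duration_s=540.0)


def switching_design(seed: int = 0, trial_spacing_s: float = 3.5,
                     first_onset_s: float = 5.0) -> TaskDesign:
    """Default event-related switching design: 150 trials, 42 switches.

    The cue colour sequence is built by seeded placement of exactly 42
    colour changes among trials 2..150; a trial is a "switch" when the
    colour differs from the previous trial.  Trial 1 has no predecessor
    and is labelled no-switch.
    """
    n_trials, n_switch = 150, 42
    rng = np.random.default_rng(seed)
    change_positions = rng.choice(np.arange(1, n_trials), size=n_switch, replace=False)
    change = np.zeros(n_trials, dtype=bool)
    change[change_positions] = True
    colours = np.empty(n_trials, dtype=object)
    colours[0] = "green"
    for i in range(1, n_trials):
        prev = colours[i - 1]
        colours[i] = ("blue" if prev == "green" else "green") if change[i] else prev
    cond = np.where(change, "switch", "no_switch")
    onsets = first_onset_s + trial_spacing_s * np.arange(n_trials)
    ev = pd.DataFrame(
        {
            "onset_s": onsets,
            "duration_s": 2.0,
            "condition": cond,
            "colour": colours,
        }
    )
    return TaskDesign(ev, "switching", total_duration_s=540.0)


def gamma_hrf(dt_s: float, duration_s: float = 30.0) -> np.ndarray:
    """Gamma HRF with mean lag 6 s and SD 3 s, sampled at dt_s, unit area.

    Mean m and standard deviation s give shape (m/s)^2 = 4 and scale
    s^2/m = 1.5 s; the kernel is normalised so that sum(h) * dt = 1.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    shape = (HRF_MEAN_S / HRF_SD_S) ** 2
    scale = HRF_SD_S**2 / HRF_MEAN_S
    t = np.arange(0.0, duration_s, dt_s)
    h = gamma_dist.pdf(t, a=shape, scale=scale)
    return h / (h.sum() * dt_s)


def dct_highpass_basis(n_volumes: int, tr_s: float, cutoff_s: float = 100.0) -> np.ndarray:
    """Constant + low-frequency DCT-II columns with periods above the cutoff."""
    n_low = int(np.floor(2.0 * n_volumes * tr_s / cutoff_s))
    i = np.arange(n_volumes)
    cols = [np.ones(n_volumes)]
    for k in range(1, n_low + 1):
        cols.append(np.cos(np.pi * k * (i + 0.5) / n_volumes))
    return np.column_stack(cols)


def high_pass_filter(data: np.ndarray, tr_s: float, cutoff_s: float = 100.0) -> np.ndarray:
    """Remove drift by projecting out the low-frequency DCT basis (idempotent)."""
    x = np.asarray(data, dtype=float)
    flat = x.reshape(x.shape[0], -1)
    basis = dct_highpass_basis(x.shape[0], tr_s, cutoff_s)
    coef, *_ = np.linalg.lstsq(basis, flat, rcond=None)
    return (flat - basis @ coef).reshape(x.shape)


def _convolved_regressors(
    design: TaskDesign,
    tr_s: float,
    n_volumes: int,
    fine_dt_s: float = 0.01,
    hrf_duration_s: float = 30.0,
) -> tuple[pd.DataFrame, list[str]]:
    """HRF-convolved condition regressors + temporal derivatives at volume midpoints."""
    if n_volumes * tr_s + 1e-9 < design.total_duration_s:
        raise ValueError("run shorter than the task design")
    t_fine = np.arange(0.0, n_volumes * tr_s, fine_dt_s)
    kernel = gamma_hrf(fine_dt_s, hrf_duration_s)
    t_mid = (np.arange(n_volumes) + 0.5) * tr_s
    cols: dict[str, np.ndarray] = {}
    task_cols: list[str] = []
    for cond in design.conditions:
        box = np.zeros_like(t_fine)
        ev = design.events[design.events["condition"] == cond]
        for onset, dur in zip(ev["onset_s"], ev["duration_s"]):
            box[(t_fine >= onset) & (t_fine < onset + dur)] = 1.0
        conv = np.convolve(box, kernel)[: t_fine.size] * fine_dt_s
        sampled = np.interp(t_mid, t_fine, conv)
        deriv = np.interp(t_mid, t_fine, np.gradient(conv, fine_dt_s))
        cols[cond] = sampled
        cols[cond + "_deriv"] = deriv
        task_cols += [cond, cond + "_deriv"]
    return pd.DataFrame(cols), task_cols


def build_design_matrix(
    design: TaskDesign,
    tr_s: float,
    n_volumes: int,
    motion: np.ndarray | None = None,
    hp_cutoff_s: float | None = 100.0,
    fine_dt_s: float = 0.01,
    conditions: Sequence[str] | None = None,
) -> DesignMatrix:
    """GLM design: convolved task regressors, derivatives, motion nuisance, intercept.

    Task and derivative columns are HRF-convolved on a fine grid and
    sampled at volume midpoints; motion regressors are appended
    unconvolved.  The high-pass projection is applied to task, derivative
    and motion columns alike (the intercept is retained unfiltered).
    """
    if conditions is not None:
        missing = set(conditions) - set(design.conditions)
        if missing:
            raise ValueError(f"conditions absent from design: {sorted(missing)}")
    df, task_cols = _convolved_regressors(design, tr_s, n_volumes, fine_dt_s)
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.shape[0] != n_volumes:
            motion = motion.T
        if motion.shape[0] != n_volumes:
            raise ValueError("motion traces must have one row per volume")
        for j in range(motion.shape[1]):
            df[f"motion_{j}"] = motion[:, j]
    if hp_cutoff_s is not None:
        filtered = high_pass_filter(df.to_numpy(), tr_s, hp_cutoff_s)
        df = pd.DataFrame(filtered, columns=df.columns)
    df["intercept"] = 1.0
    return DesignMatrix(df, tr_s, tuple(task_cols), hp_cutoff_s)


def fit_glm(run: BOLDRun, dm: DesignMatrix, ar1: bool = False) -> GLMResult:
    """Ordinary least squares per series; the data get the design's high-pass.

    With ``ar1=True`` a single Cochrane–Orcutt pass is applied: the lag-1
    residual autocorrelation is estimated, data and design are
    quasi-differenced and the model refitted.
    """
    X = dm.values
    n, p = X.shape
    if run.n_volumes != n:
        raise ValueError("run length does not match design matrix")
    if n < p + 2:
        raise ValueError("too few volumes for the number of regressors")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name offending columns via small R diagonal in a pivoted QR proxy
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [dm.frame.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    y = run.data
    if dm.hp_cutoff_s is not None:
        y = high_pass_filter(y, run.tr_s, dm.hp_cutoff_s)

    def ols(Xm, ym):
        beta, *_ = np.linalg.lstsq(Xm, ym, rcond=None)
        resid = ym - Xm @ beta
        return beta, resid

    beta, resid = ols(X, y)
    if ar1:
        num = (resid[1:] * resid[:-1]).sum(axis=0)
        den = (resid[:-1] ** 2).sum(axis=0)
        rho = float(np.mean(np.divide(num, den, out=np.zeros_like(num), where=den > 0)))
        Xq = X[1:] - rho * X[:-1]
        yq = y[1:] - rho * y[:-1]
        beta, resid = ols(Xq, yq)
        n = n - 1
    dof = n - p
    residual_var = (resid**2).sum(axis=0) / max(dof, 1)
    return GLMResult(
        betas=pd.DataFrame(beta, index=dm.frame.columns),
        residual_var=np.atleast_1d(residual_var),
        dof=dof,
        design=dm,
    )


def compute_contrast(result: GLMResult | pd.DataFrame, contrast_name: str) -> ContrastResult:
    """Contrast of condition betas; derivative/nuisance weights are zero.

    Known contrasts: ``wm_load`` ("1&2-back>0-back", weights −1, +0.5,
    +0.5 on 0/1/2-back) and ``switch`` ("switch>no-switch", −1/+1).
    Given a full :class:`GLMResult`, the contrast t-statistic
    ``c'b / sqrt(s^2 c'(X'X)^-1 c)`` and its two-sided p (residual dof)
    are filled in as well.
    """
    name = CONTRAST_ALIASES.get(contrast_name, contrast_name)
    if name not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast_name!r}")
    weights = CONTRASTS[name]
    betas = result.betas if isinstance(result, GLMResult) else result
    missing = set(weights) - set(betas.index)
    if missing:
        raise ValueError(f"betas missing conditions {sorted(missing)} for {name!r}")
    pe = np.zeros(betas.shape[1])
    for cond, w in weights.items():
        pe = pe + w * betas.loc[cond].to_numpy()
    t = p = None
    if isinstance(result, GLMResult):
        from scipy import stats as _stats

        c = np.array([weights.get(col, 0.0) for col in betas.index])
        X = result.design.values
        xtx_inv = np.linalg.pinv(X.T @ X)
        var_c = float(c @ xtx_inv @ c)
        se = np.sqrt(result.residual_var * var_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, pe / se, np.nan)
        p = 2.0 * _stats.t.sf(np.abs(t), result.dof)
    return ContrastResult(contrast_name=name, pe=pe, weights=dict(weights), t=t,
                          p_two_sided=p)


def extract_roi_pe(pe_map: np.ndarray, mask: np.ndarray) -> float:
    """Mean parameter estimate over an ROI mask (shared kernel with PET)."""
    from .kinetics import roi_mean_from_map

    return roi_mean_from_map(pe_map, mask)


def behavioural_stats(record: pd.DataFrame, task_name: str) -> dict:
    """Behavioural summaries per subject.

    N-back: per-block accuracy = 100 x correct / responded trials;
    ``mean_12back_accuracy`` averages the 1-back and 2-back condition
    accuracies.  Switching: ``switch_cost_s`` = mean RT(switch) − mean
    RT(no-switch) over responded trials.  Conditions with zero responses
    are flagged in ``missing_conditions`` (subject excludable) and yield
    NaN summaries.
    """
    rec = record.copy()
    responded = rec["response_time_s"].notna()
    if task_name == "nback":
        out: dict = {"block_accuracy": {}, "missing_conditions": []}
        cond_acc = {}
        for cond in ("0back", "1back", "2back"):
            sub = rec[(rec["condition"] == cond) & responded]
            if len(sub) == 0:
                out["missing_conditions"].append(cond)
                cond_acc[cond] = np.nan
                continue
            cond_acc[cond] = 100.0 * sub["correct"].mean()
        if "block" in rec.columns:
            for b, grp in rec.groupby("block"):
                resp = grp[grp["response_time_s"].notna()]
                out["block_accuracy"][int(b)] = (
                    100.0 * resp["correct"].mean() if len(resp) else np.nan
                )
        out["condition_accuracy"] = cond_acc
        out["mean_12back_accuracy"] = float(
            np.mean([cond_acc["1back"], cond_acc["2back"]])
        )
        return out
    if task_name == "switching":
        out = {"missing_conditions": []}
        means = {}
        for cond in ("switch", "no_switch"):
            sub = rec[(rec["condition"] == cond) & responded]
            if len(sub) == 0:
                out["missing_conditions"].append(cond)
                means[cond] = np.nan
            else:
                means[cond] = float(sub["response_time_s"].mean())
        out["mean_rt_s"] = means
        out["switch_cost_s"] = means["switch"] - means["no_switch"]
        return out
    raise ValueError(f"unknown task {task_name!r}")


def _longest_run(flags: np.ndarray) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def qc_exclusions(
    performance: Mapping[str, float] | pd.Series,
    motion_traces: Mapping[str, np.ndarray] | None = None,
    performance_sd: float = 2.5,
    motion_threshold_mm: float = 0.5,
    motion_consecutive: int = 30,
) -> pd.DataFrame:
    """Study exclusion rules applied to a cohort.

    A subject is flagged for performance when their score is strictly
    below group mean − ``performance_sd`` x sample SD, and for motion when
    the mean relative RMS displacement exceeds ``motion_threshold_mm`` AND
    the above-threshold condition persists for a run of more than
    ``motion_consecutive`` consecutive volumes.
    """
    perf = pd.Series(dict(performance), dtype=float)
    if len(perf) == 0:
        return pd.DataFrame(columns=["included", "reasons"])
    if len(perf) < 3:
        raise ValueError("performance rule needs >= 3 subjects")
    cut = perf.mean() - performance_sd * perf.std(ddof=1)
    rows = {}
    for subj in perf.index:
        reasons = []
        if perf[subj] < cut:
            reasons.append("performance")
        if motion_traces is not None and subj in motion_traces:
            trace = np.asarray(motion_traces[subj], dtype=float)
            high = trace > motion_threshold_mm
            if trace.mean() > motion_threshold_mm and _longest_run(high) > motion_consecutive:
                reasons.append("motion")
        rows[subj] = {"included": not reasons, "reasons": reasons}
    return pd.DataFrame.from_dict(rows, orient="index")


def smooth_volume(
    data: np.ndarray,
    fwhm_mm: float = 6.0,
    voxel_size_mm: float | Sequence[float] = 1.0,
    truncate: float = 6.0,
) -> np.ndarray:
    """Separable Gaussian smoothing of a 3-D (or 4-D, per-volume) image.

    ``sd = fwhm / (2 sqrt(2 ln 2))`` per axis in mm, converted to voxels.
    Edges are handled by renormalised truncation (the kernel mass inside
    the volume is divided out), so constant images are preserved exactly.
    """
    x = np.asarray(data, dtype=float)
    spatial = 3 if x.ndim == 4 else x.ndim
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (spatial,))
    if np.any(vox <= 0):
        raise ValueError("voxel size must be positive")
    sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / vox
    out = x.copy()
    norm = np.ones(x.shape[:spatial])
    for ax in range(spatial):
        out = gaussian_filter1d(out, sigma_vox[ax], axis=ax, mode="constant",
                                truncate=truncate)
        norm = gaussian_filter1d(norm, sigma_vox[ax], axis=ax, mode="constant",
                                 truncate=truncate)
    if x.ndim == 4:
        norm = norm[..., None]
    return out / norm
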