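"""One-tissue-compartment (1TC) kinetic modelling of regional PET time-activity curves.

The measured PET signal in a region is modelled as

    C_PET(t) = (1 - V_B) * C_T(t) + V_B * C_wb(t)
    dC_T/dt  = K1 * C_p(t) - k2 * C_T(t)

where ``C_p`` is the metabolite-corrected arterial plasma concentration
(the input function), ``C_wb = C_p / plasma-to-whole-blood ratio`` is the
whole-blood activity, ``K1`` (mL cm^-3 min^-1) the plasma-to-tissue influx
rate, ``k2`` (min^-1) the efflux rate and ``V_B`` the fractional blood
volume (fixed, default 5%).  The total distribution volume is
``V_T = K1 / k2`` (mL/cm^3).  Regional V_T values are normalised by the
centrum semiovale (a region with minimal specific SV2A binding) to give
the distribution volume ratio DVRcs = V_T(roi) / V_T(CS).

The input function is treated as piecewise linear between its samples and
the convolution with ``exp(-k2 t)`` is evaluated analytically per linear
segment, so the forward model is exact for the interpolant and the frame
averages carry no quadrature error into the fit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FrameSchedule",
    "InputFunction",
    "TissueTAC",
    "OneTCParams",
    "simulate_tac",
    "fit_1tc",
    "compute_dvr",
    "roi_mean_from_map",
    "variability_stats",
    "read_tac_table",
    "write_tac_table",
]

DEFAULT_VB = 0.05

# bounds and multi-start grid for the bounded least-squares fit (per-minute units)
K1_BOUNDS = (1e-4, 2.0)
K2_BOUNDS = (1e-4, 1.0)
FIT_STARTS = ((0.1, 0.01), (0.3, 0.03), (0.5, 0.1), (1.0, 0.3))


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous PET frame timing in seconds."""

    start_s: np.ndarray
    end_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        end = np.asarray(self.end_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "end_s", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValueError("frame starts/ends must be equal-length 1-D arrays")
        if not np.all(np.diff(start) > 0):
            raise ValueError("frame starts must be strictly increasing")
        if not np.all(end > start):
            raise ValueError("frame ends must exceed starts")
        if not np.allclose(start[1:], end[:-1]):
            raise ValueError("frames must be contiguous (next start == previous end)")

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def durations_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    @property
    def midpoints_s(self) -> np.ndarray:
        return 0.5 * (self.start_s + self.end_s)

    @property
    def total_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])

    @classmethod
    def default(cls) -> "FrameSchedule":
        """90-min 26-frame schedule: 8x15 s, 3x60 s, 5x120 s, 5x300 s, 5x600 s."""
        durs = np.concatenate(
            [
                np.full(8, 15.0),
                np.full(3, 60.0),
                np.full(5, 120.0),
                np.full(5, 300.0),
                np.full(5, 600.0),
            ]
        )
        ends = np.cumsum(durs)
        return cls(start_s=ends - durs, end_s=ends)


@dataclass(frozen=True)
class InputFunction:
    """Arterial input: metabolite-corrected plasma concentration over time.

    ``p2wb_ratio`` is the plasma-to-whole-blood activity ratio, either a
    scalar or one value per sample; the whole-blood curve used for the
    blood-volume term is ``C_p / p2wb_ratio``.
    """

    time_s: np.ndarray
    plasma_kbq_ml: np.ndarray
    p2wb_ratio: float | np.ndarray = 1.0

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        c = np.asarray(self.plasma_kbq_ml, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "plasma_kbq_ml", c)
        if t.ndim != 1 or t.shape != c.shape or t.size < 2:
            raise ValueError("input function needs >= 2 (time, concentration) samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("input-function times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("plasma concentrations must be non-negative")
        r = self.p2wb_ratio
        if np.ndim(r) == 0:
            if float(r) <= 0:
                raise ValueError("plasma-to-whole-blood ratio must be positive")
        else:
            r = np.asarray(r, dtype=float)
            object.__setattr__(self, "p2wb_ratio", r)
            if r.shape != t.shape or np.any(r <= 0):
                raise ValueError("ratio series must match times and be positive")

    def plasma_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.time_s, self.plasma_kbq_ml)

    def wholeblood_at(self, t: np.ndarray) -> np.ndarray:
        wb = self.plasma_kbq_ml / np.asarray(self.p2wb_ratio, dtype=float)
        return np.interp(t, self.time_s, wb)

    def covers(self, start_s: float, end_s: float) -> bool:
        return self.time_s[0] <= start_s and self.time_s[-1] >= end_s

    @classmethod
    def from_tsv(cls, path) -> "InputFunction":
        df = pd.read_csv(path, sep="\t")
        ratio = df["p2wb_ratio"].to_numpy() if "p2wb_ratio" in df else 1.0
        if np.ndim(ratio) and np.allclose(ratio, ratio[0]):
            ratio = float(ratio[0])
        return cls(df["time_s"].to_numpy(), df["plasma_kBq_per_mL"].to_numpy(), ratio)

    def to_tsv(self, path) -> None:
        ratio = np.broadcast_to(np.asarray(self.p2wb_ratio, float), self.time_s.shape)
        pd.DataFrame(
            {
                "time_s": self.time_s,
                "plasma_kBq_per_mL": self.plasma_kbq_ml,
                "p2wb_ratio": ratio,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class TissueTAC:
    """Frame-averaged regional tissue activity (kBq/cm^3)."""

    schedule: FrameSchedule
    activity: np.ndarray
    roi_label: str = ""

    def __post_init__(self):
        a = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", a)
        if a.shape != (self.schedule.n_frames,):
            raise ValueError("activity length must match frame schedule")
        if not np.all(np.isfinite(a)):
            raise ValueError("activity values must be finite")


@dataclass
class OneTCParams:
    """1TC parameters; ``vt`` is K1/k2 by definition."""

    k1: float
    k2: float
    v_b: float = DEFAULT_VB
    converged: bool = True
    residual_norm: float = math.nan
    n_starts_used: int = 0
    message: str = ""

    @property
    def vt(self) -> float:
        return self.k1 / self.k2


def _exp_segment_terms(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (1-e^-a)/a and (a - (1-e^-a))/a^2 with small-a safe evaluation."""
    a = np.asarray(a, dtype=float)
    small = a < 1e-8
    safe = np.where(small, 1.0, a)
    em = -np.expm1(-safe)  # 1 - e^-a
    f1 = np.where(small, 1.0 - a / 2.0, em / safe)
    f2 = np.where(small, 0.5 - a / 6.0, (safe - em) / safe**2)
    return f1, f2


def _tissue_curve_on_grid(
    k1_per_min: float, k2_per_min: float, t: np.ndarray, cp: np.ndarray
) -> np.ndarray:
    """Exact C_T at grid points for piecewise-linear C_p (times in seconds)."""
    k1 = k1_per_min / 60.0
    k2 = k2_per_min / 60.0
    dt = np.diff(t)
    c0 = cp[:-1]
    c1 = np.diff(cp) / dt  # slope per segment
    a = k2 * dt
    f1, f2 = _exp_segment_terms(a)
    # integral_0^dt (c0 + c1 s) e^{-k2 (dt - s)} ds = dt*(c0*f1 + c1*dt*f2)
    seg = k1 * dt * (c0 * f1 + c1 * dt * f2)
    decay = np.exp(-a)
    ct = np.empty_like(t)
    ct[0] = 0.0
    if a.sum() < 500.0:
        # closed form of the linear recurrence via cumulative attenuation
        # (safe from under/overflow while total attenuation < e^500)
        D = np.concatenate([[1.0], np.cumprod(decay)])
        ct[1:] = D[1:] * np.cumsum(seg / D[1:])
    else:  # pragma: no cover - only for extreme k2 * duration
        for i in range(dt.size):
            ct[i + 1] = ct[i] * decay[i] + seg[i]
    return ct


def simulate_tac(
    params: OneTCParams,
    aif: InputFunction,
    schedule: FrameSchedule | None = None,
) -> TissueTAC:
    """Forward-simulate a frame-averaged 1TC tissue curve.

    Frame values are exact time-averages of the continuous model over each
    frame, assuming the plasma curve is piecewise linear between its
    samples.  The schedule must lie inside the AIF support (no
    extrapolation).
    """
    if schedule is None:
        schedule = FrameSchedule.default()
    if params.k1 < 0 or params.k2 <= 0:
        raise ValueError("K1 must be >= 0 and k2 > 0")
    if not aif.covers(schedule.start_s[0], schedule.end_s[-1]):
        raise ValueError("frame schedule extends beyond AIF support")

    edges = np.union1d(
        aif.time_s[(aif.time_s >= schedule.start_s[0]) & (aif.time_s <= schedule.end_s[-1])],
        np.concatenate([schedule.start_s, schedule.end_s[-1:]]),
    )
    # the model starts at schedule.start (tissue empty at injection)
    cp = aif.plasma_at(edges)
    cwb = aif.wholeblood_at(edges)
    ct = _tissue_curve_on_grid(params.k1, params.k2, edges, cp)

    # cumulative trapezoid integrals (exact for piecewise-linear cp/cwb)
    def cumint(y):
        return np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(edges))])

    Icp = cumint(cp)
    Icwb = cumint(cwb)
    k1 = params.k1 / 60.0
    k2 = params.k2 / 60.0
    # integral of C_T between grid points via dC_T/dt = k1 cp - k2 C_T
    #   => int C_T = (k1 * int cp - delta C_T) / k2
    idx0 = np.searchsorted(edges, schedule.start_s)
    idx1 = np.searchsorted(edges, schedule.end_s)
    dur = schedule.durations_s
    int_ct = (k1 * (Icp[idx1] - Icp[idx0]) - (ct[idx1] - ct[idx0])) / k2
    mean_ct = int_ct / dur
    mean_cwb = (Icwb[idx1] - Icwb[idx0]) / dur
    vals = (1.0 - params.v_b) * mean_ct + params.v_b * mean_cwb
    return TissueTAC(schedule=schedule, activity=vals, roi_label="")


def fit_1tc(
    tac: TissueTAC,
    aif: InputFunction,
    v_b_fixed: float = DEFAULT_VB,
) -> OneTCParams:
    """Fit (K1, k2) by bounded weighted nonlinear least squares, V_B fixed.

    Frame weights are proportional to frame duration (a proxy for count
    statistics).  Four fixed starting points are tried and the best
    converged solution kept.  Non-convergence and degenerate (all-zero)
    inputs return a flagged failure result rather than raising.
    """
    y = tac.activity
    if tac.schedule.n_frames < 4:
        raise ValueError("need at least 4 frames to fit the 1TC model")
    if not aif.covers(tac.schedule.start_s[0], tac.schedule.end_s[-1]):
        raise ValueError("AIF does not cover the TAC time span")
    if np.allclose(y, 0.0):
        return OneTCParams(math.nan, math.nan, v_b_fixed, converged=False,
                           message="all-zero TAC")

    w = np.sqrt(tac.schedule.durations_s / tac.schedule.durations_s.sum())

    def resid(theta):
        sim = simulate_tac(
            OneTCParams(theta[0], theta[1], v_b_fixed), aif, tac.schedule
        ).activity
        return w * (sim - y)

    best = None
    n_used = 0
    for start in FIT_STARTS:
        n_used += 1
        try:
            sol = least_squares(
                resid,
                x0=np.asarray(start),
                bounds=(np.array([K1_BOUNDS[0], K2_BOUNDS[0]]),
                        np.array([K1_BOUNDS[1], K2_BOUNDS[1]])),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=400,
            )
        except Exception:  # pragma: no cover - optimiser-internal failure
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        # early exit: an essentially perfect fit will not be improved
        if best is not None and best.cost < 1e-20 * max(1.0, float(np.dot(y, y))):
            break
    if best is None:
        return OneTCParams(math.nan, math.nan, v_b_fixed, converged=False,
                           n_starts_used=n_used, message="no start converged")
    k1, k2 = best.x
    return OneTCParams(
        float(k1), float(k2), v_b_fixed,
        converged=True,
        residual_norm=float(np.linalg.norm(best.fun)),
        n_starts_used=n_used,
        message=best.message,
    )


def compute_dvr(
    regional_vt: Mapping[str, float] | pd.Series,
    cs_label: str = "centrum_semiovale",
) -> pd.DataFrame:
    """Normalise regional V_T by the centrum-semiovale V_T.

    Returns a frame indexed by ROI with columns ``vt`` and ``dvr_cs``;
    the reference region has DVRcs exactly 1.
    """
    vt = pd.Series(dict(regional_vt), dtype=float)
    if cs_label not in vt.index:
        raise ValueError(f"reference region {cs_label!r} missing from V_T table")
    cs = vt[cs_label]
    if not np.isfinite(cs) or cs <= 0:
        raise ValueError(f"reference V_T must be positive, got {cs!r}")
    out = pd.DataFrame({"vt": vt, "dvr_cs": vt / cs})
    out.loc[cs_label, "dvr_cs"] = 1.0
    return out


def roi_mean_from_map(parametric_values: np.ndarray, mask: np.ndarray) -> float:
    """Unweighted mean of a parametric map over a boolean ROI mask."""
    values = np.asarray(parametric_values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("map and mask shapes differ")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return float(values[mask].mean())


def variability_stats(values: pd.DataFrame) -> pd.DataFrame:
    """Across-subject variability per ROI: sample variance and CV.

    ``values`` is subjects x ROIs.  Variance uses the n-1 denominator; the
    coefficient of variation is sample sd over mean and is flagged
    undefined (NaN, ``cv_defined`` False) when the mean is zero.
    """
    if values.shape[0] < 2:
        raise ValueError("variability requires >= 2 subjects")
    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=1)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    defined = mean != 0
    cv = cv.where(defined)
    return pd.DataFrame({"variance": var, "cv": cv, "cv_defined": defined})


def read_tac_table(path) -> tuple[FrameSchedule, dict[str, TissueTAC]]:
    """Read a TAC TSV (frame_start_s, frame_end_s, one activity column per ROI)."""
    df = pd.read_csv(path, sep="\t")
    sched = FrameSchedule(df["frame_start_s"].to_numpy(), df["frame_end_s"].to_numpy())
    tacs = {}
    for col in df.columns:
        if col in ("frame_start_s", "frame_end_s"):
            continue
        tacs[col] = TissueTAC(sched, df[col].to_numpy(), roi_label=col)
    return sched, tacs


def write_tac_table(path, schedule: FrameSchedule, tacs: Mapping[str, Sequence[float]]) -> None:
    data = {"frame_start_s": schedule.start_s, "frame_end_s": schedule.end_s}
    for roi, act in tacs.items():
        act = np.asarray(act, dtype=float)
        if act.shape != (schedule.n_frames,):
            raise ValueError(f"TAC for {roi!r} does not match the schedule")
        data[roi] = act
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
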