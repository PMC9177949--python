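"""ROI-signal preprocessing: volume discard, motion screening, nuisance
regression and bandpass/detrend.

The chain mirrors standard resting-state practice at the region-of-interest
level (image-space steps such as realignment and spatial normalization are
out of scope): drop initial volumes acquired before magnetization
equilibrium, exclude subjects whose head motion exceeds 2.0 mm translation
or 2.0 degrees rotation in any direction, regress nuisance signals (motion
parameters, global mean, white matter, CSF) from every ROI column, then
linearly detrend and bandpass filter to the low-frequency BOLD band
(0.01-0.08 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRANSLATION_COLUMNS = ("trans_x_mm", "trans_y_mm", "trans_z_mm")
ROTATION_COLUMNS = ("rot_x_deg", "rot_y_deg", "rot_z_deg")
MOTION_COLUMNS = TRANSLATION_COLUMNS + ROTATION_COLUMNS


class PreprocessError(ValueError):
    """Raised for invalid preprocessing inputs or configuration."""


@dataclass
class ROITimeSeries:
    """A single subject's T x N BOLD table plus repetition time.

    ``values`` rows are time points, columns are ROI labels (unique, >= 2);
    all entries must be finite.
    """

    values: pd.DataFrame
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        t, n = self.values.shape
        if t < 2 or n < 2:
            raise PreprocessError(f"time series must be at least 2 x 2, got {t} x {n}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise PreprocessError(f"duplicate ROI labels: {dupes}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise PreprocessError("time series contains non-finite values")
        if self.tr_s <= 0:
            raise PreprocessError(f"tr_s must be positive, got {self.tr_s}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def roi_labels(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class MotionTrace:
    """T x 6 rigid-body motion parameters: 3 translations (mm), 3 rotations (deg)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(np.asarray(self.values), columns=list(MOTION_COLUMNS))
        if self.values.shape[1] != 6:
            raise PreprocessError(f"motion trace needs 6 columns, got {self.values.shape[1]}")
        if self.values.shape[0] < 1:
            raise PreprocessError("motion trace is empty")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise PreprocessError("motion trace contains non-finite values")
        self.values.columns = list(MOTION_COLUMNS)


@dataclass
class NuisanceSet:
    """T x K confound table (motion parameters, global mean, WM, CSF...)."""

    confounds: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.confounds, pd.DataFrame):
            self.confounds = pd.DataFrame(self.confounds)
        if self.confounds.shape[1] < 1:
            raise PreprocessError("nuisance set needs at least one confound column")
        if not np.isfinite(self.confounds.to_numpy(dtype=float)).all():
            raise PreprocessError("confounds contain non-finite values")


@dataclass
class MotionScreenResult:
    include: bool
    offending_column: str | None = None
    offending_index: int | None = None
    offending_value: float | None = None

    def as_dict(self) -> dict:
        return {
            "include": self.include,
            "offending_column": self.offending_column,
            "offending_index": self.offending_index,
            "offending_value": self.offending_value,
        }


def discard_initial_volumes(ts: ROITimeSeries, n_discard: int = 10) -> ROITimeSeries:
    """Drop the first ``n_discard`` rows (pre-equilibrium volumes)."""
    if n_discard < 0:
        raise PreprocessError(f"n_discard must be >= 0, got {n_discard}")
    if n_discard >= ts.n_timepoints:
        raise PreprocessError(
            f"cannot discard {n_discard} of {ts.n_timepoints} volumes"
        )
    if n_discard == 0:
        return ROITimeSeries(ts.values.copy(), ts.tr_s)
    return ROITimeSeries(ts.values.iloc[n_discard:].reset_index(drop=True), ts.tr_s)


def screen_head_motion(
    trace: MotionTrace,
    trans_limit_mm: float = 2.0,
    rot_limit_deg: float = 2.0,
) -> MotionScreenResult:
    """Exclude iff any |translation| > ``trans_limit_mm`` or |rotation| >
    ``rot_limit_deg`` (strict inequality: a value exactly at the limit is
    retained)."""
    vals = trace.values
    for cols, limit in ((TRANSLATION_COLUMNS, trans_limit_mm), (ROTATION_COLUMNS, rot_limit_deg)):
        for col in cols:
            series = vals[col].abs()
            idx = int(series.idxmax())
            worst = float(series.loc[idx])
            if worst > limit:
                return MotionScreenResult(
                    include=False,
                    offending_column=col,
                    offending_index=idx,
                    offending_value=float(vals[col].loc[idx]),
                )
    return MotionScreenResult(include=True)


def global_mean_signal(ts: ROITimeSeries) -> pd.Series:
    """Whole-brain surrogate: row mean over all ROI columns."""
    return ts.values.mean(axis=1).rename("global_mean")


def regress_nuisance(ts: ROITimeSeries, nuisance: NuisanceSet) -> ROITimeSeries:
    """Replace every ROI column by its least-squares residual against an
    intercept plus all confound columns.

    Raises a collinearity error naming dependent columns when the confound
    design (with intercept) is rank deficient.
    """
    x = ts.to_numpy()
    conf = nuisance.confounds.to_numpy(dtype=float)
    if conf.shape[0] != x.shape[0]:
        raise PreprocessError(
            f"confound rows ({conf.shape[0]}) do not match time series rows ({x.shape[0]})"
        )
    design = np.column_stack([np.ones(x.shape[0]), conf])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the columns that add no rank beyond the preceding ones
        dependent = []
        running = design[:, :1]
        for j, name in enumerate(nuisance.confounds.columns):
            candidate = np.column_stack([running, conf[:, j]])
            if np.linalg.matrix_rank(candidate) == np.linalg.matrix_rank(running):
                dependent.append(str(name))
            else:
                running = candidate
        raise PreprocessError(f"confound table is rank deficient; dependent columns: {dependent}")
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    return ROITimeSeries(pd.DataFrame(resid, columns=ts.values.columns), ts.tr_s)


def bandpass_detrend(
    ts: ROITimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    taper_hz: float = 0.002,
) -> ROITimeSeries:
    """Linear detrend followed by an FFT-domain bandpass.

    The filter is an ideal rectangular response on [low_hz, high_hz] with
    cosine-tapered edges of width ``taper_hz``; deterministic and free of
    filter-order ambiguity.  The trend is removed first so that the ramp
    does not ring through the sharp filter edges.
    """
    nyquist = 1.0 / (2.0 * ts.tr_s)
    if not (0.0 < low_hz < high_hz):
        raise PreprocessError(f"need 0 < low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= nyquist:
        raise PreprocessError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    x = ts.to_numpy()
    t = np.arange(x.shape[0], dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    x = x - design @ beta

    freqs = np.fft.rfftfreq(x.shape[0], d=ts.tr_s)
    response = np.zeros_like(freqs)
    response[(freqs >= low_hz) & (freqs <= high_hz)] = 1.0
    if taper_hz > 0:
        lo_edge = (freqs > low_hz - taper_hz) & (freqs < low_hz)
        response[lo_edge] = 0.5 * (1 + np.cos(np.pi * (low_hz - freqs[lo_edge]) / taper_hz))
        hi_edge = (freqs > high_hz) & (freqs < high_hz + taper_hz)
        response[hi_edge] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_edge] - high_hz) / taper_hz))
    filtered = np.fft.irfft(np.fft.rfft(x, axis=0) * response[:, None], n=x.shape[0], axis=0)
    return ROITimeSeries(pd.DataFrame(filtered, columns=ts.values.columns), ts.tr_s)


@dataclass
class PreprocessLog:
    """Per-subject record of the decisions the chain made."""

    n_discarded: int = 0
    motion: MotionScreenResult | None = None
    confound_columns: list[str] = field(default_factory=list)
    bandpass_hz: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        return {
            "n_discarded": self.n_discarded,
            "motion": self.motion.as_dict() if self.motion else None,
            "confound_columns": self.confound_columns,
            "bandpass_hz": list(self.bandpass_hz) if self.bandpass_hz else None,
        }


def preprocess_subject(
    ts: ROITimeSeries,
    motion: MotionTrace,
    extra_confounds: pd.DataFrame | None = None,
    n_discard: int = 10,
    trans_limit_mm: float = 2.0,
    rot_limit_deg: float = 2.0,
    bandpass_hz: tuple[float, float] | None = (0.01, 0.08),
    include_global_mean: bool = True,
) -> tuple[ROITimeSeries | None, PreprocessLog]:
    """Run the fixed chain discard -> screen -> regress -> bandpass/detrend.

    Returns ``(None, log)`` when the subject is excluded for head motion.
    ``extra_confounds`` (e.g. white-matter and CSF signals) must already be
    aligned to the acquired series; they are trimmed together with it.
    """
    log = PreprocessLog(n_discarded=n_discard)
    if motion.values.shape[0] != ts.n_timepoints:
        raise PreprocessError(
            f"motion rows ({motion.values.shape[0]}) do not match series rows ({ts.n_timepoints})"
        )
    trimmed = discard_initial_volumes(ts, n_discard)
    motion_trimmed = MotionTrace(motion.values.iloc[n_discard:].reset_index(drop=True))
    log.motion = screen_head_motion(motion_trimmed, trans_limit_mm, rot_limit_deg)
    if not log.motion.include:
        return None, log

    confounds = [motion_trimmed.values]
    if include_global_mean:
        confounds.append(global_mean_signal(trimmed).to_frame())
    if extra_confounds is not None:
        confounds.append(extra_confounds.iloc[n_discard:].reset_index(drop=True))
    conf = pd.concat(confounds, axis=1)
    # constant confounds (e.g. an all-zero motion trace) carry no signal and
    # would make the design rank deficient alongside the intercept
    keep = conf.std(axis=0) > 0
    conf = conf.loc[:, keep]
    log.confound_columns = [str(c) for c in conf.columns]
    if conf.shape[1] == 0:
        cleaned = trimmed
        if bandpass_hz is not None:
            cleaned = bandpass_detrend(cleaned, *bandpass_hz)
            log.bandpass_hz = tuple(bandpass_hz)
        return cleaned, log
    cleaned = regress_nuisance(trimmed, NuisanceSet(conf))
    if bandpass_hz is not None:
        cleaned = bandpass_detrend(cleaned, *bandpass_hz)
        log.bandpass_hz = tuple(bandpass_hz)
    return cleaned, log
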