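"""ROI-level BOLD denoising and motion quality control.

The denoising chain operates entirely on ROI time series (image-space steps
such as realignment or smoothing happen upstream, outside this package):

1. drop the first ``n_drop_volumes`` volumes (T1-equilibration);
2. despike: frames whose framewise differential signal intensity exceeds
   ``despike_z`` z-scores are replaced by the per-ROI mean of clean frames;
3. regress out nuisance signals (6 motion parameters, white matter, CSF);
4. zero-phase band-pass filter (default 0.008–0.09 Hz).

Regression precedes filtering so the confound fit cannot reintroduce
frequencies the filter has already removed; the stage order is configurable
at the pipeline level.

Subjects are excluded when the mean relative RMS displacement of the
translation parameters reaches 0.20 mm, or any translation exceeds 2.0 mm,
or any rotation exceeds 2.0 degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class DenoiseSettings:
    """Denoising and motion-QC parameters (defaults are the study values)."""

    n_drop_volumes: int = 5
    despike_z: float = 9.0
    band_low_hz: float = 0.008
    band_high_hz: float = 0.09
    rms_exclusion: float = 0.20        # mm, exclusion at >= this mean relative RMS
    displacement_limit: float = 2.0    # mm, absolute per-axis translation limit
    rotation_limit: float = 2.0        # degrees, absolute per-axis rotation limit

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not 0.0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if self.band_high_hz >= nyquist:
            raise ValueError(
                f"band_high_hz {self.band_high_hz} must be below Nyquist "
                f"{nyquist:.4f} Hz for TR {tr_seconds}s"
            )


@dataclass
class QCReport:
    """Per-subject motion quality-control summary."""

    subject_id: str
    mean_relative_rms: float
    max_abs_translation: float
    max_abs_rotation: float
    n_despiked_frames: int = 0
    excluded: bool = False
    exclusion_reasons: list = field(default_factory=list)

    def __post_init__(self):
        if self.excluded != bool(self.exclusion_reasons):
            raise ValueError("excluded flag must mirror exclusion_reasons")


def drop_initial_volumes(timeseries, motion, nuisance, k: int):
    """Remove the first ``k`` rows from all three arrays synchronously."""
    arrays = [np.asarray(a) for a in (timeseries, motion, nuisance)]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("timeseries, motion and nuisance must have equal row counts")
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= n:
        raise ValueError(f"cannot drop {k} volumes from a series of {n}")
    return tuple(a[k:] for a in arrays)


def despike_frames(timeseries, z_thresh: float = 9.0):
    """Replace frames with outlying framewise signal change.

    The framewise differential signal at frame t (t >= 1) is the
    root-mean-square across ROIs of the first difference x[t] - x[t-1].
    Differentials are z-scored over frames; frames exceeding ``z_thresh``
    are replaced, in every ROI, by that ROI's mean over non-flagged frames.

    Returns ``(cleaned, n_flagged)``.
    """
    x = np.asarray(timeseries, dtype=float).copy()
    if x.shape[0] < 3:
        raise ValueError("despiking needs at least 3 time points")
    diffs = np.sqrt(np.mean(np.diff(x, axis=0) ** 2, axis=1))  # length n-1
    sd = diffs.std()
    if sd == 0 or not np.isfinite(z_thresh):
        return x, 0
    z = (diffs - diffs.mean()) / sd
    flagged = np.zeros(x.shape[0], dtype=bool)
    flagged[1:] = z > z_thresh
    n_flagged = int(flagged.sum())
    if n_flagged:
        clean_mean = x[~flagged].mean(axis=0)
        x[flagged] = clean_mean
    return x, n_flagged


def bandpass_filter(timeseries, tr_seconds: float,
                    band_low_hz: float = 0.008, band_high_hz: float = 0.09,
                    taper_hz: float = 0.002):
    """Zero-phase frequency-domain band-pass, applied per ROI column.

    The transfer function rises from 0 to 1 over a raised-cosine taper of
    width ``taper_hz`` starting at ``band_low_hz`` and falls symmetrically
    ending at ``band_high_hz``; the DC bin is always zeroed, so the output
    is mean-free. A frequency-domain filter has no order/phase ambiguity
    and is reproducible across platforms.
    """
    x = np.asarray(timeseries, dtype=float)
    n = x.shape[0]
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0.0 < band_low_hz < band_high_hz:
        raise ValueError("need 0 < band_low_hz < band_high_hz")
    if band_high_hz >= nyquist:
        raise ValueError(f"band_high_hz {band_high_hz} >= Nyquist {nyquist:.4f} Hz")
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    h = np.zeros_like(freqs)
    lo, hi, w = band_low_hz, band_high_hz, taper_hz
    rising = (freqs >= lo) & (freqs < lo + w)
    passband = (freqs >= lo + w) & (freqs <= hi - w)
    falling = (freqs > hi - w) & (freqs <= hi)
    h[rising] = 0.5 - 0.5 * np.cos(np.pi * (freqs[rising] - lo) / w)
    h[passband] = 1.0
    h[falling] = 0.5 + 0.5 * np.cos(np.pi * (freqs[falling] - (hi - w)) / w)
    h[0] = 0.0
    spec = np.fft.rfft(x, axis=0)
    return np.fft.irfft(spec * h[:, None], n=n, axis=0)


def regress_confounds(timeseries, motion, nuisance):
    """OLS residual of each ROI column on [intercept, 6 motion, WM, CSF].

    Collinear design columns are dropped with a warning (the residual is
    unchanged by dropping redundant regressors). Residuals are orthogonal
    to every retained regressor.
    """
    y = np.asarray(timeseries, dtype=float)
    m = np.asarray(motion, dtype=float)
    nz = np.asarray(nuisance, dtype=float)
    n = y.shape[0]
    if m.shape[0] != n or nz.shape[0] != n:
        raise ValueError("confound row counts must match the time series")
    design = np.column_stack([np.ones(n), m, nz])
    # detect collinearity by rank-revealing QR via SVD on centered columns
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        keep = [0]
        for j in range(1, design.shape[1]):
            trial = design[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                warnings.warn(f"dropping collinear confound column {j}")
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def mean_relative_rms(motion) -> float:
    """Mean relative RMS displacement of the translation parameters.

    Per-frame displacement is the root-mean-square of the three
    frame-to-frame translation differences ("relative" = successive
    differences); the mean over frames is returned. Rotations do not enter
    this summary (they are covered by the absolute 2-degree rule).
    """
    m = np.asarray(motion, dtype=float)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.diff(m[:, :3], axis=0)
    return float(np.sqrt(np.mean(d ** 2, axis=1)).mean())


def qc_subject(motion, settings: DenoiseSettings = DenoiseSettings(),
               subject_id: str = "", n_despiked: int = 0) -> QCReport:
    """Apply the motion exclusion rules to one subject's trace."""
    m = np.asarray(motion, dtype=float)
    rms = mean_relative_rms(m)
    max_t = float(np.abs(m[:, :3]).max())
    max_r = float(np.abs(m[:, 3:6]).max())
    reasons = []
    if rms >= settings.rms_exclusion:
        reasons.append(f"mean relative RMS {rms:.3f} >= {settings.rms_exclusion}")
    if max_t > settings.displacement_limit:
        reasons.append(f"translation {max_t:.2f} mm > {settings.displacement_limit}")
    if max_r > settings.rotation_limit:
        reasons.append(f"rotation {max_r:.2f} deg > {settings.rotation_limit}")
    return QCReport(
        subject_id=subject_id,
        mean_relative_rms=rms,
        max_abs_translation=max_t,
        max_abs_rotation=max_r,
        n_despiked_frames=n_despiked,
        excluded=bool(reasons),
        exclusion_reasons=reasons,
    )


def denoise_subject(timeseries, motion, nuisance, tr_seconds: float,
                    settings: DenoiseSettings = DenoiseSettings()):
    """Full chain: drop -> despike -> confound regression -> band-pass.

    Returns ``(clean_timeseries, trimmed_motion, n_despiked)``; the trimmed
    motion trace is what QC should be computed on, matching the volumes
    actually analysed.
    """
    settings.validate(tr_seconds)
    ts, mo, nu = drop_initial_volumes(timeseries, motion, nuisance,
                                      settings.n_drop_volumes)
    ts, n_flagged = despike_frames(ts, settings.despike_z)
    ts = regress_confounds(ts, mo, nu)
    ts = bandpass_filter(ts, tr_seconds, settings.band_low_hz, settings.band_high_hz)
    return ts, mo, n_flagged
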