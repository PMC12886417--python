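"""Time-series conditioning and univariate analysis.

High-pass filtering by discrete-cosine basis projection, dynamic division of
blood-nulled by not-nulled series to remove BOLD contamination from VASO,
ordinary-least-squares GLM with the canonical HRF, percent-signal-change
computation, and the Fourier phase analysis used for phase-encoded
retinotopy.

The GLM is fit with plain OLS without prewhitening; residual temporal
autocorrelation therefore inflates nominal statistics on strongly
autocorrelated data (noted, not corrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import RunDesign
from .hrf import HrfParams, canonical_hrf


@dataclass
class TimeSeries:
    """A (volumes x voxels) sampled series with its repetition time."""

    data: np.ndarray
    tr_s: float
    times: np.ndarray | None = None  # acquisition times; defaults to k * tr
    #: cutoff of a high-pass filter already applied to the data; glm_fit
    #: applies the same filter to its design matrix (as GLM packages do)
    highpass_cutoff_hz: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if np.isnan(self.data).any():
            raise ValueError("time series contains missing values")
        if self.times is None:
            self.times = self.tr_s * np.arange(self.n_volumes)
        else:
            self.times = np.asarray(self.times, float)
            if len(self.times) != self.n_volumes:
                raise ValueError("times length must match volume count")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def dct_highpass_basis(n_volumes: int, tr_s: float,
                       cutoff_hz: float) -> np.ndarray:
    """DCT-II drift basis spanning all periods longer than 1/cutoff_hz.

    Basis function k has period 2 * n_volumes * tr_s / k; all k with period
    longer than the cutoff period are included (the constant term is handled
    separately by the projection).
    """
    order = int(np.floor(2.0 * n_volumes * tr_s * cutoff_hz))
    n = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2.0 * n_volumes))
            for k in range(1, order + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def highpass_filter(ts: TimeSeries, cutoff_hz: float) -> TimeSeries:
    """Remove slow drifts below ``cutoff_hz`` by regressing out a
    discrete-cosine basis (the mean is always removed).

    This is an orthogonal projection, hence idempotent, and a GLM on the
    filtered series is equivalent to including the basis as confound
    regressors in the unfiltered fit.
    """
    nyquist = 1.0 / (2.0 * ts.tr_s)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    basis = dct_highpass_basis(ts.n_volumes, ts.tr_s, cutoff_hz)
    x = np.column_stack([np.ones(ts.n_volumes), basis])
    beta, *_ = np.linalg.lstsq(x, ts.data, rcond=None)
    return TimeSeries(ts.data - x @ beta, ts.tr_s, times=ts.times,
                      highpass_cutoff_hz=cutoff_hz)


# ---------------------------------------------------------------------------
# VASO BOLD-contamination correction


@dataclass
class VasoCorrected:
    series: TimeSeries
    clamped: np.ndarray  # boolean (volumes x voxels): denominator floored
    undefined: np.ndarray  # boolean (voxels,): all-zero denominator


def vaso_bold_correct(nulled: TimeSeries, not_nulled: TimeSeries,
                      target_tr_s: float = 3.0,
                      denominator_floor_frac: float = 0.1) -> VasoCorrected:
    """Divide the nulled by the not-nulled series on a common time grid.

    Both series are linearly interpolated (edge hold) onto a grid of spacing
    ``target_tr_s`` anchored at the run start, matching the effective
    temporal resolution of the BOLD acquisitions; the corrected series is the
    voxel-wise, time-point-wise ratio.  Denominator samples with magnitude
    below ``denominator_floor_frac`` times the voxel's temporal median are
    clamped to that floor and flagged; all-zero denominator voxels are
    flagged and set to 1.
    """
    if nulled.n_voxels != not_nulled.n_voxels:
        raise ValueError("nulled and not-nulled voxel grids differ")
    duration = max(nulled.times[-1], not_nulled.times[-1])
    if target_tr_s > max(nulled.tr_s, not_nulled.tr_s):
        raise ValueError("target_tr_s exceeds the native effective TR")
    grid = np.arange(0.0, duration + 1e-9, target_tr_s)

    def resample(ts):
        out = np.empty((len(grid), ts.n_voxels))
        for v in range(ts.n_voxels):
            out[:, v] = np.interp(grid, ts.times, ts.data[:, v])
        return out

    num = resample(nulled)
    den = resample(not_nulled)
    med = np.median(np.abs(den), axis=0)
    undefined = med == 0
    floor = denominator_floor_frac * med
    clamped = np.abs(den) < floor
    den_safe = np.where(clamped, np.where(den < 0, -1, 1) * floor, den)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den_safe
    ratio[:, undefined] = 1.0
    if clamped.any():
        warnings.warn(f"{int(clamped.sum())} denominator samples clamped "
                      "during VASO correction")
    return VasoCorrected(TimeSeries(ratio, target_tr_s, times=grid),
                         clamped, undefined)


# ---------------------------------------------------------------------------
# GLM


@dataclass
class GlmResult:
    betas: np.ndarray  # (regressors, voxels)
    residual_var: np.ndarray  # (voxels,)
    contrast: np.ndarray  # (voxels,)
    t: np.ndarray
    z: np.ndarray
    dof: int
    regressor_names: list = field(default_factory=list)
    undefined: np.ndarray | None = None  # voxels with zero residual variance


def _t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Convert t to z by two-sided tail-probability matching."""
    logp = stats.t.logsf(np.abs(t), dof)
    z = -stats.norm.ppf(np.exp(np.clip(logp, -700, 0)))
    z = np.clip(z, 0, 40)  # beyond ~40 sigma the mapping saturates
    return np.sign(t) * z


def design_matrix(designs, tr_s: float | None = None,
                  hrf_params: HrfParams = HrfParams(),
                  extra_regressors: np.ndarray | None = None,
                  dt_s: float = 0.5):
    """Left/right HRF regressors (plus per-run intercepts) for one or more
    concatenated runs."""
    if isinstance(designs, RunDesign):
        designs = [designs]
    tr = tr_s if tr_s is not None else designs[0].tr_s
    cols, names = [], []
    left_all, right_all = [], []
    n_total = sum(d.n_volumes for d in designs)
    h = canonical_hrf(dt_s, hrf_params)
    offset = 0
    intercepts = np.zeros((n_total, len(designs)))
    for i, d in enumerate(designs):
        t_fine = np.arange(int(np.ceil(d.duration_s / dt_s)) + 1) * dt_s
        times = tr * np.arange(d.n_volumes)
        for cond, store in (("left", left_all), ("right", right_all)):
            box = np.zeros(len(t_fine))
            for onset, c in zip(d.block_onsets(), d.block_conditions):
                if c == cond:
                    box[(t_fine >= onset) & (t_fine < onset + d.block_s)] = 1.0
            conv = np.convolve(box, h * dt_s)[: len(t_fine)]
            store.append(np.interp(times, t_fine, conv))
        intercepts[offset:offset + d.n_volumes, i] = 1.0
        offset += d.n_volumes
    cols = [np.concatenate(left_all), np.concatenate(right_all)]
    names = ["left", "right"]
    for i in range(len(designs)):
        cols.append(intercepts[:, i])
        names.append(f"intercept_run{i + 1}")
    x = np.column_stack(cols)
    if extra_regressors is not None:
        x = np.column_stack([x, extra_regressors])
        names += [f"confound{i}" for i in range(extra_regressors.shape[1])]
    return x, names


def glm_fit(ts: TimeSeries, design, contrast=None,
            hrf_params: HrfParams = HrfParams(),
            extra_regressors: np.ndarray | None = None) -> GlmResult:
    """OLS fit of [left boxcar (x) HRF, right boxcar (x) HRF, intercept(s)].

    ``design`` is a RunDesign or a list of them (concatenated runs, one
    intercept each).  ``contrast`` is a weight vector over the regressors;
    default left - right.  t statistics are converted to z scores by
    two-sided tail matching at the residual degrees of freedom.
    """
    x, names = design_matrix(design, tr_s=ts.tr_s, hrf_params=hrf_params,
                             extra_regressors=extra_regressors)
    if x.shape[0] != ts.n_volumes:
        raise ValueError("design does not cover the series duration")
    if ts.highpass_cutoff_hz is not None:
        # filter the condition regressors like the data (intercepts exempt,
        # they absorb whatever offset remains)
        basis = dct_highpass_basis(ts.n_volumes, ts.tr_s,
                                   ts.highpass_cutoff_hz)
        k = np.column_stack([np.ones(ts.n_volumes), basis])
        proj, *_ = np.linalg.lstsq(k, x[:, :2], rcond=None)
        x = x.copy()
        x[:, :2] -= k @ proj
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the collinear columns for the error message
        keep, bad = [], []
        for j in range(x.shape[1]):
            trial = x[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    if contrast is None:
        contrast = np.zeros(x.shape[1])
        contrast[0], contrast[1] = 1.0, -1.0
    contrast = np.asarray(contrast, float)
    beta, *_ = np.linalg.lstsq(x, ts.data, rcond=None)
    resid = ts.data - x @ beta
    dof = ts.n_volumes - x.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    c_var = float(contrast @ xtx_inv @ contrast)
    con = contrast @ beta
    undefined = sigma2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = con / np.sqrt(sigma2 * c_var)
    t = np.where(undefined, np.nan, t)
    z = np.full_like(t, np.nan)
    ok = ~undefined
    z[ok] = _t_to_z(t[ok], dof)
    return GlmResult(beta, sigma2, con, t, z, dof, names, undefined)


# ---------------------------------------------------------------------------
# percent signal change


@dataclass
class PscResult:
    psc: np.ndarray  # (voxels,)
    undefined: np.ndarray  # voxels with zero baseline mean
    invert_for_display: bool = False  # VASO convention: flip the y axis


def percent_signal_change(ts: TimeSeries, design: RunDesign,
                          invert_for_display: bool = False) -> PscResult:
    """Block-mean percent signal change (both eyes > baseline).

    Uses the decoding retention rule on the stimulation side (the first two
    volumes of every block are dropped) and its mirror on the baseline side
    (the first two volumes after each block ends are dropped).  Requires an
    unstandardized series; VASO values keep their native sign, with
    ``invert_for_display`` recording the presentation convention.
    """
    if ts.n_volumes != design.n_volumes:
        raise ValueError("series length does not match the design")
    stim = design.retained_mask()
    base = design.baseline_mask()
    stim_mean = ts.data[stim].mean(axis=0)
    base_mean = ts.data[base].mean(axis=0)
    undefined = base_mean == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        psc = 100.0 * (stim_mean - base_mean) / base_mean
    psc[undefined] = np.nan
    return PscResult(psc, undefined, invert_for_display)


def percent_signal_change_beta(ts: TimeSeries, design: RunDesign,
                               hrf_params: HrfParams = HrfParams()) -> PscResult:
    """GLM-based PSC alternative: mean of the left and right condition betas
    over the intercept, x100 (the block-mean estimator is the default)."""
    res = glm_fit(ts, design, hrf_params=hrf_params)
    baseline = res.betas[2]
    undefined = baseline == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        psc = 100.0 * 0.5 * (res.betas[0] + res.betas[1]) / baseline
    psc[undefined] = np.nan
    return PscResult(psc, undefined)


# ---------------------------------------------------------------------------
# phase-encoded retinotopy


@dataclass
class PhaseMapResult:
    amplitude: np.ndarray
    phase: np.ndarray  # in [-pi, pi); NaN where undefined
    undefined: np.ndarray


def retinotopy_phase_map(series_fwd: TimeSeries, series_rev: TimeSeries,
                         cycles: float, cycle_period_s: float) -> PhaseMapResult:
    """Voxel-wise Fourier analysis of phase-encoded runs.

    The first quarter stimulus cycle is discarded; the complex coefficient at
    the stimulus frequency is computed per voxel per run, the
    reversed-direction run's coefficient is conjugated before averaging so
    the hemodynamic phase lag cancels, and the recovered phase is that of a
    ``cos(2 pi f t - phase)`` response.
    """
    if series_fwd.n_volumes != series_rev.n_volumes:
        raise ValueError("runs of unequal length")
    if series_fwd.n_voxels != series_rev.n_voxels:
        raise ValueError("runs on different voxel grids")
    tr = series_fwd.tr_s
    n_discard = int(round(cycle_period_s / 4.0 / tr))
    f = 1.0 / cycle_period_s

    def coefficient(ts):
        x = ts.data[n_discard:]
        t = ts.times[n_discard:]
        # restrict to an integer number of stimulus cycles so the projection
        # is leakage-free (8.25 cycles minus the discarded quarter -> 8)
        n_keep = int(np.floor(len(t) * tr * f) / (f * tr))
        x, t = x[:n_keep], t[:n_keep]
        x = x - x.mean(axis=0)
        basis = np.exp(-2j * np.pi * f * t)
        return (basis @ x) * (2.0 / len(t))

    c_fwd = coefficient(series_fwd)
    c_rev = np.conj(coefficient(series_rev))
    c = 0.5 * (c_fwd + c_rev)
    amplitude = np.abs(c)
    undefined = amplitude == 0
    phase = -np.angle(c)
    phase = np.mod(phase + np.pi, 2 * np.pi) - np.pi
    phase[undefined] = np.nan
    return PhaseMapResult(amplitude, phase, undefined)
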