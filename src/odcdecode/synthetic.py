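"""Synthetic ocular-dominance-column fMRI sessions with known ground truth.

The generator emulates a depth-resolved block-design mapping session on a
flattened rectangular patch of V1:

* an ODC ocularity map (per-vertex preference in [-1, 1]) built from
  band-pass filtered spatial noise, producing the characteristic ~1 mm
  stripe pattern (default stripe fundamental 0.5 cycles/mm);
* a laminar response model: a monocularity profile across cortical depth that
  peaks at the thalamorecipient layer 4C (relative depth 0.27 from the GM/WM
  boundary, i.e. 73% measured from the pial surface) atop a binocular floor,
  plus a linear "draining vein" accumulation term that integrates signal from
  deeper compartments toward the pial surface;
* block-design time series per run, per depth, per vertex: condition boxcars
  weighted by eye preference, convolved with the canonical HRF, scaled by the
  drained laminar response, with slow drift and white Gaussian noise;
* for VASO, interleaved blood-nulled / not-nulled series at an effective TR
  of 5 s, with inverted contrast sign and a configurable multiplicative BOLD
  contamination of the nulled series.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import RunDesign, LEFT, session_designs
from .hrf import HrfParams, canonical_hrf
from .surface import SurfaceMesh

GE_BOLD = "GE-BOLD"
SE_BOLD = "SE-BOLD"
VASO = "VASO"

#: default pial-ward accumulation coefficients per contrast; the ordering
#: (GE > SE > VASO) encodes the relative macrovascular sensitivity of the
#: three acquisition techniques.
DEFAULT_DRAIN_LAMBDA = {GE_BOLD: 2.0, SE_BOLD: 1.0, VASO: 0.3}


# ---------------------------------------------------------------------------
# cortical sheet


@dataclass(frozen=True)
class CorticalSheet:
    """Rectangular flattened cortical patch embedded in a volume frame.

    Vertices are ordered row-major over the (n_x, n_y) grid.  The white
    surface lies in the z = 0 plane; the pial surface is displaced by
    ``thickness`` along +z, so relative depth d maps to z = d * thickness.
    """

    n_x: int
    n_y: int
    spacing: float  # mm per grid step
    thickness: float = 2.5  # cortical thickness in mm

    def __post_init__(self):
        if self.spacing <= 0 or self.thickness <= 0:
            raise ValueError("spacing and thickness must be positive")
        if self.n_x < 2 or self.n_y < 2:
            raise ValueError("sheet needs at least 2 vertices per axis")

    @property
    def n_vertices(self) -> int:
        return self.n_x * self.n_y

    def grid_coords(self) -> np.ndarray:
        """(n_vertices, 2) in-plane world coordinates in mm."""
        ix, iy = np.meshgrid(np.arange(self.n_x), np.arange(self.n_y),
                             indexing="ij")
        return np.column_stack([ix.ravel() * self.spacing,
                                iy.ravel() * self.spacing])

    @property
    def white_coords(self) -> np.ndarray:
        xy = self.grid_coords()
        return np.column_stack([xy, np.zeros(self.n_vertices)])

    @property
    def pial_coords(self) -> np.ndarray:
        xy = self.grid_coords()
        return np.column_stack([xy, np.full(self.n_vertices, self.thickness)])

    def faces(self) -> np.ndarray:
        """Triangulation of the grid (two triangles per cell)."""
        idx = np.arange(self.n_vertices).reshape(self.n_x, self.n_y)
        a = idx[:-1, :-1].ravel()
        b = idx[1:, :-1].ravel()
        c = idx[:-1, 1:].ravel()
        d = idx[1:, 1:].ravel()
        return np.concatenate([np.column_stack([a, b, c]),
                               np.column_stack([b, d, c])])

    def white_mesh(self, labels=None) -> SurfaceMesh:
        return SurfaceMesh(self.white_coords, self.faces(), labels)

    def pial_mesh(self, labels=None) -> SurfaceMesh:
        return SurfaceMesh(self.pial_coords, self.faces(), labels)


# ---------------------------------------------------------------------------
# ODC pattern


@dataclass(frozen=True)
class ODCPattern:
    """Per-vertex ocularity in [-1, 1]: +1 fully left-eye, -1 fully right."""

    ocularity: np.ndarray
    main_frequency: float  # cycles/mm
    bandwidth: float  # cycles/mm
    seed: int

    def __post_init__(self):
        oc = np.asarray(self.ocularity, float)
        if np.any(np.abs(oc) > 1 + 1e-12):
            raise ValueError("ocularity values must lie in [-1, 1]")


def generate_odc_pattern(sheet: CorticalSheet, main_frequency: float = 0.5,
                         bandwidth: float = 0.1, sharpness: float = 3.0,
                         seed: int = 0) -> ODCPattern:
    """Band-pass filtered noise model of an ocular dominance map.

    White Gaussian noise on the sheet grid is filtered with an annular
    Gaussian in the 2D spatial-frequency domain centered at
    ``main_frequency`` (width ``bandwidth``, both in cycles/mm), normalized
    to unit variance, and squashed through tanh(sharpness * x).  A stripe
    fundamental of 0.5 cycles/mm corresponds to ~1 mm wide columns of
    alternating eye preference.
    """
    if main_frequency <= 0 or bandwidth <= 0:
        raise ValueError("main_frequency and bandwidth must be positive")
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((sheet.n_x, sheet.n_y))
    fx = np.fft.fftfreq(sheet.n_x, d=sheet.spacing)
    fy = np.fft.fftfreq(sheet.n_y, d=sheet.spacing)
    r = np.hypot(*np.meshgrid(fx, fy, indexing="ij"))
    annulus = np.exp(-0.5 * ((r - main_frequency) / bandwidth) ** 2)
    filtered = np.fft.ifft2(np.fft.fft2(noise) * annulus).real
    sd = filtered.std()
    if sd == 0:  # pragma: no cover - only for degenerate tiny grids
        raise ValueError("filtered field is constant; grid too small")
    oc = np.tanh(sharpness * filtered / sd)
    return ODCPattern(oc.ravel(), main_frequency, bandwidth, seed)


def radial_power_spectrum(pattern: ODCPattern, sheet: CorticalSheet,
                          n_bins: int = 40):
    """Radially averaged 2D power spectrum of the ocularity map.

    Returns (bin centers in cycles/mm, mean power per bin), DC excluded.
    """
    oc = np.asarray(pattern.ocularity).reshape(sheet.n_x, sheet.n_y)
    power = np.abs(np.fft.fft2(oc - oc.mean())) ** 2
    fx = np.fft.fftfreq(sheet.n_x, d=sheet.spacing)
    fy = np.fft.fftfreq(sheet.n_y, d=sheet.spacing)
    r = np.hypot(*np.meshgrid(fx, fy, indexing="ij")).ravel()
    p = power.ravel()
    f_max = min(fx.max(), fy.max())
    edges = np.linspace(0, f_max, n_bins + 1)
    which = np.digitize(r, edges) - 1
    centers, means = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.any() and edges[b] > 0:
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(p[sel].mean())
    return np.array(centers), np.array(means)


# ---------------------------------------------------------------------------
# laminar response model


def default_monocularity_profile(depths: np.ndarray, center: float = 0.27,
                                 width: float = 0.15,
                                 floor: float = 0.3) -> np.ndarray:
    """Depth profile of eye selectivity in [0, 1].

    A Gaussian bump at the thalamorecipient layer 4C (relative depth 0.27
    from GM/WM) on top of a binocular floor: above and below 4C the two
    eyes' signals converge onto single neurons, so selectivity never reaches
    zero but is clearly maximal at the input layer.
    """
    d = np.asarray(depths, float)
    return floor + (1.0 - floor) * np.exp(-0.5 * ((d - center) / width) ** 2)


@dataclass(frozen=True)
class LaminarResponseModel:
    """Laminar signal model for one acquisition contrast.

    Fields
    ------
    contrast_type : 'GE-BOLD' | 'SE-BOLD' | 'VASO'
    depths : strictly increasing relative depths in [0, 1]
        0 = GM/WM boundary, 1 = GM/CSF (pial) boundary.
    neuronal_profile : per-depth eye-selectivity amplitude in [0, 1]
    drain_lambda : pial-ward accumulation coefficient (>= 0, per unit depth)
    base_amplitude : response scale in percent signal change
    noise_sd : per-volume thermal/physiological noise, percent of baseline;
        scalar or per-depth vector
    sign : +1 for BOLD, -1 for VASO (CBV increase darkens the nulled image)
    """

    contrast_type: str = GE_BOLD
    depths: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 11))
    neuronal_profile: np.ndarray | None = None
    drain_lambda: float | None = None
    base_amplitude: float = 2.0
    noise_sd: float | np.ndarray = 5.0
    sign: int | None = None
    ar1_coef: float = 0.0  # optional temporal autocorrelation of the noise

    def __post_init__(self):
        if self.contrast_type not in (GE_BOLD, SE_BOLD, VASO):
            raise ValueError(f"unknown contrast type {self.contrast_type!r}")
        d = np.asarray(self.depths, float)
        if d.ndim != 1 or len(d) < 2 or np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        if d[0] < 0 or d[-1] > 1:
            raise ValueError("depths must lie in [0, 1]")
        object.__setattr__(self, "depths", d)
        if self.neuronal_profile is None:
            object.__setattr__(self, "neuronal_profile",
                               default_monocularity_profile(d))
        prof = np.asarray(self.neuronal_profile, float)
        if prof.shape != d.shape:
            raise ValueError("neuronal_profile must match depths")
        if np.any(prof < 0):
            raise ValueError("neuronal_profile must be non-negative")
        object.__setattr__(self, "neuronal_profile", prof)
        if self.drain_lambda is None:
            object.__setattr__(self, "drain_lambda",
                               DEFAULT_DRAIN_LAMBDA[self.contrast_type])
        if self.drain_lambda < 0:
            raise ValueError("drain_lambda must be >= 0")
        if self.sign is None:
            object.__setattr__(self, "sign",
                               -1 if self.contrast_type == VASO else +1)

    @property
    def n_depths(self) -> int:
        return len(self.depths)

    def noise_sd_by_depth(self) -> np.ndarray:
        """Per-depth noise SD; scalar inputs are scaled from 0.8x at GM/WM to
        1.2x at GM/CSF (CSF pulsatility raises variability in upper layers)."""
        sd = np.asarray(self.noise_sd, float)
        if sd.ndim == 0:
            return float(sd) * (0.8 + 0.4 * self.depths)
        if sd.shape != self.depths.shape:
            raise ValueError("noise_sd vector must match depths")
        return sd


def drained_laminar_response(model: LaminarResponseModel,
                             neuronal_signal_by_depth: np.ndarray) -> np.ndarray:
    """Apply the draining-vein accumulation and contrast scaling.

    For depths d_0 < ... < d_n (GM/WM to GM/CSF) and input amplitudes s, the
    drained amplitude at depth i is

        s'(d_i) = s(d_i) + drain_lambda * sum_{j<i} s(d_j) * (d_{j+1} - d_j)

    i.e. a running depth-integral over all deeper compartments, multiplied by
    ``sign * base_amplitude``.  With drain_lambda = 0 this reduces to a pure
    rescaling.  Works on arrays whose first axis is depth.
    """
    s = np.asarray(neuronal_signal_by_depth, float)
    if s.shape[0] != model.n_depths:
        raise ValueError("signal length does not match model depths")
    dd = np.diff(model.depths)
    shape = (model.n_depths,) + (1,) * (s.ndim - 1)
    acc = np.zeros_like(s)
    if model.drain_lambda > 0:
        weights = dd.reshape((-1,) + (1,) * (s.ndim - 1))
        acc[1:] = model.drain_lambda * np.cumsum(s[:-1] * weights, axis=0)
    return model.sign * model.base_amplitude * (s + acc)


# ---------------------------------------------------------------------------
# session simulation


@dataclass
class SimulatedRun:
    """One simulated run in vertex space.

    ``series`` has shape (n_depths, n_volumes, n_vertices), in raw signal
    units (baseline level 100).  For VASO runs, ``nulled`` / ``not_nulled``
    hold the interleaved pair at the native effective TR and ``series`` is
    None until BOLD correction.
    """

    design: RunDesign
    series: np.ndarray | None
    events: pd.DataFrame
    nulled: np.ndarray | None = None
    not_nulled: np.ndarray | None = None
    nulled_times: np.ndarray | None = None
    not_nulled_times: np.ndarray | None = None


@dataclass
class SimulatedSession:
    sheet: CorticalSheet
    pattern: ODCPattern
    model: LaminarResponseModel
    runs: list
    seed: int

    @property
    def n_depths(self) -> int:
        return self.model.n_depths


BASELINE_LEVEL = 100.0


def _eye_weights(pattern: ODCPattern, monocularity: np.ndarray):
    """Per (depth, vertex) response amplitudes to left / right eye stimulation.

    The preferred eye drives |ocularity|; the non-preferred eye drives
    |ocularity| * (1 - m_d), where m_d is the depth's monocularity.  The
    decodable left-right difference is therefore |ocularity| * m_d, maximal
    at the input layer.
    """
    oc = np.asarray(pattern.ocularity, float)
    m = np.asarray(monocularity, float)[:, None]  # (depth, 1)
    amp = np.abs(oc)[None, :]
    pref_left = (oc > 0)[None, :]
    w_pref = amp
    w_non = amp * (1.0 - m)
    w_left = np.where(pref_left, w_pref, w_non)
    w_right = np.where(pref_left, w_non, w_pref)
    return w_left, w_right


def _condition_responses(design: RunDesign, times: np.ndarray,
                         hrf_params: HrfParams, dt_s: float = 0.5):
    """HRF-convolved left/right boxcars evaluated at acquisition times."""
    n_fine = int(np.ceil(design.duration_s / dt_s)) + 1
    t_fine = np.arange(n_fine) * dt_s
    resp = {}
    h = canonical_hrf(dt_s, hrf_params)
    for cond in ("left", "right"):
        box = np.zeros(n_fine)
        for onset, c in zip(design.block_onsets(), design.block_conditions):
            if c == cond:
                box[(t_fine >= onset) & (t_fine < onset + design.block_s)] = 1.0
        conv = np.convolve(box, h * dt_s)[:n_fine]
        resp[cond] = np.interp(times, t_fine, conv)
    return resp["left"], resp["right"]


def _noise(rng, shape, sd_by_depth, ar1):
    eps = rng.standard_normal(shape)  # (depth, time, vertex)
    if ar1:
        for t in range(1, shape[1]):
            eps[:, t] = ar1 * eps[:, t - 1] + np.sqrt(1 - ar1**2) * eps[:, t]
    return eps * sd_by_depth[:, None, None]


def _drift(rng, times, duration, amplitude):
    """Slow cosine drift (period twice the run length, random phase)."""
    if amplitude == 0:
        return np.zeros_like(times)
    phase = rng.uniform(0, 2 * np.pi)
    return amplitude * np.cos(2 * np.pi * times / (2 * duration) + phase)


def simulate_session(sheet: CorticalSheet, pattern: ODCPattern,
                     model: LaminarResponseModel,
                     design: RunDesign | None = None,
                     hrf_params: HrfParams = HrfParams(),
                     drift_amplitude: float = 1.0,
                     bold_contamination_eps: float = 1.0,
                     vaso_bold_amplitude: float = 2.0,
                     seed: int = 0) -> SimulatedSession:
    """Simulate a full multi-run session in vertex space.

    Per vertex and depth the noise-free percent-signal response is the sum of
    the HRF-convolved left/right condition boxcars weighted by eye preference,
    passed through :func:`drained_laminar_response`; a slow drift and white
    Gaussian noise are added and the series is placed on a baseline level of
    100 (so amplitudes read directly as percent signal change).

    With ``design.vaso_pairing`` set, each run yields a blood-nulled series
    (CBV-weighted, inverted sign, multiplied by ``1 + eps * BOLD(t)`` as
    residual BOLD contamination) and a not-nulled series (pure BOLD with the
    GE drain coefficient), interleaved at the native effective TR.
    """
    if pattern.ocularity.shape[0] != sheet.n_vertices:
        raise ValueError("pattern and sheet vertex counts differ")
    if design is None:
        design = RunDesign(vaso_pairing=model.contrast_type == VASO)
    if model.contrast_type == VASO and not design.vaso_pairing:
        warnings.warn("VASO model without vaso_pairing: emitting a plain "
                      "inverted-contrast series")

    ss = np.random.SeedSequence(seed)
    run_seeds = ss.spawn(design.n_runs)
    w_left, w_right = _eye_weights(pattern, model.neuronal_profile)
    sd_by_depth = model.noise_sd_by_depth()
    runs = []
    for r in range(design.n_runs):
        rng = np.random.default_rng(run_seeds[r])
        # pseudorandomize the block order independently per run
        order = rng.permutation(design.n_blocks)
        rdesign = design.with_conditions(
            np.asarray(design.block_conditions, dtype=object)[order])
        if design.vaso_pairing:
            run = _simulate_vaso_run(rdesign, w_left, w_right, model,
                                     hrf_params, drift_amplitude,
                                     bold_contamination_eps,
                                     vaso_bold_amplitude, sd_by_depth, rng)
        else:
            run = _simulate_bold_run(rdesign, w_left, w_right, model,
                                     hrf_params, drift_amplitude,
                                     sd_by_depth, rng)
        runs.append(run)
    return SimulatedSession(sheet, pattern, model, runs, seed)


def _simulate_bold_run(design, w_left, w_right, model, hrf_params,
                       drift_amplitude, sd_by_depth, rng) -> SimulatedRun:
    times = design.volume_times()
    rl, rr = _condition_responses(design, times, hrf_params)
    # (depth, time, vertex) neuronal percent-signal amplitudes
    neural = rl[None, :, None] * w_left[:, None, :] \
        + rr[None, :, None] * w_right[:, None, :]
    resp = drained_laminar_response(model, neural)
    drift = _drift(rng, times, design.duration_s, drift_amplitude)
    eps = _noise(rng, resp.shape, sd_by_depth, model.ar1_coef)
    series = BASELINE_LEVEL * (1.0 + (resp + drift[None, :, None] + eps) / 100.0)
    return SimulatedRun(design, series.astype(np.float32),
                        design.events_frame())


def _simulate_vaso_run(design, w_left, w_right, model, hrf_params,
                       drift_amplitude, eps_bold, bold_amplitude,
                       sd_by_depth, rng) -> SimulatedRun:
    eff = design.vaso_effective_tr_s
    n_pairs = int(round(design.duration_s / eff))
    t_null = eff * np.arange(n_pairs)
    t_nn = t_null + eff / 2.0

    def pct_response(m, times):
        rl, rr = _condition_responses(design, times, hrf_params)
        neural = rl[None, :, None] * w_left[:, None, :] \
            + rr[None, :, None] * w_right[:, None, :]
        return drained_laminar_response(m, neural)

    # CBV-weighted (inverted) response on the nulled grid
    vaso_resp = pct_response(model, t_null)
    # pure BOLD response (GE-like drain, positive sign) for the not-nulled
    # series and for the contamination of the nulled series
    from dataclasses import replace as _replace
    bold_model = _replace(model, contrast_type=GE_BOLD, sign=+1,
                          base_amplitude=bold_amplitude,
                          drain_lambda=DEFAULT_DRAIN_LAMBDA[GE_BOLD])
    bold_nn = pct_response(bold_model, t_nn)
    bold_null = pct_response(bold_model, t_null)

    drift_n = _drift(rng, t_null, design.duration_s, drift_amplitude)
    drift_nn = np.interp(t_nn, t_null, drift_n)
    eps_n = _noise(rng, vaso_resp.shape, sd_by_depth, model.ar1_coef)
    eps_nn = _noise(rng, bold_nn.shape, sd_by_depth, model.ar1_coef)

    nulled = BASELINE_LEVEL * (1.0 + vaso_resp / 100.0) \
        * (1.0 + eps_bold * bold_null / 100.0)
    nulled = nulled * (1.0 + (drift_n[None, :, None] + eps_n) / 100.0)
    not_nulled = BASELINE_LEVEL * (1.0 + bold_nn / 100.0) \
        * (1.0 + (drift_nn[None, :, None] + eps_nn) / 100.0)
    return SimulatedRun(design, None, design.events_frame(),
                        nulled=nulled.astype(np.float32),
                        not_nulled=not_nulled.astype(np.float32),
                        nulled_times=t_null, not_nulled_times=t_nn)


# ---------------------------------------------------------------------------
# voxelization and file output


def sheet_affine(sheet: CorticalSheet, n_depths: int) -> np.ndarray:
    """Affine of the simulation volume grid: voxel (i, j, k) sits at world
    (i * spacing, j * spacing, k * dz) with dz spanning the thickness."""
    dz = sheet.thickness / (n_depths - 1)
    aff = np.diag([sheet.spacing, sheet.spacing, dz, 1.0])
    return aff


def voxelize_run(sheet: CorticalSheet, run_series: np.ndarray,
                 affine: np.ndarray) -> np.ndarray:
    """Fill vertex x depth values into the volume grid.

    Each (depth, vertex) sample is deposited into the voxel containing its
    world coordinate (between the white and pial surfaces); voxels hit more
    than once hold the mean of their contributions, untouched voxels are 0.
    Returns a (nx, ny, nz, t) array.
    """
    n_depths, n_t, n_vert = run_series.shape
    inv = np.linalg.inv(affine)
    xy = sheet.grid_coords()
    depths = np.linspace(0, 1, n_depths)
    shape = None
    # voxel index per (depth, vertex)
    coords = []
    for d in depths:
        world = np.column_stack([xy, np.full(len(xy), d * sheet.thickness),
                                 np.ones(len(xy))])
        vox = (inv @ world.T).T[:, :3]
        coords.append(np.rint(vox).astype(int))
    coords = np.stack(coords)  # (depth, vertex, 3)
    nx = coords[..., 0].max() + 1
    ny = coords[..., 1].max() + 1
    nz = coords[..., 2].max() + 1
    vol = np.zeros((nx, ny, nz, n_t), dtype=np.float32)
    count = np.zeros((nx, ny, nz), dtype=np.int32)
    flat = np.ravel_multi_index(
        (coords[..., 0], coords[..., 1], coords[..., 2]), (nx, ny, nz))
    np.add.at(count.ravel(), flat.ravel(), 1)
    vals = np.moveaxis(run_series, 1, 2)  # (depth, vertex, t)
    np.add.at(vol.reshape(-1, n_t), flat.ravel(),
              vals.reshape(-1, n_t))
    nz_mask = count > 0
    vol[nz_mask] /= count[nz_mask][:, None]
    return vol


def write_session(session: SimulatedSession, out_dir, write_volumes=True):
    """Write the session to disk: NIfTI volumes (one per run; nulled and
    not-nulled pairs for VASO), per-run events tables, the ground-truth
    ocularity map, and both boundary meshes as plain-text tables."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = session.sheet
    affine = sheet_affine(sheet, session.n_depths)
    for r, run in enumerate(session.runs):
        run.events.to_csv(out / f"run-{r + 1:02d}_events.tsv", sep="\t",
                          index=False)
        if not write_volumes:
            continue

        def save(series, times, tag):
            vol = voxelize_run(sheet, series, affine)
            img = nib.Nifti1Image(vol, affine)
            tr = times[1] - times[0] if len(times) > 1 else run.design.tr_s
            img.header["pixdim"][4] = tr
            nib.save(img, out / f"run-{r + 1:02d}{tag}.nii.gz")

        if run.series is not None:
            save(run.series, run.design.volume_times(), "")
        if run.nulled is not None:
            save(run.nulled, run.nulled_times, "_nulled")
            save(run.not_nulled, run.not_nulled_times, "_notnulled")
    np.savetxt(out / "ground_truth_ocularity.txt", session.pattern.ocularity,
               header="per-vertex ocularity in [-1, 1] (+1 = left eye)")
    sheet.white_mesh().save_txt(out / "white")
    sheet.pial_mesh().save_txt(out / "pial")
    return out
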