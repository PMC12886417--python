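"""End-to-end orchestration: simulate -> preprocess -> layer/sample ->
decode -> stats, deterministic given the master seed.

Every stage draws its randomness from a named child of the master seed
sequence, so results are bit-reproducible for a given configuration.  The
analysis runs through the volume representation on purpose: simulated series
are voxelized, then sampled back onto the layer stack with trilinear
interpolation, exactly as acquired data would be.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import decode as dec
from . import preprocess as pre
from . import stats as st
from . import synthetic as syn
from .config import PipelineConfig
from .design import RunDesign
from .surface import equidistant_layers, sample_volume_to_surface

log = logging.getLogger("odcdecode")


def _stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    """Named, collision-free substream of the master seed."""
    tag = int.from_bytes(stage.encode()[:4].ljust(4, b"\0"), "little")
    return np.random.SeedSequence([master, tag])


@dataclass
class SessionAnalysis:
    """Per-session analysis products in memory."""

    accuracies: np.ndarray  # (n_depths, n_folds)
    psc_by_depth: np.ndarray  # (n_depths, n_vertices)
    zmap_mid_depth: np.ndarray  # (n_vertices,)
    selected: np.ndarray  # vertex indices used for profile summaries
    depths: np.ndarray


def simulate_one_session(cfg: PipelineConfig, session_idx: int,
                         pattern=None) -> syn.SimulatedSession:
    sheet = syn.CorticalSheet(cfg.sheet_nx, cfg.sheet_ny,
                              cfg.sheet_spacing_mm, cfg.thickness_mm)
    seed_pat = int(_stage_seed(cfg.seed, "patt").generate_state(1)[0] % 2**31)
    if pattern is None:
        pattern = syn.generate_odc_pattern(
            sheet, cfg.column_frequency_cpm, cfg.column_bandwidth_cpm,
            cfg.pattern_sharpness, seed=seed_pat)
    model = syn.LaminarResponseModel(
        contrast_type=cfg.contrast,
        depths=np.linspace(0, 1, cfg.n_layers),
        drain_lambda=cfg.drain_lambda,
        base_amplitude=cfg.base_amplitude_pct,
        noise_sd=cfg.noise_sd_pct)
    design = RunDesign(tr_s=cfg.tr_s, n_volumes=cfg.n_volumes,
                       baseline_s=cfg.baseline_s, block_s=cfg.block_s,
                       n_runs=cfg.n_runs,
                       vaso_pairing=cfg.contrast == "VASO")
    seed_sess = int(_stage_seed(cfg.seed, f"ses{session_idx}")
                    .generate_state(1)[0] % 2**31)
    return syn.simulate_session(sheet, pattern, model, design,
                                drift_amplitude=cfg.drift_amplitude_pct,
                                seed=seed_sess)


def _run_to_layer_series(session: syn.SimulatedSession, run,
                         cfg: PipelineConfig) -> np.ndarray:
    """Voxelize one run and sample it back onto the equidistant layer stack.

    Returns the raw sampled series (n_layers, n_volumes, n_vertices); VASO
    runs are BOLD-corrected onto the analysis TR grid first (and rescaled to
    the common baseline level of 100).
    """
    sheet = session.sheet
    affine = syn.sheet_affine(sheet, session.n_depths)
    if run.series is not None:
        vol = syn.voxelize_run(sheet, run.series, affine)
        return _sample_layers(session, vol, affine, cfg)
    vol_n = syn.voxelize_run(sheet, run.nulled, affine)
    vol_nn = syn.voxelize_run(sheet, run.not_nulled, affine)
    series_vd, _ = _sample_and_correct_vaso(session, run, vol_n, vol_nn,
                                            affine, cfg)
    return series_vd


def _highpass_runs(layer_series, cfg: PipelineConfig):
    """Filtered copy for decoding/GLM; PSC uses the unfiltered series.

    The DCT projection removes the mean, so the voxel mean is restored to
    keep signal units comparable across runs."""
    out = []
    for series in layer_series:
        filt = np.empty_like(series)
        for d in range(series.shape[0]):
            ts = pre.TimeSeries(series[d], cfg.tr_s)
            filt[d] = pre.highpass_filter(ts, cfg.highpass_cutoff_hz).data
        out.append(filt)
    return out


def _sample_layers(session, vol4, affine, cfg) -> np.ndarray:
    stack = equidistant_layers(session.sheet.white_mesh(),
                               session.sheet.pial_mesh(),
                               cfg.n_intermediate_layers)
    layers = []
    for surf in stack:
        sampled = sample_volume_to_surface(vol4, affine, surf)  # (v, t)
        layers.append(sampled.T)
    return np.stack(layers)  # (n_layers, t, v)


def _sample_and_correct_vaso(session, run, vol_n, vol_nn, affine, cfg):
    nulled_layers = _sample_layers(session, vol_n, affine, cfg)
    nn_layers = _sample_layers(session, vol_nn, affine, cfg)
    n_layers = nulled_layers.shape[0]
    out = None
    for d in range(n_layers):
        ts_n = pre.TimeSeries(nulled_layers[d], run.design.vaso_effective_tr_s,
                              times=run.nulled_times)
        ts_nn = pre.TimeSeries(nn_layers[d], run.design.vaso_effective_tr_s,
                               times=run.not_nulled_times)
        corrected = pre.vaso_bold_correct(ts_n, ts_nn,
                                          target_tr_s=cfg.tr_s).series
        if out is None:
            out = np.empty((n_layers,) + corrected.data.shape)
        # rescale the ratio back to signal units (baseline level 100)
        out[d] = 100.0 * corrected.data
    times = cfg.tr_s * np.arange(out.shape[1])
    # pad/trim to the design's volume count
    n_target = run.design.n_volumes
    if out.shape[1] > n_target:
        out = out[:, :n_target]
    elif out.shape[1] < n_target:
        pad = np.repeat(out[:, -1:], n_target - out.shape[1], axis=1)
        out = np.concatenate([out, pad], axis=1)
    return out, times


def analyze_session(session: syn.SimulatedSession,
                    cfg: PipelineConfig) -> SessionAnalysis:
    """Run the laminar decoding analysis on one (simulated) session."""
    log.info("sampling %d runs onto %d layers", len(session.runs),
             cfg.n_layers)
    layer_series = [_run_to_layer_series(session, run, cfg)
                    for run in session.runs]
    designs = [run.design for run in session.runs]
    depths = np.linspace(0, 1, cfg.n_layers)
    filtered = _highpass_runs(layer_series, cfg)
    samples = dec.session_samples(filtered, designs, depths=depths)

    invert = session.model.contrast_type == "VASO"
    psc = np.stack([
        np.mean([pre.percent_signal_change(
            pre.TimeSeries(s[d], cfg.tr_s), des,
            invert_for_display=invert).psc
            for s, des in zip(layer_series, designs)], axis=0)
        for d in range(cfg.n_layers)])

    policy = (cfg.selection_policy if cfg.selection_policy
              in (dec.DEPTH_AVERAGED, dec.PER_DEPTH)
              else dec.DEPTH_AVERAGED)
    config = dec.DecoderConfig(C=cfg.svm_c, k_features=cfg.k_features,
                               selection_policy=policy)
    log.info("decoding (k=%d, C=%g, policy=%s)", config.k_features,
             config.C, policy)
    result = dec.loro_cross_validate(samples, config)

    # session-level GLM z-map at mid-depth for the repeatability analysis
    mid = cfg.n_layers // 2
    concat = np.concatenate([s[mid] for s in filtered], axis=0)
    glm = pre.glm_fit(pre.TimeSeries(concat, cfg.tr_s), designs)
    selection = dec.select_features(samples, policy, cfg.k_features)
    return SessionAnalysis(result.accuracies, psc, glm.z,
                           selection.selected_at(mid), depths)


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> Path:
    """Execute the full pipeline and write result tables (and figures).

    Outputs in the report directory: accuracy_profile.tsv (per-depth mean
    accuracy with bootstrap CI and FDR-corrected significance vs 50%),
    psc_profile.tsv, accuracy_by_fold.tsv, repeatability.tsv (when at least
    two sessions are simulated), and the resolved config.  Every table
    carries the config hash.
    """
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    chash = cfg.hash()
    log.info("pipeline start (config %s, seed %d)", chash, cfg.seed)
    cfg.to_yaml(out / "config.yaml")

    stage = "simulate" if cfg.simulate else "load"
    if not cfg.simulate:
        raise NotImplementedError(
            "only the synthetic data path is implemented; prepare data in "
            "the simulated session layout and set simulate: true")
    try:
        sessions = []
        pattern = None
        for s in range(cfg.n_sessions):
            sess = simulate_one_session(cfg, s, pattern=pattern)
            pattern = sess.pattern  # same columns, independent noise
            sessions.append(sess)
            if cfg.write_volumes:
                syn.write_session(sess, out / f"session-{s + 1:02d}")
            else:
                syn.write_session(sess, out / f"session-{s + 1:02d}",
                                  write_volumes=False)
        stage = "analyze"
        analyses = [analyze_session(sess, cfg) for sess in sessions]
        stage = "stats"
        tables = _summarize(analyses, cfg, chash)
        for name, frame in tables.items():
            _write_tsv(frame, out / f"{name}.tsv", chash)
        if cfg.make_plots:
            _plots(tables, cfg, out)
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err
    log.info("pipeline done -> %s", out)
    return out


def _summarize(analyses, cfg: PipelineConfig, chash: str) -> dict:
    n_layers = cfg.n_layers
    # units for the bootstrap: cross-validation folds, pooled over sessions
    acc_units = np.concatenate([a.accuracies.T for a in analyses], axis=0)
    seed_boot = int(_stage_seed(cfg.seed, "boot").generate_state(1)[0] % 2**31)
    profile = st.accuracy_significance_profile(
        acc_units, n_boot=cfg.n_boot, alpha=cfg.alpha, seed=seed_boot)
    acc_tab = pd.DataFrame({
        "depth_index": profile.depth_index,
        "relative_depth": np.linspace(0, 1, n_layers),
        "mean_accuracy": profile.point_estimate,
        "ci_low": profile.ci_low,
        "ci_high": profile.ci_high,
        "p_value": profile.p_values,
        "q_value": profile.q_values,
        "significant": profile.significant,
    })

    fold_rows = []
    for s, a in enumerate(analyses):
        for f in range(a.accuracies.shape[1]):
            for d in range(n_layers):
                fold_rows.append((s, f, d, a.accuracies[d, f]))
    folds_tab = pd.DataFrame(fold_rows,
                             columns=["session", "fold", "depth_index",
                                      "accuracy"])

    psc_units = []
    for a in analyses:
        psc_units.append([np.nanmean(a.psc_by_depth[d, a.selected])
                          for d in range(n_layers)])
    psc_units = np.asarray(psc_units)
    if len(analyses) >= 2:
        seed_psc = int(_stage_seed(cfg.seed, "pboo").generate_state(1)[0] % 2**31)
        pprof = st.depth_profile(psc_units, n_boot=cfg.n_boot, units="% PSC",
                                 seed=seed_psc)
        lo, hi = pprof.ci_low, pprof.ci_high
    else:
        lo = hi = psc_units.mean(axis=0)
    psc_tab = pd.DataFrame({
        "depth_index": np.arange(n_layers),
        "relative_depth": np.linspace(0, 1, n_layers),
        "mean_psc": psc_units.mean(axis=0),
        "ci_low": lo,
        "ci_high": hi,
        "display_inverted": cfg.contrast == "VASO",
    })

    tables = {"accuracy_profile": acc_tab, "accuracy_by_fold": folds_tab,
              "psc_profile": psc_tab}

    if len(analyses) >= 2:
        rows = []
        seed_perm = int(_stage_seed(cfg.seed, "perm").generate_state(1)[0] % 2**31)
        for i in range(len(analyses)):
            for j in range(i + 1, len(analyses)):
                res = st.permutation_pvalue(analyses[i].zmap_mid_depth,
                                            analyses[j].zmap_mid_depth,
                                            n_perm=cfg.n_perm,
                                            seed=seed_perm)
                rows.append((i, j, res.r_observed, res.k_exceed, res.sigma,
                             res.p_corrected, res.significant))
        tables["repeatability"] = pd.DataFrame(
            rows, columns=["session_a", "session_b", "spearman_r",
                           "k_exceed", "sigma", "p_corrected", "significant"])
    return tables


def _write_tsv(frame: pd.DataFrame, path: Path, chash: str):
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {chash}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _plots(tables: dict, cfg: PipelineConfig, out: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    acc = tables["accuracy_profile"]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.fill_between(acc["relative_depth"], acc["ci_low"], acc["ci_high"],
                    color="0.8", label="95% bootstrap CI")
    ax.plot(acc["relative_depth"], acc["mean_accuracy"], "k-")
    ax.axhline(0.5, ls=":", c="r", label="chance")
    ax.set_xlabel("relative cortical depth (0 = GM/WM)")
    ax.set_ylabel("prediction accuracy")
    ax.set_title(cfg.contrast)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "accuracy_profile.png", dpi=150)
    plt.close(fig)

    psc = tables["psc_profile"]
    sign = -1.0 if cfg.contrast == "VASO" else 1.0
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.fill_between(psc["relative_depth"], sign * psc["ci_low"],
                    sign * psc["ci_high"], color="0.8")
    ax.plot(psc["relative_depth"], sign * psc["mean_psc"], "k-")
    ax.set_xlabel("relative cortical depth (0 = GM/WM)")
    label = "percent signal change"
    if cfg.contrast == "VASO":
        label += " (sign inverted for display)"
    ax.set_ylabel(label)
    ax.set_title(cfg.contrast)
    fig.tight_layout()
    fig.savefig(out / "psc_profile.png", dpi=150)
    plt.close(fig)
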