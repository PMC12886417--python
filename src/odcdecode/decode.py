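"""Depth-resolved multivariate decoding of eye-of-origin.

Single retained time points (baseline volumes and the first two volumes of
every stimulation block discarded) are classified with a linear soft-margin
SVM (C = 1) per cortical depth, under leave-one-run-out cross-validation.
Feature (vertex) selection uses a one-way ANOVA F score computed on the
training folds only; by default the training data are averaged across depth
first so the same 200 vertices are used at every depth, honoring the
columnar organization of the signal.

No information flows from the held-out run into feature scores, selections,
or standardization parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .design import RunDesign, LEFT, RIGHT

DEPTH_AVERAGED = "depth-averaged"
PER_DEPTH = "per-depth"


def single_depth(d: int) -> tuple:
    """Selection policy scoring only depth index ``d`` (the selected set is
    still reused at all depths)."""
    return ("single-depth", int(d))


@dataclass
class LabeledSamples:
    """Retained time points x vertices, stacked over depths and runs.

    ``data`` has shape (n_depths, n_samples, n_vertices); ``labels`` and
    ``run_ids`` are per sample.  Baseline time points are never present.
    """

    data: np.ndarray
    labels: np.ndarray
    run_ids: np.ndarray
    depths: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        self.labels = np.asarray(self.labels)
        self.run_ids = np.asarray(self.run_ids)
        if not (len(self.labels) == len(self.run_ids) == self.data.shape[1]):
            raise ValueError("labels/run_ids must match the sample axis")
        for r in np.unique(self.run_ids):
            sel = self.run_ids == r
            n_left = int(np.sum(self.labels[sel] == LEFT))
            n_right = int(np.sum(self.labels[sel] == RIGHT))
            if n_left != n_right:
                raise ValueError(
                    f"run {r}: unbalanced classes ({n_left} left, "
                    f"{n_right} right)")

    @property
    def n_depths(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[2]

    def subset(self, sample_mask) -> "LabeledSamples":
        return LabeledSamples(self.data[:, sample_mask], self.labels[sample_mask],
                              self.run_ids[sample_mask], self.depths)

    @staticmethod
    def concat(parts) -> "LabeledSamples":
        return LabeledSamples(
            np.concatenate([p.data for p in parts], axis=1),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.run_ids for p in parts]),
            parts[0].depths)


def select_timepoints(run_series: np.ndarray, design: RunDesign,
                      run_id: int = 0,
                      depths: np.ndarray | None = None) -> LabeledSamples:
    """Apply the retention rule to one run.

    ``run_series`` is (n_depths, n_volumes, n_vertices) — or (n_volumes,
    n_vertices) for a single depth.  All baseline volumes and the first two
    volumes of every stimulation block are discarded; the rest are labeled by
    their block's condition.
    """
    series = np.asarray(run_series, float)
    if series.ndim == 2:
        series = series[None]
    if series.shape[1] != design.n_volumes:
        raise ValueError("series length does not equal design.n_volumes")
    if design.block_s / design.tr_s < 3:
        raise ValueError("blocks shorter than 3 volumes retain nothing")
    keep = design.retained_mask()
    labels = design.volume_conditions()[keep]
    return LabeledSamples(series[:, keep], labels,
                          np.full(int(keep.sum()), run_id), depths)


def session_samples(session_series, designs, depths=None) -> LabeledSamples:
    """Stack retained samples over a session's runs (one series per run)."""
    parts = [select_timepoints(s, d, run_id=i, depths=depths)
             for i, (s, d) in enumerate(zip(session_series, designs))]
    return LabeledSamples.concat(parts)


# ---------------------------------------------------------------------------
# feature selection


def anova_f_scores(samples: LabeledSamples,
                   data: np.ndarray | None = None) -> np.ndarray:
    """One-way two-group ANOVA F per vertex (between-group mean square over
    within-group mean square); equals the squared equal-variance two-sample
    t statistic."""
    x = samples.data.mean(axis=0) if data is None else np.asarray(data, float)
    y = samples.labels
    groups = [x[y == LEFT], x[y == RIGHT]]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each class needs at least 2 samples")
    n = len(x)
    grand = x.mean(axis=0)
    ss_between = sum(len(g) * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    df_between = len(groups) - 1
    df_within = n - len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    degenerate = ss_within == 0
    if np.any(degenerate):
        f = np.where(degenerate & (ss_between > 0), np.inf, f)
        f = np.where(degenerate & (ss_between == 0), 0.0, f)
    return f


@dataclass
class FeatureSelection:
    """Selected vertex indices (descending score, ties by ascending index)."""

    scores: np.ndarray
    selected: np.ndarray
    k: int
    policy: object = DEPTH_AVERAGED
    per_depth_selected: list | None = None  # only for the per-depth policy

    def selected_at(self, depth: int) -> np.ndarray:
        if self.per_depth_selected is not None:
            return self.per_depth_selected[depth]
        return self.selected


def _top_k(scores: np.ndarray, k: int,
           eligible: np.ndarray | None = None) -> np.ndarray:
    s = np.asarray(scores, float).copy()
    idx = np.arange(len(s))
    if eligible is not None:
        idx = idx[eligible]
        s = s[eligible]
    if k > len(idx):
        warnings.warn(f"k={k} exceeds {len(idx)} eligible vertices; "
                      "selecting all")
        k = len(idx)
    s = np.nan_to_num(s, nan=-np.inf)
    order = np.lexsort((idx, -s))  # descending score, ties ascending index
    return idx[order[:k]]


def select_features(training: LabeledSamples, policy=DEPTH_AVERAGED,
                    k: int = 200,
                    eligible: np.ndarray | None = None) -> FeatureSelection:
    """Score vertices on training data and pick the top k.

    Policies: ``"depth-averaged"`` (default — score the depth-averaged
    training data once, reuse the set at every depth), ``single_depth(d)``
    (score depth d only, still reused everywhere), ``"per-depth"`` (score and
    select independently at each depth).  ``eligible`` restricts selection to
    a vertex mask (e.g. V1 vertices inside every session's field of view).
    """
    if policy == DEPTH_AVERAGED:
        scores = anova_f_scores(training)
        return FeatureSelection(scores, _top_k(scores, k, eligible), k, policy)
    if isinstance(policy, tuple) and policy[0] == "single-depth":
        d = policy[1]
        scores = anova_f_scores(training, data=training.data[d])
        return FeatureSelection(scores, _top_k(scores, k, eligible), k, policy)
    if policy == PER_DEPTH:
        per_depth, score_list = [], []
        for d in range(training.n_depths):
            scores = anova_f_scores(training, data=training.data[d])
            score_list.append(scores)
            per_depth.append(_top_k(scores, k, eligible))
        return FeatureSelection(np.stack(score_list), per_depth[0], k, policy,
                                per_depth_selected=per_depth)
    raise ValueError(f"unknown selection policy {policy!r}")


# ---------------------------------------------------------------------------
# cross-validated decoding


@dataclass
class DecoderConfig:
    """Classifier settings: linear hinge-loss SVM, no kernel, no class
    weighting (C and k fixed, as in the reference procedure)."""

    C: float = 1.0
    k_features: int = 200
    selection_policy: object = DEPTH_AVERAGED
    standardize_per: str = "vertex"  # or "timepoint" (sensitivity analysis)

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.k_features < 1:
            raise ValueError("k_features must be >= 1")
        if self.standardize_per not in ("vertex", "timepoint"):
            raise ValueError("standardize_per must be 'vertex' or 'timepoint'")


@dataclass
class DecodingResult:
    accuracies: np.ndarray  # (n_depths, n_folds)
    folds: np.ndarray  # held-out run id per fold

    @property
    def mean_by_depth(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)


def _standardize(train: np.ndarray, test: np.ndarray, per: str):
    if per == "timepoint":
        def z(x):
            mu = x.mean(axis=1, keepdims=True)
            sd = x.std(axis=1, keepdims=True)
            sd0 = sd == 0
            if sd0.any():
                sd = np.where(sd0, 1.0, sd)
            return (x - mu) / sd
        return z(train), z(test)
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} constant training features; "
                      "standardized values set to 0")
        sd = np.where(dead, 1.0, sd)
    ztr = (train - mu) / sd
    zte = (test - mu) / sd
    ztr[:, dead] = 0.0
    zte[:, dead] = 0.0
    return ztr, zte


def loro_cross_validate(samples: LabeledSamples,
                        config: DecoderConfig = DecoderConfig(),
                        eligible: np.ndarray | None = None) -> DecodingResult:
    """Leave-one-run-out decoding accuracy per cortical depth.

    Per fold, features are selected and per-vertex standardization
    parameters estimated on the training runs only; a linear SVM (penalty C)
    is then trained per depth and scored on the held-out run.
    """
    runs = np.unique(samples.run_ids)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    acc = np.zeros((samples.n_depths, len(runs)))
    for fold, held_out in enumerate(runs):
        test_mask = samples.run_ids == held_out
        train = samples.subset(~test_mask)
        test = samples.subset(test_mask)
        selection = select_features(train, config.selection_policy,
                                    config.k_features, eligible)
        for d in range(samples.n_depths):
            cols = selection.selected_at(d)
            xtr, xte = _standardize(train.data[d][:, cols],
                                    test.data[d][:, cols],
                                    config.standardize_per)
            clf = SVC(kernel="linear", C=config.C)
            clf.fit(xtr, train.labels)
            acc[d, fold] = float(np.mean(clf.predict(xte) == test.labels))
    return DecodingResult(acc, runs)


def feature_count_sweep(samples: LabeledSamples, config: DecoderConfig,
                        k_grid, psc_maps: np.ndarray | None = None,
                        eligible: np.ndarray | None = None):
    """Mean decoding accuracy as a function of the number of selected
    vertices.

    Returns (accuracy surface (len(k_grid) x n_depths), PSC surface or None).
    The PSC surface averages ``psc_maps`` (n_depths x n_vertices) over each
    k's vertex set selected from all runs (descriptive, no cross-validation
    needed for PSC).
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    from dataclasses import replace
    acc = np.zeros((len(k_grid), samples.n_depths))
    for i, k in enumerate(k_grid):
        res = loro_cross_validate(samples, replace(config, k_features=int(k)),
                                  eligible)
        acc[i] = res.mean_by_depth
    psc_surface = None
    if psc_maps is not None:
        psc_maps = np.asarray(psc_maps, float)
        psc_surface = np.zeros_like(acc)
        for i, k in enumerate(k_grid):
            sel = select_features(samples, config.selection_policy, int(k),
                                  eligible)
            for d in range(samples.n_depths):
                psc_surface[i, d] = psc_maps[d, sel.selected_at(d)].mean()
    return acc, psc_surface
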