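"""Iterative selection of endogenous retention-time anchor peptides.

Instead of spiked-in iRT standards, anchor ("nRT") peptides are chosen from
the sample itself: peptides that elute close to their library retention
time (at most 10 min away), with sharp peaks (base width under 16.5 s),
adequate intensity (at least 1e5), and consistent detection across runs
(at least 20). Survivors are spread over the gradient by splitting it into
20 equal-width RT bins and subsampling each to at most 100 peptides, then
a lasso model mapping library RT to observed RT is fitted per run. The
whole cycle repeats — re-aligning features against the model predictions —
until the number of identifications stabilizes (typically within five
iterations).

Feature tables are pandas DataFrames with columns
``peptide, run, rt_obs, rt_lib, width, intensity``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

FEATURE_COLUMNS = ["peptide", "run", "rt_obs", "rt_lib", "width", "intensity"]


class RTCalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class NrtFilterConfig:
    """Anchor-peptide selection thresholds.

    Boundary semantics follow the selection rules: |observed - library| RT
    at most ``max_rt_delta`` (inclusive), peak width strictly below
    ``max_width``, intensity at least ``min_intensity`` (inclusive),
    detected in at least ``min_runs`` runs (peptides in fewer are
    discarded).
    """

    max_rt_delta: float = 600.0  # s (10 min)
    max_width: float = 16.5  # s, strict <
    min_intensity: float = 1e5  # inclusive >=
    min_runs: int = 20
    n_bins: int = 20
    max_per_bin: int = 100
    gradient_start: float = 0.0
    gradient_end: float = 7200.0
    seed: int = 0
    count_any_detection: bool = False  # count all detections toward min_runs

    def __post_init__(self) -> None:
        if min(self.max_rt_delta, self.max_width, self.min_intensity) <= 0:
            raise RTCalibrationError("all thresholds must be positive")
        if self.n_bins < 1:
            raise RTCalibrationError("need at least one RT bin")
        if self.gradient_end <= self.gradient_start:
            raise RTCalibrationError("gradient span must be positive")


@dataclass
class RTModel:
    """Polynomial lasso model predicting observed RT from library RT."""

    degree: int
    coefficients: np.ndarray  # on the standardized basis
    intercept: float
    alpha: float
    basis_mean: np.ndarray
    basis_scale: np.ndarray
    residual_sd: float

    def predict(self, rt_lib: np.ndarray) -> np.ndarray:
        x = np.asarray(rt_lib, dtype=float)
        basis = np.vander(x, self.degree + 1, increasing=True)[:, 1:]
        z = (basis - self.basis_mean) / self.basis_scale
        return z @ self.coefficients + self.intercept


@dataclass
class IterationTrace:
    """Per-iteration bookkeeping of the calibration loop."""

    anchor_counts: list[int] = field(default_factory=list)
    identified_peptides: list[int] = field(default_factory=list)
    identified_proteins: list[int] = field(default_factory=list)

    def append(self, anchors: int, peptides: int, proteins: int) -> None:
        self.anchor_counts.append(anchors)
        self.identified_peptides.append(peptides)
        self.identified_proteins.append(proteins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": range(len(self.anchor_counts)),
                "anchor_peptides": self.anchor_counts,
                "identified_peptides": self.identified_peptides,
                "identified_proteins": self.identified_proteins,
            }
        )


def _check_features(features: pd.DataFrame) -> pd.DataFrame:
    missing = set(FEATURE_COLUMNS) - set(features.columns)
    if missing:
        raise RTCalibrationError(f"feature table missing columns {sorted(missing)}")
    return features


def _qualifying_mask(
    features: pd.DataFrame, cfg: NrtFilterConfig, rt_delta: pd.Series
) -> pd.Series:
    return (
        (rt_delta.abs() <= cfg.max_rt_delta)
        & (features["width"] < cfg.max_width)
        & (features["intensity"] >= cfg.min_intensity)
    )


def filter_rt_candidates(
    features: pd.DataFrame,
    cfg: NrtFilterConfig = NrtFilterConfig(),
    rt_delta: pd.Series | None = None,
) -> set[str]:
    """Apply the four anchor filters; returns surviving peptide sequences.

    ``rt_delta`` overrides the raw observed-minus-library difference, which
    lets later iterations filter against model-corrected deviations.
    """
    _check_features(features)
    if features.empty:
        raise RTCalibrationError("feature table is empty")
    if rt_delta is None:
        rt_delta = features["rt_obs"] - features["rt_lib"]
    ok = _qualifying_mask(features, cfg, rt_delta)
    if cfg.count_any_detection:
        runs = features.groupby("peptide")["run"].nunique()
        qualified = set(features.loc[ok, "peptide"])
        counted = runs[runs >= cfg.min_runs]
        return qualified & set(counted.index)
    runs = features.loc[ok].groupby("peptide")["run"].nunique()
    return set(runs[runs >= cfg.min_runs].index)


def bin_subsample(
    candidates: set[str],
    library_rt: pd.Series,
    cfg: NrtFilterConfig = NrtFilterConfig(),
    rng: np.random.Generator | None = None,
) -> set[str]:
    """Spread candidates across the gradient: equal-width library-RT bins,
    each randomly subsampled to at most ``max_per_bin`` peptides.

    Bins are half-open [lo, hi) with the last bin closed; sampling is
    deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    edges = np.linspace(cfg.gradient_start, cfg.gradient_end, cfg.n_bins + 1)
    rts = library_rt.loc[library_rt.index.isin(candidates)]
    selected: set[str] = set()
    for b in range(cfg.n_bins):
        lo, hi = edges[b], edges[b + 1]
        if b == cfg.n_bins - 1:
            in_bin = rts[(rts >= lo) & (rts <= hi)]
        else:
            in_bin = rts[(rts >= lo) & (rts < hi)]
        members = sorted(in_bin.index)
        if len(members) > cfg.max_per_bin:
            members = list(
                rng.choice(members, size=cfg.max_per_bin, replace=False)
            )
        selected.update(members)
    return selected


def fit_rt_model(
    pairs: np.ndarray | list[tuple[float, float]],
    degree: int = 1,
    alphas: np.ndarray | None = None,
    cv: int = 5,
    seed: int = 0,
) -> RTModel:
    """Fit an L1-regularized polynomial mapping library RT -> observed RT.

    The polynomial basis is standardized before fitting and the
    regularization strength is chosen by ``cv``-fold cross-validation over
    ``alphas`` (default: logarithmic grid from 1e-4 to 10).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise RTCalibrationError("pairs must be an (n, 2) array of (lib, obs) RT")
    n = arr.shape[0]
    if n < max(10, degree + 2):
        raise RTCalibrationError(
            f"need at least {max(10, degree + 2)} pairs, got {n}"
        )
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise RTCalibrationError("library RTs are constant; model undefined")
    basis = np.vander(x, degree + 1, increasing=True)[:, 1:]
    mean = basis.mean(axis=0)
    scale = basis.std(axis=0)
    scale[scale == 0] = 1.0
    z = (basis - mean) / scale
    if alphas is None:
        alphas = np.logspace(-7, 1, 17)
    folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
    cv_mse = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for alpha in alphas:
            errs = []
            for tr, te in folds.split(z):
                m = Lasso(alpha=alpha, max_iter=5000).fit(z[tr], y[tr])
                errs.append(float(np.mean((m.predict(z[te]) - y[te]) ** 2)))
            cv_mse.append(float(np.mean(errs)))
        # smallest alpha wins ties so an exact fit is never shrunk
        best_alpha = min(zip(cv_mse, alphas))[1]
        model = Lasso(alpha=best_alpha, max_iter=5000).fit(z, y)
    resid = y - model.predict(z)
    return RTModel(
        degree=degree,
        coefficients=model.coef_.copy(),
        intercept=float(model.intercept_),
        alpha=float(best_alpha),
        basis_mean=mean,
        basis_scale=scale,
        residual_sd=float(np.std(resid)),
    )


def iterate_nrt(
    features: pd.DataFrame,
    cfg: NrtFilterConfig = NrtFilterConfig(),
    max_iter: int = 5,
    rel_tol: float = 0.005,
    degree: int = 1,
    peptide_to_protein: dict[str, str] | None = None,
) -> tuple[set[str], dict[str, RTModel], IterationTrace]:
    """Run the full calibration loop until identifications stabilize.

    Iteration 0 scores features against raw library RTs (identity
    alignment). Each subsequent iteration filters candidates, spreads them
    over the gradient, fits one lasso model per run on the anchors, then
    re-computes every feature's RT deviation against the model prediction
    and recounts identifications (a feature is identified when its
    model-corrected |deltaRT| is at most ``cfg.max_rt_delta``). The loop
    stops after ``max_iter`` model fits or when the relative change in the
    identified-peptide count drops below ``rel_tol``.
    """
    _check_features(features)
    runs = sorted(features["run"].unique())
    if not runs:
        raise RTCalibrationError("no runs in feature table")
    lib_rt = features.groupby("peptide")["rt_lib"].median()

    def count_proteins(peptides: set[str]) -> int:
        if peptide_to_protein is None:
            return len(peptides)
        return len({peptide_to_protein[p] for p in peptides if p in peptide_to_protein})

    def identified(delta: pd.Series) -> set[str]:
        ok = delta.abs() <= cfg.max_rt_delta
        return set(features.loc[ok, "peptide"])

    trace = IterationTrace()
    rng = np.random.default_rng(cfg.seed)
    models: dict[str, RTModel] = {}
    delta = features["rt_obs"] - features["rt_lib"]

    ident0 = identified(delta)
    trace.append(0, len(ident0), count_proteins(ident0))
    prev_count = len(ident0)

    anchors: set[str] = set()
    for _ in range(max_iter):
        candidates = filter_rt_candidates(features, cfg, rt_delta=delta)
        if not candidates:
            if not trace.anchor_counts[1:]:
                raise RTCalibrationError(
                    "no anchor candidates survive the filters; loosen "
                    "max_rt_delta / max_width / min_intensity / min_runs"
                )
            break
        anchors = bin_subsample(candidates, lib_rt, cfg, rng)
        new_models: dict[str, RTModel] = {}
        pred = pd.Series(features["rt_lib"].to_numpy(), index=features.index)
        for run in runs:
            in_run = features["run"] == run
            sub = features.loc[in_run & features["peptide"].isin(anchors)]
            try:
                m = fit_rt_model(
                    np.column_stack([sub["rt_lib"], sub["rt_obs"]]),
                    degree=degree,
                    seed=cfg.seed,
                )
            except RTCalibrationError:
                m = models.get(run)  # keep last good model for sparse runs
            if m is not None:
                new_models[run] = m
                pred.loc[in_run] = m.predict(features.loc[in_run, "rt_lib"].to_numpy())
        models = new_models
        delta = features["rt_obs"] - pred
        ident = identified(delta)
        trace.append(len(anchors), len(ident), count_proteins(ident))
        change = abs(len(ident) - prev_count) / max(prev_count, 1)
        prev_count = len(ident)
        if change < rel_tol:
            break
    return anchors, models, trace
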