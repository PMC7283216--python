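"""Per-pair differential-expression scoring for matched case-control
time courses.

Two scores are produced for each (feature, pair):

* BF-score — whole-time-course evidence.  Separate GPs for case and
  control versus one joint GP on the pooled samples; the score is the log
  Bayes factor log[p(x_A|M_A) p(x_B|M_B) / p(x_S|M_S)] with each marginal
  likelihood estimated by CCD integration.  A feature is called DE in a
  pair when the score exceeds 4 (about 54.6 on the linear scale), the
  conventional "strong evidence" cut.

* KL-score — evidence restricted to a fixed time window before an event
  (e.g. seroconversion).  The separate and joint models' CCD predictive
  distributions are evaluated on a weekly grid inside the window, stacked
  into two multivariate Gaussians of dimension 2 x window length, and
  compared by symmetric Kullback-Leibler divergence.  The KL threshold is
  calibrated from features that are borderline under the BF-score.

Scores are direction-agnostic and computed independently per pair, so a
gene may be DE in different pairs through different probe-sets; probe-set
to gene collapsing keeps, per pair, the probe-set with the largest score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import linalg, stats

from .gp import (
    GPConfig,
    GPLinalgError,
    GPPosterior,
    HyperPriors,
    TimeSeries,
    estimate_log_ml,
    fit_ccd,
    predictive_distribution,
)

logger = logging.getLogger(__name__)

BF_THRESHOLD_DEFAULT = 4.0
KL_THRESHOLD_DEFAULT = 250.0


@dataclass(frozen=True)
class PairSeries:
    """One feature's observations for one matched case-control pair."""

    pair_id: str
    feature_id: str
    case: TimeSeries
    control: TimeSeries

    def pooled(self) -> TimeSeries:
        return TimeSeries(
            np.concatenate([self.case.times, self.control.times]),
            np.concatenate([self.case.values, self.control.values]),
        )


@dataclass(frozen=True)
class DEScore:
    feature_id: str
    pair_id: str
    score: float
    score_type: str  # "BF" or "KL"
    threshold: float
    is_de: bool

    @staticmethod
    def from_score(feature_id, pair_id, score, score_type, threshold) -> "DEScore":
        return DEScore(feature_id, pair_id, float(score), score_type, float(threshold), bool(score > threshold))


@dataclass(frozen=True)
class WindowSpec:
    """A fixed-length time window ending at an event, on a weekly grid."""

    event_time: float
    length: float = 26.0
    resolution: float = 1.0

    def __post_init__(self):
        if self.length <= 0 or self.resolution <= 0:
            raise ValueError("window length and resolution must be positive")

    @property
    def test_times(self) -> np.ndarray:
        """length/resolution points ending at (and including) the event time."""
        n = int(round(self.length / self.resolution))
        return self.event_time - self.resolution * np.arange(n)[::-1]


@dataclass(frozen=True)
class WindowModelPair:
    """Separate (M0) and joint (M1) window predictive Gaussians.

    M0 stacks the case and control predictives with zero cross-covariance;
    M1 duplicates the joint predictive.  Both have dimension
    k = 2 x number of test points.
    """

    mean0: np.ndarray
    cov0: np.ndarray
    mean1: np.ndarray
    cov1: np.ndarray

    @property
    def k(self) -> int:
        return self.mean0.size


# ---------------------------------------------------------------------------
# BF scoring (whole time course)
# ---------------------------------------------------------------------------


def bf_score(
    pair: PairSeries,
    priors: HyperPriors | None = None,
    cfg: GPConfig | None = None,
    threshold: float = BF_THRESHOLD_DEFAULT,
) -> DEScore:
    """Log Bayes factor of the separate model against the joint model.

    Case, control and pooled series are each mean-centred independently
    before fitting.  A shift common to both groups cancels exactly; a
    constant offset *between* the groups survives inside the pooled
    series and counts as evidence for the separate model, so the score
    responds to level shifts as well as to shape differences.
    """
    priors = priors or HyperPriors()
    try:
        case_c, _ = pair.case.centred()
        ctrl_c, _ = pair.control.centred()
        pooled_c, _ = pair.pooled().centred()
        lml_case = estimate_log_ml(case_c, priors, cfg)
        lml_ctrl = estimate_log_ml(ctrl_c, priors, cfg)
        lml_joint = estimate_log_ml(pooled_c, priors, cfg)
    except GPLinalgError as e:
        raise GPLinalgError(f"feature {pair.feature_id!r} pair {pair.pair_id!r}: {e}") from e
    score = lml_case + lml_ctrl - lml_joint
    return DEScore.from_score(pair.feature_id, pair.pair_id, score, "BF", threshold)


# ---------------------------------------------------------------------------
# window scoring (KL divergence)
# ---------------------------------------------------------------------------


def window_predictives(
    pair: PairSeries,
    window: WindowSpec,
    priors: HyperPriors | None = None,
    cfg: GPConfig | None = None,
) -> WindowModelPair:
    """Separate and joint CCD predictives on the window grid.

    GPs are fit to the full (centred) series; predictions inside the
    window therefore interpolate (or extrapolate) even when the window
    contains no observations.  Centring means are added back before the
    models are compared, so the two Gaussians live on the original data
    scale.
    """
    priors = priors or HyperPriors()
    tt = window.test_times
    try:
        case_c, mu_case = pair.case.centred()
        ctrl_c, mu_ctrl = pair.control.centred()
        pooled_c, mu_pool = pair.pooled().centred()
        post = {}
        for name, (series, mu) in {
            "case": (case_c, mu_case),
            "control": (ctrl_c, mu_ctrl),
            "joint": (pooled_c, mu_pool),
        }.items():
            grid = fit_ccd(series, priors, cfg)
            p = predictive_distribution(series, tt, grid, cfg)
            post[name] = GPPosterior(p.mean + mu, p.cov, tt)
    except GPLinalgError as e:
        raise GPLinalgError(f"feature {pair.feature_id!r} pair {pair.pair_id!r}: {e}") from e

    n = tt.size
    mean0 = np.concatenate([post["case"].mean, post["control"].mean])
    cov0 = np.zeros((2 * n, 2 * n))
    cov0[:n, :n] = post["case"].cov
    cov0[n:, n:] = post["control"].cov
    mean1 = np.concatenate([post["joint"].mean, post["joint"].mean])
    cov1 = np.zeros((2 * n, 2 * n))
    cov1[:n, :n] = post["joint"].cov
    cov1[n:, n:] = post["joint"].cov
    return WindowModelPair(mean0, cov0, mean1, cov1)


def _chol_psd(S: np.ndarray, rel: float = 1e-10, max_rel: float = 1e-2) -> np.ndarray:
    scale = float(np.mean(np.diag(S))) or 1.0
    jitter = 0.0
    n = S.shape[0]
    while True:
        try:
            return linalg.cholesky(S + jitter * np.eye(n), lower=True)
        except linalg.LinAlgError:
            if rel > max_rel:
                raise GPLinalgError("covariance not PSD after jitter escalation") from None
            jitter = rel * abs(scale)
            rel *= 10.0


def kl_mvn(mean0: np.ndarray, cov0: np.ndarray, mean1: np.ndarray, cov1: np.ndarray) -> float:
    """KL( N(mean0, cov0) || N(mean1, cov1) ) via Cholesky factors.

    0.5 * ( tr(S1^-1 S0) + (m1-m0)' S1^-1 (m1-m0) - k + ln det S1 - ln det S0 )
    """
    mean0 = np.asarray(mean0, dtype=float)
    mean1 = np.asarray(mean1, dtype=float)
    k = mean0.size
    if mean1.size != k or cov0.shape != (k, k) or cov1.shape != (k, k):
        raise ValueError("dimension mismatch in kl_mvn")
    L0 = _chol_psd(np.asarray(cov0, dtype=float))
    L1 = _chol_psd(np.asarray(cov1, dtype=float))
    # tr(S1^-1 S0) = ||L1^-1 L0||_F^2
    M = linalg.solve_triangular(L1, L0, lower=True)
    tr = float(np.sum(M**2))
    d = mean1 - mean0
    y = linalg.solve_triangular(L1, d, lower=True)
    maha = float(y @ y)
    logdet0 = 2.0 * float(np.sum(np.log(np.diag(L0))))
    logdet1 = 2.0 * float(np.sum(np.log(np.diag(L1))))
    return 0.5 * (tr + maha - k + logdet1 - logdet0)


def kl_score(
    models: WindowModelPair,
    feature_id: str = "",
    pair_id: str = "",
    threshold: float = KL_THRESHOLD_DEFAULT,
) -> DEScore:
    """Symmetric KL divergence between the separate and joint window models."""
    fwd = kl_mvn(models.mean0, models.cov0, models.mean1, models.cov1)
    bwd = kl_mvn(models.mean1, models.cov1, models.mean0, models.cov0)
    score = 0.5 * (fwd + bwd)
    return DEScore.from_score(feature_id, pair_id, max(score, 0.0), "KL", threshold)


def calibrate_kl_threshold(
    bf_scores: np.ndarray,
    kl_scores: np.ndarray,
    bf_threshold: float = BF_THRESHOLD_DEFAULT,
    band: float = 1.0,
    default: float = KL_THRESHOLD_DEFAULT,
    min_count: int = 30,
) -> float:
    """KL threshold = mode of KL-scores of borderline-BF features.

    Features (pooled across all pairs) with BF-score within +/- ``band``
    of the BF threshold define the borderline set; the mode of their
    KL-scores is estimated with a Gaussian KDE (Silverman bandwidth) on
    log(1 + score) and mapped back.  With fewer than ``min_count``
    borderline features the configured default is returned.
    """
    bf_scores = np.asarray(bf_scores, dtype=float)
    kl_scores = np.asarray(kl_scores, dtype=float)
    if bf_scores.shape != kl_scores.shape:
        raise ValueError("bf_scores and kl_scores must align")
    sel = np.abs(bf_scores - bf_threshold) <= band
    sel &= np.isfinite(kl_scores)
    kls = kl_scores[sel]
    if kls.size < min_count:
        logger.warning(
            "only %d borderline features (need %d); falling back to KL threshold %g",
            kls.size,
            min_count,
            default,
        )
        return float(default)
    x = np.log1p(kls)
    if np.ptp(x) == 0.0:  # degenerate: all identical
        return float(kls[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    mode_log = grid[np.argmax(kde(grid))]
    return float(np.expm1(mode_log))


# ---------------------------------------------------------------------------
# dataset-level scoring
# ---------------------------------------------------------------------------


def iter_pair_series(
    matrix: pd.DataFrame, metadata: pd.DataFrame, feature_id: str
) -> tuple[list[PairSeries], list[str]]:
    """Assemble PairSeries for one feature; returns (pairs, skipped_pair_ids).

    Pairs with either group entirely unobserved are skipped, never scored.
    """
    row = matrix.loc[feature_id]
    out, skipped = [], []
    for pair_id, sub in metadata.groupby("pair_id", sort=True):
        case = sub[sub["group"] == "case"]
        ctrl = sub[sub["group"] == "control"]
        if len(case) == 0 or len(ctrl) == 0:
            skipped.append(str(pair_id))
            continue
        out.append(
            PairSeries(
                pair_id=str(pair_id),
                feature_id=str(feature_id),
                case=TimeSeries(case["time_weeks"].to_numpy(), row[case["sample_id"]].to_numpy()),
                control=TimeSeries(ctrl["time_weeks"].to_numpy(), row[ctrl["sample_id"]].to_numpy()),
            )
        )
    return out, skipped


def _collect(per_feature_results: list[tuple[list[tuple], list[tuple]]]) -> pd.DataFrame:
    records = [r for chunk, _ in per_feature_results for r in chunk]
    rejects = [r for _, rej in per_feature_results for r in rej]
    out = pd.DataFrame(records, columns=["feature_id", "pair_id", "score_type", "score", "is_de"])
    # quarantined (feature, pair, error) triples; the run continues without them
    out.attrs["rejects"] = rejects
    if rejects:
        logger.warning("%d feature/pair scorings failed and were quarantined", len(rejects))
    return out


def score_dataset_tc(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    priors: HyperPriors | None = None,
    cfg: GPConfig | None = None,
    threshold: float = BF_THRESHOLD_DEFAULT,
    features: list[str] | None = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """BF-score every (feature, pair); long-format result table.

    Features are scored independently (embarrassingly parallel); results
    are identical for any ``n_jobs`` and collected in feature order.
    """
    priors = priors or HyperPriors()
    cfg = cfg or GPConfig()
    feats = list(features) if features is not None else list(matrix.index)

    def one_feature(fid):
        pairs, skipped = iter_pair_series(matrix, metadata, fid)
        if skipped:
            logger.warning("feature %s: pairs skipped (one group unobserved): %s", fid, ", ".join(skipped))
        out, rejects = [], []
        for pair in pairs:
            try:
                s = bf_score(pair, priors, cfg, threshold)
            except GPLinalgError as e:
                rejects.append((pair.feature_id, pair.pair_id, str(e)))
                continue
            out.append((s.feature_id, s.pair_id, s.score_type, s.score, s.is_de))
        return out, rejects

    if n_jobs == 1:
        chunks = [one_feature(f) for f in feats]
    else:
        chunks = Parallel(n_jobs=n_jobs)(delayed(one_feature)(f) for f in feats)
    return _collect(chunks)


def score_dataset_window(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    events: dict[str, float],
    priors: HyperPriors | None = None,
    cfg: GPConfig | None = None,
    window_length: float = 26.0,
    resolution: float = 1.0,
    threshold: float = KL_THRESHOLD_DEFAULT,
    features: list[str] | None = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """KL-score every (feature, pair) in each pair's pre-event window.

    ``events`` maps pair_id to its event time (weeks); pairs without an
    event entry are skipped.  Results are identical for any ``n_jobs``.
    """
    priors = priors or HyperPriors()
    cfg = cfg or GPConfig()
    feats = list(features) if features is not None else list(matrix.index)

    def one_feature(fid):
        pairs, _ = iter_pair_series(matrix, metadata, fid)
        out, rejects = [], []
        for pair in pairs:
            if pair.pair_id not in events:
                continue
            window = WindowSpec(event_time=float(events[pair.pair_id]), length=window_length, resolution=resolution)
            try:
                models = window_predictives(pair, window, priors, cfg)
                s = kl_score(models, pair.feature_id, pair.pair_id, threshold)
            except GPLinalgError as e:
                rejects.append((pair.feature_id, pair.pair_id, str(e)))
                continue
            out.append((s.feature_id, s.pair_id, s.score_type, s.score, s.is_de))
        return out, rejects

    if n_jobs == 1:
        chunks = [one_feature(f) for f in feats]
    else:
        chunks = Parallel(n_jobs=n_jobs)(delayed(one_feature)(f) for f in feats)
    return _collect(chunks)


def collapse_probesets(scores: pd.DataFrame, mapping: dict[str, str] | None) -> pd.DataFrame:
    """Collapse probe-set scores to gene scores by the per-pair maximum.

    Each gene is represented, independently in each pair, by its highest
    scoring probe-set — different pairs may pick different probe-sets.
    Probe-sets absent from the mapping are dropped (count logged).  With
    ``mapping=None`` features are taken to be genes already.
    """
    if scores.empty:
        out = scores.copy()
        out["gene"] = pd.Series(dtype=str)
        return out
    df = scores.copy()
    if mapping is None:
        df["gene"] = df["feature_id"]
    else:
        df["gene"] = df["feature_id"].map(mapping)
        n_drop = int(df["gene"].isna().sum())
        if n_drop:
            logger.info("dropping %d scores from unmapped probe-sets", n_drop)
            df = df.dropna(subset=["gene"])
    idx = df.groupby(["gene", "pair_id", "score_type"], sort=True)["score"].idxmax()
    out = df.loc[idx].reset_index(drop=True)
    cols = ["gene", "feature_id", "pair_id", "score_type", "score", "is_de"]
    return out[cols].sort_values(["score_type", "gene", "pair_id"]).reset_index(drop=True)
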