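"""Population-wide baseline: pooled DE scoring and Fisher's exact
pathway enrichment.

All cases are pooled into one series and all controls into another, so a
single separate-vs-joint GP comparison is made per feature.  The pooled
design assumes expression differences are homogeneous across the study
population; genes perturbed in different directions or at different times
in different pairs average out and are missed — precisely the contrast
the personalised per-pair scoring is built to expose.  Enrichment of the
single pooled DE gene list is tested with a one-sided Fisher's exact
(hypergeometric) test per pathway, BH-adjusted.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .de import (
    BF_THRESHOLD_DEFAULT,
    KL_THRESHOLD_DEFAULT,
    score_dataset_tc,
    score_dataset_window,
)
from .enrichment import PathwayCollection, bh_adjust
from .gp import GPConfig, HyperPriors

logger = logging.getLogger(__name__)

POOLED_PAIR_ID = "combined"


def pool_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Collapse all pairs into a single pseudo-pair keeping sample->time maps."""
    pooled = metadata.copy()
    pooled["pair_id"] = POOLED_PAIR_ID
    return pooled


def pooled_de(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    priors: HyperPriors | None = None,
    cfg: GPConfig | None = None,
    mode: str = "tc",
    event_time: float | None = None,
    window_length: float = 26.0,
    resolution: float = 1.0,
    bf_threshold: float = BF_THRESHOLD_DEFAULT,
    kl_threshold: float = KL_THRESHOLD_DEFAULT,
    features: list[str] | None = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Score each feature once on the pooled cases-vs-controls design.

    The scoring machinery, centring rules and thresholds are identical to
    the personalised path; only the pairing changes.  ``mode`` selects
    whole-time-course BF scoring ("tc") or pre-event window KL scoring
    ("window", which requires ``event_time``).
    """
    pooled_meta = pool_metadata(metadata)
    if mode == "tc":
        return score_dataset_tc(
            matrix, pooled_meta, priors, cfg, threshold=bf_threshold, features=features, n_jobs=n_jobs
        )
    if mode == "window":
        if event_time is None:
            raise ValueError("window mode requires an event_time")
        return score_dataset_window(
            matrix,
            pooled_meta,
            events={POOLED_PAIR_ID: float(event_time)},
            priors=priors,
            cfg=cfg,
            window_length=window_length,
            resolution=resolution,
            threshold=kl_threshold,
            features=features,
            n_jobs=n_jobs,
        )
    raise ValueError(f"unknown mode {mode!r}")


def fisher_enrichment(
    de_genes: set[str],
    universe: set[str],
    pathways: PathwayCollection,
) -> pd.DataFrame:
    """One-sided Fisher's exact test of DE-gene overlap per pathway.

    For each pathway the 2x2 table partitions the platform universe into
    DE/not-DE x in-pathway/not; the p-value is the upper hypergeometric
    tail P(overlap >= observed).  Pathways disjoint from the universe get
    p = 1.
    """
    de_genes = set(de_genes)
    universe = set(universe)
    if not de_genes <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    M = len(universe)
    n_de = len(de_genes)
    restricted = pathways.restricted_to(universe)
    rows = []
    for name, members in restricted.items():
        K = len(members)
        k = len(members & de_genes)
        if K == 0:
            p = 1.0
        else:
            # P(X >= k) for X ~ Hypergeom(M, K, n_de)
            p = float(stats.hypergeom.sf(k - 1, M, K, n_de))
        rows.append((name, K, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["pathway", "n_genes_platform", "overlap", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else out["p_value"]
    out["method"] = "combined"
    return out.sort_values(["p_value", "pathway"]).reset_index(drop=True)
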