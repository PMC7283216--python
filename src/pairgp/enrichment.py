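"""Heterogeneity-aware pathway enrichment over per-pair DE gene lists.

A pathway's statistic is the *adjusted geometric mean* of its scaled
overlaps across case-control pairs:

    f[i, j] = |pathway_i  ∩  DEGs_j| / |DEGs_j| + alpha
    adj.geo.mean[i] = ( prod_j f[i, j] )^(1/m)

Scaling by the pair's DEG count stops DEG-rich pairs from dominating, and
the geometric mean rewards pathways hit consistently across pairs even
when each pair hits them through different member genes — the regime a
population-level test misses.

Significance is assessed by permuting the feature labels of the score
matrix S (whole rows move together, preserving the cross-pair score
correlations), re-collapsing probe-sets to genes, re-thresholding, and
recomputing every pathway's statistic.  Empirical p-values use the
add-one estimator (r + 1) / (B + 1) and are BH-adjusted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 1e-6


class EmptyDEGError(ValueError):
    """A pair contributes zero DE genes; drop the pair or lower the threshold."""


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets (GMT-backed)."""

    pathways: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self):
        for name, genes in self.pathways.items():
            if len(genes) == 0:
                raise ValueError(f"pathway {name!r} is empty")

    def __len__(self) -> int:
        return len(self.pathways)

    def names(self) -> list[str]:
        return list(self.pathways)

    def restricted_to(self, universe: set[str]) -> dict[str, frozenset[str]]:
        """Membership intersected with a platform universe (may be empty)."""
        return {name: frozenset(g & universe) for name, g in self.pathways.items()}


@dataclass
class ScoreMatrix:
    """G x m matrix of per-feature, per-pair DE scores.

    Unscored (feature, pair) combinations are imputed as -inf (never DE)
    and recorded in ``imputed``.
    """

    S: np.ndarray
    feature_ids: list[str]
    pair_ids: list[str]
    score_type: str
    de_threshold: float
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape != (len(self.feature_ids), len(self.pair_ids)):
            raise ValueError("score matrix shape must match feature and pair labels")
        if self.S.shape[0] == 0 or self.S.shape[1] == 0:
            raise ValueError("score matrix must be non-empty")
        if self.imputed is None:
            self.imputed = np.zeros(self.S.shape, dtype=bool)

    @staticmethod
    def from_scores(scores: pd.DataFrame, score_type: str, de_threshold: float) -> "ScoreMatrix":
        """Pivot a long-format score table (one score_type) into a matrix."""
        df = scores[scores["score_type"] == score_type]
        if df.empty:
            raise ValueError(f"no scores of type {score_type!r}")
        wide = df.pivot_table(index="feature_id", columns="pair_id", values="score", aggfunc="max")
        imputed = wide.isna().to_numpy()
        if imputed.any():
            logger.warning("%d unscored feature/pair combinations imputed as -inf", int(imputed.sum()))
        S = wide.to_numpy(dtype=float)
        S[imputed] = -np.inf
        return ScoreMatrix(
            S,
            [str(i) for i in wide.index],
            [str(c) for c in wide.columns],
            score_type,
            de_threshold,
            imputed=imputed,
        )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def scaled_overlap(de_genes: set[str], pathway: frozenset[str] | set[str], alpha: float = ALPHA_DEFAULT) -> float:
    """|pathway ∩ DEGs| / |DEGs| + alpha for one pair."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if len(de_genes) == 0:
        raise EmptyDEGError(
            "a pair has zero DE genes; drop the pair from the analysis or relax the threshold"
        )
    return len(de_genes & set(pathway)) / len(de_genes) + alpha


def adjusted_geometric_mean(f: np.ndarray) -> float:
    """Geometric mean of per-pair scaled overlaps, computed in log space."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("scaled overlaps must be positive")
    return float(np.exp(np.mean(np.log(f))))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def _gene_universe(feature_ids: list[str], mapping: dict[str, str] | None) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Map features to gene indices; unmapped features are excluded.

    Returns (keep row mask, gene labels, per-kept-row gene index).
    """
    if mapping is None:
        genes = sorted(set(feature_ids))
        gidx_of = {g: i for i, g in enumerate(genes)}
        keep = np.ones(len(feature_ids), dtype=bool)
        gidx = np.array([gidx_of[f] for f in feature_ids], dtype=np.int64)
        return keep, genes, gidx
    keep = np.array([f in mapping for f in feature_ids], dtype=bool)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("excluding %d unmapped probe-sets from enrichment", n_drop)
    genes = sorted({mapping[f] for f, k in zip(feature_ids, keep) if k})
    gidx_of = {g: i for i, g in enumerate(genes)}
    gidx = np.array([gidx_of[mapping[f]] for f, k in zip(feature_ids, keep) if k], dtype=np.int64)
    return keep, genes, gidx


def _stats_for_order(
    order: np.ndarray,
    D: np.ndarray,
    gidx: np.ndarray,
    n_genes: int,
    P: np.ndarray,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """adj.geo.mean for every pathway under one feature-label assignment.

    ``order[r]`` is the feature-label index assigned to row r of the DE
    indicator matrix D (G x m bool).  Collapsing probe-sets by maximum
    score and thresholding commutes to: a gene is DE iff any of its rows
    is DE.  Returns (stats, deg counts per pair, overlap counts).
    """
    m = D.shape[1]
    gene_de = np.zeros((n_genes, m), dtype=bool)
    g_of_row = gidx[order]
    for j in range(m):
        hit = np.bincount(g_of_row[D[:, j]], minlength=n_genes)
        gene_de[:, j] = hit > 0
    deg = gene_de.sum(axis=0)
    if np.any(deg == 0):
        bad = [j for j in range(m) if deg[j] == 0]
        raise EmptyDEGError(f"pair column(s) {bad} have zero DE genes under the threshold")
    overlap = P @ gene_de  # (n_pathways, m)
    f = overlap / deg[None, :] + alpha
    stats_ = np.exp(np.mean(np.log(f), axis=1))
    return stats_, deg, overlap


def permutation_test(
    score_matrix: ScoreMatrix,
    mapping: dict[str, str] | None,
    pathways: PathwayCollection,
    n_permutations: int = 100_000,
    seed: int = 0,
    alpha: float = ALPHA_DEFAULT,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Feature-label permutation test of the adjusted geometric mean.

    Each iteration applies one shared random permutation to the feature
    labels of S (whole rows, the same relabelling for every pair), then
    re-collapses probe-sets to genes, re-thresholds, and recomputes every
    pathway's statistic.  ``exhaustive=True`` enumerates all G!
    label assignments instead of sampling (tiny problems only); the
    add-one p-value estimator is used in both modes.

    Pathways with no member genes on the platform are reported with
    p = 1 and flag ``no_platform_genes`` rather than dropped.
    """
    if not exhaustive and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    sm = score_matrix
    keep, genes, gidx = _gene_universe(sm.feature_ids, mapping)
    D = (sm.S[keep] > sm.de_threshold)
    G = int(keep.sum())
    n_genes = len(genes)
    gidx_of = {g: i for i, g in enumerate(genes)}

    restricted = pathways.restricted_to(set(genes))
    names = list(restricted)
    P = np.zeros((len(names), n_genes), dtype=np.float64)
    empty_flag = np.zeros(len(names), dtype=bool)
    for i, name in enumerate(names):
        members = restricted[name]
        if not members:
            empty_flag[i] = True
            continue
        P[i, [gidx_of[g] for g in members]] = 1.0

    identity = np.arange(G)
    stat_obs, deg_obs, overlap_obs = _stats_for_order(identity, D, gidx, n_genes, P, alpha)

    exceed = np.zeros(len(names), dtype=np.int64)
    if exhaustive:
        B = 0
        for perm in itertools.permutations(range(G)):
            stat_b, _, _ = _stats_for_order(np.array(perm), D, gidx, n_genes, P, alpha)
            exceed += stat_b >= stat_obs
            B += 1
    else:
        rng = np.random.default_rng(seed)
        B = int(n_permutations)
        report_every = max(1000, B // 20)
        for b in range(B):
            perm = rng.permutation(G)
            stat_b, _, _ = _stats_for_order(perm, D, gidx, n_genes, P, alpha)
            exceed += stat_b >= stat_obs
            if (b + 1) % report_every == 0:
                logger.info("permutation %d / %d", b + 1, B)

    p = (1.0 + exceed) / (B + 1.0)
    p[empty_flag] = 1.0
    fdr = bh_adjust(p)

    out = pd.DataFrame(
        {
            "pathway": names,
            "n_genes_platform": P.sum(axis=1).astype(int),
            "adj_geo_mean": stat_obs,
            "p_value": p,
            "fdr": fdr,
            "no_platform_genes": empty_flag,
        }
    )
    for j, pair in enumerate(sm.pair_ids):
        out[f"overlap_{pair}"] = overlap_obs[:, j].astype(int)
        out[f"deg_{pair}"] = int(deg_obs[j])
    return out.sort_values(["p_value", "pathway"]).reset_index(drop=True)
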