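"""Tabular I/O (TSV expression/metadata/scores, GMT pathway sets),
run configuration and the end-to-end pipeline.

All tabular formats are plain tab-separated text.  Expression matrices
are features x samples with a header row of sample IDs; metadata maps
each sample to its pair, group and sampling time in weeks; score and
enrichment tables are long-format and carry the run's config hash as a
leading comment line for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .combined import fisher_enrichment, pooled_de
from .de import (
    BF_THRESHOLD_DEFAULT,
    KL_THRESHOLD_DEFAULT,
    calibrate_kl_threshold,
    collapse_probesets,
    score_dataset_tc,
    score_dataset_window,
)
from .enrichment import PathwayCollection, ScoreMatrix, permutation_test
from .gp import GPConfig, HyperPriors
from .simulate import SimConfig, SimResult, simulate

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Features x samples TSV with a sample-ID header; NaN cells rejected."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "feature_id"
    mat = df.to_numpy()
    if not np.issubdtype(mat.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise ValueError(f"non-numeric expression column(s): {list(bad)}")
    if np.isnan(mat).any():
        r, c = np.argwhere(np.isnan(mat))[0]
        raise ValueError(f"NaN expression value at feature {df.index[r]!r}, sample {df.columns[c]!r}")
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pair_id": str, "group": str})
    required = {"sample_id", "pair_id", "group", "time_weeks"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    bad = set(meta["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"metadata group must be case|control, found {sorted(bad)}")
    return meta


def validate_samples(matrix: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Every metadata sample must be a matrix column (error names the sample)."""
    cols = set(matrix.columns)
    for s in metadata["sample_id"]:
        if s not in cols:
            raise ValueError(f"sample {s!r} in metadata but not in the expression matrix")


def read_mapping(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_symbol"} <= set(df.columns):
        raise ValueError("mapping file needs columns probe_id, gene_symbol")
    return dict(zip(df["probe_id"], df["gene_symbol"]))


def write_mapping(mapping: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(mapping.items()), columns=["probe_id", "gene_symbol"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> PathwayCollection:
    """MSigDB-style GMT: name<TAB>description<TAB>gene...; CRLF and
    trailing tabs tolerated; duplicate pathway names are an error;
    duplicate genes within a set are deduplicated (count logged)."""
    pathways: dict[str, frozenset[str]] = {}
    n_dup_genes = 0
    with open(path, "r", newline="") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            while parts and parts[-1] == "":
                parts.pop()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name, _desc, *genes = parts
            if name in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            gene_set = frozenset(genes)
            n_dup_genes += len(genes) - len(gene_set)
            pathways[name] = gene_set
    if n_dup_genes:
        logger.info("deduplicated %d repeated genes within GMT sets", n_dup_genes)
    return PathwayCollection(pathways, source=str(path))


def write_gmt(pathways: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in pathways.names():
            genes = sorted(pathways.pathways[name])
            fh.write("\t".join([name, pathways.source or "na", *genes]) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    """TSV with an optional leading ``# config_hash=...`` provenance line."""
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_events(events: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(sorted(events.items()), columns=["pair_id", "event_time_weeks"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_events(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str})
    if not {"pair_id", "event_time_weeks"} <= set(df.columns):
        raise ValueError("event table needs columns pair_id, event_time_weeks")
    return dict(zip(df["pair_id"], df["event_time_weeks"].astype(float)))


def write_simulation(sim: SimResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(sim.matrix, outdir / "matrix.tsv")
    sim.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    write_mapping(sim.mapping, outdir / "mapping.tsv")
    write_gmt(sim.pathways, outdir / "pathways.gmt")
    write_events(sim.events, outdir / "events.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(sim.truth.to_dict(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated end-to-end run description, serialised for provenance."""

    seed: int = 0
    mode: str = "tc"  # tc | window | both
    bf_threshold: float = BF_THRESHOLD_DEFAULT
    kl_threshold: float | str = "calibrate"  # number, or "calibrate"
    n_permutations: int = 100_000
    fdr_levels: tuple[float, ...] = (0.1, 0.05)
    n_jobs: int = 1
    sim: SimConfig | None = None  # simulate inputs when no paths given
    matrix_path: str | None = None
    metadata_path: str | None = None
    mapping_path: str | None = None
    gmt_path: str | None = None
    events_path: str | None = None
    window_length: float = 26.0
    resolution: float = 1.0
    priors: HyperPriors = field(default_factory=HyperPriors)
    gp: GPConfig = field(default_factory=GPConfig)

    def validate(self) -> None:
        if self.mode not in ("tc", "window", "both"):
            raise ValueError("mode must be tc, window or both")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if isinstance(self.kl_threshold, str) and self.kl_threshold != "calibrate":
            raise ValueError('kl_threshold must be a number or "calibrate"')
        have_paths = self.matrix_path is not None
        if not have_paths and self.sim is None:
            raise ValueError("either input paths or a simulation config are required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, cls in (("sim", SimConfig), ("priors", HyperPriors), ("gp", GPConfig)):
            if isinstance(raw.get(key), dict):
                raw[key] = cls(**raw[key])
        if isinstance(raw.get("fdr_levels"), list):
            raw["fdr_levels"] = tuple(raw["fdr_levels"])
        return RunConfig(**raw)


def _load_inputs(config: RunConfig):
    if config.matrix_path is not None:
        matrix = read_expression(config.matrix_path)
        metadata = read_metadata(config.metadata_path)
        validate_samples(matrix, metadata)
        mapping = read_mapping(config.mapping_path) if config.mapping_path else None
        pathways = read_gmt(config.gmt_path) if config.gmt_path else None
        events = read_events(config.events_path) if config.events_path else None
        return matrix, metadata, mapping, pathways, events
    sim = simulate(config.sim)
    return sim.matrix, sim.metadata, sim.mapping, sim.pathways, sim.events


def run_pipeline(config: RunConfig, outdir: str | Path, resume: bool = False) -> dict:
    """simulate/load -> score -> calibrate -> enrich -> report.

    Writes score tables, enrichment tables, a machine-readable manifest
    and a human-readable summary under ``outdir``.  Rerunning with an
    identical config reproduces identical score and p-value tables.
    Stage outputs already on disk with a matching config hash are reused
    when ``resume`` is set, so interrupted runs restart cheaply.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    t0 = time.time()
    matrix, metadata, mapping, pathways, events = _load_inputs(config)
    logger.info("inputs ready (%d features, %d samples) in %.1fs", *matrix.shape, time.time() - t0)

    def stage(path: Path, fn):
        if resume and path.exists():
            with open(path) as fh:
                if fh.readline().strip() == f"# config_hash={chash}":
                    logger.info("resuming: reusing %s", path.name)
                    return read_table(path)
        df = fn()
        write_table(df, path, chash)
        rejects = df.attrs.get("rejects", [])
        if rejects:
            rej = pd.DataFrame(rejects, columns=["feature_id", "pair_id", "error"])
            write_table(rej, path.with_name(f"rejects_{path.name}"), chash)
            logger.warning("%d rejected scorings written to rejects_%s", len(rejects), path.name)
        return df

    results: dict = {"config_hash": chash}
    universe = sorted(set(mapping.values())) if mapping else sorted(matrix.index)
    summary_lines = [f"pairgp run {chash} ({config.mode} analysis)"]

    scores_tc = None
    if config.mode in ("tc", "both") or (
        config.mode == "window" and config.kl_threshold == "calibrate"
    ):
        t0 = time.time()
        scores_tc = stage(
            outdir / "scores_tc.tsv",
            lambda: score_dataset_tc(
                matrix, metadata, config.priors, config.gp,
                threshold=config.bf_threshold, n_jobs=config.n_jobs,
            ),
        )
        logger.info("TC scoring done in %.1fs", time.time() - t0)
        results["scores_tc"] = scores_tc

    scores_window = None
    kl_threshold = config.kl_threshold
    if config.mode in ("window", "both"):
        if events is None:
            raise ValueError("window analysis requires an event table")
        t0 = time.time()
        scores_window = stage(
            outdir / "scores_window.tsv",
            lambda: score_dataset_window(
                matrix, metadata, events, config.priors, config.gp,
                window_length=config.window_length, resolution=config.resolution,
                threshold=KL_THRESHOLD_DEFAULT, n_jobs=config.n_jobs,
            ),
        )
        logger.info("window scoring done in %.1fs", time.time() - t0)
        if kl_threshold == "calibrate":
            merged = scores_tc.merge(
                scores_window, on=["feature_id", "pair_id"], suffixes=("_bf", "_kl")
            )
            kl_threshold = calibrate_kl_threshold(
                merged["score_bf"].to_numpy(), merged["score_kl"].to_numpy(),
                bf_threshold=config.bf_threshold,
            )
            summary_lines.append(f"calibrated KL threshold: {kl_threshold:.6g}")
        kl_threshold = float(kl_threshold)
        scores_window = scores_window.assign(is_de=scores_window["score"] > kl_threshold)
        results["scores_window"] = scores_window
        results["kl_threshold"] = kl_threshold

    analyses = []
    if scores_tc is not None and config.mode in ("tc", "both"):
        analyses.append(("tc", "BF", scores_tc, config.bf_threshold))
    if scores_window is not None:
        analyses.append(("window", "KL", scores_window, kl_threshold))

    for label, stype, scores, threshold in analyses:
        genes = collapse_probesets(scores, mapping)
        write_table(genes, outdir / f"gene_scores_{label}.tsv", chash)
        results[f"gene_scores_{label}"] = genes
        if pathways is None:
            continue
        sm = ScoreMatrix.from_scores(scores, stype, threshold)
        # pairs contributing zero DE genes cannot enter the scaled-overlap
        # statistic; drop them from the enrichment (not from scoring)
        has_de = (sm.S > threshold).any(axis=0)
        if not has_de.all():
            dropped = [p for p, k in zip(sm.pair_ids, has_de) if not k]
            logger.warning("%s enrichment: dropping pair(s) with no DE genes: %s", label, dropped)
            summary_lines.append(f"{label}: pairs without DE genes excluded from enrichment: {dropped}")
            if not has_de.any():
                summary_lines.append(f"{label}: no DE genes in any pair; enrichment skipped")
                continue
            sm = ScoreMatrix(
                sm.S[:, has_de],
                sm.feature_ids,
                [p for p, k in zip(sm.pair_ids, has_de) if k],
                sm.score_type,
                sm.de_threshold,
                imputed=sm.imputed[:, has_de],
            )
        t0 = time.time()
        enr = stage(
            outdir / f"enrichment_personalised_{label}.tsv",
            lambda: permutation_test(
                sm, mapping, pathways, n_permutations=config.n_permutations, seed=config.seed
            ),
        )
        logger.info("%s permutation test done in %.1fs", label, time.time() - t0)
        results[f"enrichment_personalised_{label}"] = enr

        # combined baseline on the same inputs
        if label == "tc":
            pooled = pooled_de(
                matrix, metadata, config.priors, config.gp, mode="tc",
                bf_threshold=config.bf_threshold, n_jobs=config.n_jobs,
            )
        else:
            pooled_event = float(np.median(list(events.values())))
            pooled = pooled_de(
                matrix, metadata, config.priors, config.gp, mode="window",
                event_time=pooled_event, window_length=config.window_length,
                resolution=config.resolution, kl_threshold=kl_threshold, n_jobs=config.n_jobs,
            )
        pooled_genes = collapse_probesets(pooled, mapping)
        write_table(pooled_genes, outdir / f"gene_scores_combined_{label}.tsv", chash)
        de_genes = set(pooled_genes.loc[pooled_genes["is_de"], "gene"])
        fisher = fisher_enrichment(de_genes, set(universe), pathways)
        write_table(fisher, outdir / f"enrichment_combined_{label}.tsv", chash)
        results[f"gene_scores_combined_{label}"] = pooled_genes
        results[f"enrichment_combined_{label}"] = fisher

        for level in config.fdr_levels:
            n_pers = int((enr["fdr"] < level).sum())
            n_comb = int((fisher["fdr"] < level).sum())
            summary_lines.append(
                f"{label}: enriched pathways at FDR<{level}: personalised={n_pers} combined={n_comb}"
            )

    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "pairgp_version": __version__,
        "n_features": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    results["summary"] = summary_lines
    return results
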