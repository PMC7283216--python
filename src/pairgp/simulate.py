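"""Synthetic matched case-control time-course expression with planted,
heterogeneous differential expression.

The generator emulates the structure of longitudinal case-control omics
studies: a handful of matched pairs, each individual sampled 3-12 times
at irregular ages (weeks), probe-set level measurements mapping
many-to-one onto genes, and log-scale intensities.  Trajectories are
squared-exponential GP draws observed with iid Gaussian noise.

* Null features: case and control of a pair observe one shared latent
  draw with independent noise.
* DE features: in each pair where the gene is active, the case observes
  a perturbed trajectory — an independent draw, a smooth bump confined to
  a pre-event window, or a sign-flipped copy — through one randomly
  chosen carrier probe-set; the gene's other probe-sets stay null.
* Heterogeneity: each DE gene is active in each pair independently with
  a configurable probability, so different pairs perturb different (and
  differently directed) gene subsets; planted pathways draw their
  members from the DE pool with their own per-pair activation rate.

Identical (config, seed) yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .enrichment import PathwayCollection
from .gp import Hyperparameters, se_kernel

MECHANISMS = ("independent", "bump", "signflip")


@dataclass
class SimConfig:
    """Study-design and signal parameters for one simulated dataset."""

    n_pairs: int = 6
    samples_min: int = 3
    samples_max: int = 12
    time_horizon: float = 104.0  # weeks of follow-up
    n_genes: int = 200
    probesets_min: int = 1
    probesets_max: int = 3
    frac_de_genes: float = 0.15  # background DE genes outside planted pathways
    activation_prob: float = 0.25  # per-pair probability a background DE gene is active
    mechanism: str = "independent"
    bump_amplitude: float = 2.0
    flip_prob: float = 0.5  # bump sign flip between pairs
    lengthscale: float = 30.0
    signal_var: float = 1.0
    noise_sd: float = 0.5  # signal-to-noise signal_var / noise_sd^2 = 4
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    event_frac: float = 0.75  # event time as a fraction of the horizon
    window_length: float = 26.0
    n_random_pathways: int = 20
    pathway_size: int = 30
    n_planted_pathways: int = 1
    planted_size: int = 30
    planted_activation: float = 0.4  # per-pair fraction of planted members active
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_de_genes": self.frac_de_genes,
            "activation_prob": self.activation_prob,
            "planted_activation": self.planted_activation,
            "flip_prob": self.flip_prob,
            "event_frac": self.event_frac,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if self.samples_min < 1 or self.samples_max < self.samples_min:
            raise ValueError("need samples_max >= samples_min >= 1")
        if self.probesets_min < 1 or self.probesets_max < self.probesets_min:
            raise ValueError("need probesets_max >= probesets_min >= 1")
        n_planted_genes = self.n_planted_pathways * self.planted_size
        n_bg = round(self.frac_de_genes * self.n_genes)
        if n_planted_genes + n_bg > self.n_genes:
            raise ValueError(
                f"infeasible config: {n_planted_genes} planted + {n_bg} background DE genes "
                f"exceed n_genes={self.n_genes}"
            )


@dataclass
class SimTruth:
    """Planted structure: what a perfect analysis should recover."""

    de_genes_by_pair: dict[str, list[str]]
    carrier_probeset: dict[str, dict[str, str]]  # pair -> gene -> probe-set
    direction: dict[str, dict[str, int]]  # pair -> gene -> +1/-1 (0: independent draw)
    planted_pathways: list[str]
    de_gene_pool: list[str]
    window_de: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimResult:
    matrix: pd.DataFrame  # probe-sets x samples, log intensities
    metadata: pd.DataFrame  # sample_id, pair_id, group, time_weeks
    mapping: dict[str, str]  # probe-set -> gene
    pathways: PathwayCollection
    truth: SimTruth
    events: dict[str, float]  # pair -> event time (weeks)
    config: SimConfig


def irregular_sampling(lo: float, hi: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sorted, non-uniform sampling times strictly inside (lo, hi)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not hi > lo:
        raise ValueError("need hi > lo")
    return np.sort(rng.uniform(lo, hi, size=n))


def _draw_gp(times: np.ndarray, hp: Hyperparameters, rng: np.random.Generator) -> np.ndarray:
    K = se_kernel(times, times, hp) + 1e-9 * hp.signal_variance * np.eye(times.size)
    L = linalg.cholesky(K, lower=True)
    return L @ rng.standard_normal(times.size)


def _bump(times: np.ndarray, event: float, length: float, amplitude: float) -> np.ndarray:
    centre = event - 0.5 * length
    width = length / 4.0
    return amplitude * np.exp(-0.5 * ((times - centre) / width) ** 2)


def simulate(config: SimConfig) -> SimResult:
    """Generate one dataset (expression, metadata, mapping, pathways, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    hp = Hyperparameters(config.lengthscale, config.signal_var, max(config.noise_sd, 1e-12) ** 2)

    pair_ids = [f"pair{p+1}" for p in range(config.n_pairs)]
    genes = [f"G{g:04d}" for g in range(config.n_genes)]
    event = config.event_frac * config.time_horizon
    events = {p: event for p in pair_ids}

    # planted pathway members first, then background DE genes, all disjoint
    gene_perm = [genes[i] for i in rng.permutation(config.n_genes)]
    planted_names, planted_sets = [], {}
    cursor = 0
    for i in range(config.n_planted_pathways):
        name = f"PLANTED_{i+1}"
        members = sorted(gene_perm[cursor : cursor + config.planted_size])
        cursor += config.planted_size
        planted_names.append(name)
        planted_sets[name] = members
    n_bg = round(config.frac_de_genes * config.n_genes)
    background_de = sorted(gene_perm[cursor : cursor + n_bg])
    de_pool = sorted({g for m in planted_sets.values() for g in m} | set(background_de))

    # per-pair activation and direction of every DE gene
    active: dict[str, set[str]] = {p: set() for p in pair_ids}
    for members in planted_sets.values():
        for g in members:
            for p in pair_ids:
                if rng.uniform() < config.planted_activation:
                    active[p].add(g)
    for g in background_de:
        for p in pair_ids:
            if rng.uniform() < config.activation_prob:
                active[p].add(g)

    # probe-sets
    mapping: dict[str, str] = {}
    probes_of: dict[str, list[str]] = {}
    for g in genes:
        n_ps = int(rng.integers(config.probesets_min, config.probesets_max + 1))
        probes = [f"{g}_at{k+1}" for k in range(n_ps)]
        probes_of[g] = probes
        for pr in probes:
            mapping[pr] = g
    all_probes = [pr for g in genes for pr in probes_of[g]]

    # sampling design
    meta_rows = []
    times_of: dict[tuple[str, str], np.ndarray] = {}
    for p in pair_ids:
        for group in ("case", "control"):
            n = int(rng.integers(config.samples_min, config.samples_max + 1))
            t = irregular_sampling(0.0, config.time_horizon, n, rng)
            times_of[(p, group)] = t
            for i, ti in enumerate(t):
                meta_rows.append((f"{p}_{group}_{i:02d}", p, group, ti))
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "pair_id", "group", "time_weeks"])

    # carrier probe-set per (pair, active gene); directions
    carrier: dict[str, dict[str, str]] = {p: {} for p in pair_ids}
    direction: dict[str, dict[str, int]] = {p: {} for p in pair_ids}
    for p in pair_ids:
        for g in sorted(active[p]):
            carrier[p][g] = probes_of[g][int(rng.integers(len(probes_of[g])))]
            if config.mechanism == "independent":
                direction[p][g] = 0
            elif config.mechanism == "signflip":
                direction[p][g] = -1
            else:
                direction[p][g] = -1 if rng.uniform() < config.flip_prob else 1

    # expression draws: loop probes x pairs in fixed order for determinism
    sample_ids = metadata["sample_id"].tolist()
    col_of = {s: i for i, s in enumerate(sample_ids)}
    X = np.zeros((len(all_probes), len(sample_ids)))
    for r, pr in enumerate(all_probes):
        g = mapping[pr]
        baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal()
        for p in pair_ids:
            t_case = times_of[(p, "case")]
            t_ctrl = times_of[(p, "control")]
            t_all = np.concatenate([t_case, t_ctrl])
            shared = _draw_gp(t_all, hp, rng)
            f_case = shared[: t_case.size].copy()
            f_ctrl = shared[t_case.size :]
            if g in active[p] and carrier[p][g] == pr:
                d = direction[p][g]
                if config.mechanism == "independent":
                    f_case = _draw_gp(t_case, hp, rng)
                elif config.mechanism == "signflip":
                    f_case = -f_case
                else:  # bump confined to the pre-event window
                    f_case = f_case + d * _bump(t_case, event, config.window_length, config.bump_amplitude)
            vals = np.concatenate([f_case, f_ctrl]) + config.noise_sd * rng.standard_normal(t_all.size)
            vals += baseline
            for (group, tvec, sub) in (
                ("case", t_case, vals[: t_case.size]),
                ("control", t_ctrl, vals[t_case.size :]),
            ):
                for i in range(tvec.size):
                    X[r, col_of[f"{p}_{group}_{i:02d}"]] = sub[i]

    matrix = pd.DataFrame(X, index=pd.Index(all_probes, name="feature_id"), columns=sample_ids)

    # pathways: planted + size-matched random sets over the whole gene universe
    pathway_dict: dict[str, frozenset[str]] = {
        name: frozenset(members) for name, members in planted_sets.items()
    }
    for i in range(config.n_random_pathways):
        members = rng.choice(config.n_genes, size=min(config.pathway_size, config.n_genes), replace=False)
        pathway_dict[f"RANDOM_{i+1:03d}"] = frozenset(genes[j] for j in sorted(members))
    pathways = PathwayCollection(pathway_dict, source="synthetic")

    truth = SimTruth(
        de_genes_by_pair={p: sorted(active[p]) for p in pair_ids},
        carrier_probeset=carrier,
        direction=direction,
        planted_pathways=planted_names,
        de_gene_pool=de_pool,
        window_de=(config.mechanism == "bump"),
    )
    return SimResult(matrix, metadata, mapping, pathways, truth, events, config)
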