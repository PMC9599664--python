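"""Synthetic source/sink panels with the structure of real community mixtures.

A panel consists of M candidate sources plus one hidden unknown source,
each a community subsampled to a fixed read depth; sinks are multinomial
draws from sparse convex combinations of K contributing sources and the
unknown. Mixing vectors are Pareto-distributed (heavy-tailed, a few
dominant contributors), scaled so the known mass plus a configurable
unknown proportion equals 1.

When no real count table is supplied, base communities use seeded
log-normal abundance weights, emulating the skewed rank-abundance
structure of real microbiomes. Nuisance sources can also be manufactured
by shuffling observed abundances: each synthetic source gets a uniformly
drawn richness between the real sources' min and max nonzero-taxon counts,
its taxa chosen uniformly, and its counts drawn without replacement from
the pool of all real nonzero counts.

All randomness flows through one seeded generator, so a dataset is fully
reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import json

import numpy as np

from .io import (
    CountTable,
    SampleMetadata,
    SourceSinkProblem,
    write_count_table,
    write_metadata,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "draw_source_profiles",
    "draw_mixing_proportions",
    "generate_sink",
    "generate_nuisance_sources",
    "build_dataset",
    "export_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Panel design: M candidates, K contributing, depths and unknown mass.

    Defaults reproduce the benchmark design: 50 candidates, 10 contributing,
    both sources and sinks at 10,000 reads, 30 sinks, Pareto shape 1.0
    (heavy tail: a few dominant contributors), 500 taxa.
    """

    n_taxa: int = 500
    n_candidates: int = 50
    n_contributing: int = 10
    source_depth: int = 10_000
    sink_depth: int = 10_000
    unknown_prop: float = 0.0
    pareto_shape: float = 1.0
    n_sinks: int = 30
    seed: int = 0
    lognormal_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.n_contributing > self.n_candidates:
            raise ValueError("K (contributing) must not exceed M (candidates)")
        if not (0.0 <= self.unknown_prop < 1.0):
            raise ValueError("unknown_prop must lie in [0, 1)")
        if self.source_depth <= 0 or self.sink_depth <= 0:
            raise ValueError("depths must be positive")
        if self.n_taxa < 2 or self.n_sinks < 1:
            raise ValueError("need at least 2 taxa and 1 sink")


@dataclass
class SimulatedDataset:
    """Panel ground truth: per-sink problems over shared candidate sources.

    ``true_alphas`` is n_sinks x (M+1); the last column is the unknown
    proportion. Exactly K entries among the first M are positive per sink,
    at the shared ``contributing_ids``. The hidden unknown source's counts
    are withheld from every problem.
    """

    problems: list[SourceSinkProblem]
    true_alphas: np.ndarray
    contributing_ids: list[str]
    config: SimulationConfig
    unknown_counts: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        sums = self.true_alphas.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("true mixing vectors must sum to 1")


def draw_source_profiles(
    config: SimulationConfig,
    base_sources: CountTable | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw M+1 source count vectors at exactly ``source_depth`` reads each.

    From a real table, each source is subsampled without replacement
    (multivariate hypergeometric); otherwise each community's latent
    profile has independent log-normal taxon weights, normalized, and reads
    are a multinomial draw. The last row is the hidden unknown source.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m_total = config.n_candidates + 1
    if base_sources is not None:
        totals = base_sources.sample_totals()
        if np.any(totals < config.source_depth):
            short = [
                s
                for s, t in zip(base_sources.sample_ids, totals)
                if t < config.source_depth
            ]
            raise ValueError(
                f"samples {short} have fewer than {config.source_depth} reads"
            )
        if base_sources.n_samples < m_total:
            raise ValueError(f"need at least {m_total} base samples")
        pick = rng.choice(base_sources.n_samples, size=m_total, replace=False)
        return np.stack(
            [
                rng.multivariate_hypergeometric(
                    base_sources.counts[:, j], config.source_depth
                )
                for j in pick
            ]
        )
    weights = rng.lognormal(
        mean=0.0, sigma=config.lognormal_sigma, size=(m_total, config.n_taxa)
    )
    profiles = weights / weights.sum(axis=1, keepdims=True)
    return np.stack(
        [rng.multinomial(config.source_depth, p) for p in profiles]
    )


def draw_mixing_proportions(
    k: int,
    unknown_prop: float,
    pareto_shape: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """K Pareto draws scaled to sum to 1 - unknown_prop, unknown appended.

    Draws use the Pareto II (Lomax) form so a handful of sources dominate
    the mixture, matching the sparse-contribution structure of real
    community assembly.
    """
    if k < 1:
        raise ValueError("need at least one contributing source")
    draws = rng.pareto(pareto_shape, size=k)
    while draws.sum() == 0:  # vanishingly rare; resample for a valid mixture
        draws = rng.pareto(pareto_shape, size=k)
    known = draws / draws.sum() * (1.0 - unknown_prop)
    return np.concatenate([known, [unknown_prop]])


def generate_sink(
    profiles: np.ndarray,
    alpha: np.ndarray,
    sink_depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One multinomial draw of sink_depth reads from beta = alpha^T profiles."""
    profiles = np.asarray(profiles, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = alpha @ profiles
    beta = beta / beta.sum()
    return rng.multinomial(sink_depth, beta)


def generate_nuisance_sources(
    real_sources: CountTable,
    n_nuisance: int,
    rng: np.random.Generator,
) -> CountTable:
    """Shuffled-abundance nuisance sources with realistic richness and counts.

    For each synthetic source: richness T ~ uniform integer between the real
    sources' min and max nonzero-taxon counts; T taxa chosen uniformly
    without replacement; each assigned a count drawn without replacement
    (per synthetic source) from the pooled nonzero counts of all real
    sources.
    """
    counts = real_sources.counts
    richness = (counts > 0).sum(axis=0)
    t_lo, t_hi = int(richness.min()), int(richness.max())
    pool = counts[counts > 0].astype(np.int64)
    if t_hi > pool.size:
        raise ValueError(
            "nonzero-count pool smaller than the largest possible richness; "
            "supply more real sources"
        )
    out = np.zeros((real_sources.n_taxa, n_nuisance), dtype=np.int64)
    for i in range(n_nuisance):
        t_i = int(rng.integers(t_lo, t_hi + 1))
        taxa = rng.choice(real_sources.n_taxa, size=t_i, replace=False)
        out[taxa, i] = rng.choice(pool, size=t_i, replace=False)
    return CountTable(
        taxa_ids=list(real_sources.taxa_ids),
        sample_ids=[f"nuisance_{i + 1:03d}" for i in range(n_nuisance)],
        counts=out,
    )


def build_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Compose a full panel: sources, contributing set, sinks, ground truth.

    One hidden unknown source is drawn alongside the M candidates and
    withheld from the problems. The K contributing candidates are fixed for
    the panel; each sink gets a freshly drawn Pareto mixing vector over them
    plus the configured unknown proportion.
    """
    rng = np.random.default_rng(config.seed)
    m, k = config.n_candidates, config.n_contributing
    source_counts = draw_source_profiles(config, rng=rng)  # (M+1) x N
    candidates, unknown_counts = source_counts[:m], source_counts[m]
    contributing = np.sort(rng.choice(m, size=k, replace=False))
    taxon_ids = [f"T{j + 1:04d}" for j in range(source_counts.shape[1])]
    source_ids = [f"S{i + 1:03d}" for i in range(m)]

    cand_profiles = candidates / candidates.sum(axis=1, keepdims=True)
    unk_profile = unknown_counts / unknown_counts.sum()
    problems: list[SourceSinkProblem] = []
    true_alphas = np.zeros((config.n_sinks, m + 1))
    for s in range(config.n_sinks):
        mix = draw_mixing_proportions(
            k, config.unknown_prop, config.pareto_shape, rng
        )
        stack = np.vstack([cand_profiles[contributing], unk_profile])
        sink = generate_sink(stack, mix, config.sink_depth, rng)
        true_alphas[s, contributing] = mix[:k]
        true_alphas[s, m] = mix[k]
        problems.append(
            SourceSinkProblem(
                sink=sink,
                sources=candidates,
                taxon_ids=taxon_ids,
                source_ids=source_ids,
                sink_id=f"sink_{s + 1:03d}",
            )
        )
    return SimulatedDataset(
        problems=problems,
        true_alphas=true_alphas,
        contributing_ids=[source_ids[i] for i in contributing],
        config=config,
        unknown_counts=unknown_counts,
    )


def export_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write counts, metadata, truth TSVs and a config JSON echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    first = dataset.problems[0]
    sink_mat = np.stack([p.sink for p in dataset.problems], axis=1)
    counts = np.concatenate([first.sources.T, sink_mat], axis=1)
    sample_ids = list(first.source_ids) + [p.sink_id for p in dataset.problems]
    table = CountTable(
        taxa_ids=list(first.taxon_ids), sample_ids=sample_ids, counts=counts
    )
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
        "config": out / "config.json",
    }
    write_count_table(table, paths["counts"])
    meta = [
        SampleMetadata(sample_id=s, env_label=f"env_{s}", role="Source")
        for s in first.source_ids
    ] + [
        SampleMetadata(sample_id=p.sink_id, env_label="sink", role="Sink")
        for p in dataset.problems
    ]
    write_metadata(meta, paths["metadata"])
    lines = ["SinkID\tSampleID\tproportion"]
    for p, alpha in zip(dataset.problems, dataset.true_alphas):
        for sid, a in zip(list(first.source_ids) + ["Unknown"], alpha):
            lines.append(f"{p.sink_id}\t{sid}\t{a:.6f}")
    paths["truth"].write_text("\n".join(lines) + "\n")
    paths["config"].write_text(json.dumps(asdict(cfg), indent=2) + "\n")
    return paths
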