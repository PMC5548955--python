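"""Synthetic paired IP/Input TRAP-seq count data with planted ground truth.

The generator emulates the study design the analysis assumes: P littermate
pairs (default six), each contributing a WT and a KO animal, each animal an
Input (total RNA) and an IP (ribosome-bound) library — 24 samples at the
default. Counts are negative binomial with

    mean  = baseline_g * size_factor_j * pair_effect_{pair(j)}
            * ip_enrichment_g^[fraction=IP] * 2^(lfc_{g,fraction} * [KO])
    var   = mean + alpha_g * mean^2

where alpha_g follows the trend a1/baseline + a0 with log-normal gene
noise. Three gene sets are planted: an up-set and a down-set with IP-only
genotype effects (log2 ~ +1 and -1), mirroring genes whose translation but
not transcription changes, and a larger "target" set with a small negative
shift (log2 ~ -0.2) applied in BOTH fractions, mirroring a transcript
population that is mildly depleted everywhere. Clan annotations are drawn
at random, with a configurable number of clans overrepresented in the
up-set so clan-enrichment recovery is testable.

Planted sets are drawn from robustly expressed genes (baseline above a
configurable floor), since the phenomena they emulate concern genes inside
the analyzed abundance range. All randomness flows from the single config
seed through named child streams, so outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import (
    ClanMap,
    CountMatrix,
    GeneSet,
    SampleSheet,
    write_clan_map,
    write_counts,
    write_gmt,
    write_lengths,
    write_sample_sheet,
)

UP_SET = "planted_up"
DOWN_SET = "planted_down"
TARGET_SET = "targets"


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; defaults reproduce the study design."""

    n_pairs: int = 6
    n_genes: int = 15000
    seed: int = 0

    # expression structure (natural-log scale unless noted)
    baseline_log_mean: float = math.log(1000.0)
    baseline_log_sd: float = 1.2
    ip_enrichment_log_sd: float = 0.7
    library_size_log_sd: float = 0.15
    pair_effect_log_sd: float = 0.1

    # dispersion trend alpha(mu) = a1/mu + a0, log-normal gene noise
    dispersion_a0: float = 0.01
    dispersion_a1: float = 2.0
    dispersion_log_noise_sd: float = 0.3

    # planted IP-only genotype effects (log2 scale)
    n_up: int = 90
    up_log2_mean: float = 1.0
    up_log2_sd: float = 0.1
    n_down: int = 31
    down_log2_mean: float = -1.0
    down_log2_sd: float = 0.1

    # planted target-set shift, applied in both fractions (log2 scale)
    target_size: int = 800
    target_log2_mean: float = -0.2
    target_log2_sd: float = 0.05

    # clan annotation
    n_clans: int = 40
    n_enriched_clans: int = 2
    clan_coverage: float = 0.6
    second_clan_prob: float = 0.1
    enriched_clan_fraction: float = 0.3

    # gene effective lengths (log-normal around 2 kb)
    length_log_mean: float = math.log(2000.0)
    length_log_sd: float = 0.5

    # planted sets are drawn from genes with baseline >= 10^this
    min_planted_log10_mean: float = 2.0

    def __post_init__(self) -> None:
        sds = (
            self.baseline_log_sd,
            self.ip_enrichment_log_sd,
            self.library_size_log_sd,
            self.pair_effect_log_sd,
            self.dispersion_log_noise_sd,
            self.up_log2_sd,
            self.down_log2_sd,
            self.target_log2_sd,
            self.length_log_sd,
        )
        if any(sd < 0 for sd in sds):
            raise ConfigError("standard deviations must be non-negative")
        if self.n_pairs < 1 or self.n_genes < 1:
            raise ConfigError("n_pairs and n_genes must be positive")
        if self.n_up + self.n_down + self.target_size > self.n_genes:
            raise ConfigError("planted set sizes exceed n_genes")
        if self.n_enriched_clans > self.n_clans:
            raise ConfigError("n_enriched_clans exceeds n_clans")


@dataclass
class SimTruth:
    """Planted per-gene parameters and memberships, plus per-sample truth."""

    genes: pd.DataFrame
    size_factors: pd.Series
    enriched_clans: list[str]

    @property
    def up_genes(self) -> frozenset[str]:
        return frozenset(self.genes.index[self.genes["in_up"]])

    @property
    def down_genes(self) -> frozenset[str]:
        return frozenset(self.genes.index[self.genes["in_down"]])

    @property
    def target_genes(self) -> frozenset[str]:
        return frozenset(self.genes.index[self.genes["in_target"]])


@dataclass
class SimOutput:
    counts: CountMatrix
    samples: SampleSheet
    lengths: pd.Series
    clan_map: ClanMap
    gene_sets: list[GeneSet]
    truth: SimTruth


def null_config(config: SimConfig) -> SimConfig:
    """The same design with every planted effect removed (global null)."""
    return dataclasses.replace(
        config,
        n_up=0,
        up_log2_mean=0.0,
        up_log2_sd=0.0,
        n_down=0,
        down_log2_mean=0.0,
        down_log2_sd=0.0,
        target_size=0,
        target_log2_mean=0.0,
        target_log2_sd=0.0,
    )


def sample_nb(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Draw NB counts with mean mu and variance mu + alpha*mu^2 (Poisson at alpha~0)."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = alpha < 1e-10
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    if (~tiny).any():
        size = 1.0 / alpha[~tiny]
        p = size / (size + mu[~tiny])
        out[~tiny] = rng.negative_binomial(size, p)
    return out


def _sample_grid(config: SimConfig) -> pd.DataFrame:
    rows = []
    for pair in range(1, config.n_pairs + 1):
        for genotype in ("WT", "KO"):
            for fraction in ("Input", "IP"):
                rows.append(
                    {
                        "sample_id": f"P{pair}_{genotype}_{fraction}",
                        "fraction": fraction,
                        "genotype": genotype,
                        "pair_id": pair,
                        "animal_id": f"P{pair}_{genotype}",
                    }
                )
    return pd.DataFrame(rows)


def generate(config: SimConfig) -> SimOutput:
    """Draw one complete simulated experiment plus its ground truth."""
    root = np.random.SeedSequence(config.seed)
    (
        seq_genes,
        seq_sets,
        seq_clans,
        seq_samples,
        seq_counts,
        seq_lengths,
    ) = root.spawn(6)
    rng_genes = np.random.default_rng(seq_genes)
    rng_sets = np.random.default_rng(seq_sets)
    rng_clans = np.random.default_rng(seq_clans)
    rng_samples = np.random.default_rng(seq_samples)
    rng_counts = np.random.default_rng(seq_counts)
    rng_lengths = np.random.default_rng(seq_lengths)

    g = config.n_genes
    width = max(5, len(str(g)))
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(1, g + 1)])

    baseline = np.exp(rng_genes.normal(config.baseline_log_mean, config.baseline_log_sd, g))
    ip_enrichment = np.exp(rng_genes.normal(0.0, config.ip_enrichment_log_sd, g))
    alpha = (config.dispersion_a1 / baseline + config.dispersion_a0) * np.exp(
        rng_genes.normal(0.0, config.dispersion_log_noise_sd, g)
    )

    # planted sets, disjoint, drawn from robustly expressed genes
    n_planted = config.n_up + config.n_down + config.target_size
    eligible = np.where(baseline >= 10.0**config.min_planted_log10_mean)[0]
    if n_planted > eligible.size:
        raise ConfigError(
            f"planted sets need {n_planted} genes above the baseline floor, "
            f"only {eligible.size} available"
        )
    picked = rng_sets.choice(eligible, size=n_planted, replace=False)
    up_idx = picked[: config.n_up]
    down_idx = picked[config.n_up : config.n_up + config.n_down]
    target_idx = picked[config.n_up + config.n_down :]

    lfc_ip = np.zeros(g)
    lfc_input = np.zeros(g)
    if config.n_up:
        lfc_ip[up_idx] = rng_sets.normal(config.up_log2_mean, config.up_log2_sd, config.n_up)
    if config.n_down:
        lfc_ip[down_idx] = rng_sets.normal(
            config.down_log2_mean, config.down_log2_sd, config.n_down
        )
    if config.target_size:
        shift = rng_sets.normal(config.target_log2_mean, config.target_log2_sd, config.target_size)
        lfc_ip[target_idx] += shift
        lfc_input[target_idx] += shift

    # clan annotation
    clan_ids = [f"CL{i:04d}" for i in range(1, config.n_clans + 1)]
    mapping: dict[str, set[str]] = {}
    if config.n_clans:
        has_clan = rng_clans.random(g) < config.clan_coverage
        first = rng_clans.integers(0, config.n_clans, g)
        second_draw = rng_clans.random(g) < config.second_clan_prob
        second = rng_clans.integers(0, config.n_clans, g)
        for i in np.where(has_clan)[0]:
            clans = {clan_ids[first[i]]}
            if second_draw[i]:
                clans.add(clan_ids[second[i]])
            mapping[gene_ids[i]] = clans
    enriched_clans = clan_ids[: config.n_enriched_clans]
    if config.n_up:
        n_extra = int(round(config.enriched_clan_fraction * config.n_up))
        for clan in enriched_clans:
            extra = rng_clans.choice(up_idx, size=min(n_extra, up_idx.size), replace=False)
            for i in extra:
                mapping.setdefault(gene_ids[i], set()).add(clan)
    clan_map = ClanMap({k: frozenset(v) for k, v in mapping.items()})

    # samples
    grid = _sample_grid(config)
    n_samples = len(grid)
    size = np.exp(rng_samples.normal(0.0, config.library_size_log_sd, n_samples))
    pair_mult = np.exp(rng_samples.normal(0.0, config.pair_effect_log_sd, config.n_pairs))

    is_ip = (grid["fraction"] == "IP").to_numpy()
    is_ko = (grid["genotype"] == "KO").to_numpy()
    pair_of = grid["pair_id"].to_numpy() - 1

    mu = baseline[:, None] * (size * pair_mult[pair_of])[None, :]
    mu = mu * np.where(is_ip[None, :], ip_enrichment[:, None], 1.0)
    lfc = np.where(is_ip[None, :], lfc_ip[:, None], lfc_input[:, None])
    mu = mu * np.exp2(lfc * is_ko[None, :])

    counts = sample_nb(rng_counts, mu, alpha[:, None])
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=grid["sample_id"].to_list()))
    sheet = SampleSheet(grid)

    lengths = pd.Series(
        np.exp(rng_lengths.normal(config.length_log_mean, config.length_log_sd, g)).round(1),
        index=gene_ids,
        name="length",
    )

    in_up = np.zeros(g, dtype=bool)
    in_up[up_idx] = True
    in_down = np.zeros(g, dtype=bool)
    in_down[down_idx] = True
    in_target = np.zeros(g, dtype=bool)
    in_target[target_idx] = True
    truth_genes = pd.DataFrame(
        {
            "baseline_mean": baseline,
            "ip_enrichment": ip_enrichment,
            "true_log2fc_ip": lfc_ip,
            "true_log2fc_input": lfc_input,
            "dispersion": alpha,
            "in_up": in_up,
            "in_down": in_down,
            "in_target": in_target,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = SimTruth(
        genes=truth_genes,
        size_factors=pd.Series(size, index=grid["sample_id"].to_list(), name="size_factor"),
        enriched_clans=list(enriched_clans),
    )

    gene_sets = []
    for name, idx in ((UP_SET, up_idx), (DOWN_SET, down_idx), (TARGET_SET, target_idx)):
        if idx.size:
            gene_sets.append(
                GeneSet(name=name, description="simulated", genes=frozenset(gene_ids[idx]))
            )
    return SimOutput(
        counts=cm,
        samples=sheet,
        lengths=lengths,
        clan_map=clan_map,
        gene_sets=gene_sets,
        truth=truth,
    )


def write_simulation(sim: SimOutput, out_dir) -> dict[str, Path]:
    """Write counts.tsv, samples.tsv, lengths.tsv, clans.tsv, sets.gmt, truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "lengths": out / "lengths.tsv",
        "clans": out / "clans.tsv",
        "sets": out / "sets.gmt",
        "truth": out / "truth.tsv",
    }
    write_counts(sim.counts, paths["counts"])
    write_sample_sheet(sim.samples, paths["samples"])
    write_lengths(sim.lengths, paths["lengths"])
    write_clan_map(sim.clan_map, paths["clans"])
    write_gmt(sim.gene_sets, paths["sets"])
    sim.truth.genes.to_csv(paths["truth"], sep="\t")
    return paths
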