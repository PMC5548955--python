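"""End-to-end orchestration: simulate (or load) -> normalize -> DE -> shift
-> clan enrichment -> report.

A run is fully described by a ``RunConfig`` (YAML on disk). All randomness
flows from the single run seed: per-stage sub-seeds are derived with
``numpy.random.SeedSequence(seed).spawn``, in a fixed order, so any stage
can be re-run independently and the whole run is reproducible bit-for-bit
for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .differential_translation import DEConfig, DEResult, run_de
from .errors import ConfigError
from .io_formats import (
    read_clan_map,
    read_counts,
    read_gmt,
    read_lengths,
    read_sample_sheet,
    write_results,
)
from .quantification import size_factors, tpm
from .set_enrichment import (
    adjust_target_list,
    clan_enrichment,
    expressed_background,
    overlap_report,
)
from .synthetic_data import SimConfig, TARGET_SET, generate, write_simulation
from .target_shift import WINDOW_EXPONENTS, AnalysisConfig, shift_test

logger = logging.getLogger(__name__)

_TOP_KEYS = {
    "seed",
    "out_dir",
    "fdr",
    "clan_alpha",
    "n_random_sets",
    "windows",
    "design",
    "min_base_mean",
    "simulate",
    "counts",
    "samples",
    "lengths",
    "clans",
    "sets",
    "target_set",
    "log_level",
}


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "trapshift_run"
    fdr: float = 0.1
    clan_alpha: float = 0.01
    n_random_sets: int = 5
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(WINDOW_EXPONENTS)
    )
    design: str = "paired"
    min_base_mean: float = 0.5
    simulate: SimConfig | None = None
    counts: str | None = None
    samples: str | None = None
    lengths: str | None = None
    clans: str | None = None
    sets: str | None = None
    target_set: str = TARGET_SET
    log_level: str = "INFO"

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            windows=dict(self.windows),
            n_random_sets=self.n_random_sets,
            seed=self.seed,
            fdr=self.fdr,
            clan_alpha=self.clan_alpha,
        )

    def config_hash(self) -> str:
        """Hash of the scientific configuration (excludes out_dir / log level)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _parse_window(value) -> tuple[float, float]:
    if isinstance(value, str):
        lo, hi = value.split(":")
        return float(lo), float(hi)
    lo, hi = value
    return float(lo), float(hi)


def validate_config(path) -> RunConfig:
    """Load a YAML run config, fill defaults, reject unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a YAML mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig()
    for key in ("seed", "out_dir", "fdr", "clan_alpha", "n_random_sets", "design",
                "min_base_mean", "counts", "samples", "lengths", "clans", "sets",
                "target_set", "log_level"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "windows" in raw:
        windows = dict(cfg.windows)
        for fraction, value in raw["windows"].items():
            if fraction not in windows:
                raise ConfigError(f"unknown fraction {fraction!r} in windows")
            windows[fraction] = _parse_window(value)
        cfg.windows = windows
    if "simulate" in raw:
        sim_raw = raw["simulate"] or {}
        known = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(sim_raw) - known
        if unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
        cfg.simulate = SimConfig(**sim_raw)
    if cfg.simulate is None:
        required = ("counts", "samples", "lengths")
        missing = [k for k in required if getattr(cfg, k) is None]
        if missing:
            raise ConfigError(
                f"config must either set 'simulate' or provide input paths: missing {missing}"
            )
        for key in ("counts", "samples", "lengths", "clans", "sets"):
            value = getattr(cfg, key)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{key} file does not exist: {value}")
    return cfg


@dataclass
class RunReport:
    """Digest of one full run, also written as report.json."""

    version: str
    seed: int
    config_hash: str
    n_genes: int
    n_tested: dict[str, int]
    n_significant: dict[str, int]
    shift: dict[str, dict]
    enriched_clans_de: list[str]
    enriched_clans_targets: list[str]
    overlap: str

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage in order, writing intermediates under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_root = np.random.SeedSequence(config.seed)
    sim_seed, shift_seed = (int(s.generate_state(1)[0] % (2**31)) for s in seed_root.spawn(2))

    stage = "inputs"
    try:
        if config.simulate is not None:
            stage = "simulate"
            sim_cfg = dataclasses.replace(config.simulate, seed=sim_seed)
            sim = generate(sim_cfg)
            write_simulation(sim, out / "sim")
            counts, samples = sim.counts, sim.samples
            lengths, clan_map = sim.lengths, sim.clan_map
            gene_sets = {gs.name: gs for gs in sim.gene_sets}
        else:
            samples = read_sample_sheet(config.samples)
            counts = read_counts(config.counts, samples)
            lengths = read_lengths(config.lengths)
            clan_map = read_clan_map(config.clans) if config.clans else None
            gene_sets = (
                {gs.name: gs for gs in read_gmt(config.sets)} if config.sets else {}
            )

        stage = "normalize"
        tpm_table = tpm(counts, lengths)
        write_results(tpm_table.round(3), out / "tpm.tsv")
        sf = size_factors(counts)
        sf.to_csv(out / "size_factors.tsv", sep="\t")

        stage = "differential expression"
        de_cfg = DEConfig(fdr=config.fdr, design=config.design, min_base_mean=config.min_base_mean)
        de: dict[str, DEResult] = {}
        for fraction in ("IP", "Input"):
            de[fraction] = run_de(counts, samples, fraction=fraction, config=de_cfg)
            write_results(de[fraction].table, out / f"de_{fraction.lower()}.tsv")

        stage = "target shift"
        shift_digest: dict[str, dict] = {}
        target = gene_sets.get(config.target_set)
        if target is not None:
            for fraction in ("IP", "Input"):
                result = shift_test(
                    de[fraction].table,
                    target.genes,
                    window=config.windows[fraction],
                    n_random_sets=config.n_random_sets,
                    seed=shift_seed,
                )
                shift_digest[fraction] = result.as_dict()
            with open(out / "shift.json", "w") as fh:
                json.dump(shift_digest, fh, indent=2)
        else:
            logger.warning("no target set %r available; shift stage skipped", config.target_set)

        stage = "clan enrichment"
        enriched_de: list[str] = []
        enriched_targets: list[str] = []
        overlap_summary = "0 out of 0"
        if clan_map is not None and len(clan_map):
            background = expressed_background(tpm_table)
            sig_ip = set(de["IP"].significant) & background
            table_de = None
            if sig_ip:
                table_de = clan_enrichment(sig_ip, background, clan_map, alpha=config.clan_alpha)
                write_results(table_de, out / "enrichment_de.tsv", index_label="clan")
                enriched_de = list(table_de.index[table_de["enriched"]])
            if target is not None:
                ip_samples = samples.subset(fraction="IP").sample_ids
                adjusted = adjust_target_list(target, tpm_table, ip_samples)
                if adjusted is not None:
                    genes = frozenset(adjusted.genes) & background
                    if genes:
                        table_t = clan_enrichment(
                            genes, background, clan_map, alpha=config.clan_alpha
                        )
                        write_results(table_t, out / "enrichment_targets.tsv", index_label="clan")
                        enriched_targets = list(table_t.index[table_t["enriched"]])
                        if table_de is not None:
                            overlap_summary = overlap_report(table_de, table_t).summary

        stage = "report"
        report = RunReport(
            version=__version__,
            seed=config.seed,
            config_hash=config.config_hash(),
            n_genes=counts.shape[0],
            n_tested={f: int(de[f].table["tested"].sum()) for f in de},
            n_significant={f: int(len(de[f].significant)) for f in de},
            shift=shift_digest,
            enriched_clans_de=sorted(enriched_de),
            enriched_clans_targets=sorted(enriched_targets),
            overlap=overlap_summary,
        )
        with open(out / "report.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=2)
        return report
    except Exception as exc:
        from .errors import TrapshiftError

        if isinstance(exc, TrapshiftError):
            raise type(exc)(f"[stage: {stage}] {exc}") from exc
        raise TrapshiftError(f"[stage: {stage}] {exc!r}") from exc
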