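"""Abundance-matched distribution-shift testing for a target gene set.

The question: within a window of comparable expression (baseMean between
10^lo and 10^hi), is the log2 fold-change distribution of a target set
(e.g. FMRP-bound mRNAs) shifted relative to all window genes? The shift is
measured by the two-sample Kolmogorov-Smirnov statistic on the empirical
CDFs, with an asymptotic p-value; a resampling null re-runs the comparison
on random gene sets of the same size drawn from the window, and a Fisher
test compares the up/down split of targets against non-targets.

The default abundance windows are fraction-specific: Input uses exponents
(2.5, 4.25) and IP uses (2.75, 4.75), both closed intervals on baseMean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contingency_stats import fisher_exact
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: default abundance-window exponents (log10 of baseMean) per fraction
WINDOW_EXPONENTS: dict[str, tuple[float, float]] = {
    "Input": (2.5, 4.25),
    "IP": (2.75, 4.75),
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the shift and enrichment analyses.

    windows: per-fraction (lo, hi) exponents of the closed baseMean window.
    n_random_sets: size of the resampling null (random same-size gene sets).
    fdr: significance threshold on BH-adjusted DE p-values.
    clan_alpha: fixed per-clan Fisher threshold for enrichment.
    """

    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(WINDOW_EXPONENTS)
    )
    n_random_sets: int = 5
    seed: int = 0
    fdr: float = 0.1
    clan_alpha: float = 0.01

    def __post_init__(self) -> None:
        for fraction, (lo, hi) in self.windows.items():
            if not lo < hi:
                raise ValidationError(f"window for {fraction}: need lo < hi, got ({lo}, {hi})")
        if self.n_random_sets < 1:
            raise ValidationError("n_random_sets must be >= 1")


@dataclass
class ShiftResult:
    n_target: int
    n_background: int
    ks_statistic: float
    ks_p: float
    median_target_lfc: float
    median_background_lfc: float
    n_target_up: int
    n_target_down: int
    n_other_up: int
    n_other_down: int
    updown_fisher_p: float
    random_sets: list[tuple[float, float]] = field(default_factory=list)
    random_set_seed: int | None = None
    #: set when fewer than 10 target genes fall in the window
    few_targets: bool = False

    def as_dict(self) -> dict:
        return {
            "n_target": self.n_target,
            "n_background": self.n_background,
            "ks_statistic": self.ks_statistic,
            "ks_p": self.ks_p,
            "median_target_lfc": self.median_target_lfc,
            "median_background_lfc": self.median_background_lfc,
            "n_target_up": self.n_target_up,
            "n_target_down": self.n_target_down,
            "n_other_up": self.n_other_up,
            "n_other_down": self.n_other_down,
            "updown_fisher_p": self.updown_fisher_p,
            "random_sets": [list(t) for t in self.random_sets],
            "few_targets": self.few_targets,
        }


def abundance_window(de_table: pd.DataFrame, lo: float, hi: float) -> pd.Index:
    """Genes whose baseMean lies in the closed interval [10^lo, 10^hi].

    Only tested genes with a finite log2 fold change are eligible, since the
    shift test operates on their fold changes.
    """
    if "baseMean" not in de_table.columns:
        raise ValidationError("DE table lacks a baseMean column")
    base = de_table["baseMean"]
    lfc = de_table.get("log2FoldChange")
    ok = base.notna() & (base >= 10.0**lo) & (base <= 10.0**hi)
    if lfc is not None:
        ok &= lfc.notna()
    genes = de_table.index[ok]
    if len(genes) == 0:
        logger.warning("abundance window [10^%g, 10^%g] contains no genes", lo, hi)
    return genes


def _ecdf_sup_distance(x: np.ndarray, y: np.ndarray) -> float:
    """sup over pooled observation points of |ECDF_x - ECDF_y| (right-continuous)."""
    pooled = np.concatenate([x, y])
    pooled.sort(kind="mergesort")
    cdf_x = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    cdf_y = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    return float(np.abs(cdf_x - cdf_y).max())


def kolmogorov_sf(lam: float, terms: int = 100) -> float:
    """Asymptotic Kolmogorov tail Q(lam) = 2 * sum_{j>=1} (-1)^(j-1) exp(-2 j^2 lam^2)."""
    if lam <= 0:
        return 1.0
    j = np.arange(1, terms + 1)
    total = 2.0 * np.sum((-1.0) ** (j - 1) * np.exp(-2.0 * j * j * lam * lam))
    return float(min(max(total, 0.0), 1.0))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact sup distance between the two empirical CDFs; the p-value
    uses the asymptotic Kolmogorov distribution with the small-sample
    lambda correction lam = (sqrt(n_e) + 0.12 + 0.11 / sqrt(n_e)) * D where
    n_e = n*m/(n+m). p is clamped into (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("K-S test requires non-empty samples")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValidationError("K-S test requires finite values")
    d = _ecdf_sup_distance(x, y)
    n_e = x.size * y.size / (x.size + y.size)
    lam = (math.sqrt(n_e) + 0.12 + 0.11 / math.sqrt(n_e)) * d
    p = kolmogorov_sf(lam)
    return d, float(min(max(p, np.finfo(float).tiny), 1.0))


def shift_test(
    de_table: pd.DataFrame,
    target_genes,
    window: tuple[float, float],
    include_targets_in_background: bool = True,
    n_random_sets: int = 0,
    seed: int | None = None,
) -> ShiftResult:
    """K-S shift test of a target set against abundance-matched window genes.

    The abundance window is applied first; the target sample is the
    intersection of the target set with the window, and the background is by
    default ALL window genes (targets included). The up/down Fisher test
    compares the sign split of targets with that of non-target window genes.
    """
    lo, hi = window
    window_genes = abundance_window(de_table, lo, hi)
    target_genes = set(target_genes)
    in_window_targets = [g for g in window_genes if g in target_genes]
    if include_targets_in_background:
        background_genes = list(window_genes)
    else:
        background_genes = [g for g in window_genes if g not in target_genes]
    if not in_window_targets or not background_genes:
        raise ValidationError("no target or background genes left inside the window")
    few = len(in_window_targets) < 10
    if few:
        logger.warning("only %d target genes in the window", len(in_window_targets))

    lfc = de_table["log2FoldChange"]
    t_lfc = lfc.loc[in_window_targets].to_numpy(dtype=float)
    b_lfc = lfc.loc[background_genes].to_numpy(dtype=float)
    d, p = ks_two_sample(t_lfc, b_lfc)

    other = [g for g in window_genes if g not in target_genes]
    o_lfc = lfc.loc[other].to_numpy(dtype=float)
    t_up, t_down = int((t_lfc > 0).sum()), int((t_lfc < 0).sum())
    o_up, o_down = int((o_lfc > 0).sum()), int((o_lfc < 0).sum())
    if (t_up + t_down) and (o_up + o_down):
        fisher_p = fisher_exact([[t_up, t_down], [o_up, o_down]]).p_value
    else:
        fisher_p = math.nan

    result = ShiftResult(
        n_target=len(in_window_targets),
        n_background=len(background_genes),
        ks_statistic=d,
        ks_p=p,
        median_target_lfc=float(np.median(t_lfc)),
        median_background_lfc=float(np.median(b_lfc)),
        n_target_up=t_up,
        n_target_down=t_down,
        n_other_up=o_up,
        n_other_down=o_down,
        updown_fisher_p=fisher_p,
        few_targets=few,
    )
    if n_random_sets > 0:
        result.random_sets = random_set_null(
            de_table, window, len(in_window_targets), n_random_sets, seed=seed or 0
        )
        result.random_set_seed = seed or 0
    return result


def random_set_null(
    de_table: pd.DataFrame,
    window: tuple[float, float],
    set_size: int,
    k: int,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """K-S results for k random same-size gene sets drawn from the window.

    Sets are sampled without replacement from window genes and compared, like
    the real target set, against all window genes. Deterministic given seed.
    """
    lo, hi = window
    window_genes = np.asarray(abundance_window(de_table, lo, hi))
    if set_size > window_genes.size:
        raise ValidationError(
            f"random set size {set_size} exceeds window size {window_genes.size}"
        )
    lfc = de_table["log2FoldChange"]
    all_lfc = lfc.loc[window_genes].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    out: list[tuple[float, float]] = []
    for _ in range(k):
        picked = rng.choice(window_genes.size, size=set_size, replace=False)
        out.append(ks_two_sample(all_lfc[picked], all_lfc))
    return out
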