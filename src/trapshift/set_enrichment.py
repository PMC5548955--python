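"""Pfam-clan enrichment of a gene list against an expressed-gene background.

The background is gene-based: every gene with TPM > 0 in at least one sample
belongs to it, whether or not it carries a clan annotation — unannotated
genes stay in the "outside the clan" cells and dilute enrichment. A target
list is first adjusted to the genes actually detected (TPM > 0) in at least
one IP sample. Each clan observed in the list is tested with a two-sided
Fisher's exact test on the 2x2 table (in list / not in list) x (in clan /
not in clan); a clan is flagged enriched when p < alpha AND the clan is
overrepresented in the list relative to the background. No multiplicity
correction is applied by default (a fixed p < 0.01 rule); BH adjustment is
available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .contingency_stats import fisher_exact
from .differential_translation import bh_adjust
from .errors import ValidationError
from .io_formats import ClanMap, GeneSet

logger = logging.getLogger(__name__)


def expressed_background(tpm_table: pd.DataFrame) -> frozenset[str]:
    """Genes with TPM > 0 in at least one sample."""
    mask = (tpm_table > 0).any(axis=1)
    return frozenset(tpm_table.index[mask])


def adjust_target_list(gene_set: GeneSet, tpm_table: pd.DataFrame, ip_samples) -> GeneSet | None:
    """Restrict a gene set to genes detected (TPM > 0) in at least one IP sample.

    Returns None with a warning when nothing survives.
    """
    ip_samples = list(ip_samples)
    missing = [s for s in ip_samples if s not in tpm_table.columns]
    if missing:
        raise ValidationError(f"IP samples not in TPM table: {missing}")
    present = tpm_table.index.intersection(list(gene_set.genes))
    detected = present[(tpm_table.loc[present, ip_samples] > 0).any(axis=1)]
    if len(detected) == 0:
        logger.warning("no gene of set %r detected in any IP sample", gene_set.name)
        return None
    return GeneSet(
        name=f"{gene_set.name}_ip_adjusted",
        description=gene_set.description,
        genes=frozenset(detected),
    )


def clan_enrichment(
    gene_list,
    background,
    clan_map: ClanMap,
    alpha: float = 0.01,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-clan Fisher enrichment of ``gene_list`` against ``background``.

    One test per clan with at least one list gene. Returns a DataFrame
    indexed by clan id, sorted by p, with the 2x2 cells (a = list in clan,
    b = list outside clan, c = rest of background in clan, d = rest outside),
    the odds ratio (Haldane 0.5 continuity applied only when a cell is zero,
    flagged in ``continuity``), p, optionally padj, and the enriched flag.
    """
    gene_list = frozenset(gene_list)
    background = frozenset(background)
    if not gene_list or not background:
        raise ValidationError("gene list and background must be non-empty")
    extra = gene_list - background
    if extra:
        raise ValidationError(
            f"gene list must be a subset of the background ({len(extra)} genes outside it)"
        )

    clan_counts_list: dict[str, int] = {}
    clan_counts_bg: dict[str, int] = {}
    for gene in background:
        for clan in clan_map[gene]:
            clan_counts_bg[clan] = clan_counts_bg.get(clan, 0) + 1
            if gene in gene_list:
                clan_counts_list[clan] = clan_counts_list.get(clan, 0) + 1

    n_list = len(gene_list)
    n_bg = len(background)
    rows = []
    for clan, a in clan_counts_list.items():
        in_clan_bg = clan_counts_bg[clan]
        b = n_list - a
        c = in_clan_bg - a
        d = (n_bg - n_list) - c
        res = fisher_exact([[a, b], [c, d]])
        if res.degenerate_odds:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            continuity = True
        else:
            odds, continuity = res.odds_ratio, False
        overrepresented = a / n_list > in_clan_bg / n_bg
        rows.append(
            {
                "clan": clan,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "continuity": continuity,
                "p": res.p_value,
                "overrepresented": overrepresented,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["a", "b", "c", "d", "odds_ratio", "continuity", "p", "enriched"]
        ).rename_axis("clan")

    table = pd.DataFrame(rows).set_index("clan").sort_values(["p", "clan"])
    if bh:
        table["padj"] = bh_adjust(table["p"].to_numpy())
        table["enriched"] = (table["padj"] < alpha) & table["overrepresented"]
    else:
        table["enriched"] = (table["p"] < alpha) & table["overrepresented"]
    return table.drop(columns=["overrepresented"])


@dataclass(frozen=True)
class OverlapReport:
    shared: frozenset[str]
    n_shared: int
    n_a: int
    n_b: int

    @property
    def summary(self) -> str:
        return f"{self.n_shared} out of {self.n_a}"


def overlap_report(enriched_a: pd.DataFrame, enriched_b: pd.DataFrame) -> OverlapReport:
    """Overlap between the enriched clans of two enrichment tables.

    Reports the intersection and the "x out of y" summary, with y the number
    of clans enriched in the first table.
    """
    set_a = frozenset(enriched_a.index[enriched_a["enriched"]]) if len(enriched_a) else frozenset()
    set_b = frozenset(enriched_b.index[enriched_b["enriched"]]) if len(enriched_b) else frozenset()
    shared = set_a & set_b
    return OverlapReport(shared=shared, n_shared=len(shared), n_a=len(set_a), n_b=len(set_b))
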