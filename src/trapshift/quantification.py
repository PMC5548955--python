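"""Normalization and abundance computations.

Size factors follow the median-of-ratios convention: the per-sample median
of count ratios to a geometric-mean pseudo-reference built strictly from
genes observed in every sample. TPM is computed at gene level from counts
and effective lengths. Heatmap normalization divides each gene by its mean
over wild-type samples and then row-scales to zero mean / unit variance.
Relative quantification implements the delta-delta-Ct rule used for qPCR,
with perfect amplification efficiency (fold change per cycle = 2).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import NormalizationError, ValidationError
from .io_formats import CountMatrix

logger = logging.getLogger(__name__)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, one positive scale per sample.

    Only genes with a positive count in every sample enter the geometric-mean
    reference; if none exists the data cannot be normalized this way.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise NormalizationError("size factors need at least two samples")
    all_positive = np.all(counts > 0, axis=1)
    if not all_positive.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; "
            "median-of-ratios normalization is undefined"
        )
    log_counts = np.log(counts[all_positive])
    log_geomean = log_counts.mean(axis=1)
    log_ratios = log_counts - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def tpm(cm: CountMatrix, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from gene-level counts and effective lengths.

    rate_g = count_g / length_g; TPM_g = 1e6 * rate_g / sum_g rate_g per
    sample. Columns with no reads at all come back as zeros with a warning.
    """
    missing = [g for g in cm.gene_ids if g not in lengths.index]
    if missing:
        raise ValidationError(f"no length for gene {missing[0]!r} (and {len(missing) - 1} more)")
    lens = lengths.reindex(cm.gene_ids).to_numpy(dtype=float)
    rates = cm.counts.to_numpy(dtype=float) / lens[:, None]
    totals = rates.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        logger.warning(
            "samples with zero total counts left as all-zero TPM columns: %s",
            [s for s, z in zip(cm.sample_ids, zero_cols) if z],
        )
    safe_totals = np.where(zero_cols, 1.0, totals)
    values = 1e6 * rates / safe_totals
    values[:, zero_cols] = 0.0
    return pd.DataFrame(values, index=cm.gene_ids, columns=cm.sample_ids)


def heatmap_normalize(tpm_table: pd.DataFrame, wt_samples) -> pd.DataFrame:
    """Divide each gene by its mean TPM over WT samples, then row z-score.

    Genes with zero WT mean or zero variance after division are dropped with
    a warning (they carry no displayable contrast).
    """
    wt_samples = list(wt_samples)
    if not wt_samples:
        raise ValidationError("wt_samples must be non-empty")
    missing = [s for s in wt_samples if s not in tpm_table.columns]
    if missing:
        raise ValidationError(f"WT samples not in TPM table: {missing}")
    wt_mean = tpm_table[wt_samples].mean(axis=1)
    keep = wt_mean > 0
    if not keep.all():
        logger.warning("dropping %d genes with zero WT mean", int((~keep).sum()))
    if not keep.any():
        raise NormalizationError("all genes have zero WT mean; nothing to normalize")
    ratio = tpm_table.loc[keep].div(wt_mean[keep], axis=0)
    sd = ratio.std(axis=1, ddof=1)
    varying = sd > 0
    if not varying.all():
        logger.warning("dropping %d constant genes (zero variance)", int((~varying).sum()))
    ratio = ratio.loc[varying]
    centered = ratio.sub(ratio.mean(axis=1), axis=0)
    return centered.div(centered.std(axis=1, ddof=1), axis=0)


def rel_quant(
    ct_target_ip: float,
    ct_ref_ip: float,
    ct_target_input: float,
    ct_ref_input: float,
) -> float:
    """Delta-delta-Ct fold change: normalize to the reference gene, then IP to Input.

    ddCt = (Ct_target_IP - Ct_ref_IP) - (Ct_target_Input - Ct_ref_Input);
    fold = 2 ** (-ddCt).
    """
    cts = (ct_target_ip, ct_ref_ip, ct_target_input, ct_ref_input)
    if not all(math.isfinite(c) for c in cts):
        raise ValidationError("Ct values must be finite")
    ddct = (ct_target_ip - ct_ref_ip) - (ct_target_input - ct_ref_input)
    return float(2.0 ** (-ddct))
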