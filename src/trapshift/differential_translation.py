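"""Paired negative-binomial differential expression with a Wald test.

The model for gene g in sample j is a log-link NB GLM

    K_gj ~ NB(mean = mu_gj, variance = mu_gj + alpha_g * mu_gj^2)
    log mu_gj = log s_j + x_j' beta_g

with s_j the median-of-ratios size factor and, in the default paired
design, x_j encoding an intercept, littermate-pair indicators and a KO
genotype indicator. The genotype coefficient, converted to log2, is the
reported fold change; its Wald statistic is referred, two-sided, to a
moderated t distribution whose degrees of freedom add the within-group
residual df to the prior df implied by the dispersion-shrinkage width
(the quasi-likelihood convention), which keeps the extreme tail calibrated
when dispersions are estimated from few samples; a standard-normal
reference is available by config. P-values are BH-adjusted at an FDR
threshold of 0.1 by default. No fold-change shrinkage is applied.

Dispersion estimation is deliberately simple and auditable: a
method-of-moments gene-wise estimate from within-genotype variance of
normalized counts, a fitted mean-dispersion trend alpha(mu) = a1/mu + a0,
and log-scale shrinkage of the gene-wise estimate toward the trend with a
fixed prior width. Genes far above the trend keep their own estimate.

IP and Input fractions are analyzed separately; there is no interaction
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import polygamma

from .errors import DesignError, ValidationError
from .io_formats import CountMatrix, SampleSheet
from .quantification import size_factors as compute_size_factors

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)

_DISPERSION_FLOOR = 1e-8
_DISPERSION_CEILING = 30.0


@dataclass(frozen=True)
class DEConfig:
    """Tunables of the DE stage.

    fdr: BH threshold defining the significant set.
    design: "paired" (~ pair + genotype) or "unpaired" (~ genotype).
    min_base_mean: genes below this mean normalized count are not tested.
    prior_ln_disp_sd: prior standard deviation of log dispersion around the
        trend, controlling both the shrinkage weight and the prior df of the
        moderated t reference.
    wald_reference: "t" (moderated df, default) or "normal".
    """

    fdr: float = 0.1
    design: str = "paired"
    min_base_mean: float = 0.5
    prior_ln_disp_sd: float = 0.5
    wald_reference: str = "t"
    max_iter: int = 50
    deviance_tol: float = 1e-8


@dataclass
class DispersionFit:
    """Gene-wise, trend and final (shrunken) NB dispersions."""

    alpha_gene: np.ndarray
    alpha_trend: np.ndarray
    alpha_final: np.ndarray
    a0: float
    a1: float
    shrink_weight: float


@dataclass
class DEResult:
    """Per-gene DE table plus the dispersion fit and run metadata."""

    table: pd.DataFrame
    dispersions: DispersionFit | None
    fraction: str | None
    design: str
    size_factors: pd.Series
    fdr: float

    @property
    def significant(self) -> pd.Index:
        padj = self.table["padj"]
        return self.table.index[padj.notna() & (padj < self.fdr)]


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs are excluded from the number of tests and propagate unchanged.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if pv.size == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    result = np.empty(m)
    result[order] = adjusted
    out[mask] = result
    return out


def prior_df(prior_ln_disp_sd: float) -> float:
    """Degrees of freedom carried by the log-dispersion prior.

    A chi-square-style dispersion estimate with d0 df has log-scale variance
    trigamma(d0/2); inverting that at the prior variance expresses the prior
    width as an equivalent number of observations, added to the residual df
    of the moderated t reference.
    """
    target = prior_ln_disp_sd**2
    return 2.0 * brentq(lambda h: polygamma(1, h) - target, 1e-3, 1e6)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def design_matrix(sheet: SampleSheet, design: str = "paired") -> tuple[np.ndarray, list[str]]:
    """Build the model matrix for one fraction's samples.

    "paired": intercept + pair indicators (first pair as reference) + KO
    indicator. "unpaired": intercept + KO indicator. The genotype column is
    always last.
    """
    t = sheet.table
    n = len(t)
    genotype = (t["genotype"] == "KO").to_numpy(dtype=float)
    if design == "paired":
        pairs = sorted(t["pair_id"].unique())
        if len(pairs) < 2:
            raise DesignError("paired design needs at least two littermate pairs")
        cols = [np.ones(n)]
        names = ["intercept"]
        for pair in pairs[1:]:
            cols.append((t["pair_id"] == pair).to_numpy(dtype=float))
            names.append(f"pair_{pair}")
        cols.append(genotype)
        names.append("genotype_KO")
        x = np.column_stack(cols)
    elif design == "unpaired":
        x = np.column_stack([np.ones(n), genotype])
        names = ["intercept", "genotype_KO"]
    else:
        raise DesignError(f"unknown design {design!r}")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError("design matrix is rank deficient")
    if x.shape[0] - x.shape[1] < 2:
        raise DesignError("fewer than two residual degrees of freedom")
    return x, names


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(
    counts: np.ndarray,
    size_factors: np.ndarray,
    groups: np.ndarray,
    prior_ln_disp_sd: float = 0.5,
) -> DispersionFit:
    """Method-of-moments dispersions with a fitted trend and log-scale shrinkage.

    counts: genes x samples raw counts; groups: per-sample labels (genotype)
    used for the within-group variance, whose residual degrees of freedom
    also set the sampling-variance term of the shrinkage weight.

    Gene-wise: alpha_hat = max((var_within - mean_q) / mean_q^2, 1e-8) on
    normalized counts q. Trend: a1/mu + a0 by iteratively trimmed least
    squares over genes above the floor. Final: exp(w*ln alpha_hat +
    (1-w)*ln alpha_trend); floored genes take the trend value; genes with
    alpha_hat > 10*alpha_trend keep alpha_hat (outlier rule).
    """
    q = counts / size_factors[None, :]
    n = counts.shape[1]
    labels = np.unique(groups)
    if n - len(labels) < 1:
        raise DesignError("need residual degrees of freedom within groups")
    mean_q = q.mean(axis=1)
    ss = np.zeros(counts.shape[0])
    for lab in labels:
        cols = groups == lab
        sub = q[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_within = n - len(labels)
    var_within = ss / df_within
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var_within - mean_q) / mean_q**2
    raw[~np.isfinite(raw)] = _DISPERSION_FLOOR
    alpha_gene = np.clip(raw, _DISPERSION_FLOOR, _DISPERSION_CEILING)

    a0, a1 = _fit_trend(mean_q, alpha_gene)
    with np.errstate(divide="ignore"):
        alpha_trend = np.where(mean_q > 0, a1 / np.maximum(mean_q, 1e-12) + a0, a0)
    alpha_trend = np.clip(alpha_trend, _DISPERSION_FLOOR, _DISPERSION_CEILING)

    # normal-normal shrinkage on the log scale; the sampling variance of the
    # log MoM estimate is approximated by trigamma(df/2)
    sampling_var = float(polygamma(1, max(df_within, 1) / 2.0))
    w = prior_ln_disp_sd**2 / (prior_ln_disp_sd**2 + sampling_var)
    informative = alpha_gene > _DISPERSION_FLOOR * 1.01
    ln_shrunk = w * np.log(alpha_gene) + (1 - w) * np.log(alpha_trend)
    alpha_final = np.where(informative, np.exp(ln_shrunk), alpha_trend)
    outlier = alpha_gene > 10.0 * alpha_trend
    alpha_final = np.where(outlier, alpha_gene, alpha_final)
    alpha_final = np.clip(alpha_final, _DISPERSION_FLOOR, _DISPERSION_CEILING)
    return DispersionFit(
        alpha_gene=alpha_gene,
        alpha_trend=alpha_trend,
        alpha_final=alpha_final,
        a0=a0,
        a1=a1,
        shrink_weight=w,
    )


def _fit_trend(mean_q: np.ndarray, alpha_gene: np.ndarray) -> tuple[float, float]:
    """Fit alpha = a1/mu + a0 by iteratively trimmed, inverse-variance weighted LS."""
    use = (alpha_gene > _DISPERSION_FLOOR * 1.01) & (mean_q > 0)
    if use.sum() < 10:
        # too few informative genes: flat trend at the median
        med = float(np.median(alpha_gene[use])) if use.any() else 0.01
        return max(med, _DISPERSION_FLOOR), 0.0
    x = 1.0 / mean_q[use]
    y = alpha_gene[use]
    keep = np.ones(y.size, dtype=bool)
    a0, a1 = float(np.median(y)), 0.0
    for _ in range(10):
        fitted = np.maximum(a1 * x + a0, _DISPERSION_FLOOR)
        weights = 1.0 / fitted**2 if np.isfinite(fitted).all() else np.ones_like(fitted)
        xw = np.column_stack([np.ones(x.size), x])[keep] * np.sqrt(weights[keep])[:, None]
        yw = y[keep] * np.sqrt(weights[keep])
        coef, *_ = np.linalg.lstsq(xw, yw, rcond=None)
        new_a0 = max(float(coef[0]), _DISPERSION_FLOOR)
        new_a1 = max(float(coef[1]), 0.0)
        fitted = np.maximum(new_a1 * x + new_a0, _DISPERSION_FLOOR)
        ratio = y / fitted
        new_keep = (ratio > 1e-4) & (ratio < 15.0)
        converged = abs(new_a0 - a0) < 1e-8 * (a0 + 1e-8) and abs(new_a1 - a1) < 1e-8 * (a1 + 1e-8)
        a0, a1 = new_a0, new_a1
        if converged and np.array_equal(new_keep, keep):
            break
        keep = new_keep if new_keep.sum() >= 10 else keep
    return a0, a1


# ---------------------------------------------------------------------------
# NB GLM (vectorized IRLS across genes)
# ---------------------------------------------------------------------------

def fit_nb_glm(
    counts: np.ndarray,
    design: np.ndarray,
    size_factors: np.ndarray,
    dispersions: np.ndarray,
    max_iter: int = 50,
    deviance_tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit log-link NB GLMs with offset log(s_j), one per gene, by IRLS.

    counts: (G, n) non-negative integers; design: (n, p) full-rank matrix;
    dispersions: per-gene alpha (scalar broadcasts). Returns (beta, se,
    converged) with beta and se on the natural-log scale, shape (G, p).
    Standard errors come from the inverse expected information (X' W X)^-1.
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    x = np.asarray(design, dtype=float)
    n, p = x.shape
    if y.shape[1] != n:
        raise ValidationError("counts and design have incompatible shapes")
    g = y.shape[0]
    alpha = np.broadcast_to(np.asarray(dispersions, dtype=float), (g,)).copy()
    offset = np.log(np.asarray(size_factors, dtype=float))

    pinv = np.linalg.pinv(x)
    z0 = np.log(np.maximum(y / np.exp(offset)[None, :], 0.5))
    beta = z0 @ pinv.T  # (G, p)

    eye = np.eye(p)
    dev = _nb_deviance(y, _mu(beta, x, offset), alpha)
    active = np.ones(g, dtype=bool)
    converged = np.zeros(g, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        eta = np.clip(beta[idx] @ x.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[idx, None] * mu)
        z = eta - offset[None, :] + (y[idx] - mu) / mu
        xtwx = np.einsum("ni,gn,nj->gij", x, w, x) + 1e-10 * eye[None, :, :]
        xtwz = np.einsum("ni,gn,gn->gi", x, w, z)
        try:
            new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # isolate the offending genes; leave them unconverged
            new_beta = beta[idx].copy()
            for k in range(idx.size):
                try:
                    new_beta[k] = np.linalg.solve(xtwx[k], xtwz[k])
                except np.linalg.LinAlgError:
                    active[idx[k]] = False
        new_dev = _nb_deviance(y[idx], _mu(new_beta, x, offset), alpha[idx])
        improved = np.isfinite(new_dev)
        beta[idx[improved]] = new_beta[improved]
        done = improved & (np.abs(new_dev - dev[idx]) < deviance_tol * (np.abs(new_dev) + 0.1))
        converged[idx[done]] = True
        dev[idx] = np.where(improved, new_dev, dev[idx])
        active[idx[done | ~improved]] = False

    # final information at the converged coefficients
    eta = np.clip(beta @ x.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    xtwx = np.einsum("ni,gn,nj->gij", x, w, x) + 1e-10 * eye[None, :, :]
    cov = np.linalg.solve(xtwx, np.broadcast_to(eye, (g, p, p)).copy())
    se = np.sqrt(np.clip(np.diagonal(cov, axis1=1, axis2=2), 0.0, None))
    return beta, se, converged


def _mu(beta: np.ndarray, x: np.ndarray, offset: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(beta @ x.T + offset[None, :], -30.0, 30.0))


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """2 * (loglik(saturated) - loglik(fitted)) for the NB2 family."""
    alpha = alpha[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
        term2 = (y + 1.0 / alpha) * np.log((1.0 + alpha * y) / (1.0 + alpha * mu))
    return 2.0 * np.sum(term1 - term2, axis=1)


# ---------------------------------------------------------------------------
# full DE stage
# ---------------------------------------------------------------------------

def run_de(
    counts: CountMatrix,
    samples: SampleSheet,
    fraction: str | None = None,
    config: DEConfig | None = None,
) -> DEResult:
    """Size factors -> dispersions -> per-gene paired NB GLM -> Wald -> BH.

    ``fraction`` restricts the analysis to IP or Input samples; the
    significant set is padj < config.fdr (0.1 by default). Genes that are
    all-zero, below the baseMean filter, or whose GLM failed to converge are
    reported untested with NA statistics.
    """
    config = config or DEConfig()
    sheet = samples.subset(fraction=fraction) if fraction is not None else samples
    if len(sheet.table) == 0:
        raise DesignError(f"no samples in fraction {fraction!r}")
    cm = counts.subset_samples(sheet.sample_ids)
    x, coef_names = design_matrix(sheet, config.design)

    sf = compute_size_factors(cm)
    raw = cm.counts.to_numpy(dtype=float)
    s = sf.to_numpy()
    base_mean = (raw / s[None, :]).mean(axis=1)

    testable = (raw.sum(axis=1) > 0) & (base_mean >= config.min_base_mean)
    genes = np.asarray(cm.gene_ids)

    n_genes = raw.shape[0]
    lfc = np.full(n_genes, np.nan)
    se_out = np.full(n_genes, np.nan)
    wald = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    tested = np.zeros(n_genes, dtype=bool)

    disp_fit = None
    if testable.any():
        groups = sheet.table["genotype"].to_numpy()
        disp_fit = estimate_dispersions(raw[testable], s, groups, config.prior_ln_disp_sd)
        beta, se, converged = fit_nb_glm(
            raw[testable],
            x,
            s,
            disp_fit.alpha_final,
            max_iter=config.max_iter,
            deviance_tol=config.deviance_tol,
        )
        if not converged.all():
            logger.info("%d genes did not converge and are not tested", int((~converged).sum()))
        geno = len(coef_names) - 1  # genotype column is last
        t_idx = np.where(testable)[0]
        ok = converged & np.isfinite(se[:, geno]) & (se[:, geno] > 0)
        rows = t_idx[ok]
        lfc[rows] = beta[ok, geno] / LN2
        se_out[rows] = se[ok, geno] / LN2
        wald[rows] = beta[ok, geno] / se[ok, geno]
        if config.wald_reference == "t":
            n_groups = len(np.unique(groups))
            df = (x.shape[0] - n_groups) + prior_df(config.prior_ln_disp_sd)
            pval[rows] = 2.0 * stats.t.sf(np.abs(wald[rows]), df=df)
        elif config.wald_reference == "normal":
            pval[rows] = 2.0 * stats.norm.sf(np.abs(wald[rows]))
        else:
            raise ValidationError(f"unknown wald_reference {config.wald_reference!r}")
        tested[rows] = True

    padj = bh_adjust(pval)
    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "lfcSE": se_out,
            "stat": wald,
            "pvalue": pval,
            "padj": padj,
            "tested": tested,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return DEResult(
        table=table,
        dispersions=disp_fit,
        fraction=fraction,
        design=config.design,
        size_factors=sf,
        fdr=config.fdr,
    )
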