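"""Negative-binomial differential-expression engine.

A deliberately transparent re-implementation of the standard bulk RNA-seq
workflow: median-of-ratios size factors, method-of-moments per-gene
dispersion shrunk toward a mean–dispersion trend, per-gene Wald contrasts
of group means on the normalised scale, and Benjamini–Hochberg FDR within
each contrast.  It is not a clone of DESeq2 — no empirical-Bayes
dispersion posterior, no Cook's-distance outlier handling, no independent
filtering — but an adapter (:func:`read_deseq2_results`) accepts
DESeq2-shaped result tables so externally produced contrasts can drop
into the classification layer.

The NB parameterisation throughout is variance = mu + alpha * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, HilexError, PARENT_B, PARENT_N, samples_in_group

__all__ = [
    "DEError",
    "ContrastTriplet",
    "size_factors",
    "estimate_dispersion",
    "nb_wald_contrast",
    "bh_adjust",
    "build_triplet",
    "read_deseq2_results",
    "write_contrast",
    "read_contrast",
]

_CONTRAST_COLUMNS = ["log2fc", "se", "p", "padj", "base_mean"]

#: lower bound on the per-gene dispersion estimate
ALPHA_FLOOR = 1e-8


class DEError(HilexError):
    """Design or data unsuitable for the DE engine."""


@dataclass
class ContrastTriplet:
    """Aligned per-gene results for the three pairwise contrasts of one HIL.

    ``bvn`` is species B vs species N, ``hvn`` the HIL vs species N and
    ``hvb`` the HIL vs species B; log2 fold changes are oriented
    first-group over second-group, so the two H contrasts are already
    "H minus parent".
    """

    hil_label: str
    bvn: pd.DataFrame
    hvn: pd.DataFrame
    hvb: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.bvn.index.equals(self.hvn.index) and self.hvn.index.equals(self.hvb.index)):
            raise DEError("contrast triplet has misaligned gene sets")

    @property
    def gene_ids(self) -> pd.Index:
        return self.bvn.index


def size_factors(m: CountMatrix, reference_samples=None) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j the pre-rescale factor is the median over genes of
    count_{gj} / geomean_g, where geomean_g is the per-gene geometric
    mean across the reference samples (all samples by default), taken
    over genes with positive counts in every reference sample.

    Passing the background species' samples as *reference_samples*
    anchors normalisation to the profile the majority of genes are
    expected to match.  With a grand pseudo-reference, heavy expression
    divergence combined with poor cross-reference mappability of one
    group skews the ratio distribution of that group's columns and
    biases its median; a reference-group profile keeps the median inside
    the majority, unchanged-gene mass.
    """
    counts = m.counts.to_numpy(dtype=float)
    if reference_samples is None:
        ref = np.ones(counts.shape[1], dtype=bool)
    else:
        ref = np.asarray(m.sample_ids.isin(list(reference_samples)))
        if not ref.any():
            raise DEError("reference_samples not found in the count matrix")
    all_pos = (counts[:, ref] > 0).all(axis=1)
    if not all_pos.any():
        raise DEError(
            "no gene has positive counts in every reference sample; "
            "median-of-ratios normalisation needs at least one — consider "
            "a pseudo-reference fallback"
        )
    log_geo = np.log(counts[all_pos][:, ref]).mean(axis=1)
    ratios = counts[all_pos] / np.exp(log_geo)[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise DEError("a sample's median ratio is zero; too many zero counts")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def estimate_dispersion(
    m: CountMatrix, sf: pd.Series, groups: dict
) -> pd.Series:
    """Per-gene NB dispersion alpha, method-of-moments plus trend shrinkage.

    Within each group with >=2 replicates the raw estimate is
    max(0, (s^2 - mu) / mu^2) on size-factor-normalised counts; groups are
    pooled by replicate-weighted averaging.  Genes with a positive raw
    estimate are then blended 50/50 with a trend fitted by log-linear
    regression of alpha on the log normalised mean; genes whose raw
    estimate is exactly zero (no excess variance observed) stay at the
    floor rather than being pulled up to the trend.

    Parameters
    ----------
    groups
        Mapping of group label -> list of sample IDs (all columns used).
    """
    usable = {g: s for g, s in groups.items() if len(s) >= 2}
    if not usable:
        raise DEError("dispersion estimation needs >=2 replicates in >=1 group")
    norm = m.counts / sf
    num = pd.Series(0.0, index=m.gene_ids)
    weight = 0
    overall_mean = pd.Series(0.0, index=m.gene_ids)
    n_samples = 0
    for g, samples in usable.items():
        sub = norm[list(samples)]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw_g = (s2 - mu) / mu**2
        raw_g = raw_g.where(mu > 0, 0.0).clip(lower=0.0).fillna(0.0)
        w = len(samples) - 1
        num += raw_g * w
        weight += w
        overall_mean += mu * len(samples)
        n_samples += len(samples)
    raw = num / weight
    mean = overall_mean / n_samples

    positive = (raw > 0) & (mean > 0)
    if positive.sum() >= 10:
        x = np.log(mean[positive])
        y = np.log(raw[positive])
        slope, intercept = np.polyfit(x, y, 1)
        with np.errstate(over="ignore"):
            trend = np.exp(intercept + slope * np.log(mean.clip(lower=1e-8)))
        trend = pd.Series(trend, index=m.gene_ids).clip(upper=10.0)
    else:
        trend = pd.Series(float(raw[positive].median()) if positive.any() else 0.0,
                          index=m.gene_ids)
    alpha = pd.Series(ALPHA_FLOOR, index=m.gene_ids, dtype=float)
    alpha[positive] = 0.5 * raw[positive] + 0.5 * trend[positive]
    return alpha.clip(lower=ALPHA_FLOOR).rename("alpha")


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def nb_wald_contrast(
    m: CountMatrix,
    sf: pd.Series,
    alpha: pd.Series,
    group_a: list,
    group_b: list,
    labels: tuple = ("A", "B"),
) -> pd.DataFrame:
    """Per-gene Wald test of group A vs group B on normalised counts.

    Group means are plug-in estimates (mean of normalised counts); the
    log2 fold change is log2((mu_A + eps) / (mu_B + eps)) with a small
    depth-scaled pseudocount guard, and its standard error comes from the
    NB variance mu/sf + alpha*mu^2 of each normalised observation.
    All-zero gene pairs report log2fc = 0, p = 1.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise DEError(f"empty group in contrast {labels[0]} vs {labels[1]}")
    norm = m.counts / sf
    eps = 0.5 / float(np.median(m.counts.sum(axis=0) / sf))

    def _moments(samples):
        sub = norm[list(samples)]
        mu = sub.mean(axis=1).clip(lower=0.0)
        inv_sf = (1.0 / sf[list(samples)]).to_numpy()
        # Var(mean of K_j/sf_j) with K_j ~ NB(sf_j*mu, alpha)
        var = (mu.to_numpy()[:, None] * inv_sf[None, :]).sum(axis=1)
        var = (var + alpha.to_numpy() * mu.to_numpy() ** 2 * len(samples)) / len(samples) ** 2
        return mu, pd.Series(var, index=mu.index)

    mu_a, var_a = _moments(group_a)
    mu_b, var_b = _moments(group_b)
    ln2sq = np.log(2.0) ** 2
    log2fc = np.log2((mu_a + eps) / (mu_b + eps))
    se2 = var_a / ((mu_a + eps) ** 2 * ln2sq) + var_b / ((mu_b + eps) ** 2 * ln2sq)
    se = np.sqrt(se2)
    both_zero = (mu_a == 0) & (mu_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    z = z.where(~both_zero, 0.0).fillna(0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(both_zero, 1.0, p)
    log2fc = log2fc.where(~both_zero, 0.0)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": bh_adjust(p),
            "base_mean": (mu_a * len(group_a) + mu_b * len(group_b))
            / (len(group_a) + len(group_b)),
        },
        index=m.gene_ids,
    )
    out.attrs["groupA"], out.attrs["groupB"] = labels
    return out


def build_triplet(
    m: CountMatrix,
    samples: pd.DataFrame,
    hil_label: str,
    sf: pd.Series | None = None,
    alpha: pd.Series | None = None,
) -> ContrastTriplet:
    """Run the three pairwise contrasts (B vs N, HIL vs N, HIL vs B).

    Size factors are median-of-ratios against the species-N reference
    profile (the background genome most genes are expected to match) and
    dispersions are estimated once across all groups in the sample sheet
    (one alpha per gene for the whole design); BH correction is applied
    within each contrast.
    """
    for group in (PARENT_B, PARENT_N, hil_label):
        if group not in set(samples["group"]):
            raise DEError(f"group {group!r} missing from sample sheet")
    if sf is None:
        sf = size_factors(m, samples_in_group(samples, PARENT_N))
    if alpha is None:
        groups = {g: samples_in_group(samples, g) for g in samples["group"].unique()}
        alpha = estimate_dispersion(m, sf, groups)
    b = samples_in_group(samples, PARENT_B)
    n = samples_in_group(samples, PARENT_N)
    h = samples_in_group(samples, hil_label)
    return ContrastTriplet(
        hil_label=hil_label,
        bvn=nb_wald_contrast(m, sf, alpha, b, n, (PARENT_B, PARENT_N)),
        hvn=nb_wald_contrast(m, sf, alpha, h, n, (hil_label, PARENT_N)),
        hvb=nb_wald_contrast(m, sf, alpha, h, b, (hil_label, PARENT_B)),
    )


def write_contrast(contrast: pd.DataFrame, path) -> None:
    contrast[_CONTRAST_COLUMNS].to_csv(path, sep="\t", index_label="gene_id")


def read_contrast(path) -> pd.DataFrame:
    """Read a contrast TSV written by :func:`write_contrast`."""
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    missing = set(_CONTRAST_COLUMNS) - set(frame.columns)
    if missing:
        raise DEError(f"{path}: contrast table missing columns {sorted(missing)}")
    return frame[_CONTRAST_COLUMNS]


def read_deseq2_results(path) -> pd.DataFrame:
    """Adapter for DESeq2 ``results()``-shaped TSV tables.

    Maps baseMean/log2FoldChange/lfcSE/pvalue/padj onto the internal
    contrast schema so externally computed contrasts (e.g. from the
    original R workflow) feed the classification layer directly.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    mapping = {
        "log2FoldChange": "log2fc",
        "lfcSE": "se",
        "pvalue": "p",
        "padj": "padj",
        "baseMean": "base_mean",
    }
    missing = set(mapping) - set(frame.columns)
    if missing:
        raise DEError(f"{path}: DESeq2 table missing columns {sorted(missing)}")
    out = frame.rename(columns=mapping)[_CONTRAST_COLUMNS]
    out.index.name = "gene_id"
    # DESeq2 reports NA padj for filtered genes; treat them as not significant
    out["padj"] = out["padj"].fillna(1.0)
    out["p"] = out["p"].fillna(1.0)
    return out
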