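"""Dropout-screen quantification, normalization and depletion testing.

Reads are quantified by exact 20-mer matching against the library manifest.
Per-sample size factors come from median-of-ratios normalization restricted
to the safe-harbor control guides.  Depletion per guide is tested with a
two-group negative-binomial model: counts in sample ``s`` have mean
``q_g * sizefactor_s * exp(beta * x_s)`` (``x_s`` = 1 in the timepoint arm)
and variance ``mu + alpha_g * mu**2``.  ``beta`` is estimated as the log
ratio of size-factor-scaled arm means (the NB maximum-likelihood solution
when dispersion is shared within a guide), its standard error from the
expected information at the fit, and significance from the two-sided normal
tail of the Wald statistic, BH-adjusted per contrast.  A gene is significant
when at least one of its guides is; essential genes additionally deplete
(log2FC < 0) at both timepoints with growing magnitude.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats as sps
from sklearn.decomposition import PCA

from .stats import bh_adjust, z_to_p

GUIDE_LEN = 20
CONTRASTS = ("T7vsT0", "T14vsT0")


def count_guides(
    fastq_path: str | Path,
    manifest: pd.DataFrame,
    offset: int | None = None,
) -> tuple[pd.Series, float]:
    """Count exact guide matches in a FASTQ file.

    Each read is scanned for an exact manifest 20-mer — at ``offset`` when
    given, else at every position (first unique hit counted).  Returns the
    per-guide counts (manifest order) and the mapping rate.
    """
    seqs = manifest["sequence"].tolist()
    if len(set(seqs)) != len(seqs):
        dup = manifest["sequence"][manifest["sequence"].duplicated()].tolist()
        raise ValueError(f"duplicate manifest sequences: {dup[:5]}")
    lut = dict(zip(seqs, range(len(seqs))))
    counts = np.zeros(len(seqs), dtype=np.int64)
    total = 0
    with pysam.FastxFile(str(fastq_path)) as fh:
        for read in fh:
            total += 1
            seq = read.sequence
            if offset is not None:
                hit = lut.get(seq[offset : offset + GUIDE_LEN])
                if hit is not None:
                    counts[hit] += 1
                continue
            for i in range(len(seq) - GUIDE_LEN + 1):
                hit = lut.get(seq[i : i + GUIDE_LEN])
                if hit is not None:
                    counts[hit] += 1
                    break
    if total == 0:
        raise ValueError(f"empty FASTQ: {fastq_path}")
    return (
        pd.Series(counts, index=pd.Index(manifest["guide_id"], name="guide_id")),
        counts.sum() / total,
    )


def sample_qc(
    matrix: pd.DataFrame,
    size_factors: pd.Series | None = None,
    mapping_rates: pd.Series | None = None,
) -> dict:
    """Per-sample QC: totals, mapping rates, and a 2-component PCA.

    PCA runs on log1p of size-factor-scaled counts with guides as features
    (samples as observations).  Without explicit factors, median-of-ratios
    factors over all guides are used when computable, else totals-based
    factors.  A constant matrix yields zero coordinates and zero explained
    variance.
    """
    if matrix.shape[1] < 2:
        raise ValueError("sample_qc needs at least 2 samples")
    if size_factors is None:
        try:
            size_factors = control_size_factors(matrix, matrix.index)
        except ValueError:
            totals = matrix.sum(axis=0).astype(float)
            size_factors = totals / np.exp(np.log(totals).mean())
    X = np.log1p(matrix.values / size_factors.reindex(matrix.columns).values).T
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    if n_comp < 1 or np.allclose(X, X[0]):
        coords = np.zeros((X.shape[0], 2))
        evr = np.zeros(2)
    else:
        pca = PCA(n_components=n_comp)
        c = pca.fit_transform(X)
        coords = np.zeros((X.shape[0], 2))
        coords[:, :n_comp] = c
        evr = np.zeros(2)
        evr[:n_comp] = pca.explained_variance_ratio_
    return {
        "totals": matrix.sum(axis=0),
        "size_factors": size_factors,
        "mapping_rates": mapping_rates,
        "pca_coords": pd.DataFrame(
            coords, index=matrix.columns, columns=["PC1", "PC2"]
        ),
        "explained_variance_ratio": evr,
    }


def control_size_factors(
    matrix: pd.DataFrame, control_ids
) -> pd.Series:
    """Median-of-ratios size factors restricted to control guides.

    The reference for each control guide is its geometric mean across
    samples (guides with any zero count are excluded); a sample's factor is
    the median over controls of count/reference.  Factors are reported
    unscaled.
    """
    sub = matrix.loc[matrix.index.intersection(control_ids)].astype(float)
    usable = sub[(sub > 0).all(axis=1)]
    if len(usable) == 0:
        raise ValueError("no control guide with nonzero counts in every sample")
    ref = np.exp(np.log(usable.values).mean(axis=1))
    ratios = usable.values / ref[:, None]
    return pd.Series(np.median(ratios, axis=0), index=matrix.columns)


def _dispersion_mom(
    y: np.ndarray, i0: np.ndarray, i1: np.ndarray, inv_c_mean: float
) -> np.ndarray:
    """Per-guide method-of-moments dispersion on scaled counts, pooled across arms."""
    n0, n1 = len(i0), len(i1)
    m0 = y[:, i0].mean(axis=1)
    m1 = y[:, i1].mean(axis=1)
    ss = ((y[:, i0] - m0[:, None]) ** 2).sum(axis=1) + (
        (y[:, i1] - m1[:, None]) ** 2
    ).sum(axis=1)
    v = ss / max(n0 + n1 - 2, 1)
    m_bar = (n0 * m0 + n1 * m1) / (n0 + n1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m_bar * inv_c_mean) / m_bar**2
    return np.where(np.isfinite(alpha), np.maximum(alpha, 0.0), 0.0)


def nb_depletion_test(
    matrix: pd.DataFrame,
    baseline_samples: list[str],
    timepoint_samples: list[str],
    size_factors: pd.Series,
    dispersion_prior_df: float = 20.0,
    pseudocount: float = 0.5,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Two-group NB Wald test of differential guide abundance.

    Per-guide dispersion is estimated by method of moments on size-factor-
    scaled counts pooled across both arms and moderated toward the
    across-guide median with prior weight ``dispersion_prior_df`` (the
    per-guide estimate alone, from a handful of samples, is too noisy for a
    calibrated normal-tail Wald p; set the prior weight to 0 for the raw
    estimate).  Arms whose total count is zero receive a ``pseudocount``
    added to both arm totals.  Guides absent in every sample are flagged
    not testable (all-NaN row) and excluded from BH adjustment downstream.

    Returns a DataFrame indexed by guide with columns log2fc, se, wald, p,
    dispersion, testable.
    """
    if len(baseline_samples) < 2 or len(timepoint_samples) < 2:
        raise ValueError("each arm needs at least 2 samples")
    samples = list(baseline_samples) + list(timepoint_samples)
    c = size_factors.reindex(samples).values.astype(float)
    if np.any(~np.isfinite(c)) or np.any(c <= 0):
        raise ValueError("size factors must be positive for all samples")
    raw = matrix[samples].values.astype(float)
    y = raw / c[None, :]
    i0 = np.arange(len(baseline_samples))
    i1 = np.arange(len(baseline_samples), len(samples))
    n0, n1 = len(i0), len(i1)

    testable = raw.sum(axis=1) > 0
    alpha_raw = _dispersion_mom(y, i0, i1, float((1.0 / c).mean()))
    alpha_med = float(np.median(alpha_raw[testable])) if testable.any() else 0.0
    df_g = n0 + n1 - 2
    alpha = (df_g * alpha_raw + dispersion_prior_df * alpha_med) / (
        df_g + dispersion_prior_df
    )
    alpha = np.maximum(alpha, dispersion_floor)

    t0 = y[:, i0].sum(axis=1)
    t1 = y[:, i1].sum(axis=1)
    zero_arm = (t0 == 0) | (t1 == 0)
    t0 = np.where(zero_arm, t0 + pseudocount, t0)
    t1 = np.where(zero_arm, t1 + pseudocount, t1)
    m0, m1 = t0 / n0, t1 / n1

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.log(m1 / m0)
        mu0 = m0[:, None] * c[None, i0]
        mu1 = m1[:, None] * c[None, i1]
        w0 = (mu0 / (1.0 + alpha[:, None] * mu0)).sum(axis=1)
        w1 = (mu1 / (1.0 + alpha[:, None] * mu1)).sum(axis=1)
        se = np.sqrt(1.0 / w0 + 1.0 / w1)
        wald = beta / se
    p = z_to_p(wald)
    p = np.clip(p, 1e-300, 1.0)

    res = pd.DataFrame(
        {
            "log2fc": beta / np.log(2.0),
            "se": se,
            "wald": wald,
            "p": p,
            "dispersion": alpha,
            "testable": testable,
        },
        index=matrix.index,
    )
    res.loc[~testable, ["log2fc", "se", "wald", "p"]] = np.nan
    return res


def adjusted_results(results: pd.DataFrame) -> pd.DataFrame:
    """Add BH-adjusted p-values (family = testable guides of this contrast)."""
    out = results.copy()
    out["padj"] = bh_adjust(out["p"].values)
    return out


def gene_level_call(
    results: pd.DataFrame, manifest: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene significance for one contrast.

    A gene is significant when at least one of its guides has padj < alpha.
    Genes with no testable guide are flagged not testable.
    """
    guides = manifest[manifest["target_class"] == "targeting"]
    joined = guides.set_index("guide_id").join(results, how="left")
    grp = joined.groupby("target_gene")
    out = pd.DataFrame(
        {
            "n_guides": grp.size(),
            "n_testable": grp["testable"].sum().astype(int),
            "min_padj": grp["padj"].min(),
        }
    )
    out["testable"] = out["n_testable"] > 0
    out["significant"] = out["testable"] & (out["min_padj"] < alpha)
    out.index.name = "gene"
    return out


def _gene_lfc(
    results: pd.DataFrame, manifest: pd.DataFrame, aggregate: str
) -> pd.DataFrame:
    guides = manifest[manifest["target_class"] == "targeting"]
    joined = guides.set_index("guide_id").join(results, how="left")
    grp = joined.groupby("target_gene")
    min_padj = grp["padj"].min()
    if aggregate == "min_padj":
        best = joined.sort_values("padj", kind="mergesort").drop_duplicates(
            "target_gene"
        )
        lfc = best.set_index("target_gene")["log2fc"]
    elif aggregate == "mean":
        lfc = grp["log2fc"].mean()
    else:
        raise ValueError(f"unknown aggregate: {aggregate}")
    out = pd.DataFrame({"log2fc": lfc, "padj": min_padj})
    out["testable"] = grp["testable"].sum() > 0
    return out


def call_essential(
    results_t7: pd.DataFrame,
    results_t14: pd.DataFrame,
    manifest: pd.DataFrame,
    alpha: float = 0.05,
    aggregate: str = "min_padj",
) -> pd.DataFrame:
    """Continuous-depletion essentiality calls across the two contrasts.

    Gene-level log2FC per contrast comes from the minimum-padj guide
    (``aggregate='mean'`` averages guides instead; significance always uses
    the minimum padj).  A gene is essential when it depletes at both
    timepoints (log2FC < 0), the depletion magnitude grows from T7 to T14,
    and both adjusted p-values are below ``alpha``.
    """
    g7 = _gene_lfc(results_t7, manifest, aggregate)
    g14 = _gene_lfc(results_t14, manifest, aggregate)
    out = g7.join(g14, lsuffix="_T7", rsuffix="_T14", how="outer")
    out.index.name = "gene"
    out["significant_T7"] = out["padj_T7"] < alpha
    out["significant_T14"] = out["padj_T14"] < alpha
    out["testable"] = out["testable_T7"].fillna(False) & out["testable_T14"].fillna(
        False
    )
    out["essential"] = (
        out["testable"]
        & (out["log2fc_T7"] < 0)
        & (out["log2fc_T14"] < 0)
        & (out["log2fc_T14"].abs() > out["log2fc_T7"].abs())
        & out["significant_T7"]
        & out["significant_T14"]
    )
    return out


def run_screen_analysis(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    manifest: pd.DataFrame,
    alpha: float = 0.05,
    dispersion_prior_df: float = 20.0,
) -> dict:
    """Full depletion analysis: size factors, both contrasts, gene calls.

    Contrasts are T7 vs T0 and T14 vs T0 (timepoints from the sample
    sheet); BH families are per contrast.  Returns size factors, per-guide
    results, per-gene significance and essentiality tables.
    """
    by_tp = {
        tp: sample_sheet.loc[sample_sheet["timepoint"] == tp, "sample"].tolist()
        for tp in ("T0", "T7", "T14")
    }
    sh_ids = manifest.loc[manifest["target_class"] == "safe_harbor", "guide_id"]
    factors = control_size_factors(matrix, sh_ids)
    results = {}
    gene_calls = {}
    for contrast, tp in zip(CONTRASTS, ("T7", "T14")):
        res = nb_depletion_test(
            matrix,
            by_tp["T0"],
            by_tp[tp],
            factors,
            dispersion_prior_df=dispersion_prior_df,
        )
        res = adjusted_results(res)
        results[contrast] = res
        gene_calls[contrast] = gene_level_call(res, manifest, alpha=alpha)
    essential = call_essential(
        results["T7vsT0"], results["T14vsT0"], manifest, alpha=alpha
    )
    return {
        "size_factors": factors,
        "results": results,
        "gene_calls": gene_calls,
        "essential": essential,
    }
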