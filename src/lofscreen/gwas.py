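"""GWAS-catalog preprocessing and permutation trait enrichment.

The enrichment statistic asks whether the focal gene set accumulates more
unique LoF gene–trait associations than random gene sets of the same size
drawn from the catalog's intragenic gene universe:

    z = (observed - mean_random) / sd_random

with a two-sided normal p and Benjamini–Hochberg adjustment across traits.
Preprocessing mirrors the catalog conventions: unmapped SNPs are assigned to
the nearest gene, traits are standardized to the mapped-trait field with the
disease-trait string as fallback, and studies reporting >10 traits or >1,000
genes and traits with <5 genes are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geneset import GeneSet, classify_consequences
from .stats import bh_adjust, z_to_p

RESULT_COLUMNS = ("trait", "observed", "null_mean", "null_sd", "z", "p", "q", "n_hits")


def assign_nearest_gene(
    catalog: pd.DataFrame, intervals: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Fill missing ``mapped_gene`` with the nearest same-chromosome gene.

    Distance to a gene is 0 when the position lies inside its 0-based
    half-open interval, else the base-pair distance to the nearer interval
    edge, ``min(|pos - start|, |pos - (end - 1)|)``.  Ties break by smaller
    start, then lexicographic symbol.  Rows on chromosomes without genes are
    dropped (their number is returned).  A ``distance`` column is added for
    every row; rows already mapped get the distance to their own gene (0 when
    the gene is absent from the interval table).
    """
    bad = intervals[intervals["start"] >= intervals["end"]]
    if len(bad):
        raise ValueError(
            f"malformed intervals (start >= end): {bad['symbol'].tolist()}"
        )
    out = catalog.copy()
    out["distance"] = 0.0

    def _dist(pos: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        inside = (start[None, :] <= pos[:, None]) & (pos[:, None] < end[None, :])
        d = np.minimum(
            np.abs(pos[:, None] - start[None, :]),
            np.abs(pos[:, None] - (end[None, :] - 1)),
        )
        d[inside] = 0
        return d

    # distance of already-mapped rows to their own gene
    mapped = out["mapped_gene"].notna()
    if mapped.any():
        iv = intervals.set_index("symbol")
        sub = out.loc[mapped]
        known = sub["mapped_gene"].isin(iv.index)
        idx = sub.index[known]
        if len(idx):
            g = out.loc[idx, "mapped_gene"]
            s = iv.loc[g, "start"].values
            e = iv.loc[g, "end"].values
            p = out.loc[idx, "position"].values
            inside = (s <= p) & (p < e)
            d = np.minimum(np.abs(p - s), np.abs(p - (e - 1)))
            out.loc[idx, "distance"] = np.where(inside, 0, d).astype(float)

    unmapped = out.index[out["mapped_gene"].isna()]
    dropped = []
    for chrom, grp in out.loc[unmapped].groupby("chromosome"):
        genes = intervals[intervals["chrom"] == chrom]
        if len(genes) == 0:
            dropped.extend(grp.index.tolist())
            continue
        # deterministic tie-break: order candidates by (start, symbol)
        genes = genes.sort_values(["start", "symbol"], kind="mergesort")
        d = _dist(
            grp["position"].values.astype(np.int64),
            genes["start"].values.astype(np.int64),
            genes["end"].values.astype(np.int64),
        )
        best = np.argmin(d, axis=1)  # first minimum = smallest start, then symbol
        out.loc[grp.index, "mapped_gene"] = genes["symbol"].values[best]
        out.loc[grp.index, "distance"] = d[np.arange(len(grp)), best].astype(float)
    out = out.drop(index=dropped)
    return out, len(dropped)


def standardize_traits(catalog: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse mapped_trait/disease_trait into a single ``trait`` column.

    The mapped trait wins when present and non-empty; otherwise the disease
    trait is used.  Values are whitespace-trimmed, case preserved.  Rows with
    both fields empty are dropped (their number is returned).
    """
    out = catalog.copy()
    mt = out["mapped_trait"].fillna("").astype(str).str.strip()
    dt = out["disease_trait"].fillna("").astype(str).str.strip()
    out["trait"] = np.where(mt != "", mt, dt)
    n_dropped = int((out["trait"] == "").sum())
    out = out[out["trait"] != ""].copy()
    return out, n_dropped


def filter_catalog(catalog: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the catalog exclusion filters in a single ordered pass.

    (1) drop studies reporting more than 10 distinct traits; (2) drop studies
    mapping more than 1,000 distinct genes; (3) drop traits with fewer than 5
    distinct genes, computed on the survivors of steps 1–2.  Returns the
    filtered catalog and a per-step report of removed studies/traits/rows.
    """
    report: dict = {}
    df = catalog

    traits_per_study = df.groupby("study_id")["trait"].nunique()
    bad_studies = set(traits_per_study[traits_per_study > 10].index)
    report["studies_gt10_traits"] = sorted(bad_studies)
    report["rows_removed_step1"] = int(df["study_id"].isin(bad_studies).sum())
    df = df[~df["study_id"].isin(bad_studies)]

    genes_per_study = df.groupby("study_id")["mapped_gene"].nunique()
    bad_studies = set(genes_per_study[genes_per_study > 1000].index)
    report["studies_gt1000_genes"] = sorted(bad_studies)
    report["rows_removed_step2"] = int(df["study_id"].isin(bad_studies).sum())
    df = df[~df["study_id"].isin(bad_studies)]

    genes_per_trait = df.groupby("trait")["mapped_gene"].nunique()
    bad_traits = set(genes_per_trait[genes_per_trait < 5].index)
    report["traits_lt5_genes"] = sorted(bad_traits)
    report["rows_removed_step3"] = int(df["trait"].isin(bad_traits).sum())
    df = df[~df["trait"].isin(bad_traits)].copy()

    return df, report


def _lof_intragenic_pairs(catalog: pd.DataFrame) -> pd.DataFrame:
    """Unique (gene, trait) pairs restricted to intragenic LoF associations."""
    df = catalog[catalog["mapped_gene"].notna()]
    is_lof, _ = classify_consequences(df["consequence"])
    df = df[is_lof.values]
    if "distance" in df.columns:
        df = df[df["distance"] == 0]
    return df[["mapped_gene", "trait"]].drop_duplicates()


def permutation_trait_enrichment(
    catalog: pd.DataFrame,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    p_mode: str = "normal",
) -> pd.DataFrame:
    """Permutation-null trait enrichment of the gene set.

    Only unique (gene, trait) pairs among intragenic LoF associations are
    counted.  The null resamples, ``n_perm`` times without replacement, gene
    sets of size ``|set ∩ catalog genes|`` from all intragenic catalog genes
    and recounts each trait.  ``z`` is undefined (NaN) when the null SD is 0;
    such traits are excluded from the BH family.

    ``p_mode='normal'`` (canonical) uses the two-sided normal tail of z;
    ``'empirical'`` uses the permutation rank ``(1 + #{|null - mean| >=
    |obs - mean|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if p_mode not in ("normal", "empirical"):
        raise ValueError(f"unknown p_mode: {p_mode}")
    pairs = _lof_intragenic_pairs(catalog)
    genes = np.sort(pairs["mapped_gene"].unique())
    members = set(gene_set.members)
    k = int(np.isin(genes, list(members)).sum())
    if k == 0:
        raise ValueError("gene set shares no genes with the catalog")

    traits = np.sort(pairs["trait"].unique())
    g_pos = pd.Series(np.arange(len(genes)), index=genes)
    t_pos = pd.Series(np.arange(len(traits)), index=traits)
    M = np.zeros((len(traits), len(genes)), dtype=np.float32)
    M[t_pos[pairs["trait"]].values, g_pos[pairs["mapped_gene"]].values] = 1.0

    set_mask = np.isin(genes, list(members))
    observed = M[:, set_mask].sum(axis=1).astype(int)

    rng = np.random.default_rng(seed)
    # each row of idx is one sampled gene set (without replacement)
    idx = rng.random((n_perm, len(genes))).argpartition(k - 1, axis=1)[:, :k]
    S = np.zeros((len(genes), n_perm), dtype=np.float32)
    S[idx.T, np.arange(n_perm)[None, :].repeat(k, axis=0)] = 1.0
    null_counts = M @ S  # traits x n_perm

    null_mean = null_counts.mean(axis=1)
    null_sd = null_counts.std(axis=1, ddof=1) if n_perm > 1 else np.zeros(len(traits))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)
    if p_mode == "normal":
        p = z_to_p(z)
    else:
        dev = np.abs(null_counts - null_mean[:, None])
        obs_dev = np.abs(observed - null_mean)
        p = (1.0 + (dev >= obs_dev[:, None] - 1e-12).sum(axis=1)) / (n_perm + 1.0)
        p = np.where(np.isnan(z), np.nan, p)
    q = bh_adjust(p)

    res = pd.DataFrame(
        {
            "trait": traits,
            "observed": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p": p,
            "q": q,
            "n_hits": observed,
        }
    )
    res.attrs["provenance"] = {
        "n_perm": n_perm,
        "seed": seed,
        "set_size_in_catalog": k,
        "n_catalog_genes": int(len(genes)),
        "p_mode": p_mode,
    }
    return res


def report_traits(
    results: pd.DataFrame, min_hits: int = 5, z_cut: float = 2.0
) -> pd.DataFrame:
    """Reportable traits: observed >= min_hits and |z| > z_cut, by |z| descending."""
    keep = (results["observed"] >= min_hits) & (results["z"].abs() > z_cut)
    keep &= results["z"].notna()
    out = results[keep].copy()
    return out.reindex(out["z"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
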