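"""PheWAS phenotype-category resampling enrichment, per cohort.

For each cohort table the observed statistic is the distribution of
phenotype categories among significant associations involving the focal gene
set.  The null resamples the same number of association rows from the
cohort's full significant-association pool and recomputes the category
proportions; z, p and BH-q follow the same conventions as the GWAS trait
enrichment.  Cohorts are processed independently.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geneset import GeneSet
from .stats import bh_adjust, z_to_p

RESULT_COLUMNS = (
    "dataset_id",
    "category",
    "observed_prop",
    "null_mean",
    "null_sd",
    "z",
    "p",
    "q",
    "n_hits",
)


def phewas_enrichment(
    table: pd.DataFrame,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Category-proportion resampling enrichment within each dataset.

    The resampling unit is the significant association row (one deduplicated
    (phenotype, gene) pair); each permutation draws, without replacement, as
    many rows from the dataset's full pool as the observed set-gene rows.
    Datasets without any set-gene association are skipped with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = set(gene_set.members)
    rng = np.random.default_rng(seed)
    frames = []
    # deterministic per-dataset streams, independent of iteration order
    dataset_ids = np.sort(table["dataset_id"].unique())
    streams = {d: np.random.default_rng(s) for d, s in
               zip(dataset_ids, rng.integers(0, 2**31, size=len(dataset_ids)))}
    for dataset in dataset_ids:
        sub = table[table["dataset_id"] == dataset]
        pool = (
            sub[sub["significant"].astype(bool)]
            .drop_duplicates(subset=["phenotype", "gene"])
            .reset_index(drop=True)
        )
        obs_rows = pool[pool["gene"].isin(members)]
        m = len(obs_rows)
        if m == 0:
            warnings.warn(
                f"dataset {dataset}: no significant set-gene associations; skipped"
            )
            continue
        categories = np.sort(pool["category"].unique())
        c_pos = pd.Series(np.arange(len(categories)), index=categories)
        obs_counts = np.bincount(
            c_pos[obs_rows["category"]].values, minlength=len(categories)
        )
        observed_prop = obs_counts / m

        codes = c_pos[pool["category"]].values
        drng = streams[dataset]
        null_props = np.empty((n_perm, len(categories)))
        n = len(pool)
        for b in range(n_perm):
            draw = drng.choice(n, size=m, replace=False)
            null_props[b] = np.bincount(codes[draw], minlength=len(categories)) / m

        null_mean = null_props.mean(axis=0)
        null_sd = (
            null_props.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(len(categories))
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(null_sd > 0, (observed_prop - null_mean) / null_sd, np.nan)
        p = z_to_p(z)
        q = bh_adjust(p)
        frames.append(
            pd.DataFrame(
                {
                    "dataset_id": dataset,
                    "category": categories,
                    "observed_prop": observed_prop,
                    "null_mean": null_mean,
                    "null_sd": null_sd,
                    "z": z,
                    "p": p,
                    "q": q,
                    "n_hits": obs_counts,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=list(RESULT_COLUMNS))
    res = pd.concat(frames, ignore_index=True)
    res.attrs["provenance"] = {
        "n_perm": n_perm,
        "seed": seed,
        "resampling_unit": "association_row",
    }
    return res


def report_categories(
    results: pd.DataFrame, min_hits: int = 5, z_cut: float = 2.0
) -> pd.DataFrame:
    """Reportable categories: n_hits >= min_hits and |z| > z_cut, by |z| descending."""
    keep = (results["n_hits"] >= min_hits) & (results["z"].abs() > z_cut)
    keep &= results["z"].notna()
    out = results[keep].copy()
    return out.reindex(out["z"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
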