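"""Targeted sgRNA library design and representation QC.

The library comprises two sets (SET1, SET2) that target the same gene list
at different sites: per set, one guide per gene plus non-targeting controls
and safe-harbor-locus guides.  Representation QC reports the Pearson
correlation between two aligned count vectors (e.g. oligo pool vs cloned
plasmid pool) and the 90th/10th percentile count ratio, with six-fold as the
minimum acceptable distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geneset import GeneSet

SET_IDS = ("SET1", "SET2")
SAFE_HARBOR_SITES = ("SH_SITE_1", "SH_SITE_2")
#: Maximum acceptable 90th/10th percentile count ratio.
RATIO_CRITERION = 6.0

_BASES = np.array(list("ACGT"))


@dataclass
class LibraryQCReport:
    """Representation QC of a guide count vector (optionally vs a second pool)."""

    pearson_r: float | None
    p10: float
    p90: float
    p90_p10_ratio: float
    passes_ratio_criterion: bool
    p10_floored: bool
    summary: dict = field(default_factory=dict)
    curve: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "pearson_r": self.pearson_r,
            "p10": self.p10,
            "p90": self.p90,
            "p90_p10_ratio": self.p90_p10_ratio,
            "passes_ratio_criterion": self.passes_ratio_criterion,
            "p10_floored": self.p10_floored,
        }
        d.update(self.summary)
        return d


def _unique_sequences(n: int, rng: np.random.Generator) -> list[str]:
    """n distinct random 20-mers over ACGT, by rejection."""
    if n > 4**20:
        raise ValueError(f"cannot draw {n} unique 20-mers")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = _BASES[rng.integers(0, 4, size=(n - len(out), 20))]
        for row in batch:
            s = "".join(row)
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def design_library(
    gene_set: GeneSet,
    n_ntc: int = 100,
    n_safeharbor: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Design the two-set manifest for a gene set.

    Each set carries one targeting guide per gene, ``n_ntc`` non-targeting
    controls and ``n_safeharbor`` guides against the two safe-harbor sites
    (alternating).  Sequences are synthetic unique 20-mers; the two sets
    share the gene list but no sequences.
    """
    if n_ntc < 0 or n_safeharbor < 0:
        raise ValueError("control counts must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(gene_set.members)
    per_set = len(genes) + n_ntc + n_safeharbor
    seqs = iter(_unique_sequences(2 * per_set, rng))

    rows = []
    for set_id in SET_IDS:
        for g in genes:
            rows.append((f"{set_id}:{g}", set_id, "targeting", g, next(seqs)))
        for i in range(n_ntc):
            rows.append((f"{set_id}:NTC{i + 1:04d}", set_id, "non_targeting", None, next(seqs)))
        for i in range(n_safeharbor):
            site = SAFE_HARBOR_SITES[i % len(SAFE_HARBOR_SITES)]
            rows.append((f"{set_id}:SH{i + 1:02d}", set_id, "safe_harbor", site, next(seqs)))
    manifest = pd.DataFrame(
        rows, columns=["guide_id", "set_id", "target_class", "target_gene", "sequence"]
    )
    manifest.attrs["provenance"] = {
        "gene_set": gene_set.name,
        "n_genes": len(genes),
        "n_ntc": n_ntc,
        "n_safeharbor": n_safeharbor,
        "seed": seed,
    }
    return manifest


def representation_qc(
    counts_a: pd.Series,
    counts_b: pd.Series | None = None,
    log1p_pearson: bool = False,
) -> LibraryQCReport:
    """Compute representation QC for a per-guide count vector.

    ``pearson_r`` compares ``counts_a`` and ``counts_b`` aligned on guide id
    (raw counts by default; ``log1p_pearson`` transforms both first).
    Percentiles of ``counts_a`` use linear interpolation between order
    statistics; a zero 10th percentile is floored at 1 pseudocount to keep
    the ratio finite (flagged in the report).  The cumulative curve gives the
    fraction of reads carried by the bottom x fraction of guides.
    """
    if len(counts_a) == 0:
        raise ValueError("counts_a is empty")
    pearson_r = None
    if counts_b is not None:
        if not counts_a.index.equals(counts_b.index):
            only_a = sorted(set(counts_a.index) - set(counts_b.index))
            only_b = sorted(set(counts_b.index) - set(counts_a.index))
            if only_a or only_b:
                raise ValueError(
                    f"guide ids misaligned; only in a: {only_a[:10]}, "
                    f"only in b: {only_b[:10]}"
                )
            counts_b = counts_b.reindex(counts_a.index)
        a, b = counts_a.values.astype(float), counts_b.values.astype(float)
        if log1p_pearson:
            a, b = np.log1p(a), np.log1p(b)
        pearson_r = float(sps.pearsonr(a, b).statistic)

    x = counts_a.values.astype(float)
    p10, p90 = np.percentile(x, [10, 90])  # linear interpolation
    floored = p10 == 0
    ratio = float(p90 / max(p10, 1.0)) if floored else float(p90 / p10)

    order = np.sort(x)
    total = order.sum()
    curve = pd.DataFrame(
        {
            "frac_guides": np.arange(1, len(order) + 1) / len(order),
            "frac_reads": np.cumsum(order) / total if total > 0 else 0.0,
        }
    )
    return LibraryQCReport(
        pearson_r=pearson_r,
        p10=float(p10),
        p90=float(p90),
        p90_p10_ratio=ratio,
        passes_ratio_criterion=bool(ratio <= RATIO_CRITERION),
        p10_floored=bool(floored),
        summary={
            "n_guides": int(len(x)),
            "total_reads": float(total),
            "mean": float(x.mean()),
            "median": float(np.median(x)),
            "frac_zero": float((x == 0).mean()),
        },
        curve=curve,
    )
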