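"""Construction and characterization of a common loss-of-function gene set.

A gene enters the set when the aggregate mean allele frequency (MAF) of its
predicted loss-of-function (pLoF) variants exceeds a threshold (default 0.1%),
provided the gene is protein-coding and not misannotated.  The module also
classifies Ensembl consequence terms into LoF / non-LoF and compares the
consequence-term composition of catalog associations inside versus outside
the set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ensembl consequence terms treated as loss-of-function.
LOF_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)

#: Required columns of a gene-level table (TSV; intervals 0-based half-open).
GENE_TABLE_COLUMNS = (
    "symbol",
    "chrom",
    "start",
    "end",
    "strand",
    "plof_maf",
    "coding",
    "misannotated",
)


@dataclass
class GeneSet:
    """A named, ordered set of gene symbols with filter provenance."""

    name: str
    members: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.members)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            dups = pd.Series(self.members).value_counts()
            dups = dups[dups > 1].index.tolist()
            raise ValueError(f"duplicate gene symbols in set: {dups}")


@dataclass(frozen=True)
class ConsequenceClass:
    """A consequence term and whether it is loss-of-function."""

    term: str
    is_lof: bool


def validate_gene_table(gene_table: pd.DataFrame) -> None:
    """Check symbol uniqueness and MAF domain; raise ``ValueError`` naming offenders."""
    dup = gene_table["symbol"][gene_table["symbol"].duplicated()]
    if len(dup):
        raise ValueError(
            f"duplicate gene symbols: {sorted(dup.unique().tolist())}"
        )
    maf = pd.to_numeric(gene_table["plof_maf"], errors="coerce")
    bad = gene_table["symbol"][maf.isna() | (maf < 0) | (maf > 1)]
    if len(bad):
        raise ValueError(
            f"aggregate pLoF MAF outside [0, 1] for: {sorted(bad.tolist())}"
        )


def build_lof_geneset(
    gene_table: pd.DataFrame,
    maf_threshold: float = 0.001,
    name: str = "common_lof",
) -> GeneSet:
    """Filter a gene-level aggregate pLoF MAF table into a common-LoF gene set.

    Keeps genes with ``plof_maf`` strictly greater than ``maf_threshold`` that
    are coding and not misannotated.  Drop accounting uses the precedence
    misannotated -> non-coding -> MAF, so the three drop counts are disjoint
    and sum with the output size to the input size.

    Parameters
    ----------
    gene_table
        One row per gene with columns :data:`GENE_TABLE_COLUMNS`.
    maf_threshold
        Aggregate pLoF MAF cutoff as a fraction (0.001 means 0.1%); the
        comparison is strict.
    name
        Name recorded on the resulting :class:`GeneSet`.
    """
    if not 0 <= maf_threshold < 1:
        raise ValueError(f"maf_threshold must be in [0, 1): {maf_threshold}")
    if len(gene_table) == 0:
        return GeneSet(
            name=name,
            members=[],
            provenance={
                "maf_threshold": maf_threshold,
                "n_input": 0,
                "dropped_misannotated": 0,
                "dropped_noncoding": 0,
                "dropped_maf": 0,
            },
        )
    validate_gene_table(gene_table)

    mis = gene_table["misannotated"].astype(bool)
    noncoding = ~gene_table["coding"].astype(bool) & ~mis
    below = (
        ~(gene_table["plof_maf"].astype(float) > maf_threshold) & ~mis & ~noncoding
    )
    keep = ~(mis | noncoding | below)
    return GeneSet(
        name=name,
        members=gene_table.loc[keep, "symbol"].tolist(),
        provenance={
            "maf_threshold": maf_threshold,
            "n_input": int(len(gene_table)),
            "dropped_misannotated": int(mis.sum()),
            "dropped_noncoding": int(noncoding.sum()),
            "dropped_maf": int(below.sum()),
        },
    )


def classify_consequence(term: str) -> ConsequenceClass:
    """Classify an Ensembl consequence term as LoF or non-LoF.

    Matching is case-insensitive on the whitespace-trimmed term.  Unknown
    terms classify as non-LoF (real catalogs carry novel terms); the empty
    string is rejected.
    """
    if not term or not term.strip():
        raise ValueError("consequence term must be non-empty")
    return ConsequenceClass(term=term, is_lof=term.strip().lower() in LOF_TERMS)


def classify_consequences(terms: pd.Series) -> tuple[pd.Series, int]:
    """Vectorized LoF classification.

    Returns the boolean LoF mask and the number of terms outside the known
    Ensembl vocabulary used here (they classify as non-LoF).
    """
    norm = terms.astype(str).str.strip().str.lower()
    is_lof = norm.isin(LOF_TERMS)
    known_non_lof = {
        "missense_variant",
        "synonymous_variant",
        "intron_variant",
        "intergenic_variant",
        "3_prime_utr_variant",
        "5_prime_utr_variant",
        "regulatory_region_variant",
        "non_coding_transcript_exon_variant",
        "inframe_deletion",
        "inframe_insertion",
        "splice_region_variant",
        "start_lost",
        "stop_lost",
        "tf_binding_site_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
    }
    n_unknown = int((~is_lof & ~norm.isin(known_non_lof)).sum())
    return is_lof, n_unknown


def consequence_frequency_diff(
    catalog: pd.DataFrame, gene_set: GeneSet
) -> pd.DataFrame:
    """Percent difference of consequence-term frequencies inside vs outside a set.

    For each term ``t`` appearing in ``catalog`` (columns ``mapped_gene`` and
    ``consequence``), computes the share ``f_in`` of term ``t`` among
    associations to set members and ``f_out`` among associations to
    non-members, and reports ``100 * (f_in - f_out) / f_out``.  A term never
    seen outside the set has an undefined difference: ``pct_diff`` is NaN and
    ``undefined`` is True.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    members = set(gene_set.members)
    in_set = catalog["mapped_gene"].isin(members)
    f_in = catalog.loc[in_set, "consequence"].value_counts(normalize=True)
    f_out = catalog.loc[~in_set, "consequence"].value_counts(normalize=True)
    terms = sorted(set(f_in.index) | set(f_out.index))
    rows = []
    for t in terms:
        fi = float(f_in.get(t, 0.0))
        fo = float(f_out.get(t, 0.0))
        undefined = fo == 0.0
        rows.append(
            {
                "consequence": t,
                "f_in": fi,
                "f_out": fo,
                "pct_diff": math.nan if undefined else 100.0 * (fi - fo) / fo,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)
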