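"""Readers and writers for the pipeline's tabular and sequence formats.

All tables are plain text: gene tables and catalogs as TSV, gene intervals as
BED (0-based half-open), library manifests as CSV, gene sets as
one-symbol-per-line text with a YAML provenance sidecar, reads as 4-line
FASTQ.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .geneset import GENE_TABLE_COLUMNS, GeneSet

GWAS_COLUMNS = (
    "study_id",
    "snp_id",
    "chromosome",
    "position",
    "mapped_gene",
    "consequence",
    "mapped_trait",
    "disease_trait",
)

PHEWAS_COLUMNS = ("dataset_id", "phenotype", "category", "gene", "significant")

MANIFEST_COLUMNS = ("guide_id", "set_id", "target_class", "target_gene", "sequence")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} missing columns: {sorted(missing)}")
    return df


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED4 interval file into columns chrom/start/end/symbol."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "symbol"],
        dtype={"chrom": str, "symbol": str},
    )
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"malformed intervals (start >= end): {bad['symbol'].tolist()}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "symbol"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gene_set(path: str | Path) -> GeneSet:
    """Read a one-symbol-per-line gene set; loads a ``.provenance.yaml`` sidecar if present."""
    path = Path(path)
    members = [
        line.strip() for line in path.read_text().splitlines() if line.strip()
    ]
    sidecar = path.with_suffix(path.suffix + ".provenance.yaml")
    provenance = {}
    if sidecar.exists():
        provenance = yaml.safe_load(sidecar.read_text()) or {}
    return GeneSet(name=path.stem, members=members, provenance=provenance)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    path = Path(path)
    path.write_text("".join(f"{m}\n" for m in gene_set.members))
    sidecar = path.with_suffix(path.suffix + ".provenance.yaml")
    sidecar.write_text(yaml.safe_dump(gene_set.provenance, sort_keys=False))


def read_gwas_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(GWAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"GWAS catalog {path} missing columns: {sorted(missing)}")
    df["position"] = pd.to_numeric(df["position"])
    df = df.replace({"mapped_gene": {"": None}, "mapped_trait": {"": None}})
    return df


def write_gwas_catalog(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_phewas_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"dataset_id": str, "gene": str})
    missing = set(PHEWAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PheWAS table {path} missing columns: {sorted(missing)}")
    df["significant"] = df["significant"].astype(bool)
    return df


def write_phewas_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    df = df.replace({"target_gene": {"": None}})
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a guide x sample count matrix (TSV, first column guide_id)."""
    return pd.read_csv(path, sep="\t", index_col="guide_id")


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="guide_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample", "timepoint", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {sorted(missing)}")
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_fastq(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs as 4-line FASTQ with fixed quality 'I'."""
    with open(path, "w") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
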