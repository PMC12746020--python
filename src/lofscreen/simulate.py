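"""Synthetic inputs for every pipeline stage.

The generators emulate the tabular exports the real analyses consume: a
gene-level aggregate pLoF MAF table (gnomAD-style), a GWAS-catalog-style
association table, per-cohort PheWAS association tables, and a pooled CRISPR
dropout screen's count matrix (optionally as error-free FASTQ reads).  All
outputs are deterministic functions of a :class:`SimulationConfig` — the same
config and seed reproduce byte-identical files.

Count noise follows a negative binomial with variance mu + alpha * mu**2
(``dispersion`` = alpha; alpha = 0 degenerates to Poisson).  Spiked essential
genes deplete geometrically per population doubling, so a guide at ``d``
doublings with per-doubling retention ``r`` has expected log2 fold change
``d * log2(r)`` against baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

# rng stream tags so each generator draws independently of the others
_TAG_UNIVERSE, _TAG_GWAS, _TAG_PHEWAS, _TAG_SCREEN = 11, 23, 37, 53

NON_LOF_TERMS = (
    "missense_variant",
    "synonymous_variant",
    "intron_variant",
    "3_prime_UTR_variant",
    "5_prime_UTR_variant",
)
LOF_TERM_CHOICES = (
    "stop_gained",
    "frameshift_variant",
    "splice_donor_variant",
    "splice_acceptor_variant",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design the pipeline targets: a ~0.1% aggregate
    pLoF MAF cutoff, two guide sets with 100 non-targeting and 5 safe-harbor
    controls each, three baseline (T0) and four time-course samples per
    timepoint, sampled at 7 (T7) and 14 (T14) population doublings.
    """

    seed: int = 0

    # gene universe
    n_genes: int = 2000
    frac_set: float = 0.25
    frac_flagged: float = 0.0  # misannotated/non-coding fraction
    maf_threshold: float = 0.001
    n_chromosomes: int = 5
    chromosome_length: int | None = None

    # GWAS catalog
    n_traits: int = 200
    assoc_rate: float = 0.1  # per (trait, gene) association probability
    lof_fraction: float = 0.5
    frac_unmapped: float = 0.1  # rows emitted without a mapped gene
    frac_trait_unmapped: float = 0.05  # rows relying on the disease-trait fallback
    n_enriched_traits: int = 0
    enrichment_effect: float = 1.0

    # PheWAS tables
    n_datasets: int = 4
    n_phenotypes: int = 500
    n_categories: int = 10
    phewas_rate: float = 0.005
    n_enriched_categories: int = 0
    category_effect: float = 1.0

    # screen library & counts
    n_guides_per_gene: int = 1  # per set; two sets give two guides per gene
    n_ntc: int = 100
    n_safeharbor: int = 5
    baseline_mean: float = 500.0
    sigma_log: float = 0.5  # lognormal sd of baseline guide abundance
    dispersion: float = 0.05
    n_essential: int = 0
    depletion_per_doubling: float = 0.8
    doublings_per_timepoint: tuple[int, int] = (7, 14)  # (T7, T14)
    n_t0: int = 3
    n_t7: int = 4
    n_t14: int = 4
    library_size_multipliers: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.frac_set <= 1:
            raise ValueError("frac_set must be in [0, 1]")
        if not 0 <= self.frac_flagged <= 1:
            raise ValueError("frac_flagged must be in [0, 1]")
        if self.enrichment_effect < 1 or self.category_effect < 1:
            raise ValueError("enrichment effects are multipliers >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 < self.depletion_per_doubling <= 1:
            raise ValueError("depletion_per_doubling must be in (0, 1]")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.library_size_multipliers is not None:
            if any(m <= 0 for m in self.library_size_multipliers):
                raise ValueError("library size multipliers must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["doublings_per_timepoint"] = list(self.doublings_per_timepoint)
        if self.library_size_multipliers is not None:
            d["library_size_multipliers"] = list(self.library_size_multipliers)
        return d


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


def gen_gene_universe(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the gene-level aggregate pLoF MAF table and its BED intervals.

    Genes are packed left to right on synthetic chromosomes with random
    lengths and gaps (0-based half-open, non-overlapping).  A ``frac_set``
    fraction of genes receives an aggregate pLoF MAF above the threshold, the
    rest below; a ``frac_flagged`` fraction is flagged misannotated or
    non-coding (alternating), with above-threshold MAF so that the flag alone
    removes them.
    """
    rng = _rng(config, _TAG_UNIVERSE)
    n = config.n_genes
    symbols = np.array([f"G{i + 1:05d}" for i in range(n)])
    chroms = np.array([f"chr{(i % config.n_chromosomes) + 1}" for i in range(n)])
    lengths = rng.integers(1_000, 10_001, size=n)
    gaps = rng.integers(500, 5_001, size=n)

    start = np.zeros(n, dtype=np.int64)
    end = np.zeros(n, dtype=np.int64)
    cursor: dict[str, int] = {}
    for i in range(n):
        c = chroms[i]
        s = cursor.get(c, 0)
        start[i], end[i] = s, s + lengths[i]
        cursor[c] = end[i] + gaps[i]
    if config.chromosome_length is not None:
        over = max(cursor.values())
        if over > config.chromosome_length:
            raise ValueError(
                f"infeasible packing: need {over} bp > chromosome_length "
                f"{config.chromosome_length}"
            )

    n_flagged = int(round(config.frac_flagged * n))
    flagged = rng.choice(n, size=n_flagged, replace=False)
    misannotated = np.zeros(n, dtype=bool)
    coding = np.ones(n, dtype=bool)
    # alternate the two removal reasons among flagged genes
    misannotated[flagged[::2]] = True
    coding[flagged[1::2]] = False

    n_set = int(round(config.frac_set * n))
    unflagged = np.setdiff1d(np.arange(n), flagged)
    in_set = np.zeros(n, dtype=bool)
    if n_set > len(unflagged):
        in_set[unflagged] = True
        in_set[rng.choice(flagged, size=n_set - len(unflagged), replace=False)] = True
    else:
        in_set[rng.choice(unflagged, size=n_set, replace=False)] = True
    # flagged genes pass the MAF cut so the annotation flags drive their removal
    above = in_set | misannotated | ~coding
    thr = config.maf_threshold
    maf = np.where(
        above,
        np.exp(rng.uniform(np.log(thr * 1.1), np.log(0.05), size=n)),
        np.exp(rng.uniform(np.log(1e-5), np.log(thr * 0.9), size=n)) if thr > 0
        else 0.0,
    )

    table = pd.DataFrame(
        {
            "symbol": symbols,
            "chrom": chroms,
            "start": start,
            "end": end,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
            "plof_maf": maf,
            "coding": coding,
            "misannotated": misannotated,
        }
    )
    bed = table[["chrom", "start", "end", "symbol"]].copy()
    return table, bed


def _set_mask(universe: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    return (
        (universe["plof_maf"].values > config.maf_threshold)
        & universe["coding"].values
        & ~universe["misannotated"].values
    )


def gen_gwas_catalog(
    universe: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Generate a GWAS-catalog-style association table over the gene universe.

    Each (trait, gene) pair associates independently with probability
    ``assoc_rate``, multiplied by ``enrichment_effect`` for the first
    ``n_enriched_traits`` traits when the gene belongs to the focal set.  SNP
    positions fall inside the gene interval (intragenic); a ``frac_unmapped``
    fraction of rows is emitted without the mapped gene to exercise
    nearest-gene assignment, and a ``frac_trait_unmapped`` fraction without
    the mapped trait to exercise the disease-trait fallback.
    """
    rng = _rng(config, _TAG_GWAS)
    in_set = _set_mask(universe, config)
    n_genes = len(universe)
    traits = [f"Trait{j + 1:04d}" for j in range(config.n_traits)]
    enriched = np.zeros(config.n_traits, dtype=bool)
    enriched[: config.n_enriched_traits] = True

    rate = np.full((config.n_traits, n_genes), config.assoc_rate)
    rate[np.ix_(enriched, in_set)] *= config.enrichment_effect
    hits = rng.random(rate.shape) < np.minimum(rate, 1.0)
    t_idx, g_idx = np.nonzero(hits)
    m = len(t_idx)

    starts = universe["start"].values[g_idx]
    ends = universe["end"].values[g_idx]
    pos = rng.integers(starts, ends)
    is_lof = rng.random(m) < config.lof_fraction
    cons = np.where(
        is_lof,
        rng.choice(LOF_TERM_CHOICES, size=m),
        rng.choice(NON_LOF_TERMS, size=m),
    )
    unmapped = rng.random(m) < config.frac_unmapped
    trait_unmapped = rng.random(m) < config.frac_trait_unmapped
    trait_names = np.array(traits, dtype=object)[t_idx]

    return pd.DataFrame(
        {
            "study_id": [f"S{j // 2 + 1:04d}" for j in t_idx],
            "snp_id": [f"rs{i + 1:07d}" for i in range(m)],
            "chromosome": universe["chrom"].values[g_idx],
            "position": pos,
            "mapped_gene": np.where(
                unmapped, None, universe["symbol"].values[g_idx]
            ),
            "consequence": cons,
            "mapped_trait": np.where(trait_unmapped, None, trait_names),
            "disease_trait": trait_names,
        }
    )


def gen_phewas_table(
    universe: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Generate per-cohort PheWAS significant-association tables.

    Phenotypes are spread round-robin over categories.  Each (phenotype,
    gene) pair associates with probability ``phewas_rate``, multiplied by
    ``category_effect`` for set genes in the first ``n_enriched_categories``
    categories.  Every emitted row is flagged significant (the generator
    stands in for upstream significance thresholding).
    """
    rng = _rng(config, _TAG_PHEWAS)
    in_set = _set_mask(universe, config)
    n_genes = len(universe)
    cats = np.array(
        [f"CAT{(j % config.n_categories) + 1:02d}" for j in range(config.n_phenotypes)]
    )
    cat_enriched = np.array(
        [
            int(c[3:]) <= config.n_enriched_categories
            for c in cats
        ]
    )
    frames = []
    for d in range(config.n_datasets):
        rate = np.full((config.n_phenotypes, n_genes), config.phewas_rate)
        rate[np.ix_(cat_enriched, in_set)] *= config.category_effect
        hits = rng.random(rate.shape) < np.minimum(rate, 1.0)
        p_idx, g_idx = np.nonzero(hits)
        frames.append(
            pd.DataFrame(
                {
                    "dataset_id": f"COHORT{d + 1}",
                    "phenotype": [f"P{j + 1:04d}" for j in p_idx],
                    "category": cats[p_idx],
                    "gene": universe["symbol"].values[g_idx],
                    "significant": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def screen_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Sample layout: n_t0 baseline, n_t7 and n_t14 time-course samples."""
    rows = []
    for tp, n_rep in (("T0", config.n_t0), ("T7", config.n_t7), ("T14", config.n_t14)):
        for r in range(1, n_rep + 1):
            rows.append({"sample": f"{tp}_r{r}", "timepoint": tp, "replicate": str(r)})
    return pd.DataFrame(rows)


def gen_screen_counts(
    manifest: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the guide x sample count matrix of a dropout screen.

    Baseline guide abundances are lognormal around ``baseline_mean``
    (log-scale sd ``sigma_log``).  Counts are negative binomial with mean
    ``multiplier_s * abundance_g * depletion_{g,s}`` and dispersion alpha;
    guides targeting a spiked essential gene deplete by
    ``depletion_per_doubling ** doublings``; non-targeting and safe-harbor
    guides never deplete.

    Returns (counts, sample_sheet, truth) where ``truth`` records the
    essential genes, abundances and size multipliers used.
    """
    required = {"guide_id", "target_class", "target_gene"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest missing columns: {sorted(required - set(manifest.columns))}")
    rng = _rng(config, _TAG_SCREEN)
    sheet = screen_sample_sheet(config)
    n_samples = len(sheet)
    mult = (
        np.ones(n_samples)
        if config.library_size_multipliers is None
        else np.asarray(config.library_size_multipliers, dtype=float)
    )
    if len(mult) != n_samples:
        raise ValueError(
            f"library_size_multipliers has {len(mult)} entries for {n_samples} samples"
        )

    n_guides = len(manifest)
    abundance = config.baseline_mean * np.exp(
        config.sigma_log * rng.standard_normal(n_guides)
    )

    target_genes = manifest.loc[
        manifest["target_class"] == "targeting", "target_gene"
    ].unique()
    if config.n_essential > len(target_genes):
        raise ValueError(
            f"n_essential={config.n_essential} exceeds {len(target_genes)} targeted genes"
        )
    essential = set(rng.choice(target_genes, size=config.n_essential, replace=False))
    guide_essential = (
        manifest["target_gene"].isin(essential)
        & (manifest["target_class"] == "targeting")
    ).values

    d7, d14 = config.doublings_per_timepoint
    doublings = sheet["timepoint"].map({"T0": 0, "T7": d7, "T14": d14}).values
    depl = np.where(
        guide_essential[:, None],
        config.depletion_per_doubling ** doublings[None, :],
        1.0,
    )
    mu = mult[None, :] * abundance[:, None] * depl
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    counts_df = pd.DataFrame(
        counts, index=pd.Index(manifest["guide_id"], name="guide_id"),
        columns=sheet["sample"].tolist(),
    )
    truth = {
        "essential_genes": sorted(essential),
        "abundance": pd.Series(abundance, index=counts_df.index),
        "multipliers": dict(zip(sheet["sample"], mult)),
    }
    return counts_df, sheet, truth


#: Fixed flanks around the guide 20-mer in emitted reads (vector homology arms).
READ_PREFIX = "ACCG"
READ_SUFFIX = "GTTT"


def screen_fastq_records(
    counts: pd.Series, manifest: pd.DataFrame
) -> list[tuple[str, str]]:
    """Expand one sample's counts into error-free (read_id, sequence) records.

    Each guide's 20-mer appears verbatim, flanked by fixed vector sequence,
    exactly ``counts[guide]`` times, so exact-match counting inverts the
    expansion.
    """
    seq_of = dict(zip(manifest["guide_id"], manifest["sequence"]))
    records = []
    i = 0
    for gid, k in counts.items():
        seq = READ_PREFIX + seq_of[gid] + READ_SUFFIX
        for _ in range(int(k)):
            i += 1
            records.append((f"read{i:08d}", seq))
    return records
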