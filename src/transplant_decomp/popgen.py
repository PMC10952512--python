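"""Population-genetic signals around the expression analysis.

Per-site divergence between the two populations of an ecotype pair is
measured with the Hudson estimator of FST in the sample-size-corrected form
of Bhatia et al.:

    N_hat = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D_hat = p1(1-p2) + p2(1-p1)
    fst   = N_hat / D_hat

with p the alt-allele frequency and n the number of sampled alleles (twice
the genotyped diploids).  Sites in the top 5% of the per-site distribution
are divergence outliers; a gene carries the signal when at least one of its
sites is an outlier.  Private alleles — present in exactly one population and
absent in all others — and their minor-allele frequencies serve as an
ancestry proxy across populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix
from .overlap import OverlapTest, overlap_test

__all__ = [
    "site_fst",
    "hudson_fst_ratio",
    "assign_sites_to_genes",
    "fst_outlier_genes",
    "de_fst_overlap",
    "private_alleles",
    "maf_summary",
    "PrivateAlleleReport",
]


def _allele_stats(dosage: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt-allele frequency, sampled-allele count) per site for one population."""
    d = dosage[:, cols].astype(float)
    obs = d >= 0
    n = 2.0 * obs.sum(axis=1)
    alt = np.where(obs, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, np.nan)
    return p, n


def site_fst(
    geno: GenotypeMatrix, pop_a: str, pop_b: str, min_alleles: int = 4
) -> pd.DataFrame:
    """Per-site Hudson/Bhatia FST between two populations.

    Sites where either population has fewer than ``min_alleles`` non-missing
    alleles are skipped.  ``fst`` is NaN when the denominator is 0 (both
    populations fixed for the same allele); a fixed difference gives exactly 1
    regardless of sample sizes.

    Returns a DataFrame with site keys plus p1, p2, n1, n2, numerator,
    denominator, fst.
    """
    ca = geno.population_columns(pop_a)
    cb = geno.population_columns(pop_b)
    p1, n1 = _allele_stats(geno.dosage, ca)
    p2, n2 = _allele_stats(geno.dosage, cb)

    keep = (n1 >= min_alleles) & (n2 >= min_alleles)
    p1, p2, n1, n2 = p1[keep], p2[keep], n1[keep], n2[keep]

    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / den, np.nan)

    out = geno.sites.loc[keep].reset_index(drop=True).copy()
    out["p1"], out["p2"], out["n1"], out["n2"] = p1, p2, n1, n2
    out["numerator"], out["denominator"], out["fst"] = num, den, fst
    return out


def hudson_fst_ratio(fst_table: pd.DataFrame) -> float:
    """Ratio-of-averages estimator sum(N_hat)/sum(D_hat) over all usable sites."""
    ok = fst_table["denominator"] > 0
    den = fst_table.loc[ok, "denominator"].sum()
    if den == 0:
        return float("nan")
    return float(fst_table.loc[ok, "numerator"].sum() / den)


def assign_sites_to_genes(sites: pd.DataFrame, gene_map: pd.DataFrame) -> pd.Series:
    """Gene id per site (1-based inclusive interval containment), NaN outside genes.

    Overlapping genes are allowed; a site in several genes is assigned to each
    via the companion :func:`_site_gene_pairs`; this convenience picks the
    first by gene_id order.
    """
    pairs = _site_gene_pairs(sites, gene_map)
    first = pairs.sort_values("gene_id").drop_duplicates("site_idx").set_index("site_idx")
    out = pd.Series(np.nan, index=sites.index, dtype=object)
    out.loc[first.index] = first["gene_id"]
    return out


def _site_gene_pairs(sites: pd.DataFrame, gene_map: pd.DataFrame) -> pd.DataFrame:
    """All (site index, gene_id) containment pairs."""
    rows = []
    for chrom, genes in gene_map.groupby("chrom"):
        sub = sites[sites["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].values
        order = np.argsort(pos, kind="mergesort")
        sorted_pos = pos[order]
        idx = sub.index.values[order]
        for gene_id, start, end in zip(genes["gene_id"], genes["start"], genes["end"]):
            lo = np.searchsorted(sorted_pos, start, side="left")
            hi = np.searchsorted(sorted_pos, end, side="right")
            for i in idx[lo:hi]:
                rows.append((i, gene_id))
    return pd.DataFrame(rows, columns=["site_idx", "gene_id"])


def fst_outlier_genes(
    fst_table: pd.DataFrame, gene_map: pd.DataFrame, quantile: float = 0.95
) -> tuple[set[str], float]:
    """Genes carrying at least one site in the top tail of the FST distribution.

    The threshold is the empirical ``quantile`` (linear interpolation) of all
    defined per-site fst values — including negative ones and sites outside
    genes, which shape the distribution but cannot mark a gene.  Carriage uses
    fst >= threshold.
    """
    if not (0 < quantile < 1):
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    defined = fst_table["fst"].dropna()
    if len(defined) < 20:
        raise ValueError(f"need >= 20 sites with defined fst, got {len(defined)}")
    threshold = float(np.quantile(defined.values, quantile))

    pairs = _site_gene_pairs(fst_table, gene_map)
    if pairs.empty:
        return set(), threshold
    fst_per_pair = fst_table.loc[pairs["site_idx"], "fst"].values
    carriers = set(pairs.loc[fst_per_pair >= threshold, "gene_id"])
    return carriers, threshold


def de_fst_overlap(
    de_genes, carriers, universe, fst_table: pd.DataFrame | None = None,
    gene_map: pd.DataFrame | None = None,
) -> tuple[OverlapTest, pd.DataFrame]:
    """Overlap test between DE genes and outlier-carrier genes.

    Returns the test plus the joint gene list annotated with each gene's
    maximum per-site fst (when a site table and gene map are supplied).
    """
    test = overlap_test(de_genes, carriers, universe)
    joint = pd.DataFrame({"gene_id": test.intersection})
    if fst_table is not None and gene_map is not None and not joint.empty:
        pairs = _site_gene_pairs(fst_table, gene_map)
        pairs["fst"] = fst_table.loc[pairs["site_idx"], "fst"].values
        max_fst = pairs.groupby("gene_id")["fst"].max()
        joint["max_site_fst"] = max_fst.reindex(joint["gene_id"]).values
    return test, joint


@dataclass
class PrivateAlleleReport:
    """Private-allele counts and minor-allele frequencies per population."""

    table: pd.DataFrame  # population, n_private, n_samples, normalized, mean_maf
    site_maf: dict[str, np.ndarray]  # population -> MAF of each private site

    def normalized(self, population: str) -> float:
        row = self.table.set_index("population").loc[population]
        return float(row["normalized"])


def private_alleles(
    geno: GenotypeMatrix, max_missing: float = 0.0, min_carrier_dosage_sum: int = 1
) -> PrivateAlleleReport:
    """Detect alleles present in exactly one population and absent elsewhere.

    Sites whose overall fraction of missing genotypes exceeds ``max_missing``
    are excluded first (default 0: no missing data allowed).  At a kept site,
    an allele (ref or alt) is private to population P when its allele count is
    at least ``min_carrier_dosage_sum`` in P and zero in every other
    population.  Counts are normalized by the number of samples per
    population; the MAF of a private site is the minor-allele frequency
    within the carrier population.
    """
    pops = geno.population_labels()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    cols = {p: geno.population_columns(p) for p in pops}
    n_samples = {p: len(c) for p, c in cols.items()}

    labeled = np.concatenate(list(cols.values()))
    miss_frac = (geno.dosage[:, labeled] < 0).mean(axis=1) if len(labeled) else np.array([])
    keep = miss_frac <= max_missing

    alt_count, ref_count, freq_alt = {}, {}, {}
    for p in pops:
        pf, n = _allele_stats(geno.dosage, cols[p])
        alt = np.where(np.isnan(pf), 0.0, pf * n)
        ref = np.where(np.isnan(pf), 0.0, (1 - pf) * n)
        alt_count[p], ref_count[p], freq_alt[p] = alt, ref, pf

    rows, site_maf = [], {}
    for p in pops:
        others = [q for q in pops if q != p]
        alt_private = (
            (alt_count[p] >= min_carrier_dosage_sum)
            & np.all([alt_count[q] == 0 for q in others], axis=0)
        )
        ref_private = (
            (ref_count[p] >= min_carrier_dosage_sum)
            & np.all([ref_count[q] == 0 for q in others], axis=0)
        )
        private = keep & (alt_private | ref_private)
        pf = freq_alt[p][private]
        maf = np.minimum(pf, 1 - pf)
        site_maf[p] = maf
        rows.append(
            (
                p,
                int(private.sum()),
                n_samples[p],
                private.sum() / n_samples[p],
                float(np.mean(maf)) if len(maf) else float("nan"),
            )
        )
    table = pd.DataFrame(
        rows, columns=["population", "n_private", "n_samples", "normalized", "mean_maf"]
    )
    return PrivateAlleleReport(table, site_maf)


def maf_summary(report: PrivateAlleleReport) -> pd.DataFrame:
    """Mean and sd of private-site MAF per population (NaN when none)."""
    rows = []
    for p, maf in report.site_maf.items():
        if len(maf):
            rows.append((p, float(np.mean(maf)), float(np.std(maf, ddof=1)) if len(maf) > 1 else 0.0))
        else:
            rows.append((p, float("nan"), float("nan")))
    return pd.DataFrame(rows, columns=["population", "mean_maf", "sd_maf"])
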