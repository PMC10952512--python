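"""Synthetic reciprocal-transplant data with known ground truth.

The generator emulates the statistical structure the analysis assumes, at
the design of the field experiment it models: two ecotype pairs x two
ecotypes x two growing environments with five biological replicates per cell,
except the montane-ecotype-in-alpine-environment cell of pair 3 which has
only two survivors.  Counts are negative binomial around planted group means
(constitutive ecotype differences, ecotype-specific plastic responses, or
null); genotypes follow a Balding-Nichols divergence model with planted
high-FST outlier sites and population-private alleles; annotations form a
random term DAG with planted enriched terms.  Every planted quantity is
returned in a :class:`SimTruth` so recovery can be scored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import AnnotationMap, CountMatrix, GenotypeMatrix, SampleDesign

__all__ = ["SimConfig", "SimTruth", "simulate_counts", "simulate_genotypes",
           "simulate_annotation", "make_gene_map", "balding_nichols_genotypes"]

# sub-stream keys so each generator's draws are independent of the others
_STREAM_COUNTS = 1
_STREAM_GENOTYPES = 2
_STREAM_ANNOTATION = 3


@dataclass
class SimConfig:
    """Parameters of the synthetic world.

    Defaults mirror the modeled experiment: 16000 genes, 5 replicates per
    (pair, ecotype, environment) cell with the (pair 3, montane ecotype,
    alpine environment) cell reduced to 2; effect genes are rare (2%
    constitutive, 3% plastic in the montane ecotype, 1% in the alpine — the
    montane-biased plasticity the experiment observed) with |log2FC| drawn
    from N(1.5, 0.5); genotypes carry 5% FST outlier sites (F=0.6 against a
    background F=0.1) and twice as many alpine-private as montane-private
    sites.
    """

    n_genes: int = 16000
    replicates: dict = field(default_factory=lambda: {("3", "montane", "alpine"): 2})
    default_replicates: int = 5
    library_size_range: tuple[float, float] = (5e5, 1.5e6)
    baseline_log2_mean: tuple[float, float] = (5.0, 2.0)  # normal(mean, sd)
    dispersion_range: tuple[float, float] = (0.05, 0.5)  # log-uniform
    frac_constitutive: float = 0.02
    frac_plastic_montane: float = 0.03
    frac_plastic_alpine: float = 0.01
    effect_log2fc: tuple[float, float] = (1.5, 0.5)  # |delta| ~ normal(mean, sd)
    n_sites: int = 20000
    sites_per_gene: float = 2.0  # Poisson rate
    fst_background: float = 0.1
    fst_outlier: float = 0.6
    frac_outlier_sites: float = 0.05
    outlier_gene_pool: str = "constitutive"  # or "random"
    n_outlier_genes: int = 100  # outlier sites cluster in this many genes (sweep-like)
    n_private_sites_montane: int = 250  # per pair; alpine gets the rate below
    private_allele_rate_alpine: float = 2.0
    genotype_samples: dict = field(
        default_factory=lambda: {
            ("1", "montane"): 10, ("1", "alpine"): 10,
            ("3", "montane"): 7, ("3", "alpine"): 10,
        }
    )
    n_terms: int = 300
    annotation_rate: float = 0.02
    n_planted_terms: int = 10
    planted_term_size: int = 30
    planted_term_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.frac_constitutive + self.frac_plastic_montane + self.frac_plastic_alpine
        for name in ("frac_constitutive", "frac_plastic_montane", "frac_plastic_alpine"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if fr > 1:
            raise ValueError(f"effect fractions sum to {fr} > 1; a gene gets one category")
        reps = dict(self.replicates)
        if self.default_replicates < 2 or any(v < 2 for v in reps.values()):
            raise ValueError("every cell needs >= 2 replicates")

    def n_replicates(self, pair: str, ecotype: str, environment: str) -> int:
        return self.replicates.get((pair, ecotype, environment), self.default_replicates)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class SimTruth:
    """Planted ground truth of one simulated dataset."""

    gene_table: pd.DataFrame | None = None  # gene_id, pair, category, log2fc
    site_table: pd.DataFrame | None = None  # chrom,pos,... outlier flag, freqs, private
    outlier_genes: dict[str, set[str]] = field(default_factory=dict)  # per pair
    planted_terms: list[str] = field(default_factory=list)

    def genes_of(self, pair: str, category: str) -> set[str]:
        t = self.gene_table
        return set(t.loc[(t["pair"] == pair) & (t["category"] == category), "gene_id"])


def _design(cfg: SimConfig) -> SampleDesign:
    rows = []
    for pair in ("1", "3"):
        for eco in ("montane", "alpine"):
            for env in ("montane", "alpine"):
                for r in range(cfg.n_replicates(pair, eco, env)):
                    rows.append(
                        {
                            "sample": f"p{pair}_{eco[:3]}eco_{env[:3]}env_r{r + 1}",
                            "pair": pair,
                            "ecotype": eco,
                            "environment": env,
                        }
                    )
    return SampleDesign(pd.DataFrame(rows))


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw NB counts over the transplant design with planted effect genes.

    Per pair each gene is independently assigned at most one category.
    Constitutive genes shift the montane-ecotype mean by the planted log2FC in
    both environments; plastic genes shift the non-native environment cell of
    the affected ecotype only; null genes share one mean across the four
    cells.  Counts are gamma-Poisson draws with per-gene dispersion and
    per-sample library size; group means are normalized per sample so library
    size is the exact expected total.
    """
    rng = cfg.rng(_STREAM_COUNTS)
    G = cfg.n_genes
    genes = [f"g{i:05d}" for i in range(G)]
    design = _design(cfg)
    S = len(design.samples)

    base_log2 = rng.normal(*cfg.baseline_log2_mean, size=G)
    q_base = 2.0 ** base_log2
    lo, hi = cfg.dispersion_range
    phi = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))
    lib = rng.uniform(*cfg.library_size_range, size=S)

    cells = [("montane", "montane"), ("montane", "alpine"),
             ("alpine", "montane"), ("alpine", "alpine")]
    truth_rows = []
    # per pair: genes x 4 cell multipliers (log2 scale)
    log2_shift = {p: np.zeros((G, 4)) for p in ("1", "3")}
    for pair in ("1", "3"):
        n_con = int(round(cfg.frac_constitutive * G))
        n_pm = int(round(cfg.frac_plastic_montane * G))
        n_pa = int(round(cfg.frac_plastic_alpine * G))
        chosen = rng.choice(G, size=n_con + n_pm + n_pa, replace=False)
        con, pm, pa = np.split(chosen, [n_con, n_con + n_pm])
        deltas = np.abs(rng.normal(*cfg.effect_log2fc, size=len(chosen)))
        deltas *= rng.choice([-1.0, 1.0], size=len(chosen))
        d_con, d_pm, d_pa = np.split(deltas, [n_con, n_con + n_pm])

        # constitutive: montane-ecotype cells shifted in both environments
        for idx, d in zip(con, d_con):
            log2_shift[pair][idx, cells.index(("montane", "montane"))] += d
            log2_shift[pair][idx, cells.index(("montane", "alpine"))] += d
            truth_rows.append((genes[idx], pair, "constitutive", d))
        # plastic montane: montane ecotype responds to the non-native (alpine) env
        for idx, d in zip(pm, d_pm):
            log2_shift[pair][idx, cells.index(("montane", "alpine"))] += d
            truth_rows.append((genes[idx], pair, "plastic_montane", d))
        # plastic alpine: alpine ecotype responds to the non-native (montane) env
        for idx, d in zip(pa, d_pa):
            log2_shift[pair][idx, cells.index(("alpine", "montane"))] += d
            truth_rows.append((genes[idx], pair, "plastic_alpine", d))
        null_idx = np.setdiff1d(np.arange(G), chosen)
        truth_rows.extend((genes[i], pair, "null", 0.0) for i in null_idx)

    counts = np.empty((G, S), dtype=np.int64)
    meta = design.table
    for s in range(S):
        pair, eco, env = meta.loc[s, "pair"], meta.loc[s, "ecotype"], meta.loc[s, "environment"]
        cell = cells.index((eco, env))
        q = q_base * 2.0 ** log2_shift[pair][:, cell]
        mu = lib[s] * q / q.sum()
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        counts[:, s] = rng.poisson(lam)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=design.samples),
        design,
    )
    truth = SimTruth(
        gene_table=pd.DataFrame(truth_rows, columns=["gene_id", "pair", "category", "log2fc"])
    )
    return cm, truth


def make_gene_map(
    n_genes: int, gene_length: int = 1000, gap: int = 200, chrom: str = "chr1"
) -> pd.DataFrame:
    """Deterministic single-chromosome gene layout (1-based inclusive)."""
    starts = 1 + np.arange(n_genes) * (gene_length + gap)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "chrom": chrom,
            "start": starts,
            "end": starts + gene_length - 1,
        }
    )


def balding_nichols_genotypes(
    rng: np.random.Generator,
    n_sites: int,
    pop_sizes: list[int],
    F,
    p_anc: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw diploid genotypes under the Balding-Nichols divergence model.

    Each population's allele frequency at a site is Beta(p(1-F)/F,
    (1-p)(1-F)/F) around a shared ancestral frequency p ~ U(0.05, 0.95);
    E[FST] between any two populations drawn at the same F is ~F, which makes
    estimator recovery directly checkable.  ``F`` may be a scalar or a
    per-site vector.  Returns (dosage sites x samples, pop frequencies
    sites x pops).
    """
    if p_anc is None:
        p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    F = np.broadcast_to(np.asarray(F, float), (n_sites,))
    freqs = np.empty((n_sites, len(pop_sizes)))
    near_zero = F < 1e-12
    for j in range(len(pop_sizes)):
        a = p_anc * (1 - F) / np.maximum(F, 1e-12)
        b = (1 - p_anc) * (1 - F) / np.maximum(F, 1e-12)
        draw = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
        freqs[:, j] = np.where(near_zero, p_anc, draw)
    dosage = np.concatenate(
        [
            rng.binomial(2, freqs[:, [j]].repeat(nj, axis=1)).astype(np.int8)
            for j, nj in enumerate(pop_sizes)
        ],
        axis=1,
    )
    return dosage, freqs


def simulate_genotypes(
    cfg: SimConfig, gene_map: pd.DataFrame, truth: SimTruth | None = None
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw genotypes for the four populations with planted FST outliers and
    private alleles.

    Background sites diverge at ``fst_background``; a fraction
    ``frac_outlier_sites`` of sites is placed inside a designated outlier-gene
    pool (the constitutive-truth genes when a count ``truth`` is supplied and
    ``outlier_gene_pool='constitutive'``, otherwise a random gene subset) and
    diverges at ``fst_outlier``.  Additional sites are private to single
    populations: alt frequency ~ U(0.05, 0.45) in the carrier, 0 elsewhere,
    with each pair's alpine population receiving ``private_allele_rate_alpine``
    times as many as its montane population.
    """
    rng = cfg.rng(_STREAM_GENOTYPES)
    pops = list(cfg.genotype_samples)  # [(pair, ecotype)]
    pop_names = [f"pair{p}_{e}" for p, e in pops]
    pop_sizes = [cfg.genotype_samples[k] for k in pops]
    samples = [
        f"{name}_s{i + 1}" for name, n in zip(pop_names, pop_sizes) for i in range(n)
    ]
    populations = {
        s: name for name, n in zip(pop_names, pop_sizes) for s in
        [f"{name}_s{i + 1}" for i in range(n)]
    }

    gene_ids = gene_map["gene_id"].values
    n_outlier = int(round(cfg.frac_outlier_sites * cfg.n_sites))

    # designated outlier genes: a small subset so divergent sites cluster
    # (sweep-like multi-site support; a lone F=0.6 site is often not extreme)
    if (
        cfg.outlier_gene_pool == "constitutive"
        and truth is not None
        and truth.gene_table is not None
    ):
        pool = sorted(
            (truth.genes_of("1", "constitutive") | truth.genes_of("3", "constitutive"))
            & set(gene_ids)
        )
    else:
        pool = sorted(rng.choice(gene_ids, size=max(1, len(gene_ids) // 20), replace=False))
    designated = list(rng.choice(pool, size=min(cfg.n_outlier_genes, len(pool)), replace=False))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    out_rows = np.array([gene_index[g] for g in rng.choice(designated, size=n_outlier)])

    # background sites: Poisson(rate) candidates per gene, downsampled
    per_gene = rng.poisson(cfg.sites_per_gene, size=len(gene_map))
    bg_rows = np.repeat(np.arange(len(gene_map)), per_gene)
    n_background = max(cfg.n_sites - n_outlier, 0)
    if len(bg_rows) > n_background:
        bg_rows = bg_rows[np.sort(rng.choice(len(bg_rows), size=n_background, replace=False))]

    gene_rows = np.concatenate([bg_rows, out_rows])
    offsets = rng.random(len(gene_rows))
    starts = gene_map["start"].values[gene_rows]
    ends = gene_map["end"].values[gene_rows]
    positions = (starts + np.floor(offsets * (ends - starts + 1))).astype(int)

    n_sites = len(positions)
    is_outlier = np.zeros(n_sites, dtype=bool)
    is_outlier[len(bg_rows):] = True

    F = np.where(is_outlier, cfg.fst_outlier, cfg.fst_background)
    dosage, freqs = balding_nichols_genotypes(rng, n_sites, pop_sizes, F)

    # planted private sites, per population
    priv_rows, priv_dosage, priv_carrier = [], [], []
    chrom = gene_map["chrom"].iloc[0]
    span_end = int(gene_map["end"].max())
    for (pair, eco), name, size in zip(pops, pop_names, pop_sizes):
        n_priv = int(round(cfg.n_private_sites_montane
                           * (cfg.private_allele_rate_alpine if eco == "alpine" else 1.0)))
        pos = rng.integers(span_end + 1000, span_end + 10_000_000, size=n_priv)
        pf = rng.uniform(0.05, 0.45, size=n_priv)
        d = np.zeros((n_priv, sum(pop_sizes)), dtype=np.int8)
        col0 = sum(pop_sizes[: pop_names.index(name)])
        d[:, col0 : col0 + size] = rng.binomial(2, pf[:, None].repeat(size, axis=1))
        priv_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
        priv_dosage.append(d)
        priv_carrier.extend([name] * n_priv)

    bases = np.array(list("ACGT"))
    all_pos = np.concatenate([positions, *[r["pos"].values for r in priv_rows]])
    n_total = len(all_pos)
    ref_idx = rng.integers(0, 4, size=n_total)
    ref = bases[ref_idx]
    alt = bases[(ref_idx + rng.integers(1, 4, size=n_total)) % 4]
    sites = pd.DataFrame({"chrom": chrom, "pos": all_pos, "ref": ref, "alt": alt})
    dosage_all = np.vstack([dosage, *priv_dosage])

    site_truth = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "outlier": np.concatenate([is_outlier, np.zeros(n_total - n_sites, bool)]),
            "private_carrier": ["" ] * n_sites + priv_carrier,
        }
    )
    for j, name in enumerate(pop_names):
        site_truth[f"freq_{name}"] = np.concatenate(
            [freqs[:, j], np.full(n_total - n_sites, np.nan)]
        )

    planted_outliers = set(gene_ids[out_rows])
    outlier_gene_sets = {pair: set(planted_outliers) for pair in ("1", "3")}
    new_truth = SimTruth(
        gene_table=truth.gene_table if truth is not None else None,
        site_table=site_truth,
        outlier_genes=outlier_gene_sets,
        planted_terms=truth.planted_terms if truth is not None else [],
    )
    geno = GenotypeMatrix(sites, dosage_all, samples, populations)
    return geno, new_truth


def simulate_annotation(cfg: SimConfig, truth: SimTruth) -> tuple[AnnotationMap, SimTruth]:
    """Random term DAG with planted enriched terms.

    Terms t000..t299 form a DAG in which each term has 0-2 parents among
    earlier terms.  Background annotation assigns each (gene, term) pair with
    probability ``annotation_rate``.  ``n_planted_terms`` terms of size
    ``planted_term_size`` draw ``planted_term_fraction`` of their members from
    the constitutive-truth gene pool, making them detectably enriched in any
    study set that recovers constitutive genes.
    """
    rng = cfg.rng(_STREAM_ANNOTATION)
    G = cfg.n_genes
    genes = [f"g{i:05d}" for i in range(G)]
    terms = [f"t{i:03d}" for i in range(cfg.n_terms)]

    edges = []
    for i, term in enumerate(terms[1:], start=1):
        for parent in rng.choice(i, size=min(rng.integers(0, 3), i), replace=False):
            edges.append((term, terms[parent]))

    gene_terms: dict[str, set[str]] = {g: set() for g in genes}
    if cfg.annotation_rate > 0:
        hit = rng.random((G, cfg.n_terms)) < cfg.annotation_rate
        gi, ti = np.nonzero(hit)
        for g, t in zip(gi, ti):
            gene_terms[genes[g]].add(terms[t])

    planted: list[str] = []
    if truth.gene_table is not None and cfg.n_planted_terms > 0:
        pool = sorted(truth.genes_of("1", "constitutive") | truth.genes_of("3", "constitutive"))
        others = sorted(set(genes) - set(pool))
        # plant into leaf terms only: a term with descendants inherits their
        # annotations under the true-path rule, which would swamp the signal
        parents = {p for _, p in edges}
        leaves = [t for t in terms if t not in parents]
        chosen_terms = rng.choice(len(leaves), size=min(cfg.n_planted_terms, len(leaves)),
                                  replace=False)
        n_from_pool = int(round(cfg.planted_term_fraction * cfg.planted_term_size))
        for ti in chosen_terms:
            term = leaves[ti]
            planted.append(term)
            members = list(rng.choice(pool, size=min(n_from_pool, len(pool)), replace=False))
            members += list(
                rng.choice(others, size=cfg.planted_term_size - len(members), replace=False)
            )
            for g in members:
                gene_terms[g].add(term)

    ann = AnnotationMap(
        {g: frozenset(t) for g, t in gene_terms.items() if t}, edges
    )
    new_truth = SimTruth(
        gene_table=truth.gene_table,
        site_table=truth.site_table,
        outlier_genes=truth.outlier_genes,
        planted_terms=planted,
    )
    return ann, new_truth
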