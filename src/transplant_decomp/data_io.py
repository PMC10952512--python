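"""Readers and writers for every external format the pipeline touches.

Everything downstream operates on the in-memory containers defined here:
:class:`CountMatrix` (counts + reciprocal-transplant design), GenotypeMatrix
(biallelic SNP dosages + population labels), gene interval maps and GO-style
annotation maps.  Validation is strict and fails loudly with coordinates, so
malformed inputs never propagate into the statistics.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

PAIRS = ("1", "3")
ECOTYPES = ("montane", "alpine")
ENVIRONMENTS = ("montane", "alpine")  # montane = low altitude, alpine = high

__all__ = [
    "SampleDesign",
    "CountMatrix",
    "GenotypeMatrix",
    "AnnotationMap",
    "read_counts",
    "write_counts",
    "read_gene_map",
    "read_vcf",
    "write_vcf",
    "read_annotation",
    "write_results",
]


@dataclass
class SampleDesign:
    """Sample metadata of the 2-pair x 2-ecotype x 2-environment design.

    ``environment`` uses the same level names as ``ecotype``: "montane" is the
    low-altitude site and "alpine" the high-altitude one, mirroring the field
    naming of the transplant sites.
    """

    table: pd.DataFrame  # columns: sample, pair, ecotype, environment

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample", "pair", "ecotype", "environment"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        t = t[required].copy()
        t["sample"] = t["sample"].astype(str)
        t["pair"] = t["pair"].astype(str)
        if t["sample"].duplicated().any():
            dupes = t.loc[t["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicated sample ids: {dupes}")
        for col, levels in (
            ("pair", PAIRS),
            ("ecotype", ECOTYPES),
            ("environment", ENVIRONMENTS),
        ):
            bad = set(t[col]) - set(levels)
            if bad:
                raise ValueError(f"unknown {col} level(s) {sorted(bad)}; allowed {levels}")
        self.table = t.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    def group_labels(self) -> pd.Series:
        """(pair, ecotype, environment) cell label per sample, e.g. '1:montane:alpine'."""
        t = self.table
        return (t["pair"] + ":" + t["ecotype"] + ":" + t["environment"]).set_axis(
            t["sample"]
        )

    def subset(self, mask) -> "SampleDesign":
        return SampleDesign(self.table.loc[mask].reset_index(drop=True))


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) with library sizes and design."""

    counts: pd.DataFrame  # index gene_id, columns sample ids
    design: SampleDesign
    library_size: pd.Series = None  # per sample; defaults to column sums

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ValueError("duplicated gene ids in count matrix")
        if list(c.columns) != self.design.samples:
            raise ValueError("count columns do not match design sample order")
        if (c.values < 0).any():
            g, s = np.argwhere(c.values < 0)[0]
            raise ValueError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        if self.library_size is None:
            self.library_size = c.sum(axis=0).astype(float)
        else:
            self.library_size = pd.Series(self.library_size, index=c.columns, dtype=float)
        if (self.library_size <= 0).any():
            bad = self.library_size.index[self.library_size <= 0].tolist()
            raise ValueError(f"non-positive library size for sample(s) {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        mask = self.design.table["sample"].isin(samples).values
        design = self.design.subset(mask)
        return CountMatrix(
            self.counts[design.samples],
            design,
            self.library_size[design.samples],
        )

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.design, self.library_size)


def read_counts(path, metadata_path) -> CountMatrix:
    """Read a genes x samples count TSV together with its sample metadata.

    The metadata row order defines the column order of the returned matrix.
    Mismatched sample sets or non-integer/negative cells are fatal.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    design = SampleDesign(meta)

    count_samples, meta_samples = set(counts.columns), set(design.samples)
    if count_samples != meta_samples:
        only_counts = sorted(count_samples - meta_samples)
        only_meta = sorted(meta_samples - count_samples)
        raise ValueError(
            "sample sets differ between counts and metadata: "
            f"only in counts {only_counts}; only in metadata {only_meta}"
        )

    values = counts.values
    if not np.issubdtype(values.dtype, np.integer):
        frac, _ = np.modf(values.astype(float))
        bad = np.argwhere(frac != 0)
        if len(bad):
            g, s = bad[0]
            raise ValueError(
                f"non-integer count at gene {counts.index[g]!r}, "
                f"sample {counts.columns[s]!r}: {values[g, s]!r}"
            )
        counts = counts.astype(np.int64)
    return CountMatrix(counts[design.samples], design)


def write_counts(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.design.table.to_csv(metadata_path, sep="\t", index=False)


def read_gene_map(path) -> pd.DataFrame:
    """Read the 4-column gene interval map (gene_id, chrom, start, end; 1-based inclusive)."""
    gm = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "chrom": str, "start": int, "end": int}
    )
    required = ["gene_id", "chrom", "start", "end"]
    missing = [c for c in required if c not in gm.columns]
    if missing:
        raise ValueError(f"gene map missing columns: {missing}")
    if gm["gene_id"].duplicated().any():
        raise ValueError("duplicated gene_id in gene map")
    if (gm["start"] > gm["end"]).any():
        bad = gm.loc[gm["start"] > gm["end"], "gene_id"].tolist()
        raise ValueError(f"start > end for gene(s) {bad}")
    return gm[required]


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (sites x samples) with population labels.

    ``dosage`` holds alt-allele counts per diploid genotype: 0, 1, 2, or -1
    for missing.  ``sites`` carries 1-based VCF coordinates keyed by
    (chrom, pos, ref, alt).
    """

    sites: pd.DataFrame  # columns chrom, pos, ref, alt
    dosage: np.ndarray  # int8, sites x samples, -1 = missing
    samples: list[str]
    populations: dict[str, str]  # sample -> population label
    n_dropped_malformed: int = 0

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage shape does not match sites/samples")
        missing = set(self.populations) - set(self.samples)
        if missing:
            raise ValueError(f"populations reference unknown sample(s): {sorted(missing)}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def population_columns(self, pop: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.populations.get(s) == pop]
        if not idx:
            raise ValueError(f"population {pop!r} has no samples")
        return np.asarray(idx)

    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            p = self.populations.get(s)
            if p is not None:
                seen.setdefault(p, None)
        return list(seen)


_SNP_ALLELES = {"A", "C", "G", "T"}


def read_vcf(path, populations: dict[str, str]) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Indels, multiallelic records and non-ACGT alleles are discarded.  Samples
    named in ``populations`` must exist in the VCF; extra VCF samples are kept
    in the matrix but carry no population label.  Records whose GT field
    cannot be interpreted are dropped and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    absent = set(populations) - set(samples)
    if absent:
        raise ValueError(f"sample(s) in populations absent from VCF: {sorted(absent)}")

    rows, dosages, dropped = [], [], 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1:
            continue
        if ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
            continue
        gt = rec.gt_types  # 0=hom-ref, 1=het, 2=hom-alt, 3=unknown (gts012)
        if gt is None or len(gt) != len(samples):
            dropped += 1
            continue
        d = gt.astype(np.int8)
        d[d == 3] = -1
        rows.append((rec.CHROM, rec.POS, ref, alt))
        dosages.append(d)
    if dropped:
        warnings.warn(f"dropped {dropped} site(s) with malformed GT fields")

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = (
        np.vstack(dosages) if dosages else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(sites, dosage, samples, dict(populations), dropped)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a GT-only VCF v4.2 (plain text) from a dosage matrix."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(geno.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for (_, site), row in zip(geno.sites.iterrows(), geno.dosage):
            gts = "\t".join(gt_str[int(d)] for d in row)
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


@dataclass
class AnnotationMap:
    """Gene -> GO-style term assignments plus the term DAG (child -> parent edges)."""

    gene_terms: dict[str, frozenset[str]]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        g = self.dag()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology edges contain a cycle: {cycle}")

    def dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g

    @property
    def terms(self) -> set[str]:
        out = set()
        for t in self.gene_terms.values():
            out |= t
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out


def read_annotation(map_path, edges_path) -> AnnotationMap:
    """Read gene->terms TSV (gene_id, comma-separated terms) and child->parent edges."""
    gene_terms: dict[str, set[str]] = {}
    ann = pd.read_csv(
        map_path, sep="\t", header=None, names=["gene_id", "terms"], dtype=str
    )
    for gene, terms in zip(ann["gene_id"], ann["terms"]):
        if pd.isna(terms) or not str(terms).strip():
            continue
        ids = {t.strip() for t in str(terms).split(",") if t.strip()}
        gene_terms.setdefault(str(gene), set()).update(ids)
    edges_df = pd.read_csv(
        edges_path, sep="\t", header=None, names=["child", "parent"], dtype=str
    )
    edges = list(
        dict.fromkeys(zip(edges_df["child"].astype(str), edges_df["parent"].astype(str)))
    )
    return AnnotationMap({g: frozenset(t) for g, t in gene_terms.items()}, edges)


def write_annotation(ann: AnnotationMap, map_path, edges_path) -> None:
    with open(map_path, "w") as fh:
        for gene in sorted(ann.gene_terms):
            fh.write(f"{gene}\t{','.join(sorted(ann.gene_terms[gene]))}\n")
    with open(edges_path, "w") as fh:
        for child, parent in ann.edges:
            fh.write(f"{child}\t{parent}\n")


def _format_float(x) -> str:
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def write_results(tables: dict[str, pd.DataFrame], out_dir, config: dict | None = None,
                  seed: int | None = None) -> list[Path]:
    """Write result tables as deterministic TSVs plus a JSON run summary.

    Rows are sorted by the first column (gene_id by convention); floats are
    rendered with 6 significant digits, so identical inputs always produce
    byte-identical files.
    """
    if not tables:
        raise ValueError("no result tables to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        df = table.sort_values(table.columns[0], kind="mergesort")
        with open(path, "w") as fh:
            fh.write("\t".join(map(str, df.columns)) + "\n")
            for row in df.itertuples(index=False):
                fh.write("\t".join(_format_float(v) for v in row) + "\n")
        written.append(path)

    cfg = dict(config or {})
    summary = {
        "tables": sorted(tables),
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    spath = out_dir / "run_summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(spath)
    return written
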