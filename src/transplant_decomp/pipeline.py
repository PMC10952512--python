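"""End-to-end orchestration: simulate -> normalize/DE -> classify -> overlap
-> enrich -> popgen, driven by one validated configuration.

``run_all`` executes the enabled stages in dependency order and returns a
machine-readable report; every stage's outputs also land as TSV/JSON files in
the output directory so a run is fully inspectable afterwards.  Stage
failures map to distinct exit codes at the CLI (2 config, 3 I/O, 4
numerical).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import classify as dc
from . import data_io, de, enrichment, popgen
from .overlap import overlap_test
from .simulate import (
    SimConfig,
    make_gene_map,
    simulate_annotation,
    simulate_counts,
    simulate_genotypes,
)

log = logging.getLogger("transplant_decomp")

EXIT_CONFIG, EXIT_IO, EXIT_NUMERICAL = 2, 3, 4


class RunConfig(BaseModel):
    """Fully resolved pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "results"
    seed: int = 0

    # input paths; unset means "simulate"
    counts: Optional[str] = None
    metadata: Optional[str] = None
    vcf: Optional[str] = None
    populations: Optional[str] = None  # TSV sample \t population
    gene_map: Optional[str] = None
    annotation: Optional[str] = None
    edges: Optional[str] = None

    # thresholds
    alpha: float = Field(0.05, gt=0, lt=1)
    cpm_threshold: float = Field(1.0, ge=0)
    fc_threshold: float = 1.5
    fc_scale: Literal["linear_fc", "log2fc"] = "linear_fc"
    fst_quantile: float = Field(0.95, gt=0, lt=1)
    min_term_size: int = Field(5, ge=1)
    prior_df: float = Field(10.0, ge=0)
    max_missing: float = Field(0.0, ge=0, le=1)
    per_pair_filter: bool = False

    # stage toggles
    run_de: bool = True
    run_enrichment: bool = True
    run_popgen: bool = True

    # simulation size knobs (used only when inputs are simulated)
    n_genes: int = Field(16000, ge=10)
    n_sites: int = Field(20000, ge=100)

    @field_validator("fc_threshold")
    @classmethod
    def _fc_positive(cls, v):
        if v <= 0:
            raise ValueError("fc_threshold must be positive")
        return v


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; empty file = all defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    return RunConfig(**raw)


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _read_populations(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    return dict(zip(df["sample"], df["population"]))


def run_all(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the run report.

    The report is also written to ``<out_dir>/run_report.json`` and all
    per-gene tables to TSVs under ``out_dir``.  Disabled stages appear as
    ``null`` blocks so downstream consumers see a stable shape.
    """
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO,
        format="[%(levelname)s %(name)s] %(message)s",
    )
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": cfg.seed,
        "config": cfg.model_dump(),
        "stages": {"de": None, "overlap": None, "enrichment": None, "popgen": None},
    }
    tables: dict[str, pd.DataFrame] = {}

    # ---- inputs: load or simulate
    sim_cfg = SimConfig(seed=cfg.seed, n_genes=cfg.n_genes, n_sites=cfg.n_sites)
    truth = None
    if cfg.counts and cfg.metadata:
        log.info("[io] counts %s (hash %s)", cfg.counts, _file_hash(cfg.counts))
        counts = data_io.read_counts(cfg.counts, cfg.metadata)
    else:
        log.info("[simulate] drawing counts (%d genes, seed %d)", cfg.n_genes, cfg.seed)
        counts, truth = simulate_counts(sim_cfg)

    # ---- DE + classification
    classifications: dict[str, dc.GeneClassification] = {}
    universe: list[str] = []
    if cfg.run_de:
        filtered = de.filter_low_expression(counts, cfg.cpm_threshold)
        log.info("[de] %d of %d genes pass the CPM filter", filtered.n_genes, counts.n_genes)
        norm = de.tmm_factors(filtered)
        disp = de.estimate_dispersion(filtered, norm, prior_df=cfg.prior_df)
        log.info("[de] common dispersion %.4f", disp.common)
        universe = filtered.gene_ids.tolist()

        de_block: dict = {
            "n_filtered_genes": filtered.n_genes,
            "common_dispersion": disp.common,
            "pairs": {},
        }
        per_pair_results: dict[str, dict[str, pd.DataFrame]] = {}
        for pair in ("1", "3"):
            fit = de.fit_nb_glm(filtered, norm, disp, pair)
            results: dict[str, pd.DataFrame] = {}
            for contrast in de.pair_contrasts(pair):
                res = de.lrt_contrast(fit, contrast, alpha=cfg.alpha)
                results[contrast.name] = res
                tables[contrast.name] = res.reset_index(names="gene_id")
            per_pair_results[pair] = results

            low = results[f"pair{pair}_ecotype_in_env_montane"]
            high = results[f"pair{pair}_ecotype_in_env_alpine"]
            cls = dc.classify_constitutive(low, high, alpha=cfg.alpha, pair=pair)
            cls.table["plastic_montane"] = dc.classify_plastic(
                results[f"pair{pair}_env_in_ecotype_montane"],
                cfg.alpha, cfg.fc_threshold, cfg.fc_scale,
            )
            cls.table["plastic_alpine"] = dc.classify_plastic(
                results[f"pair{pair}_env_in_ecotype_alpine"],
                cfg.alpha, cfg.fc_threshold, cfg.fc_scale,
            )
            classifications[pair] = cls
            summary = dc.summarize_plasticity(cls)
            de_block["pairs"][pair] = summary.to_dict()
            tables[f"classification_pair{pair}"] = cls.table.reset_index(names="gene_id")
            log.info(
                "[classify] pair %s: %d constitutive, %d/%d plastic (montane/alpine)",
                pair, summary.n_constitutive, summary.n_plastic_montane,
                summary.n_plastic_alpine,
            )
        report["stages"]["de"] = de_block

        # ---- set-overlap tests mirroring the headline comparisons
        overlap_block: dict = {}
        for pair, cls in classifications.items():
            t = cls.table
            low_set = set(t.index[t["de_ecotype_low"]])
            high_set = set(t.index[t["de_ecotype_high"]])
            overlap_block[f"pair{pair}_de_low_vs_de_high"] = overlap_test(
                low_set, high_set, universe
            ).to_dict()
        overlap_block["constitutive_pair1_vs_pair3"] = overlap_test(
            set(classifications["1"].constitutive_genes),
            set(classifications["3"].constitutive_genes),
            universe,
        ).to_dict()
        plastic1 = set(classifications["1"].plastic_genes("montane")) | set(
            classifications["1"].plastic_genes("alpine")
        )
        plastic3 = set(classifications["3"].plastic_genes("montane")) | set(
            classifications["3"].plastic_genes("alpine")
        )
        overlap_block["plastic_pair1_vs_pair3"] = overlap_test(
            plastic1, plastic3, universe
        ).to_dict()
        for pair, cls in classifications.items():
            overlap_block[f"pair{pair}_plastic_montane_vs_alpine"] = overlap_test(
                set(cls.plastic_genes("montane")),
                set(cls.plastic_genes("alpine")),
                universe,
            ).to_dict()
        report["stages"]["overlap"] = overlap_block

    # ---- GO enrichment of constitutive genes
    if cfg.run_enrichment and cfg.run_de:
        if cfg.annotation and cfg.edges:
            ann = data_io.read_annotation(cfg.annotation, cfg.edges)
        else:
            if truth is None:
                log.info("[enrich] no annotation supplied and no simulation truth; skipping")
                ann = None
            else:
                ann, truth = simulate_annotation(sim_cfg, truth)
        if ann is not None:
            ann_prop = enrichment.propagate_annotations(ann)
            enr_block = {}
            for pair, cls in classifications.items():
                study = cls.constitutive_genes
                if not study:
                    enr_block[f"pair{pair}_constitutive"] = None
                    continue
                fc = cls.table["log2fc_low"]
                res = enrichment.fisher_enrichment(
                    study, universe, ann_prop,
                    min_term_size=cfg.min_term_size, alpha=cfg.alpha, log2fc=fc,
                )
                tables[f"enrichment_pair{pair}_constitutive"] = res
                enr_block[f"pair{pair}_constitutive"] = {
                    "n_terms_tested": int(len(res)),
                    "n_significant": int(res["significant"].sum()),
                    "top_terms": res.head(5)["term_id"].tolist(),
                }
            report["stages"]["enrichment"] = enr_block

    # ---- population genetics
    if cfg.run_popgen:
        if cfg.vcf and cfg.populations:
            pops = _read_populations(cfg.populations)
            geno = data_io.read_vcf(cfg.vcf, pops)
            gene_map = data_io.read_gene_map(cfg.gene_map) if cfg.gene_map else None
        else:
            gene_map = make_gene_map(cfg.n_genes)
            geno, truth = simulate_genotypes(
                sim_cfg, gene_map, truth if truth is not None else None
            )
            log.info("[popgen] simulated %d sites for %d samples",
                     geno.n_sites, len(geno.samples))

        pop_block: dict = {"pairs": {}, "private_alleles": None}
        pop_labels = geno.population_labels()
        pair_pops = {}
        for pair in ("1", "3"):
            mine = [p for p in pop_labels if f"pair{pair}" in p]
            if len(mine) == 2:
                pair_pops[pair] = sorted(mine)
        for pair, (pa, pb) in pair_pops.items():
            fst = popgen.site_fst(geno, pa, pb)
            entry = {
                "pop_a": pa,
                "pop_b": pb,
                "n_sites": int(len(fst)),
                "fst_ratio_of_averages": popgen.hudson_fst_ratio(fst),
            }
            if gene_map is not None:
                carriers, threshold = popgen.fst_outlier_genes(
                    fst, gene_map, cfg.fst_quantile
                )
                entry["fst_threshold"] = threshold
                entry["n_carrier_genes"] = len(carriers)
                if cfg.run_de and pair in classifications:
                    t = classifications[pair].table
                    de_union = set(t.index[t["de_ecotype_low"] | t["de_ecotype_high"]])
                    carriers_in_universe = carriers & set(universe)
                    test, joint = popgen.de_fst_overlap(
                        de_union, carriers_in_universe, universe, fst, gene_map
                    )
                    entry["de_fst_overlap"] = test.to_dict()
                    tables[f"pair{pair}_de_fst_joint"] = joint
            tables[f"pair{pair}_site_fst"] = fst
            pop_block["pairs"][pair] = entry

        priv = popgen.private_alleles(geno, max_missing=cfg.max_missing)
        tables["private_alleles"] = priv.table
        pop_block["private_alleles"] = priv.table.to_dict(orient="records")
        report["stages"]["popgen"] = pop_block

    if tables:
        data_io.write_results(tables, out_dir, config=cfg.model_dump(), seed=cfg.seed)
    report_path = out_dir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    log.info("[done] report at %s", report_path)
    return report
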