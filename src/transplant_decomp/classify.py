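"""Constitutive / plastic classification of differential expression.

The four per-pair contrast tables are folded into the biological decomposition
of expression divergence:

* **constitutive** genes are DE between ecotypes in *both* growing
  environments with the same sign of change — environment-independent,
  genetically fixed divergence;
* **plastic** genes change expression within one ecotype when that ecotype is
  moved between environments (significant altitude contrast and a minimum
  fold change), separately for the montane and the alpine ecotype.

Asymmetry of plasticity between ecotypes, the cross-environment correlation
of fold changes, and a PCA QC of the normalized counts round out the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data_io import CountMatrix
from .de import NormFactors, cpm

__all__ = [
    "GeneClassification",
    "PlasticityReport",
    "classify_constitutive",
    "classify_plastic",
    "summarize_plasticity",
    "fc_correlation",
    "ordination_qc",
]


@dataclass
class GeneClassification:
    """Per-gene classification table for one ecotype pair.

    ``table`` is indexed by gene and carries boolean columns de_ecotype_low,
    de_ecotype_high, constitutive, plastic_montane, plastic_alpine,
    direction_consistent plus the two ecotype-contrast log2 fold changes
    (log2fc_low = montane environment, log2fc_high = alpine environment;
    sign is montane ecotype minus alpine ecotype).
    """

    pair: str
    table: pd.DataFrame

    @property
    def constitutive_genes(self) -> list[str]:
        return self.table.index[self.table["constitutive"]].tolist()

    def plastic_genes(self, ecotype: str) -> list[str]:
        return self.table.index[self.table[f"plastic_{ecotype}"]].tolist()


def classify_constitutive(
    de_low: pd.DataFrame, de_high: pd.DataFrame, alpha: float = 0.05, pair: str = "?"
) -> GeneClassification:
    """Flag genes DE between ecotypes in both environments with consistent sign.

    ``de_low`` / ``de_high`` are the ecotype contrasts in the montane (low)
    and alpine (high) environments over the same gene universe.
    """
    if not de_low.index.equals(de_high.index):
        raise ValueError("gene universes differ between the two DE tables")
    de_l = de_low["p_adj"] < alpha
    de_h = de_high["p_adj"] < alpha
    sign_l = np.sign(de_low["log2fc"])
    sign_h = np.sign(de_high["log2fc"])
    consistent = (sign_l == sign_h) & (sign_l != 0)
    table = pd.DataFrame(
        {
            "de_ecotype_low": de_l,
            "de_ecotype_high": de_h,
            "constitutive": de_l & de_h & consistent,
            "direction_consistent": consistent,
            "log2fc_low": de_low["log2fc"],
            "log2fc_high": de_high["log2fc"],
        },
        index=de_low.index,
    )
    return GeneClassification(pair, table)


def classify_plastic(
    de_alt: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    scale: str = "linear_fc",
) -> pd.Series:
    """Flag plastic genes from one within-ecotype altitude contrast.

    A gene is plastic when the altitude contrast is significant and the fold
    change clears the gate: with ``scale='linear_fc'`` the gate is
    |log2fc| >= log2(fc_threshold) (default 1.5-fold, i.e. 0.585 on the log2
    scale); with ``scale='log2fc'`` the threshold is applied on the log2
    scale directly.
    """
    if scale not in ("linear_fc", "log2fc"):
        raise ValueError(f"unknown scale {scale!r}")
    if scale == "linear_fc":
        if fc_threshold <= 1:
            raise ValueError("linear fold-change threshold must exceed 1")
        gate = math.log2(fc_threshold)
    else:
        gate = fc_threshold
    return (de_alt["p_adj"] < alpha) & (de_alt["log2fc"].abs() >= gate)


@dataclass
class PlasticityReport:
    """Counts and summaries of the constitutive/plastic decomposition for one pair."""

    pair: str
    n_de_ecotype_low: int
    n_de_ecotype_high: int
    n_under_low: int  # under-expressed in montane ecotype, montane environment
    n_over_low: int
    n_under_high: int
    n_over_high: int
    n_constitutive: int
    n_plastic_montane: int
    n_plastic_alpine: int
    constitutive_share_low: float
    constitutive_share_high: float
    plasticity_ratio: float  # montane / alpine plastic counts; inf when alpine = 0
    spearman_rho: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extras"}
        d.update(self.extras)
        return d


def summarize_plasticity(cls: GeneClassification) -> PlasticityReport:
    """Fold a classification into headline counts and the asymmetry ratio.

    The under/over split follows the montane-minus-alpine sign convention:
    negative log2fc = under-expressed in the montane ecotype.  When no alpine
    plastic genes exist the montane:alpine ratio is reported as ``inf``.
    """
    t = cls.table
    n_low = int(t["de_ecotype_low"].sum())
    n_high = int(t["de_ecotype_high"].sum())
    n_con = int(t["constitutive"].sum())
    n_pm = int(t["plastic_montane"].sum()) if "plastic_montane" in t else 0
    n_pa = int(t["plastic_alpine"].sum()) if "plastic_alpine" in t else 0
    ratio = n_pm / n_pa if n_pa > 0 else float("inf")
    return PlasticityReport(
        pair=cls.pair,
        n_de_ecotype_low=n_low,
        n_de_ecotype_high=n_high,
        n_under_low=int((t["de_ecotype_low"] & (t["log2fc_low"] < 0)).sum()),
        n_over_low=int((t["de_ecotype_low"] & (t["log2fc_low"] > 0)).sum()),
        n_under_high=int((t["de_ecotype_high"] & (t["log2fc_high"] < 0)).sum()),
        n_over_high=int((t["de_ecotype_high"] & (t["log2fc_high"] > 0)).sum()),
        n_constitutive=n_con,
        n_plastic_montane=n_pm,
        n_plastic_alpine=n_pa,
        constitutive_share_low=n_con / n_low if n_low else float("nan"),
        constitutive_share_high=n_con / n_high if n_high else float("nan"),
        plasticity_ratio=ratio,
        spearman_rho=fc_correlation(cls),
    )


def fc_correlation(cls: GeneClassification, gene_set: str = "union_de") -> float:
    """Spearman correlation of ecotype log2 fold changes across environments.

    ``gene_set='union_de'`` restricts to genes DE in at least one environment
    (the plotted set); ``'all_tested'`` uses every gene.  Fewer than 3 genes
    yields NaN.
    """
    t = cls.table
    if gene_set == "union_de":
        t = t[t["de_ecotype_low"] | t["de_ecotype_high"]]
    elif gene_set != "all_tested":
        raise ValueError(f"unknown gene_set {gene_set!r}")
    if len(t) < 3:
        return float("nan")
    rho, _ = spearmanr(t["log2fc_low"], t["log2fc_high"])
    return float(rho)


def ordination_qc(
    counts: CountMatrix, norm: NormFactors | None = None, n_components: int = 8
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of gene-centered log2(CPM + 0.5) across samples.

    Returns (scores, variance shares): scores is samples x components, shares
    are each component's fraction of total variance (non-increasing, sum <= 1).
    """
    from sklearn.decomposition import PCA

    if counts.counts.shape[1] < 3:
        raise ValueError("ordination needs at least 3 samples")
    x = np.log2(cpm(counts, norm) + 0.5)
    x = x.sub(x.mean(axis=1), axis=0)  # center each gene
    n_components = min(n_components, x.shape[1] - 1, x.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x.values.T)
    df = pd.DataFrame(
        scores,
        index=counts.design.samples,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return df, pca.explained_variance_ratio_
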