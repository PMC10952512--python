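"""Filtering, normalization and negative-binomial differential expression.

The testing engine is a group-means NB generalized linear model: within one
ecotype pair the 2x2 (ecotype x environment) layout is fitted saturated, one
log-scale coefficient per cell with a log effective-library-size offset, and
contrasts between cells are evaluated by likelihood-ratio tests against a
model in which the two contrasted cells share a mean.  Dispersions are
estimated by maximizing the Cox-Reid adjusted profile likelihood, with a
common dispersion shared across genes and per-gene estimates shrunk toward it
on the log scale.  Normalization is TMM (trimmed mean of M-values), and the
expression filter keeps genes whose mean CPM exceeds a threshold.

var(y) = mu + phi * mu^2 throughout: phi is the NB dispersion, r = 1/phi the
size parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .data_io import CountMatrix

__all__ = [
    "NormFactors",
    "DispersionModel",
    "ContrastSpec",
    "cpm",
    "filter_low_expression",
    "tmm_factors",
    "estimate_dispersion",
    "fit_nb_glm",
    "lrt_contrast",
    "bh_adjust",
    "pair_contrasts",
]

MEAN_FLOOR = 1e-8  # relative-rate floor for all-zero groups


@dataclass
class NormFactors:
    """Per-sample TMM factors; geometric mean is 1 by construction."""

    tmm_factor: pd.Series

    @property
    def samples(self) -> pd.Index:
        return self.tmm_factor.index

    def effective_library_size(self, library_size: pd.Series) -> pd.Series:
        return library_size * self.tmm_factor

    @classmethod
    def unit(cls, samples) -> "NormFactors":
        return cls(pd.Series(1.0, index=pd.Index(samples)))


@dataclass
class DispersionModel:
    """Common, genewise, and shrunken NB dispersions."""

    common: float
    genewise: pd.Series
    shrunken: pd.Series
    prior_df: float
    n_fallback: int = 0  # genes whose genewise fit fell back to the common value


@dataclass(frozen=True)
class ContrastSpec:
    """One of the four per-pair cell contrasts.

    ``kind`` 'ecotype_in_env' compares montane vs alpine ecotype within
    ``fixed_level`` environment; 'env_in_ecotype' compares montane vs alpine
    environment within ``fixed_level`` ecotype.  ``group_a`` minus ``group_b``
    defines the sign of the log fold change.
    """

    pair: str
    kind: str  # ecotype_in_env | env_in_ecotype
    fixed_level: str

    def __post_init__(self):
        if self.kind not in ("ecotype_in_env", "env_in_ecotype"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        if self.fixed_level not in ("montane", "alpine"):
            raise ValueError(f"unknown level {self.fixed_level!r}")

    @property
    def group_a(self) -> tuple[str, str]:
        """(ecotype, environment) of the first cell (montane side)."""
        if self.kind == "ecotype_in_env":
            return ("montane", self.fixed_level)
        return (self.fixed_level, "montane")

    @property
    def group_b(self) -> tuple[str, str]:
        if self.kind == "ecotype_in_env":
            return ("alpine", self.fixed_level)
        return (self.fixed_level, "alpine")

    @property
    def name(self) -> str:
        return f"pair{self.pair}_{self.kind}_{self.fixed_level}"


def pair_contrasts(pair: str) -> list[ContrastSpec]:
    """The four contrasts reported per ecotype pair."""
    return [
        ContrastSpec(pair, "ecotype_in_env", "montane"),
        ContrastSpec(pair, "ecotype_in_env", "alpine"),
        ContrastSpec(pair, "env_in_ecotype", "montane"),
        ContrastSpec(pair, "env_in_ecotype", "alpine"),
    ]


def cpm(counts: CountMatrix, norm: NormFactors | None = None) -> pd.DataFrame:
    """Counts per million over (effective) library sizes."""
    lib = counts.library_size
    if norm is not None:
        lib = norm.effective_library_size(lib)
    if (lib <= 0).any():
        raise ValueError("non-positive library size")
    return counts.counts / lib.values[None, :] * 1e6


def filter_low_expression(counts: CountMatrix, threshold: float = 1.0) -> CountMatrix:
    """Keep genes whose mean raw-library CPM across all samples exceeds ``threshold``.

    The gate is strict (> threshold) and is applied before TMM, on raw library
    sizes.
    """
    mean_cpm = cpm(counts).mean(axis=1)
    keep = mean_cpm > threshold
    return counts.subset_genes(counts.gene_ids[keep.values])


def _tmm_pair_factor(
    y_s: np.ndarray, y_r: np.ndarray, N_s: float, N_r: float,
    trim_m: float, trim_a: float,
) -> float:
    both = (y_s > 0) & (y_r > 0)
    if not both.any():
        return np.nan
    ys, yr = y_s[both].astype(float), y_r[both].astype(float)
    M = np.log2((ys / N_s) / (yr / N_r))
    A = 0.5 * np.log2((ys / N_s) * (yr / N_r))
    w = (N_s - ys) / (N_s * ys) + (N_r - yr) / (N_r * yr)

    n = len(M)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = pd.Series(M).rank(method="average").values
    rank_a = pd.Series(A).rank(method="average").values
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    return float(2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])))


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """Trimmed-mean-of-M-values scale factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile CPM is closest to the
    across-sample mean upper quartile.  M-values are doubly trimmed (by M and
    by average log abundance A) and combined with inverse asymptotic-variance
    weights.  A sample sharing no expressed gene with the reference gets
    factor 1 with a warning.
    """
    import warnings

    y = counts.counts.values
    N = counts.library_size.values
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if (y.sum(axis=0) == 0).any():
        raise ValueError("sample with all-zero counts")

    uq = np.quantile(y / N[None, :] * 1e6, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    for s in range(y.shape[1]):
        if s == ref:
            continue
        f = _tmm_pair_factor(y[:, s], y[:, ref], N[s], N[ref], trim_m, trim_a)
        if np.isnan(f):
            warnings.warn(
                f"sample {counts.counts.columns[s]!r} shares no expressed gene "
                "with the TMM reference; factor set to 1"
            )
            f = 1.0
        factors[s] = f
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(pd.Series(factors, index=pd.Index(counts.counts.columns)))


# ---------------------------------------------------------------------------
# NB group-means fitting machinery (vectorized across genes)
# ---------------------------------------------------------------------------


def _group_indicator(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = list(dict.fromkeys(labels))
    idx = np.array([levels.index(l) for l in labels])
    return idx, levels


def _fit_group_means(
    y: np.ndarray, offset: np.ndarray, group_idx: np.ndarray, n_groups: int,
    phi: np.ndarray, tol: float = 1e-8, max_iter: int = 50,
) -> np.ndarray:
    """MLE of per-group log-rates for NB counts with log offsets.

    ``y`` is genes x samples, ``phi`` per-gene (broadcastable).  Returns beta
    (genes x groups), the log relative rate of each cell; fitted means are
    exp(beta + offset).  Fisher-scoring updates are independent across groups
    in this saturated one-way layout, so the whole matrix is updated at once.
    All-zero groups are floored at log(MEAN_FLOOR).
    """
    G, S = y.shape
    phi = np.broadcast_to(np.asarray(phi, float).reshape(-1, 1), (G, 1))
    exp_off = np.exp(offset)

    # init: per-group pooled rate
    beta = np.empty((G, n_groups))
    for g in range(n_groups):
        cols = group_idx == g
        beta[:, g] = np.log(
            np.maximum(y[:, cols].sum(axis=1), 0.0) / exp_off[cols].sum() + MEAN_FLOOR
        )

    onehot = np.eye(n_groups)[group_idx]  # samples x groups
    for _ in range(max_iter):
        mu = np.exp(beta[:, group_idx] + offset[None, :])
        w = mu / (1.0 + phi * mu)  # Fisher information weights
        score = (y - mu) / (1.0 + phi * mu)
        num = score @ onehot
        den = w @ onehot
        step = num / np.maximum(den, 1e-300)
        step = np.clip(step, -10.0, 10.0)
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    return np.maximum(beta, np.log(MEAN_FLOOR))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples; phi per gene."""
    phi = np.asarray(phi, float).reshape(-1, 1)
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-300)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB deviance (2 * [ll_saturated - ll_fitted]).

    Uses log1p forms so the Poisson limit (phi -> 0) stays accurate.
    """
    phi = np.asarray(phi, float).reshape(-1, 1)
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    r = 1.0 / phi
    term2 = (y + r) * (np.log1p(y * phi) - np.log1p(mu * phi))
    return 2.0 * (term1 - term2).sum(axis=1)


def _cox_reid_adjustment(
    mu: np.ndarray, phi: np.ndarray, group_idx: np.ndarray, n_groups: int
) -> np.ndarray:
    """0.5 * log det(X^T W X) for the one-way layout: diagonal per group."""
    phi = np.asarray(phi, float).reshape(-1, 1)
    w = mu / (1.0 + phi * mu)
    onehot = np.eye(n_groups)[group_idx]
    per_group = w @ onehot
    return 0.5 * np.log(np.maximum(per_group, 1e-300)).sum(axis=1)


def _apl(
    y: np.ndarray, offset: np.ndarray, group_idx: np.ndarray, n_groups: int,
    phi: np.ndarray,
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at dispersion phi."""
    beta = _fit_group_means(y, offset, group_idx, n_groups, phi)
    mu = np.exp(beta[:, group_idx] + offset[None, :])
    return _nb_loglik(y, mu, phi) - _cox_reid_adjustment(mu, phi, group_idx, n_groups)


def estimate_dispersion(
    counts: CountMatrix,
    norm: NormFactors,
    prior_df: float = 10.0,
    grid: tuple[float, float, int] = (1e-4, 4.0, 31),
) -> DispersionModel:
    """Estimate NB dispersions by Cox-Reid adjusted profile likelihood.

    The design is the full set of (pair, ecotype, environment) cells.  The
    common dispersion maximizes the summed APL over a log grid refined by
    golden-section search; per-gene dispersions maximize each gene's APL on
    the same grid (quadratic-interpolated); shrinkage combines the two on the
    log scale with weight ``prior_df`` against the residual df.
    """
    y = counts.counts.values.astype(float)
    offset = np.log(norm.effective_library_size(counts.library_size).values)
    group_idx, levels = _group_indicator(counts.design.group_labels().values)
    n_groups = len(levels)
    G, S = y.shape
    df_res = max(S - n_groups, 1)

    lo, hi, n_grid = grid
    log_grid = np.linspace(np.log(lo), np.log(hi), n_grid)
    apl_grid = np.empty((n_grid, G))
    for i, lphi in enumerate(log_grid):
        apl_grid[i] = _apl(y, offset, group_idx, n_groups, np.full(G, np.exp(lphi)))

    # ---- common dispersion: grid argmax + golden-section refinement
    total = apl_grid.sum(axis=1)
    i0 = int(np.argmax(total))
    a = log_grid[max(i0 - 1, 0)]
    b = log_grid[min(i0 + 1, n_grid - 1)]

    def neg_total_apl(lphi: float) -> float:
        return -float(_apl(y, offset, group_idx, n_groups, np.full(G, np.exp(lphi))).sum())

    invphi = (np.sqrt(5) - 1) / 2
    x1, x2 = b - invphi * (b - a), a + invphi * (b - a)
    f1, f2 = neg_total_apl(x1), neg_total_apl(x2)
    for _ in range(40):
        if b - a < 1e-4:
            break
        if f1 < f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = neg_total_apl(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = neg_total_apl(x2)
    phi0 = float(np.exp((a + b) / 2))

    # ---- genewise: grid argmax with quadratic interpolation on log phi
    i_best = np.argmax(apl_grid, axis=0)
    log_phi_g = log_grid[i_best]
    interior = (i_best > 0) & (i_best < n_grid - 1)
    ii = i_best[interior]
    fm1 = apl_grid[ii - 1, np.where(interior)[0]]
    f0 = apl_grid[ii, np.where(interior)[0]]
    fp1 = apl_grid[ii + 1, np.where(interior)[0]]
    denom = fm1 - 2 * f0 + fp1
    h = log_grid[1] - log_grid[0]
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (fm1 - fp1) / denom * h, 0.0)
    log_phi_g[interior] += np.clip(shift, -h, h)

    flat = np.ptp(apl_grid, axis=0) < 1e-9  # no information: fall back to common
    log_phi_g[flat] = np.log(phi0)

    log_shrunk = (prior_df * np.log(phi0) + df_res * log_phi_g) / (prior_df + df_res)
    genes = counts.gene_ids
    return DispersionModel(
        common=phi0,
        genewise=pd.Series(np.exp(log_phi_g), index=genes),
        shrunken=pd.Series(np.exp(log_shrunk), index=genes),
        prior_df=prior_df,
        n_fallback=int(flat.sum()),
    )


@dataclass
class NBFit:
    """Fitted saturated group-means NB model for one ecotype pair."""

    counts: CountMatrix  # pair subset
    norm_offset: np.ndarray  # log effective library sizes, per sample
    group_idx: np.ndarray
    group_levels: list[str]  # 'ecotype:environment'
    beta: np.ndarray  # genes x groups, log relative rates
    phi: np.ndarray  # per-gene shrunken dispersion
    deviance: np.ndarray  # per gene

    def fitted_mu(self) -> np.ndarray:
        return np.exp(self.beta[:, self.group_idx] + self.norm_offset[None, :])

    def group_cpm(self) -> np.ndarray:
        """Fitted relative rate per cell on the CPM scale."""
        return np.exp(self.beta) * 1e6

    def group_index(self, ecotype: str, environment: str) -> int:
        return self.group_levels.index(f"{ecotype}:{environment}")


def fit_nb_glm(
    counts: CountMatrix, norm: NormFactors, disp: DispersionModel, pair: str
) -> NBFit:
    """Fit the saturated (ecotype x environment) NB model for one pair.

    Uses a log effective-library-size offset and the shrunken dispersions at
    fixed values; each cell gets one coefficient, so fitted cell means are the
    NB MLEs of the cells.
    """
    design = counts.design.table
    mask = (design["pair"] == str(pair)).values
    if not mask.any():
        raise ValueError(f"no samples for pair {pair!r}")
    sub = counts.subset_samples(design.loc[mask, "sample"].tolist())

    y = sub.counts.values.astype(float)
    offset = np.log(norm.effective_library_size(counts.library_size)[sub.design.samples].values)
    labels = (sub.design.table["ecotype"] + ":" + sub.design.table["environment"]).values
    group_idx, levels = _group_indicator(pd.Series(labels))
    phi = disp.shrunken.loc[sub.gene_ids].values
    beta = _fit_group_means(y, offset, group_idx, len(levels), phi)
    mu = np.exp(beta[:, group_idx] + offset[None, :])
    dev = _nb_deviance(y, mu, phi)
    return NBFit(sub, offset, group_idx, levels, beta, phi, dev)


def lrt_contrast(
    fit: NBFit,
    contrast: ContrastSpec,
    alpha: float = 0.05,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Likelihood-ratio test of one cell contrast against the saturated fit.

    The null model forces the contrast's two cells to share a mean (other
    cells keep their own); dispersions are held fixed.  The statistic is the
    deviance difference, referred to chi-square with 1 df.  log2 fold changes
    come from fitted cell CPMs moderated by ``prior_count``.

    Returns a DataFrame indexed by gene with columns log2fc, lrt_stat, p,
    p_adj, mean_log2cpm, de_flag.
    """
    ia = fit.group_index(*contrast.group_a)
    ib = fit.group_index(*contrast.group_b)

    # null model: merge groups a and b
    merged_idx = fit.group_idx.copy()
    merged_idx[merged_idx == ib] = ia
    # re-densify group labels
    uniq = np.unique(merged_idx)
    remap = {g: i for i, g in enumerate(uniq)}
    null_idx = np.array([remap[g] for g in merged_idx])

    y = fit.counts.counts.values.astype(float)
    beta0 = _fit_group_means(y, fit.norm_offset, null_idx, len(uniq), fit.phi)
    mu0 = np.exp(beta0[:, null_idx] + fit.norm_offset[None, :])
    dev0 = _nb_deviance(y, mu0, fit.phi)

    stat = dev0 - fit.deviance
    if (stat < -1e-6).any():
        worst = float(stat.min())
        raise RuntimeError(
            f"negative LRT statistic {worst:.3g}: null fit beat the full fit "
            "beyond numerical tolerance"
        )
    stat = np.maximum(stat, 0.0)
    p = chi2.sf(stat, df=1)
    p_adj = bh_adjust(p)

    cpm_cells = fit.group_cpm()
    log2fc = np.log2(
        (cpm_cells[:, ia] + prior_count) / (cpm_cells[:, ib] + prior_count)
    )
    obs_cpm = cpm(
        fit.counts,
        NormFactors(pd.Series(np.exp(fit.norm_offset) / fit.counts.library_size.values,
                              index=fit.counts.design.samples)),
    )
    mean_log2cpm = np.log2(obs_cpm + 0.5).mean(axis=1).values

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "lrt_stat": stat,
            "p": p,
            "p_adj": p_adj,
            "mean_log2cpm": mean_log2cpm,
            "de_flag": p_adj < alpha,
        },
        index=fit.counts.gene_ids,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
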