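"""Shared fixtures: small designed datasets built in memory or in tmp dirs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from transplant_decomp.data_io import CountMatrix, GenotypeMatrix, SampleDesign


def make_design(pairs=("1",), reps=5) -> SampleDesign:
    rows = []
    for pair in pairs:
        for eco in ("montane", "alpine"):
            for env in ("montane", "alpine"):
                for r in range(reps):
                    rows.append(
                        {
                            "sample": f"p{pair}_{eco[:3]}_{env[:3]}_{r}",
                            "pair": pair,
                            "ecotype": eco,
                            "environment": env,
                        }
                    )
    return SampleDesign(pd.DataFrame(rows))


def nb_counts(
    rng: np.random.Generator,
    n_genes: int,
    design: SampleDesign,
    mu: float | np.ndarray = 50.0,
    phi: float = 0.1,
    log2fc: float = 0.0,
    affected: str = "ecotype_in_env_montane",
    n_affected: int = 0,
    library_size: float = 1e6,
) -> tuple[CountMatrix, np.ndarray]:
    """NB counts with an optional planted effect in the first ``n_affected`` genes.

    ``affected='ecotype_in_env_montane'`` shifts the (montane ecotype, montane
    environment) cell; ``'constitutive'`` shifts both montane-ecotype cells.
    Returns the matrix and a boolean planted-gene mask.
    """
    t = design.table
    S = len(t)
    base = np.broadcast_to(np.asarray(mu, float).reshape(-1, 1), (n_genes, S)).copy()
    planted = np.zeros(n_genes, dtype=bool)
    planted[:n_affected] = True
    if n_affected:
        if affected == "ecotype_in_env_montane":
            cols = ((t["ecotype"] == "montane") & (t["environment"] == "montane")).values
        elif affected == "env_in_ecotype_montane":
            cols = ((t["ecotype"] == "montane") & (t["environment"] == "alpine")).values
        elif affected == "constitutive":
            cols = (t["ecotype"] == "montane").values
        else:
            raise ValueError(affected)
        base[np.ix_(planted, cols)] *= 2.0 ** log2fc
    lam = rng.gamma(1.0 / phi, phi * base) if phi > 0 else base
    y = rng.poisson(lam)
    cm = CountMatrix(
        pd.DataFrame(y, index=[f"g{i:04d}" for i in range(n_genes)], columns=design.samples),
        design,
        pd.Series(library_size, index=design.samples),
    )
    return cm, planted


def make_genotypes(
    dosage: np.ndarray, populations: dict[str, str], chrom: str = "chr1"
) -> GenotypeMatrix:
    samples = list(populations)
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, dosage.shape[0] + 1),
            "ref": "A",
            "alt": "C",
        }
    )
    return GenotypeMatrix(sites, dosage.astype(np.int8), samples, populations)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def pair1_design() -> SampleDesign:
    return make_design()


@pytest.fixture
def tiny_counts(tmp_path):
    """3-gene x 4-sample count TSV + metadata on disk."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "gene_id\ts1\ts2\ts3\ts4\n"
        "g1\t10\t20\t0\t5\n"
        "g2\t1\t2\t3\t4\n"
        "g3\t0\t0\t0\t0\n"
    )
    meta = tmp_path / "meta.tsv"
    meta.write_text(
        "sample\tpair\tecotype\tenvironment\n"
        "s1\t1\tmontane\tmontane\n"
        "s2\t1\tmontane\talpine\n"
        "s3\t1\talpine\tmontane\n"
        "s4\t1\talpine\talpine\n"
    )
    return counts, meta
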