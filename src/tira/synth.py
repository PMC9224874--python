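"""Synthetic cohort generator.

Emulates the study conditions of the genotype-to-expression pipeline: a
cohort of 234 Crohn's-disease patients with 14 non-durable responders (NDR,
cases) and 220 durable responders (DR, controls); Hardy–Weinberg-distributed
biallelic hard-call genotypes over a post-QC minor-allele-frequency
spectrum; sparse per-gene cis weight models (a disjoint SNP block per gene);
latent expression = weighted dosage sum + Gaussian noise; and a logistic
phenotype model with planted effects on a small set of genes plus weak
clinical effects.

Ground truth (true weights, latent expression, noise draws, intercept) is
returned alongside the data so recovery tests are exact.  All draws come
from purpose-tagged streams derived from the seed, so adding a generator
step never shifts downstream draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._utils import rng_for
from .containers import (
    CLINICAL_MULTICLASS,
    VARIANT_COLUMNS,
    GenotypeMatrix,
    WeightDB,
    validate_clinical,
)
from .errors import ConfigError, DataError
from . import io

_BASES = np.array(list("ACGT"))

#: Control-group frequencies used for clinical covariates (typical of a
#: Korean Crohn's-disease cohort at first anti-TNF exposure).
_CLINICAL_FREQS = {
    "sex": 0.73,  # male
    "smoking": 0.22,
    "family_history": 0.03,
    "upper_gi": 0.05,
    "perianal": 0.39,
}
_LOCATION_P = [0.25, 0.14, 0.61]  # ileal, colonic, ileocolonic
_BEHAVIOR_P = [0.73, 0.11, 0.16]  # inflammatory, stricturing, penetrating


@dataclass
class SynthConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_samples: int = 234
    n_cases: int = 14
    n_genes: int = 500
    snps_per_gene: tuple[int, int] = (2, 6)
    n_null_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    weight_sparsity: float = 0.7
    expression_noise_sd: float = 0.15
    effect_genes: tuple[tuple[str, float], ...] = (("G0001", 2.0),)
    clinical_effects: tuple[tuple[str, float], ...] = (("age", 0.2), ("smoking", 0.3))
    missing_rate: float = 0.0
    hard_calls: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_cases < self.n_samples):
            raise ConfigError("need 0 < n_cases < n_samples")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5] with lo <= hi")
        if min(self.n_genes, self.snps_per_gene[0], self.n_null_snps + 1) <= 0:
            raise ConfigError("counts must be positive")
        if self.snps_per_gene[0] > self.snps_per_gene[1]:
            raise ConfigError("snps_per_gene range inverted")
        if not (0 <= self.weight_sparsity <= 1):
            raise ConfigError("weight_sparsity in [0,1]")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate in [0,1)")
        if self.expression_noise_sd < 0:
            raise ConfigError("expression_noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic cohort."""

    gene_weights: dict[str, pd.Series]  # gene -> variant-indexed true weights
    latent: pd.DataFrame  # samples x genes latent expression
    noise: pd.DataFrame  # the recorded noise draws (same shape)
    effect_sizes: dict[str, float]  # planted log-OR per SD of latent expression
    unimputable: list[str] = field(default_factory=list)
    intercept: float | None = None


def _block_sizes(config: SynthConfig) -> np.ndarray:
    lo, hi = config.snps_per_gene
    return rng_for(config.seed, "blocks").integers(lo, hi + 1, size=config.n_genes)


def gen_genotypes(config: SynthConfig) -> GenotypeMatrix:
    """Draw HWE hard-call genotypes for every gene block plus null SNPs.

    Per variant the MAF is Uniform(maf_range) and dosages are drawn from the
    Hardy–Weinberg proportions ((1-p)^2, 2p(1-p), p^2) for alt frequency p.
    """
    sizes = _block_sizes(config)
    n_var = int(sizes.sum()) + config.n_null_snps
    n = config.n_samples
    mafs = rng_for(config.seed, "maf").uniform(*config.maf_range, size=n_var)
    u = rng_for(config.seed, "geno").random((n, n_var))
    p0 = (1 - mafs) ** 2
    p01 = p0 + 2 * mafs * (1 - mafs)
    dos = (u >= p0).astype(float) + (u >= p01)

    allele_rng = rng_for(config.seed, "alleles")
    ref_i = allele_rng.integers(0, 4, size=n_var)
    alt_i = (ref_i + allele_rng.integers(1, 4, size=n_var)) % 4

    vids = [f"snp{i + 1:06d}" for i in range(n_var)]
    sids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id")
    variants = pd.DataFrame(
        {"chrom": "1", "pos": 10_000 * (np.arange(n_var) + 1), "ref": _BASES[ref_i], "alt": _BASES[alt_i]},
        index=pd.Index(vids, name="id"),
    )[VARIANT_COLUMNS]
    complete = pd.DataFrame(dos, index=sids, columns=vids)
    observed = complete.copy()
    if config.missing_rate > 0:
        mask = rng_for(config.seed, "missing").random((n, n_var)) < config.missing_rate
        observed = observed.mask(mask)
    return GenotypeMatrix(observed, variants, complete=complete)


def _draw_weights(rng: np.random.Generator, k: int) -> np.ndarray:
    """Nonzero cis weights: Normal(0, 0.3) truncated away from 0 at |w| > 0.05."""
    out = np.empty(k)
    filled = 0
    while filled < k:
        w = rng.normal(0.0, 0.3, size=2 * (k - filled) + 8)
        w = w[np.abs(w) > 0.05]
        take = min(len(w), k - filled)
        out[filled : filled + take] = w[:take]
        filled += take
    return out


def gen_weight_db(config: SynthConfig, genotypes: GenotypeMatrix) -> tuple[WeightDB, SyntheticTruth]:
    """Assign each gene a disjoint SNP block and sparse cis weights.

    Latent expression is the weighted dosage sum (pre-missingness dosages)
    plus recorded Gaussian noise.  Genes whose block draws no nonzero weight
    are unimputable: flagged in the truth, not emitted in the WeightDB.
    """
    sizes = _block_sizes(config)
    need = int(sizes.sum())
    if genotypes.n_variants < need:
        raise DataError(f"need {need} variants for {config.n_genes} gene blocks, have {genotypes.n_variants}")
    mask_rng = rng_for(config.seed, "wmask")
    w_rng = rng_for(config.seed, "wvals")
    dose = genotypes.complete if genotypes.complete is not None else genotypes.dosages.fillna(genotypes.dosages.mean())

    effect_set = {gene for gene, _ in config.effect_genes}
    records, gene_weights, latents, unimputable = [], {}, {}, []
    start = 0
    for gi, size in enumerate(sizes):
        gene = f"G{gi + 1:04d}"
        block = genotypes.variant_ids[start : start + size]
        start += size
        nz = mask_rng.random(size) < config.weight_sparsity
        if not nz.any() and gene in effect_set:
            nz[0] = True  # a planted effect gene must be imputable
        w = np.zeros(size)
        w[nz] = _draw_weights(w_rng, int(nz.sum()))
        if not nz.any():
            unimputable.append(gene)
            continue
        keep = np.flatnonzero(nz)
        meta = genotypes.variants.loc[block]
        for j in keep:
            records.append((gene, block[j], meta.iloc[j]["alt"], meta.iloc[j]["ref"], w[j]))
        gene_weights[gene] = pd.Series(w[keep], index=[block[j] for j in keep])
        # same contiguous float64 product as the imputer, so the noise-free
        # truth is reproduced bit-for-bit
        arr = np.ascontiguousarray(dose[[block[j] for j in keep]].to_numpy(dtype=float))
        latents[gene] = arr @ np.ascontiguousarray(w[keep])

    if not records:
        raise DataError("no imputable gene: weight_sparsity too low for every block")
    wdf = pd.DataFrame(records, columns=["gene", "variant_id", "effect_allele", "non_effect_allele", "weight"])
    latent = pd.DataFrame(latents, index=genotypes.sample_ids)
    noise = pd.DataFrame(
        rng_for(config.seed, "enoise").normal(0.0, config.expression_noise_sd, size=latent.shape),
        index=latent.index,
        columns=latent.columns,
    )
    truth = SyntheticTruth(
        gene_weights=gene_weights,
        latent=latent + noise,
        noise=noise,
        effect_sizes=dict(config.effect_genes),
        unimputable=unimputable,
    )
    return WeightDB(wdf, tissue="synthetic"), truth


def gen_clinical(config: SynthConfig) -> pd.DataFrame:
    """Draw the eight-covariate clinical table (no label column)."""
    rng = rng_for(config.seed, "clinical")
    n = config.n_samples
    sids = [f"S{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(index=pd.Index(sids, name="sample_id"))
    df["age"] = np.round(np.clip(rng.normal(28.0, 9.0, n), 16, 70), 1)
    df["sex"] = np.where(rng.random(n) < _CLINICAL_FREQS["sex"], "male", "female")
    for col in ["smoking", "family_history", "upper_gi", "perianal"]:
        df[col] = (rng.random(n) < _CLINICAL_FREQS[col]).astype(int)
    df["location"] = rng.choice(CLINICAL_MULTICLASS["location"], size=n, p=_LOCATION_P)
    df["behavior"] = rng.choice(CLINICAL_MULTICLASS["behavior"], size=n, p=_BEHAVIOR_P)
    return validate_clinical(df[["age", "sex", "smoking", "family_history", "location", "upper_gi", "behavior", "perianal"]])


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _linear_predictor(truth: SyntheticTruth, clinical: pd.DataFrame, config: SynthConfig) -> np.ndarray:
    eta = np.zeros(len(clinical))
    for gene, gamma in config.effect_genes:
        if gene in truth.latent.columns:
            eta += gamma * _standardize(truth.latent[gene].to_numpy())
        elif gene not in truth.unimputable:
            raise ConfigError(f"effect gene {gene} not generated")
    for cov, beta in config.clinical_effects:
        col = clinical[cov]
        if cov == "age":
            eta += beta * _standardize(col.to_numpy(dtype=float))
        elif col.dtype == object:
            eta += beta * (col == "male").to_numpy(dtype=float)
        else:
            eta += beta * col.to_numpy(dtype=float)
    return eta


def gen_phenotype(
    truth: SyntheticTruth,
    clinical: pd.DataFrame,
    config: SynthConfig,
    mode: str = "bernoulli",
    max_retries: int = 1000,
) -> pd.Series:
    """Draw NDR/DR labels from the planted logistic model.

    label ~ Bernoulli(logistic(b + sum gamma_g z_g + clinical effects)) with
    the intercept b solved so the expected case fraction equals
    n_cases/n_samples.  ``mode='rejection'`` redraws until the realized case
    count equals n_cases exactly (bounded by ``max_retries``).
    """
    if mode not in {"bernoulli", "rejection"}:
        raise ConfigError(f"unknown mode {mode!r}")
    eta = _linear_predictor(truth, clinical, config)
    target = config.n_cases / config.n_samples

    def excess(b: float) -> float:
        return expit(b + eta).mean() - target

    intercept = brentq(excess, -40.0, 40.0, xtol=1e-12)
    truth.intercept = float(intercept)
    p = expit(intercept + eta)
    rng = rng_for(config.seed, "labels")
    for _ in range(max_retries if mode == "rejection" else 1):
        y = (rng.random(len(p)) < p).astype(int)
        if mode == "bernoulli" or y.sum() == config.n_cases:
            return pd.Series(np.where(y == 1, "NDR", "DR"), index=clinical.index, name="label")
    raise DataError(f"rejection mode: case count {config.n_cases} not realized in {max_retries} draws")


def simulate_cohort(config: SynthConfig, mode: str = "rejection"):
    """Convenience: genotypes, weights, clinical (with label), truth."""
    g = gen_genotypes(config)
    db, truth = gen_weight_db(config, g)
    clinical = gen_clinical(config)
    labels = gen_phenotype(truth, clinical, config, mode=mode)
    clinical = clinical.assign(label=labels)
    return g, db, clinical, truth


def write_fixture(
    outdir: str | Path,
    genotypes: GenotypeMatrix,
    weights: WeightDB,
    clinical: pd.DataFrame,
    labels: pd.Series | None = None,
    vcf: bool = False,
) -> dict[str, Path]:
    """Emit the cohort in the on-disk dialects consumed by the pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if labels is not None:
        clinical = clinical.assign(label=labels)
    validate_clinical(clinical, require_label="label" in clinical.columns)
    if list(clinical.index) != genotypes.sample_ids:
        raise DataError("sample ids of clinical table and genotypes disagree")
    paths = {
        "genotypes": io.write_dosage_tsv(genotypes, outdir / "dosages.tsv"),
        "weights": io.write_weights_tsv(weights, outdir / "weights.tsv"),
        "clinical": io.write_clinical_csv(clinical, outdir / "clinical.csv"),
    }
    if vcf:
        paths["vcf"] = io.write_vcf(genotypes, outdir / "genotypes.vcf")
    return paths
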