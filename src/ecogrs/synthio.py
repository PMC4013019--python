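"""Synthetic genotype panels, case-control studies and event-rate tables.

The generator emulates the statistical structure assumed by the downstream
pipeline stages:

* allele frequencies follow logit-linear clines over latitude/longitude, so
  population mean risk scores show smooth geographic gradients;
* linkage disequilibrium is produced blockwise through a latent Gaussian
  copula on haplotypes — within a block the latent vector is an AR(1)
  process with parameter ``rho``, which yields tunable adjacent-SNP r²
  while keeping exact marginal allele frequencies;
* case-control studies are drawn from an additive logistic disease model
  with age and sex covariates, accumulating sampled individuals until both
  quotas are filled;
* population coronary event rates are linearly coupled to population mean
  genetic risk score plus Gaussian noise.

All draws are deterministic given the integer seed passed to each function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .datatypes import GenotypeDataset, InvalidArgumentError, SnpRecord, concat_samples

# Default contigs mirror the three nitric-oxide-synthase gene regions
# (NOS3/ATG9B on chr7, NOS1 on chr12, NOS2A on chr17).
DEFAULT_CONTIGS = ("7", "12", "17")
# ~1 SNP every 5 kb, the density of the genotyping design being emulated.
SNP_SPACING_BP = 5000


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClineSpec:
    """Logit-linear allele-frequency surfaces: logit p_s = a_s + b_s*lat + c_s*lon."""

    a: np.ndarray  # intercepts, logit units
    b: np.ndarray  # latitude slopes, logit per degree
    c: np.ndarray  # longitude slopes, logit per degree

    def __post_init__(self):
        for name in ("a", "b", "c"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if not np.all(np.isfinite(v)):
                raise InvalidArgumentError(f"ClineSpec.{name} must be finite")
            object.__setattr__(self, name, v)
        if not (self.a.shape == self.b.shape == self.c.shape):
            raise InvalidArgumentError("ClineSpec fields must have equal length")

    @property
    def n_snps(self) -> int:
        return self.a.size


@dataclass(frozen=True)
class LDBlockSpec:
    """Contiguous SNP blocks sharing a latent AR(1) correlation ``rho``."""

    block_sizes: tuple  # sizes of contiguous blocks, partitioning the SNP range
    rho: float = 0.0    # adjacent latent correlation within a block, in [0, 1)

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.block_sizes)
        if not sizes or any(s < 1 for s in sizes):
            raise InvalidArgumentError("block sizes must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise InvalidArgumentError("rho must be in [0, 1)")
        object.__setattr__(self, "block_sizes", sizes)

    @classmethod
    def uniform(cls, n_snps: int, block_size: int, rho: float) -> "LDBlockSpec":
        """Partition ``n_snps`` into blocks of ``block_size`` (last may be short)."""
        sizes = [block_size] * (n_snps // block_size)
        if n_snps % block_size:
            sizes.append(n_snps % block_size)
        return cls(tuple(sizes), rho)

    @property
    def n_snps(self) -> int:
        return sum(self.block_sizes)

    def slices(self):
        start = 0
        for s in self.block_sizes:
            yield slice(start, start + s)
            start += s


@dataclass(frozen=True)
class DiseaseModelSpec:
    """Additive logistic disease model on SNP dosages, age and sex."""

    beta0: float                 # baseline log-odds
    beta_snps: np.ndarray        # per-SNP log-odds-ratio per alternate allele copy
    beta_age: float = 0.0        # per year
    beta_sex: float = 0.0        # sex=1 vs sex=0

    def __post_init__(self):
        v = np.atleast_1d(np.asarray(self.beta_snps, dtype=float))
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("beta_snps must be finite")
        for name in ("beta0", "beta_age", "beta_sex"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidArgumentError(f"{name} must be finite")
        object.__setattr__(self, "beta_snps", v)


@dataclass(frozen=True)
class PopulationSpec:
    """A sampled population: name, coordinates (decimal degrees) and size."""

    name: str
    lat: float   # north positive
    lon: float   # east positive
    n: int

    def __post_init__(self):
        if not (abs(self.lat) <= 90 and abs(self.lon) <= 180):
            raise InvalidArgumentError(f"{self.name}: coordinates out of range")
        if self.n < 1:
            raise InvalidArgumentError(f"{self.name}: sample size must be >= 1")


# ---------------------------------------------------------------------------
# Frequencies and genotypes
# ---------------------------------------------------------------------------

def allele_freq_at(cline: ClineSpec, lat: float, lon: float) -> np.ndarray:
    """Per-SNP alternate-allele frequency at a coordinate.

    Returns ``expit(a + b*lat + c*lon)``; raises if any frequency is not
    strictly inside (0, 1) at double precision.
    """
    if not (np.isfinite(lat) and np.isfinite(lon)):
        raise InvalidArgumentError("coordinates must be finite")
    p = expit(cline.a + cline.b * lat + cline.c * lon)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise InvalidArgumentError("cline yields degenerate frequency (0 or 1) at this coordinate")
    return p


def default_snp_records(n_snps: int, contigs: Sequence[str] = DEFAULT_CONTIGS,
                        rng: Optional[np.random.Generator] = None) -> list:
    """Default SNP records spread over the three NOS-region contigs."""
    alleles = ["A", "C", "G", "T"]
    rng = rng or np.random.default_rng(0)
    chunks = np.array_split(np.arange(n_snps), len(contigs))
    records = []
    for contig, chunk in zip(contigs, chunks):
        for k, j in enumerate(chunk):
            ref, alt = rng.choice(alleles, size=2, replace=False)
            records.append(SnpRecord(
                id=f"snp{j + 1:04d}", chrom=str(contig),
                pos=10_000 + k * SNP_SPACING_BP, ref=ref, alt=alt,
            ))
    return records


def _draw_haplotypes(rng: np.random.Generator, n_hap: int, freqs: np.ndarray,
                     blocks: LDBlockSpec) -> np.ndarray:
    """Draw haplotypes via the blockwise AR(1) Gaussian copula.

    Within a block the latent vector z follows z_t = rho*z_{t-1} +
    sqrt(1-rho^2)*e_t with standard-normal marginals; the allele at SNP s is
    alternate iff z_s < Phi^{-1}(p_s), so marginal frequencies are exact.
    """
    m = freqs.size
    if blocks.n_snps != m:
        raise InvalidArgumentError(
            f"LD blocks cover {blocks.n_snps} SNPs but {m} frequencies given")
    z = np.empty((n_hap, m))
    rho = blocks.rho
    innov_sd = np.sqrt(1.0 - rho ** 2)
    for sl in blocks.slices():
        e = rng.standard_normal((n_hap, sl.stop - sl.start))
        zb = np.empty_like(e)
        zb[:, 0] = e[:, 0]
        for t in range(1, e.shape[1]):
            zb[:, t] = rho * zb[:, t - 1] + innov_sd * e[:, t]
        z[:, sl] = zb
    thresh = norm.ppf(freqs)
    return (z < thresh[None, :]).astype(np.int8)


def _draw_genotypes(rng: np.random.Generator, n: int, freqs: np.ndarray,
                    blocks: LDBlockSpec) -> np.ndarray:
    """Diploid dosages = sum of two independent copula haplotypes."""
    h = _draw_haplotypes(rng, 2 * n, freqs, blocks)
    return (h[:n] + h[n:]).astype(float)


def draw_population_panel(pops: Sequence[PopulationSpec], cline: ClineSpec,
                          blocks: LDBlockSpec, seed: int,
                          snps: Optional[list] = None) -> GenotypeDataset:
    """Draw a multi-population genotype panel with clinal frequencies.

    Individuals within a population are independent draws at that
    population's cline frequencies; populations are independent.
    """
    if not pops:
        raise InvalidArgumentError("population list is empty")
    rng = np.random.default_rng(seed)
    if snps is None:
        snps = default_snp_records(cline.n_snps, rng=np.random.default_rng(12345))
    if len(snps) != cline.n_snps:
        raise InvalidArgumentError("SNP record count does not match cline length")
    parts, labels, lats, lons, names = [], [], [], [], []
    for pop in pops:
        freqs = allele_freq_at(cline, pop.lat, pop.lon)
        parts.append(_draw_genotypes(rng, pop.n, freqs, blocks))
        labels += [pop.name] * pop.n
        lats += [pop.lat] * pop.n
        lons += [pop.lon] * pop.n
        names += [f"{pop.name}_{i + 1:04d}" for i in range(pop.n)]
    dosage = np.vstack(parts)
    return GenotypeDataset(
        samples=names, snps=list(snps), dosage=dosage,
        missing=np.zeros(dosage.shape, dtype=bool),
        population=np.array(labels), lat=np.array(lats, float),
        lon=np.array(lons, float),
    )


# ---------------------------------------------------------------------------
# Case-control sampling
# ---------------------------------------------------------------------------

def draw_case_control_study(freqs: np.ndarray, model: DiseaseModelSpec,
                            n_cases: int, n_controls: int,
                            blocks: LDBlockSpec, seed: int,
                            age_mean_sd: tuple = (60.0, 10.0),
                            sex_prob: float = 0.5,
                            study: str = "study",
                            snps: Optional[list] = None) -> GenotypeDataset:
    """Draw a case-control study from the logistic disease model.

    Individuals are sampled in batches — genotype from the copula at
    ``freqs``, age ~ Normal, sex ~ Bernoulli, case status ~
    Bernoulli(expit(beta0 + sum beta_s*g_s + beta_age*age + beta_sex*sex)) —
    and accumulated until both quotas are filled.  Total attempts are capped
    at ``100 * (n_cases + n_controls)``; exceeding the cap (e.g. a saturated
    baseline log-odds) raises.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if model.beta_snps.size != freqs.size:
        raise InvalidArgumentError(
            f"disease model has {model.beta_snps.size} SNP effects "
            f"but {freqs.size} frequencies given")
    if n_cases < 1 or n_controls < 1:
        raise InvalidArgumentError("case and control quotas must be >= 1")
    if np.any(freqs <= 0) or np.any(freqs >= 1):
        raise InvalidArgumentError("frequencies must be strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    if snps is None:
        snps = default_snp_records(freqs.size, rng=np.random.default_rng(12345))

    cap = 100 * (n_cases + n_controls)
    need_ca, need_co = n_cases, n_controls
    got_g, got_age, got_sex, got_y = [], [], [], []
    attempts = 0
    while need_ca > 0 or need_co > 0:
        batch = min(max(1024, need_ca + need_co), cap - attempts)
        if batch <= 0:
            raise EcoSimulationError(
                f"attempt cap {cap} exhausted with {need_ca} cases / "
                f"{need_co} controls still unfilled (saturated disease model?)")
        g = _draw_genotypes(rng, batch, freqs, blocks)
        age = rng.normal(age_mean_sd[0], age_mean_sd[1], size=batch)
        sex = (rng.random(batch) < sex_prob).astype(int)
        eta = model.beta0 + g @ model.beta_snps + model.beta_age * age + model.beta_sex * sex
        y = (rng.random(batch) < expit(eta)).astype(int)
        attempts += batch
        for take_y, need in ((1, need_ca), (0, need_co)):
            idx = np.flatnonzero(y == take_y)[:need]
            if idx.size:
                got_g.append(g[idx]); got_age.append(age[idx])
                got_sex.append(sex[idx]); got_y.append(y[idx])
        need_ca = n_cases - sum(int((yy == 1).sum()) for yy in got_y)
        need_co = n_controls - sum(int((yy == 0).sum()) for yy in got_y)

    dosage = np.vstack(got_g)
    y = np.concatenate(got_y)
    order = np.argsort(-y, kind="stable")  # cases first, deterministic
    dosage = dosage[order]
    return GenotypeDataset(
        samples=[f"{study}_{i + 1:05d}" for i in range(dosage.shape[0])],
        snps=list(snps), dosage=dosage,
        missing=np.zeros(dosage.shape, dtype=bool),
        phenotype=y[order],
        age=np.concatenate(got_age)[order],
        sex=np.concatenate(got_sex)[order],
        population=np.array([study] * dosage.shape[0]),
    )


class EcoSimulationError(InvalidArgumentError):
    """Sampling could not fill the case/control quotas within the attempt cap."""


# ---------------------------------------------------------------------------
# Missingness and event-rate tables
# ---------------------------------------------------------------------------

def apply_missingness(ds: GenotypeDataset, rate: float, seed: int) -> GenotypeDataset:
    """Mask each observed genotype independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise InvalidArgumentError(f"missingness rate must be in [0, 1), got {rate}")
    out = ds.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    hit = (rng.random(out.dosage.shape) < rate) & ~out.missing
    out.dosage[hit] = np.nan
    out.missing |= hit
    return out


def draw_event_rate_table(mean_scores: pd.Series, intercept: float, slope: float,
                          noise_sd: float, seed: int,
                          sex_strata: Sequence[str] = ("men", "women"),
                          risk_factors: bool = False) -> pd.DataFrame:
    """Population event-rate table linearly coupled to mean GRS.

    ``event_rate = intercept + slope * mean_score + Normal(0, noise_sd)``
    per population and sex stratum (independent noise per stratum).  Rates
    are events per 100,000 per year; negative draws are truncated at 0 with
    a warning.  Optional risk-factor columns (SBP mm Hg, TCH mmol/L, BMI
    kg/m², SMK %) are drawn from plausible uncorrelated distributions.
    """
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    if len(mean_scores) == 0:
        raise InvalidArgumentError("population list is empty")
    rng = np.random.default_rng(seed)
    rows = []
    for stratum in sex_strata:
        rates = intercept + slope * mean_scores.to_numpy(dtype=float)
        rates = rates + rng.normal(0.0, noise_sd, size=len(mean_scores))
        if np.any(rates < 0):
            warnings.warn("negative simulated event rates truncated at 0", stacklevel=2)
            rates = np.clip(rates, 0.0, None)
        df = pd.DataFrame({
            "population": mean_scores.index.to_numpy(),
            "sex_stratum": stratum,
            "event_rate": rates,
        })
        if risk_factors:
            n = len(df)
            df["sbp"] = rng.normal(135.0, 8.0, n)   # mm Hg
            df["tch"] = rng.normal(5.8, 0.5, n)     # mmol/L
            df["bmi"] = rng.normal(26.5, 1.5, n)    # kg/m^2
            df["smk"] = np.clip(rng.normal(30.0, 8.0, n), 0, 100)  # %
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
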