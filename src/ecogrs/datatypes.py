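"""Shared containers and exception types.

The central object is :class:`GenotypeDataset`, a samples x SNPs dosage
matrix (alternate-allele counts, possibly fractional after imputation)
together with phenotype/covariate metadata.  Two boolean masks track data
provenance: ``missing`` marks entries that were not observed in the original
genotyping, and ``imputed`` marks the subset of those that have since been
filled with an expected dosage.  Entries that are missing and not imputed
hold NaN in the dosage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class EcoGRSError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EcoGRSError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedResultError(EcoGRSError):
    """The requested quantity is mathematically undefined for this input."""


class EmptyResultError(EcoGRSError):
    """A filtering step removed everything; the report is attached."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class SeparationError(EcoGRSError):
    """Quasi-complete separation detected during a logistic fit."""


class CollinearityError(EcoGRSError):
    """A design matrix is rank deficient / the information matrix singular."""


class MissingVariantError(EcoGRSError):
    """A required variant is absent from the dataset."""

    def __init__(self, message: str, snp_ids: Sequence[str] = ()):
        super().__init__(message)
        self.snp_ids = list(snp_ids)


# ---------------------------------------------------------------------------
# SNP records and the genotype container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP: identifier, location and REF/ALT alleles."""

    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise InvalidArgumentError(f"position must be 1-based positive, got {self.pos}")
        if self.ref == self.alt:
            raise InvalidArgumentError(f"{self.id}: REF and ALT alleles are identical")


@dataclass
class GenotypeDataset:
    """Samples x SNPs dosage matrix with masks and per-sample metadata.

    Parameters
    ----------
    samples : list of str
        Sample identifiers (rows).
    snps : list of SnpRecord
        Variant records (columns), in genomic order.
    dosage : ndarray, shape (n_samples, n_snps)
        Alternate-allele dosage; NaN where missing and not imputed.
    missing : bool ndarray
        True where the genotype was not observed originally.
    imputed : bool ndarray
        True where a missing genotype has been filled with an expected
        dosage.  Always a subset of ``missing``.
    phenotype : int ndarray or None
        Case (1) / control (0) status; ``None`` for general-population panels.
    age, sex : float/int ndarrays or None
        Covariates (age in years; sex coded 0/1).
    population : ndarray of str or None
        Population or study label per sample.
    lat, lon : float ndarrays or None
        Per-sample coordinates in decimal degrees.
    impq : float ndarray or None
        Per-SNP imputation-quality score in [0, 1].
    """

    samples: list
    snps: list
    dosage: np.ndarray
    missing: np.ndarray = None
    imputed: np.ndarray = None
    phenotype: Optional[np.ndarray] = None
    age: Optional[np.ndarray] = None
    sex: Optional[np.ndarray] = None
    population: Optional[np.ndarray] = None
    lat: Optional[np.ndarray] = None
    lon: Optional[np.ndarray] = None
    impq: Optional[np.ndarray] = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if len(self.samples) != n or len(self.snps) != m:
            raise InvalidArgumentError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.missing is None:
            self.missing = np.isnan(self.dosage)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros_like(self.missing)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.missing.shape != (n, m) or self.imputed.shape != (n, m):
            raise InvalidArgumentError("mask shapes inconsistent with dosage")
        if np.any(self.imputed & ~self.missing):
            raise InvalidArgumentError("imputed mask must be a subset of missing mask")
        for name in ("phenotype", "age", "sex", "population", "lat", "lon"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (n,):
                    raise InvalidArgumentError(f"{name} must have length {n}")
                setattr(self, name, v)
        if self.impq is not None:
            self.impq = np.asarray(self.impq, dtype=float)
            if self.impq.shape != (m,):
                raise InvalidArgumentError(f"impq must have length {m}")
        # observed (non-imputed) dosages must be hard calls in {0, 1, 2}
        obs = self.dosage[~self.missing]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise InvalidArgumentError("observed (non-imputed) dosages must be in {0, 1, 2}")

    # -- basic introspection ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list:
        return [s.id for s in self.snps]

    @property
    def is_case_control(self) -> bool:
        return self.phenotype is not None

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise MissingVariantError(f"SNP {snp_id!r} not in dataset", [snp_id])

    # -- subsetting ---------------------------------------------------------

    def _take_meta(self, idx):
        out = {}
        for name in ("phenotype", "age", "sex", "population", "lat", "lon"):
            v = getattr(self, name)
            out[name] = None if v is None else v[idx]
        return out

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeDataset":
        """Return a copy restricted to the given sample/SNP index arrays."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            samples=[self.samples[i] for i in si],
            snps=[self.snps[j] for j in vi],
            dosage=self.dosage[np.ix_(si, vi)].copy(),
            missing=self.missing[np.ix_(si, vi)].copy(),
            imputed=self.imputed[np.ix_(si, vi)].copy(),
            impq=None if self.impq is None else self.impq[vi].copy(),
            **self._take_meta(si),
        )

    def copy(self) -> "GenotypeDataset":
        return self.subset()

    # -- convenience --------------------------------------------------------

    def observed_dosage(self) -> np.ndarray:
        """Dosage with imputed entries blanked back to NaN (hard calls only)."""
        d = self.dosage.copy()
        d[self.missing] = np.nan
        return d

    def sample_table(self) -> pd.DataFrame:
        """Per-sample metadata as a DataFrame (synthio TSV dialect)."""
        def col(v, default):
            return default if v is None else v
        n = self.n_samples
        return pd.DataFrame({
            "sample_id": self.samples,
            "population": col(self.population, np.array(["NA"] * n)),
            "status": col(self.phenotype, np.full(n, np.nan)),
            "age": col(self.age, np.full(n, np.nan)),
            "sex": col(self.sex, np.full(n, np.nan)),
            "lat": col(self.lat, np.full(n, np.nan)),
            "lon": col(self.lon, np.full(n, np.nan)),
        })


def concat_samples(datasets: Sequence[GenotypeDataset]) -> GenotypeDataset:
    """Stack datasets that share an identical SNP panel along the sample axis."""
    if not datasets:
        raise InvalidArgumentError("no datasets to concatenate")
    first = datasets[0]
    ids = first.snp_ids
    for ds in datasets[1:]:
        if ds.snp_ids != ids:
            raise InvalidArgumentError("datasets do not share the same SNP panel")

    def cat(name):
        vals = [getattr(ds, name) for ds in datasets]
        if any(v is None for v in vals):
            return None
        return np.concatenate(vals)

    return GenotypeDataset(
        samples=[s for ds in datasets for s in ds.samples],
        snps=list(first.snps),
        dosage=np.vstack([ds.dosage for ds in datasets]),
        missing=np.vstack([ds.missing for ds in datasets]),
        imputed=np.vstack([ds.imputed for ds in datasets]),
        phenotype=cat("phenotype"),
        age=cat("age"),
        sex=cat("sex"),
        population=cat("population"),
        lat=cat("lat"),
        lon=cat("lon"),
        impq=None if first.impq is None else first.impq.copy(),
    )
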