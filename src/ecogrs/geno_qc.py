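"""Genotype quality control and expected-dosage imputation.

Implements the standard pre-association QC battery on a
:class:`~ecogrs.datatypes.GenotypeDataset`: per-SNP/per-sample call rates,
minor allele frequencies, the Hardy-Weinberg exact test, composite LD r²,
and threshold filters (call rate >= 0.75 by default, removal of
monomorphic SNPs, optional imputation-quality filter keeping scores
strictly above 0.6).  Missing genotypes can be filled with the expected
dosage 2*p̂ estimated within the sample's own population group, mirroring
a within-population reference imputation at the dosage level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import (EmptyResultError, GenotypeDataset,
                        InvalidArgumentError, UndefinedResultError)


@dataclass
class QCReport:
    """Per-SNP and per-sample QC summaries plus filter decisions.

    ``snp_qc`` columns: snp_id, call_rate, maf, hwe_p, polymorphic, impq.
    ``sample_qc`` columns: sample_id, call_rate.
    ``removed_snps`` / ``removed_samples`` columns: id, reason (one primary
    reason code per removed item).
    """

    snp_qc: pd.DataFrame
    sample_qc: pd.DataFrame
    removed_snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"]))
    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"]))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums, over all
    heterozygote counts of matching parity, the probabilities of the
    genotype configurations whose probability does not exceed that of the
    observed configuration (the standard two-sided exact definition; no
    mid-p correction).
    """
    counts = (int(n_homref), int(n_het), int(n_homalt))
    if any(c < 0 for c in counts):
        raise InvalidArgumentError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise UndefinedResultError("all genotype counts are zero")
    n_a = 2 * counts[2] + counts[1]          # alternate allele count
    rare = min(n_a, 2 * n - n_a)             # minor allele count
    obs_het = counts[1]

    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts) up to a constant:
    #   log n! - log n_AA! - log n_Aa! - log n_aa! + h*log 2
    homr = (rare - hets) // 2
    homc = (n - hets - homr)
    logp = (hets * np.log(2.0)
            - gammaln(homr + 1) - gammaln(hets + 1) - gammaln(homc + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[np.searchsorted(hets, obs_het)]
    # tolerance guards against ties lost to floating-point rounding
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _genotype_counts(obs: np.ndarray) -> tuple:
    """(hom-ref, het, hom-alt) counts from an observed dosage column."""
    v = obs[~np.isnan(obs)]
    return (int((v == 0).sum()), int((v == 1).sum()), int((v == 2).sum()))


def summarize_qc(ds: GenotypeDataset) -> QCReport:
    """Call rates, MAF, HWE exact p and polymorphism flags.

    All statistics use observed (hard-call) genotypes only; a SNP with no
    observed genotypes gets call rate 0 and NaN MAF/HWE p (flagged, no
    exception).
    """
    if ds.n_samples == 0 or ds.n_snps == 0:
        raise InvalidArgumentError("dataset is empty")
    obs = ds.observed_dosage()
    observed = ~np.isnan(obs)
    snp_call = observed.mean(axis=0)
    sample_call = observed.mean(axis=1)

    maf = np.full(ds.n_snps, np.nan)
    hwe = np.full(ds.n_snps, np.nan)
    poly = np.zeros(ds.n_snps, dtype=bool)
    for j in range(ds.n_snps):
        c = _genotype_counts(obs[:, j])
        n = sum(c)
        if n == 0:
            continue
        f_alt = (2 * c[2] + c[1]) / (2 * n)
        maf[j] = min(f_alt, 1 - f_alt)
        poly[j] = maf[j] > 0
        hwe[j] = hwe_exact_p(*c)
    return QCReport(
        snp_qc=pd.DataFrame({
            "snp_id": ds.snp_ids, "call_rate": snp_call, "maf": maf,
            "hwe_p": hwe, "polymorphic": poly,
            "impq": np.full(ds.n_snps, np.nan) if ds.impq is None else ds.impq,
        }),
        sample_qc=pd.DataFrame({"sample_id": ds.samples, "call_rate": sample_call}),
    )


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(ds: GenotypeDataset, snp_i: int, snp_j: int) -> float:
    """Composite LD: squared Pearson correlation of dosage vectors.

    Computed over pairwise-complete samples (imputed fractional dosages
    count as available).  Symmetric and invariant under allele relabeling.
    """
    x = ds.dosage[:, snp_i]
    y = ds.dosage[:, snp_j]
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        raise UndefinedResultError("fewer than 2 pairwise-complete samples")
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise UndefinedResultError("zero dosage variance at one of the SNPs")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def ld_r2_matrix(ds: GenotypeDataset, indices=None) -> np.ndarray:
    """Pairwise r² matrix (NaN where undefined) for the given SNP indices."""
    idx = np.arange(ds.n_snps) if indices is None else np.asarray(indices)
    d = ds.dosage[:, idx]
    m = d.shape[1]
    out = np.full((m, m), np.nan)
    for a in range(m):
        out[a, a] = 1.0
        for b in range(a + 1, m):
            try:
                out[a, b] = out[b, a] = ld_r2(ds, idx[a], idx[b])
            except UndefinedResultError:
                pass
    return out


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_variants(ds: GenotypeDataset, min_call_rate: float = 0.75,
                    require_polymorphic: bool = True,
                    min_imputation_quality: Optional[float] = None):
    """Remove SNPs failing call-rate / polymorphism / imputation-quality criteria.

    Semantics follow the QC protocol being emulated: call rate strictly
    below the threshold removes; monomorphic removes (if enabled);
    imputation quality is kept only if strictly above the threshold.
    Returns ``(filtered dataset, QCReport)``; raises
    :class:`EmptyResultError` (report attached) if nothing survives.
    """
    for name, v in (("min_call_rate", min_call_rate),
                    ("min_imputation_quality", min_imputation_quality)):
        if v is not None and not (0.0 <= v <= 1.0):
            raise InvalidArgumentError(f"{name} must be in [0, 1], got {v}")
    rep = summarize_qc(ds)
    q = rep.snp_qc
    reasons = {}
    for j, row in q.iterrows():
        if row.call_rate < min_call_rate:
            reasons[j] = "low_call_rate"
        elif require_polymorphic and not row.polymorphic:
            reasons[j] = "monomorphic"
        elif (min_imputation_quality is not None and ds.impq is not None
              and not (ds.impq[j] > min_imputation_quality)):
            reasons[j] = "low_imputation_quality"
    rep.removed_snps = pd.DataFrame(
        {"id": [ds.snp_ids[j] for j in reasons], "reason": list(reasons.values())})
    keep = [j for j in range(ds.n_snps) if j not in reasons]
    if not keep:
        raise EmptyResultError("all SNPs removed by variant filters", rep)
    return ds.subset(snp_idx=keep), rep


def filter_samples(ds: GenotypeDataset, min_call_rate: float = 0.75):
    """Remove samples with call rate strictly below the threshold."""
    if not (0.0 <= min_call_rate <= 1.0):
        raise InvalidArgumentError(f"min_call_rate must be in [0, 1], got {min_call_rate}")
    rep = summarize_qc(ds)
    bad = rep.sample_qc.index[rep.sample_qc.call_rate < min_call_rate].to_numpy()
    rep.removed_samples = pd.DataFrame(
        {"id": [ds.samples[i] for i in bad], "reason": "low_call_rate"})
    keep = np.setdiff1d(np.arange(ds.n_samples), bad)
    if keep.size == 0:
        raise EmptyResultError("all samples removed by sample filter", rep)
    return ds.subset(sample_idx=keep), rep


def run_qc(ds: GenotypeDataset, min_call_rate: float = 0.75,
           require_polymorphic: bool = True,
           min_imputation_quality: Optional[float] = None):
    """Variants → samples → variants-recheck filter sequence.

    The final variant pass re-evaluates polymorphism on the surviving
    samples, so the output is a fixed point of both filters.
    """
    ds1, rep_v = filter_variants(ds, min_call_rate, require_polymorphic,
                                 min_imputation_quality)
    ds2, rep_s = filter_samples(ds1, min_call_rate)
    ds3, rep_v2 = filter_variants(ds2, min_call_rate, require_polymorphic,
                                  min_imputation_quality)
    report = QCReport(
        snp_qc=rep_v2.snp_qc, sample_qc=rep_s.sample_qc,
        removed_snps=pd.concat([rep_v.removed_snps, rep_v2.removed_snps],
                               ignore_index=True),
        removed_samples=rep_s.removed_samples,
    )
    return ds3, report


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_expected_dosage(ds: GenotypeDataset, group_by: bool = True) -> GenotypeDataset:
    """Fill missing genotypes with 2*p̂ from the sample's own group.

    ``p̂`` is the observed alternate-allele frequency within the sample's
    population group (the whole dataset if ``group_by`` is False or no
    labels exist).  Imputed entries become fractional dosages and are
    flagged in the ``imputed`` mask; SNPs with no observed genotype in a
    group are left missing with a warning.
    """
    out = ds.copy()
    obs = out.observed_dosage()
    if group_by and out.population is not None:
        groups = [np.flatnonzero(out.population == g)
                  for g in pd.unique(out.population)]
    else:
        groups = [np.arange(out.n_samples)]
    unfilled = []
    for rows in groups:
        sub = obs[rows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            p_hat = np.nanmean(sub, axis=0) / 2.0
        for j in range(out.n_snps):
            hole = rows[np.isnan(out.dosage[rows, j])]
            if hole.size == 0:
                continue
            if np.isnan(p_hat[j]):
                unfilled.append(out.snp_ids[j])
                continue
            out.dosage[hole, j] = 2.0 * p_hat[j]
            out.imputed[hole, j] = True
    if unfilled:
        warnings.warn(
            f"{len(set(unfilled))} SNP(s) had no observed genotypes in some "
            f"group and were left missing: {sorted(set(unfilled))[:5]}...",
            stacklevel=2)
    return out
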