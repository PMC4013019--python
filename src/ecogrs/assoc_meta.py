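"""Case-control association scans and fixed-effect meta-analysis.

Per study, myocardial-infarction status is regressed on SNP dosages with a
multivariate logistic model adjusted for age, sex and the remaining scanned
SNPs (one joint fit; per-SNP Wald statistics are read off that fit).
Studies are then pooled per SNP by inverse-variance fixed-effect
meta-analysis on the log-odds scale, after aligning the tested allele
across studies.

The logistic fitter is a Newton/IRLS maximiser with step-halving, which
guarantees a non-decreasing log-likelihood path, detects quasi-complete
separation (any |beta| > 15 during iteration) and reports Wald standard
errors from the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .datatypes import (CollinearityError, GenotypeDataset,
                        InvalidArgumentError, SeparationError,
                        UndefinedResultError)
from .geno_qc import ld_r2

SEPARATION_BOUND = 15.0
SCORE_TOL = 1e-8
MAX_ITER = 100


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    columns: Optional[list] = None


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: sum y*eta - log(1+e^eta)
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def fit_logistic(y: np.ndarray, X: np.ndarray,
                 columns: Optional[Sequence[str]] = None) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS with step-halving.

    ``X`` must already contain the intercept column.  Convergence is
    declared when the maximum absolute score falls below 1e-8 (or after 100
    iterations).  Raises :class:`SeparationError` if any coefficient
    exceeds 15 in absolute value during iteration and
    :class:`CollinearityError` on a singular information matrix.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise InvalidArgumentError(f"need n > columns, got n={n}, k={k}")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise InvalidArgumentError("outcome must contain both classes coded 0/1")
    cols = list(columns) if columns is not None else [f"x{j}" for j in range(k)]

    beta = np.zeros(k)
    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise CollinearityError("singular information matrix (collinear design)")
        # step-halving keeps the log-likelihood non-decreasing at every step
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik(y, X @ cand)
            if ll_new >= ll - 1e-10:
                break
            scale *= 0.5
        assert ll_new >= ll - 1e-10, "log-likelihood decreased during IRLS"
        beta, ll, eta = cand, ll_new, X @ cand
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            raise SeparationError(
                "quasi-complete separation: |beta| exceeded "
                f"{SEPARATION_BOUND} at column "
                f"{cols[int(np.argmax(np.abs(beta)))]!r}")

    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise CollinearityError("singular information matrix at the optimum")
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    return LogisticFit(beta=beta, se=se, p=np.clip(p, np.finfo(float).tiny, 1.0),
                       loglik=ll, n_iter=it, converged=converged, columns=cols)


# ---------------------------------------------------------------------------
# LD prefilter (r2 < 0.8 rule)
# ---------------------------------------------------------------------------

def ld_prefilter(ds: GenotypeDataset, r2_max: float = 0.8):
    """Greedy genomic-order scan keeping SNPs with r² < ``r2_max`` vs all kept.

    Returns ``(kept indices, drop log DataFrame)``.  The first SNP of a
    correlated group (dataset order = genomic order) wins ties.
    """
    kept: List[int] = []
    dropped = []
    for j in range(ds.n_snps):
        clash = None
        for i in kept:
            try:
                if ld_r2(ds, i, j) >= r2_max:
                    clash = i
                    break
            except UndefinedResultError:
                continue
        if clash is None:
            kept.append(j)
        else:
            dropped.append({"snp_id": ds.snp_ids[j],
                            "dropped_for": ds.snp_ids[clash]})
    return kept, pd.DataFrame(dropped, columns=["snp_id", "dropped_for"])


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------

def association_scan(ds: GenotypeDataset, snps: Optional[Sequence[int]] = None,
                     adjust_age: bool = True, adjust_sex: bool = True,
                     adjust_other_snps: bool = True,
                     study: str = "study") -> pd.DataFrame:
    """Per-SNP logistic association results for one case-control study.

    With ``adjust_other_snps`` a single joint model containing every
    scanned SNP dosage (plus age/sex) is fitted and per-SNP Wald statistics
    are extracted from it; if that joint fit is collinear or separates, the
    scan falls back (with a warning) to per-SNP models adjusted for age and
    sex only.  Samples with any missing dosage among the scanned SNPs are
    dropped.

    Returns a DataFrame with columns
    ``study, snp_id, ref, alt, tested_allele, beta, se, p, n``.
    """
    if not ds.is_case_control:
        raise InvalidArgumentError("dataset has no phenotype (not a case-control study)")
    idx = list(range(ds.n_snps)) if snps is None else list(snps)
    if not idx:
        raise InvalidArgumentError("empty SNP subset")

    def covariates(rows):
        cols, names = [], []
        if adjust_age:
            if ds.age is None:
                raise InvalidArgumentError("age adjustment requested but age absent")
            cols.append(ds.age[rows]); names.append("age")
        if adjust_sex:
            if ds.sex is None:
                raise InvalidArgumentError("sex adjustment requested but sex absent")
            cols.append(ds.sex[rows]); names.append("sex")
        return cols, names

    D = ds.dosage[:, idx]
    rows = np.flatnonzero(~np.isnan(D).any(axis=1))
    if rows.size == 0:
        raise InvalidArgumentError("no samples with complete dosages for the scan")
    y = np.asarray(ds.phenotype, dtype=float)[rows]

    results = None
    if adjust_other_snps:
        cov, cov_names = covariates(rows)
        X = np.column_stack([np.ones(rows.size), D[rows]] + cov)
        names = ["intercept"] + [ds.snp_ids[j] for j in idx] + cov_names
        try:
            fit = fit_logistic(y, X, columns=names)
            results = [(j, fit.beta[1 + a], fit.se[1 + a], fit.p[1 + a])
                       for a, j in enumerate(idx)]
        except (CollinearityError, SeparationError) as exc:
            warnings.warn(
                f"joint association model failed ({exc}); falling back to "
                "per-SNP models adjusted for age and sex", stacklevel=2)
    if results is None:
        results = []
        for j in idx:
            cov, cov_names = covariates(rows)
            X = np.column_stack([np.ones(rows.size), ds.dosage[rows, j]] + cov)
            fit = fit_logistic(y, X, columns=["intercept", ds.snp_ids[j]] + cov_names)
            results.append((j, fit.beta[1], fit.se[1], fit.p[1]))

    recs = []
    for j, b, se, p in results:
        s = ds.snps[j]
        recs.append({"study": study, "snp_id": s.id, "ref": s.ref, "alt": s.alt,
                     "tested_allele": s.alt, "beta": b, "se": se, "p": p,
                     "n": int(rows.size)})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Allele alignment across studies
# ---------------------------------------------------------------------------

def align_alleles(results: Dict[str, pd.DataFrame]):
    """Harmonise the tested allele across per-study association tables.

    For each SNP the canonical tested allele is the lexicographically
    smallest alternate allele seen in any study; a study reporting the
    ref/alt-swapped orientation has its beta sign flipped.  SNPs whose
    alleles are not a plain ref/alt swap between studies are excluded.

    Returns ``(aligned dict of DataFrames, exclusion DataFrame)``.
    """
    allele_sets: Dict[str, set] = {}
    alts_seen: Dict[str, set] = {}
    excluded: Dict[str, str] = {}
    for df in results.values():
        for _, r in df.iterrows():
            allele_sets.setdefault(r.snp_id, set()).add(frozenset((r.ref, r.alt)))
            alts_seen.setdefault(r.snp_id, set()).add(r.alt)
    for snp_id, sets in allele_sets.items():
        if len(sets) > 1:
            excluded[snp_id] = "allele mismatch beyond ref/alt swap"
    # canonical tested allele = lexicographically smallest alternate observed
    # in any study; the other member of the pair becomes the reference
    canon: Dict[str, tuple] = {}
    for snp_id, alts in alts_seen.items():
        if snp_id in excluded:
            continue
        pair = next(iter(allele_sets[snp_id]))
        tested = min(alts)
        other = next(a for a in pair if a != tested)
        canon[snp_id] = (tested, other)
    aligned = {}
    for study, df in results.items():
        df = df[~df.snp_id.isin(excluded)].copy()
        flip = np.zeros(len(df), dtype=bool)
        tested, refs, alts = [], [], []
        for i, (_, r) in enumerate(df.iterrows()):
            t, other = canon[r.snp_id]
            tested.append(t); refs.append(other); alts.append(t)
            flip[i] = (r.tested_allele != t)
        df["tested_allele"] = tested
        df["ref"] = refs
        df["alt"] = alts
        df.loc[flip, "beta"] = -df.loc[flip, "beta"]
        aligned[study] = df.reset_index(drop=True)
    exclusions = pd.DataFrame(
        [{"snp_id": k, "reason": v} for k, v in excluded.items()],
        columns=["snp_id", "reason"])
    return aligned, exclusions


# ---------------------------------------------------------------------------
# Fixed-effect meta-analysis
# ---------------------------------------------------------------------------

@dataclass
class MetaResult:
    snp_id: str
    tested_allele: str
    beta: float
    se: float
    z: float
    p: float
    k: int
    studies: pd.DataFrame = None


def meta_fixed_effects(per_study: pd.DataFrame) -> MetaResult:
    """Inverse-variance fixed-effect pooling of one SNP's per-study rows.

    Weights ``w_i = 1/SE_i²``; pooled beta is the weighted mean, pooled SE
    ``sqrt(1/sum w)``, two-sided normal p on ``z = beta/SE``.
    """
    df = per_study[np.isfinite(per_study.beta) & (per_study.se > 0)]
    if len(df) == 0:
        raise UndefinedResultError("no study with finite beta and positive SE")
    w = 1.0 / df.se.to_numpy() ** 2
    beta = float(np.sum(w * df.beta.to_numpy()) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = beta / se
    p = float(2.0 * norm.sf(abs(z)))
    return MetaResult(snp_id=str(df.snp_id.iloc[0]),
                      tested_allele=str(df.tested_allele.iloc[0]),
                      beta=beta, se=se, z=z, p=max(p, np.finfo(float).tiny),
                      k=len(df), studies=df.reset_index(drop=True))


def meta_scan(results: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Align alleles then meta-analyse every SNP present in >= 1 study.

    Returns a DataFrame with columns
    ``snp_id, ref, alt, tested_allele, beta, se, z, p, k``.
    """
    aligned, _ = align_alleles(results)
    pooled = pd.concat(aligned.values(), ignore_index=True)
    rows = []
    for snp_id, grp in pooled.groupby("snp_id", sort=False):
        m = meta_fixed_effects(grp)
        rows.append({"snp_id": m.snp_id, "ref": grp.ref.iloc[0],
                     "alt": grp.alt.iloc[0], "tested_allele": m.tested_allele,
                     "beta": m.beta, "se": m.se, "z": m.z, "p": m.p, "k": m.k})
    return pd.DataFrame(rows)
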