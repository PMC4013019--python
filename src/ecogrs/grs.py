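"""Genetic risk score construction and interindividual prediction metrics.

The score follows the allele-counting convention: for every selected risk
SNP, homozygotes for the reference allele contribute 0, heterozygotes 1 and
homozygotes for the risk allele 2 (fractional imputed dosages contribute
their expectation), so the score ranges over [0, 2m] for m SNPs.

SNP selection replays the two-filter rule used to build the score: a
candidate must reach p < 0.1 with a concordant effect direction in every
replicate meta-analysis, and the surviving candidates are LD-pruned at
r² < 0.2, preferentially keeping the SNP with the lowest p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.diagnostic import normal_ad

from .datatypes import (EmptyResultError, GenotypeDataset,
                        InvalidArgumentError, MissingVariantError,
                        SeparationError, UndefinedResultError)
from .assoc_meta import fit_logistic
from .geno_qc import impute_expected_dosage, ld_r2


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

@dataclass
class RiskScoreModel:
    """Selected risk SNPs with their risk alleles (unweighted by default).

    ``table`` columns: snp_id, risk_allele, weight, p_rep1..p_repk, min_p,
    kept, pruned_by.
    """

    table: pd.DataFrame
    p_max: float = 0.1
    r2_max: float = 0.2

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table.kept].reset_index(drop=True)

    @property
    def snp_ids(self) -> list:
        return self.kept.snp_id.tolist()

    @property
    def size(self) -> int:
        return len(self.kept)


def select_score_snps(meta_replicates: Sequence[pd.DataFrame],
                      ld_reference: GenotypeDataset,
                      p_max: float = 0.1, r2_max: float = 0.2) -> RiskScoreModel:
    """Select score SNPs by replicate-intersection p filter and LD pruning.

    Candidates must have ``p < p_max`` in *all* replicate meta-analyses with
    concordant (same-sign, nonzero) pooled effects.  The risk allele is the
    allele whose dosage carries a positive pooled log-odds ratio.  Pruning
    is greedy in ascending order of the minimum p across replicates: a
    candidate is kept iff its r² in ``ld_reference`` is below ``r2_max``
    against every SNP already kept.
    """
    if not meta_replicates:
        raise InvalidArgumentError("need at least one replicate meta result")
    merged = None
    for r, df in enumerate(meta_replicates, start=1):
        part = df[["snp_id", "ref", "alt", "tested_allele", "beta", "p"]].copy()
        part = part.rename(columns={"beta": f"beta_rep{r}", "p": f"p_rep{r}"})
        if merged is None:
            merged = part
        else:
            merged = merged.merge(part, on=["snp_id", "ref", "alt", "tested_allele"],
                                  how="inner")
    k = len(meta_replicates)
    p_cols = [f"p_rep{r}" for r in range(1, k + 1)]
    b_cols = [f"beta_rep{r}" for r in range(1, k + 1)]
    P = merged[p_cols].to_numpy()
    B = merged[b_cols].to_numpy()
    low_p = np.all(P < p_max, axis=1)
    signs = np.sign(B)
    concordant = np.all(signs == signs[:, [0]], axis=1) & np.all(signs != 0, axis=1)
    cand = merged[low_p & concordant].copy()
    if len(cand) == 0:
        raise EmptyResultError(
            f"no SNP reaches p < {p_max} with concordant direction in all "
            f"{k} replicate meta-analyses")

    pos = cand[b_cols[0]].to_numpy() > 0
    cand["risk_allele"] = np.where(pos, cand.tested_allele, cand.ref)
    cand["min_p"] = cand[p_cols].min(axis=1)
    cand = cand.sort_values("min_p", kind="stable").reset_index(drop=True)

    ref_idx = {s: ld_reference.snp_index(s) for s in cand.snp_id
               if s in set(ld_reference.snp_ids)}
    missing = [s for s in cand.snp_id if s not in ref_idx]
    if missing:
        raise MissingVariantError(
            "candidate SNPs absent from LD reference", missing)

    kept_rows: List[int] = []
    pruned_by = [""] * len(cand)
    kept_flag = np.zeros(len(cand), dtype=bool)
    for i in range(len(cand)):
        clash = None
        for j in kept_rows:
            try:
                r2 = ld_r2(ld_reference, ref_idx[cand.snp_id[i]], ref_idx[cand.snp_id[j]])
            except UndefinedResultError:
                continue
            if r2 >= r2_max:
                clash = j
                break
        if clash is None:
            kept_rows.append(i)
            kept_flag[i] = True
        else:
            pruned_by[i] = cand.snp_id[clash]
    cand["weight"] = 1.0
    cand["kept"] = kept_flag
    cand["pruned_by"] = pruned_by
    cols = (["snp_id", "ref", "alt", "risk_allele", "weight"]
            + p_cols + ["min_p", "kept", "pruned_by"])
    return RiskScoreModel(table=cand[cols], p_max=p_max, r2_max=r2_max)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class ScoreSet:
    """Per-individual scores plus per-group summary statistics."""

    scores: pd.DataFrame      # sample_id, group, grs
    groups: pd.DataFrame      # group, n, mean, sd, min, max, normality_p


def _normality_p(x: np.ndarray) -> float:
    """Anderson-Darling composite-normality p (NaN if n < 8 or degenerate)."""
    x = x[np.isfinite(x)]
    if x.size < 8 or np.std(x) == 0:
        return float("nan")
    return float(normal_ad(x)[1])


def compute_scores(ds: GenotypeDataset, model: RiskScoreModel,
                   weighted: bool = False) -> ScoreSet:
    """Risk-allele dosage sum per individual plus per-group summaries.

    The risk-allele dosage is the raw alternate dosage where the risk
    allele is the alternate, else ``2 - dosage``.  Remaining missing
    dosages are filled with the group expected dosage first (so the score
    is always defined).  With ``weighted`` the per-SNP weight column
    multiplies each dosage (off by default: allele counting).
    """
    kept = model.kept
    if kept.empty:
        raise InvalidArgumentError("risk score model is empty")
    missing = [s for s in kept.snp_id if s not in set(ds.snp_ids)]
    if missing:
        raise MissingVariantError(
            f"model SNPs absent from dataset: {missing}", missing)
    work = ds
    if np.isnan(ds.dosage[:, [ds.snp_index(s) for s in kept.snp_id]]).any():
        work = impute_expected_dosage(ds)
    total = np.zeros(ds.n_samples)
    for _, row in kept.iterrows():
        j = work.snp_index(row.snp_id)
        snp = work.snps[j]
        if row.risk_allele == snp.alt:
            d = work.dosage[:, j]
        elif row.risk_allele == snp.ref:
            d = 2.0 - work.dosage[:, j]
        else:
            raise InvalidArgumentError(
                f"risk allele {row.risk_allele!r} matches neither allele of "
                f"{snp.id} ({snp.ref}/{snp.alt})")
        if np.isnan(d).any():
            warnings.warn(f"{snp.id}: unimputable missing dosages treated as 0 "
                          "risk alleles", stacklevel=2)
            d = np.nan_to_num(d, nan=0.0)
        total += (row.weight if weighted else 1.0) * d

    group = ds.population if ds.population is not None else np.array(["all"] * ds.n_samples)
    scores = pd.DataFrame({"sample_id": ds.samples, "group": group, "grs": total})
    rows = []
    for g, grp in scores.groupby("group", sort=False):
        v = grp.grs.to_numpy()
        rows.append({"group": g, "n": len(v), "mean": v.mean(),
                     "sd": v.std(ddof=1) if len(v) > 1 else float("nan"),
                     "min": v.min(), "max": v.max(),
                     "normality_p": _normality_p(v)})
    return ScoreSet(scores=scores, groups=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Prediction metrics
# ---------------------------------------------------------------------------

@dataclass
class NagelkerkeR2:
    value: float
    separated: bool = False


def nagelkerke_r2(y: np.ndarray, scores: np.ndarray) -> NagelkerkeR2:
    """Nagelkerke pseudo-R² of the logistic model ``y ~ 1 + GRS``.

    Cox-Snell R² = 1 - exp((2/n)(ll0 - ll1)) rescaled by its maximum
    1 - exp((2/n) ll0).  Perfect separation is reported as R² = 1 with a
    flag rather than an exception.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size != 2:
        raise InvalidArgumentError("outcome must contain both classes")
    n = y.size
    p1 = y.mean()
    ll0 = n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1))
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    try:
        fit = fit_logistic(y, np.column_stack([np.ones(n), s]),
                           columns=["intercept", "grs"])
        ll1 = fit.loglik
    except SeparationError:
        return NagelkerkeR2(value=1.0, separated=True)
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    return NagelkerkeR2(value=float(cox_snell / denom), separated=False)


def roc_auc_ci(y: np.ndarray, scores: np.ndarray, alpha: float = 0.05):
    """Tie-corrected AUC with a Hanley-McNeil (1 - alpha) confidence interval.

    AUC is the rank statistic (concordant case-control pairs, ties counting
    one half) over all n1*n0 pairs; the CI uses the Hanley-McNeil variance
    approximation and is truncated to [0, 1].

    Returns ``(auc, (lo, hi))``.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise InvalidArgumentError("both classes must be present")
    ranks = rankdata(s)  # mid-ranks handle ties exactly
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
           + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    var = max(var, 0.0)
    zq = float(-norm.ppf(alpha / 2.0))
    half = zq * np.sqrt(var)
    lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    return float(auc), (float(lo), float(hi))


@dataclass
class PredictionMetrics:
    nagelkerke_r2: float
    separated: bool
    auc: float
    auc_ci: tuple
    n_cases: int
    n_controls: int


def prediction_metrics(y: np.ndarray, scores: np.ndarray,
                       alpha: float = 0.05) -> PredictionMetrics:
    """Bundle Nagelkerke R² and AUC with CI for one case-control sample."""
    r2 = nagelkerke_r2(y, scores)
    auc, ci = roc_auc_ci(y, scores, alpha=alpha)
    y = np.asarray(y)
    return PredictionMetrics(nagelkerke_r2=r2.value, separated=r2.separated,
                             auc=auc, auc_ci=ci,
                             n_cases=int((y == 1).sum()),
                             n_controls=int((y == 0).sum()))
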