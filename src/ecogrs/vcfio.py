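"""VCF and TSV input/output for genotype datasets.

Genotypes travel as VCF v4.2 with unphased GT (one ALT per record); a DS
FORMAT field carries fractional expected dosages whenever the dataset
contains imputed entries (GT then holds the nearest integer call).
Sample metadata, per-SNP imputation quality and population event-rate
tables travel as TSV.  VCF access goes through pysam.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .datatypes import GenotypeDataset, InvalidArgumentError, SnpRecord

SAMPLE_TSV_COLUMNS = ["sample_id", "study", "population", "status",
                      "age", "sex", "lat", "lon"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(ds: GenotypeDataset, path) -> None:
    """Write a dataset as VCF v4.2, records sorted by (contig, position).

    Observed dosages must be integer hard calls; imputed fractional
    dosages are exported through DS with GT rounded to the nearest call.
    Entries still missing are ``./.``.
    """
    has_ds = bool(ds.imputed.any())
    header = pysam.VariantHeader()
    contigs = []
    for s in ds.snps:
        if s.chrom not in contigs:
            contigs.append(s.chrom)
    for c in contigs:
        header.contigs.add(c)
    header.formats.add("GT", 1, "String", "Genotype")
    if has_ds:
        header.formats.add("DS", 1, "Float", "Expected alternate allele dosage")
    for name in ds.samples:
        header.add_sample(str(name))

    order = sorted(range(ds.n_snps),
                   key=lambda j: (contigs.index(ds.snps[j].chrom), ds.snps[j].pos))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j in order:
            s = ds.snps[j]
            rec = vcf.new_record(contig=s.chrom, start=s.pos - 1,
                                 stop=s.pos - 1 + len(s.ref),
                                 alleles=(s.ref, s.alt), id=s.id)
            for i, name in enumerate(ds.samples):
                d = ds.dosage[i, j]
                smp = rec.samples[str(name)]
                if np.isnan(d):
                    smp["GT"] = (None, None)
                else:
                    g = int(round(d))
                    smp["GT"] = (1, 1) if g == 2 else ((0, 1) if g == 1 else (0, 0))
                    smp.phased = False
                if has_ds and not np.isnan(d):
                    smp["DS"] = float(d)
            vcf.write(rec)


def read_vcf(path, meta: Optional[pd.DataFrame] = None,
             impq: Optional[pd.DataFrame] = None) -> GenotypeDataset:
    """Read a VCF v4.2 into a :class:`GenotypeDataset`.

    Dosage is the ALT-allele count from GT (a DS field, when present,
    overrides GT with the fractional expected dosage and marks the entry
    imputed if it is non-integer); ``./.`` is missing.  Multi-ALT records
    are rejected.  ``meta`` is an optional sample table (synthio TSV
    dialect) supplying phenotype/covariates; ``impq`` an optional per-SNP
    quality table with columns ``snp_id, quality``.
    """
    snps, cols_dosage, cols_missing, cols_imputed = [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise InvalidArgumentError(
                    f"{rec.chrom}:{rec.pos}: exactly one ALT allele required")
            snps.append(SnpRecord(id=rec.id or f"{rec.chrom}:{rec.pos}",
                                  chrom=rec.chrom, pos=rec.pos,
                                  ref=rec.ref, alt=rec.alts[0]))
            dos = np.full(len(samples), np.nan)
            mis = np.ones(len(samples), dtype=bool)
            imp = np.zeros(len(samples), dtype=bool)
            for i, name in enumerate(samples):
                smp = rec.samples[name]
                gt = smp.get("GT")
                ds_val = smp.get("DS") if "DS" in rec.format else None
                if gt is None or any(a is None for a in gt):
                    continue
                if ds_val is not None:
                    dos[i] = float(ds_val)
                    frac = abs(dos[i] - round(dos[i])) > 1e-6
                    mis[i] = frac
                    imp[i] = frac
                else:
                    dos[i] = float(sum(gt))
                    mis[i] = False
            cols_dosage.append(dos)
            cols_missing.append(mis)
            cols_imputed.append(imp)
    if not snps:
        raise InvalidArgumentError(f"no records in {path}")
    dosage = np.column_stack(cols_dosage)
    missing = np.column_stack(cols_missing)
    imputed = np.column_stack(cols_imputed)

    kw = {}
    if meta is not None:
        meta = meta.set_index("sample_id").reindex(samples)
        if meta.isna().all(axis=1).any():
            raise InvalidArgumentError("metadata missing for some VCF samples")
        status = pd.to_numeric(meta["status"], errors="coerce")
        if status.notna().any():
            kw["phenotype"] = status.to_numpy(dtype=float).astype(int) \
                if status.notna().all() else None
        for col, name in (("age", "age"), ("sex", "sex"),
                          ("lat", "lat"), ("lon", "lon")):
            v = pd.to_numeric(meta[col], errors="coerce")
            if v.notna().all():
                kw[name] = v.to_numpy(dtype=float)
        if "population" in meta:
            kw["population"] = meta["population"].astype(str).to_numpy()
    impq_arr = None
    if impq is not None:
        lookup = impq.set_index("snp_id")["quality"]
        impq_arr = np.array([lookup.get(s.id, np.nan) for s in snps], dtype=float)
    return GenotypeDataset(samples=samples, snps=snps, dosage=dosage,
                           missing=missing, imputed=imputed, impq=impq_arr, **kw)


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_sample_tsv(ds: GenotypeDataset, path, study: Optional[str] = None) -> None:
    """Sample metadata TSV: sample_id, study, population, status, age, sex, lat, lon."""
    t = ds.sample_table()
    t.insert(1, "study", study if study is not None else t["population"])
    t = t.rename(columns={"population": "population"})
    t.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_sample_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(SAMPLE_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"sample TSV missing columns: {sorted(missing)}")
    return df


def write_eco_tsv(eco: pd.DataFrame, path) -> None:
    eco.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_eco_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("population", "sex_stratum", "event_rate"):
        if col not in df.columns:
            raise InvalidArgumentError(f"eco TSV missing column {col!r}")
    return df
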