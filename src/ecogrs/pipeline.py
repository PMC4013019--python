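"""End-to-end pipeline: simulate → QC → association/meta → GRS →
population scores → spatial autocorrelation → kriging → eco-regression.

One structured YAML config drives everything; a single master seed derives
per-stage sub-seeds by fixed offsets, so identical config + seed yields
byte-identical stage outputs.  Every stage writes its tables into a run
directory and the manifest records a SHA-256 hash, wall time and status
per stage (the manifest is written even when a stage fails).

The association stage runs on k >= 2 replicate dosage sets per study that
differ only in the missingness-mask sub-seed before expected-dosage
imputation; the GRS selection step then applies the p < 0.1 intersection
rule across the replicate meta-analyses.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import assoc_meta, ecoreg, geno_qc, grs, kriging, spatial, synthio, vcfio
from .datatypes import GenotypeDataset, InvalidArgumentError

log = logging.getLogger("ecogrs")

# fixed sub-seed offsets per stage (master seed kept small so these stay < 2^31)
SEED_OFFSETS = {"panel": 11, "study": 101, "missing": 211, "eco": 307,
                "spatial": 401, "correlogram": 409}


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "seed": 1,
    "simulate": {
        "n_snps": 60,
        "block_size": 5,
        "rho": 0.6,
        "maf_range": [0.15, 0.5],
        "lat_slope_sd": 0.015,       # logit per degree latitude
        "lon_slope_sd": 0.008,       # logit per degree longitude
        "causal_lat_slope": 0.03,    # mean northward cline of risk alleles
        "n_causal": 4,
        "beta_range": [0.2, 0.5],
        "beta0": -1.0,
        "beta_age": 0.01,
        "beta_sex": 0.3,
        "studies": [
            {"name": "STUDY_N", "lat": 61.0, "lon": 25.0, "n_cases": 2000, "n_controls": 2000},
            {"name": "STUDY_S1", "lat": 45.5, "lon": 9.2, "n_cases": 2000, "n_controls": 2000},
            {"name": "STUDY_S2", "lat": 41.4, "lon": 2.2, "n_cases": 2000, "n_controls": 2000},
        ],
        "n_populations": 30,
        "pop_size": 40,
        "lat_range": [35.0, 62.0],
        "lon_range": [-9.0, 35.0],
        "missing_rate": 0.05,
        "eco_intercept": 20.0,       # events /100k/yr at GRS 0 (linear coupling)
        "eco_slope": 30.0,           # events /100k/yr per score unit
        "eco_noise_sd": 8.0,
    },
    "qc": {"min_call_rate": 0.75, "min_imputation_quality": 0.6},
    "assoc": {"r2_prefilter": 0.8, "n_replicates": 2},
    "score": {"p_max": 0.1, "r2_max": 0.2},
    "spatial": {"weights": "inverse_distance", "n_perm": 999, "n_classes": 6},
    "krige": {"n_lags": 10, "ncols": 100},
    "ecoreg": {"predictors": ["mean_grs", "lat"], "outlier_policy": "exclude-and-refit",
               "alpha_enter": 0.05},
}

_RANGES = {
    ("qc", "min_call_rate"): (0.0, 1.0),
    ("qc", "min_imputation_quality"): (0.0, 1.0),
    ("assoc", "r2_prefilter"): (0.0, 1.0),
    ("score", "p_max"): (0.0, 1.0),
    ("score", "r2_max"): (0.0, 1.0),
    ("simulate", "rho"): (0.0, 0.999),
    ("simulate", "missing_rate"): (0.0, 0.999),
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring)."""

    data: dict

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @classmethod
    def from_dict(cls, user: Optional[dict] = None) -> "PipelineConfig":
        merged = json.loads(json.dumps(_DEFAULT_CONFIG))  # deep copy
        errors = []
        for section, values in (user or {}).items():
            if section == "seed":
                merged["seed"] = values
                continue
            if section not in merged:
                errors.append(f"unknown config section {section!r}")
                continue
            if not isinstance(values, dict):
                errors.append(f"section {section!r} must be a mapping")
                continue
            for key, val in values.items():
                if key not in merged[section]:
                    errors.append(f"unknown key {section}.{key}")
                else:
                    merged[section][key] = val
        for (section, key), (lo, hi) in _RANGES.items():
            v = merged[section][key]
            if v is not None and not (lo <= v <= hi):
                errors.append(f"{section}.{key}={v} outside [{lo}, {hi}]")
        if not isinstance(merged["seed"], int) or not (0 <= merged["seed"] < 2 ** 31):
            errors.append("seed must be an integer in [0, 2^31)")
        if errors:
            raise InvalidArgumentError(
                "invalid configuration:\n  - " + "\n  - ".join(errors))
        return cls(data=merged)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    seed: int
    stages: list = field(default_factory=list)   # {stage, outputs{name: sha}, seconds, status}

    def record(self, stage: str, outputs: dict, seconds: float, status: str = "ok"):
        self.stages.append({"stage": stage, "outputs": outputs,
                            "seconds": round(seconds, 3), "status": status})

    def write(self, path):
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stages": self.stages}, fh, indent=2)

    def hashes(self) -> dict:
        out = {}
        for st in self.stages:
            out.update({f"{st['stage']}/{k}": v for k, v in st["outputs"].items()})
        return out


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _simulate(config: PipelineConfig, seed: int):
    """Generate panel, studies and the generative specs from the config."""
    c = config["simulate"]
    rng = np.random.default_rng(seed + SEED_OFFSETS["panel"])
    m = int(c["n_snps"])
    maf_lo, maf_hi = c["maf_range"]
    base = rng.uniform(maf_lo, maf_hi, size=m)
    a = np.log(base / (1 - base))
    b = rng.normal(0.0, c["lat_slope_sd"], size=m)
    lon_slopes = rng.normal(0.0, c["lon_slope_sd"], size=m)
    # risk alleles ride a south-to-north frequency cline: causal SNPs get a
    # positive latitude slope so the population mean GRS increases northwards
    causal = rng.choice(m, size=int(c["n_causal"]), replace=False)
    b[causal] = np.abs(rng.normal(c["causal_lat_slope"],
                                  c["lat_slope_sd"], size=causal.size))
    # anchor the cline so intercepts refer to the centre of the map
    lat_mid = np.mean(c["lat_range"])
    lon_mid = np.mean(c["lon_range"])
    cline = synthio.ClineSpec(a=a - b * lat_mid - lon_slopes * lon_mid,
                              b=b, c=lon_slopes)
    blocks = synthio.LDBlockSpec.uniform(m, int(c["block_size"]), float(c["rho"]))
    snps = synthio.default_snp_records(m, rng=np.random.default_rng(12345))

    beta = np.zeros(m)
    beta[causal] = rng.uniform(*c["beta_range"], size=causal.size)
    model = synthio.DiseaseModelSpec(beta0=float(c["beta0"]), beta_snps=beta,
                                     beta_age=float(c["beta_age"]),
                                     beta_sex=float(c["beta_sex"]))

    pops = []
    for i in range(int(c["n_populations"])):
        pops.append(synthio.PopulationSpec(
            name=f"POP{i + 1:02d}",
            lat=float(rng.uniform(*c["lat_range"])),
            lon=float(rng.uniform(*c["lon_range"])),
            n=int(c["pop_size"])))
    panel = synthio.draw_population_panel(pops, cline, blocks,
                                          seed=seed + SEED_OFFSETS["panel"] + 1,
                                          snps=snps)
    studies = {}
    for si, st in enumerate(c["studies"]):
        freqs = synthio.allele_freq_at(cline, st["lat"], st["lon"])
        studies[st["name"]] = synthio.draw_case_control_study(
            freqs, model, int(st["n_cases"]), int(st["n_controls"]),
            blocks, seed=seed + SEED_OFFSETS["study"] + si,
            study=st["name"], snps=snps)
    return panel, studies, causal, cline, blocks


def _write_and_hash(writers: dict, out_dir: Path) -> dict:
    hashes = {}
    for name, write in writers.items():
        path = out_dir / name
        write(path)
        hashes[name] = _sha256(path)
    return hashes


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir, seed: Optional[int] = None) -> RunManifest:
    """Run all stages, writing tables + manifest into ``out_dir``.

    Returns the manifest; a stage failure halts downstream stages but the
    manifest (with the failure recorded) is still written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)
    manifest = RunManifest(seed=seed)
    try:
        _run_stages(config, out, seed, manifest)
    except Exception as exc:
        log.error("pipeline halted: %s", exc)
        manifest.record("failure", {}, 0.0, status=f"error: {exc}")
        raise
    finally:
        manifest.write(out / "manifest.json")
    return manifest


def _run_stages(config: PipelineConfig, out: Path, seed: int, manifest: RunManifest):
    c = config.data

    # -- simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    panel, studies, causal, cline, blocks = _simulate(config, seed)
    miss_rate = c["simulate"]["missing_rate"]
    raw_studies = {name: synthio.apply_missingness(ds, miss_rate,
                                                   seed + SEED_OFFSETS["missing"] + i)
                   for i, (name, ds) in enumerate(studies.items())}
    writers = {"panel.vcf": lambda p: vcfio.write_vcf(panel, p),
               "panel_samples.tsv": lambda p: vcfio.write_sample_tsv(panel, p)}
    for name, ds in raw_studies.items():
        writers[f"{name}.vcf"] = (lambda p, d=ds: vcfio.write_vcf(d, p))
        writers[f"{name}_samples.tsv"] = (lambda p, d=ds, n=name: vcfio.write_sample_tsv(d, p, study=n))
    manifest.record("simulate", _write_and_hash(writers, out), time.perf_counter() - t0)
    log.info("simulate: %d SNPs, %d studies, %d panel samples",
             panel.n_snps, len(studies), panel.n_samples)

    # -- qc ----------------------------------------------------------------
    t0 = time.perf_counter()
    qc_cfg = c["qc"]
    clean_studies, qc_tables = {}, []
    for name, ds in raw_studies.items():
        clean, rep = geno_qc.run_qc(ds, min_call_rate=qc_cfg["min_call_rate"])
        clean_studies[name] = clean
        tab = rep.snp_qc.copy()
        tab.insert(0, "study", name)
        qc_tables.append(tab)
    panel_clean, rep_panel = geno_qc.run_qc(panel, min_call_rate=qc_cfg["min_call_rate"])
    panel_imp = geno_qc.impute_expected_dosage(panel_clean, group_by=True)
    qc_all = pd.concat(qc_tables, ignore_index=True)
    manifest.record("qc", _write_and_hash(
        {"qc_snps.tsv": lambda p: qc_all.to_csv(p, sep="\t", index=False, float_format="%.6g")},
        out), time.perf_counter() - t0)
    log.info("qc: %s SNPs retained per study",
             {k: v.n_snps for k, v in clean_studies.items()})

    # -- association + meta, per replicate ---------------------------------
    t0 = time.perf_counter()
    n_rep = int(c["assoc"]["n_replicates"])
    r2_pref = float(c["assoc"]["r2_prefilter"])
    meta_reps, assoc_frames = [], []
    for rep_i in range(n_rep):
        per_study = {}
        for si, (name, ds) in enumerate(clean_studies.items()):
            replicate = synthio.apply_missingness(
                ds, miss_rate, seed + SEED_OFFSETS["missing"] + 1000 * (rep_i + 1) + si)
            replicate = geno_qc.impute_expected_dosage(replicate, group_by=True)
            kept, _ = assoc_meta.ld_prefilter(replicate, r2_max=r2_pref)
            res = assoc_meta.association_scan(replicate, snps=kept, study=name)
            res.insert(0, "replicate", rep_i + 1)
            per_study[name] = res
            assoc_frames.append(res)
        meta = assoc_meta.meta_scan({k: v.drop(columns="replicate")
                                     for k, v in per_study.items()})
        meta.insert(0, "replicate", rep_i + 1)
        meta_reps.append(meta)
    assoc_all = pd.concat(assoc_frames, ignore_index=True)
    meta_all = pd.concat(meta_reps, ignore_index=True)
    manifest.record("assoc", _write_and_hash({
        "association.tsv": lambda p: assoc_all.to_csv(p, sep="\t", index=False, float_format="%.6g"),
        "meta.tsv": lambda p: meta_all.to_csv(p, sep="\t", index=False, float_format="%.6g"),
    }, out), time.perf_counter() - t0)

    # -- risk score --------------------------------------------------------
    t0 = time.perf_counter()
    sc = c["score"]
    model = grs.select_score_snps([m.drop(columns="replicate") for m in meta_reps],
                                  ld_reference=panel_imp,
                                  p_max=sc["p_max"], r2_max=sc["r2_max"])
    log.info("score: %d SNPs selected (%s)", model.size, model.snp_ids)
    metrics_rows = []
    for name, ds in clean_studies.items():
        ss = grs.compute_scores(geno_qc.impute_expected_dosage(ds), model)
        pm = grs.prediction_metrics(ds.phenotype, ss.scores.grs.to_numpy())
        metrics_rows.append({"study": name, "nagelkerke_r2": pm.nagelkerke_r2,
                             "auc": pm.auc, "auc_lo": pm.auc_ci[0],
                             "auc_hi": pm.auc_ci[1], "n_cases": pm.n_cases,
                             "n_controls": pm.n_controls})
    metrics = pd.DataFrame(metrics_rows)
    pop_scores = grs.compute_scores(panel_imp, model)
    pop_coords = (panel_imp.sample_table()
                  .groupby("population", sort=False)[["lat", "lon"]].first())
    pop_summary = pop_scores.groups.merge(pop_coords, left_on="group",
                                          right_index=True)
    pop_summary = pop_summary.rename(columns={"group": "population",
                                              "mean": "mean_grs"})
    manifest.record("score", _write_and_hash({
        "model.tsv": lambda p: model.table.to_csv(p, sep="\t", index=False, float_format="%.6g"),
        "scores.tsv": lambda p: pop_scores.scores.to_csv(p, sep="\t", index=False, float_format="%.6g"),
        "pop_summary.tsv": lambda p: pop_summary.to_csv(p, sep="\t", index=False, float_format="%.6g"),
        "prediction.tsv": lambda p: metrics.to_csv(p, sep="\t", index=False, float_format="%.6g"),
    }, out), time.perf_counter() - t0)

    # -- spatial -----------------------------------------------------------
    t0 = time.perf_counter()
    sp = c["spatial"]
    frame = spatial.SpatialFrame.from_frame(pop_summary, "mean_grs")
    W = spatial.build_weights(frame, scheme=sp["weights"])
    res_i = spatial.randomization_test("I", frame.values, W, n_perm=sp["n_perm"],
                                       seed=seed + SEED_OFFSETS["spatial"])
    res_c = spatial.randomization_test("C", frame.values, W, n_perm=sp["n_perm"],
                                       seed=seed + SEED_OFFSETS["spatial"])
    corr = spatial.correlogram(frame, n_classes=sp["n_classes"],
                               n_perm=sp["n_perm"],
                               seed=seed + SEED_OFFSETS["correlogram"])
    auto = pd.DataFrame([
        {"statistic": "moran_i", "observed": res_i.observed, "p": res_i.p,
         "alternative": res_i.alternative, "n_perm": res_i.n_perm},
        {"statistic": "geary_c", "observed": res_c.observed, "p": res_c.p,
         "alternative": res_c.alternative, "n_perm": res_c.n_perm},
    ])
    manifest.record("spatial", _write_and_hash({
        "autocorrelation.tsv": lambda p: auto.to_csv(p, sep="\t", index=False, float_format="%.6g"),
        "correlogram.tsv": lambda p: corr.table.to_csv(p, sep="\t", index=False, float_format="%.6g"),
    }, out), time.perf_counter() - t0)

    # -- kriging -----------------------------------------------------------
    t0 = time.perf_counter()
    kg = c["krige"]
    emp = kriging.empirical_semivariogram(frame, n_lags=kg["n_lags"])
    vmodel = kriging.fit_spherical(emp)
    grid = kriging.ordinary_krige(frame, vmodel,
                                  kriging.GridSpec.from_frame(frame, ncols=kg["ncols"]))
    vario = pd.DataFrame({"h_km": emp.h, "gamma": emp.gamma, "n_pairs": emp.counts})
    vfit = pd.DataFrame([{"c0": vmodel.c0, "c1": vmodel.c1, "a_km": vmodel.a,
                          "model": vmodel.model, "flat": vmodel.flat}])
    manifest.record("krige", _write_and_hash({
        "variogram.tsv": lambda p: vario.to_csv(p, sep="\t", index=False, float_format="%.6g"),
        "variogram_fit.tsv": lambda p: vfit.to_csv(p, sep="\t", index=False, float_format="%.6g"),
        "grs_surface.asc": lambda p: kriging.write_ascii_grid(grid, p),
    }, out), time.perf_counter() - t0)

    # -- eco-regression ----------------------------------------------------
    t0 = time.perf_counter()
    sim = c["simulate"]
    eco = synthio.draw_event_rate_table(
        pop_summary.set_index("population")["mean_grs"],
        intercept=sim["eco_intercept"], slope=sim["eco_slope"],
        noise_sd=sim["eco_noise_sd"], seed=seed + SEED_OFFSETS["eco"])
    eco = eco.merge(pop_summary[["population", "mean_grs", "lat", "lon"]],
                    on="population")
    er = c["ecoreg"]
    result = ecoreg.eco_report(eco, predictors=er["predictors"],
                               outlier_policy=er["outlier_policy"],
                               alpha_enter=er["alpha_enter"])
    table = result.table()
    manifest.record("ecoreg", _write_and_hash({
        "eco_table.tsv": lambda p: vcfio.write_eco_tsv(eco, p),
        "eco_regression.tsv": lambda p: table.to_csv(p, sep="\t", index=False, float_format="%.6g"),
    }, out), time.perf_counter() - t0)

    # expose results for programmatic callers (acceptance script, tests)
    manifest.results = {
        "panel": panel_imp, "studies": clean_studies, "model": model,
        "metrics": metrics, "pop_summary": pop_summary, "moran": res_i,
        "geary": res_c, "correlogram": corr, "variogram": vmodel,
        "grid": grid, "eco": eco, "eco_result": result, "causal": causal,
        "meta_replicates": meta_reps,
    }
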