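"""End-to-end orchestration: simulate -> filter -> relate -> pretreat ->
fit -> downstream -> report, from a single configuration.

Every stage writes its outputs (all plain text: VCF, CSV/TSV, JSON) under
the configured output directory, a manifest records the seed and SHA-256
hashes of the stage outputs, and re-running with an identical
configuration reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .downstream import (
    build_accession_summaries,
    fit_cross_temperature,
    fit_emergence_model,
    fit_latitude_model,
)
from .filtering import run_filter_chain, write_plink_text, FilterReport
from .glm_latent import attach_gra
from .lmm import fit_model_suite
from .relatedness import compute_grm, mds_of_relationships, write_gcta_grm
from .simulate import simulate_cohort, write_cohort

log = logging.getLogger(__name__)

#: violation counts planted in the simulated VCF so the filter stage has
#: something to do; the manifest records the expectation per rule.
DEFAULT_PLANT_SPEC = {
    "multiallelic": 7,
    "near_indel": 5,
    "low_mq": 4,
    "depth_outlier": 6,
    "low_allele_depth": 4,
    "non_chromosome_scaffold": 3,
}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReportBundle:
    """Tables a reader needs to audit one pipeline run."""

    phenotype_summary: pd.DataFrame
    heritability: pd.DataFrame
    fixed_effects: pd.DataFrame
    downstream: pd.DataFrame
    filter_report: FilterReport
    manifest: dict = field(default_factory=dict)


KNOWN_TYPES = {"wild", "landrace"}


def summarize_phenotypes(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sample SD of the germination indicator and of germination
    time (germinated seeds only), per species x type x temperature, with
    the n behind every mean."""
    unknown = set(phenotypes["type"].astype(str)) - KNOWN_TYPES
    if unknown:
        raise ValueError(f"unknown accession type level(s): {sorted(unknown)}")
    rows = []
    for (sp, t, temp), sub in phenotypes.groupby(
        ["species", "type", "temperature"], observed=True
    ):
        germ = sub["germinated"].astype(float)
        gt = sub.loc[sub["germinated"].astype(bool), "gt_hours"].astype(float)
        rows.append(
            {
                "species": sp,
                "type": t,
                "temperature": temp,
                "n_seeds": len(sub),
                "gr_mean": germ.mean(),
                "gr_sd": germ.std(ddof=1) if len(sub) > 1 else 0.0,
                "n_germinated": int(germ.sum()),
                "gt_mean": gt.mean() if len(gt) else np.nan,
                "gt_sd": gt.std(ddof=1) if len(gt) > 1 else (0.0 if len(gt) else np.nan),
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str) + "\n")


def _split_cold_warm(fits: dict, cold_label: str, warm_label: str):
    cold = {k.split(":")[0]: v for k, v in fits.items() if k.endswith(f":{cold_label}")}
    warm = {k.split(":")[0]: v for k, v in fits.items() if k.endswith(f":{warm_label}")}
    return cold, warm


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages in order; outputs land under ``config.out_dir``.

    A stage failure aborts with the stage name; outputs of completed
    stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    manifest: dict = {"seed": config.rng_seed, "stages": {}}
    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(config.simulation, rng_seed=config.rng_seed)
        if config.vcf_path is None:
            cohort = simulate_cohort(sim_cfg)
            write_cohort(cohort, out, plant_spec=DEFAULT_PLANT_SPEC,
                         rng_seed=config.rng_seed)
            vcf_path = out / "cohort.vcf"
            phenotypes = cohort.phenotypes
            emergence = cohort.emergence
        else:
            vcf_path = Path(config.vcf_path)
            if config.phenotype_csv is None:
                raise ValueError("phenotype_csv is required with an external VCF")
            phenotypes = pd.read_csv(config.phenotype_csv)
            emergence = None
            if config.emergence_csv is not None:
                em = pd.read_csv(config.emergence_csv)
                emergence = em.set_index("accession")["emergence"]
        manifest["stages"]["simulate"] = {"vcf": _sha256(vcf_path)}

        stage = "filter"
        genotypes, filter_report = run_filter_chain(vcf_path, config.filters)
        filter_report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        write_plink_text(genotypes, out / "filtered")
        manifest["stages"]["filter"] = {
            "n_snps": genotypes.n_snps,
            "accessions_removed": filter_report.accessions_removed,
            "report": _sha256(out / "filter_report.tsv"),
        }

        stage = "relate"
        rel = compute_grm(genotypes)
        write_gcta_grm(rel, out / "panel")
        mds = mds_of_relationships(rel, n_axes=4)
        coords = pd.DataFrame(
            mds.coordinates,
            index=rel.accession_ids,
            columns=[f"axis{k + 1}" for k in range(mds.coordinates.shape[1])],
        )
        coords.to_csv(out / "mds.tsv", sep="\t")
        manifest["stages"]["relate"] = {
            "pct_variance": [round(float(v), 6) for v in mds.pct_variance],
        }

        stage = "pretreat"
        phenotypes = phenotypes.loc[
            phenotypes["accession"].isin(rel.accession_ids)
        ].reset_index(drop=True)
        phen_gra, glm_fits = attach_gra(phenotypes, residual_type=config.residual_type)
        phen_gra.to_csv(out / "phenotypes_gra.csv", index=False)
        _write_json({k: v.to_dict() for k, v in glm_fits.items()}, out / "glm_fits.json")
        manifest["stages"]["pretreat"] = {"residual_type": config.residual_type}

        stage = "fit"
        if config.vcf_path is None:
            labels = sim_cfg.temperature_labels
        elif "temperature_c" in phen_gra.columns:
            labels = list(
                phen_gra.groupby("temperature", observed=True)["temperature_c"]
                .mean().sort_values().index
            )
        else:
            labels = sorted(phen_gra["temperature"].astype(str).unique())
        all_fits: dict = {}
        herit_rows = []
        fixef_rows = []
        for species, sub in phen_gra.groupby("species", observed=True):
            for trait, suites in (("GT", config.gt_suites), ("GRA", config.gra_suites)):
                for suite in suites:
                    fits = fit_model_suite(sub, rel, trait, suite)
                    for label, fit in fits.items():
                        key = f"{species}/{trait}/{suite}/{label}"
                        all_fits[key] = fit
                        herit_rows.append(
                            {
                                "species": species, "trait": trait, "suite": suite,
                                "subset": label, "h2": fit.h2,
                                "sigma2_g": fit.sigma2_g, "sigma2_e": fit.sigma2_e,
                                "n_obs": fit.n_obs,
                            }
                        )
                        for term in fit.params.index:
                            z, p = fit.wald_z(term)
                            fixef_rows.append(
                                {
                                    "species": species, "trait": trait,
                                    "suite": suite, "subset": label, "term": term,
                                    "estimate": fit.params[term],
                                    "se": fit.bse[term], "z": z, "p": p,
                                }
                            )
        herit = pd.DataFrame(herit_rows)
        fixef = pd.DataFrame(fixef_rows)
        herit.to_csv(out / "heritability.tsv", sep="\t", index=False)
        fixef.to_csv(out / "fixed_effects.tsv", sep="\t", index=False)
        _write_json({k: v.to_dict() for k, v in all_fits.items()}, out / "fits.json")
        gblup_rows = []
        for key, fit in all_fits.items():
            s = fit.gblups.rename(key)
            gblup_rows.append(s)
        pd.concat(gblup_rows, axis=1).rename_axis("accession").to_csv(
            out / "gblups.tsv", sep="\t"
        )
        manifest["stages"]["fit"] = {"n_models": len(all_fits)}

        stage = "downstream"
        meta_cols = ["accession", "species", "type", "country", "latitude"]
        meta = phen_gra[meta_cols].drop_duplicates("accession")
        down_rows = []
        downstream_fits = {}
        for species, msub in meta.groupby("species", observed=True):
            for trait in ("GT", "GRA"):
                suite = "1c" if trait == "GT" else "3c"
                fits = {
                    k.split("/", 3)[3]: v
                    for k, v in all_fits.items()
                    if k.startswith(f"{species}/{trait}/{suite}/")
                }
                cold, warm = _split_cold_warm(fits, labels[0], labels[1])
                if not cold or not warm:
                    continue
                summaries = build_accession_summaries(cold, warm, msub, emergence)
                summaries.to_csv(
                    out / f"summary_{species}_{trait}.tsv", sep="\t", index=False
                )
                ct = fit_cross_temperature(summaries, trait=trait)
                for k, f in ct.items():
                    downstream_fits[f"{species}/{trait}/model4/{k}"] = f
                lat = fit_latitude_model(summaries)
                for k, f in lat.items():
                    downstream_fits[f"{species}/{trait}/model5/{k}"] = f
                if trait == "GRA" and emergence is not None:
                    # mu3: n-weighted mean of the cold stage-two intercepts;
                    # a fixed offset only shifts mu6, never slope or R2
                    mu3s = [(f.params.get("intercept", np.nan), f.n_obs) for f in cold.values()]
                    w = np.array([n for _, n in mu3s], dtype=float)
                    mu3 = float(np.average([m for m, _ in mu3s], weights=w))
                    try:
                        f6 = fit_emergence_model(summaries, mu3)
                        downstream_fits[f"{species}/{trait}/model6/pooled"] = f6
                    except Exception as err:  # degenerate emergence data
                        log.warning("emergence model skipped: %s", err)
        for key, f in downstream_fits.items():
            for term in f.params.index:
                down_rows.append(
                    {
                        "model": key, "term": term,
                        "estimate": f.params[term], "se": f.bse[term],
                        "z": f.z[term], "p": f.p[term],
                        "n": f.n, "adj_r2": f.adj_r2,
                    }
                )
        down = pd.DataFrame(down_rows)
        down.to_csv(out / "downstream.tsv", sep="\t", index=False)
        manifest["stages"]["downstream"] = {"n_models": len(downstream_fits)}

        stage = "report"
        summary = summarize_phenotypes(phen_gra)
        summary.to_csv(out / "phenotype_summary.tsv", sep="\t", index=False)
        for f in ("phenotype_summary.tsv", "heritability.tsv", "fixed_effects.tsv",
                  "downstream.tsv", "gblups.tsv", "mds.tsv"):
            manifest["stages"].setdefault("report", {})[f] = _sha256(out / f)
        _write_json(manifest, out / "manifest.json")
    except Exception as err:
        if isinstance(err, PipelineStageError):
            raise
        raise PipelineStageError(stage, err) from err

    return ReportBundle(
        phenotype_summary=summary,
        heritability=herit,
        fixed_effects=fixef,
        downstream=down,
        filter_report=filter_report,
        manifest=manifest,
    )
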