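"""Self-contained validation experiments.

Each function re-runs one verifiable property of the pipeline from
scratch — planted-violation filter accounting, closed-form REML and GLM
oracles, and simulation-based parameter recovery — and returns the
measured quantities.  The test suite asserts on these numbers and the
acceptance script reports them.

Experiment sizes are chosen so the whole battery runs in well under ten
minutes on one CPU; parameter-recovery cohorts are simulated under the
assumptions of the model being fitted (cross-temperature genetic
correlation 1 where a single genetic value is estimated), because
recovery against a deliberately misspecified generator would measure the
misspecification, not the estimator.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .config import FilterConfig, SimulationConfig
from .downstream import (
    build_accession_summaries,
    fit_cross_temperature,
    fit_latitude_model,
)
from .filtering import run_filter_chain
from .lmm import GBLUPModel, fit_model_suite
from .relatedness import compute_grm
from .simulate import simulate_cohort, simulate_genotypes, write_contaminated_vcf

#: violation counts for the filter fixture (~2,000 sites, 30 accessions)
FIXTURE_PLANT_SPEC = {
    "multiallelic": 7,
    "near_indel": 5,
    "low_mq": 4,
    "depth_outlier": 6,
    "low_allele_depth": 4,
    "non_chromosome_scaffold": 3,
}


def filter_fixture_counts(seed: int = 0, n_sites: int = 2000, n_accessions: int = 30):
    """Write the contaminated VCF and run the filter chain.

    Returns ``(expected, observed, accession_ok)``: per-rule removal counts
    expected from the planted manifest, the counts the chain reported, and
    whether exactly the planted low-depth accession was removed.
    """
    cfg = SimulationConfig(
        n_accessions=n_accessions, n_snps=n_sites, rng_seed=seed, seeds_per_cell=1
    )
    geno = simulate_genotypes(cfg)
    low_acc = (geno.accession_ids[1],)
    with tempfile.TemporaryDirectory() as tmp:
        vcf = Path(tmp) / "fixture.vcf"
        manifest = write_contaminated_vcf(
            geno, FIXTURE_PLANT_SPEC, vcf, rng_seed=seed, low_depth_accessions=low_acc
        )
        _, report = run_filter_chain(vcf, FilterConfig())
    expected = manifest["expected_removals"]
    observed = {rule: report.removed(rule) for rule in expected}
    accession_ok = report.accessions_removed == list(low_acc)
    return expected, observed, accession_ok


def reml_balanced_oracle(tol: float = 1e-14):
    """EM-REML on the balanced one-way layout y = (1,2,3,4), two
    accessions of two seeds, identity relationships, intercept only.
    The closed-form ANOVA-REML solution is sigma2_e = MSW = 0.5 and
    sigma2_g = (MSB - MSW)/n = (4 - 0.5)/2 = 1.75."""
    y = np.array([1.0, 2.0, 3.0, 4.0])
    X = np.ones((4, 1))
    idx = np.array([0, 0, 1, 1])
    fit = GBLUPModel(y, X, idx, np.eye(2), xnames=["intercept"]).fit(
        tol=tol, max_iter=20000
    )
    return fit.sigma2_g, fit.sigma2_e


def grm_hand_oracle():
    """GRM of a single SNP with dosages (0, 2): the estimator gives
    G = [[2, -2], [-2, 2]], G* = [[1, -1], [-1, 1]], D = [[0, 2], [2, 0]]."""
    import pandas as pd

    from .simulate import GenotypeMatrix

    geno = GenotypeMatrix(
        dosages=np.array([[0], [2]], dtype=np.int8),
        accession_ids=["a", "b"],
        snps=pd.DataFrame({"chrom": ["A01"], "pos": [100], "ref": ["A"], "alt": ["C"]}),
    )
    rel = compute_grm(geno)
    return rel.G, rel.G_star, rel.D


def mds_collinear_oracle():
    """Classical MDS of three collinear points (distances 1, 1, 2): one
    positive eigenvalue carrying 100% of the variance, coordinates
    (+1, 0, -1) under the first-accession sign convention."""
    from .relatedness import classical_mds

    D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
    res = classical_mds(D, n_axes=2)
    return res.pct_variance, res.coordinates


def glm_intercept_oracle():
    """Intercept-only logit of a 0/1 outcome with mean 0.75: the MLE is
    logit(0.75) = log 3."""
    import pandas as pd

    from .glm_latent import PretreatmentModel

    df = pd.DataFrame(
        {
            "germinated": [1, 1, 1, 0] * 50,
            "temperature": "cold",
            "batch": 0,
            "year": "y1",
            "conservation_days": 100.0,
        }
    )
    res = PretreatmentModel(df, terms=()).fit()
    return float(res.params["intercept"])


#: conditions of the heritability-recovery experiment
H2_RECOVERY = dict(n_accessions=100, n_snps=400, seeds_per_cell=25, truth=0.3)


def h2_recovery(n_reps: int = 50, seed: int = 0):
    """Mean EM-REML heritability across simulated cohorts of 100
    accessions x 50 seeds (25 per temperature) at true h2 = 0.3."""
    h2s = []
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_accessions=H2_RECOVERY["n_accessions"],
            n_snps=H2_RECOVERY["n_snps"],
            seeds_per_cell=H2_RECOVERY["seeds_per_cell"],
            ge_correlation=1.0,
            latitude_slope=0.0,
            rng_seed=int(seed) * 1000 + rep,
        )
        cohort = simulate_cohort(cfg)
        rel = compute_grm(cohort.genotypes)
        fit = fit_model_suite(cohort.phenotypes, rel, "GT", "1", tol=1e-8)["all"]
        h2s.append(fit.h2)
    h2s = np.asarray(h2s)
    return {
        "mean_h2": float(h2s.mean()),
        "sd_h2": float(h2s.std(ddof=1)),
        "truth": H2_RECOVERY["truth"],
        "n_reps": n_reps,
    }


def _cold_warm_summaries(cohort, rel):
    fits = fit_model_suite(cohort.phenotypes, rel, "GT", "1c")
    cold = {k.split(":")[0]: v for k, v in fits.items() if k.endswith(":cold")}
    warm = {k.split(":")[0]: v for k, v in fits.items() if k.endswith(":warm")}
    meta = cohort.phenotypes[["accession", "species", "type", "country", "latitude"]]
    return build_accession_summaries(cold, warm, meta)


def ge_null_recovery(n_reps: int = 20, seed: int = 0):
    """Cohorts with cross-temperature genetic correlation 1 and no
    latitude cline: the cross-temperature regression slope should sit
    near 1 (gBLUP reliability keeps it slightly below) and the latitude
    term of the heat-tolerance model should be non-significant."""
    slopes, lat_p = [], []
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_accessions=80, n_snps=300, seeds_per_cell=40,
            ge_correlation=1.0, latitude_slope=0.0,
            rng_seed=int(seed) * 1000 + 500 + rep,
        )
        cohort = simulate_cohort(cfg)
        rel = compute_grm(cohort.genotypes)
        summ = _cold_warm_summaries(cohort, rel)
        slopes.append(float(fit_cross_temperature(summ)["pooled"].params["C"]))
        for t, f in fit_latitude_model(summ).items():
            lat_p.append(float(f.p["latitude"]))
    return {
        "median_slope": float(np.median(slopes)),
        "frac_latitude_nonsignificant": float(np.mean(np.asarray(lat_p) > 0.05)),
        "n_reps": n_reps,
    }


#: conditions of the latitude-slope recovery experiment (low residual noise)
LATITUDE_RECOVERY = dict(truth=-0.02, sigma2_e=4.0, seeds_per_cell=50,
                         latitude_range=(20.0, 70.0))


def latitude_slope_recovery(n_reps: int = 20, seed: int = 0):
    """Cohorts with a planted latitude effect of -0.02 h per degree on the
    warm-temperature genetic values, low residual noise: the latitude
    coefficient of the heat-tolerance regression (types pooled with a
    type covariate) should recover the planted slope."""
    coefs = []
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_accessions=80, n_snps=300,
            seeds_per_cell=LATITUDE_RECOVERY["seeds_per_cell"],
            sigma2_e=LATITUDE_RECOVERY["sigma2_e"],
            ge_correlation=1.0,
            latitude_slope=LATITUDE_RECOVERY["truth"],
            latitude_range=LATITUDE_RECOVERY["latitude_range"],
            rng_seed=int(seed) * 1000 + 900 + rep,
        )
        cohort = simulate_cohort(cfg)
        rel = compute_grm(cohort.genotypes)
        summ = _cold_warm_summaries(cohort, rel)
        joint = fit_latitude_model(summ, joint=True)["joint"]
        coefs.append(float(joint.params["latitude"]))
    return {
        "mean_latitude_coef": float(np.mean(coefs)),
        "sd": float(np.std(coefs, ddof=1)),
        "truth": LATITUDE_RECOVERY["truth"],
        "n_reps": n_reps,
    }
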