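"""Synthetic cohort generator.

Produces accession-panel genotypes with ancestral population structure
(Balding-Nichols model), polygenic right-censored germination times and
binary germination outcomes under a two-temperature design, accession-level
G-by-E correlated with latitude, field emergence rates linked to the
germination-rate genetic values, and a deliberately contaminated VCF whose
planted rule violations exercise the variant filters.

The generator is deterministic: identical configurations (including
``rng_seed``) yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig

_BASES = ("A", "C", "G", "T")

# Planted-violation classes and the filter rule expected to remove each.
PLANT_RULES = {
    "multiallelic": "multiallelic",
    "near_indel": "near_indel",
    "low_mq": "mapping_quality",
    "depth_outlier": "site_depth",
    "low_allele_depth": "allele_depth",
    "non_chromosome_scaffold": "chromosome",
}
# The indel half of each near_indel pair is itself removed at this step.
INDEL_RULE = "indel"

CLEAN_DEPTH = 60  # constant per-sample DP at clean sites; keeps depth
# percentiles degenerate so the 5th-95th band removes planted outliers only.


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs allele-dosage matrix with SNP metadata."""

    dosages: np.ndarray                 # (n_accessions, n_snps), values in {0,1,2}
    accession_ids: list
    snps: pd.DataFrame                  # columns chrom, pos, ref, alt
    populations: np.ndarray | None = None   # dominant ancestral population index

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def take_snps(self, index) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            accession_ids=list(self.accession_ids),
            snps=self.snps.iloc[index].reset_index(drop=True),
            populations=self.populations,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{c}:{p}" for c, p in zip(self.snps["chrom"], self.snps["pos"])]
        return pd.DataFrame(self.dosages, index=self.accession_ids, columns=cols)


@dataclass
class SimulatedCohort:
    """A full synthetic study: genotypes, per-seed phenotypes, truth."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    emergence: pd.Series                # per-accession rate in [0, 1]
    latitudes: pd.Series                # degrees
    true_gblups_cold: pd.Series         # GT genetic values, hours
    true_gblups_warm: pd.Series
    true_liability_cold: pd.Series      # GR genetic values, logit scale
    true_liability_warm: pd.Series
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        geno_ids = set(self.genotypes.accession_ids)
        if not set(self.phenotypes["accession"]).issubset(geno_ids):
            raise ValueError("phenotype accession ids not a subset of genotype ids")
        germ = self.phenotypes["germinated"].astype(bool)
        gt = self.phenotypes["gt_hours"]
        if gt[germ].isna().any() or gt[~germ].notna().any():
            raise ValueError("germination time must be present iff germinated")
        censor = self.truth.get("censor_hours", np.inf)
        if (gt[germ] >= censor).any():
            raise ValueError("recorded germination times must be below the censor")


def _rng(seed, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Draw structured diploid dosages under the Balding-Nichols model.

    Ancestral allele frequencies are Uniform(0.05, 0.95); each of the
    ``k_pops`` populations draws its frequency from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst``; accession-level
    frequencies are admixture-weighted mixtures (Dirichlet weights, or
    equal-size blocks when ``hard_split``); dosages are Binomial(2, freq).
    Monomorphic columns are re-drawn so every SNP is polymorphic.
    """
    rng = _rng(cfg.rng_seed, 0)
    n, m, k, f = cfg.n_accessions, cfg.n_snps, cfg.k_pops, cfg.fst

    if cfg.hard_split:
        pops = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
        Q = np.zeros((n, k))
        Q[np.arange(n), pops] = 1.0
    else:
        Q = rng.dirichlet(np.full(k, cfg.admixture_concentration), size=n)
        pops = np.argmax(Q, axis=1)

    def draw(n_cols: int) -> np.ndarray:
        p_anc = rng.uniform(0.05, 0.95, size=n_cols)
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        p_pop = rng.beta(a, b, size=(k, n_cols))          # (k, m)
        p_acc = Q @ p_pop                                 # (n, m)
        return rng.binomial(2, p_acc).astype(np.int8)

    X = draw(m)
    for _ in range(100):
        mono = (X == X[0]).all(axis=0)
        if not mono.any():
            break
        X[:, mono] = draw(int(mono.sum()))
    else:  # pragma: no cover - vanishingly unlikely at n >= 2
        raise RuntimeError("could not draw a fully polymorphic panel")

    # SNP metadata: ten chromosome scaffolds, positions spaced >= 100 bp so
    # that planted VCF records can be interleaved without accidental
    # indel-proximity to clean sites.
    n_chrom = 10
    chrom_of = np.minimum(np.arange(m) * n_chrom // max(m, 1), n_chrom - 1)
    chroms = np.array([f"A{c + 1:02d}" for c in chrom_of])
    pos = np.empty(m, dtype=np.int64)
    for c in range(n_chrom):
        idx = np.flatnonzero(chrom_of == c)
        steps = rng.integers(100, 1000, size=idx.size)
        pos[idx] = 1000 + np.cumsum(steps)
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    snps = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": [_BASES[i] for i in ref_i],
            "alt": [_BASES[i] for i in alt_i],
        }
    )
    ids = [f"acc{i:03d}" for i in range(n)]
    return GenotypeMatrix(dosages=X, accession_ids=ids, snps=snps, populations=pops)


def _bend_grm(G: np.ndarray, eps: float = 1e-6, min_eig: float = 1e-8) -> np.ndarray:
    """Add ``eps`` to the diagonal until the smallest eigenvalue clears
    ``min_eig``; small simulated panels can be rank-deficient."""
    G = np.asarray(G, dtype=float).copy()
    for _ in range(60):
        w = np.linalg.eigvalsh(G)
        if w[0] >= min_eig:
            return G
        G[np.diag_indices_from(G)] += eps
        eps *= 2.0
    raise np.linalg.LinAlgError("relationship matrix could not be bent to PSD")


def simulate_phenotypes(cfg: SimulationConfig, genotypes: GenotypeMatrix) -> SimulatedCohort:
    """Draw per-seed phenotypes and per-accession emergence on the panel.

    Cold genetic values are a_C ~ N(0, sigma2_g * G); warm values are
    a_W = rho a_C + sqrt(1 - rho^2) a_perp + latitude_slope * (lat - mean lat),
    so the simulated heat tolerance a_W - a_C carries both a G-by-E term and
    a latitude cline.  Germination time is Gaussian around the fixed-effect
    + genetic mean (log-normal optionally), right-censored at
    ``censor_hours``; the binary germination outcome follows a logistic
    latent scale with its own genetic values; emergence is a logistic
    function of the cold germination-rate genetic value plus noise.
    """
    from .relatedness import compute_grm

    rng = _rng(cfg.rng_seed, 1)
    n = genotypes.n_accessions
    fe = cfg.fixed_effects
    ids = list(genotypes.accession_ids)

    G = compute_grm(genotypes).G
    L = np.linalg.cholesky(_bend_grm(G))

    def mvn(scale2: float) -> np.ndarray:
        z = rng.standard_normal(n)
        return np.sqrt(scale2) * (L @ z)

    lat = rng.uniform(*cfg.latitude_range, size=n)
    lat_c = lat - lat.mean()
    rho = cfg.ge_correlation

    a_c = mvn(cfg.sigma2_g)
    a_w = rho * a_c + np.sqrt(max(0.0, 1.0 - rho**2)) * mvn(cfg.sigma2_g)
    a_w = a_w + cfg.latitude_slope * lat_c
    b_c = mvn(cfg.sigma2_g_liability)
    b_w = rho * b_c + np.sqrt(max(0.0, 1.0 - rho**2)) * mvn(cfg.sigma2_g_liability)
    b_w = b_w + cfg.latitude_slope * lat_c

    pops = genotypes.populations
    if pops is None:
        pops = np.zeros(n, dtype=int)
    is_wild = pops == 0          # first ancestral cluster plays the wild group
    countries = np.array([cfg.countries[p % len(cfg.countries)] for p in pops])
    year_idx = rng.integers(0, len(cfg.years), size=n)
    cons_days = rng.uniform(*cfg.conservation_range, size=n)
    cons_c = cons_days - cons_days.mean()

    batch_gt = rng.normal(0.0, fe.gt_batch_sd, size=cfg.n_batches)
    batch_gr = rng.normal(0.0, fe.gr_batch_sd, size=cfg.n_batches)

    labels = cfg.temperature_labels
    degrees = dict(cfg.temperatures)
    rows = []
    s = cfg.seeds_per_cell
    for i in range(n):
        for t_idx, lab in enumerate(labels):
            warm = t_idx == 1
            a = a_w[i] if warm else a_c[i]
            b = b_w[i] if warm else b_c[i]
            batches = rng.integers(0, cfg.n_batches, size=s)
            mu_gt = (
                fe.gt_intercept
                + (fe.gt_temperature if warm else 0.0)
                + (fe.gt_type_wild if is_wild[i] else 0.0)
                + batch_gt[batches]
                + (fe.gt_year if year_idx[i] == 1 else 0.0)
                + fe.gt_conservation * cons_c[i]
                + a
            )
            if cfg.gt_distribution == "gaussian":
                gt = mu_gt + np.sqrt(cfg.sigma2_e) * rng.standard_normal(s)
            else:  # log-normal, heavier right tail, variance approx sigma2_e
                mu_pos = np.maximum(mu_gt, 1.0)
                cv = np.sqrt(np.log1p(cfg.sigma2_e / mu_pos**2))
                gt = mu_pos * np.exp(cv * rng.standard_normal(s) - cv**2 / 2.0)
            eta = (
                fe.gr_intercept
                + (fe.gr_temperature if warm else 0.0)
                + (fe.gr_type_wild if is_wild[i] else 0.0)
                + batch_gr[batches]
                + (fe.gr_year if year_idx[i] == 1 else 0.0)
                + fe.gr_conservation * cons_c[i]
                + (fe.gr_conservation_x_temp * cons_c[i] if warm else 0.0)
                + b
            )
            viable = rng.random(s) < 1.0 / (1.0 + np.exp(-eta))
            germinated = viable & (gt < cfg.censor_hours)
            for j in range(s):
                rows.append(
                    (
                        ids[i],
                        cfg.species,
                        "wild" if is_wild[i] else "landrace",
                        countries[i],
                        round(lat[i], 6),
                        lab,
                        degrees[lab],
                        int(batches[j]),
                        cfg.years[year_idx[i]],
                        round(cons_days[i], 3),
                        int(germinated[j]),
                        round(float(gt[j]), 4) if germinated[j] else np.nan,
                    )
                )
    phen = pd.DataFrame(
        rows,
        columns=[
            "accession", "species", "type", "country", "latitude",
            "temperature", "temperature_c", "batch", "year",
            "conservation_days", "germinated", "gt_hours",
        ],
    )

    noise = rng.normal(0.0, fe.emergence_noise_sd, size=n)
    emergence = 1.0 / (1.0 + np.exp(-(fe.emergence_intercept + fe.emergence_gamma * b_c + noise)))

    truth = {
        "config": cfg.to_dict(),
        "censor_hours": cfg.censor_hours,
        "batch_effects_gt": batch_gt.tolist(),
        "batch_effects_gr": batch_gr.tolist(),
        "is_wild": is_wild.tolist(),
        "latitude_centered": lat_c.tolist(),
        "true_heat_tolerance": (a_w - a_c).tolist(),
    }
    return SimulatedCohort(
        genotypes=genotypes,
        phenotypes=phen,
        emergence=pd.Series(emergence, index=ids, name="emergence"),
        latitudes=pd.Series(lat, index=ids, name="latitude"),
        true_gblups_cold=pd.Series(a_c, index=ids, name="true_gblup_cold"),
        true_gblups_warm=pd.Series(a_w, index=ids, name="true_gblup_warm"),
        true_liability_cold=pd.Series(b_c, index=ids, name="true_liability_cold"),
        true_liability_warm=pd.Series(b_w, index=ids, name="true_liability_warm"),
        truth=truth,
    )


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Genotypes and phenotypes in one call."""
    return simulate_phenotypes(cfg, simulate_genotypes(cfg))


def _clean_sample_fields(dosage: int, depth: int) -> str:
    ref_d = {0: depth, 1: depth // 2, 2: 0}[dosage]
    alt_d = depth - ref_d
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[dosage]
    return f"{gt}:{ref_d},{alt_d}:{depth}"


def write_contaminated_vcf(
    genotypes: GenotypeMatrix,
    plant_spec: dict,
    path,
    rng_seed: int = 0,
    low_depth_accessions: tuple = (),
) -> dict:
    """Write a VCF 4.2 of the panel plus planted filter-rule violations.

    ``plant_spec`` maps violation classes (multiallelic, near_indel, low_mq,
    depth_outlier, low_allele_depth, non_chromosome_scaffold) to counts.
    Clean sites carry a constant per-sample depth so that only planted
    records fall outside the 5th-95th site-depth percentile band.
    Accessions named in ``low_depth_accessions`` are written with a mean
    depth below the retention threshold at every site.

    Returns a manifest: for every planted record, its coordinates, class and
    the filter rule expected to remove it.
    """
    unknown = set(plant_spec) - set(PLANT_RULES)
    if unknown:
        raise ConfigurationError(f"unknown violation classes: {sorted(unknown)}")
    rng = _rng(rng_seed, 2)
    snps = genotypes.snps
    n_acc = genotypes.n_accessions
    low_idx = {genotypes.accession_ids.index(a) for a in low_depth_accessions}

    # Host gaps: each planted record sits 37 bp after a distinct clean site,
    # far enough (>= 5 bp) from every clean SNP and from other plants.
    n_plants = sum(int(v) for v in plant_spec.values())
    eligible = np.flatnonzero(np.arange(len(snps)) < len(snps))
    if n_plants > len(eligible):
        raise ConfigurationError("more planted records than available gaps")
    hosts = rng.choice(eligible, size=n_plants, replace=False)

    records = []  # (chrom, pos, line-fields tuple)
    manifest = []

    def sample_cols(dosages, depth_override=None):
        cols = []
        for j in range(n_acc):
            depth = 15 if j in low_idx else CLEAN_DEPTH
            if depth_override is not None:
                depth = depth_override
            cols.append(_clean_sample_fields(int(dosages[j]), depth))
        return cols

    for s_i in range(len(snps)):
        row = snps.iloc[s_i]
        records.append(
            (
                row["chrom"], int(row["pos"]), row["ref"], row["alt"], "60",
                sample_cols(genotypes.dosages[:, s_i]),
            )
        )

    host_iter = iter(hosts)
    out_i = 0
    for cls in sorted(plant_spec):
        for rep in range(int(plant_spec[cls])):
            h = next(host_iter)
            chrom = snps.iloc[h]["chrom"]
            base = int(snps.iloc[h]["pos"]) + 37
            if cls == "multiallelic":
                cols = [f"0/1:{CLEAN_DEPTH - 20},10,10:{CLEAN_DEPTH}"] * n_acc
                records.append((chrom, base, "A", "T,G", "60", cols))
                manifest.append(
                    {"chrom": chrom, "pos": base, "class": cls,
                     "expected_rule": PLANT_RULES[cls]}
                )
            elif cls == "near_indel":
                half = CLEAN_DEPTH // 2
                cols = [f"0/1:{half},{half}:{CLEAN_DEPTH}"] * n_acc
                records.append((chrom, base, "AT", "A", "60", cols))   # indel anchor
                records.append((chrom, base + 3, "C", "G", "60", cols))  # SNP 3 bp away
                manifest.append(
                    {"chrom": chrom, "pos": base, "class": cls,
                     "expected_rule": INDEL_RULE}
                )
                manifest.append(
                    {"chrom": chrom, "pos": base + 3, "class": cls,
                     "expected_rule": PLANT_RULES[cls]}
                )
            elif cls == "low_mq":
                # exercise the boundary (MQ == 40 fails the strict > rule)
                mq = "40" if rep == 0 else "35"
                records.append((chrom, base, "G", "A", mq, sample_cols(np.zeros(n_acc))))
                manifest.append(
                    {"chrom": chrom, "pos": base, "class": cls,
                     "expected_rule": PLANT_RULES[cls]}
                )
            elif cls == "depth_outlier":
                depth = 5 if rep % 2 == 0 else 400
                cols = [f"0/1:{depth // 2},{depth - depth // 2}:{depth}"] * n_acc
                records.append((chrom, base, "T", "C", "60", cols))
                manifest.append(
                    {"chrom": chrom, "pos": base, "class": cls,
                     "expected_rule": PLANT_RULES[cls]}
                )
            elif cls == "low_allele_depth":
                cols = sample_cols(np.ones(n_acc))
                retained = [j for j in range(n_acc) if j not in low_idx]
                cols[retained[rep % len(retained)]] = f"0/1:9,9:{CLEAN_DEPTH}"
                records.append((chrom, base, "A", "G", "60", cols))
                manifest.append(
                    {"chrom": chrom, "pos": base, "class": cls,
                     "expected_rule": PLANT_RULES[cls]}
                )
            elif cls == "non_chromosome_scaffold":
                scaf = f"scaffold_{441 + rep}"
                records.append((scaf, 1000 + 100 * rep, "C", "T", "60",
                                sample_cols(np.zeros(n_acc))))
                manifest.append(
                    {"chrom": scaf, "pos": 1000 + 100 * rep, "class": cls,
                     "expected_rule": PLANT_RULES[cls]}
                )
            out_i += 1

    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(r[0] for r in records))}
    # chromosomes first (sorted), scaffolds after
    names = sorted(chrom_order, key=lambda c: (c.startswith("scaffold"), c))
    chrom_rank = {c: i for i, c in enumerate(names)}
    records.sort(key=lambda r: (chrom_rank[r[0]], r[1]))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=germtherm-synthetic\n")
        for c in names:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.accession_ids)
            + "\n"
        )
        for chrom, pos, ref, alt, mq, cols in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t100\tPASS\tMQ={mq}\tGT:AD:DP\t"
                + "\t".join(cols)
                + "\n"
            )

    expected = {}
    for rec in manifest:
        expected[rec["expected_rule"]] = expected.get(rec["expected_rule"], 0) + 1
    return {
        "planted": manifest,
        "n_clean_sites": len(snps),
        "expected_removals": expected,
        "low_depth_accessions": list(low_depth_accessions),
    }


def write_cohort(cohort: SimulatedCohort, out_dir, plant_spec=None, rng_seed: int = 0) -> dict:
    """Write VCF, phenotype CSV, emergence CSV and truth JSON to ``out_dir``."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = write_contaminated_vcf(
        cohort.genotypes, plant_spec or {}, out / "cohort.vcf", rng_seed=rng_seed
    )
    phen = cohort.phenotypes.copy()
    phen.to_csv(out / "phenotypes.csv", index=False)
    cohort.emergence.rename_axis("accession").reset_index().to_csv(
        out / "emergence.csv", index=False
    )
    cohort.latitudes.rename_axis("accession").reset_index().to_csv(
        out / "latitudes.csv", index=False
    )
    truth = dict(cohort.truth)
    truth["true_gblups_cold"] = cohort.true_gblups_cold.round(10).to_dict()
    truth["true_gblups_warm"] = cohort.true_gblups_warm.round(10).to_dict()
    truth["vcf_manifest"] = manifest
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return manifest
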