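"""Post-calling variant filters and LD pruning.

All filters are explicit, counted and order-preserving operations on a
:class:`VariantTable`.  The canonical chain applied by
:func:`run_filter_chain` is

    accession depth -> multiallelic -> near-indel SNPs -> indel records
    -> site-depth percentiles -> mapping quality -> chromosome scaffolds
    -> allele depth -> LD pruning

Splitting "retain only biallelic SNPs" into a multiallelic step and a
later indel-record step lets the near-indel rule see indels before they
are themselves discarded, and keeps per-rule removal counts unambiguous.
The depth-percentile band is computed on the *current* (partially
filtered) site set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FilterConfig
from .simulate import GenotypeMatrix

log = logging.getLogger(__name__)


class FilterError(ValueError):
    pass


@dataclass
class VariantTable:
    """Variant sites x accessions with the attributes the filters read."""

    chrom: np.ndarray                    # (m,) str
    pos: np.ndarray                      # (m,) int, 1-based
    ref: np.ndarray                      # (m,) str
    alt: list                            # list of tuples of alt alleles
    mq: np.ndarray                       # (m,) float, NaN when absent
    is_indel: np.ndarray                 # (m,) bool
    ad_ref: np.ndarray                   # (m, n) int
    ad_alt: np.ndarray                   # (m, n) int
    dp: np.ndarray                       # (m, n) int
    dosage: np.ndarray                   # (m, n) int8, -1 for missing/non-diploid
    accession_ids: list

    def __post_init__(self) -> None:
        if (self.pos < 1).any():
            raise FilterError("positions must be 1-based")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def take_sites(self, keep: np.ndarray) -> "VariantTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        else:
            keep = keep.astype(np.intp)    # empty masks arrive as float64
        return VariantTable(
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            ref=self.ref[keep],
            alt=[self.alt[i] for i in keep],
            mq=self.mq[keep],
            is_indel=self.is_indel[keep],
            ad_ref=self.ad_ref[keep],
            ad_alt=self.ad_alt[keep],
            dp=self.dp[keep],
            dosage=self.dosage[keep],
            accession_ids=list(self.accession_ids),
        )

    def take_accessions(self, keep_idx) -> "VariantTable":
        keep_idx = list(keep_idx)
        return VariantTable(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            mq=self.mq,
            is_indel=self.is_indel,
            ad_ref=self.ad_ref[:, keep_idx],
            ad_alt=self.ad_alt[:, keep_idx],
            dp=self.dp[:, keep_idx],
            dosage=self.dosage[:, keep_idx],
            accession_ids=[self.accession_ids[i] for i in keep_idx],
        )


@dataclass
class FilterReport:
    """Ordered per-rule removal accounting."""

    steps: list = field(default_factory=list)   # (rule, before, removed, after)
    accessions_removed: list = field(default_factory=list)

    def add(self, rule: str, before: int, removed: int) -> None:
        if removed < 0 or removed > before:
            raise FilterError(f"inconsistent counts for rule {rule}")
        self.steps.append((rule, before, removed, before - removed))

    def removed(self, rule: str) -> int:
        return sum(s[2] for s in self.steps if s[0] == rule)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["rule", "sites_before", "sites_removed", "sites_after"]
        )

    def validate(self) -> None:
        for rule, before, removed, after in self.steps:
            if after != before - removed or removed < 0:
                raise FilterError(f"inconsistent report row for {rule}")


def read_vcf(path) -> VariantTable:
    """Load a multi-sample VCF (FORMAT AD/DP, INFO MQ) into a VariantTable.

    Records without usable AD/DP fields are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    n = len(samples)
    chrom, pos, ref, alt, mq, is_indel = [], [], [], [], [], []
    ad_ref, ad_alt, dp, dosage = [], [], [], []
    skipped = 0
    for v in vcf:
        try:
            ad = v.format("AD")
            d = v.format("DP")
            if ad is None or d is None:
                skipped += 1
                continue
            ad = np.asarray(ad)
            d = np.asarray(d).reshape(n)
        except Exception:
            skipped += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(tuple(v.ALT))
        info_mq = v.INFO.get("MQ")
        mq.append(float(info_mq) if info_mq is not None else np.nan)
        indel = len(v.REF) != 1 or any(len(a) != 1 for a in v.ALT)
        is_indel.append(indel)
        ar = ad[:, 0].astype(np.int64)
        aa = ad[:, 1].astype(np.int64) if ad.shape[1] > 1 else np.zeros(n, np.int64)
        ar[ar < 0] = 0
        aa[aa < 0] = 0
        ad_ref.append(ar)
        ad_alt.append(aa)
        dp.append(np.clip(d.astype(np.int64), 0, None))
        gt = v.gt_types.astype(np.int8)     # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = -1
        if len(v.ALT) != 1 or indel:
            gt = np.full(n, -1, dtype=np.int8)
        dosage.append(gt)
    if skipped:
        log.warning("skipped %d malformed VCF records", skipped)
    m = len(pos)
    return VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=alt,
        mq=np.array(mq, dtype=float),
        is_indel=np.array(is_indel, dtype=bool),
        ad_ref=np.array(ad_ref).reshape(m, n),
        ad_alt=np.array(ad_alt).reshape(m, n),
        dp=np.array(dp).reshape(m, n),
        dosage=np.array(dosage).reshape(m, n),
        accession_ids=samples,
    )


def filter_accessions_by_depth(table: VariantTable, min_mean_depth: float = 20.0):
    """Drop accessions whose mean site depth is not strictly above the
    threshold; returns (table, removed accession ids)."""
    if table.n_sites == 0:
        return table, []
    means = table.dp.mean(axis=0)
    keep = means > min_mean_depth
    removed = [a for a, k in zip(table.accession_ids, keep) if not k]
    if not keep.any():
        raise FilterError("no accessions left after the depth filter")
    if removed:
        log.info("accession depth filter removed %s", removed)
        table = table.take_accessions(np.flatnonzero(keep))
    return table, removed


def filter_multiallelic(table: VariantTable) -> VariantTable:
    """Remove sites with more than one ALT allele."""
    keep = np.array([len(a) == 1 for a in table.alt])
    return table.take_sites(keep)


def filter_indel_records(table: VariantTable) -> VariantTable:
    """Remove indel records themselves."""
    return table.take_sites(~table.is_indel)


def filter_biallelic_snps(table: VariantTable) -> VariantTable:
    """Retain only biallelic SNPs (drops multiallelic sites and indels)."""
    return filter_indel_records(filter_multiallelic(table))


def filter_near_indel(table: VariantTable, min_distance_bp: int = 5) -> VariantTable:
    """Remove SNPs situated less than ``min_distance_bp`` from an indel
    anchor position on the same chromosome.  Indel records are retained by
    this operation (they are dropped by :func:`filter_indel_records`)."""
    keep = np.ones(table.n_sites, dtype=bool)
    for c in np.unique(table.chrom[table.is_indel]):
        on_c = table.chrom == c
        indel_pos = table.pos[on_c & table.is_indel]
        snp_idx = np.flatnonzero(on_c & ~table.is_indel)
        if indel_pos.size == 0 or snp_idx.size == 0:
            continue
        d = np.abs(table.pos[snp_idx][:, None] - indel_pos[None, :]).min(axis=1)
        keep[snp_idx[d < min_distance_bp]] = False
    return table.take_sites(keep)


def filter_site_depth_percentiles(
    table: VariantTable,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
    method: str = "linear",
) -> VariantTable:
    """Keep sites whose mean depth lies inside the closed [lo, hi]
    percentile band of the current site-mean-depth distribution."""
    if table.n_sites < 20:
        log.warning("fewer than 20 sites: depth-percentile filter skipped")
        return table
    means = table.dp.mean(axis=1)
    lo, hi = np.percentile(means, [lo_pct, hi_pct], method=method)
    return table.take_sites((means >= lo) & (means <= hi))


def filter_mq(table: VariantTable, min_mq: float = 40.0) -> VariantTable:
    """Keep sites with mapping quality strictly above ``min_mq``; missing
    MQ counts as failing."""
    missing = np.isnan(table.mq)
    if missing.any():
        log.info("%d sites without MQ treated as failing", int(missing.sum()))
    return table.take_sites(~missing & (table.mq > min_mq))


def filter_chromosome_scaffolds(table: VariantTable, chromosome_names) -> VariantTable:
    """Keep sites mapped on the named chromosome scaffolds."""
    names = set(chromosome_names)
    if not names:
        raise FilterError("chromosome name list must be non-empty")
    keep = np.array([c in names for c in table.chrom])
    return table.take_sites(keep)


def filter_allele_depth(table: VariantTable, min_depth: int = 10) -> VariantTable:
    """Remove a site if, in any retained accession, both allelic depths are
    below ``min_depth`` — this also removes all sites with missing calls."""
    bad = ((table.ad_ref < min_depth) & (table.ad_alt < min_depth)).any(axis=1)
    return table.take_sites(~bad)


def to_genotype_matrix(table: VariantTable) -> GenotypeMatrix:
    if (table.dosage < 0).any():
        raise FilterError("missing dosages remain; apply the allele-depth filter first")
    snps = pd.DataFrame(
        {
            "chrom": table.chrom.astype(str),
            "pos": table.pos,
            "ref": table.ref.astype(str),
            "alt": [a[0] if a else "." for a in table.alt],
        }
    )
    return GenotypeMatrix(
        dosages=table.dosage.T.astype(np.int8).copy(),
        accession_ids=list(table.accession_ids),
        snps=snps,
    )


def ld_prune(
    genotypes: GenotypeMatrix,
    r2_max: float = 0.2,
    window: int = 1000,
    window_unit: str = "sites",
) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning per chromosome.

    A site is kept unless its squared Pearson correlation of dosages with
    any previously *kept* site inside the trailing window exceeds
    ``r2_max``.  The window is 1000 sites by default (the literal reading
    of the bcftools ``-w 1000`` flag) or base pairs when
    ``window_unit='bp'``.  Monomorphic sites have r^2 defined as 0.
    """
    X = genotypes.dosages.astype(float)
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    chroms = genotypes.snps["chrom"].to_numpy()
    pos = genotypes.snps["pos"].to_numpy()
    keep: list = []
    for c in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == c)
        kept_local: list = []
        for j in idx:
            in_window = []
            for k in reversed(kept_local):
                if window_unit == "sites":
                    if j - k >= window:
                        break
                else:
                    if pos[j] - pos[k] >= window:
                        break
                in_window.append(k)
            ok = True
            if in_window and norms[j] > 0:
                r = (Xc[:, in_window].T @ Xc[:, j]) / (norms[in_window] * norms[j])
                r[norms[in_window] == 0] = 0.0
                if (r**2 > r2_max).any():
                    ok = False
            if ok:
                kept_local.append(j)
        keep.extend(kept_local)
    keep = np.array(sorted(keep), dtype=int)
    return genotypes.take_snps(keep)


def run_filter_chain(vcf_path, config: FilterConfig | None = None):
    """Apply the full ordered filter chain to a VCF.

    Returns ``(GenotypeMatrix, FilterReport)``.  The report lists, in
    order, each rule with sites before/removed/after, plus the accessions
    removed by the depth rule.
    """
    config = config or FilterConfig()
    table = read_vcf(vcf_path)
    report = FilterReport()

    table, removed_acc = (
        filter_accessions_by_depth(table, config.min_accession_mean_depth)
        if table.n_sites
        else (table, [])
    )
    report.accessions_removed = removed_acc
    report.add("accession_depth", table.n_sites, 0)

    steps = [
        ("multiallelic", lambda t: filter_multiallelic(t)),
        ("near_indel", lambda t: filter_near_indel(t, config.indel_distance_bp)),
        ("indel", lambda t: filter_indel_records(t)),
        (
            "site_depth",
            lambda t: filter_site_depth_percentiles(
                t, config.depth_lo_pct, config.depth_hi_pct, config.percentile_method
            ),
        ),
        ("mapping_quality", lambda t: filter_mq(t, config.min_mq)),
        ("chromosome", lambda t: filter_chromosome_scaffolds(t, config.chromosome_names)),
        ("allele_depth", lambda t: filter_allele_depth(t, config.min_allele_depth)),
    ]
    for rule, fn in steps:
        before = table.n_sites
        table = fn(table)
        report.add(rule, before, before - table.n_sites)

    if table.n_sites == 0:
        report.add("ld_prune", 0, 0)
        report.validate()
        empty = GenotypeMatrix(
            dosages=np.zeros((table.n_accessions, 0), dtype=np.int8),
            accession_ids=list(table.accession_ids),
            snps=pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
        )
        return empty, report

    geno = to_genotype_matrix(table)
    before = geno.n_snps
    geno = ld_prune(geno, config.ld_r2_max, config.ld_window, config.ld_window_unit)
    report.add("ld_prune", before, before - geno.n_snps)
    report.validate()
    return geno, report


def write_plink_text(genotypes: GenotypeMatrix, prefix) -> None:
    """Write filtered genotypes as plink-text .ped/.map plus a dosage TSV."""
    from pathlib import Path

    prefix = Path(prefix)
    snps = genotypes.snps
    with open(f"{prefix}.map", "w") as fh:
        for _, row in snps.iterrows():
            name = f"{row['chrom']}:{row['pos']}"
            fh.write(f"{row['chrom']}\t{name}\t0\t{row['pos']}\n")
    with open(f"{prefix}.ped", "w") as fh:
        for i, acc in enumerate(genotypes.accession_ids):
            alleles = []
            for j in range(genotypes.n_snps):
                d = genotypes.dosages[i, j]
                ref, alt = snps.iloc[j]["ref"], snps.iloc[j]["alt"]
                pair = {0: (ref, ref), 1: (ref, alt), 2: (alt, alt)}[int(d)]
                alleles.extend(pair)
            fh.write(f"FAM\t{acc}\t0\t0\t0\t-9\t" + "\t".join(alleles) + "\n")
    genotypes.to_frame().to_csv(f"{prefix}.dosage.tsv", sep="\t")
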