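"""Variant-filter unit and property tests: boundary semantics, planted
fixtures, LD pruning, and idempotence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from germtherm.config import FilterConfig, SimulationConfig
from germtherm.filtering import (
    FilterError,
    filter_accessions_by_depth,
    filter_allele_depth,
    filter_biallelic_snps,
    filter_chromosome_scaffolds,
    filter_mq,
    filter_multiallelic,
    filter_near_indel,
    filter_site_depth_percentiles,
    ld_prune,
    read_vcf,
    run_filter_chain,
    to_genotype_matrix,
)
from germtherm.simulate import GenotypeMatrix, simulate_genotypes, write_contaminated_vcf

from conftest import make_variant_table


class TestAccessionDepth:
    def test_strictly_above_threshold_retained(self):
        dp = np.tile([19, 20, 21], (4, 1))
        t = make_variant_table([100, 200, 300, 400], dp=dp)
        out, removed = filter_accessions_by_depth(t, 20.0)
        assert out.accession_ids == ["s2"]
        assert removed == ["s0", "s1"]

    def test_deep_panel_untouched(self):
        t = make_variant_table([100, 200], dp=50)
        out, removed = filter_accessions_by_depth(t, 20.0)
        assert removed == [] and out.n_accessions == 3

    def test_everything_shallow_errors(self):
        t = make_variant_table([100], dp=5)
        with pytest.raises(FilterError):
            filter_accessions_by_depth(t, 20.0)


class TestSiteFilters:
    def test_multiallelic_removed_biallelic_kept(self):
        t = make_variant_table([100, 200], alt=[("A", "T"), ("T",)])
        out = filter_multiallelic(t)
        assert out.pos.tolist() == [200]
        out2 = filter_biallelic_snps(t)
        assert out2.pos.tolist() == [200]

    def test_near_indel_boundary_is_strict(self):
        # SNP at 100 with indel at 103 (distance 3 < 5): removed;
        # SNP at 200 with indel at 205 (distance 5): retained
        t = make_variant_table(
            [100, 103, 200, 205], is_indel=[False, True, False, True]
        )
        out = filter_near_indel(t, 5)
        assert out.pos[~out.is_indel].tolist() == [200]

    def test_mq_boundary_exactly_40_fails(self):
        t = make_variant_table([100, 200, 300], mq=[40.0, 40.1, np.nan])
        out = filter_mq(t, 40.0)
        assert out.pos.tolist() == [200]

    def test_allele_depth_both_below_10(self):
        ad = np.array(
            [
                [(9, 9), (30, 30), (30, 30)],     # one failing cell -> removed
                [(9, 30), (9, 30), (9, 30)],      # one allele >= 10 -> kept
                [(0, 0), (30, 30), (30, 30)],     # missing call -> removed
            ]
        )
        t = make_variant_table([100, 200, 300], ad=ad)
        out = filter_allele_depth(t, 10)
        assert out.pos.tolist() == [200]

    def test_depth_percentiles_match_sort_and_index_oracle(self):
        depths = np.arange(1, 101, dtype=float)
        dp = np.tile(depths[:, None], (1, 3))
        t = make_variant_table(list(range(100, 10100, 100)), dp=dp)
        out = filter_site_depth_percentiles(t, 5, 95, "linear")
        lo, hi = np.percentile(depths, [5, 95], method="linear")
        expected = depths[(depths >= lo) & (depths <= hi)]
        assert np.allclose(out.dp[:, 0].astype(float), expected)

    def test_constant_depth_is_noop(self):
        t = make_variant_table(list(range(100, 3100, 100)), dp=60)
        assert filter_site_depth_percentiles(t).n_sites == 30

    def test_few_sites_skips_percentile_filter(self):
        t = make_variant_table([100, 200], dp=[[1, 1, 1], [99, 99, 99]])
        assert filter_site_depth_percentiles(t).n_sites == 2

    def test_chromosome_scaffolds(self):
        t = make_variant_table([100, 200], chrom=np.array(["scaffold_441", "A01"], object))
        out = filter_chromosome_scaffolds(t, [f"A{i:02d}" for i in range(1, 11)])
        assert out.chrom.tolist() == ["A01"]
        with pytest.raises(FilterError):
            filter_chromosome_scaffolds(t, [])

    @pytest.mark.parametrize(
        "fn",
        [
            filter_multiallelic,
            filter_biallelic_snps,
            lambda t: filter_near_indel(t, 5),
            lambda t: filter_mq(t, 40.0),
            lambda t: filter_allele_depth(t, 10),
        ],
    )
    def test_filters_idempotent(self, fn):
        # threshold-based filters are idempotent; the rank-based
        # depth-percentile filter is deliberately one-shot (re-ranking a
        # filtered set would trim new tails) and is excluded
        rng = np.random.default_rng(0)
        m = 60
        t = make_variant_table(
            sorted(rng.choice(np.arange(100, 100000), size=m, replace=False)),
            mq=rng.uniform(20, 60, size=m),
            is_indel=rng.random(m) < 0.2,
            dp=rng.integers(5, 120, size=(m, 3)),
            ad=np.stack(
                [rng.integers(0, 40, size=(m, 3)), rng.integers(0, 40, size=(m, 3))],
                axis=-1,
            ),
            alt=[("T", "G") if rng.random() < 0.2 else ("T",) for _ in range(m)],
        )
        once = fn(t)
        twice = fn(once)
        assert once.pos.tolist() == twice.pos.tolist()


class TestLdPrune:
    def _geno(self, dosages, pos=None):
        import pandas as pd

        dosages = np.asarray(dosages, dtype=np.int8)
        m = dosages.shape[1]
        pos = pos or list(range(100, 100 + 10 * m, 10))
        snps = pd.DataFrame(
            {"chrom": ["A01"] * m, "pos": pos, "ref": ["A"] * m, "alt": ["C"] * m}
        )
        return GenotypeMatrix(dosages, [f"a{i}" for i in range(dosages.shape[0])], snps)

    def test_correlated_pair_keeps_first_and_independent(self):
        col = np.array([0, 1, 2, 0, 1, 2])
        indep = np.array([0, 2, 1, 2, 0, 1])   # exactly uncorrelated with col
        geno = self._geno(np.column_stack([col, col, indep]))
        out = ld_prune(geno, r2_max=0.2)
        assert out.snps["pos"].tolist() == [100, 120]

    def test_uncorrelated_panel_is_identity(self):
        rng = np.random.default_rng(1)
        # orthogonal-ish columns: independent draws at n=40 rarely reach r2=0.2,
        # verified against the exhaustive pairwise oracle below
        X = rng.integers(0, 3, size=(40, 8)).astype(np.int8)
        r2 = np.corrcoef(X.T) ** 2
        np.fill_diagonal(r2, 0.0)
        geno = self._geno(X)
        out = ld_prune(geno, r2_max=max(0.21, r2.max() + 0.01))
        assert out.n_snps == 8

    def test_duplicate_column_collapses_to_one(self):
        col = np.array([0, 1, 2, 1, 0, 2])
        geno = self._geno(np.tile(col[:, None], (1, 5)))
        out = ld_prune(geno, r2_max=0.2)
        assert out.n_snps == 1

    def test_postcondition_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(7)
        base = rng.integers(0, 3, size=(30, 1))
        X = np.clip(base + rng.integers(-1, 2, size=(30, 40)), 0, 2).astype(np.int8)
        geno = self._geno(X)
        out = ld_prune(geno, r2_max=0.2, window=1000)
        Y = out.dosages.astype(float)
        if out.n_snps > 1:
            r2 = np.corrcoef(Y.T) ** 2
            np.fill_diagonal(r2, 0.0)
            assert np.nanmax(r2) <= 0.2 + 1e-12

    def test_monomorphic_site_always_kept(self):
        X = np.column_stack([np.ones(6), [0, 1, 2, 0, 1, 2]]).astype(np.int8)
        out = ld_prune(self._geno(X), r2_max=0.2)
        assert out.n_snps == 2


class TestChain:
    def test_planted_counts_match_manifest(self, tmp_path):
        cfg = SimulationConfig(n_accessions=12, n_snps=300, rng_seed=17)
        geno = simulate_genotypes(cfg)
        spec = {"multiallelic": 3, "near_indel": 2, "low_mq": 2,
                "depth_outlier": 4, "low_allele_depth": 2,
                "non_chromosome_scaffold": 2}
        manifest = write_contaminated_vcf(
            geno, spec, tmp_path / "f.vcf", rng_seed=1,
            low_depth_accessions=(geno.accession_ids[0],),
        )
        _, report = run_filter_chain(tmp_path / "f.vcf", FilterConfig())
        for rule, n_expected in manifest["expected_removals"].items():
            assert report.removed(rule) == n_expected, rule
        assert report.accessions_removed == [geno.accession_ids[0]]

    def test_clean_vcf_zero_removals_and_roundtrip(self, tmp_path):
        cfg = SimulationConfig(n_accessions=10, n_snps=150, rng_seed=23)
        geno = simulate_genotypes(cfg)
        write_contaminated_vcf(geno, {}, tmp_path / "clean.vcf", rng_seed=1)
        table = read_vcf(tmp_path / "clean.vcf")
        back = to_genotype_matrix(table)
        assert np.array_equal(back.dosages, geno.dosages)
        out, report = run_filter_chain(tmp_path / "clean.vcf", FilterConfig())
        non_ld = report.to_frame().query("rule != 'ld_prune'")
        assert (non_ld["sites_removed"] == 0).all()

    def test_empty_vcf_gives_empty_matrix(self, tmp_path):
        cfg = SimulationConfig(n_accessions=5, n_snps=1, rng_seed=2)
        geno = simulate_genotypes(cfg)
        write_contaminated_vcf(geno, {}, tmp_path / "one.vcf", rng_seed=1)
        lines = (tmp_path / "one.vcf").read_text().splitlines()
        (tmp_path / "empty.vcf").write_text(
            "\n".join(l for l in lines if l.startswith("#")) + "\n"
        )
        out, report = run_filter_chain(tmp_path / "empty.vcf", FilterConfig())
        assert out.n_snps == 0
        assert (report.to_frame()["sites_removed"] == 0).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_report_counts_consistent(self, seed):
        """FilterReport bookkeeping: after = before - removed at every step."""
        rng = np.random.default_rng(seed)
        from germtherm.filtering import FilterReport

        rep = FilterReport()
        n = int(rng.integers(0, 500))
        for rule in ("a", "b", "c"):
            removed = int(rng.integers(0, n + 1))
            rep.add(rule, n, removed)
            n -= removed
        rep.validate()
        df = rep.to_frame()
        assert (df["sites_after"] == df["sites_before"] - df["sites_removed"]).all()
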