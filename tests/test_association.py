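"""The three haplotype tests against independent oracles and identities."""

import numpy as np
import pytest

from haploblock import synth
from haploblock.association import (
    block_test,
    bonferroni_correct,
    bonferroni_threshold,
    complete_test,
    genome_scan,
    results_to_frame,
    single_snp_test,
    single_test,
)
from haploblock.haplotypes import BlockHaplotypes, enumerate_block, reference_dosage

from conftest import ne_block_f, ne_t_tests, panel_from_haplotypes, whole_panel_block


def random_instance(rng, n=None, p=None, pool=None):
    """A small (y, X, bh) instance with a full-rank design."""
    n = n or int(rng.integers(18, 31))
    p = p if p is not None else int(rng.integers(0, 4))
    pools = [
        {"00": 0.5, "01": 0.5},
        {"000": 0.4, "010": 0.35, "111": 0.25},
        {"0000": 0.4, "0100": 0.3, "1110": 0.2, "1111": 0.1},
        {"000": 0.3, "001": 0.3, "010": 0.2, "100": 0.1, "111": 0.1},
    ]
    pool = pool or pools[int(rng.integers(0, len(pools)))]
    n_snps = len(next(iter(pool)))
    while True:
        spec = synth.SimSpec(
            n_individuals=n,
            blocks=[synth.BlockSpec(n_snps, pool)],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        panel, _ = synth.simulate_panel(spec)
        bh = enumerate_block(panel, whole_panel_block(panel))
        X = rng.normal(size=(n, p))
        D = np.column_stack([np.ones(n), X, bh.H])
        if bh.m >= 1 and np.linalg.matrix_rank(D) == D.shape[1] and n > D.shape[1]:
            y = rng.normal(size=n)
            return y, X, bh


class TestOracleEquivalence:
    def test_all_three_tests_match_normal_equations(self, rng):
        for _ in range(50):
            y, X, bh = random_instance(rng)
            H = bh.H.astype(float)
            f_ref, pf_ref = ne_block_f(y, X, H)
            rb = block_test(y, X, bh)
            assert rb.statistic == pytest.approx(f_ref, rel=1e-10)
            assert rb.p_raw == pytest.approx(pf_ref, rel=1e-10)

            t_ref = ne_t_tests(y, X, H)
            rc = complete_test(y, X, bh)
            assert len(rc) == bh.m
            for r, (t, pt) in zip(rc, t_ref):
                assert r.statistic == pytest.approx(t, rel=1e-10)
                assert r.p_raw == pytest.approx(pt, rel=1e-10)

            for r in single_test(y, X, bh):
                j = r.haplotype_index
                d = (
                    reference_dosage(bh)
                    if j == 0
                    else bh.H[:, j - 1].astype(float)
                )
                t, pt = ne_t_tests(y, X, d[:, None])[0]
                assert r.statistic == pytest.approx(t, rel=1e-10)
                assert r.p_raw == pytest.approx(pt, rel=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        y, X, bh = random_instance(rng, n=30, p=2, pool={"000": 0.4, "010": 0.35, "111": 0.25})
        D = sm.add_constant(np.column_stack([X, bh.H]))
        fit = sm.OLS(y, D).fit()
        rc = complete_test(y, X, bh)
        for k, r in enumerate(rc):
            assert r.statistic == pytest.approx(fit.tvalues[3 + k], rel=1e-9)
            assert r.p_raw == pytest.approx(fit.pvalues[3 + k], rel=1e-9)
        rb = block_test(y, X, bh)
        wald = fit.f_test(np.eye(D.shape[1])[3:])
        assert rb.statistic == pytest.approx(float(wald.fvalue), rel=1e-9)


class TestAlgebraicIdentities:
    def test_m1_block_f_equals_t_squared(self, rng):
        y, X, bh = random_instance(rng, pool={"00": 0.6, "01": 0.4})
        rb = block_test(y, X, bh)
        (rc,) = complete_test(y, X, bh)
        assert rb.statistic == pytest.approx(rc.statistic**2, rel=1e-10)
        assert rb.p_raw == pytest.approx(rc.p_raw, rel=1e-10)

    def test_m1_single_reference_is_sign_flipped(self, rng):
        y, X, bh = random_instance(rng, pool={"00": 0.6, "01": 0.4})
        r0, r1 = single_test(y, X, bh)
        assert (r0.haplotype_index, r1.haplotype_index) == (0, 1)
        assert r0.statistic == pytest.approx(-r1.statistic, rel=1e-10)
        assert r0.p_raw == pytest.approx(r1.p_raw, rel=1e-10)

    def test_single_haplotype_equals_single_snp(self, rng):
        # two haplotypes differing at one SNP: dosage of the alternative
        # haplotype is exactly the alternate-allele count at that SNP
        y, X, bh = random_instance(rng, n=40, p=2, pool={"00": 0.65, "01": 0.35})
        panel_dosage = bh.H[:, 0].astype(float)  # == alt count at SNP 2
        r_hap = [r for r in single_test(y, X, bh) if r.haplotype_index == 1][0]
        r_snp = single_snp_test(y, X, panel_dosage, snp_id="s2")
        assert r_snp.statistic == pytest.approx(r_hap.statistic, rel=1e-12)
        assert r_snp.p_raw == pytest.approx(r_hap.p_raw, rel=1e-12)

    def test_affine_invariance(self, rng):
        y, X, bh = random_instance(rng, n=28, p=2)
        base_f = block_test(y, X, bh).statistic
        base_t = [r.statistic for r in complete_test(y, X, bh)]
        y2 = (y - y.mean()) / y.std() * 3.7
        X2 = (X - X.mean(axis=0)) / X.std(axis=0)
        assert block_test(y2, X2, bh).statistic == pytest.approx(base_f, rel=1e-10)
        for a, b in zip([r.statistic for r in complete_test(y2, X2, bh)], base_t):
            assert a == pytest.approx(b, rel=1e-10)

    def test_nesting_consistency_f_nonnegative(self, rng):
        for _ in range(20):
            y, X, bh = random_instance(rng)
            r = block_test(y, X, bh)
            assert r.statistic >= 0
            assert 0 < r.p_raw <= 1


class TestEdgeCases:
    def test_duplicate_haplotype_column_dropped_with_warning(self, rng, caplog):
        y, X, bh = random_instance(rng, n=30, p=1, pool={"000": 0.4, "010": 0.35, "111": 0.25})
        dup = BlockHaplotypes(
            block=bh.block,
            haplotype_strings=bh.haplotype_strings + ["dup"],
            counts=np.append(bh.counts, bh.counts[-1]),
            H=np.column_stack([bh.H, bh.H[:, 0]]).astype(np.int8),
            valid_mask=bh.valid_mask,
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="haploblock.association"):
            rc = complete_test(y, X, dup)
        assert len(rc) == bh.m  # the later duplicate contributes no result
        assert any("collinear" in rec.message for rec in caplog.records)
        # the block F uses the effective rank, matching the unpolluted block
        assert block_test(y, X, dup).statistic == pytest.approx(
            block_test(y, X, bh).statistic, rel=1e-10
        )

    def test_monomorphic_block_untestable(self):
        panel = panel_from_haplotypes([("00", "00"), ("00", "00")] * 10)
        bh = enumerate_block(panel, whole_panel_block(panel))
        assert block_test(np.random.default_rng(0).normal(size=20), None, bh) is None
        assert complete_test(np.random.default_rng(0).normal(size=20), None, bh) == []

    def test_monomorphic_snp_untestable(self, rng):
        y = rng.normal(size=30)
        assert single_snp_test(y, rng.normal(size=(30, 1)), np.ones(30)) is None

    def test_insufficient_residual_df(self, rng):
        panel = panel_from_haplotypes([("00", "00"), ("01", "01")])
        bh = enumerate_block(panel, whole_panel_block(panel))
        with pytest.raises(ValueError, match="insufficient residual df"):
            # n == 1 + p + m_eff leaves no residual df
            block_test(np.array([0.3, 1.2]), np.empty((2, 0)), bh)

    def test_missing_rows_dropped_listwise(self, rng):
        y, X, bh = random_instance(rng, n=40, p=2)
        y2 = y.copy()
        y2[:5] = np.nan
        r = block_test(y2, X, bh)
        assert r.n_used == bh.valid_mask[5:].sum()


class TestBonferroni:
    def test_threshold_values(self):
        assert bonferroni_threshold(123 * 10**6) == pytest.approx(4.0650407e-10)
        assert bonferroni_threshold(14_703_239) == pytest.approx(3.4e-9, abs=5e-11)

    def test_correction_clamps_at_one(self, rng):
        y, X, bh = random_instance(rng)
        results = [block_test(y, X, bh)]
        corrected, acct = bonferroni_correct(results * 30)
        assert acct.n_t == {"block": 30}
        assert all(r.p_corrected == min(1.0, r.p_raw * 30) for r in corrected)
        assert acct.threshold("block") == pytest.approx(0.05 / 30)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bonferroni_correct([])

    def test_accounting_counts_emitted_statistics(self, rng):
        spec = synth.SimSpec(n_individuals=120, blocks=synth.default_blocks(4), seed=3)
        panel, gmap, covars, raw, _ = synth.simulate_study(spec)
        from haploblock.genetic_map import annotate_panel
        from haploblock.blocks import segment_blocks

        blocks = segment_blocks(annotate_panel({"1": gmap}, panel), panel.snps)
        results, acct = genome_scan(panel, blocks, raw, covars)
        frame = results_to_frame(results)
        for fam in ("block", "complete", "single"):
            assert acct.n_t[fam] == (frame["test"] == fam).sum()
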