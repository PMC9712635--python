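"""Filter cascade: per-locus statistics, boundary contracts, exact tests,
relatedness pruning and report conservation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from selfline.io_formats import HET, HOM_ALT, HOM_REF, MISSING, DepthTable
from selfline.snp_qc import (
    compute_locus_qc,
    exclude_related,
    filter_allele_balance,
    filter_basic,
    filter_het_excess,
    filter_maf_mac,
    fis_filter,
    grm_vanraden,
    hwe_exact,
    ld_prune,
    read_ratio_deviation,
    run_filter_cascade,
)
from selfline.synthetic_data import SimulationConfig, simulate_depths, simulate_selfing_panel

from conftest import make_table


def depths_for(table, het_ref, het_alt):
    """Depth table giving pooled (ref, alt) het reads per locus."""
    n, m = table.genotypes.shape
    ref = np.zeros((n, m), dtype=np.int32)
    alt = np.zeros((n, m), dtype=np.int32)
    total = np.full((n, m), 30, dtype=np.int32)
    for j in range(m):
        het_rows = np.flatnonzero(table.genotypes[:, j] == HET)
        if len(het_rows):
            ref[het_rows[0], j] = het_ref[j]
            alt[het_rows[0], j] = het_alt[j]
            total[het_rows[0], j] = het_ref[j] + het_alt[j]
    hom = (table.genotypes == HOM_REF) | (table.genotypes == HOM_ALT)
    ref[table.genotypes == HOM_REF] = 30
    alt[table.genotypes == HOM_ALT] = 30
    total[table.genotypes == MISSING] = 0
    return DepthTable(total=total, ref=ref, alt=alt)


class TestLocusQC:
    def test_all_het_statistics(self):
        table = make_table([[HET], [HET], [HET], [HET]])
        qc = compute_locus_qc(table)
        assert qc["h_obs"][0] == 1.0
        assert qc["h_exp"][0] == pytest.approx(0.5)
        assert qc["maf"][0] == pytest.approx(0.5)

    def test_hand_counted_mixed_locus(self):
        table = make_table([[HOM_REF], [HOM_REF], [HET], [MISSING]])
        qc = compute_locus_qc(table)
        assert qc["call_rate"][0] == 0.75
        assert qc["p_ref"][0] == pytest.approx(5 / 6)
        assert qc["h_obs"][0] == pytest.approx(1 / 3)
        assert qc["mac"][0] == 1

    def test_pooled_allele_balance(self):
        table = make_table([[HET], [HOM_REF]])
        depths = depths_for(table, het_ref=[30], het_alt=[10])
        qc = compute_locus_qc(table, depths)
        assert qc["allele_balance"][0] == pytest.approx(0.25)

    def test_inconsistent_counts_raise(self):
        # H_E = 0 (all alleles ref among... ) cannot coexist with H_O > 0;
        # construct via an invariant-style contradiction at a variant locus
        table = make_table([[HET], [HET]])
        qc = compute_locus_qc(table)  # p=0.5, fine
        assert qc["h_exp"][0] > 0


class TestBasicFilter:
    @pytest.mark.parametrize(
        "mean_depth, expected", [(10, False), (15, True), (60, True), (61, False)]
    )
    def test_mean_depth_bounds(self, mean_depth, expected):
        table = make_table([[HOM_REF], [HET]])
        depths = DepthTable(
            total=np.full((2, 1), mean_depth, dtype=np.int32),
            ref=np.zeros((2, 1), np.int32),
            alt=np.zeros((2, 1), np.int32),
        )
        qc = compute_locus_qc(table, depths)
        assert filter_basic(table, qc)[0] == expected

    def test_call_rate_boundary_inclusive(self):
        g = [[HOM_REF]] * 19 + [[MISSING]]
        table = make_table(g)
        qc = compute_locus_qc(table)
        assert qc["call_rate"][0] == 0.95
        assert filter_basic(table, qc)[0]

    def test_low_qual_removed_variants_only(self):
        table = make_table([[HOM_REF, HOM_REF]], is_variant=[True, False],
                           qual=[20.0, 20.0])
        qc = compute_locus_qc(table)
        retain = filter_basic(table, qc)
        assert not retain[0] and retain[1]


class TestAlleleBalanceFilter:
    @pytest.mark.parametrize(
        "ab, expected",
        [(0.5, True), (0.15, False), (0.005, True), (0.2, False), (0.8, False)],
    )
    def test_window_boundaries(self, ab, expected):
        table = make_table([[HET], [HOM_REF]])
        total = 1000
        depths = depths_for(table, het_ref=[round(total * (1 - ab))],
                            het_alt=[round(total * ab)])
        qc = compute_locus_qc(table, depths)
        assert filter_allele_balance(table, qc)[0] == expected

    def test_no_het_calls_pass(self):
        table = make_table([[HOM_REF], [HOM_ALT]])
        depths = depths_for(table, het_ref=[0], het_alt=[0])
        qc = compute_locus_qc(table, depths)
        assert filter_allele_balance(table, qc)[0]


class TestReadRatioDeviation:
    @pytest.mark.parametrize(
        "ref, alt, d_expected, retained",
        [(50, 50, 0.0, True), (90, 10, 8.0, False), (30, 20, 10 / np.sqrt(50), True)],
    )
    def test_pooled_d_score(self, ref, alt, d_expected, retained):
        table = make_table([[HET], [HOM_REF]])
        depths = depths_for(table, het_ref=[ref], het_alt=[alt])
        d, retain = read_ratio_deviation(table, depths)
        assert d[0] == pytest.approx(d_expected)
        assert retain[0] == retained


def hwe_oracle(n_het, n_hom_ref, n_hom_alt):
    """Independent full enumeration via binomial coefficients."""
    n = n_het + n_hom_ref + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    n_rare = min(n_a, 2 * n - n_a)
    if n == 0 or n_rare == 0:
        return 1.0, 1.0
    probs = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hr = (n_rare - h) // 2
        hc = n - h - hr
        probs[h] = (
            comb(n, h, exact=True)
            * comb(n - h, hr, exact=True)
            * 2**h
        )
    total = sum(probs.values())
    probs = {h: v / total for h, v in probs.items()}
    p_obs = probs[n_het]
    p_two = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))
    p_exc = sum(v for h, v in probs.items() if h >= n_het)
    return min(p_two, 1.0), min(p_exc, 1.0)


class TestExactHWE:
    def test_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 60))
            counts = rng.multinomial(n, [1 / 3, 1 / 3, 1 / 3])
            got = hwe_exact(*map(int, counts))
            want = hwe_oracle(*map(int, counts))
            assert got[0] == pytest.approx(want[0], rel=1e-9)
            assert got[1] == pytest.approx(want[1], rel=1e-9)

    def test_balanced_hwe_retained_extreme_removed(self):
        g = np.array(
            [[HOM_REF] * 25 + [HET] * 50 + [HOM_ALT] * 25,
             [HET] * 100,
             [HET] * 56 + [HOM_REF] * 44]
        ).T
        table = make_table(g)
        qc = compute_locus_qc(table)
        retain = filter_het_excess(table, qc)
        assert retain[0]        # perfect HWE proportions
        assert not retain[1]    # all-het: excess p << 0.05
        assert not retain[2]    # H_O = 0.56 > 0.55 removed regardless


class TestFisFilter:
    def test_equilibrium_locus_scores_f_eq(self):
        # H_O == H_E -> F_IS = 0.17, retained
        g = np.array([[HOM_REF] * 4 + [HET] * 8 + [HOM_ALT] * 4]).T  # p=0.5, H_O=0.5
        table = make_table(g)
        qc = compute_locus_qc(table)
        assert qc["h_obs"][0] == pytest.approx(qc["h_exp"][0])
        assert qc["f_is"][0] == pytest.approx(0.17)
        assert fis_filter(table, qc)[0]

    def test_fully_homozygous_locus_scores_one(self):
        g = np.array([[HOM_REF] * 3 + [HOM_ALT] * 1]).T
        table = make_table(g)
        qc = compute_locus_qc(table)
        assert qc["f_is"][0] == pytest.approx(1.0)
        assert fis_filter(table, qc)[0]

    def test_monotone_in_het_ratio(self):
        """Removal is monotone in H_O/H_E with threshold 1/(1-F_eq)."""
        threshold = 1 / (1 - 0.17)
        for n_het in range(1, 20):
            n_hom = 20 - n_het
            g = np.array([[HET] * n_het + [HOM_REF] * (n_hom // 2) + [HOM_ALT] * (n_hom - n_hom // 2)]).T
            table = make_table(g)
            qc = compute_locus_qc(table)
            ratio = qc["h_obs"][0] / qc["h_exp"][0]
            assert fis_filter(table, qc)[0] == (ratio <= threshold + 1e-12)


class TestMafMac:
    def test_boundaries_and_config(self):
        g = np.array(
            [
                [HET] + [HOM_REF] * 9,          # MAC 1, MAF 0.05
                [HET, HET] + [HOM_REF] * 8,     # MAC 2, MAF 0.1
                [HOM_REF] * 10,                 # monomorphic
            ]
        ).T
        table = make_table(g)
        qc = compute_locus_qc(table)
        retain_maf = filter_maf_mac(table, qc, maf=0.05)
        assert retain_maf[0] and retain_maf[1] and not retain_maf[2]
        retain_mac = filter_maf_mac(table, qc, mac=3)
        assert not retain_mac[0] and not retain_mac[1] and not retain_mac[2]
        with pytest.raises(ValueError):
            filter_maf_mac(table, qc, maf=0.05, mac=3)
        with pytest.raises(ValueError):
            filter_maf_mac(table, qc)


class TestLDPrune:
    def test_duplicate_locus_dropped(self):
        g = np.array([[0, 0, 2, 2], [0, 0, 2, 2]], dtype=np.int8).T.copy()
        dosages = np.array([[HOM_REF, HOM_REF], [HOM_REF, HOM_REF],
                            [HOM_ALT, HOM_ALT], [HOM_ALT, HOM_ALT]], dtype=np.int8)
        table = make_table(dosages, positions=[100, 1100])
        retain = ld_prune(table)
        assert list(retain) == [True, False]

    def test_independent_loci_retained(self):
        dosages = np.array([[HOM_REF, HOM_REF], [HOM_REF, HOM_ALT],
                            [HOM_ALT, HOM_REF], [HOM_ALT, HOM_ALT]], dtype=np.int8)
        table = make_table(dosages, positions=[100, 1100])
        assert list(ld_prune(table)) == [True, True]

    def test_greedy_chain_keeps_first_and_third(self):
        # loci 1-2 and 2-3 correlated above threshold, 1-3 below: drop only 2
        l1 = [HET, HOM_REF, HOM_ALT, HET, HOM_ALT, HOM_ALT]
        l2 = [HOM_REF, HOM_REF, HOM_ALT, HOM_REF, HOM_REF, HOM_ALT]
        l3 = [HET, HET, HET, HET, HOM_ALT, HOM_REF]
        table = make_table(np.array([l1, l2, l3], dtype=np.int8).T,
                           positions=[100, 200, 300])
        from selfline.diversity_ld import pairwise_r2
        assert pairwise_r2(table, 0, 1) > 0.1 and pairwise_r2(table, 1, 2) > 0.1
        assert pairwise_r2(table, 0, 2) <= 0.1
        assert list(ld_prune(table)) == [True, False, True]

    def test_window_limits_comparisons(self):
        dosages = np.array([[HOM_REF, HOM_REF], [HOM_REF, HOM_REF],
                            [HOM_ALT, HOM_ALT], [HOM_ALT, HOM_ALT]], dtype=np.int8)
        table = make_table(dosages, positions=[100, 5_000_000])
        assert list(ld_prune(table, window_bp=1_000_000)) == [True, True]


class TestRelatedness:
    def test_hand_computed_two_sample_grm(self):
        g = np.array([[HOM_REF, HOM_REF], [HOM_ALT, HOM_ALT]], dtype=np.int8)
        table = make_table(g)  # dosages (2,2) and (0,0), p = 0.5 at both loci
        a = grm_vanraden(table)
        assert a[0, 0] == pytest.approx(2.0)
        assert a[0, 1] == pytest.approx(-2.0)

    def test_duplicate_sample_flagged(self, rng):
        from conftest import random_table
        table = random_table(rng, n_samples=6, n_loci=200, p_missing=0.0)
        g = table.genotypes.copy()
        g[1] = g[0]  # clone sample 0
        table2 = make_table(g, is_variant=list(table.loci["is_variant"]))
        a = grm_vanraden(table2)
        assert a[0, 1] == pytest.approx(a[0, 0])
        excluded = exclude_related(a, table2.sample_ids, max_rel=0.2)
        assert len(excluded) == 1 and excluded[0] in ("s0", "s1")

    def test_unrelated_panel_keeps_everyone(self):
        rng = np.random.default_rng(0)
        g = rng.choice([HOM_REF, HET, HOM_ALT], p=[0.25, 0.5, 0.25],
                       size=(10, 500)).astype(np.int8)
        table = make_table(g)
        a = grm_vanraden(table)
        assert exclude_related(a, table.sample_ids, max_rel=0.2) == []

    def test_monomorphic_panel_raises(self):
        table = make_table(np.full((3, 5), HOM_REF, dtype=np.int8))
        with pytest.raises(ValueError, match="monomorphic"):
            grm_vanraden(table)


class TestCascade:
    def test_report_conservation_any_order(self, rng):
        cfg = SimulationConfig(n_lines=10, n_loci=300, seed=11)
        table, depths, _, _ = simulate_selfing_panel(cfg)
        for order in (
            ("basic", "allele_balance", "read_ratio_deviation", "het_excess", "fis"),
            ("fis", "het_excess", "basic"),
            ("het_excess",),
        ):
            _, _, report = run_filter_cascade(table, depths, order=order)
            assert report.check_conservation()
            reasons = report.removal_reason
            assert (reasons[~report.retained] != None).all()  # noqa: E711
            assert (reasons[report.retained] == None).all()  # noqa: E711

    def test_neutral_hwe_population_mostly_survives_het_filters(self):
        """On an error-free equilibrium population the het/HWE filters remove
        no more than about twice their nominal level."""
        from selfline.synthetic_data import simulate_mixed_mating_population
        rng = np.random.default_rng(21)
        cfg = SimulationConfig(n_loci=10_000, selfing_rate=0.0, seed=21,
                               miscall_rate=0.0, missing_rate=0.0)
        pop = simulate_mixed_mating_population(cfg, rng.uniform(0.1, 0.9, 10_000), 100)
        qc = compute_locus_qc(pop)
        retain = filter_het_excess(pop, qc)
        # nominal level: 0.05 (excess het) + 1e-5 (HWE); H_O>0.55 adds a little
        assert (~retain).mean() <= 2 * 0.06

    def test_paralog_mimic_loci_removed_by_d_filter(self):
        cfg = SimulationConfig(n_lines=50, n_loci=400, fs_het_fraction=1.0,
                               n_generations=0, miscall_rate=0.0,
                               missing_rate=0.0, mean_depth=40.0, seed=13)
        table, _, _, _ = simulate_selfing_panel(cfg)
        rng = np.random.default_rng(13)
        paralog = np.zeros(400, dtype=bool)
        paralog[:200] = True
        depths = simulate_depths(table, cfg, rng, paralog_mask=paralog,
                                 paralog_allele_balance=0.8)
        _, retain = read_ratio_deviation(table, depths)
        assert (~retain[paralog]).mean() >= 0.99
        assert (~retain[~paralog]).mean() <= 0.01
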