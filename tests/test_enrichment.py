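import numpy as np
import pandas as pd
import pytest

from sirscan.enrichment import (
    bh_adjust,
    binomial_spacer_test,
    call_highly_mutated,
    collapse_to_sites,
    hotspot_spacer_tests,
    odds_ratio_spacer_control,
    signature_odds_ratios,
)
from sirscan.mutations import assign_to_domains
from sirscan.simulate import SimulationConfig, generate_genome, generate_mutations

from conftest import (
    bh_stepup_oracle,
    binom_sf_summation_oracle,
    make_sir,
    muts_frame,
)


class TestBinomial:
    def test_zero_observed_is_one(self):
        assert binomial_spacer_test(0, 4, 560, 0.001) == 1.0

    def test_derived_tail_sum(self):
        # P[X>=2 | n=40, p=0.01] = 1 - P(0) - P(1)
        expected = 1 - 0.99**40 - 40 * 0.01 * 0.99**39
        assert binomial_spacer_test(2, 4, 10, 0.01) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_count(self):
        ps = [binomial_spacer_test(k, 5, 100, 0.01) for k in range(0, 20)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_zero_background_convention(self):
        assert binomial_spacer_test(3, 4, 10, 0.0) == 0.0
        assert binomial_spacer_test(0, 4, 10, 0.0) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_spacer_test(50, 4, 10, 0.01)  # count exceeds trials
        with pytest.raises(ValueError):
            binomial_spacer_test(1, 4, 10, 1.5)

    def test_agrees_with_summation_oracle(self):
        from scipy.stats import binom

        rng = np.random.default_rng(21)
        for _ in range(200):
            n = int(rng.integers(1, 2000))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0, 0.2))
            got = binomial_spacer_test(k, 1, n, p)
            assert got == pytest.approx(binom_sf_summation_oracle(k, n, p), rel=1e-12, abs=1e-300)
            # dual route: agree with the incomplete-beta survival function
            # wherever that evaluation does not underflow
            sf = float(binom.sf(k - 1, n, p)) if k > 0 else 1.0
            if sf > 1e-250:
                assert got == pytest.approx(sf, rel=1e-9)

    def test_large_trials_continuous_at_boundary(self):
        # summation route and survival-function route agree near the cutover
        from sirscan.enrichment import _SUMMATION_TRIALS_MAX
        from scipy.stats import binom

        n = _SUMMATION_TRIALS_MAX
        for k in (1, 5, 120, 1000):
            assert binomial_spacer_test(k, 1, n, 1e-3) == pytest.approx(
                float(binom.sf(k - 1, n, 1e-3)), rel=1e-9
            )


class TestBH:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.05] * 7) == pytest.approx([0.05] * 7)

    def test_order_preserving_vs_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 50)))
            assert bh_adjust(p) == pytest.approx(bh_stepup_oracle(p), rel=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestHighlyMutated:
    def test_planted_excess_flagged(self):
        # 100 SIRs; one with a 20-fold spacer excess over an explicit background
        rng = np.random.default_rng(30)
        sirs = [make_sir(1000 + i * 1000, 7, "GAAC", chrom="c") for i in range(100)]
        rows = []
        n_samples = 50
        d = 2e-3
        for i, r in enumerate(sirs):
            lam_spacer = 4 * n_samples * d * (20.0 if i == 0 else 1.0)
            for _ in range(rng.poisson(lam_spacer)):
                rows.append((f"s{rng.integers(n_samples)}", "c", int(r.spacer_start + rng.integers(4)) + 1, "G", "T", "substitution"))
            for _ in range(rng.poisson(200 * n_samples * d)):
                off = int(rng.integers(100))
                pos = r.start - 100 + off if rng.random() < 0.5 else r.end + off
                rows.append((f"s{rng.integers(n_samples)}", "c", pos + 1, "A", "G", "substitution"))
        muts = muts_frame(rows)
        res = call_highly_mutated(muts, sirs, n_samples)
        flagged = res[res["is_highly_mutated"]]
        assert 0 in set(flagged["sir_index"])
        assert res["q_value"].between(0, 1).all()
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()

    def test_family_restricted_to_mutated_spacers(self):
        sirs = [make_sir(1000, 7, "GAAC", chrom="c"), make_sir(5000, 7, "GCAC", chrom="c")]
        muts = muts_frame([("s1", "c", sirs[0].spacer_start + 1, "G", "T", "substitution")])
        res = call_highly_mutated(muts, sirs, 10)
        assert list(res["sir_index"]) == [0]

    def test_empty_family(self):
        sirs = [make_sir(1000, 7, "GAAC", chrom="c")]
        muts = muts_frame([("s1", "c", 50_000, "A", "G", "substitution")])
        res = call_highly_mutated(muts, sirs, 10)
        assert len(res) == 0


class TestSites:
    def _flagged_frame(self, idxs):
        return pd.DataFrame({"sir_index": idxs, "is_highly_mutated": [True] * len(idxs)})

    def test_three_overlapping_collapse_to_one(self):
        sirs = [
            make_sir(1000, 7, "GAAC", chrom="c"),
            make_sir(1005, 9, "GAAC", chrom="c"),   # longest: 22 bp
            make_sir(1010, 7, "GAAC", chrom="c"),
        ]
        sites = collapse_to_sites(self._flagged_frame([0, 1, 2]), sirs)
        assert len(sites) == 1
        assert sites[0].representative == sirs[1]
        assert len(sites[0].members) == 3

    def test_disjoint_sites_stay_separate(self):
        sirs = [make_sir(1000, 7, "GAAC", chrom="c"), make_sir(5000, 7, "GAAC", chrom="c")]
        sites = collapse_to_sites(self._flagged_frame([0, 1]), sirs)
        assert len(sites) == 2

    def test_site_count_equals_connected_components(self):
        rng = np.random.default_rng(31)
        sirs = []
        for _ in range(60):
            start = int(rng.integers(0, 3000))
            sirs.append(make_sir(start, int(rng.integers(6, 12)), "GAAC", chrom="c"))
        sites = collapse_to_sites(self._flagged_frame(list(range(len(sirs)))), sirs)
        # union-find oracle over the overlap graph
        parent = list(range(len(sirs)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(sirs)):
            for j in range(i + 1, len(sirs)):
                a, b = sirs[i], sirs[j]
                if a.start < b.end and b.start < a.end:
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(len(sirs))})
        assert len(sites) == n_components


class TestHotspotSpacers:
    def test_null_fold_near_one_and_not_flagged(self):
        cfg = SimulationConfig(seed=40, chrom_length=80_000, n_planted_sirs=60,
                               n_samples=60, background_density=2e-3, spacer_fold=1.0)
        genome, truth = generate_genome(cfg)
        muts = generate_mutations(cfg, genome, truth)
        from sirscan.detect import find_sirs_genome

        sirs = find_sirs_genome(genome)
        # min_spacer_mutations=0: conditioning on observed spacer mutations
        # would bias the pooled in-SIR density upward at this low coverage
        res = hotspot_spacer_tests(muts, sirs, genome, cfg.n_samples, min_spacer_mutations=0)
        testable = res[res["testable"]]
        assert not testable.empty
        pooled = testable["n_in_sir"].sum() / testable["len_in_sir"].sum()
        pooled /= testable["n_out_sir"].sum() / testable["len_out_sir"].sum()
        assert pooled == pytest.approx(1.0, abs=0.4)
        assert not res["is_hotspot"].any()

    def test_zero_mutation_spacer_not_tested(self):
        genome = {"c": "G" * 500 + "AGGCTAGCTGGCTAGCCT" + "G" * 500 + "CTGG" + "G" * 200}
        sirs = [make_sir(500, 7, "CTGG", chrom="c", left_arm="AGGCTAG")]
        muts = muts_frame([("s1", "c", 50, "G", "T", "substitution")])
        res = hotspot_spacer_tests(muts, sirs, genome, 10, min_spacer_mutations=0)
        row = res[res["spacer_seq"] == min("CTGG", "CCAG")].iloc[0]
        assert row["p_value"] == 1.0
        assert not row["is_hotspot"]


class TestOddsRatio:
    def test_equal_densities_is_one(self):
        or_, (lo, hi) = odds_ratio_spacer_control(10, 1000, 10, 1000)
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_hand_table(self):
        or_, _ = odds_ratio_spacer_control(10, 1000, 5, 1000)
        assert or_ == pytest.approx((10 / 990) / (5 / 995), rel=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        or_, (lo, hi) = odds_ratio_spacer_control(0, 100, 5, 1000)
        assert np.isfinite(or_) and or_ > 0
        assert np.isfinite(lo) and np.isfinite(hi)

    def test_rejects_zero_totals(self):
        with pytest.raises(ValueError):
            odds_ratio_spacer_control(1, 0, 1, 10)


def test_signature_odds_ratios_with_labels():
    cfg = SimulationConfig(seed=41, chrom_length=60_000, n_planted_sirs=50, n_samples=40,
                           background_density=2e-3, spacer_fold=2.0,
                           signature_mix={"APOBEC": 0.5, "flat": 0.5})
    genome, truth = generate_genome(cfg)
    muts = generate_mutations(cfg, genome, truth)
    from sirscan.detect import find_sirs_genome

    sirs = find_sirs_genome(genome)
    assignment = assign_to_domains(muts, sirs)
    ors = signature_odds_ratios(muts, assignment, sirs, cfg.n_samples, genome=genome)
    assert not ors.empty
    # the spacer fold lifts every signature's spacer:control OR above 1
    well_covered = ors[(ors["n_spacer"] >= 10) & (ors["n_control"] >= 10)]
    assert (well_covered["odds_ratio"] > 1.2).all()
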