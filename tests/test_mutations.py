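import itertools

import numpy as np
import pandas as pd
import pytest

from sirscan.detect import SearchConfig
from sirscan.mutations import (
    assign_to_domains,
    classify_substitution,
    distance_profile,
    domain_density,
    effective_domain_lengths,
    per_sir_counts,
    read_variants_tsv,
    read_variants_vcf,
    read_breakpoints_bedpe,
)

from conftest import make_sir, muts_frame


class TestClassifySubstitution:
    def test_already_pyrimidine(self):
        cl = classify_substitution("C", "T", "T", "A")
        assert cl.six == "C>T"
        assert cl.context == "TCA"
        assert cl.label96 == "T[C>T]A"

    def test_purine_strand_flip(self):
        # G>A with 5'=T, 3'=C on the purine strand reads C>T in context G_A
        cl = classify_substitution("G", "A", "T", "C")
        assert cl.six == "C>T"
        assert cl.context == "GCA"

    def test_all_twelve_pairs_map_to_six_classes(self):
        seen = {}
        for ref, alt in itertools.permutations("ACGT", 2):
            cl = classify_substitution(ref, alt, "A", "A")
            seen.setdefault(cl.six, []).append((ref, alt))
        assert sorted(seen) == ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
        assert all(len(v) == 2 for v in seen.values())

    def test_n_flank_gives_six_class_only(self):
        cl = classify_substitution("C", "A", "N", "T")
        assert cl.six == "C>A" and cl.context is None and cl.label96 is None

    def test_n_ref_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("N", "A")


class TestAssign:
    def setup_method(self):
        self.sir = make_sir(1000, 7, "GAAC", chrom="c")  # spacer [1007,1011)

    def test_point_containment(self):
        muts = muts_frame([
            ("s1", "c", 1009, "A", "G", "substitution"),   # 2nd spacer base
            ("s1", "c", 951, "A", "G", "substitution"),    # 50 bp upstream -> control
            ("s1", "c", 1003, "A", "G", "substitution"),   # left arm
            ("s1", "c", 5000, "A", "G", "substitution"),   # far -> outside
        ])
        a = assign_to_domains(muts, [self.sir])
        assert list(a["domain"]) == ["spacer", "control", "arm", "outside"]
        assert list(a["sir_index"][:3]) == [0, 0, 0]

    def test_control_widths_by_variant_class(self):
        # 500 bp downstream: control for rearrangements (1000 bp), outside for subs
        muts = muts_frame([
            ("s1", "c", 1520, "A", "G", "substitution"),
            ("s1", "c", 1520, "N", ".", "rearrangement_breakpoint"),
        ])
        a = assign_to_domains(muts, [self.sir])
        assert list(a["domain"]) == ["outside", "control"]

    def test_control_base_inside_other_sir_keeps_that_domain(self):
        other = make_sir(1100, 7, "GCAC", chrom="c")  # inside first SIR's control reach
        muts = muts_frame([("s1", "c", 1108, "A", "G", "substitution")])  # other's spacer
        a = assign_to_domains(muts, [self.sir, other])
        assert list(a["domain"]) == ["spacer"]
        assert list(a["sir_index"]) == [1]

    def test_unknown_chromosome_warns_outside(self):
        muts = muts_frame([("s1", "chrZ", 10, "A", "G", "substitution")])
        with pytest.warns(UserWarning, match="chrZ"):
            a = assign_to_domains(muts, [self.sir])
        assert list(a["domain"]) == ["outside"]

    def test_matches_bruteforce_membership(self):
        rng = np.random.default_rng(9)
        sirs = [make_sir(int(s), 7, "GAAC", chrom="c") for s in range(500, 50_000, 1000)]
        positions = rng.integers(1, 51_000, size=1000)
        muts = muts_frame([("s1", "c", int(p), "A", "G", "substitution") for p in positions])
        a = assign_to_domains(muts, sirs)
        cw = 100
        for p1, dom in zip(positions, a["domain"]):
            p = p1 - 1
            expected = "outside"
            best = None
            for r in sirs:
                if r.start <= p < r.end:
                    expected = "spacer" if r.spacer_start <= p < r.spacer_end else "arm"
                    break
            else:
                for r in sirs:
                    if r.start - cw <= p < r.start or r.end <= p < r.end + cw:
                        expected = "control"
                        break
            assert dom == expected

    def test_count_conservation(self):
        rng = np.random.default_rng(10)
        sirs = [make_sir(int(s), 7, "GAAC", chrom="c") for s in range(500, 20_000, 700)]
        muts = muts_frame(
            [("s1", "c", int(p), "A", "G", "substitution") for p in rng.integers(1, 21_000, size=500)]
        )
        a = assign_to_domains(muts, sirs)
        counts = a["domain"].value_counts()
        assert counts.sum() == len(muts)
        assert set(counts.index) <= {"spacer", "arm", "control", "outside"}


class TestDensity:
    def test_arithmetic(self):
        # 7 mutations over 1000 bp of spacer across 10 samples -> 700 per Mb
        sirs = [make_sir(i * 1000, 6, "GCAAC" * 2, chrom="c") for i in range(100)]  # 10bp spacers
        rows = []
        for i in range(7):
            s = sirs[i]
            rows.append(("s%d" % i, "c", s.spacer_start + 1, "G", "T", "substitution"))
        muts = muts_frame(rows)
        a = assign_to_domains(muts, sirs)
        dens = domain_density(a, muts, sirs, n_samples=10)
        spacer = dens[dens["domain"] == "spacer"].iloc[0]
        assert spacer["effective_length"] == 1000
        assert spacer["density_per_mb"] == pytest.approx(7 / (1000 * 10) * 1e6)

    def test_no_mutations_zero_density(self):
        sirs = [make_sir(1000, 7, "GAAC", chrom="c")]
        muts = muts_frame([]).astype({"pos": int}, errors="ignore")
        a = assign_to_domains(muts, sirs)
        dens = domain_density(a, muts, sirs, n_samples=5)
        assert (dens["density_per_mb"].fillna(0) == 0).all()

    def test_effective_lengths_exclude_n_and_bodies(self):
        genome = {"c": "A" * 980 + "N" * 20 + "A" * 9000}
        sir = make_sir(1000, 7, "GAAC", chrom="c")
        lengths = effective_domain_lengths([sir], genome=genome)
        assert lengths["spacer"] == 4
        assert lengths["arm"] == 14
        assert lengths["control"] == 200 - 20  # 20 N bases inside upstream control

    def test_overlapping_controls_counted_once_globally(self):
        # bodies [1000,1018) and [1100,1118); window union is [900,1218)
        a = make_sir(1000, 7, "GAAC", chrom="c")
        b = make_sir(1100, 7, "GCAC", chrom="c")
        lengths = effective_domain_lengths([a, b])
        assert lengths["control"] == (1218 - 900) - 2 * 18


class TestPerSir:
    def test_per_sir_control_counts_both_neighbours(self):
        a = make_sir(1000, 7, "GAAC", chrom="c")
        b = make_sir(1100, 7, "GCAC", chrom="c")
        # position 1050 is in the downstream control of a AND upstream control of b
        muts = muts_frame([("s1", "c", 1051, "A", "G", "substitution")])
        counts = per_sir_counts(muts, [a, b])
        assert counts["n_control"].tolist() == [1, 1]

    def test_spacer_counts(self):
        sir = make_sir(1000, 7, "GAAC", chrom="c")
        muts = muts_frame([
            ("s1", "c", 1008, "G", "T", "substitution"),
            ("s2", "c", 1009, "A", "T", "substitution"),
            ("s3", "c", 1003, "G", "T", "substitution"),
        ])
        counts = per_sir_counts(muts, [sir])
        row = counts.iloc[0]
        assert (row["n_spacer"], row["n_arm"], row["n_control"]) == (2, 1, 0)
        assert row["len_spacer"] == 4 and row["len_arm"] == 14 and row["len_control"] == 200


class TestDistanceProfile:
    def test_center_spike(self):
        sirs = [make_sir(i * 1000, 7, "GAAC", chrom="c") for i in range(1, 20)]
        muts = muts_frame(
            [("s1", "c", r.center + 1, "A", "G", "substitution") for r in sirs]
        )
        prof = distance_profile(muts, sirs, half_window=50)
        spike = prof[prof["offset"] == 0].iloc[0]
        assert spike["count"] == len(sirs)
        assert spike["likelihood"] == pytest.approx(1.0)
        assert prof[prof["offset"] != 0]["count"].sum() == 0

    def test_flat_background(self):
        rng = np.random.default_rng(12)
        sirs = [make_sir(i * 2000, 7, "GAAC", chrom="c") for i in range(1, 50)]
        muts = muts_frame(
            [("s1", "c", int(p), "A", "G", "substitution")
             for p in rng.integers(1, 100_000, size=20_000)]
        )
        prof = distance_profile(muts, sirs, half_window=30)
        assert prof["n_sirs"].eq(49).all()
        # uniform background: per-offset likelihood ~ Binomial(n_sirs*density)
        expected = 20_000 / 100_000
        assert prof["likelihood"].mean() == pytest.approx(expected, rel=0.15)

    def test_count_conservation(self):
        sirs = [make_sir(1000, 7, "GAAC", chrom="c")]
        muts = muts_frame([
            ("s1", "c", 995, "A", "G", "substitution"),
            ("s1", "c", 1050, "A", "G", "substitution"),
            ("s1", "c", 5000, "A", "G", "substitution"),  # beyond window
        ])
        prof = distance_profile(muts, sirs, half_window=60)
        c = sirs[0].center
        in_window = sum(1 for p in (994, 1049, 4999) if abs(p - c) <= 60)
        assert prof["count"].sum() == in_window


class TestIO:
    def test_tsv_roundtrip_and_class_inference(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "sample\tchrom\tpos\tref\talt\n"
            "s1\tc\t10\tA\tG\n"
            "s1\tc\t20\tAT\tA\n"
        )
        df = read_variants_tsv(p)
        assert list(df["var_class"]) == ["substitution", "indel"]

    def test_tsv_missing_column(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("sample\tchrom\tpos\tref\n" "s1\tc\t10\tA\n")
        with pytest.raises(ValueError, match="alt"):
            read_variants_tsv(p)

    def test_minimal_vcf(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tSAMPLE\n"
            "c\t10\t.\tA\tG\ts1\n"
        )
        df = read_variants_vcf(p)
        assert df.iloc[0]["sample"] == "s1" and df.iloc[0]["pos"] == 10

    def test_bedpe_two_breakpoints_per_line(self, tmp_path):
        p = tmp_path / "r.bedpe"
        p.write_text("c\t100\t101\tc\t5000\t5001\ts1\n")
        df = read_breakpoints_bedpe(p)
        assert len(df) == 2
        assert list(df["pos"]) == [101, 5001]
        assert set(df["var_class"]) == {"rearrangement_breakpoint"}
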