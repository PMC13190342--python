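"""Usage tables, strand/region summaries, convergence, productivity, Welch test."""

import numpy as np
import pytest
from scipy import stats as sps

from kappascan.errors import ConfigError, NormalizationError
from kappascan.junction_io import JunctionLibrary, JunctionRecord
from kappascan.locus_model import Rearrangement, apply_rearrangement
from kappascan.repertoire_stats import (
    NormalizationPolicy,
    benjamini_hochberg,
    call_productivity,
    convergent_fraction,
    normalize_library,
    pooled_offtarget_profile,
    productive_fraction,
    region_orientation_summary,
    vk_usage_table,
    welch_t_test,
)


def _rec(i, pos=100, strand="-", cls="cryptic", name="", prod="n/a", **kw):
    return JunctionRecord(
        read_id=f"r{i}",
        bait_name="Jk1",
        bait_position=0,
        prey_position=pos,
        prey_strand=strand,
        junction_class=cls,
        prey_name=name,
        productive=prod,
        **kw,
    )


def _lib(records, rep="rep1", raw=None):
    return JunctionLibrary("Jk1", rep, records, raw_total=raw)


class TestNormalization:
    def test_target_total_exact(self):
        lib = _lib([_rec(i) for i in range(10)], raw=500_000)
        out = normalize_library(lib)
        assert all(r.weight == 1.0 for r in out.records)
        lib2 = _lib([_rec(i) for i in range(10)], raw=1_000_000)
        out2 = normalize_library(lib2)
        assert all(r.weight == 0.5 for r in out2.records)
        assert sum(r.weight for r in out2.records) * (1_000_000 / 10) == pytest.approx(500_000)

    def test_proportions_preserved(self):
        rng = np.random.default_rng(6)
        names = rng.choice(["A", "B", "C"], 300)
        lib = _lib([_rec(i, name=n, cls="bona_fide_coding") for i, n in enumerate(names)],
                   raw=123_457)
        out = normalize_library(lib)

        def share(library, name):
            tot = sum(r.weight for r in library.records)
            return sum(r.weight for r in library.records if r.prey_name == name) / tot

        for n in "ABC":
            assert abs(share(out, n) - share(lib, n)) < 1e-12

    def test_double_normalization_and_zero_total(self):
        lib = _lib([_rec(0)], raw=100)
        out = normalize_library(lib)
        with pytest.raises(NormalizationError):
            normalize_library(out)
        with pytest.raises(NormalizationError):
            normalize_library(_lib([], raw=0))
        with pytest.raises(ConfigError):
            NormalizationPolicy(target_total=0)


class TestUsage:
    def test_single_vk_is_100_percent(self, mini_locus):
        lib = _lib([_rec(i, cls="bona_fide_coding", name="Vk-d1") for i in range(5)])
        table = vk_usage_table([lib], mini_locus).set_index("vk")
        assert table.loc["Vk-d1", "mean_percent"] == pytest.approx(100.0)

    def test_three_to_one_split(self, mini_locus):
        recs = [_rec(i, cls="bona_fide_coding", name="Vk-d1") for i in range(3)]
        recs.append(_rec(3, cls="bona_fide_coding", name="Vk-m2"))
        table = vk_usage_table([_lib(recs)], mini_locus).set_index("vk")
        assert table.loc["Vk-d1", "mean_percent"] == pytest.approx(75.0)
        assert table.loc["Vk-m2", "mean_percent"] == pytest.approx(25.0)

    def test_identical_replicates_sem_zero_and_sum_100(self, mini_locus):
        recs = [_rec(i, cls="bona_fide_coding", name=n)
                for i, n in enumerate(["Vk-d1"] * 3 + ["Vk-p3"])]
        libs = [_lib(list(recs), rep=f"rep{k}") for k in range(3)]
        table = vk_usage_table(libs, mini_locus)
        assert (table["sem_percent"] == 0).all()
        assert table["mean_percent"].sum() == pytest.approx(100.0, abs=1e-9)


class TestProfilesAndRegions:
    def test_single_bin_minus_strand(self, mini_locus):
        lib = _lib([_rec(i, pos=123, strand="-") for i in range(4)])
        prof = pooled_offtarget_profile(lib, mini_locus, bin_size=10_000)
        assert prof.loc[0, "percent_minus"] == pytest.approx(100.0)
        assert prof["percent_plus"].sum() == 0

    def test_empty_library_and_bad_bin(self, mini_locus):
        prof = pooled_offtarget_profile(_lib([]), mini_locus, bin_size=10_000)
        assert prof["percent_plus"].sum() == 0 and prof["percent_minus"].sum() == 0
        with pytest.raises(ConfigError):
            pooled_offtarget_profile(_lib([]), mini_locus, bin_size=0)

    def test_region_orientation_examples(self, mini_locus):
        mid_lo = dict((lab, (a, b)) for lab, a, b in mini_locus.regions)["middle"][0]
        lib = _lib([_rec(0, pos=mid_lo + 5, strand="+")])
        summary = region_orientation_summary(lib, mini_locus)
        row = summary[(summary.region == "middle") & (summary.orientation == "inversional")]
        assert row["count"].iloc[0] == 1 and row["percent"].iloc[0] == pytest.approx(100.0)
        empty = summary[(summary.region == "distal") & (summary.orientation == "deletional")]
        assert empty["count"].iloc[0] == 0 and empty["percent"].iloc[0] == 0.0

    def test_region_summary_matches_brute_force(self, mini_locus):
        rng = np.random.default_rng(7)
        recs = [
            _rec(i, pos=int(rng.integers(0, mini_locus.length)),
                 strand=rng.choice(["+", "-"]))
            for i in range(200)
        ]
        summary = region_orientation_summary(_lib(recs), mini_locus)
        from kappascan.locus_model import region_of
        for (lab, orient), grp in summary.groupby(["region", "orientation"]):
            expected = sum(
                1
                for r in recs
                if region_of(r.prey_position, mini_locus) == lab
                and (r.prey_strand == "-") == (orient == "deletional")
            )
            assert grp["count"].iloc[0] == expected
        assert summary["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_strand_orientation_convention_is_a_bijection(self, mini_locus):
        """Metamorphic: flipping every prey strand flips every orientation."""
        rng = np.random.default_rng(8)
        recs = [
            _rec(i, pos=int(rng.integers(0, mini_locus.length)),
                 strand=rng.choice(["+", "-"]))
            for i in range(100)
        ]
        flipped = [
            _rec(i, pos=r.prey_position, strand="+" if r.prey_strand == "-" else "-")
            for i, r in enumerate(recs)
        ]
        a = region_orientation_summary(_lib(recs), mini_locus).set_index(["region", "orientation"])
        b = region_orientation_summary(_lib(flipped), mini_locus).set_index(["region", "orientation"])
        for (lab, orient) in a.index:
            other = "deletional" if orient == "inversional" else "inversional"
            assert a.loc[(lab, orient), "count"] == b.loc[(lab, other), "count"]


class TestConvergence:
    def test_mixed_80_20(self):
        recs = [_rec(i, strand="-") for i in range(8)] + [
            _rec(8 + i, strand="+") for i in range(2)
        ]
        res = convergent_fraction(_lib(recs))
        assert res.fraction == pytest.approx(0.8)
        assert res.n_used == 10 and res.n_excluded == 0

    def test_deleted_interval_junctions_excluded(self, mini_locus):
        v = mini_locus.segment("Vk-p4")
        _, t = apply_rearrangement(mini_locus, Rearrangement("Vk-p4", "Jk1"))
        inside_deleted = v.cut_point + 100
        recs = [_rec(0, pos=inside_deleted, strand="-"), _rec(1, pos=10, strand="-")]
        res = convergent_fraction(_lib(recs), t)
        assert res.n_excluded == 1 and res.n_used == 1

    def test_invariant_under_projection_round_trip(self, mini_locus):
        """Convergence computed in allele coordinates does not change when the
        records are re-expressed through project→unproject."""
        _, t = apply_rearrangement(mini_locus, Rearrangement("Vk-m1", "Jk1"))
        rng = np.random.default_rng(9)
        recs = []
        for i in range(100):
            apos = int(rng.integers(0, t.allele_length))
            strand = rng.choice(["+", "-"])
            rpos, rstrand = t.project_boundary(apos, strand)
            recs.append(_rec(i, pos=rpos, strand=rstrand))
        res = convergent_fraction(_lib(recs), t)
        # recompute from the allele frame directly
        n_conv = 0
        for r in recs:
            _, s = t.unproject_boundary(r.prey_position, r.prey_strand)
            n_conv += s == "-"
        assert res.fraction == pytest.approx(n_conv / 100)


class TestProductivity:
    def _join_record(self, v_name, bait="Jk4", ins="", bd=0, pd=0):
        return JunctionRecord(
            read_id="r0",
            bait_name=bait,
            bait_position=0,
            prey_position=0,
            prey_strand="-",
            insertion_seq=ins,
            bait_deletion=bd,
            prey_deletion=pd,
            junction_class="bona_fide_coding",
            prey_name=v_name,
        )

    def test_zero_trim_in_frame_is_productive(self, mini_locus):
        assert call_productivity(self._join_record("Vk-d1"), mini_locus) == "productive"

    def test_plus_one_insertion_shifts_frame(self, mini_locus):
        assert call_productivity(self._join_record("Vk-d1", ins="G"), mini_locus) == "nonproductive"

    def test_stop_codon_across_junction(self, mini_locus):
        assert call_productivity(self._join_record("Vk-d1", ins="TAA"), mini_locus) == "nonproductive"
        assert call_productivity(self._join_record("Vk-d1", ins="GGA"), mini_locus) == "productive"

    def test_missing_annotation_is_na(self, mini_locus):
        rec = self._join_record("")
        assert call_productivity(rec, mini_locus) == "n/a"

    def test_productive_fraction(self):
        libs = [
            _lib([_rec(i, prod="productive") for i in range(3)]
                 + [_rec(3, prod="nonproductive")], rep="rep1"),
            _lib([_rec(i, prod="productive") for i in range(4)], rep="rep2"),
            _lib([], rep="rep3"),
        ]
        df = productive_fraction(libs).set_index("replicate")
        assert df.loc["rep1", "fraction"] == pytest.approx(0.75)
        assert df.loc["rep2", "fraction"] == pytest.approx(1.0)
        assert np.isnan(df.loc["rep3", "fraction"])


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_reference_implementation(self):
        a = [2.1, 3.4, 2.9, 4.0, 3.3]
        b = [1.2, 2.2, 1.9, 2.5]
        t, df, p = welch_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)
        assert df == pytest.approx(ref.df, abs=1e-9)

    def test_scale_invariance(self):
        a = [2.1, 3.4, 2.9, 4.0]
        b = [1.2, 2.2, 1.9, 2.5]
        t1, _, p1 = welch_t_test(a, b)
        t2, _, p2 = welch_t_test([x * -7.5 for x in a], [x * -7.5 for x in b])
        assert abs(t1) == pytest.approx(abs(t2)) and p1 == pytest.approx(p2)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])

    def test_benjamini_hochberg_monotone(self):
        p = [0.001, 0.04, 0.03, 0.9]
        adj = benjamini_hochberg(p)
        assert (adj >= p).all() and adj.max() <= 1.0
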