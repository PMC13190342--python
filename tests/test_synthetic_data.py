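"""Mini-locus construction, the two joining mechanisms and read emission."""

from dataclasses import replace as dc_replace

import numpy as np
import pytest

from kappascan.errors import ConfigError
from kappascan.junction_io import call_reads, detect_p_nucleotides
from kappascan.locus_model import Rearrangement, locus_to_fasta
from kappascan.repertoire_stats import convergent_fraction
from kappascan.synthetic_data import (
    HEPTAMER_CONSENSUS,
    NONAMER_CONSENSUS,
    SPACER12_CONSENSUS,
    LocusConfig,
    NoiseModel,
    SimulationConfig,
    ZERO_NOISE,
    emit_reads,
    make_mini_locus,
    simulate_primary_diffusion,
    simulate_secondary_scanning,
)


class TestMiniLocus:
    def test_structure_defaults(self, mini_locus):
        assert len(mini_locus.v_segments) == 12
        assert sorted(s.name for s in mini_locus.j_segments) == ["Jk1", "Jk2", "Jk4", "Jk5"]
        middles = [s for s in mini_locus.v_segments if s.region == "middle"]
        assert middles and all(s.vk_orientation == "inversional" for s in middles)
        prox = [s for s in mini_locus.v_segments if s.region == "proximal"]
        assert {s.vk_orientation for s in prox} == {"deletional", "inversional"}
        assert prox[-1].vk_orientation == "deletional"  # most proximal Vκ

    def test_same_seed_byte_identical_fasta(self):
        a = locus_to_fasta(make_mini_locus(seed=42))
        b = locus_to_fasta(make_mini_locus(seed=42))
        assert a == b
        c = locus_to_fasta(make_mini_locus(seed=43))
        assert a != c

    def test_planted_cryptic_sites_have_cac_heptamer(self, mini_locus):
        S = mini_locus.sequence
        from kappascan.locus_model import revcomp
        for site in mini_locus.cryptic_sites:
            if site.strand == "-":
                assert S[site.position : site.position + 3] == "CAC"
            else:
                assert revcomp(S[site.position - 3 : site.position]) == "CAC"

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigError):
            LocusConfig(n_distal=0)
        with pytest.raises(ConfigError):
            LocusConfig(v_coding_len=301)


class TestDiffusion:
    def test_zero_cryptic_rate_no_cryptic_records(self, mini_locus):
        cfg = SimulationConfig(seed=10, n_junctions=500, cryptic_rate=0.0)
        sim = simulate_primary_diffusion(mini_locus, cfg)
        assert (sim.truth.kind == "bona_fide").all()

    def test_scanning_leg_confined_between_cer_and_jk(self, mini_locus):
        cfg = SimulationConfig(seed=10, n_junctions=4000)
        sim = simulate_primary_diffusion(mini_locus, cfg)
        bounds = dict((lab, (a, b)) for lab, a, b in mini_locus.regions)
        lo, hi = bounds["cer_to_jk"]
        leg = sim.truth[sim.truth.mech == "scanning_leg"]
        assert len(leg) > 0
        assert ((leg.ref_pos >= lo) & (leg.ref_pos < hi)).all()
        assert (leg.ref_strand == "-").all()  # convergent-only

    def test_symmetric_weights_give_1_to_1_orientation_usage(self, mini_locus):
        """With identical RSSs everywhere, deletional and inversional Vκs are
        used 1:1 within binomial error (orientation-independent diffusion)."""
        import copy

        locus = copy.deepcopy(mini_locus)
        consensus = HEPTAMER_CONSENSUS + SPACER12_CONSENSUS + NONAMER_CONSENSUS
        for seg in locus.v_segments:
            seg.rss = dc_replace(seg.rss, sequence=consensus)
        cfg = SimulationConfig(seed=10, n_junctions=10_000, cryptic_rate=0.0)
        sim = simulate_primary_diffusion(locus, cfg)
        orient = {s.name: s.vk_orientation for s in locus.v_segments}
        n_del = sum(orient[n] == "deletional" for n in sim.truth.prey_name)
        frac = n_del / len(sim.truth)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 10_000) + 0.01

    def test_capture_proportional_to_weight(self, mini_locus):
        cfg = SimulationConfig(seed=10, n_junctions=20_000, cryptic_rate=0.0)
        sim = simulate_primary_diffusion(mini_locus, cfg)
        counts = sim.truth.prey_name.value_counts()
        w = sim.capture_weights
        total_w = sum(w.values())
        for name, weight in w.items():
            expected = 20_000 * weight / total_w
            got = counts.get(name, 0)
            assert abs(got - expected) < 5 * np.sqrt(expected + 1) + 5

    def test_mechanism_wrong_config_rejected(self, mini_locus):
        cfg = SimulationConfig(mechanism="scanning_secondary")
        with pytest.raises(ConfigError):
            simulate_primary_diffusion(mini_locus, cfg)


class TestScanning:
    def test_requires_rearrangement(self, mini_locus):
        cfg = SimulationConfig(mechanism="scanning_secondary")
        with pytest.raises(ConfigError):
            simulate_secondary_scanning(mini_locus, None, cfg)

    def test_cryptic_captures_convergent_in_allele_frame(self, mini_locus):
        cfg = SimulationConfig(seed=12, n_junctions=3000, mechanism="scanning_secondary")
        sim = simulate_secondary_scanning(mini_locus, Rearrangement("Vk-m1", "Jk1"), cfg)
        cryptic = sim.truth[sim.truth.kind == "cryptic"]
        assert len(cryptic) > 50
        assert (cryptic.allele_strand == "-").all()
        lib_cryptic = sim.library.with_records(
            [r for r in sim.library.records if r.junction_class == "cryptic"]
        )
        res = convergent_fraction(lib_cryptic, sim.transform)
        assert res.fraction == 1.0

    def test_inverted_middle_domain_projects_to_plus_strand(self, mini_locus):
        cfg = SimulationConfig(seed=12, n_junctions=3000, mechanism="scanning_secondary")
        sim = simulate_secondary_scanning(mini_locus, Rearrangement("Vk-m1", "Jk1"), cfg)
        bounds = dict((lab, (a, b)) for lab, a, b in mini_locus.regions)
        lo, hi = bounds["middle"]
        cryptic = sim.truth[sim.truth.kind == "cryptic"]
        middle = cryptic[(cryptic.ref_pos >= lo) & (cryptic.ref_pos < hi)]
        assert len(middle) > 10
        assert (middle.ref_strand == "+").all()

    def test_impediment_bonus_increases_transcribed_usage(self, mini_locus):
        r = Rearrangement("Vk-m1", "Jk1")
        base = SimulationConfig(seed=12, n_junctions=20_000,
                                mechanism="scanning_secondary", impediment_bonus=1.0)
        boosted = dc_replace(base, impediment_bonus=4.0)
        sim_a = simulate_secondary_scanning(mini_locus, r, base)
        sim_b = simulate_secondary_scanning(mini_locus, r, boosted)
        transcribed = {s.name for s in mini_locus.v_segments if s.transcribed}
        share_a = sim_a.truth.prey_name.isin(transcribed).mean()
        share_b = sim_b.truth.prey_name.isin(transcribed).mean()
        assert share_b > share_a

    def test_usage_concentrates_immediately_upstream(self, mini_locus):
        """Linear scanning saturates on the nearest capturable Vκs."""
        cfg = SimulationConfig(seed=12, n_junctions=5000, mechanism="scanning_secondary")
        sim = simulate_secondary_scanning(mini_locus, Rearrangement("Vk-m1", "Jk1"), cfg)
        bona = sim.truth[sim.truth.kind == "bona_fide"]
        # distance from the RC in allele coordinates
        rc_pos = bona.allele_pos.max() + 1
        near = bona[bona.allele_pos >= rc_pos - 15_000]
        assert len(near) / len(bona) > 0.6


class TestEmission:
    def test_zero_noise_reads_reconstruct_truth_exactly(self, mini_locus, seed_index):
        cfg = SimulationConfig(seed=14, n_junctions=400)
        sim = emit_reads(simulate_primary_diffusion(mini_locus, cfg), ZERO_NOISE, seed=15)
        lib = call_reads(sim.reads, sim.bait, mini_locus, seed_index=seed_index)
        assert len(lib.records) == 400
        truth_by_id = {r.read_id: r for r in sim.library.records}
        for rec in lib.records:
            t = truth_by_id[rec.read_id]
            assert (rec.prey_position, rec.prey_strand) == (t.prey_position, t.prey_strand)
            assert rec.insertion_seq == "" and rec.bait_deletion == 0
            assert rec.mutations_near_junction == 0

    def test_noisy_reads_match_canonical_truth(self, mini_locus, seed_index):
        cfg = SimulationConfig(seed=14, n_junctions=2000)
        sim = emit_reads(simulate_primary_diffusion(mini_locus, cfg), NoiseModel(), seed=15)
        lib = call_reads(sim.reads, sim.bait, mini_locus, seed_index=seed_index)
        truth_by_id = {r.read_id: r for r in sim.library.records}
        agree = sum(
            (rec.prey_position, rec.prey_strand)
            == (truth_by_id[rec.read_id].prey_position, truth_by_id[rec.read_id].prey_strand)
            for rec in lib.records
        )
        assert agree / len(lib.records) >= 0.999

    def test_planted_p_elements_fully_recovered_by_detector(self, mini_locus):
        """Insertions built as hairpin-derived P elements at untrimmed ends are
        attributed entirely to P by the detector (generator↔detector
        consistency on the planted, pre-canonicalization components)."""
        from kappascan.locus_model import revcomp
        from kappascan.synthetic_data import make_bait

        rng = np.random.default_rng(20)
        S = mini_locus.sequence
        bait = make_bait(mini_locus, "Jk1").sequence
        for seg in mini_locus.v_segments:
            cut = seg.cut_point
            if seg.vk_orientation == "deletional":
                prey = revcomp(S[cut - 60 : cut])
            else:
                prey = S[cut : cut + 60]
            for _ in range(5):
                k1 = int(rng.integers(1, 3))
                k2 = int(rng.integers(1, 3))
                ins = revcomp(bait[-k1:]) + revcomp(prey[:k2])
                pb, pp = detect_p_nucleotides(ins, bait, prey, 0, 0)
                assert pb >= 1
                assert pb + pp == len(ins)

    def test_p_probability_one_enriches_bait_side_p(self, mini_locus):
        """With P generation certain and no trimming, the realized libraries
        are dominated by junctions whose insertions begin with a bait-side P
        (a minority are re-attributed by the canonical junction convention)."""
        noise = NoiseModel(bait_deletion_mean=0, prey_deletion_mean=0,
                           p_probability=1.0, insertion_mean=0, mismatch_rate=0)
        cfg = SimulationConfig(seed=14, n_junctions=300)
        sim = emit_reads(simulate_primary_diffusion(mini_locus, cfg), noise, seed=15)
        with_p = sum(r.p_len_bait >= 1 for r in sim.library.records)
        assert with_p / len(sim.library.records) > 0.9
        assert all(r.effective_insertion >= 0 for r in sim.library.records)

    def test_mismatch_rate_realized_within_binomial_ci(self, mini_locus):
        noise = NoiseModel(bait_deletion_mean=0, prey_deletion_mean=0,
                           p_probability=0, insertion_mean=0, mismatch_rate=0.05)
        cfg = SimulationConfig(seed=14, n_junctions=2000)
        sim = emit_reads(simulate_primary_diffusion(mini_locus, cfg), noise, seed=15)
        mean_mut = sim.truth.mut20.mean()
        # 20 bases at 0.05/base → 1 expected mutation per window
        assert 0.8 < mean_mut < 1.2

    def test_determinism(self, mini_locus):
        cfg = SimulationConfig(seed=16, n_junctions=200)
        a = emit_reads(simulate_primary_diffusion(mini_locus, cfg), NoiseModel(), seed=17)
        b = emit_reads(simulate_primary_diffusion(mini_locus, cfg), NoiseModel(), seed=17)
        assert a.reads == b.reads
        assert a.truth.equals(b.truth)
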