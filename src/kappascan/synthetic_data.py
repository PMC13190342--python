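"""Synthetic mini-locus and junction-library simulator with full ground truth.

The generator emulates the two Igκ joining mechanisms at miniature scale so
every pipeline stage is testable without downloads:

* a ~46 kb single-contig mini-locus with a distal (deletional), middle
  (inversional) and proximal (mixed-orientation) Vκ cluster, the Cer/Sis
  element pair, four functional Jκs (Jκ1/2/4/5, plus a Jκ3 landmark), iEκ and
  the 3′ RS, with bona fide RSSs of graded information content and planted
  cryptic RSS sites on both strands of every region;
* primary *diffusional* joining: Vκ capture probability proportional to an
  RSS-score-derived weight, independent of orientation and distance, plus
  low-level cryptic junctions — a convergent-only scanning leg strictly
  confined between Cer/Sis and Jκ (RAG scanning from the primary RC
  terminates at Sis) and orientation-symmetric diffusional capture of
  Vκ-region cryptic sites;
* secondary *linear scanning* from a VκJκ1-based recombination centre on a
  rearranged allele: a sequential first-capture (competing-hazards) walk
  upstream in allele coordinates, hazard ∝ RSS weight × transcription-
  impediment bonus, attenuated by exp(−distance/decay); cryptic captures are
  convergent-only in the allele frame and inversional bona fide Vκs join at a
  penalty.  Emitted coordinates are reported in the reference frame through
  the rearrangement transform;
* read emission with a junction noise model (geometric coding-end deletions,
  P-nucleotides at untrimmed ends, untemplated insertions, per-base prey
  mismatches).  Realized truth is re-expressed in the caller's canonical
  left-assignment convention, since e.g. a mismatch planted on the junction-
  proximal prey base is indistinguishable from an inserted base.

All rates are stand-ins at mini-locus scale and are not estimates of the
biology; they are chosen only to make the two mechanisms' signatures
(orientation symmetry vs. convergent restriction, locus-wide vs. RC-proximal
usage) cleanly measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .junction_io import (
    BaitDefinition,
    JunctionLibrary,
    JunctionRecord,
    detect_p_nucleotides,
    place_junction,
)
from .locus_model import (
    CoordinateTransform,
    CrypticSite,
    GeneSegment,
    GenomicInterval,
    LocusMap,
    Rearrangement,
    RssAnnotation,
    apply_rearrangement,
    revcomp,
)
from .rss_scoring import RssModel, classify_strength, score_rss, train_rss_model

_BASES = "ACGT"

HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "ACAAAAACC"
SPACER12_CONSENSUS = "ACACAAACCCTG"
SPACER23_CONSENSUS = "GTAGTACTCCACTGTCTGGCTGT"

# mismatch budget per Vκ (locus order), mixing regions so that capture-weight
# rank is not confounded with position; all 12 values distinct
_V_MISMATCHES = (5, 0, 8, 3, 10, 1, 7, 11, 4, 9, 2, 6)
_MUTATE_TO = {"A": "C", "C": "G", "G": "T", "T": "A"}


# ---------------------------------------------------------------------------
# mini-locus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusConfig:
    n_distal: int = 4
    n_middle: int = 4
    n_proximal: int = 4
    v_coding_len: int = 300  # multiple of 3; frame 0
    j_coding_len: int = 39
    v_gap: int = 2400
    cluster_gap: int = 1200
    leader_gap: int = 1500
    scanning_leg_gap: int = 1500  # Sis → Jκ1, carries the scanning-leg cryptic sites

    def __post_init__(self) -> None:
        if min(self.n_distal, self.n_middle, self.n_proximal) < 1:
            raise ConfigError("each Vκ cluster needs at least one segment")
        if self.v_coding_len % 3 or self.j_coding_len % 3:
            raise ConfigError("coding lengths must be codon multiples")


def _random_coding(rng: np.random.Generator, length: int) -> str:
    """Random coding sequence with no stop codon in frame 0."""
    codons = []
    while len(codons) * 3 < length:
        c = "".join(rng.choice(list(_BASES), 3))
        if c not in ("TAA", "TAG", "TGA"):
            codons.append(c)
    return "".join(codons)[:length]


def _v_rss_sequence(rng: np.random.Generator, n_mismatches: int) -> str:
    """Consensus 12RSS with n deterministic-count mismatches in spacer+nonamer
    (heptamer kept at consensus)."""
    body = list(SPACER12_CONSENSUS + NONAMER_CONSENSUS)
    positions = rng.permutation(len(body))[:n_mismatches]
    for p in positions:
        body[p] = _MUTATE_TO[body[p]]
    return HEPTAMER_CONSENSUS + "".join(body)


def _cryptic_rss_sequence(rng: np.random.Generator) -> str:
    """Heptamer consensus + randomized spacer/nonamer: a plausible cryptic site."""
    body = "".join(rng.choice(list(_BASES), len(SPACER12_CONSENSUS + NONAMER_CONSENSUS)))
    return HEPTAMER_CONSENSUS + body


def make_mini_locus(config: LocusConfig | None = None, seed: int = 0) -> LocusMap:
    """Build the miniature Igκ locus: sequence, segments, regions, cryptic sites.

    Deterministic given (config, seed).  Layout 5'→3': distal Vκs (all
    deletional), middle Vκs (all inversional), proximal Vκs (alternating, the
    most proximal deletional), Cer, Sis, Jκ1, Jκ2, Jκ3 (landmark), Jκ4, Jκ5,
    iEκ, 3′RS.  The middle region starts at the most distal middle Vκ's RSS.
    """
    cfg = config or LocusConfig()
    rng = np.random.default_rng(seed)

    rss12_len = 7 + 12 + 9
    rss23_len = 7 + 23 + 9
    plan: list[dict] = []  # feature plan before sequence assembly
    cursor = cfg.leader_gap
    v_index = 0
    cryptic_plan: list[tuple[int, str]] = []

    def plan_v(name: str, region: str, orientation: str, transcribed: bool) -> None:
        nonlocal cursor, v_index
        n_mm = _V_MISMATCHES[v_index % len(_V_MISMATCHES)]
        rss_seq = _v_rss_sequence(rng, n_mm)
        if orientation == "deletional":
            coding = (cursor, cursor + cfg.v_coding_len)
            rss_iv = (coding[1], coding[1] + rss12_len)
            rss_orient = "down"
            strand = "+"
        else:
            rss_iv = (cursor, cursor + rss12_len)
            coding = (rss_iv[1], rss_iv[1] + cfg.v_coding_len)
            rss_orient = "up"
            strand = "-"
        plan.append(
            dict(
                name=name,
                kind="V",
                coding=coding,
                strand=strand,
                rss=rss_iv,
                rss_orient=rss_orient,
                rss_seq=rss_seq,
                spacer=12,
                region=region,
                vk_orientation=orientation,
                transcribed=transcribed,
                n_mm=n_mm,
            )
        )
        cursor = max(coding[1], rss_iv[1])
        # one cryptic site mid-gap after each Vκ, alternating strands
        site_strand = "-" if v_index % 2 == 0 else "+"
        site_pos = cursor + cfg.v_gap // 2
        cryptic_plan.append((site_pos, site_strand))
        cursor += cfg.v_gap
        v_index += 1

    region_starts = {"distal": 0}
    for i in range(cfg.n_distal):
        plan_v(f"Vk-d{i + 1}", "distal", "deletional", transcribed=(i % 3 == 0))
    cursor += cfg.cluster_gap
    region_starts["middle"] = cursor
    for i in range(cfg.n_middle):
        plan_v(f"Vk-m{i + 1}", "middle", "inversional", transcribed=(i % 3 == 1))
    cursor += cfg.cluster_gap
    region_starts["proximal"] = cursor
    prox_orients = [
        ("inversional" if (cfg.n_proximal - 1 - i) % 2 else "deletional")
        for i in range(cfg.n_proximal)
    ]
    for i in range(cfg.n_proximal):
        plan_v(f"Vk-p{i + 1}", "proximal", prox_orients[i], transcribed=(i % 2 == 0))

    cursor += cfg.cluster_gap
    region_starts["cer_to_jk"] = cursor

    def plan_landmark(name: str, length: int, gap_after: int) -> None:
        nonlocal cursor
        plan.append(dict(name=name, kind="landmark", coding=(cursor, cursor + length), strand="+"))
        cursor += length + gap_after

    plan_landmark("Cer", 400, 800)
    plan_landmark("Sis", 400, 0)
    # scanning leg between Sis and Jκ1: convergent-only cryptic sites
    leg_positions = [cursor + (i + 1) * cfg.scanning_leg_gap // 3 for i in range(2)]
    for p in leg_positions:
        cryptic_plan.append((p, "-"))
    cursor += cfg.scanning_leg_gap

    j_names = ["Jk1", "Jk2", "Jk3", "Jk4", "Jk5"]
    for jn in j_names:
        if jn == "Jk3":
            plan_landmark("Jk3", cfg.j_coding_len, 500)
            continue
        rss_iv = (cursor, cursor + rss23_len)
        coding = (rss_iv[1], rss_iv[1] + cfg.j_coding_len)
        plan.append(
            dict(
                name=jn,
                kind="J",
                coding=coding,
                strand="+",
                rss=rss_iv,
                rss_orient="up",
                rss_seq=HEPTAMER_CONSENSUS + SPACER23_CONSENSUS + NONAMER_CONSENSUS,
                spacer=23,
                region="other",
            )
        )
        cursor = coding[1] + 500
    plan_landmark("iEk", 500, 600)
    plan_landmark("RS3p", 300, 400)

    length = cursor + 200
    seq = rng.choice(list(_BASES), length)
    seq = "".join(seq)

    def plant(s: str, text: str, at: int) -> str:
        return s[:at] + text + s[at + len(text) :]

    segments: list[GeneSegment] = []
    contig = "miniIgk"
    for feat in plan:
        c0, c1 = feat["coding"]
        if feat["kind"] == "V":
            seq = plant(seq, _random_coding(rng, cfg.v_coding_len)
                        if feat["strand"] == "+"
                        else revcomp(_random_coding(rng, cfg.v_coding_len)), c0)
        elif feat["kind"] == "J":
            seq = plant(seq, _random_coding(rng, cfg.j_coding_len), c0)
        rss = None
        if feat["kind"] in ("V", "J"):
            r0, r1 = feat["rss"]
            oriented = feat["rss_seq"]
            seq = plant(seq, oriented if feat["rss_orient"] == "down" else revcomp(oriented), r0)
            rss = RssAnnotation(
                interval=GenomicInterval(contig, r0, r1, "+"),
                spacer_class=feat["spacer"],
                orientation=feat["rss_orient"],
                sequence=oriented,
                bona_fide=True,
            )
        segments.append(
            GeneSegment(
                name=feat["name"],
                kind=feat["kind"],
                coding_interval=GenomicInterval(contig, c0, c1, feat["strand"]),
                rss=rss,
                region=feat.get("region", "other"),
                vk_orientation=feat.get("vk_orientation"),
                transcribed=feat.get("transcribed", False),
                rss_strength_label="unset",
                frame=0,
            )
        )

    sites: list[CrypticSite] = []
    for pos, strand in sorted(cryptic_plan):
        crss = _cryptic_rss_sequence(rng)
        if strand == "-":
            seq = plant(seq, crss, pos)
        else:
            seq = plant(seq, revcomp(crss), pos - len(crss))
        sites.append(CrypticSite(pos, strand))

    jk1_start = next(f["coding"][0] for f in plan if f["name"] == "Jk1")
    regions = [
        ("distal", 0, region_starts["middle"]),
        ("middle", region_starts["middle"], region_starts["proximal"]),
        ("proximal", region_starts["proximal"], region_starts["cer_to_jk"]),
        ("cer_to_jk", region_starts["cer_to_jk"], jk1_start),
    ]

    locus = LocusMap(
        contig=contig,
        length=length,
        segments=segments,
        regions=regions,
        cryptic_sites=sites,
        sequence=seq,
    )
    # strong/weak labels follow the packaged model threshold by construction
    model = train_locus_model(locus)
    for seg in locus.v_segments:
        seg.rss_strength_label = classify_strength(
            score_rss(model, seg.rss.sequence), model.strength_threshold
        )
    return locus


def train_locus_model(locus: LocusMap, pseudocount: float = 1.0) -> RssModel:
    """Train the packaged 12RSS model on the locus's bona fide Vκ RSSs and set
    the strong/weak threshold at the median observed score."""
    seqs = [seg.rss.sequence for seg in locus.v_segments]
    model = train_rss_model(seqs, spacer_class=12, pseudocount=pseudocount)
    scores = np.array([score_rss(model, s) for s in seqs])
    model.strength_threshold = float(np.median(scores))
    return model


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Junction noise: geometric coding-end deletions, P-nucleotides at
    untrimmed ends, geometric untemplated insertions, per-base prey mismatches."""

    bait_deletion_mean: float = 1.0
    prey_deletion_mean: float = 1.0
    p_probability: float = 0.3
    insertion_mean: float = 0.3
    mismatch_rate: float = 0.005
    max_p: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.p_probability <= 1 or not 0 <= self.mismatch_rate <= 1:
            raise ConfigError("probabilities must lie in [0, 1]")
        if min(self.bait_deletion_mean, self.prey_deletion_mean, self.insertion_mean) < 0:
            raise ConfigError("means must be non-negative")


ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_junctions: int = 2_000
    mechanism: str = "diffusion_primary"  # or "scanning_secondary"
    rearrangement: Rearrangement | None = None
    bait_name: str | None = None  # default: Jκ1 (diffusion) / Jκ2 (scanning)
    decay_bp: float = 30_000.0
    cryptic_rate: float = 0.1
    scanning_leg_fraction: float = 0.5
    inversional_capture_penalty: float = 0.2
    impediment_bonus: float = 3.0
    weight_scale_bits: float = 4.0
    base_capture: float = 0.3
    cryptic_capture: float = 0.02
    noise: NoiseModel = field(default_factory=NoiseModel)
    bait_length: int = 30
    prey_length: int = 60

    def __post_init__(self) -> None:
        if self.mechanism not in ("diffusion_primary", "scanning_secondary"):
            raise ConfigError(f"unknown mechanism {self.mechanism!r}")
        for name in ("cryptic_rate", "scanning_leg_fraction", "inversional_capture_penalty"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.decay_bp <= 0 or self.n_junctions < 0:
            raise ConfigError("decay_bp must be positive and n_junctions >= 0")


@dataclass
class SimOutput:
    """A simulated junction library plus full ground truth."""

    library: JunctionLibrary  # truth junctions in reference coordinates
    truth: pd.DataFrame
    physical: LocusMap  # the DNA molecule reads come from (allele or reference)
    reference: LocusMap
    transform: CoordinateTransform | None
    bait: BaitDefinition
    capture_weights: dict[str, float]
    reads: list[tuple[str, str]] | None = None


def make_bait(physical: LocusMap, j_name: str, bait_length: int = 30) -> BaitDefinition:
    """Jκ coding-end bait: the read prefix is the reverse complement of the Jκ
    coding prefix, ending at the coding start (the junction boundary)."""
    j = physical.segment(j_name)
    js = j.coding_interval.start
    seq = revcomp(physical.sequence[js : js + bait_length])
    return BaitDefinition(name=j_name, sequence=seq, junction_boundary=js)


def capture_weights(
    locus: LocusMap, model: RssModel, config: SimulationConfig, scanning: bool
) -> dict[str, float]:
    """Per-Vκ capture weight 2^((score − max)/scale), optionally multiplied by
    the transcription-impediment bonus (linear scanning only)."""
    scores = {seg.name: score_rss(model, seg.rss.sequence) for seg in locus.v_segments}
    smax = max(scores.values())
    weights = {}
    for seg in locus.v_segments:
        w = 2.0 ** ((scores[seg.name] - smax) / config.weight_scale_bits)
        if scanning and seg.transcribed:
            w *= config.impediment_bonus
        weights[seg.name] = w
    return weights


def _first_hit_probs(
    distances: np.ndarray, hazards: np.ndarray, decay: float
) -> np.ndarray:
    """First-capture probabilities of a sequential scan over ordered sites.

    The scan reaches site i with probability exp(−d_i/decay) · Π_{j<i}(1−q_j)
    and captures there with q_i = 1 − exp(−h_i); the result is normalized to
    condition on capture."""
    order = np.argsort(distances)
    q = 1.0 - np.exp(-hazards[order])
    reach = np.exp(-distances[order] / decay) * np.concatenate(
        ([1.0], np.cumprod(1.0 - q)[:-1])
    )
    p = reach * q
    out = np.zeros_like(p)
    out[order] = p
    total = out.sum()
    if total <= 0:
        raise ConfigError("no capturable site has positive probability")
    return out / total


# ---------------------------------------------------------------------------
# mechanisms
# ---------------------------------------------------------------------------

def _truth_frame(rows: list[dict]) -> pd.DataFrame:
    cols = [
        "read_id",
        "kind",
        "mech",
        "prey_name",
        "allele_pos",
        "allele_strand",
        "ref_pos",
        "ref_strand",
        "bait_name",
        "bait_position",
    ]
    return pd.DataFrame(rows, columns=cols)


def _library_from_truth(
    truth: pd.DataFrame, bait_name: str, replicate_id: str
) -> JunctionLibrary:
    records = [
        JunctionRecord(
            read_id=row.read_id,
            bait_name=bait_name,
            bait_position=int(row.bait_position),
            prey_position=int(row.ref_pos),
            prey_strand=row.ref_strand,
            junction_class="bona_fide_coding" if row.kind == "bona_fide" else "cryptic",
            prey_name=row.prey_name,
        )
        for row in truth.itertuples()
    ]
    return JunctionLibrary(bait_name=bait_name, replicate_id=replicate_id, records=records)


def simulate_primary_diffusion(
    locus: LocusMap, config: SimulationConfig, replicate_id: str = "rep1"
) -> SimOutput:
    """Primary Vκ→Jκ1 joining by Cer/Sis-mediated short-range diffusion.

    Bona fide capture is proportional to the RSS-score weight, independent of
    orientation and distance.  Cryptic junctions split between the scanning
    leg (strictly between Cer and Jκ, convergent-only: scanning from the
    primary RC terminates at Sis) and orientation-symmetric diffusional
    capture of Vκ-region cryptic sites.
    """
    if config.mechanism != "diffusion_primary":
        raise ConfigError("config.mechanism must be 'diffusion_primary'")
    rng = np.random.default_rng(config.seed)
    model = train_locus_model(locus)
    weights = capture_weights(locus, model, config, scanning=False)
    bait_name = config.bait_name or "Jk1"
    bait = make_bait(locus, bait_name, config.bait_length)
    jk_cut = locus.segment(bait_name).cut_point

    v_segs = locus.v_segments
    v_probs = np.array([weights[s.name] for s in v_segs])
    v_probs = v_probs / v_probs.sum()

    cer_start = next(start for label, start, _ in locus.regions if label == "cer_to_jk")
    leg_sites = [
        s for s in locus.cryptic_sites if s.strand == "-" and cer_start <= s.position < jk_cut
    ]
    diff_sites = [s for s in locus.cryptic_sites if s.position < cer_start]
    if leg_sites:
        leg_probs = _first_hit_probs(
            np.array([float(jk_cut - s.position) for s in leg_sites]),
            np.full(len(leg_sites), config.cryptic_capture),
            config.decay_bp,
        )

    rows: list[dict] = []
    u_kind = rng.random(config.n_junctions)
    u_leg = rng.random(config.n_junctions)
    for i in range(config.n_junctions):
        rid = f"r{i:06d}"
        if u_kind[i] < config.cryptic_rate and (leg_sites or diff_sites):
            if u_leg[i] < config.scanning_leg_fraction and leg_sites:
                site = leg_sites[rng.choice(len(leg_sites), p=leg_probs)]
                mech = "scanning_leg"
            else:
                site = diff_sites[rng.integers(len(diff_sites))]
                mech = "diffusion_cryptic"
            rows.append(
                dict(
                    read_id=rid,
                    kind="cryptic",
                    mech=mech,
                    prey_name=f"site@{site.position}{site.strand}",
                    allele_pos=site.position,
                    allele_strand=site.strand,
                    ref_pos=site.position,
                    ref_strand=site.strand,
                    bait_name=bait_name,
                    bait_position=bait.junction_boundary,
                )
            )
        else:
            seg = v_segs[rng.choice(len(v_segs), p=v_probs)]
            strand = "-" if seg.vk_orientation == "deletional" else "+"
            rows.append(
                dict(
                    read_id=rid,
                    kind="bona_fide",
                    mech="diffusion",
                    prey_name=seg.name,
                    allele_pos=seg.cut_point,
                    allele_strand=strand,
                    ref_pos=seg.cut_point,
                    ref_strand=strand,
                    bait_name=bait_name,
                    bait_position=bait.junction_boundary,
                )
            )

    truth = _truth_frame(rows)
    return SimOutput(
        library=_library_from_truth(truth, bait_name, replicate_id),
        truth=truth,
        physical=locus,
        reference=locus,
        transform=None,
        bait=bait,
        capture_weights=weights,
    )


def simulate_secondary_scanning(
    locus: LocusMap,
    rearrangement: Rearrangement | None,
    config: SimulationConfig,
    replicate_id: str = "rep1",
) -> SimOutput:
    """Secondary Vκ→Jκ joining by linear RAG scanning from a VκJκ1-based RC.

    The primary rearrangement is applied first; scanning proceeds upstream
    from the RC in allele coordinates as a sequential first-capture process.
    Cryptic captures are convergent-only in the allele frame; inversional
    bona fide Vκs join at ``inversional_capture_penalty`` of their weight.
    Coordinates are emitted in the reference frame via the transform.
    """
    if config.mechanism != "scanning_secondary":
        raise ConfigError("config.mechanism must be 'scanning_secondary'")
    rearrangement = rearrangement or config.rearrangement
    if rearrangement is None:
        raise ConfigError("scanning_secondary requires a primary rearrangement")
    rng = np.random.default_rng(config.seed)
    model = train_locus_model(locus)
    allele, transform = apply_rearrangement(locus, rearrangement)
    weights = capture_weights(allele, model, config, scanning=True)
    bait_name = config.bait_name or "Jk2"
    bait = make_bait(allele, bait_name, config.bait_length)

    # RC sits at the primary coding join
    v0 = locus.segment(rearrangement.v_name)
    j0 = locus.segment(rearrangement.j_name)
    rc_pos = v0.cut_point if v0.vk_orientation == "deletional" else j0.cut_point

    cand: list[dict] = []
    for seg in allele.v_segments:
        cut = seg.cut_point
        if cut >= rc_pos:
            continue
        strand = "-" if seg.vk_orientation == "deletional" else "+"
        w = weights[seg.name]
        if seg.vk_orientation == "inversional":
            w *= config.inversional_capture_penalty
        cand.append(
            dict(kind="bona_fide", name=seg.name, pos=cut, strand=strand,
                 hazard=config.base_capture * w)
        )
    for site in allele.cryptic_sites:
        if site.strand != "-" or site.position >= rc_pos:
            continue  # convergent-only capture during linear scanning
        cand.append(
            dict(kind="cryptic", name=f"site@{site.position}-", pos=site.position,
                 strand="-", hazard=config.cryptic_capture)
        )
    if not cand:
        raise ConfigError("no capturable sites upstream of the RC")

    distances = np.array([float(rc_pos - c["pos"]) for c in cand])
    hazards = np.array([c["hazard"] for c in cand])
    probs = _first_hit_probs(distances, hazards, config.decay_bp)
    picks = rng.choice(len(cand), size=config.n_junctions, p=probs)

    rows: list[dict] = []
    bait_ref_boundary, _ = transform.project_boundary(bait.junction_boundary, "-")
    for i, ci in enumerate(picks):
        c = cand[ci]
        ref_pos, ref_strand = transform.project_boundary(c["pos"], c["strand"])
        rows.append(
            dict(
                read_id=f"r{i:06d}",
                kind=c["kind"],
                mech="scanning",
                prey_name=c["name"],
                allele_pos=c["pos"],
                allele_strand=c["strand"],
                ref_pos=ref_pos,
                ref_strand=ref_strand,
                bait_name=bait_name,
                bait_position=bait_ref_boundary,
            )
        )

    truth = _truth_frame(rows)
    return SimOutput(
        library=_library_from_truth(truth, bait_name, replicate_id),
        truth=truth,
        physical=allele,
        reference=locus,
        transform=transform,
        bait=bait,
        capture_weights=weights,
    )


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

def _geometric(rng: np.random.Generator, mean: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean)) - 1)


def emit_reads(
    sim: SimOutput,
    noise: NoiseModel | None = None,
    seed: int = 0,
    prey_length: int = 60,
) -> SimOutput:
    """Emit reads (bait + insertion + prey) for every truth row and update the
    truth/library with the realized, canonicalized junction annotations.

    Reads are built from the physical (allele) sequence.  P-nucleotides are
    generated only at untrimmed ends; prey mismatches are planted per base.
    Realized truth re-expresses each junction in the caller's canonical
    left-assignment convention (see ``place_junction``), then projects it to
    reference coordinates through the stored transform.
    """
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    A = sim.physical.sequence
    bait_seq = sim.bait.sequence
    Lp = prey_length
    k = 20

    reads: list[tuple[str, str]] = []
    records: list[JunctionRecord] = []
    realized_cols = {c: [] for c in (
        "bait_deletion", "prey_deletion", "insertion", "p_bait", "p_prey",
        "eff_ins", "mut20", "realized_ref_pos", "realized_ref_strand")}

    for row in sim.truth.itertuples():
        p, s = int(row.allele_pos), row.allele_strand
        d_b = min(_geometric(rng, noise.bait_deletion_mean), len(bait_seq) - k)
        d_p = min(_geometric(rng, noise.prey_deletion_mean), 10)
        bait_part = bait_seq[: len(bait_seq) - d_b]

        lp = Lp
        if s == "-":
            start = p - d_p - lp
            if start < 0:
                lp += start
                start = 0
            prey_true = revcomp(A[start : p - d_p])
        else:
            end = min(p + d_p + lp, len(A))
            prey_true = A[p + d_p : end]
            lp = len(prey_true)

        p_bait_seq = ""
        if d_b == 0 and rng.random() < noise.p_probability:
            kk = int(rng.integers(1, noise.max_p + 1))
            p_bait_seq = revcomp(bait_part[-kk:])
        p_prey_seq = ""
        if d_p == 0 and rng.random() < noise.p_probability:
            kk = int(rng.integers(1, noise.max_p + 1))
            p_prey_seq = revcomp(prey_true[:kk])
        n_un = _geometric(rng, noise.insertion_mean)
        untemplated = "".join(rng.choice(list(_BASES), n_un)) if n_un else ""
        insertion = p_bait_seq + untemplated + p_prey_seq

        mutated = list(prey_true)
        mut_mask = rng.random(len(mutated)) < noise.mismatch_rate
        for idx in np.nonzero(mut_mask)[0]:
            mutated[idx] = _MUTATE_TO[mutated[idx]]
        prey_read = "".join(mutated)

        read = bait_part + insertion + prey_read
        reads.append((row.read_id, read))

        # ---- realized truth in the canonical caller convention ----
        Lr = len(read)
        prey_read_start = len(bait_part) + len(insertion)

        def ref_base_at(j: int, _s=s, _p=p, _dp=d_p, _start=prey_read_start) -> str | None:
            # physical-frame base the read index j would align to, gapless
            off = j - _start  # offset within the planted prey alignment
            if _s == "-":
                pos = (_p - _dp - 1) - off
            else:
                pos = (_p + _dp) + off
            if 0 <= pos < len(A):
                base = A[pos]
                return base if _s == "+" else base.translate(_RC_TABLE)
            return None

        # anchor: first 20-mer window from the 3' end inside the prey with no
        # mutation (the caller's seed strategy)
        anchor_end = None
        for a in range(3):
            hi = Lr - a * k
            lo = hi - k
            if lo < prey_read_start:
                break
            w_lo = lo - prey_read_start
            if not mut_mask[w_lo : w_lo + k].any():
                anchor_end = hi
                break
        if anchor_end is None:
            anchor_end = Lr  # caller will likely drop it; keep planted values

        m = 0
        while m < min(Lr, len(bait_seq)) and read[m] == bait_seq[m]:
            m += 1
        real_d_b = len(bait_seq) - m
        j_star, mh = place_junction(read, m, anchor_end - k, ref_base_at)
        real_ins = read[m:j_star]
        off = j_star - prey_read_start
        if s == "-":
            phys_pos = p - d_p - off
        else:
            phys_pos = p + d_p + off
        real_d_p = (p - phys_pos) if s == "-" else (phys_pos - p)

        # mutation count in the first 20 realized-aligned prey bases
        mut20 = 0
        for j in range(j_star, min(j_star + 20, Lr)):
            ref = ref_base_at(j)
            if ref is None or read[j] != ref:
                mut20 += 1

        p_b, p_p = detect_p_nucleotides(
            real_ins,
            bait_seq[:m],
            read[j_star : j_star + 4],
            real_d_b,
            max(real_d_p, 0),
            max_p=4,
        )
        eff = len(real_ins) - p_b - p_p

        if sim.transform is not None:
            ref_pos, ref_strand = sim.transform.project_boundary(phys_pos, s)
        else:
            ref_pos, ref_strand = phys_pos, s

        realized_cols["bait_deletion"].append(real_d_b)
        realized_cols["prey_deletion"].append(real_d_p)
        realized_cols["insertion"].append(real_ins)
        realized_cols["p_bait"].append(p_b)
        realized_cols["p_prey"].append(p_p)
        realized_cols["eff_ins"].append(eff)
        realized_cols["mut20"].append(mut20)
        realized_cols["realized_ref_pos"].append(ref_pos)
        realized_cols["realized_ref_strand"].append(ref_strand)

        records.append(
            JunctionRecord(
                read_id=row.read_id,
                bait_name=row.bait_name,
                bait_position=int(row.bait_position),
                prey_position=int(ref_pos),
                prey_strand=ref_strand,
                insertion_seq=real_ins,
                bait_deletion=real_d_b,
                prey_deletion=real_d_p,
                p_len_bait=p_b,
                p_len_prey=p_p,
                effective_insertion=eff,
                mutations_near_junction=mut20,
                microhomology=mh,
                junction_class="bona_fide_coding" if row.kind == "bona_fide" else "cryptic",
                prey_name=row.prey_name,
                seq=read,
            )
        )

    truth = sim.truth.copy()
    for col, vals in realized_cols.items():
        truth[col] = vals
    library = JunctionLibrary(
        bait_name=sim.library.bait_name,
        replicate_id=sim.library.replicate_id,
        records=records,
    )
    return SimOutput(
        library=library,
        truth=truth,
        physical=sim.physical,
        reference=sim.reference,
        transform=sim.transform,
        bait=sim.bait,
        capture_weights=sim.capture_weights,
        reads=reads,
    )


_RC_TABLE = str.maketrans("ACGT", "TGCA")


def reads_to_fasta(reads: list[tuple[str, str]]) -> str:
    return "".join(f">{rid}\n{seq}\n" for rid, seq in reads)
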