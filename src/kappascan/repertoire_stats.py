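"""Repertoire quantification and replicate statistics.

Covers the quantities the junction assays report: per-Vκ usage percentages
(mean ± s.e.m. over biological replicates), pooled off-target junction
profiles split by reference strand, region × orientation summaries of cryptic
junctions, the convergent-orientation fraction that discriminates linear
scanning from diffusional joining, productivity calls of Vκ→Jκ coding joins,
library normalization to a fixed read total, and Welch's t-test for replicate
comparisons.

Strand ↔ orientation convention (fixed by the locus model): junctions mapping
to the reference ``-`` strand are deletional-orientation, ``+`` strand
inversional-orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, NormalizationError
from .junction_io import JunctionLibrary, JunctionRecord
from .locus_model import (
    CoordinateTransform,
    LocusMap,
    GeneSegment,
    region_of,
    revcomp,
)
from .errors import TransformError

STRAND_TO_ORIENTATION = {"-": "deletional", "+": "inversional"}


@dataclass(frozen=True)
class NormalizationPolicy:
    """Scale per-record weights so the weighted library total is fixed."""

    target_total: float = 500_000.0

    def __post_init__(self) -> None:
        if self.target_total <= 0:
            raise ConfigError("target_total must be positive")


def normalize_library(
    library: JunctionLibrary, policy: NormalizationPolicy = NormalizationPolicy()
) -> JunctionLibrary:
    """Weight every record by target_total / raw_total.

    The weighted total equals the target exactly and relative proportions are
    unchanged.  Applied at most once per library.
    """
    if library.normalized:
        raise NormalizationError("library already normalized")
    if not library.raw_total:
        raise NormalizationError("library has zero raw read total")
    w = policy.target_total / library.raw_total
    records = [replace(r, extras=dict(r.extras), weight=r.weight * w) for r in library.records]
    out = library.with_records(records)
    out.normalized = True
    return out


# ---------------------------------------------------------------------------
# Vκ usage
# ---------------------------------------------------------------------------

def vk_usage_table(
    libraries: list[JunctionLibrary],
    locus: LocusMap,
    include_unused: bool = True,
) -> pd.DataFrame:
    """Per-Vκ usage across replicates from bona fide coding junctions.

    Percent per Vκ = 100 × (Vκ-assigned count / total Vκ-joined count) within
    each replicate, then mean ± s.e.m. (sample s.d. / sqrt(n)) across
    replicates.  Junctions must already carry a ``prey_name`` assignment and
    class ``bona_fide_coding``.
    """
    if not libraries:
        raise ValueError("need at least one replicate library")
    v_names = [seg.name for seg in locus.v_segments]
    per_rep = {}
    for lib in libraries:
        counts = {name: 0.0 for name in v_names}
        for rec in lib.records:
            if rec.junction_class == "bona_fide_coding" and rec.prey_name in counts:
                counts[rec.prey_name] += rec.weight
        total = sum(counts.values())
        per_rep[lib.replicate_id] = {
            name: (100.0 * c / total if total else float("nan")) for name, c in counts.items()
        }
    df = pd.DataFrame(per_rep)  # rows = Vκ, cols = replicates
    out = pd.DataFrame(index=df.index)
    out["mean_percent"] = df.mean(axis=1)
    n = df.shape[1]
    out["sem_percent"] = df.std(axis=1, ddof=1) / math.sqrt(n) if n > 1 else 0.0
    for col in df.columns:
        out[f"percent_{col}"] = df[col]
    out.index.name = "vk"
    if not include_unused:
        out = out[out["mean_percent"] > 0]
    return out.reset_index()


def assign_vk_names(
    library: JunctionLibrary, locus: LocusMap, window: int = 10
) -> JunctionLibrary:
    """Assign ``prey_name``/class for bona fide coding junctions by proximity
    to Vκ RSS coding boundaries (convenience for truth-free libraries)."""
    boundaries = []
    for seg in locus.v_segments:
        strand = "-" if seg.vk_orientation == "deletional" else "+"
        boundaries.append((seg.cut_point, strand, seg.name))
    records = []
    for rec in library.records:
        rec = replace(rec, extras=dict(rec.extras))
        for cut, strand, name in boundaries:
            if rec.prey_strand == strand and abs(rec.prey_position - cut) <= window:
                rec.prey_name = name
                rec.junction_class = "bona_fide_coding"
                break
        records.append(rec)
    return library.with_records(records)


# ---------------------------------------------------------------------------
# pooled off-target profiles and region summaries
# ---------------------------------------------------------------------------

def pooled_offtarget_profile(
    cryptic_library: JunctionLibrary, locus: LocusMap, bin_size: int = 10_000
) -> pd.DataFrame:
    """Strand-split binned percentages of pooled cryptic junctions.

    Bins are half-open ``[start, start + bin_size)``; the two per-strand
    columns are percentages of the cryptic junction total (both strands), so
    all bins over both strands sum to 100.
    """
    if bin_size <= 0:
        raise ConfigError("bin_size must be positive")
    n_bins = (locus.length + bin_size - 1) // bin_size
    plus = np.zeros(n_bins)
    minus = np.zeros(n_bins)
    total = 0.0
    for rec in cryptic_library.records:
        b = min(rec.prey_position, locus.length - 1) // bin_size
        if rec.prey_strand == "+":
            plus[b] += rec.weight
        else:
            minus[b] += rec.weight
        total += rec.weight
    starts = np.arange(n_bins) * bin_size
    return pd.DataFrame(
        {
            "bin_start": starts,
            "bin_end": np.minimum(starts + bin_size, locus.length),
            "percent_plus": 100.0 * plus / total if total else plus,
            "percent_minus": 100.0 * minus / total if total else minus,
        }
    )


def profile_to_bedgraph(profile: pd.DataFrame, contig: str, strand: str) -> str:
    """Export one strand of a pooled profile as bedGraph text."""
    col = "percent_plus" if strand == "+" else "percent_minus"
    lines = [f'track type=bedGraph name="cryptic_{strand}"']
    for _, row in profile.iterrows():
        lines.append(f"{contig}\t{int(row.bin_start)}\t{int(row.bin_end)}\t{row[col]:.6g}")
    return "\n".join(lines) + "\n"


def region_orientation_summary(
    cryptic_library: JunctionLibrary, locus: LocusMap
) -> pd.DataFrame:
    """Count/percent of cryptic junctions per region × orientation.

    Orientation is derived from the prey strand under the fixed convention
    (``-`` deletional, ``+`` inversional).  Percentages are over the cryptic
    junction total and sum to 100.
    """
    labels = [r[0] for r in locus.regions] + ["other"]
    counts = {(lab, o): 0.0 for lab in labels for o in ("deletional", "inversional")}
    total = 0.0
    for rec in cryptic_library.records:
        lab = region_of(rec.prey_position if rec.prey_position < locus.length else locus.length - 1, locus)
        orient = STRAND_TO_ORIENTATION[rec.prey_strand]
        counts[(lab, orient)] += rec.weight
        total += rec.weight
    rows = []
    for (lab, orient), c in counts.items():
        rows.append(
            {
                "region": lab,
                "orientation": orient,
                "count": c,
                "percent": 100.0 * c / total if total else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    df["total_junctions"] = total
    return df


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvergenceResult:
    fraction: float
    n_used: int
    n_excluded: int  # junctions in reference intervals deleted from the allele


def convergent_fraction(
    cryptic_library: JunctionLibrary,
    transform: CoordinateTransform | None = None,
) -> ConvergenceResult:
    """Fraction of cryptic junctions convergent with the bait RSS in allele
    coordinates.

    The bait is a Jκ 23RSS scanning upstream, so convergent junctions are
    those on the allele ``-`` strand.  When a rearrangement transform is
    given, reference-frame junctions are unprojected first; junctions whose
    positions fall in reference intervals deleted from the allele are
    excluded and counted.
    """
    n_conv = 0
    n_used = 0
    n_excluded = 0
    for rec in cryptic_library.records:
        strand = rec.prey_strand
        if transform is not None:
            try:
                _, strand = transform.unproject_boundary(rec.prey_position, rec.prey_strand)
            except TransformError:
                n_excluded += 1
                continue
        n_used += 1
        if strand == "-":
            n_conv += 1
    frac = n_conv / n_used if n_used else float("nan")
    return ConvergenceResult(fraction=frac, n_used=n_used, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# productivity
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _coding_seq(seg: GeneSegment, locus: LocusMap) -> str:
    iv = seg.coding_interval
    raw = locus.sequence[iv.start : iv.end]
    return raw if iv.strand == "+" else revcomp(raw)


def call_productivity(record: JunctionRecord, locus: LocusMap) -> str:
    """Productive iff the join preserves the Jκ reading frame and creates no
    stop codon across the junction-spanning codons.

    Requires a bona fide coding junction with an assigned Vκ ``prey_name``
    whose segment carries a frame annotation; otherwise returns ``n/a``.
    The joined CDS is reconstructed as
    V coding (3'-trimmed by prey deletion) + insertion + J coding (5'-trimmed
    by bait deletion).
    """
    if record.junction_class != "bona_fide_coding" or not record.prey_name:
        return "n/a"
    try:
        v = locus.segment(record.prey_name)
        j = locus.segment(record.bait_name)
    except KeyError:
        return "n/a"
    if v.kind != "V" or j.kind != "J" or locus.sequence is None:
        return "n/a"
    d_prey = max(record.prey_deletion, 0)
    d_bait = max(record.bait_deletion, 0)
    v_seq = _coding_seq(v, locus)
    j_seq = _coding_seq(j, locus)
    if d_prey >= len(v_seq) or d_bait >= len(j_seq):
        return "n/a"
    vpart = v_seq[: len(v_seq) - d_prey]
    jpart = j_seq[d_bait:]
    ins = record.insertion_seq

    # frame: base i of the joined CDS sits at codon position (v.frame + i) % 3
    junction_cp = (v.frame + len(vpart) + len(ins)) % 3
    if junction_cp != (j.frame + d_bait) % 3:
        return "nonproductive"

    joined = vpart + ins + jpart
    # codons overlapping the junction region (last V base .. first J base)
    lo = max(len(vpart) - 1, 0)
    hi = min(len(vpart) + len(ins), len(joined) - 1)
    first_codon_start = (3 - v.frame) % 3
    for cstart in range(first_codon_start, len(joined) - 2, 3):
        if cstart + 2 < lo or cstart > hi:
            continue
        if joined[cstart : cstart + 3] in _STOPS:
            return "nonproductive"
    return "productive"


def productive_fraction(libraries: list[JunctionLibrary]) -> pd.DataFrame:
    """Per-replicate productive fraction plus mean ± s.e.m.

    Fraction = productive / (productive + nonproductive); replicates with no
    classified joins report NaN.
    """
    rows = []
    for lib in libraries:
        n_p = sum(r.weight for r in lib.records if r.productive == "productive")
        n_np = sum(r.weight for r in lib.records if r.productive == "nonproductive")
        frac = n_p / (n_p + n_np) if (n_p + n_np) else float("nan")
        rows.append({"replicate": lib.replicate_id, "fraction": frac})
    df = pd.DataFrame(rows)
    vals = df["fraction"].dropna()
    df.attrs["mean"] = float(vals.mean()) if len(vals) else float("nan")
    df.attrs["sem"] = (
        float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    )
    return df


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Unpaired two-sided Welch's t-test.

    Returns ``(t, df, p)`` with the Welch statistic, Satterthwaite degrees of
    freedom and the two-sided p-value.  Identical samples give t = 0, p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Optional BH adjustment for exploratory batches of Welch tests."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj
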