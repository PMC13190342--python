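"""Mouse Igκ-specific cryptic-RSS usage analysis pipeline.

Off-target (cryptic RSS) junctions are a small signal sitting under two large
backgrounds: joins to bona fide RSSs and misaligned reads.  The pipeline runs
three steps in fixed order:

1. remove junctions at annotated (and blacklisted unannotated) bona fide RSS
   boundaries;
2. filter junctions whose end processing is inconsistent with RAG coding
   joints in mouse pre-B cells — bait deletion > 5 bp, prey deletion > 7 bp,
   or effective (P-element-excluded) insertion > 2 bp.  The defaults derive
   from the empirical indel/insertion distributions of bona fide
   non-productive Vκ→Jκ joins (essentially none exceed the deletion bounds
   and only 1–2% exceed 2 bp of insertion), and `empirical_indel_profile`
   recomputes those distributions so the thresholds can be re-derived;
3. filter junctions with more than 2 mismatches within 20 bp of the
   junction-proximal prey end (misalignment screen).

Mouse pre-B cells lack TdT; the insertion-based filters are meaningless for
human pre-B data (N-regions), so the pipeline refuses ``species="human"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError
from .junction_io import JunctionLibrary, JunctionRecord
from .locus_model import GenomicInterval, LocusMap


@dataclass(frozen=True)
class FilterThresholds:
    """Printed defaults of the indel/insertion and mutation filters."""

    max_bait_deletion: int = 5
    max_prey_deletion: int = 7
    max_effective_insertion: int = 2
    mutation_window: int = 20
    max_mutations: int = 2

    def __post_init__(self) -> None:
        for name in (
            "max_bait_deletion",
            "max_prey_deletion",
            "max_effective_insertion",
            "mutation_window",
            "max_mutations",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "FilterThresholds":
        return cls(**{k: int(v) for k, v in mapping.items()})

    @classmethod
    def from_yaml(cls, text: str) -> "FilterThresholds":
        """Load thresholds from a YAML/JSON mapping (keys as in the fields)."""
        import yaml

        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("threshold config must be a mapping")
        return cls.from_mapping(data)


@dataclass
class BonaFideCatalog:
    """Bona fide RSS boundaries: annotated RSSs plus a blacklist of
    unannotated bona fide sites (file-supplied intervals)."""

    boundaries: list[tuple[int, str]]  # (junction boundary, expected prey strand)
    blacklist: list[GenomicInterval] = field(default_factory=list)

    @classmethod
    def from_locus(
        cls, locus: LocusMap, blacklist: list[GenomicInterval] | None = None
    ) -> "BonaFideCatalog":
        boundaries: list[tuple[int, str]] = []
        for seg in locus.segments:
            if seg.rss is None or not seg.rss.bona_fide:
                continue
            cut = seg.rss.coding_boundary
            coding_strand = "-" if seg.rss.orientation == "down" else "+"
            boundaries.append((cut, coding_strand))  # coding-side junctions
            boundaries.append((cut, "+" if coding_strand == "-" else "-"))  # signal side
        return cls(boundaries=boundaries, blacklist=list(blacklist or []))

    def is_bona_fide(self, record: JunctionRecord, proximity_window: int) -> bool:
        pos, strand = record.prey_position, record.prey_strand
        for boundary, s in self.boundaries:
            if s == strand and abs(pos - boundary) <= proximity_window:
                return True
        for iv in self.blacklist:
            if iv.strand == strand and iv.start - proximity_window <= pos <= iv.end + proximity_window:
                return True
        return False


def blacklist_from_bed(text: str, contig: str = "locus") -> list[GenomicInterval]:
    """Parse a supplementary blacklist of unannotated bona fide RSS intervals."""
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        cols = line.split("\t")
        strand = cols[5] if len(cols) > 5 else "+"
        out.append(GenomicInterval(contig, int(cols[1]), int(cols[2]), strand))
    return out


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------

def remove_bona_fide(
    library: JunctionLibrary, catalog: BonaFideCatalog, proximity_window: int = 10
) -> tuple[JunctionLibrary, JunctionLibrary]:
    """Partition a junction-called library into (cryptic, bona fide).

    A junction is bona fide iff its prey position falls within
    ``proximity_window`` of a catalog boundary on the matching strand; the
    partition is exhaustive and disjoint.
    """
    cryptic: list[JunctionRecord] = []
    bona: list[JunctionRecord] = []
    for rec in library.records:
        (bona if catalog.is_bona_fide(rec, proximity_window) else cryptic).append(rec)
    return library.with_records(cryptic), library.with_records(bona)


def filter_indels(
    cryptic_library: JunctionLibrary, t: FilterThresholds = FilterThresholds()
) -> JunctionLibrary:
    """Keep junctions with bait deletion <= 5, prey deletion <= 7 and
    effective insertion <= 2 bp (defaults; boundary values are retained)."""
    kept = [
        r
        for r in cryptic_library.records
        if r.bait_deletion <= t.max_bait_deletion
        and r.prey_deletion <= t.max_prey_deletion
        and r.effective_insertion <= t.max_effective_insertion
    ]
    return cryptic_library.with_records(kept)


def filter_mutations(
    cryptic_library: JunctionLibrary, t: FilterThresholds = FilterThresholds()
) -> JunctionLibrary:
    """Keep junctions with at most 2 mismatches within the 20 bp prey window."""
    kept = [
        r
        for r in cryptic_library.records
        if r.mutations_near_junction <= t.max_mutations
    ]
    return cryptic_library.with_records(kept)


@dataclass
class PipelineAudit:
    """Per-step removal counts; conserves the input record count exactly."""

    input_count: int
    removed_bona_fide: int
    removed_indels: int
    removed_mutations: int
    retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": ["input", "bona_fide_removal", "indel_filter", "mutation_filter", "retained"],
                "count": [
                    self.input_count,
                    self.removed_bona_fide,
                    self.removed_indels,
                    self.removed_mutations,
                    self.retained,
                ],
            }
        )

    def check_conservation(self) -> bool:
        return (
            self.input_count
            == self.removed_bona_fide + self.removed_indels + self.removed_mutations + self.retained
        )


def run_cryptic_pipeline(
    library: JunctionLibrary,
    catalog: BonaFideCatalog,
    thresholds: FilterThresholds = FilterThresholds(),
    proximity_window: int = 10,
    species: str = "mouse",
) -> tuple[JunctionLibrary, PipelineAudit]:
    """Run the three pipeline steps in printed order and audit the counts."""
    if species.lower() != "mouse":
        raise ConfigError(
            "this cryptic RSS pipeline is mouse Igκ-specific; human pre-B cells "
            "express TdT and add N-regions, invalidating the insertion filters"
        )
    n0 = len(library.records)
    cryptic, bona = remove_bona_fide(library, catalog, proximity_window)
    after_indels = filter_indels(cryptic, thresholds)
    after_mut = filter_mutations(after_indels, thresholds)
    audit = PipelineAudit(
        input_count=n0,
        removed_bona_fide=len(bona.records),
        removed_indels=len(cryptic.records) - len(after_indels.records),
        removed_mutations=len(after_indels.records) - len(after_mut.records),
        retained=len(after_mut.records),
    )
    return after_mut, audit


def empirical_indel_profile(records: list[JunctionRecord]) -> pd.DataFrame:
    """Empirical indel/insertion distributions over bona fide (non-productive)
    coding junctions, for re-deriving the filter thresholds.

    Returns one row per quantity with the fraction of junctions exceeding the
    packaged default threshold.
    """
    if not records:
        return pd.DataFrame(
            columns=["quantity", "mean", "p95", "max", "fraction_over_default"]
        )
    df = pd.DataFrame(
        {
            "bait_deletion": [r.bait_deletion for r in records],
            "prey_deletion": [r.prey_deletion for r in records],
            "effective_insertion": [r.effective_insertion for r in records],
        }
    )
    defaults = {"bait_deletion": 5, "prey_deletion": 7, "effective_insertion": 2}
    rows = []
    for col, cutoff in defaults.items():
        rows.append(
            {
                "quantity": col,
                "mean": df[col].mean(),
                "p95": df[col].quantile(0.95),
                "max": df[col].max(),
                "fraction_over_default": (df[col] > cutoff).mean(),
            }
        )
    return pd.DataFrame(rows)
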