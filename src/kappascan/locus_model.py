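"""Locus representation and the coordinate algebra of V(D)J rearrangements.

The mouse Igκ locus holds >100 Vκ gene segments (each flanked by a 12RSS) in
deletional or inversional orientation upstream of four functional Jκ segments
(Jκ1, Jκ2, Jκ4, Jκ5; each with an upstream-facing 23RSS), separated by the
Cer/Sis CTCF-binding-element pair.  A primary Vκ→Jκ1 join rewrites the locus:
a deletional join excises the interval between the two RSS heptamers while an
inversional join reverse-complements it in place.  This module represents the
locus (real or miniature), loads/writes its annotation, and implements the
piecewise orientation-signed coordinate transform between the rearranged
allele and the reference, which is what lets junction strand patterns observed
in reference coordinates be interpreted mechanistically.

Conventions
-----------
* All coordinates are 0-based, half-open.  BED input is native; GFF3 is
  converted on read.
* Reference ``+`` strand is the strand on which the Jκ coding segments read
  left to right.  With a Jκ coding-end bait on the unrearranged reference,
  junctions to deletional-orientation partners map to the ``-`` strand and
  junctions to inversional-orientation partners to the ``+`` strand.
* RSS ``orientation`` is ``"down"`` (heptamer at the *left* end of the RSS
  interval, pointing toward higher coordinates — a deletional Vκ 12RSS) or
  ``"up"`` (heptamer at the *right* end, pointing toward lower coordinates —
  a Jκ 23RSS or an inversional Vκ 12RSS).
* Recombination breakpoints sit at the heptamer–coding boundary; the signal
  side of a deletional join is discarded from the allele map.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace


from .errors import AnnotationError, TransformError

FUNCTIONAL_JK = ("Jk1", "Jk2", "Jk4", "Jk5")
REGION_LABELS = ("distal", "middle", "proximal", "cer_to_jk")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on one strand of a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RssAnnotation:
    """A recombination signal sequence: heptamer + 12/23 spacer + nonamer.

    ``interval`` spans the full RSS.  ``orientation`` fixes which end the
    heptamer occupies (see module docstring).  ``sequence`` is the RSS read
    heptamer-first (i.e. already oriented).
    """

    interval: GenomicInterval
    spacer_class: int
    orientation: str  # "down" | "up"
    sequence: str = ""
    bona_fide: bool = True

    def __post_init__(self) -> None:
        if self.spacer_class not in (12, 23):
            raise AnnotationError(f"spacer_class must be 12 or 23, got {self.spacer_class}")
        if self.orientation not in ("down", "up"):
            raise AnnotationError(f"RSS orientation must be 'down' or 'up'")
        expected = 7 + self.spacer_class + 9
        if len(self.interval) != expected:
            raise AnnotationError(
                f"{self.spacer_class}RSS interval length {len(self.interval)} != {expected}"
            )
        if self.sequence and len(self.sequence) != expected:
            raise AnnotationError("RSS sequence length does not match spacer class")

    @property
    def heptamer_interval(self) -> GenomicInterval:
        iv = self.interval
        if self.orientation == "down":
            return GenomicInterval(iv.contig, iv.start, iv.start + 7, iv.strand)
        return GenomicInterval(iv.contig, iv.end - 7, iv.end, iv.strand)

    @property
    def nonamer_interval(self) -> GenomicInterval:
        iv = self.interval
        if self.orientation == "down":
            return GenomicInterval(iv.contig, iv.end - 9, iv.end, iv.strand)
        return GenomicInterval(iv.contig, iv.start, iv.start + 9, iv.strand)

    @property
    def coding_boundary(self) -> int:
        """Heptamer–coding boundary: the RAG cleavage point on this RSS."""
        return self.interval.start if self.orientation == "down" else self.interval.end

    def oriented_sequence(self, contig_seq: str) -> str:
        """RSS sequence read heptamer → nonamer, regardless of orientation."""
        raw = contig_seq[self.interval.start : self.interval.end]
        return raw if self.orientation == "down" else revcomp(raw)


@dataclass(frozen=True)
class CrypticSite:
    """A planted/annotated cryptic RSS usable by RAG off-target activity.

    ``position`` is the junction boundary at the heptamer–"surrogate coding"
    edge; ``strand`` is the reference strand a Jκ-bait junction at this site
    maps to (``-`` = deletional-appearing/convergent on the unrearranged
    reference, ``+`` = inversional-appearing).
    """

    position: int
    strand: str
    score: float = 0.0


@dataclass
class GeneSegment:
    """A Vκ, Jκ or landmark element of the locus."""

    name: str
    kind: str  # "V" | "J" | "landmark"
    coding_interval: GenomicInterval
    rss: RssAnnotation | None = None
    region: str = "other"
    vk_orientation: str | None = None  # "deletional" | "inversional" | None
    transcribed: bool = False
    rss_strength_label: str = "unset"  # "strong" | "weak" | "unset"
    frame: int = 0  # codon offset of the first coding base

    def __post_init__(self) -> None:
        if self.kind not in ("V", "J", "landmark"):
            raise AnnotationError(f"unknown segment kind {self.kind!r}")
        if self.kind == "V":
            if self.rss is None or self.rss.spacer_class != 12:
                raise AnnotationError(f"V segment {self.name} must carry a 12RSS")
            if self.vk_orientation not in ("deletional", "inversional"):
                raise AnnotationError(
                    f"V segment {self.name} needs vk_orientation deletional/inversional"
                )
        if self.kind == "J":
            if self.rss is None or self.rss.spacer_class != 23:
                raise AnnotationError(f"J segment {self.name} must carry a 23RSS")

    @property
    def cut_point(self) -> int:
        """RAG cleavage point: the heptamer–coding boundary of the RSS."""
        if self.rss is None:
            raise AnnotationError(f"segment {self.name} has no RSS")
        return self.rss.coding_boundary

    @property
    def span(self) -> tuple[int, int]:
        """Footprint of coding + RSS, as (start, end)."""
        s, e = self.coding_interval.start, self.coding_interval.end
        if self.rss is not None:
            s = min(s, self.rss.interval.start)
            e = max(e, self.rss.interval.end)
        return s, e


@dataclass
class LocusMap:
    """Ordered annotation of a single-contig (mini or real) Igκ locus."""

    contig: str
    length: int
    segments: list[GeneSegment]
    regions: list[tuple[str, int, int]] = field(default_factory=list)
    cryptic_sites: list[CrypticSite] = field(default_factory=list)
    sequence: str | None = None
    is_allele: bool = False

    def __post_init__(self) -> None:
        self.segments.sort(key=lambda s: s.span[0])
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        prev_end = -1
        for seg in self.segments:
            s, e = seg.span
            if s < 0 or e > self.length:
                raise AnnotationError(f"segment {seg.name} outside contig")
            if s < prev_end:
                raise AnnotationError(f"segment {seg.name} overlaps its predecessor")
            prev_end = e
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AnnotationError("sequence length does not match contig length")
        if not self.is_allele:
            j_names = [s.name for s in self.segments if s.kind == "J"]
            if sorted(j_names) != sorted(FUNCTIONAL_JK):
                raise AnnotationError(
                    f"expected exactly the functional Jκs {FUNCTIONAL_JK}, got {j_names}"
                )
            cer, sis = self.landmark("Cer"), self.landmark("Sis")
            jk1 = self.segment("Jk1")
            if not (
                cer.coding_interval.end <= sis.coding_interval.start
                and sis.coding_interval.end <= jk1.coding_interval.start
            ):
                raise AnnotationError("expected order Cer < Sis < Jk1 along the contig")

    # -- lookups ------------------------------------------------------------

    def segment(self, name: str) -> GeneSegment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(f"no segment named {name!r}")

    def landmark(self, name: str) -> GeneSegment:
        seg = self.segment(name)
        if seg.kind != "landmark":
            raise AnnotationError(f"{name} is not a landmark")
        return seg

    @property
    def v_segments(self) -> list[GeneSegment]:
        return [s for s in self.segments if s.kind == "V"]

    @property
    def j_segments(self) -> list[GeneSegment]:
        return [s for s in self.segments if s.kind == "J"]


def region_of(position: int, locus: LocusMap) -> str:
    """Region label of a reference position.

    Regions are half-open; a boundary position belongs to the region starting
    there (equivalently, it leaves the upstream region, whose interval is
    half-open at its right edge).  Positions covered by no named region map to
    ``"other"``.
    """
    if not 0 <= position < locus.length:
        raise ValueError(f"position {position} outside contig of length {locus.length}")
    for label, start, end in locus.regions:
        if start <= position < end:
            return label
    return "other"


# ---------------------------------------------------------------------------
# rearrangement + coordinate transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rearrangement:
    """A primary Vκ→Jκ join.  join_type is derived from the Vκ orientation:
    deletional iff the Vκ 12RSS faces the Jκ 23RSS across the interval."""

    v_name: str
    j_name: str


@dataclass(frozen=True)
class TransformBlock:
    allele_start: int
    allele_end: int
    ref_start: int
    ref_end: int
    sign: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.allele_end - self.allele_start != self.ref_end - self.ref_start:
            raise TransformError("block lengths differ between allele and reference")
        if self.sign not in (1, -1):
            raise TransformError("block sign must be +1 or -1")


@dataclass
class CoordinateTransform:
    """Piecewise orientation-signed map allele → reference coordinates."""

    blocks: list[TransformBlock]

    def __post_init__(self) -> None:
        pos = 0
        for b in self.blocks:
            if b.allele_start != pos:
                raise TransformError("allele blocks must tile the allele contig")
            pos = b.allele_end

    @property
    def allele_length(self) -> int:
        return self.blocks[-1].allele_end if self.blocks else 0

    # -- base-position maps --------------------------------------------------

    def project(self, position: int, strand: str = "+") -> tuple[int, str]:
        """Allele base position (+ strand label) → reference base position."""
        for b in self.blocks:
            if b.allele_start <= position < b.allele_end:
                off = position - b.allele_start
                if b.sign == 1:
                    return b.ref_start + off, strand
                return b.ref_end - 1 - off, _flip(strand)
        raise TransformError(f"allele position {position} outside transform")

    def unproject(self, position: int, strand: str = "+") -> tuple[int, str]:
        """Reference base position → allele; raises if the base was deleted."""
        for b in self.blocks:
            if b.ref_start <= position < b.ref_end:
                if b.sign == 1:
                    return b.allele_start + (position - b.ref_start), strand
                return b.allele_start + (b.ref_end - 1 - position), _flip(strand)
        raise TransformError(f"reference position {position} has no allele preimage")

    # -- boundary maps (between-base coordinates, used for junction points) --

    def project_boundary(self, boundary: int, strand: str) -> tuple[int, str]:
        for b in self.blocks:
            if b.allele_start <= boundary <= b.allele_end:
                if b.sign == 1:
                    return b.ref_start + (boundary - b.allele_start), strand
                return b.ref_start + (b.allele_end - boundary), _flip(strand)
        raise TransformError(f"allele boundary {boundary} outside transform")

    def unproject_boundary(self, boundary: int, strand: str) -> tuple[int, str]:
        for b in self.blocks:
            if b.ref_start <= boundary <= b.ref_end:
                if b.sign == 1:
                    return b.allele_start + (boundary - b.ref_start), strand
                return b.allele_start + (b.ref_end - boundary), _flip(strand)
        raise TransformError(f"reference boundary {boundary} has no allele preimage")

    # -- sequence + serialization -------------------------------------------

    def materialize(self, reference_sequence: str) -> str:
        """Build the allele sequence from the reference through the blocks."""
        parts = []
        for b in self.blocks:
            chunk = reference_sequence[b.ref_start : b.ref_end]
            parts.append(chunk if b.sign == 1 else revcomp(chunk))
        return "".join(parts)

    def to_tsv(self) -> str:
        lines = ["allele_start\tallele_end\tref_start\tref_end\tsign"]
        for b in self.blocks:
            lines.append(
                f"{b.allele_start}\t{b.allele_end}\t{b.ref_start}\t{b.ref_end}\t{b.sign:+d}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "CoordinateTransform":
        rows = text.strip().splitlines()[1:]
        blocks = [TransformBlock(*(int(x) for x in row.split("\t"))) for row in rows]
        return cls(blocks)

    @classmethod
    def identity(cls, length: int) -> "CoordinateTransform":
        return cls([TransformBlock(0, length, 0, length, 1)])


def _map_interval(
    iv: GenomicInterval, t: CoordinateTransform, contig: str
) -> GenomicInterval | None:
    """Map a reference interval into allele coordinates if it lies entirely
    within one block of the *inverse* transform; otherwise None."""
    for b in t.blocks:
        if b.ref_start <= iv.start and iv.end <= b.ref_end:
            if b.sign == 1:
                s = b.allele_start + (iv.start - b.ref_start)
                return GenomicInterval(contig, s, s + len(iv), iv.strand)
            s = b.allele_start + (b.ref_end - iv.end)
            return GenomicInterval(contig, s, s + len(iv), _flip(iv.strand))
    return None


_FLIP_ORIENT = {"down": "up", "up": "down"}
_FLIP_VK = {"deletional": "inversional", "inversional": "deletional"}


def apply_rearrangement(
    locus: LocusMap, r: Rearrangement
) -> tuple[LocusMap, CoordinateTransform]:
    """Apply a primary Vκ→Jκ join, returning the allele map and the transform.

    Deletional joins remove the interval between the Vκ 12RSS heptamer and
    the Jκ 23RSS heptamer (the signal side, Cer/Sis included when within it);
    inversional joins reverse-complement that interval in place, flipping the
    orientation of every segment inside it.
    """
    v = locus.segment(r.v_name)
    j = locus.segment(r.j_name)
    if v.kind != "V":
        raise KeyError(f"{r.v_name} is not a V segment")
    if j.kind != "J":
        raise KeyError(f"{r.j_name} is not a functional J segment")
    cut_v = v.cut_point
    cut_j = j.cut_point
    if cut_v > cut_j:
        raise AnnotationError("V segment must lie upstream of the J segment")
    join_type = "deletional" if v.vk_orientation == "deletional" else "inversional"

    L = locus.length
    allele_contig = f"{locus.contig}|{r.v_name}-{r.j_name}"
    if join_type == "deletional":
        blocks = [TransformBlock(0, cut_v, 0, cut_v, 1)]
        if cut_j < L:
            blocks.append(TransformBlock(cut_v, cut_v + (L - cut_j), cut_j, L, 1))
    else:
        blocks = []
        if cut_v > 0:
            blocks.append(TransformBlock(0, cut_v, 0, cut_v, 1))
        blocks.append(TransformBlock(cut_v, cut_j, cut_v, cut_j, -1))
        if cut_j < L:
            blocks.append(TransformBlock(cut_j, L, cut_j, L, 1))
    transform = CoordinateTransform(blocks)

    new_segments: list[GeneSegment] = []
    for seg in locus.segments:
        new_coding = _map_interval(seg.coding_interval, transform, allele_contig)
        if new_coding is None:
            continue  # deleted, or straddles a breakpoint
        inverted = new_coding.strand != seg.coding_interval.strand
        new_rss = None
        if seg.rss is not None and _same_block(
            seg.coding_interval, seg.rss.interval, transform
        ):
            rss_iv = _map_interval(seg.rss.interval, transform, allele_contig)
            if rss_iv is not None:
                orient = seg.rss.orientation
                if _interval_inverted(seg.rss.interval, transform):
                    orient = _FLIP_ORIENT[orient]
                new_rss = replace(seg.rss, interval=rss_iv, orientation=orient)
        vk_orient = seg.vk_orientation
        if vk_orient is not None and inverted:
            vk_orient = _FLIP_VK[vk_orient]
        kind = seg.kind
        if new_rss is None and kind in ("V", "J"):
            # the joined segment loses its RSS to the signal side
            kind = "landmark"
            vk_orient = None
        new_segments.append(
            GeneSegment(
                name=seg.name,
                kind=kind,
                coding_interval=new_coding,
                rss=new_rss,
                region=seg.region,
                vk_orientation=vk_orient,
                transcribed=seg.transcribed,
                rss_strength_label=seg.rss_strength_label,
                frame=seg.frame,
            )
        )

    new_regions: list[tuple[str, int, int]] = []
    for label, start, end in locus.regions:
        for b in transform.blocks:
            lo, hi = max(start, b.ref_start), min(end, b.ref_end)
            if lo >= hi:
                continue
            if b.sign == 1:
                a_lo = b.allele_start + (lo - b.ref_start)
                new_regions.append((label, a_lo, a_lo + (hi - lo)))
            else:
                a_lo = b.allele_start + (b.ref_end - hi)
                new_regions.append((label, a_lo, a_lo + (hi - lo)))
    new_regions.sort(key=lambda t3: t3[1])

    new_sites: list[CrypticSite] = []
    for site in locus.cryptic_sites:
        try:
            pos, strand = transform.unproject_boundary(site.position, site.strand)
        except TransformError:
            continue
        new_sites.append(CrypticSite(pos, strand, site.score))
    new_sites.sort(key=lambda s: s.position)

    allele = LocusMap(
        contig=allele_contig,
        length=transform.allele_length,
        segments=new_segments,
        regions=new_regions,
        cryptic_sites=new_sites,
        sequence=transform.materialize(locus.sequence) if locus.sequence else None,
        is_allele=True,
    )
    return allele, transform


def _interval_inverted(iv: GenomicInterval, t: CoordinateTransform) -> bool:
    for b in t.blocks:
        if b.ref_start <= iv.start and iv.end <= b.ref_end:
            return b.sign == -1
    return False


def _block_index(iv: GenomicInterval, t: CoordinateTransform) -> int | None:
    for i, b in enumerate(t.blocks):
        if b.ref_start <= iv.start and iv.end <= b.ref_end:
            return i
    return None


def _same_block(a: GenomicInterval, b: GenomicInterval, t: CoordinateTransform) -> bool:
    """True iff both intervals map within one and the same transform block, so
    their adjacency (e.g. RSS next to its coding segment) is preserved."""
    ia, ib = _block_index(a, t), _block_index(b, t)
    return ia is not None and ia == ib


def project_to_reference(
    position: int, strand: str, t: CoordinateTransform
) -> tuple[int, str]:
    """Project an allele base position + strand to reference coordinates."""
    return t.project(position, strand)


# ---------------------------------------------------------------------------
# annotation I/O (BED native; GFF3 converted on read)
# ---------------------------------------------------------------------------

def _parse_attrs(text: str, sep: str = ";") -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().strip(sep).split(sep):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _read_lines(source) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    text = str(source)
    if "\n" in text or "\t" in text:
        return text.splitlines()
    with open(text) as fh:
        return fh.read().splitlines()


def _read_fasta(source) -> tuple[str, str]:
    from Bio import SeqIO

    if hasattr(source, "read"):
        handle = source
    else:
        text = str(source)
        if text.lstrip().startswith(">"):
            handle = io.StringIO(text)
        else:
            handle = open(text)
    records = list(SeqIO.parse(handle, "fasta"))
    if len(records) != 1:
        raise AnnotationError(f"expected a single-contig FASTA, got {len(records)} records")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def load_locus(annotation_source, fasta_source) -> LocusMap:
    """Load a LocusMap from a BED-like or GFF3 annotation plus a FASTA.

    BED dialect: ``contig start end name score strand attrs`` with ``attrs``
    a ``key=value;...`` string.  Rows carry ``kind`` ∈ {V, J, landmark, rss,
    region, cryptic}; ``rss`` rows name their ``parent`` segment and carry
    ``spacer_class``, ``orientation`` (down/up) and ``bona_fide``.  GFF3 rows
    use the feature-type column for ``kind`` and column 9 for attributes.
    """
    contig_name, sequence = _read_fasta(fasta_source)
    lines = _read_lines(annotation_source)

    seg_rows: dict[str, dict] = {}
    rss_rows: list[dict] = []
    regions: list[tuple[str, int, int]] = []
    sites: list[CrypticSite] = []
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) == 9 and cols[3].lstrip("-").isdigit() and cols[4].lstrip("-").isdigit():
            # GFF3: seqid source type start end score strand frame attrs
            kind = cols[2]
            start, end = int(cols[3]) - 1, int(cols[4])
            strand = cols[6] if cols[6] in "+-" else "+"
            attrs = _parse_attrs(cols[8])
            name = attrs.get("ID", attrs.get("Name", f"feature{lineno}"))
        elif len(cols) >= 7:
            # BED6 + attrs
            start, end = int(cols[1]), int(cols[2])
            name, strand = cols[3], cols[5]
            attrs = _parse_attrs(cols[6])
            kind = attrs.get("kind", "landmark")
        else:
            raise AnnotationError(f"line {lineno}: expected BED6+attrs or GFF3 row")
        attrs.setdefault("kind", kind)
        row = dict(name=name, start=start, end=end, strand=strand, **attrs)
        kind = row["kind"]
        if kind == "rss":
            rss_rows.append(row)
        elif kind == "region":
            regions.append((name, start, end))
        elif kind == "cryptic":
            sites.append(CrypticSite(start, strand))
        elif kind in ("V", "J", "landmark"):
            seg_rows[name] = row
        else:
            raise AnnotationError(f"line {lineno}: unknown kind {kind!r}")

    rss_by_parent: dict[str, RssAnnotation] = {}
    for row in rss_rows:
        parent = row.get("parent")
        if parent is None:
            raise AnnotationError(f"rss feature {row['name']} lacks a parent attribute")
        iv = GenomicInterval(contig_name, row["start"], row["end"], row["strand"])
        rss = RssAnnotation(
            interval=iv,
            spacer_class=int(row["spacer_class"]),
            orientation=row["orientation"],
            bona_fide=row.get("bona_fide", "1") not in ("0", "false", "False"),
        )
        rss = replace(rss, sequence=rss.oriented_sequence(sequence))
        rss_by_parent[parent] = rss

    segments: list[GeneSegment] = []
    for name, row in seg_rows.items():
        kind = row["kind"]
        rss = rss_by_parent.get(name)
        if kind in ("V", "J") and rss is None:
            raise AnnotationError(f"segment {name} has no RSS feature")
        segments.append(
            GeneSegment(
                name=name,
                kind=kind,
                coding_interval=GenomicInterval(
                    contig_name, row["start"], row["end"], row["strand"]
                ),
                rss=rss,
                region=row.get("region", "other"),
                vk_orientation=row.get("vk_orientation"),
                transcribed=row.get("transcribed", "0") in ("1", "true", "True"),
                rss_strength_label=row.get("strength", "unset"),
                frame=int(row.get("frame", 0)),
            )
        )

    return LocusMap(
        contig=contig_name,
        length=len(sequence),
        segments=segments,
        regions=regions,
        cryptic_sites=sorted(sites, key=lambda s: s.position),
        sequence=sequence,
    )


def locus_to_bed(locus: LocusMap) -> str:
    """Serialize a LocusMap to the package's BED6+attrs dialect."""
    rows: list[str] = []

    def bed_row(start, end, name, strand, attrs: dict) -> str:
        attr_text = ";".join(f"{k}={v}" for k, v in attrs.items())
        return f"{locus.contig}\t{start}\t{end}\t{name}\t0\t{strand}\t{attr_text}"

    for seg in locus.segments:
        attrs = {"kind": seg.kind, "region": seg.region}
        if seg.vk_orientation:
            attrs["vk_orientation"] = seg.vk_orientation
        if seg.transcribed:
            attrs["transcribed"] = "1"
        if seg.rss_strength_label != "unset":
            attrs["strength"] = seg.rss_strength_label
        if seg.frame:
            attrs["frame"] = str(seg.frame)
        iv = seg.coding_interval
        rows.append(bed_row(iv.start, iv.end, seg.name, iv.strand, attrs))
        if seg.rss is not None:
            rss = seg.rss
            rows.append(
                bed_row(
                    rss.interval.start,
                    rss.interval.end,
                    f"{seg.name}.rss",
                    rss.interval.strand,
                    {
                        "kind": "rss",
                        "parent": seg.name,
                        "spacer_class": str(rss.spacer_class),
                        "orientation": rss.orientation,
                        "bona_fide": "1" if rss.bona_fide else "0",
                    },
                )
            )
    for label, start, end in locus.regions:
        rows.append(bed_row(start, end, label, "+", {"kind": "region"}))
    for site in locus.cryptic_sites:
        rows.append(
            bed_row(site.position, site.position + 1, "cryptic", site.strand, {"kind": "cryptic"})
        )
    return "\n".join(rows) + "\n"


def locus_to_fasta(locus: LocusMap) -> str:
    if locus.sequence is None:
        raise AnnotationError("locus carries no sequence")
    seq = locus.sequence
    body = "\n".join(seq[i : i + 80] for i in range(0, len(seq), 80))
    return f">{locus.contig}\n{body}\n"
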