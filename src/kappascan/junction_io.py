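"""Junction tables, junction calling and fine-structure annotation.

HTGTS-style assays recover bait→prey junctions: reads begin with a fixed bait
side (here a Jκ coding end read toward the junction) and continue into the
joined prey sequence.  This module reads/writes a TLX-like tab-separated
junction dialect, calls junctions from reads against a locus with a seed-and-
extend toy caller, detects P-nucleotides (palindromic additions templated
from hairpin opening at *untrimmed* coding ends), and annotates near-junction
mismatches used by the misalignment filter.

Junction-point convention: bases explainable by both bait and prey
(microhomology) are assigned to the bait, and the recorded junction position
is the junction-proximal prey boundary (a 0-based between-base coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

from .errors import TlxFormatError
from .locus_model import LocusMap, revcomp

# ---------------------------------------------------------------------------
# records and libraries
# ---------------------------------------------------------------------------

JUNCTION_CLASSES = (
    "bona_fide_coding",
    "bona_fide_rss",
    "cryptic",
    "unmapped",
    "ambiguous",
    "unclassified",
)


@dataclass
class JunctionRecord:
    """One bait→prey junction."""

    read_id: str
    bait_name: str
    bait_position: int
    prey_position: int
    prey_strand: str
    insertion_seq: str = ""
    bait_deletion: int = 0
    prey_deletion: int = 0
    p_len_bait: int = 0
    p_len_prey: int = 0
    effective_insertion: int = 0
    mutations_near_junction: int = 0
    microhomology: int = 0
    junction_class: str = "unclassified"
    productive: str = "n/a"
    prey_name: str = ""
    seq: str = ""
    weight: float = 1.0
    extras: dict = field(default_factory=dict)


@dataclass
class JunctionLibrary:
    """One replicate's worth of junctions from a single bait."""

    bait_name: str
    replicate_id: str
    records: list[JunctionRecord]
    raw_total: int | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.raw_total is None:
            self.raw_total = len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def with_records(self, records: list[JunctionRecord]) -> "JunctionLibrary":
        return JunctionLibrary(
            bait_name=self.bait_name,
            replicate_id=self.replicate_id,
            records=records,
            raw_total=self.raw_total,
            normalized=self.normalized,
        )


# ---------------------------------------------------------------------------
# TLX-like dialect
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("Qname", "Rname", "Junction", "Strand", "B_Rname", "B_Junction", "Seq")
_KNOWN_OPTIONAL = (
    "BaitName",
    "Ins",
    "BaitDel",
    "PreyDel",
    "Pbait",
    "Pprey",
    "EffIns",
    "Mut20",
    "MH",
    "Class",
    "PreyName",
    "Productive",
    "Weight",
)


def write_tlx(library: JunctionLibrary, sink) -> None:
    """Write a library in the TLX-like dialect (lossless for all fields)."""
    own = hasattr(sink, "write") is False
    fh = open(sink, "w") if own else sink
    try:
        extra_cols: list[str] = []
        for rec in library.records:
            for k in rec.extras:
                if k not in extra_cols:
                    extra_cols.append(k)
        fh.write(f"#bait={library.bait_name}\treplicate={library.replicate_id}")
        fh.write(f"\traw_total={library.raw_total}")
        fh.write(f"\tnormalized={int(library.normalized)}\n")
        header = list(REQUIRED_COLUMNS) + list(_KNOWN_OPTIONAL) + extra_cols
        fh.write("\t".join(header) + "\n")
        for rec in library.records:
            row = [
                rec.read_id,
                "locus",
                str(rec.prey_position),
                rec.prey_strand,
                "locus",
                str(rec.bait_position),
                rec.seq,
                rec.bait_name,
                rec.insertion_seq,
                str(rec.bait_deletion),
                str(rec.prey_deletion),
                str(rec.p_len_bait),
                str(rec.p_len_prey),
                str(rec.effective_insertion),
                str(rec.mutations_near_junction),
                str(rec.microhomology),
                rec.junction_class,
                rec.prey_name,
                rec.productive,
                repr(rec.weight),
            ]
            row += [str(rec.extras.get(k, "")) for k in extra_cols]
            fh.write("\t".join(row) + "\n")
    finally:
        if own:
            fh.close()


def read_tlx(source, replicate_id: str | None = None) -> JunctionLibrary:
    """Read a TLX-like junction table.

    Requires the dialect's header columns; unknown columns are preserved
    verbatim in each record's ``extras``.
    """
    own = hasattr(source, "read") is False
    fh = open(source) if own else source
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()

    meta = {"bait": "", "replicate": replicate_id or "rep1", "raw_total": None, "normalized": "0"}
    idx = 0
    while idx < len(lines) and lines[idx].startswith("#"):
        for item in lines[idx].lstrip("#").split("\t"):
            k, _, v = item.partition("=")
            if k in meta or k in ("bait", "replicate", "raw_total", "normalized"):
                meta[k] = v
        idx += 1
    if idx >= len(lines):
        raise TlxFormatError("empty TLX file: missing header row")
    header = lines[idx].split("\t")
    for col in REQUIRED_COLUMNS:
        if col not in header:
            raise TlxFormatError(f"missing required column {col!r}")
    col_index = {c: i for i, c in enumerate(header)}
    known = set(REQUIRED_COLUMNS) | set(_KNOWN_OPTIONAL)
    extra_cols = [c for c in header if c not in known]

    def get(row: list[str], col: str, default: str = "") -> str:
        i = col_index.get(col)
        return row[i] if i is not None and i < len(row) else default

    def get_int(row: list[str], col: str, lineno: int, default: int = 0) -> int:
        raw = get(row, col, "")
        if raw == "":
            return default
        try:
            return int(raw)
        except ValueError:
            raise TlxFormatError(f"line {lineno}: non-numeric value {raw!r} in column {col}")

    records: list[JunctionRecord] = []
    for lineno, line in enumerate(lines[idx + 1 :], idx + 2):
        if not line.strip():
            continue
        row = line.split("\t")
        rec = JunctionRecord(
            read_id=get(row, "Qname"),
            bait_name=get(row, "BaitName") or meta["bait"],
            bait_position=get_int(row, "B_Junction", lineno),
            prey_position=get_int(row, "Junction", lineno),
            prey_strand=get(row, "Strand", "+"),
            insertion_seq=get(row, "Ins"),
            bait_deletion=get_int(row, "BaitDel", lineno),
            prey_deletion=get_int(row, "PreyDel", lineno),
            p_len_bait=get_int(row, "Pbait", lineno),
            p_len_prey=get_int(row, "Pprey", lineno),
            effective_insertion=get_int(row, "EffIns", lineno),
            mutations_near_junction=get_int(row, "Mut20", lineno),
            microhomology=get_int(row, "MH", lineno),
            junction_class=get(row, "Class") or "unclassified",
            prey_name=get(row, "PreyName"),
            productive=get(row, "Productive") or "n/a",
            seq=get(row, "Seq"),
            weight=float(get(row, "Weight") or 1.0),
            extras={k: get(row, k) for k in extra_cols},
        )
        records.append(rec)

    raw_total = int(meta["raw_total"]) if meta["raw_total"] not in (None, "", "None") else None
    return JunctionLibrary(
        bait_name=meta["bait"] or (records[0].bait_name if records else ""),
        replicate_id=meta["replicate"],
        records=records,
        raw_total=raw_total,
        normalized=meta["normalized"] in ("1", "True", "true"),
    )


# ---------------------------------------------------------------------------
# junction calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaitDefinition:
    """The fixed bait side of every read.

    ``sequence`` is the bait as it appears at the start of each read (for a
    Jκ coding-end bait this is the reverse complement of the reference Jκ
    coding prefix), ending exactly at the junction boundary
    ``junction_boundary`` (reference coordinate).
    """

    name: str
    sequence: str
    junction_boundary: int


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def place_junction(
    read: str,
    bait_match: int,
    anchor_j: int,
    ref_base_at: Callable[[int], str | None],
) -> tuple[int, int]:
    """Place the prey start within a read by gapless leftward extension.

    The read suffix starting at ``anchor_j`` is anchored to the reference;
    the prey alignment is extended leftward scoring +1/match, -1/mismatch
    (out-of-contig treated as mismatch), never past ``bait_match``.  The prey
    start is the *leftmost* index achieving the maximal cumulative score, so
    isolated interior mismatches are crossed while junction-adjacent
    mismatched bases fall to the insertion.  Returns ``(prey_start,
    microhomology)`` where microhomology counts reference-matching bases
    immediately left of the prey start that were assigned to the bait.

    This function defines the package's canonical junction-assignment
    convention; the read simulator uses it to express realized truth in the
    same convention the caller reports.
    """
    best_j = anchor_j
    best_score = 0.0
    score = 0.0
    j = anchor_j - 1
    while j >= bait_match:
        ref = ref_base_at(j)
        score += 1.0 if (ref is not None and read[j] == ref) else -1.0
        if score >= best_score:
            best_score = score
            best_j = j
        j -= 1
    mh = 0
    if best_j == bait_match:
        j = bait_match - 1
        while j >= 0:
            ref = ref_base_at(j)
            if ref is None or read[j] != ref:
                break
            mh += 1
            j -= 1
    return best_j, mh


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


_COMP = str.maketrans("ACGT", "TGCA")


def call_junction(
    read_sequence: str,
    bait: BaitDefinition,
    locus: LocusMap,
    k: int = 20,
    seed_index: dict | None = None,
) -> JunctionRecord:
    """Call one junction from a read against the locus.

    The read must begin with (a possibly end-trimmed prefix of) the bait
    sequence; the prey is anchored by an exact k-mer seed taken from the
    read's 3' end, matched on either strand of the locus.  Records whose seed
    does not match are returned with class ``unmapped``; multi-locus seeds
    yield class ``ambiguous`` (both are excluded downstream).
    """
    if locus.sequence is None:
        raise ValueError("locus carries no sequence")
    S = locus.sequence
    read = read_sequence.upper()
    m = _common_prefix_len(read, bait.sequence)
    bait_deletion = len(bait.sequence) - m

    def make(cls: str) -> JunctionRecord:
        return JunctionRecord(
            read_id="",
            bait_name=bait.name,
            bait_position=bait.junction_boundary,
            prey_position=-1,
            prey_strand=".",
            bait_deletion=bait_deletion,
            junction_class=cls,
            seq=read,
        )

    if len(read) < m + k:
        return make("unmapped")
    Lr = len(read)

    # seed from the 3' end; on no exact hit (e.g. a sequencing mismatch in the
    # window) step one window further in, up to three attempts
    found = None
    ambiguous = False
    for attempt in range(3):
        anchor_end = Lr - attempt * k
        anchor_j = anchor_end - k
        if anchor_j < m:
            break
        seed = read[anchor_j:anchor_end]
        if seed_index is not None:
            occ_plus = seed_index.get(seed, [])
            occ_minus = seed_index.get(revcomp(seed), [])
        else:
            occ_plus = _find_all(S, seed)
            occ_minus = _find_all(S, revcomp(seed))
        total = len(occ_plus) + len(occ_minus)
        if total == 1:
            found = (anchor_j, anchor_end, occ_plus, occ_minus)
            break
        if total > 1:
            ambiguous = True
            break
    if ambiguous:
        return make("ambiguous")
    if found is None:
        return make("unmapped")
    anchor_j, anchor_end, occ_plus, occ_minus = found

    if occ_plus:
        o = occ_plus[0]
        strand = "+"

        def ref_base_at(j: int) -> str | None:
            p = o + (j - anchor_j)
            return S[p] if 0 <= p < len(S) else None

    else:
        o = occ_minus[0]
        strand = "-"

        def ref_base_at(j: int) -> str | None:
            p = o + (anchor_end - 1 - j)
            return S[p].translate(_COMP) if 0 <= p < len(S) else None

    prey_start, mh = place_junction(read, m, anchor_j, ref_base_at)
    insertion = read[m:prey_start]
    if strand == "+":
        prey_position = o + (prey_start - anchor_j)
    else:
        prey_position = o + (anchor_end - prey_start)

    rec = make("unclassified")
    rec.prey_position = prey_position
    rec.prey_strand = strand
    rec.insertion_seq = insertion
    rec.effective_insertion = len(insertion)
    rec.microhomology = mh
    return rec


def call_reads(
    reads: list[tuple[str, str]],
    bait: BaitDefinition,
    locus: LocusMap,
    replicate_id: str = "rep1",
    k: int = 20,
    annotate: bool = True,
    seed_index: dict | None = None,
) -> JunctionLibrary:
    """Call and annotate a batch of (read_id, sequence) reads into a library.

    Unmapped/ambiguous reads are dropped; ``raw_total`` keeps the input read
    count so normalization reflects the full library.
    """
    idx = seed_index if seed_index is not None else build_seed_index(locus, k)
    records: list[JunctionRecord] = []
    for rid, seq in reads:
        rec = call_junction(seq, bait, locus, k=k, seed_index=idx)
        rec.read_id = rid
        if rec.junction_class in ("unmapped", "ambiguous"):
            continue
        if annotate:
            m = len(bait.sequence) - rec.bait_deletion
            prey_window = seq[m + len(rec.insertion_seq) :][:20]
            rec = annotate_junction(
                rec, locus, prey_window, bait_coding_terminal=bait.sequence[:m]
            )
        records.append(rec)
    return JunctionLibrary(
        bait_name=bait.name,
        replicate_id=replicate_id,
        records=records,
        raw_total=len(reads),
    )


def build_seed_index(locus: LocusMap, k: int = 20) -> dict[str, list[int]]:
    """Precompute a forward-strand k-mer index for fast seed lookup."""
    S = locus.sequence or ""
    index: dict[str, list[int]] = {}
    for i in range(len(S) - k + 1):
        index.setdefault(S[i : i + k], []).append(i)
    return index


# ---------------------------------------------------------------------------
# P-nucleotides and junction annotation
# ---------------------------------------------------------------------------

def detect_p_nucleotides(
    insertion_seq: str,
    bait_coding_terminal: str,
    prey_coding_terminal: str,
    bait_deletion: int,
    prey_deletion: int,
    max_p: int = 4,
) -> tuple[int, int]:
    """Detect P-nucleotides at the two ends of a junctional insertion.

    A bait-side P element is the largest ``k <= max_p`` such that the first
    ``k`` inserted bases equal the reverse complement of the last ``k`` bases
    of the bait coding end — and the bait end is untrimmed (hairpin-derived P
    nucleotides only arise at full-length coding ends).  The prey side is
    symmetric on the insertion suffix against the first ``k`` bases of the
    prey coding end (both terminals given in read orientation).  Overlapping
    claims are resolved bait-first.
    """
    p_bait = 0
    if bait_deletion == 0:
        kmax = min(max_p, len(insertion_seq), len(bait_coding_terminal))
        for k in range(kmax, 0, -1):
            if insertion_seq[:k] == revcomp(bait_coding_terminal[-k:]):
                p_bait = k
                break
    p_prey = 0
    if prey_deletion == 0:
        rest = insertion_seq[p_bait:]
        kmax = min(max_p, len(rest), len(prey_coding_terminal))
        for k in range(kmax, 0, -1):
            if rest[-k:] == revcomp(prey_coding_terminal[:k]):
                p_prey = k
                break
    return p_bait, p_prey


def annotate_junction(
    record: JunctionRecord,
    locus: LocusMap,
    aligned_prey_window: str,
    mutation_window: int = 20,
    boundary_window: int = 10,
    max_p: int = 4,
    bait_coding_terminal: str = "",
) -> JunctionRecord:
    """Enrich a called junction with deletions, P-elements, class and the
    near-junction mismatch count.

    ``aligned_prey_window`` holds the read's prey-side bases, junction-
    proximal first, in read orientation.  Mismatches are counted against the
    reference within ``mutation_window`` aligned bases of the junction-
    proximal prey end.  Deletions are measured from the annotated RSS
    heptamer–coding boundary for bona fide preys and from the recorded
    cryptic-site boundary for cryptic preys (negative values mean the called
    junction lies past the boundary, into the signal side).
    """
    if record.junction_class in ("unmapped", "ambiguous"):
        return record
    S = locus.sequence
    if S is None:
        raise ValueError("locus carries no sequence")
    rec = replace(record, extras=dict(record.extras))
    pos, strand = rec.prey_position, rec.prey_strand

    # near-junction mismatches (window anchored at the junction-proximal end)
    w = min(mutation_window, len(aligned_prey_window))
    if strand == "-":
        w = min(w, pos)
        ref_window = revcomp(S[pos - w : pos])
    else:
        w = min(w, len(S) - pos)
        ref_window = S[pos : pos + w]
    rec.mutations_near_junction = sum(
        1 for a, b in zip(aligned_prey_window[:w], ref_window) if a != b
    )

    # classification + deletion from the matching boundary
    best: tuple[int, str, str, int] | None = None  # (|d|, class, name, deletion)
    for seg in locus.segments:
        if seg.rss is None or not seg.rss.bona_fide:
            continue
        cut = seg.rss.coding_boundary
        coding_strand = "-" if seg.rss.orientation == "down" else "+"
        for cls, s in (("bona_fide_coding", coding_strand),
                       ("bona_fide_rss", "-" if coding_strand == "+" else "+")):
            if s != strand:
                continue
            deletion = (cut - pos) if s == "-" else (pos - cut)
            if abs(deletion) <= boundary_window and (best is None or abs(deletion) < best[0]):
                best = (abs(deletion), cls, seg.name, deletion)
    if best is None:
        for site in locus.cryptic_sites:
            if site.strand != strand:
                continue
            deletion = (site.position - pos) if strand == "-" else (pos - site.position)
            if abs(deletion) <= boundary_window and (best is None or abs(deletion) < best[0]):
                best = (abs(deletion), "cryptic", f"site@{site.position}{site.strand}", deletion)

    if best is not None:
        _, cls, name, deletion = best
        rec.junction_class = cls
        rec.prey_name = name
        rec.prey_deletion = deletion
    else:
        rec.junction_class = "cryptic"
        rec.prey_deletion = 0

    # P-nucleotides and effective insertion
    prey_terminal = aligned_prey_window[:max_p]
    rec.p_len_bait, rec.p_len_prey = detect_p_nucleotides(
        rec.insertion_seq,
        bait_coding_terminal,
        prey_terminal,
        rec.bait_deletion,
        max(rec.prey_deletion, 0),
        max_p=max_p,
    )
    rec.effective_insertion = len(rec.insertion_seq) - rec.p_len_bait - rec.p_len_prey
    return rec
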