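"""Information-content scoring of recombination signal sequences.

RSS quality varies widely: the heptamer consensus CACAGTG is strongly
conserved while spacer and nonamer positions carry graded information, and
RSS "strength" (recombination information content) predicts how efficiently
RAG uses a site.  This module trains a positional log-odds model from aligned
bona fide RSS sequences (order-0 by default, optional order-1 first-order
dependencies), scores candidate sequences, classifies strong vs. weak sites
against a configurable threshold, and scans arbitrary sequence on both
strands for cryptic RSS-like sites (hard CAC heptamer-prefix filter).

Scores are in bits (log2 odds against the background composition).  The
scorer is a faithful, swappable stand-in whose role is to *rank* sites; it
does not attempt to reproduce any particular published score table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ScoringError, TrainingError
from .locus_model import revcomp

_ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(_ALPHABET)}


@dataclass
class RssModel:
    """Trained positional log-odds model for a 12RSS or 23RSS."""

    spacer_class: int
    log_odds: np.ndarray  # (length, 4) positional log2 odds
    background: np.ndarray  # (4,)
    order: int = 0
    transition_log_odds: np.ndarray | None = None  # (length-1, 4, 4) if order=1
    strength_threshold: float | None = None

    @property
    def length(self) -> int:
        return 7 + self.spacer_class + 9

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "spacer_class": self.spacer_class,
            "order": self.order,
            "background": self.background.tolist(),
            "log_odds": self.log_odds.tolist(),
            "strength_threshold": self.strength_threshold,
        }
        if self.transition_log_odds is not None:
            payload["transition_log_odds"] = self.transition_log_odds.tolist()
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RssModel":
        d = json.loads(text)
        trans = d.get("transition_log_odds")
        return cls(
            spacer_class=d["spacer_class"],
            log_odds=np.asarray(d["log_odds"], dtype=float),
            background=np.asarray(d["background"], dtype=float),
            order=d.get("order", 0),
            transition_log_odds=None if trans is None else np.asarray(trans, dtype=float),
            strength_threshold=d.get("strength_threshold"),
        )


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_INDEX[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ScoringError(f"non-ACGT base in sequence: {exc}") from exc


def train_rss_model(
    training_rss_sequences: list[str],
    spacer_class: int,
    pseudocount: float = 1.0,
    order: int = 0,
    background: np.ndarray | None = None,
) -> RssModel:
    """Train a positional log-odds RSS model from aligned, oriented sequences.

    Sequences must all have length ``7 + spacer_class + 9`` and be read
    heptamer → nonamer.  With pseudocount ``c`` the positional probability is
    ``(count + c) / (n + 4c)`` and the log-odds is taken against a uniform
    background unless one is supplied.  Deterministic given its inputs.
    """
    n = len(training_rss_sequences)
    if n < 2:
        raise TrainingError("need at least 2 training sequences")
    length = 7 + spacer_class + 9
    for s in training_rss_sequences:
        if len(s) != length:
            raise TrainingError(
                f"training sequence length {len(s)} != {length} for a {spacer_class}RSS"
            )
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
        raise TrainingError("background must be 4 probabilities summing to 1")

    mat = np.stack([_encode(s) for s in training_rss_sequences])  # (n, length)
    counts = np.zeros((length, 4))
    for b in range(4):
        counts[:, b] = (mat == b).sum(axis=0)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    log_odds = np.log2(probs / background[None, :])

    transition = None
    if order == 1:
        pair_counts = np.zeros((length - 1, 4, 4))
        for i in range(length - 1):
            for a in range(4):
                sel = mat[:, i] == a
                for b in range(4):
                    pair_counts[i, a, b] = np.sum(sel & (mat[:, i + 1] == b))
        cond = (pair_counts + pseudocount) / (
            counts[:-1, :, None] + 4 * pseudocount
        )
        transition = np.log2(cond / background[None, None, :])
    elif order != 0:
        raise TrainingError("order must be 0 or 1")

    return RssModel(
        spacer_class=spacer_class,
        log_odds=log_odds,
        background=background,
        order=order,
        transition_log_odds=transition,
    )


def score_rss(model: RssModel, sequence: str) -> float:
    """Score an oriented (heptamer-first) RSS sequence, in bits.

    Order-0 scores are additive over positions.  The caller must orient the
    sequence: scoring a reverse complement is a different (and generally
    lower) score.
    """
    if len(sequence) != model.length:
        raise ScoringError(
            f"sequence length {len(sequence)} != model length {model.length}"
        )
    idx = _encode(sequence)
    score = float(model.log_odds[np.arange(model.length), idx].sum())
    if model.order == 1 and model.transition_log_odds is not None:
        pos = np.arange(model.length - 1)
        # replace order-0 terms at positions 1.. with conditional terms
        score = float(model.log_odds[0, idx[0]]) + float(
            model.transition_log_odds[pos, idx[:-1], idx[1:]].sum()
        )
    return score


def training_sequences_from_tsv(text: str) -> list[str]:
    """Read a training set from TSV text: one sequence per line, optionally
    preceded by a name column; comment lines start with '#'."""
    seqs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        seqs.append(line.split("\t")[-1].upper())
    return seqs


def score_table_to_tsv(model: RssModel, named_sequences: dict[str, str]) -> str:
    """Score a set of named, oriented RSS sequences into a TSV table."""
    lines = ["name\tscore_bits"]
    for name, seq in named_sequences.items():
        lines.append(f"{name}\t{score_rss(model, seq):.6g}")
    return "\n".join(lines) + "\n"


def classify_strength(score: float, threshold: float) -> str:
    """Classify an RSS score: ``strong`` iff score >= threshold."""
    return "strong" if score >= threshold else "weak"


def scan_cryptic_rss(
    sequence: str, model: RssModel, min_score: float
) -> list[tuple[int, str, float]]:
    """Scan both strands of a sequence for cryptic RSS-like sites.

    A site is reported iff its heptamer begins with ``CAC`` (hard filter)
    and its score is >= ``min_score``.  Returned tuples are
    ``(position, strand, score)`` where ``position`` is the leftmost base of
    the site window on the forward coordinates of ``sequence``, sorted by
    position (``+`` before ``-`` at equal position).
    """
    if not sequence:
        raise ScoringError("cannot scan an empty sequence")
    L = model.length
    seq = sequence.upper()
    hits: list[tuple[int, str, float]] = []
    for start in range(0, len(seq) - L + 1):
        window = seq[start : start + L]
        if "N" in window:
            continue
        if window.startswith("CAC"):
            s = score_rss(model, window)
            if s >= min_score:
                hits.append((start, "+", s))
        rc = revcomp(window)
        if rc.startswith("CAC"):
            s = score_rss(model, rc)
            if s >= min_score:
                hits.append((start, "-", s))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits
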