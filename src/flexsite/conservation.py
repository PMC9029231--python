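"""Cross-species conservation scoring for candidate binding sites.

Each mouse hit is mapped, via a per-species position map, into the orthologous
promoter sequence; the motif-length ungapped window centred on the mapped
position is rescored, and the per-species scores are reduced to a single
"conserved score" so that one threshold simultaneously enforces a minimum
mouse score and conservation in at least n species:

    conserved = mouse_score                          if n == 0
    conserved = min(mouse_score, nth-highest
                    available ortholog score)        if n >= 1
    conserved = 0                                    if < n species align

Thresholding the conserved score at t is then exactly equivalent to the
predicate "mouse score >= t AND at least n ortholog windows score >= t".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

from .motifs import MotifHit, PositionWeightModel, score_window

__all__ = [
    "OrthologBundle",
    "ConservationConfig",
    "map_position",
    "score_ortholog_window",
    "conserved_score",
    "annotate_conservation",
]


@dataclass
class OrthologBundle:
    """Orthologous promoter sequences for one species plus position maps.

    ``maps[promoter_id]`` is a dict mouse_pos -> ortholog_pos built from a
    strictly increasing pair list.  ``maps[promoter_id] is None`` denotes the
    identity map over the ortholog sequence (the common case for synthetic
    bundles without indels).  Promoters absent from ``sequences`` are
    unaligned for this species.
    """

    species: str
    sequences: dict[str, str]
    maps: dict[str, dict[int, int] | None] = field(default_factory=dict)

    @classmethod
    def from_files(cls, species: str, fasta: TextIO | str, tsv: TextIO | str) -> "OrthologBundle":
        from Bio import SeqIO

        fh = open(fasta) if isinstance(fasta, str) else fasta
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
        maps: dict[str, dict[int, int] | None] = {}
        th = open(tsv) if isinstance(tsv, str) else tsv
        reader = csv.reader(th, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            pid, mp, op = row[0], int(row[1]), int(row[2])
            maps.setdefault(pid, {})[mp] = op
        for pid, pmap in maps.items():
            pairs = sorted(pmap.items())
            ms = [p[0] for p in pairs]
            os_ = [p[1] for p in pairs]
            if any(b <= a for a, b in zip(os_, os_[1:])):
                raise ValueError(f"{species}/{pid}: position map not strictly increasing")
            if ms and pid in seqs and max(os_) >= len(seqs[pid]):
                raise ValueError(f"{species}/{pid}: mapped position beyond ortholog length")
        bundle = cls(species=species, sequences=seqs, maps=maps)
        for pid in seqs:
            bundle.maps.setdefault(pid, None)
        return bundle

    def to_files(self, fasta: TextIO, tsv: TextIO) -> None:
        for pid, seq in self.sequences.items():
            fasta.write(f">{pid}\n")
            for i in range(0, len(seq), 70):
                fasta.write(seq[i : i + 70] + "\n")
            pmap = self.maps.get(pid)
            if pmap is not None:
                for mp in sorted(pmap):
                    tsv.write(f"{pid}\t{mp}\t{pmap[mp]}\n")


def map_position(bundle: OrthologBundle, promoter_id: str, mouse_pos: int) -> int | None:
    """Exact position lookup; None if the promoter or position is unaligned.

    No interpolation: a position deleted in the ortholog simply has no image.
    """
    if promoter_id not in bundle.sequences:
        return None
    pmap = bundle.maps.get(promoter_id)
    if pmap is None:  # identity map
        pos = mouse_pos
        return pos if 0 <= pos < len(bundle.sequences[promoter_id]) else None
    return pmap.get(mouse_pos)


def score_ortholog_window(
    pwm: PositionWeightModel, bundle: OrthologBundle, hit: MotifHit
) -> float | None:
    """Best-of-both-strands score of the ortholog window under a mouse hit.

    The central position of the mouse match (offset + floor(m/2)) is mapped;
    the motif-length ungapped ortholog window placed so its centre falls on
    the mapped position is scored.  None if unmapped, out of bounds, or the
    window cannot be scored (N).
    """
    m = pwm.length
    center = hit.offset + m // 2
    mapped = map_position(bundle, hit.promoter_id, center)
    if mapped is None:
        return None
    seq = bundle.sequences[hit.promoter_id]
    start = mapped - m // 2
    if start < 0 or start + m > len(seq):
        return None
    s_plus = score_window(pwm, seq, start, "+")
    s_minus = score_window(pwm, seq, start, "-")
    candidates = [s for s in (s_plus, s_minus) if s is not None]
    return max(candidates) if candidates else None


def conserved_score(
    mouse_score: float, species_scores: Iterable[float], n_required: int
) -> float:
    """Reduce mouse + ortholog scores to one conservation-enforcing score."""
    if n_required < 0:
        raise ValueError("n_required must be >= 0")
    if n_required == 0:
        return float(mouse_score)
    avail = sorted((float(s) for s in species_scores), reverse=True)
    if len(avail) < n_required:
        return 0.0
    return min(float(mouse_score), avail[n_required - 1])


def annotate_conservation(
    hits: Sequence[MotifHit],
    pwm: PositionWeightModel,
    bundles: Sequence[OrthologBundle],
    n_required: int,
) -> None:
    """Fill ``species_scores`` and ``conserved_score`` on hits, in place."""
    for h in hits:
        scores: dict[str, float] = {}
        for b in bundles:
            s = score_ortholog_window(pwm, b, h)
            if s is not None:
                scores[b.species] = s
        h.species_scores = scores
        h.conserved_score = conserved_score(h.mouse_score, scores.values(), n_required)


@dataclass(frozen=True)
class ConservationConfig:
    """Which species are consulted and how many must conserve a site."""

    species_list: tuple[str, ...] = ()
    n_required: int = 0

    def __post_init__(self) -> None:
        if self.n_required < 0:
            raise ValueError("n_required must be >= 0")
        if self.n_required > len(self.species_list):
            raise ValueError("n_required exceeds number of species")
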