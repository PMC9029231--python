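"""Position weight models and promoter scanning.

Scoring follows the MatInspector-style matrix-similarity convention: each
column of the (pseudocount-adjusted, column-stochastic) frequency matrix is
weighted by its information content, and raw scores are min/max normalised so
that every score lies in [0, 1], with 1.0 attained exactly by the consensus
sequence.  Thresholds quoted as percentages elsewhere ("88%") correspond to
normalised scores (0.88).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import motifs as _bio_motifs
from Bio.Seq import Seq

ALPHABET = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# complement in index space; N (4) maps to itself
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)

__all__ = [
    "MotifParseError",
    "ModelRejectedError",
    "PositionFrequencyMatrix",
    "PositionWeightModel",
    "PromoterSet",
    "MotifHit",
    "read_jaspar",
    "read_transfac",
    "build_pwm",
    "encode_sequence",
    "score_window",
    "scan_promoters",
    "calibrate_low_threshold",
    "write_hits_bed",
]


class MotifParseError(ValueError):
    """Raised when a motif matrix record is malformed."""


class ModelRejectedError(ValueError):
    """Raised when a PFM cannot yield a usable scoring model."""


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Raw base counts per motif position, columns over (A, C, G, T)."""

    motif_id: str
    tf_name: str
    source: str  # one of JASPAR_CORE, JASPAR_PBM, TRANSFAC, CUSTOM
    counts: np.ndarray  # shape (L, 4), non-negative

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4 or c.shape[0] < 1:
            raise MotifParseError(
                f"{self.motif_id}: counts must be an L x 4 matrix, got {c.shape}"
            )
        if (c < 0).any():
            raise MotifParseError(f"{self.motif_id}: negative counts")
        if (c.sum(axis=1) <= 0).any():
            raise MotifParseError(f"{self.motif_id}: empty column (total 0)")
        object.__setattr__(self, "counts", c)

    @property
    def length(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class PositionWeightModel:
    """Information-content-weighted scoring model derived from a PFM.

    ``f`` is the column-stochastic frequency matrix, ``ci`` the per-position
    information weight in nats (ci[i] = sum_b f(b,i) ln(4 f(b,i))), and raw
    scores sum ci[i] * f(base_i, i) over positions; ``raw_min``/``raw_max``
    are the attainable bounds used for min/max normalisation.
    """

    motif_id: str
    f: np.ndarray        # (L, 4) column-stochastic
    ci: np.ndarray       # (L,) information weights, nats
    raw_min: float
    raw_max: float
    # per-position per-base raw contribution ci[i] * f(b, i), padded with a
    # NaN column so that N (index 4) poisons any window that contains it
    _weights5: np.ndarray = field(repr=False, default=None)

    @property
    def length(self) -> int:
        return self.f.shape[0]

    def normalize(self, raw: np.ndarray | float) -> np.ndarray | float:
        return (raw - self.raw_min) / (self.raw_max - self.raw_min)


def build_pwm(pfm: PositionFrequencyMatrix, pseudocount: float = 0.01) -> PositionWeightModel:
    """Build the information-weighted scoring model for ``pfm``.

    ``pseudocount`` is added to every cell before column normalisation
    (default 0.01: negligible for real count matrices, avoids ln 0).
    Raises :class:`ModelRejectedError` for matrices whose columns are all
    uniform (zero information everywhere: no score spread).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    c = pfm.counts + pseudocount
    f = c / c.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    ci = terms.sum(axis=1)
    ci = np.where(ci < 0, 0.0, ci)  # clip tiny negative rounding
    w = ci[:, None] * f
    raw_min = float(w.min(axis=1).sum())
    raw_max = float(w.max(axis=1).sum())
    if not raw_max > raw_min + 1e-12:
        raise ModelRejectedError(
            f"{pfm.motif_id}: uniform matrix, no attainable score spread"
        )
    w5 = np.column_stack([w, np.full(len(ci), np.nan)])
    return PositionWeightModel(
        motif_id=pfm.motif_id, f=f, ci=ci, raw_min=raw_min, raw_max=raw_max,
        _weights5=w5,
    )


# ---------------------------------------------------------------------------
# parsing


def _as_stream(source: str | TextIO) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_jaspar(source: str | TextIO) -> list[PositionFrequencyMatrix]:
    """Parse JASPAR-style multi-record motif text (.jaspar/.pfm).

    Records are ``>ID name`` headers followed by four base rows, either
    bracketed (``A [ 0 4 ]``) or bare numbers.  Rows are mapped to A, C, G, T
    in file order.  Malformed records raise :class:`MotifParseError` naming
    the record.
    """
    text = _as_stream(source).read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    # pre-validate record shape: Bio silently drops malformed records
    records: list[tuple[str, list[str]]] = []
    header = None
    rows: list[str] = []
    for i, ln in enumerate(lines, 1):
        if ln.startswith(">"):
            if header is not None:
                records.append((header, rows))
            header, rows = ln, []
        else:
            if header is None:
                raise MotifParseError(f"line {i}: matrix row before any '>' header")
            rows.append(ln)
    if header is not None:
        records.append((header, rows))
    for header, rows in records:
        rec_id = header[1:].split()[0] if header[1:].split() else "<unnamed>"
        if len(rows) != 4:
            raise MotifParseError(
                f"record {rec_id}: expected 4 base rows, found {len(rows)}"
            )
        for row in rows:
            body = row
            if body[:1].upper() in "ACGT" and not body[:1].isdigit():
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            for cell in body.split():
                try:
                    float(cell)
                except ValueError:
                    raise MotifParseError(
                        f"record {rec_id}: non-numeric cell {cell!r} in row {row!r}"
                    ) from None
    parsed = _bio_motifs.parse(io.StringIO(text), "jaspar")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in ALPHABET], dtype=float).T
        out.append(
            PositionFrequencyMatrix(
                motif_id=m.matrix_id or m.name or "?",
                tf_name=m.name or "",
                source="JASPAR_CORE",
                counts=counts,
            )
        )
    if len(out) != len(records):
        raise MotifParseError("record count mismatch after parsing")
    return out


def read_transfac(source: str | TextIO) -> list[PositionFrequencyMatrix]:
    """Parse TRANSFAC flat-file matrix records (AC/ID ... P0 rows ... //).

    TRANSFAC identifiers (``ID`` line, e.g. V$AP1_C) are retained as
    ``motif_id``.  Missing ``//`` terminators, out-of-order position lines or
    ragged rows raise :class:`MotifParseError`.
    """
    text = _as_stream(source).read()
    stripped = text.strip()
    if not stripped:
        return []
    n_expected = sum(1 for ln in stripped.splitlines() if ln.startswith("AC"))
    if not stripped.rstrip().endswith("//"):
        raise MotifParseError("TRANSFAC record missing '//' terminator")
    try:
        parsed = _bio_motifs.parse(io.StringIO(text), "transfac")
    except ValueError as exc:
        raise MotifParseError(str(exc)) from exc
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in ALPHABET], dtype=float).T
        ident = m.get("ID") or m.get("AC") or "?"
        out.append(
            PositionFrequencyMatrix(
                motif_id=ident, tf_name=ident, source="TRANSFAC", counts=counts
            )
        )
    if n_expected and len(out) != n_expected:
        raise MotifParseError(
            f"parsed {len(out)} matrices but found {n_expected} AC lines"
        )
    return out


# ---------------------------------------------------------------------------
# promoters


@dataclass
class PromoterSet:
    """A labelled set of promoter sequences, TSS at each sequence's 3' end.

    Sequences are stored 5'->3' on the gene's sense strand, so truncating to a
    window of w bp keeps the *last* w bases (the TSS-proximal part).
    """

    label: str  # "test" or "control"
    entries: list[tuple[str, str]]  # (gene_id, sequence over ACGTN)

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_ids in promoter set")

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def truncate(self, window_bp: int) -> "PromoterSet":
        """Keep the TSS-proximal ``window_bp`` of every promoter."""
        return PromoterSet(
            label=self.label,
            entries=[(g, s[-window_bp:]) for g, s in self.entries],
        )

    def sequence(self, gene_id: str) -> str:
        for g, s in self.entries:
            if g == gene_id:
                return s
        raise KeyError(gene_id)

    @classmethod
    def from_fasta(cls, source: str | TextIO, label: str = "test") -> "PromoterSet":
        """Read promoters from FASTA. An optional ``win=<bp>`` header token is
        honoured by truncation of that record."""
        from Bio import SeqIO

        handle = _as_stream(source) if isinstance(source, str) and source.lstrip().startswith(">") else source
        if isinstance(handle, str):
            handle = open(handle)
        entries = []
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            win = None
            for token in rec.description.split():
                if token.startswith("win="):
                    win = int(token[4:])
            if win is not None:
                seq = seq[-win:]
            entries.append((rec.id, seq))
        return cls(label=label, entries=entries)

    def to_fasta(self, handle: TextIO) -> None:
        for g, s in self.entries:
            handle.write(f">{g}\n")
            for i in range(0, len(s), 70):
                handle.write(s[i : i + 70] + "\n")


@dataclass
class MotifHit:
    """One candidate binding site in a promoter.

    ``offset`` is the 0-based start of the match window measured from the
    upstream (5') end of the stored sequence; the window is half-open
    ``[offset, offset + motif_length)``.
    """

    promoter_id: str
    offset: int
    strand: str  # '+' or '-'
    mouse_score: float
    species_scores: dict[str, float] = field(default_factory=dict)
    conserved_score: float | None = None

    def center(self, motif_length: int) -> int:
        return self.offset + motif_length // 2


# ---------------------------------------------------------------------------
# scanning


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGTN string as int8 indices (A0 C1 G2 T3 N4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    enc = lut[arr]
    if (enc < 0).any():
        bad = chr(arr[int(np.argmax(enc < 0))])
        raise ValueError(f"sequence contains invalid character {bad!r}")
    return enc


def _window_scores(pwm: PositionWeightModel, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalised scores at every offset for + and - strands.

    Windows containing N come out NaN.  Returns (plus, minus), each of length
    len(enc) - m + 1 (empty if the sequence is shorter than the motif).
    """
    m = pwm.length
    n_off = len(enc) - m + 1
    if n_off <= 0:
        e = np.empty(0)
        return e, e
    w5 = pwm._weights5
    # reverse-complement weights: scoring revcomp(window) with w equals
    # scoring window with w reversed in position and complemented in base
    w5_rc = w5[::-1][:, [3, 2, 1, 0, 4]]
    plus = np.zeros(n_off)
    minus = np.zeros(n_off)
    for i in range(m):
        col = enc[i : i + n_off]
        plus += w5[i, col]
        minus += w5_rc[i, col]
    return pwm.normalize(plus), pwm.normalize(minus)


def score_window(
    pwm: PositionWeightModel, sequence: str, offset: int, strand: str = "+"
) -> float | None:
    """Normalised score of one window; None if the window contains N.

    ``strand == '-'`` scores the reverse complement of the window.
    """
    m = pwm.length
    if offset < 0 or offset + m > len(sequence):
        raise IndexError(f"window [{offset}, {offset + m}) out of range")
    enc = encode_sequence(sequence[offset : offset + m])
    if (enc == 4).any():
        return None
    if strand == "-":
        enc = _COMP[enc][::-1]
    elif strand != "+":
        raise ValueError("strand must be '+' or '-'")
    raw = float(pwm._weights5[np.arange(m), enc].sum())
    return float(pwm.normalize(raw))


def scan_promoters(
    pwm: PositionWeightModel,
    promoters: PromoterSet,
    low_threshold: float,
) -> list[MotifHit]:
    """Scan every promoter on both strands for windows scoring >= threshold.

    At each offset only the better-scoring strand is kept (ties go to '+'),
    so a palindromic site is reported once.  N-containing windows never match.
    """
    hits: list[MotifHit] = []
    for gene_id, seq in promoters.entries:
        enc = encode_sequence(seq)
        plus, minus = _window_scores(pwm, enc)
        if plus.size == 0:
            continue
        with np.errstate(invalid="ignore"):
            best = np.where(np.nan_to_num(minus, nan=-1.0) > np.nan_to_num(plus, nan=-1.0), minus, plus)
            use_minus = np.nan_to_num(minus, nan=-1.0) > np.nan_to_num(plus, nan=-1.0)
            keep = np.nan_to_num(best, nan=-1.0) >= low_threshold
        for off in np.nonzero(keep)[0]:
            hits.append(
                MotifHit(
                    promoter_id=gene_id,
                    offset=int(off),
                    strand="-" if use_minus[off] else "+",
                    mouse_score=float(best[off]),
                )
            )
    return hits


def calibrate_low_threshold(
    pwm: PositionWeightModel,
    promoters: PromoterSet,
    target_per_kb: float = 1.0,
) -> float:
    """Pick the scan threshold giving about ``target_per_kb`` matches/kb.

    Compiles best-strand scores at every offset of ``promoters`` and returns
    the score of the k-th best window where k = ceil(total_kb * target).
    Guarantees a match frequency >= the target (never an empty hit list when
    any window is scoreable).
    """
    all_scores: list[np.ndarray] = []
    for _, seq in promoters.entries:
        enc = encode_sequence(seq)
        plus, minus = _window_scores(pwm, enc)
        if plus.size:
            best = np.fmax(np.nan_to_num(plus, nan=-np.inf), np.nan_to_num(minus, nan=-np.inf))
            all_scores.append(best[np.isfinite(best)])
    if not all_scores:
        return 0.0
    scores = np.sort(np.concatenate(all_scores))[::-1]
    k = int(np.ceil(promoters.total_length / 1000.0 * target_per_kb))
    k = min(max(k, 1), len(scores))
    return float(scores[k - 1])


def write_hits_bed(
    hits: Iterable[MotifHit], motif_length: int, handle: TextIO, name: str = "site"
) -> None:
    """Write hits as BED6: chrom = promoter_id, 0-based half-open,
    score = round(1000 * normalised score)."""
    for h in hits:
        handle.write(
            f"{h.promoter_id}\t{h.offset}\t{h.offset + motif_length}\t{name}\t"
            f"{round(1000 * h.mouse_score)}\t{h.strand}\n"
        )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
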