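"""Flexible-threshold binding-site over-representation.

For one motif model the candidate thresholds are *all* scores observed in the
test and control promoter sets; each is tested exhaustively.  At a threshold
t, A and B are the site counts (conserved score >= t) in the test and control
sets whose total lengths are lenA and lenB:

    OR ratio          (A/lenA) / (B/lenB)
    Additional Sites  A - B*lenA/lenB
    significance      one-sided exact binomial, X ~ Bin(A+B, lenA/(lenA+lenB))

Only thresholds giving a control-site frequency of 0.01-0.2 sites/kb are
admissible; the optimiser returns the admissible threshold maximising the
configured objective (the AS objective additionally requires OR >= min_or).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .conservation import OrthologBundle, annotate_conservation
from .motifs import (
    MotifHit,
    ModelRejectedError,
    PositionFrequencyMatrix,
    PositionWeightModel,
    PromoterSet,
    build_pwm,
    calibrate_low_threshold,
    scan_promoters,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentConfig",
    "ThresholdScanPoint",
    "EnrichmentResult",
    "Fragment",
    "or_ratio",
    "additional_sites",
    "binomial_p",
    "candidate_thresholds",
    "scan_thresholds",
    "optimize",
    "run_enrichment",
    "results_table",
    "flanking_regions",
    "flanking_enrichment",
]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Settings for one enrichment analysis.

    ``window_lengths`` are promoter windows in bp (TSS-proximal truncation);
    ``n_required`` how many species must conserve a site (int, or a sequence
    to scan a grid); ``objective`` 'OR' or 'AS'; ``min_or`` the minimum OR
    ratio imposed under the AS objective; ``low_rate_per_kb`` the target
    match frequency of the initial permissive scan.
    """

    window_lengths: tuple[int, ...] = (1000,)
    n_required: int | tuple[int, ...] = 0
    objective: str = "AS"
    min_or: float = 2.5
    flank_bp: int = 100
    control_freq_bounds: tuple[float, float] = (0.01, 0.2)
    sidedness: str = "over"
    p_model: str = "rate"
    low_rate_per_kb: float = 5.0

    def __post_init__(self) -> None:
        lo, hi = self.control_freq_bounds
        if not (0 < lo < hi):
            raise ValueError("control_freq_bounds must be positive and ordered")
        if self.objective not in ("OR", "AS"):
            raise ValueError("objective must be 'OR' or 'AS'")
        if self.sidedness not in ("over", "under"):
            raise ValueError("sidedness must be 'over' or 'under'")

    @property
    def n_grid(self) -> tuple[int, ...]:
        n = self.n_required
        return (n,) if isinstance(n, int) else tuple(n)


@dataclass
class ThresholdScanPoint:
    """Statistics at one candidate threshold."""

    threshold: float
    A: int
    B: int
    lenA: int
    lenB: int
    or_ratio: float  # math.inf when B == 0
    additional_sites: float
    p_value: float
    admissible: bool

    def objective_value(self, objective: str) -> float:
        return self.or_ratio if objective == "OR" else self.additional_sites


@dataclass
class EnrichmentResult:
    """Best scan point for one motif under one (window, n) setting."""

    motif_id: str
    window: int
    n_required: int
    objective: str
    best: ThresholdScanPoint | None
    hits_at_best: list[MotifHit] = field(default_factory=list)
    motif_length: int = 0
    group_id: int | None = None
    fdr: float | None = None

    @property
    def objective_value(self) -> float:
        if self.best is None:
            return -math.inf
        return self.best.objective_value(self.objective)


# ---------------------------------------------------------------------------
# elementary statistics


def or_ratio(A: int, lenA: int, B: int, lenB: int) -> float:
    """Site-frequency ratio (A/lenA)/(B/lenB); +inf when B == 0."""
    if lenA <= 0 or lenB <= 0:
        raise ValueError("promoter set lengths must be positive")
    if B == 0:
        return math.inf
    return (A / lenA) / (B / lenB)


def additional_sites(A: int, lenA: int, B: int, lenB: int) -> float:
    """Excess test-set sites over the control-rate expectation."""
    if lenB <= 0:
        raise ValueError("lenB must be positive")
    return A - B * lenA / lenB


def binomial_p(
    A: int,
    B: int,
    lenA: int,
    lenB: int,
    sidedness: str = "over",
    model: str = "conditional",
) -> float:
    """One-sided exact binomial p for the site counts in the two sets.

    Two parameterisations built from the same four numbers:

    * ``conditional`` — condition on the total count: X ~ Binomial(A+B,
      lenA/(lenA+lenB)); over-representation p = P(X >= A), under p =
      P(X <= A).  The symmetric two-sample construction.
    * ``rate`` — the control set fixes the expected site rate (the F-match
      convention): X ~ Binomial(lenA, B/lenB), p = P(X >= A) (over) or
      P(X <= A) (under).  This is what the enrichment pipeline reports.
    """
    if A < 0 or B < 0:
        raise ValueError("counts must be non-negative")
    if lenA <= 0 or lenB <= 0:
        raise ValueError("lengths must be positive")
    if sidedness not in ("over", "under"):
        raise ValueError("sidedness must be 'over' or 'under'")
    if model == "conditional":
        n, p = A + B, lenA / (lenA + lenB)
    elif model == "rate":
        n, p = lenA, min(B / lenB, 1.0)
    else:
        raise ValueError("model must be 'conditional' or 'rate'")
    if sidedness == "over":
        return float(stats.binom.sf(A - 1, n, p))
    return float(stats.binom.cdf(A, n, p))


def _scores_of(hits: Iterable) -> np.ndarray:
    vals = []
    for h in hits:
        if isinstance(h, MotifHit):
            s = h.conserved_score if h.conserved_score is not None else h.mouse_score
        else:
            s = float(h)
        vals.append(s)
    return np.asarray(vals, dtype=float)


def candidate_thresholds(test_hits: Iterable, control_hits: Iterable) -> np.ndarray:
    """All distinct scores in either set, ascending — the thresholds tested."""
    ts = _scores_of(test_hits)
    cs = _scores_of(control_hits)
    return np.unique(np.concatenate([ts, cs]))


def scan_thresholds(
    test_hits: Iterable,
    control_hits: Iterable,
    lenA: int,
    lenB: int,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[ThresholdScanPoint]:
    """Evaluate every candidate threshold (inclusive comparison, score >= t)."""
    ts = np.sort(_scores_of(test_hits))
    cs = np.sort(_scores_of(control_hits))
    cands = np.unique(np.concatenate([ts, cs])) if ts.size + cs.size else np.empty(0)
    if cands.size == 0:
        return []
    A = ts.size - np.searchsorted(ts, cands, side="left")
    B = cs.size - np.searchsorted(cs, cands, side="left")
    if config.p_model == "conditional":
        n_tot = A + B
        p0 = np.full(cands.size, lenA / (lenA + lenB))
    else:
        n_tot = np.full(cands.size, lenA)
        p0 = np.minimum(B / lenB, 1.0)
    if config.sidedness == "over":
        pvals = stats.binom.sf(A - 1, n_tot, p0)
    else:
        pvals = stats.binom.cdf(A, n_tot, p0)
    lo, hi = config.control_freq_bounds
    freq = 1000.0 * B / lenB
    adm = (freq >= lo) & (freq <= hi)
    points = []
    for i, t in enumerate(cands):
        points.append(
            ThresholdScanPoint(
                threshold=float(t),
                A=int(A[i]),
                B=int(B[i]),
                lenA=lenA,
                lenB=lenB,
                or_ratio=or_ratio(int(A[i]), lenA, int(B[i]), lenB),
                additional_sites=additional_sites(int(A[i]), lenA, int(B[i]), lenB),
                p_value=float(pvals[i]),
                admissible=bool(adm[i]),
            )
        )
    return points


def optimize(
    points: Sequence[ThresholdScanPoint], config: EnrichmentConfig = EnrichmentConfig()
) -> ThresholdScanPoint | None:
    """Best admissible scan point under the configured objective.

    The AS objective additionally requires OR >= min_or.  Ties are broken by
    smaller p-value, then larger threshold.  None if nothing is admissible.
    """
    eligible = [p for p in points if p.admissible]
    if config.objective == "AS":
        eligible = [p for p in eligible if p.or_ratio >= config.min_or]
    if not eligible:
        return None
    return max(
        eligible,
        key=lambda p: (p.objective_value(config.objective), -p.p_value, p.threshold),
    )


# ---------------------------------------------------------------------------
# cached per-promoter scanning (shared by run_enrichment and the FDR resampler)


@dataclass
class HitCache:
    """Per-promoter hits for one PWM at one (window, n) setting.

    Scanning and conservation scoring are promoter-local, so a cache built on
    the pooled promoters supports any test/control split of that pool.
    """

    motif_id: str
    motif_length: int
    low_threshold: float
    hits: dict[str, list[MotifHit]]       # promoter_id -> hits
    scores: dict[str, np.ndarray]          # promoter_id -> conserved scores
    lengths: dict[str, int]                # promoter_id -> truncated length

    def split_scores(self, ids: Sequence[str]) -> np.ndarray:
        parts = [self.scores[i] for i in ids if i in self.scores]
        return np.concatenate(parts) if parts else np.empty(0)

    def split_hits(self, ids: Sequence[str], min_score: float) -> list[MotifHit]:
        out = []
        for i in ids:
            for h in self.hits.get(i, []):
                s = h.conserved_score if h.conserved_score is not None else h.mouse_score
                if s >= min_score:
                    out.append(h)
        return out

    def total_length(self, ids: Sequence[str]) -> int:
        return sum(self.lengths[i] for i in ids)


def build_hit_cache(
    pwm: PositionWeightModel,
    entries: Sequence[tuple[str, str]],
    bundles: Sequence[OrthologBundle],
    n_required: int,
    low_rate_per_kb: float = 5.0,
) -> HitCache:
    """Scan pooled promoters once, annotate conservation, index by promoter.

    The permissive scan threshold is calibrated on the pooled set so that it
    is identical for every test/control split (the FDR resampler depends on
    this)."""
    pool = PromoterSet(label="pool", entries=list(entries))
    low_t = calibrate_low_threshold(pwm, pool, target_per_kb=low_rate_per_kb)
    hits = scan_promoters(pwm, pool, low_t)
    if n_required > 0:
        # ortholog bundles are keyed by the original promoter ids, so the
        # arm prefix added by pool_entries is stripped for the lookup
        originals = [h.promoter_id for h in hits]
        for h in hits:
            if h.promoter_id[:2] in ("t|", "c|"):
                h.promoter_id = h.promoter_id[2:]
        annotate_conservation(hits, pwm, bundles, n_required)
        for h, pid in zip(hits, originals):
            h.promoter_id = pid
    else:
        for h in hits:
            h.conserved_score = h.mouse_score
    by_prom: dict[str, list[MotifHit]] = {pid: [] for pid, _ in entries}
    for h in hits:
        by_prom[h.promoter_id].append(h)
    scores = {
        pid: np.array([h.conserved_score for h in hs], dtype=float)
        for pid, hs in by_prom.items()
    }
    return HitCache(
        motif_id=pwm.motif_id,
        motif_length=pwm.length,
        low_threshold=low_t,
        hits=by_prom,
        scores=scores,
        lengths={pid: len(seq) for pid, seq in entries},
    )


def pool_entries(
    test_entries: Sequence[tuple[str, str]],
    control_entries: Sequence[tuple[str, str]],
) -> tuple[list[tuple[str, str]], list[str], list[str]]:
    """Pool two promoter sets under arm-prefixed ids (sets may share ids)."""
    pooled = [("t|" + g, s) for g, s in test_entries] + [
        ("c|" + g, s) for g, s in control_entries
    ]
    return (
        pooled,
        [g for g, _ in pooled[: len(test_entries)]],
        [g for g, _ in pooled[len(test_entries) :]],
    )


def strip_arm_prefix(hits: Sequence[MotifHit]) -> list[MotifHit]:
    out = []
    for h in hits:
        pid = h.promoter_id.split("|", 1)[1] if "|" in h.promoter_id else h.promoter_id
        out.append(replace(h, promoter_id=pid))
    return out


def evaluate_split(
    cache: HitCache,
    test_ids: Sequence[str],
    control_ids: Sequence[str],
    config: EnrichmentConfig,
) -> tuple[ThresholdScanPoint | None, list[MotifHit]]:
    """Run the flexible-threshold optimisation for one test/control split."""
    ts = cache.split_scores(test_ids)
    cs = cache.split_scores(control_ids)
    lenA = cache.total_length(test_ids)
    lenB = cache.total_length(control_ids)
    # conserved-score counts are only complete at thresholds >= the permissive
    # scan threshold; below it the scan itself censors sites
    points = [
        p
        for p in scan_thresholds(ts, cs, lenA, lenB, config)
        if p.threshold >= cache.low_threshold
    ]
    best = optimize(points, config)
    if best is None:
        return None, []
    return best, cache.split_hits(test_ids, best.threshold)


def _as_models(pwms: Iterable) -> list[PositionWeightModel]:
    models = []
    for p in pwms:
        if isinstance(p, PositionWeightModel):
            models.append(p)
        else:
            try:
                models.append(build_pwm(p))
            except ModelRejectedError as exc:
                logger.warning("skipping motif: %s", exc)
    return models


def run_enrichment(
    test: PromoterSet,
    control: PromoterSet,
    pwms: Iterable,
    bundles: Sequence[OrthologBundle] = (),
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[EnrichmentResult]:
    """Full grid over window lengths x conservation levels, per motif.

    Returns one result per motif: its best admissible optimum across the
    grid, with the test-set hits at that optimum.  ``pwms`` may be raw PFMs
    (built here; degenerate matrices are skipped with a warning) or prebuilt
    models.  Results are ordered by motif_id.
    """
    models = _as_models(pwms)
    results: list[EnrichmentResult] = []
    for pwm in models:
        best_result: EnrichmentResult | None = None
        for window in config.window_lengths:
            t_win = test.truncate(window)
            c_win = control.truncate(window)
            pooled, test_ids, control_ids = pool_entries(t_win.entries, c_win.entries)
            for n_req in config.n_grid:
                cache = build_hit_cache(
                    pwm, pooled, bundles, n_req, config.low_rate_per_kb
                )
                best, hits = evaluate_split(cache, test_ids, control_ids, config)
                hits = strip_arm_prefix(hits)
                res = EnrichmentResult(
                    motif_id=pwm.motif_id,
                    window=window,
                    n_required=n_req,
                    objective=config.objective,
                    best=best,
                    hits_at_best=hits,
                    motif_length=pwm.length,
                )
                if best_result is None or res.objective_value > best_result.objective_value:
                    best_result = res
        results.append(best_result)
    results.sort(key=lambda r: r.motif_id)
    return results


def results_table(results: Sequence[EnrichmentResult]):
    """Flat table of enrichment results (one row per motif)."""
    import pandas as pd

    rows = []
    for r in results:
        b = r.best
        rows.append(
            dict(
                motif_id=r.motif_id,
                window=r.window,
                n_required=r.n_required,
                objective=r.objective,
                threshold=b.threshold if b else np.nan,
                A=b.A if b else 0,
                B=b.B if b else 0,
                lenA=b.lenA if b else 0,
                lenB=b.lenB if b else 0,
                or_ratio=b.or_ratio if b else np.nan,
                additional_sites=b.additional_sites if b else np.nan,
                p_value=b.p_value if b else np.nan,
                group_id=r.group_id,
                fdr=r.fdr,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flanking regions


@dataclass(frozen=True)
class Fragment:
    """A promoter sub-interval with provenance coordinates."""

    promoter_id: str
    start: int
    end: int
    sequence: str
    uid: str | None = None

    @property
    def fragment_id(self) -> str:
        return self.uid or f"{self.promoter_id}:{self.start}-{self.end}"


def flanking_regions(
    anchor_hits: Sequence[MotifHit],
    promoters: PromoterSet,
    motif_length: int,
    flank_bp: int = 100,
) -> list[Fragment]:
    """The 100 bp (default) regions either side of each anchor site.

    Every anchor-site window (for this motif) is excluded from the emitted
    fragments, including windows of *other* anchors overlapping a flank;
    intervals are clipped to promoter bounds.  Zero-length pieces are dropped.
    """
    seqs = dict(promoters.entries)
    windows: dict[str, list[tuple[int, int]]] = {}
    for h in anchor_hits:
        windows.setdefault(h.promoter_id, []).append(
            (h.offset, h.offset + motif_length)
        )
    fragments: list[Fragment] = []
    seen: set[tuple[str, int, int]] = set()
    for h in anchor_hits:
        seq = seqs[h.promoter_id]
        excl = sorted(windows[h.promoter_id])
        for lo, hi in (
            (h.offset - flank_bp, h.offset),
            (h.offset + motif_length, h.offset + motif_length + flank_bp),
        ):
            lo, hi = max(lo, 0), min(hi, len(seq))
            # subtract every anchor window from [lo, hi)
            pieces = [(lo, hi)]
            for wlo, whi in excl:
                nxt = []
                for plo, phi in pieces:
                    if whi <= plo or wlo >= phi:
                        nxt.append((plo, phi))
                        continue
                    if plo < wlo:
                        nxt.append((plo, wlo))
                    if whi < phi:
                        nxt.append((whi, phi))
                pieces = nxt
            for plo, phi in pieces:
                if phi > plo and (h.promoter_id, plo, phi) not in seen:
                    seen.add((h.promoter_id, plo, phi))
                    fragments.append(
                        Fragment(h.promoter_id, plo, phi, seq[plo:phi])
                    )
    return fragments


def _fragment_bundles(
    fragments: Sequence[Fragment], bundles: Sequence[OrthologBundle]
) -> list[OrthologBundle]:
    """Re-key ortholog bundles by fragment id, translating positions."""
    out = []
    for b in bundles:
        seqs: dict[str, str] = {}
        maps: dict[str, dict[int, int] | None] = {}
        for fr in fragments:
            if fr.promoter_id not in b.sequences:
                continue
            seqs[fr.fragment_id] = b.sequences[fr.promoter_id]
            pmap = b.maps.get(fr.promoter_id)
            if pmap is None:
                maps[fr.fragment_id] = {
                    p: fr.start + p
                    for p in range(fr.end - fr.start)
                    if fr.start + p < len(b.sequences[fr.promoter_id])
                }
            else:
                maps[fr.fragment_id] = {
                    p: pmap[fr.start + p]
                    for p in range(fr.end - fr.start)
                    if fr.start + p in pmap
                }
        out.append(OrthologBundle(species=b.species, sequences=seqs, maps=maps))
    return out


def sample_control_fragments(
    control: PromoterSet, n_fragments: int, fragment_bp: int, rng: np.random.Generator
) -> list[Fragment]:
    """Uniform random fragments from the control promoters.

    A promoter is chosen with probability proportional to its number of
    eligible start positions, then a start uniformly within it.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    weights = np.array(
        [max(0, len(s) - fragment_bp + 1) for _, s in control.entries], dtype=float
    )
    if weights.sum() == 0:
        raise ValueError(f"no control promoter is >= {fragment_bp} bp")
    probs = weights / weights.sum()
    idx = rng.choice(len(control.entries), size=n_fragments, p=probs)
    out = []
    for k, i in enumerate(idx):
        pid, seq = control.entries[i]
        start = int(rng.integers(0, len(seq) - fragment_bp + 1))
        out.append(
            Fragment(
                pid, start, start + fragment_bp,
                seq[start : start + fragment_bp],
                uid=f"ctl{k}|{pid}:{start}",
            )
        )
    return out


def flanking_enrichment(
    fragments: Sequence[Fragment],
    control_promoters: PromoterSet,
    pwms: Iterable,
    bundles: Sequence[OrthologBundle] = (),
    config: EnrichmentConfig = EnrichmentConfig(),
    n_fragments: int | None = None,
    rng_seed: int = 0,
    fragment_bp: int = 200,
) -> list[EnrichmentResult]:
    """Enrichment of motifs in anchor-flanking regions vs random fragments.

    The test set is the anchor flanks; the control set is ``n_fragments``
    random ``fragment_bp`` windows from the control promoters (default
    max(1000, 5x the flank count)).  Results are sorted by objective value,
    best first.
    """
    if not fragments:
        raise ValueError("no flanking fragments supplied")
    if n_fragments is None:
        n_fragments = max(1000, 5 * len(fragments))
    rng = np.random.default_rng(rng_seed)
    ctl_frags = sample_control_fragments(
        control_promoters, n_fragments, fragment_bp, rng
    )
    test_set = PromoterSet(
        label="test", entries=[(f.fragment_id, f.sequence) for f in fragments]
    )
    ctl_set = PromoterSet(
        label="control", entries=[(f.fragment_id, f.sequence) for f in ctl_frags]
    )
    models = _as_models(pwms)
    n_req = config.n_grid[0]
    frag_bundles: Sequence[OrthologBundle] = ()
    if n_req > 0:
        frag_bundles = _fragment_bundles(
            list(fragments) + list(ctl_frags), bundles
        )
    results = []
    pooled = list(test_set.entries) + list(ctl_set.entries)
    for pwm in models:
        cache = build_hit_cache(pwm, pooled, frag_bundles, n_req, config.low_rate_per_kb)
        best, hits = evaluate_split(
            cache,
            [g for g, _ in test_set.entries],
            [g for g, _ in ctl_set.entries],
            config,
        )
        results.append(
            EnrichmentResult(
                motif_id=pwm.motif_id,
                window=fragment_bp,
                n_required=n_req,
                objective=config.objective,
                best=best,
                hits_at_best=hits,
                motif_length=pwm.length,
            )
        )
    results.sort(key=lambda r: (-r.objective_value, r.motif_id))
    return results
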