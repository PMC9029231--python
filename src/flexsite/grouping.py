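"""Location-based motif grouping and resampling group-wise FDR.

Many matrices in a motif library are near-duplicates and detect sites at the
same promoter positions.  Matrices are therefore grouped: two matrices are
related when at least half of either one's hit centres fall within 4 bp of a
hit centre of the other on the same promoter, and groups are the connected
components of that relation.

The group-wise FDR is estimated by resampling: each run redraws the test set
(a promoters) at random from the pooled a+b promoters, re-executes the full
flexible-threshold optimisation and grouping on the permuted labels, and
counts the null groups whose optimum is equal to or better than the observed
group's.  The FDR is the mean count over runs (default 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .conservation import OrthologBundle
from .enrichment import (
    EnrichmentConfig,
    EnrichmentResult,
    build_hit_cache,
    evaluate_split,
    pool_entries,
    strip_arm_prefix,
    _as_models,
)
from .motifs import PromoterSet

__all__ = [
    "MotifGroup",
    "FdrEstimate",
    "AnalysisOutcome",
    "group_motifs",
    "resample_fdr",
    "analyze",
    "report_filter",
    "annotate_groups",
]


@dataclass
class MotifGroup:
    """A set of motifs hitting the same promoter locations."""

    group_id: int
    members: list[str]
    representative: str
    optimum: float
    member_values: dict[str, float] = field(default_factory=dict)
    annotation: str | None = None
    fdr: float | None = None


@dataclass
class FdrEstimate:
    group_id: int
    observed_optimum: float
    null_better_counts: list[int]
    fdr: float
    n_runs: int


@dataclass
class AnalysisOutcome:
    """Observed enrichment results, their groups, and group-wise FDRs."""

    results: list[EnrichmentResult]
    groups: list[MotifGroup]
    estimates: list[FdrEstimate]


def _hit_centers(result: EnrichmentResult) -> dict[str, np.ndarray]:
    by_prom: dict[str, list[int]] = {}
    for h in result.hits_at_best:
        by_prom.setdefault(h.promoter_id, []).append(h.center(result.motif_length))
    return {pid: np.sort(np.array(cs)) for pid, cs in by_prom.items()}


def _share_fraction(
    centers_a: dict[str, np.ndarray], centers_b: dict[str, np.ndarray], window_bp: int
) -> float:
    """Fraction of a's hit centres within window_bp of some b centre."""
    total = sum(len(v) for v in centers_a.values())
    if total == 0:
        return 0.0
    shared = 0
    for pid, ca in centers_a.items():
        cb = centers_b.get(pid)
        if cb is None or cb.size == 0:
            continue
        idx = np.searchsorted(cb, ca)
        left = np.abs(ca - cb[np.clip(idx - 1, 0, cb.size - 1)])
        right = np.abs(cb[np.clip(idx, 0, cb.size - 1)] - ca)
        shared += int(np.sum(np.minimum(left, right) <= window_bp))
    return shared / total


def group_motifs(
    results: Sequence[EnrichmentResult], window_bp: int = 4, frac: float = 0.5
) -> list[MotifGroup]:
    """Partition reported motifs into location groups (connected components).

    Only results with an admissible optimum participate.  Two motifs are
    directly related if >= ``frac`` of either one's hit centres lie within
    ``window_bp`` of a centre of the other on the same promoter; the pairwise
    relation is closed transitively.
    """
    reported = [r for r in results if r.best is not None]
    n = len(reported)
    centers = [_hit_centers(r) for r in reported]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if (
                _share_fraction(centers[i], centers[j], window_bp) >= frac
                or _share_fraction(centers[j], centers[i], window_bp) >= frac
            ):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    groups = []
    for gid, idxs in enumerate(sorted(comps.values(), key=lambda ix: min(ix))):
        members = [reported[i] for i in idxs]
        rep = max(members, key=lambda r: r.objective_value)
        group = MotifGroup(
            group_id=gid,
            members=[r.motif_id for r in members],
            representative=rep.motif_id,
            optimum=rep.objective_value,
            member_values={r.motif_id: r.objective_value for r in members},
        )
        for r in members:
            r.group_id = gid
        groups.append(group)
    return groups


def annotate_groups(
    groups: Iterable[MotifGroup],
    expression: dict[str, float],
    score_frac: float = 0.75,
) -> None:
    """Label each group with its highest-expressed member whose objective
    score is within ``score_frac`` of the group's top score (in place)."""
    for g in groups:
        eligible = [
            m
            for m in g.members
            if m in expression and g.member_values[m] >= score_frac * g.optimum
        ]
        if eligible:
            g.annotation = max(eligible, key=lambda m: expression[m])


def analyze(
    test: PromoterSet,
    control: PromoterSet,
    pwms: Iterable,
    bundles: Sequence[OrthologBundle] = (),
    config: EnrichmentConfig = EnrichmentConfig(),
    n_runs: int = 100,
    rng_seed: int = 0,
    group_window_bp: int = 4,
    group_frac: float = 0.5,
) -> AnalysisOutcome:
    """Observed enrichment + grouping + resampling group-wise FDR.

    Uses the first entry of any configured window/conservation grid (the FDR
    null must be computed under one fixed setting).  All randomness flows
    from ``rng_seed``.
    """
    if len(test) + len(control) < 2:
        raise ValueError("need at least 2 promoters in the pool")
    window = config.window_lengths[0]
    n_req = config.n_grid[0]
    t_win = test.truncate(window)
    c_win = control.truncate(window)
    pooled, test_ids, control_ids = pool_entries(t_win.entries, c_win.entries)
    models = _as_models(pwms)
    caches = [
        build_hit_cache(m, pooled, bundles, n_req, config.low_rate_per_kb)
        for m in models
    ]

    def evaluate(test_ids: list[str], control_ids: list[str]) -> list[EnrichmentResult]:
        out = []
        for m, cache in zip(models, caches):
            best, hits = evaluate_split(cache, test_ids, control_ids, config)
            hits = strip_arm_prefix(hits)
            out.append(
                EnrichmentResult(
                    motif_id=m.motif_id,
                    window=window,
                    n_required=n_req,
                    objective=config.objective,
                    best=best,
                    hits_at_best=hits,
                    motif_length=m.length,
                )
            )
        return out

    results = evaluate(test_ids, control_ids)
    groups = group_motifs(results, group_window_bp, group_frac)

    pool_ids = test_ids + control_ids
    a = len(test_ids)
    rng = np.random.default_rng(rng_seed)
    counts = np.zeros((len(groups), n_runs), dtype=int)
    for run in range(n_runs):
        perm = rng.permutation(pool_ids)
        null_results = evaluate(list(perm[:a]), list(perm[a:]))
        null_groups = group_motifs(null_results, group_window_bp, group_frac)
        null_optima = np.array([g.optimum for g in null_groups])
        for gi, g in enumerate(groups):
            counts[gi, run] = int(np.sum(null_optima >= g.optimum))
    estimates = []
    for gi, g in enumerate(groups):
        fdr = float(counts[gi].mean()) if n_runs > 0 else float("nan")
        g.fdr = fdr
        for r in results:
            if r.group_id == g.group_id:
                r.fdr = fdr
        estimates.append(
            FdrEstimate(
                group_id=g.group_id,
                observed_optimum=g.optimum,
                null_better_counts=counts[gi].tolist(),
                fdr=fdr,
                n_runs=n_runs,
            )
        )
    return AnalysisOutcome(results=results, groups=groups, estimates=estimates)


def resample_fdr(
    test: PromoterSet,
    control: PromoterSet,
    pwms: Iterable,
    bundles: Sequence[OrthologBundle] = (),
    config: EnrichmentConfig = EnrichmentConfig(),
    n_runs: int = 100,
    rng_seed: int = 0,
) -> list[FdrEstimate]:
    """Group-wise FDR estimates for the observed location groups."""
    return analyze(
        test, control, pwms, bundles, config, n_runs=n_runs, rng_seed=rng_seed
    ).estimates


def report_filter(items: Sequence, fdr_cut: float = 0.05) -> list:
    """Keep results/groups whose group-wise FDR is strictly below the cut."""
    return [x for x in items if x.fdr is not None and x.fdr < fdr_cut]
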