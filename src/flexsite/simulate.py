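"""Seeded synthetic promoter corpora, ortholog bundles and contrast tables.

Every generator is a pure function of its spec (including the seed), so the
same spec reproduces byte-identical output.  The generators emulate the
statistical structure the analysis assumes: background promoter sequence
(order-0 composition or order-1 Markov), planted motif occurrences at
per-kilobase Poisson rates, per-species site retention against background
divergence, and a 2-genotype x {uninjured, d1, d4, d14} expression design
with genes planted in known regulatory classes.  They do not emulate real
promoter features such as CpG islands, repeats, indel evolution or
phylogenetic tree structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CONTRAST_COLUMNS, TIMEPOINTS, benjamini_hochberg
from .conservation import OrthologBundle
from .motifs import ALPHABET, PositionFrequencyMatrix, PromoterSet, encode_sequence

__all__ = [
    "PlantSpec",
    "ConservationSpec",
    "ExpressionSpec",
    "SimulationSpec",
    "TruthTable",
    "builtin_pfms",
    "gen_promoters",
    "gen_ortholog_bundles",
    "gen_contrast_table",
    "worked_fixture",
    "WorkedFixture",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "N": "ACGT",
}

DEFAULT_SPECIES = ("rat", "guinea_pig", "rabbit", "human", "marmoset")


def _consensus_counts(
    consensus: str, dominants: Sequence[float] | None = None, total: int = 100
) -> np.ndarray:
    """Count matrix from an IUPAC consensus with per-column dominant
    frequencies (default 0.95 everywhere); non-dominant bases share the rest.

    Heterogeneous column sharpness (sharp core, softer flanks) mirrors real
    curated matrices and gives planted sites a graded score spectrum, which
    the flexible-threshold search needs to be non-degenerate.
    """
    L = len(consensus)
    if dominants is None:
        dominants = [0.95] * L
    if len(dominants) != L:
        raise ValueError("one dominant frequency per consensus position")
    counts = np.zeros((L, 4))
    for i, (letter, f) in enumerate(zip(consensus.upper(), dominants)):
        bases = _IUPAC[letter]
        strong = f * total / len(bases)
        weak = (1 - f) * total / (4 - len(bases))
        counts[i, :] = weak
        for b in bases:
            counts[i, ALPHABET.index(b)] = strong
    return counts


def builtin_pfms() -> dict[str, PositionFrequencyMatrix]:
    """A small built-in motif collection for simulations and examples.

    AP1 (TGASTCA) and CRE (TGACGTCA, the AP1 motif with one extra central
    base) plus a handful of unrelated decoys (SRF CArG box, CEBP, E-box,
    NF-kB, MEF2).  Column profiles follow the shape of curated matrices:
    near-deterministic cores flanked by softer edge positions.
    """
    consensi = {
        "AP1": ("TGASTCA", (0.83, 0.94, 0.99, 0.97, 0.99, 0.94, 0.83)),
        "CRE": ("TGACGTCA", (0.83, 0.94, 0.99, 0.96, 0.96, 0.99, 0.94, 0.83)),
        "SRF": ("CCWWWWWWGG", (0.85, 0.93, 0.9, 0.84, 0.8, 0.8, 0.84, 0.9, 0.93, 0.85)),
        "CEBP": ("TTGCGCAA", (0.8, 0.9, 0.96, 0.92, 0.92, 0.96, 0.9, 0.8)),
        "EBOX": ("CACGTG", (0.9, 0.96, 0.98, 0.98, 0.96, 0.9)),
        "NFKB": ("GGGACTTTCC", (0.88, 0.95, 0.96, 0.9, 0.8, 0.82, 0.88, 0.92, 0.95, 0.88)),
        "MEF2": ("CTAWWWWTAG", (0.85, 0.92, 0.9, 0.82, 0.8, 0.8, 0.82, 0.9, 0.92, 0.85)),
    }
    return {
        name: PositionFrequencyMatrix(
            motif_id=name, tf_name=name, source="CUSTOM",
            counts=_consensus_counts(cons, doms),
        )
        for name, (cons, doms) in consensi.items()
    }


@dataclass(frozen=True)
class PlantSpec:
    """How one motif is planted: independent per-kb rates per arm, plus an
    optional co-occurrence rule placing it near another motif's sites."""

    pfm: PositionFrequencyMatrix
    rate_test: float = 0.0       # sites per kb, test arm
    rate_control: float = 0.0    # sites per kb, control arm
    cooccur_with: str | None = None
    cooccur_dist: tuple[int, int] = (20, 80)  # bp between site edges
    cooccur_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_test < 0 or self.rate_control < 0:
            raise ValueError("plant rates must be >= 0")
        if not 0 <= self.cooccur_prob <= 1:
            raise ValueError("cooccur_prob must be in [0, 1]")


@dataclass(frozen=True)
class ConservationSpec:
    species: tuple[str, ...] = DEFAULT_SPECIES
    retention: float = 0.9       # P(planted site kept intact) per species
    divergence: float = 0.25     # per-base substitution rate elsewhere
    deletion_rate: float = 0.0   # per-base deletion rate outside sites

    def __post_init__(self) -> None:
        for p in (self.retention, self.divergence, self.deletion_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class ExpressionSpec:
    genes_per_class: int = 50
    effect: float = 2.0          # log2 fold-change magnitude
    residual_sd: float = 0.25
    replicates: int = 4
    baseline: float = 8.0        # mean log2 intensity


@dataclass(frozen=True)
class SimulationSpec:
    seed: int = 0
    n_test: int = 200
    n_control: int = 200
    promoter_length: int = 1000
    # base composition (4,) or order-1 transition matrix (4, 4);
    # default approximates mammalian promoter-region composition (~42% GC)
    background: tuple[float, ...] = (0.29, 0.21, 0.21, 0.29)
    plants: tuple[PlantSpec, ...] = ()
    conservation: ConservationSpec = field(default_factory=ConservationSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)


@dataclass
class TruthTable:
    """Planted ground truth: site coordinates and per-species conservation."""

    sites: pd.DataFrame  # arm, promoter_id, motif_id, start, end, strand
    conservation: pd.DataFrame | None = None  # site_index x species booleans

    def sites_for(self, promoter_id: str) -> pd.DataFrame:
        return self.sites[self.sites.promoter_id == promoter_id]

    def to_bed(self, handle) -> None:
        for _, r in self.sites.iterrows():
            handle.write(
                f"{r.promoter_id}\t{r.start}\t{r.end}\t{r.motif_id}\t0\t{r.strand}\n"
            )


def _sample_background(rng: np.random.Generator, length: int, background) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.ndim == 1:
        return rng.choice(4, size=length, p=bg / bg.sum()).astype(np.int8)
    # order-1 Markov chain; stationary start from row means
    trans = bg / bg.sum(axis=1, keepdims=True)
    out = np.empty(length, dtype=np.int8)
    out[0] = rng.choice(4, p=trans.mean(axis=0))
    # presample uniforms; step through cumulative rows
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i])
    return out


def _sample_site(rng: np.random.Generator, pfm: PositionFrequencyMatrix) -> np.ndarray:
    f = pfm.counts / pfm.counts.sum(axis=1, keepdims=True)
    return np.array([rng.choice(4, p=f[i]) for i in range(pfm.length)], dtype=np.int8)


_COMP_IDX = np.array([3, 2, 1, 0], dtype=np.int8)


def _place(
    occupied: list[tuple[int, int]], start: int, end: int
) -> bool:
    for lo, hi in occupied:
        if start < hi and lo < end:
            return False
    occupied.append((start, end))
    return True


def _decode(enc: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in enc)


def gen_promoters(
    spec: SimulationSpec,
) -> tuple[PromoterSet, PromoterSet, TruthTable]:
    """Generate test and control promoter sets with planted motif sites.

    Per promoter, the planted count of each motif is Poisson with mean
    rate x length; placements are non-overlapping (bounded retries) and each
    site sequence is sampled column-wise from the PFM frequencies, on a
    random strand.  Co-occurring motifs are placed at a random side and
    distance from each of their anchor's sites.
    """
    rng = np.random.default_rng(spec.seed)
    arms = {
        "test": [f"t{i:04d}" for i in range(spec.n_test)],
        "control": [f"c{i:04d}" for i in range(spec.n_control)],
    }
    entries: dict[str, list[tuple[str, str]]] = {"test": [], "control": []}
    truth_rows: list[dict] = []
    independent = [p for p in spec.plants if p.cooccur_with is None]
    dependent = [p for p in spec.plants if p.cooccur_with is not None]
    L = spec.promoter_length
    for arm, ids in arms.items():
        for pid in ids:
            seq = _sample_background(rng, L, spec.background)
            occupied: list[tuple[int, int]] = []
            planted_here: list[dict] = []

            def plant_one(ps: PlantSpec, start: int) -> bool:
                m = ps.pfm.length
                if start < 0 or start + m > L:
                    return False
                if not _place(occupied, start, start + m):
                    return False
                site = _sample_site(rng, ps.pfm)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    site = _COMP_IDX[site][::-1]
                seq[start : start + m] = site
                row = dict(
                    arm=arm, promoter_id=pid, motif_id=ps.pfm.motif_id,
                    start=start, end=start + m, strand=strand,
                )
                truth_rows.append(row)
                planted_here.append(row)
                return True

            for ps in independent:
                rate = ps.rate_test if arm == "test" else ps.rate_control
                count = rng.poisson(rate * L / 1000.0)
                for _ in range(count):
                    for _try in range(50):
                        start = int(rng.integers(0, L - ps.pfm.length + 1))
                        if plant_one(ps, start):
                            break
                    else:
                        raise RuntimeError(
                            f"could not place {ps.pfm.motif_id} site in {pid}: "
                            "planting rate too high for non-overlapping placement"
                        )
            for ps in dependent:
                anchors = [r for r in list(planted_here) if r["motif_id"] == ps.cooccur_with]
                for anchor in anchors:
                    if rng.random() >= ps.cooccur_prob:
                        continue
                    placed = False
                    for _try in range(50):
                        d = int(rng.integers(ps.cooccur_dist[0], ps.cooccur_dist[1] + 1))
                        if rng.random() < 0.5:
                            start = anchor["start"] - d - ps.pfm.length
                        else:
                            start = anchor["end"] + d
                        if plant_one(ps, start):
                            placed = True
                            break
                    # silently skip partners that cannot be placed near an
                    # anchor at the promoter edge
                rate = ps.rate_test if arm == "test" else ps.rate_control
                count = rng.poisson(rate * L / 1000.0)
                for _ in range(count):
                    for _try in range(50):
                        start = int(rng.integers(0, L - ps.pfm.length + 1))
                        if plant_one(ps, start):
                            break
            entries[arm].append((pid, _decode(seq)))
    sites = pd.DataFrame(
        truth_rows,
        columns=["arm", "promoter_id", "motif_id", "start", "end", "strand"],
    )
    return (
        PromoterSet(label="test", entries=entries["test"]),
        PromoterSet(label="control", entries=entries["control"]),
        TruthTable(sites=sites),
    )


def gen_ortholog_bundles(
    test: PromoterSet,
    control: PromoterSet,
    truth: TruthTable,
    spec: SimulationSpec,
) -> list[OrthologBundle]:
    """Pseudo-species ortholog bundles for every promoter of both arms.

    Each ortholog is the mouse sequence with independent per-base
    substitutions at the background divergence rate; each planted site window
    is kept fully intact with the retention probability, otherwise it
    diverges like background.  Position maps are identity unless a nonzero
    deletion rate introduces gaps outside site windows.  Per-site retention
    outcomes are recorded in ``truth.conservation``.
    """
    cons = spec.conservation
    rng = np.random.default_rng(spec.seed + 1_000_003)
    all_entries = list(test.entries) + list(control.entries)
    site_windows: dict[str, list[tuple[int, int, int]]] = {}
    for idx, r in truth.sites.iterrows():
        site_windows.setdefault(r.promoter_id, []).append((idx, r.start, r.end))
    retained: dict[str, list[bool]] = {sp: [False] * len(truth.sites) for sp in cons.species}
    bundles = []
    for sp in cons.species:
        seqs: dict[str, str] = {}
        maps: dict[str, dict[int, int] | None] = {}
        for pid, seq in all_entries:
            enc = encode_sequence(seq)
            n = len(enc)
            sub_mask = rng.random(n) < cons.divergence
            keep_site = np.zeros(n, dtype=bool)
            for idx, s, e in site_windows.get(pid, []):
                kept = rng.random() < cons.retention
                retained[sp][idx] = bool(kept)
                if kept:
                    keep_site[s:e] = True
            sub_mask &= ~keep_site
            orth = enc.copy()
            n_sub = int(sub_mask.sum())
            if n_sub:
                # substitute to a uniformly random *different* base
                shift = rng.integers(1, 4, size=n_sub).astype(np.int8)
                orth[sub_mask] = (orth[sub_mask] + shift) % 4
            if cons.deletion_rate > 0:
                del_mask = (rng.random(n) < cons.deletion_rate) & ~keep_site
                kept_idx = np.nonzero(~del_mask)[0]
                maps[pid] = {int(mp): i for i, mp in enumerate(kept_idx)}
                orth = orth[kept_idx]
            else:
                maps[pid] = None
            seqs[pid] = _decode(orth)
        bundles.append(OrthologBundle(species=sp, sequences=seqs, maps=maps))
    truth.conservation = pd.DataFrame(retained, index=truth.sites.index)
    return bundles


# ---------------------------------------------------------------------------
# expression design


_CLASS_PATTERNS = {
    # (wt injured delta, ko injured delta) in units of the effect size e;
    # uninjured means are the baseline for both genotypes
    "JunUP_complete": (1.0, 0.0),
    "JunUP_partial": (1.0, 0.5),
    "JunDOWN": (-1.0, 0.0),
    "AltUP": (0.0, 1.0),
    "AltDOWN": (0.0, -1.0),
    "none": (0.0, 0.0),
}


def gen_contrast_table(
    spec: SimulationSpec,
    classes: Sequence[str] = tuple(_CLASS_PATTERNS),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the 2-genotype x 4-group expression design and its contrasts.

    For every planted class the group means are placed so the class pattern
    clears the 1.5-fold / FDR 0.01 cuts with margin (given the default effect
    size 2.0 and residual sd 0.25 at 4 replicates).  Contrasts are computed
    with Welch two-sample t-tests and Benjamini-Hochberg adjustment per
    contrast, giving a long-format table with the columns the classifier
    consumes.  Returns (contrast_table, truth) where truth maps gene ->
    planted class.
    """
    ex = spec.expression
    if ex.replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = np.random.default_rng(spec.seed + 7_000_033)
    genes, gene_classes = [], []
    for cls in classes:
        if cls not in _CLASS_PATTERNS:
            raise ValueError(f"unknown class {cls!r}")
        for i in range(ex.genes_per_class):
            genes.append(f"{cls.lower()}_{i:03d}")
            gene_classes.append(cls)
    n_genes = len(genes)
    baselines = rng.normal(ex.baseline, 0.5, size=n_genes)
    groups = ["wt_0", "ko_0"] + [f"{g}_{t}" for t in TIMEPOINTS for g in ("wt", "ko")]
    data = {}
    for gi, (gene, cls) in enumerate(zip(genes, gene_classes)):
        d_wt, d_ko = _CLASS_PATTERNS[cls]
        means = {"wt_0": baselines[gi], "ko_0": baselines[gi]}
        for t in TIMEPOINTS:
            means[f"wt_{t}"] = baselines[gi] + d_wt * ex.effect
            means[f"ko_{t}"] = baselines[gi] + d_ko * ex.effect
        data[gene] = {
            g: rng.normal(means[g], ex.residual_sd, size=ex.replicates) for g in groups
        }
    rows = []
    for t in TIMEPOINTS:
        raw = {"wt": [], "ko_vs_wt": [], "ko": []}
        fcs = {"wt": [], "ko_vs_wt": [], "ko": []}
        for gene in genes:
            d = data[gene]
            pairs = {
                "wt": (d[f"wt_{t}"], d["wt_0"]),
                "ko_vs_wt": (d[f"ko_{t}"], d[f"wt_{t}"]),
                "ko": (d[f"ko_{t}"], d["ko_0"]),
            }
            for k, (x, y) in pairs.items():
                fcs[k].append(float(np.mean(x) - np.mean(y)))
                raw[k].append(float(stats.ttest_ind(x, y, equal_var=False).pvalue))
        fdrs = {k: benjamini_hochberg(v) for k, v in raw.items()}
        for gi, gene in enumerate(genes):
            max_expr = max(float(np.max(v)) for v in data[gene].values())
            rows.append(
                dict(
                    gene=gene, timepoint=t,
                    wt_log2fc=fcs["wt"][gi], wt_fdr=float(fdrs["wt"][gi]),
                    ko_vs_wt_log2fc=fcs["ko_vs_wt"][gi],
                    ko_vs_wt_fdr=float(fdrs["ko_vs_wt"][gi]),
                    ko_log2fc=fcs["ko"][gi], ko_fdr=float(fdrs["ko"][gi]),
                    max_expression=max_expr,
                )
            )
    table = pd.DataFrame(rows, columns=CONTRAST_COLUMNS)
    truth = pd.DataFrame({"gene": genes, "true_class": gene_classes})
    return table, truth


# ---------------------------------------------------------------------------
# worked fixture


@dataclass
class WorkedFixture:
    pfms: dict[str, PositionFrequencyMatrix]
    test: PromoterSet
    control: PromoterSet
    truth: TruthTable
    bundles: list[OrthologBundle]
    spec: SimulationSpec


def worked_fixture(seed: int = 20070) -> WorkedFixture:
    """The small deterministic bundle used by the oracle tests and examples.

    Three motifs (AP1-like, its CRE-like single-base-insertion variant, and
    an unrelated E-box decoy), 20 test + 20 control promoters of 500 bp, and
    two pseudo-species.  AP1 is planted at a higher rate in the test arm by
    construction; the E-box is never planted.
    """
    pfms = builtin_pfms()
    spec = SimulationSpec(
        seed=seed,
        n_test=20,
        n_control=20,
        promoter_length=500,
        plants=(
            PlantSpec(pfms["AP1"], rate_test=1.2, rate_control=0.1),
            PlantSpec(
                pfms["CRE"], rate_test=0.0, rate_control=0.1,
                cooccur_with="AP1", cooccur_prob=0.5,
            ),
        ),
        conservation=ConservationSpec(
            species=("pseudo1", "pseudo2"), retention=0.9, divergence=0.25
        ),
    )
    test, control, truth = gen_promoters(spec)
    bundles = gen_ortholog_bundles(test, control, truth, spec)
    return WorkedFixture(
        pfms={k: pfms[k] for k in ("AP1", "CRE", "EBOX")},
        test=test, control=control, truth=truth, bundles=bundles, spec=spec,
    )
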