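"""Regulatory-class gene classification from differential-expression contrasts.

Genes are classified per timepoint by (i) their wild-type response to injury
(up / down / none, at fold-change >= 1.5 and FDR < 0.01) and (ii) the effect
of the knockout (expression higher / lower / unchanged vs wild type, same
cuts), combined as:

    WT up,      KO lower   ->  JunUP      (Jun-dependent upregulation)
    WT down,    KO higher  ->  JunDOWN    (Jun-dependent downregulation)
    WT up/none, KO higher  ->  AltUP      (alternative / de novo upregulation)
    WT down/none, KO lower ->  AltDOWN
    anything else          ->  none

JunUP genes are further split into completely Jun-dependent (no residual
upregulation after injury in the knockout) and partially dependent (still
upregulated, but significantly less than wild type).

Fold-change cuts are compared on the log2 scale with an inclusive boundary:
log2FC exactly equal to log2(1.5) counts as regulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CONTRAST_COLUMNS",
    "GeneClassAssignment",
    "call_regulation",
    "classify_gene",
    "classify_table",
    "call_dependence",
    "select_control_genes",
    "benjamini_hochberg",
]

TIMEPOINTS = ("d1", "d4", "d14")

# long-format contrast table: one row per gene x timepoint
CONTRAST_COLUMNS = [
    "gene",
    "timepoint",
    "wt_log2fc",       # WT injured vs WT uninjured
    "wt_fdr",
    "ko_vs_wt_log2fc",  # KO injured vs WT injured at the same timepoint
    "ko_vs_wt_fdr",
    "ko_log2fc",       # KO injured vs KO uninjured
    "ko_fdr",
    "max_expression",  # max log2 array intensity across samples
]

_TABLE1 = {
    ("up", "lower"): "JunUP",
    ("down", "higher"): "JunDOWN",
    ("up", "higher"): "AltUP",
    ("none", "higher"): "AltUP",
    ("down", "lower"): "AltDOWN",
    ("none", "lower"): "AltDOWN",
}


@dataclass
class GeneClassAssignment:
    gene: str
    timepoint: str
    wt_direction: str   # up / down / none
    ko_relative: str    # higher / lower / none
    gene_class: str     # JunUP / JunDOWN / AltUP / AltDOWN / none
    dependence: str     # complete / partial / NA
    missing_data: bool = False


def call_regulation(
    log2fc: float, fdr: float, fc_cut: float = 1.5, fdr_cut: float = 0.01
) -> str:
    """'up', 'down' or 'none' under the fold-change and FDR cuts (inclusive
    fold-change boundary)."""
    if fc_cut <= 1:
        raise ValueError("fc_cut must be > 1")
    if np.isnan(log2fc) or np.isnan(fdr):
        return "none"
    lcut = np.log2(fc_cut)
    if fdr < fdr_cut:
        if log2fc >= lcut:
            return "up"
        if log2fc <= -lcut:
            return "down"
    return "none"


def classify_gene(
    row: pd.Series | dict, fc_cut: float = 1.5, fdr_cut: float = 0.01
) -> GeneClassAssignment:
    """Classify one gene at one timepoint from its contrast row.

    Needs wt_log2fc/wt_fdr (injury response) and ko_vs_wt_log2fc/ko_vs_wt_fdr
    (genotype effect); ko_log2fc/ko_fdr are used for the dependence call when
    the class is JunUP.  Missing contrasts give class 'none' with a flag.
    """
    get = row.get if hasattr(row, "get") else row.__getitem__
    wt_fc, wt_fdr = get("wt_log2fc"), get("wt_fdr")
    g_fc, g_fdr = get("ko_vs_wt_log2fc"), get("ko_vs_wt_fdr")
    missing = any(
        v is None or (isinstance(v, float) and np.isnan(v))
        for v in (wt_fc, wt_fdr, g_fc, g_fdr)
    )
    if missing:
        return GeneClassAssignment(
            gene=str(get("gene")), timepoint=str(get("timepoint")),
            wt_direction="none", ko_relative="none", gene_class="none",
            dependence="NA", missing_data=True,
        )
    wt_dir = call_regulation(wt_fc, wt_fdr, fc_cut, fdr_cut)
    g_dir = call_regulation(g_fc, g_fdr, fc_cut, fdr_cut)
    ko_rel = {"up": "higher", "down": "lower", "none": "none"}[g_dir]
    gene_class = _TABLE1.get((wt_dir, ko_rel), "none")
    dependence = "NA"
    if gene_class == "JunUP":
        ko_fc, ko_fdr = get("ko_log2fc"), get("ko_fdr")
        if ko_fc is not None and not (isinstance(ko_fc, float) and np.isnan(ko_fc)):
            ko_up = call_regulation(ko_fc, ko_fdr, fc_cut, fdr_cut) == "up"
            dependence = "partial" if ko_up else "complete"
    return GeneClassAssignment(
        gene=str(get("gene")), timepoint=str(get("timepoint")),
        wt_direction=wt_dir, ko_relative=ko_rel, gene_class=gene_class,
        dependence=dependence,
    )


def call_dependence(
    assignment: GeneClassAssignment,
    ko_row: pd.Series | dict,
    fc_cut: float = 1.5,
    fdr_cut: float = 0.01,
    across_timepoints: Sequence[pd.Series | dict] = (),
) -> tuple[str, bool]:
    """Jun-dependence of a JunUP gene: 'complete' if the knockout shows no
    residual injury-induced upregulation at this timepoint, else 'partial'.

    Returns (dependence, timecourse_complete) where the flag is True when the
    knockout is never upregulated at *any* supplied timepoint.
    """
    if assignment.gene_class != "JunUP":
        raise ValueError("dependence is defined only for JunUP genes")
    get = ko_row.get if hasattr(ko_row, "get") else ko_row.__getitem__
    ko_up = call_regulation(get("ko_log2fc"), get("ko_fdr"), fc_cut, fdr_cut) == "up"
    dependence = "partial" if ko_up else "complete"
    never_up = not ko_up
    for r in across_timepoints:
        g = r.get if hasattr(r, "get") else r.__getitem__
        if call_regulation(g("ko_log2fc"), g("ko_fdr"), fc_cut, fdr_cut) == "up":
            never_up = False
    return dependence, never_up


def classify_table(
    table: pd.DataFrame, fc_cut: float = 1.5, fdr_cut: float = 0.01
) -> pd.DataFrame:
    """Classify every gene x timepoint row of a long-format contrast table.

    Adds a per-gene ``timecourse_complete`` flag: JunUP at some timepoint and
    never upregulated in the knockout at any timepoint.
    """
    assignments = [classify_gene(row, fc_cut, fdr_cut) for _, row in table.iterrows()]
    out = table.copy()
    out["gene_class"] = [a.gene_class for a in assignments]
    out["dependence"] = [a.dependence for a in assignments]
    out["missing_data"] = [a.missing_data for a in assignments]
    ko_up = [
        call_regulation(r.get("ko_log2fc", np.nan), r.get("ko_fdr", np.nan), fc_cut, fdr_cut) == "up"
        for _, r in table.iterrows()
    ]
    out["_ko_up"] = ko_up
    per_gene = out.groupby("gene").agg(
        any_junup=("gene_class", lambda s: (s == "JunUP").any()),
        ever_ko_up=("_ko_up", "any"),
    )
    flag = per_gene["any_junup"] & ~per_gene["ever_ko_up"]
    out["timecourse_complete"] = out["gene"].map(flag)
    return out.drop(columns=["_ko_up"])


def select_control_genes(
    table: pd.DataFrame,
    fc_genotype_max: float = 1.3,
    min_expr: float = 7.0,
    fc_cut: float = 1.5,
    fdr_cut: float = 0.01,
) -> list[str]:
    """Genes suitable as unregulated controls for the promoter analysis.

    Requires, at every timepoint: no significant knockout effect, a genotype
    fold change below ``fc_genotype_max``; and a maximum expression level
    above ``min_expr`` (to exclude promoters likely buried in
    heterochromatin).
    """
    lcut = np.log2(fc_genotype_max)
    keep = []
    for gene, sub in table.groupby("gene", sort=True):
        sig = any(
            call_regulation(r["ko_vs_wt_log2fc"], r["ko_vs_wt_fdr"], fc_cut, fdr_cut) != "none"
            for _, r in sub.iterrows()
        )
        if sig:
            continue
        if (sub["ko_vs_wt_log2fc"].abs() >= lcut).any():
            continue
        if not (sub["max_expression"] > min_expr).all():
            continue
        keep.append(gene)
    return keep


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
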