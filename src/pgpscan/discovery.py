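"""Sliding-window CRM discovery over a gene's control region.

A control region is tiled with 1 Kbp windows; each window is scored for
every TF motif, its activity profile predicted with the trained
expression model (using a window-level baseline, since scan windows
have no trained per-CRM baseline), and the prediction compared to the
gene's endogenous pattern with the PGP score (with domain subset
selection).  Statistical significance comes from an empirical p-value
against a null set of window PGP scores from a background (in
production, genome-wide, exon-masked) scan; windows without
above-average binding-site presence for at least one activator are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import AxisProfile, GenomicInterval, MotifModel
from .hmm import crm_motif_score
from .model import ExpressionModel, predict_expression
from .pgp import select_domains

P_THRESHOLD_DEFAULT = 0.015


@dataclass
class CRMPrediction:
    interval: GenomicInterval
    predicted: AxisProfile
    pgp: float
    gene: str = ""
    empirical_p: float = float("nan")
    filters_passed: dict[str, bool] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)
    selected_domains: list[tuple[int, int]] = field(default_factory=list)

    def passes_filters(self) -> bool:
        return all(self.filters_passed.values())


def scan_locus(
    gene_expr: AxisProfile,
    control_region: str,
    model: ExpressionModel,
    motifs: Mapping[str, MotifModel],
    concentrations,
    window: int = 1000,
    step: int = 500,
    gene: str = "",
    seq_id: str = "locus",
    alpha: float | None = None,
) -> list[CRMPrediction]:
    """Score every window of a control region for pattern-generating
    potential against the gene's expression pattern.

    Returns predictions sorted by PGP, best first.  ``alpha`` defaults
    to the mean of the model's trained baselines.
    """
    if gene_expr.kind != "binary":
        raise ValueError("gene expression profile must be binary")
    if not np.any(gene_expr.values):
        raise ValueError("gene expression pattern is all-zero")
    L = len(control_region)
    if L < window:
        raise ValueError("control region shorter than one window")
    if alpha is None:
        alpha = model.mean_baseline()
    out = []
    for start in range(0, L - window + 1, step):
        seq = control_region[start : start + window]
        s_row = {tf: crm_motif_score(seq, m) for tf, m in motifs.items()}
        pred = predict_expression(
            model, None, s_row, concentrations, alpha=alpha,
            label=f"{gene}:{start}",
        )
        _, res = select_domains(pred, gene_expr)
        out.append(
            CRMPrediction(
                interval=GenomicInterval(seq_id, start, start + window),
                predicted=pred,
                pgp=res.pgp,
                gene=gene,
                scores=s_row,
                selected_domains=res.selected_domains,
            )
        )
    out.sort(key=lambda p: (-p.pgp, p.interval.start))
    return out


def empirical_pvalue(pgp_value: float, null_scores) -> float:
    """Add-one empirical p-value: (1 + #{null >= x}) / (1 + N).

    Never 0, and uniform on (0, 1] when the score is drawn from the
    null distribution itself.
    """
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise ValueError("empty null score set")
    return float((1 + np.sum(null >= pgp_value)) / (1 + null.size))


def assign_pvalues(
    predictions: Sequence[CRMPrediction], null_scores
) -> list[CRMPrediction]:
    for p in predictions:
        p.empirical_p = empirical_pvalue(p.pgp, null_scores)
    return list(predictions)


def activator_filter(
    window_scores: Mapping[str, float], activators: Sequence[str]
) -> bool:
    """True iff any listed activator has above-average site presence
    (genomic z-score > 0) in the window."""
    if not activators:
        raise ValueError("empty activator list")
    return any(window_scores.get(a, float("-inf")) > 0 for a in activators)


def call_crms(
    predictions: Sequence[CRMPrediction],
    p_threshold: float = P_THRESHOLD_DEFAULT,
    overlap_merge: bool = True,
) -> list[CRMPrediction]:
    """Retain windows under the p-value threshold that pass all filters,
    merging overlapping windows and keeping the best-p representative."""
    kept = [
        p for p in predictions
        if p.empirical_p < p_threshold and p.passes_filters()
    ]
    if not overlap_merge:
        return sorted(kept, key=lambda p: p.empirical_p)
    kept.sort(key=lambda p: (p.interval.seq_id, p.interval.start))
    clusters: list[list[CRMPrediction]] = []
    for p in kept:
        if (
            clusters
            and clusters[-1][-1].interval.seq_id == p.interval.seq_id
            and p.interval.start < max(c.interval.end for c in clusters[-1])
        ):
            clusters[-1].append(p)
        else:
            clusters.append([p])
    calls = [
        min(c, key=lambda p: (p.empirical_p, -p.pgp, p.interval.start))
        for c in clusters
    ]
    calls.sort(key=lambda p: p.empirical_p)
    return calls


def sibling_enrichment(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency of CRM classes
    (e.g. real/random x solitary/redundant)."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be nonnegative integers")
    if (a + b == 0 or c + d == 0) and (a + c == 0 or b + d == 0):
        raise ValueError("degenerate contingency table")
    return float(stats.fisher_exact([[a, b], [c, d]])[1])
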