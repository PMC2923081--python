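"""TF-CRM regulatory edge inference and occupancy evaluation.

An edge from a TF to a CRM is called when randomly permuting the TF's
100-bin concentration profile rarely yields a prediction as close to
the target pattern as the wild-type profile does: the wild-type RMSE is
compared against the null RMSE distribution from (default) 1,000
permutations, with an add-one empirical p-value that counts ties as
extreme.  A TF with zero motif score in the CRM cannot influence the
prediction, every permutation reproduces the wild-type RMSE exactly and
the p-value is 1 - such a TF never earns an edge.  Edge direction
(activation vs repression) follows the sign of the fitted weight.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AxisProfile
from .hmm import categorize
from .model import ExpressionModel, _conc_frame, sigmoid, term_name

# Repressor expression domains on the 100-bin A/P axis (1-based,
# inclusive) used for incongruous-occupancy classification.
DEFAULT_REPRESSOR_DOMAINS: dict[str, list[tuple[int, int]]] = {
    "GT": [(20, 40), (70, 80)],
    "KR": [(40, 60)],
    "KNI": [(60, 70)],
}


@dataclass
class EdgeTest:
    tf: str
    crm: str
    rmse_wt: float
    null_rmse: np.ndarray
    p: float
    sign: str  # "activator" | "repressor"


def _pair_rng(seed: int, tf: str, crm: str) -> np.random.Generator:
    """Independent, reproducible RNG stream per (tf, crm) pair."""
    tag = zlib.crc32(f"{tf}|{crm}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def edge_pvalue(
    model: ExpressionModel,
    crm: str,
    tf: str,
    s_row: Mapping[str, float],
    concentrations,
    target: AxisProfile,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float | None = None,
) -> EdgeTest:
    """Permutation test of one TF's contribution to one CRM's pattern.

    p = (1 + #{null RMSE <= wild-type RMSE}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if target.kind != "binary":
        raise ValueError("target must be a binary profile")
    conc = _conc_frame(concentrations)
    if tf not in conc.index:
        raise KeyError(f"unknown TF {tf!r}")
    if alpha is None:
        alpha = model.baselines[crm]
    y = target.values
    n_bins = conc.shape[1]
    # split the linear predictor into tf-dependent and constant parts
    c_tf = conc.loc[tf].to_numpy()
    eta_other = np.full(n_bins, float(alpha))
    w1 = w2 = 0.0
    for t in model.covariate_spec:
        nm = term_name(t["tf"], t["order"])
        w = model.tf_weights.get(nm, 0.0)
        if t["tf"] == tf:
            if t["order"] == 1:
                w1 = w
            else:
                w2 = w
        else:
            cov = conc.loc[t["tf"]].to_numpy() * float(s_row[t["tf"]])
            eta_other += w * cov ** t["order"]
    s = float(s_row[tf])

    def rmse_for(c_rows: np.ndarray) -> np.ndarray:
        cov = c_rows * s
        eta = eta_other[None, :] + w1 * cov + w2 * cov**2
        mu = sigmoid(eta)
        return np.sqrt(np.mean((mu - y[None, :]) ** 2, axis=1))

    rmse_wt = float(rmse_for(c_tf[None, :])[0])
    rng = _pair_rng(seed, tf, crm)
    perms = np.empty((n_perm, n_bins))
    for i in range(n_perm):
        perms[i] = c_tf[rng.permutation(n_bins)]
    null = rmse_for(perms)
    p = float((1 + np.sum(null <= rmse_wt)) / (1 + n_perm))
    w_eff = w1 if w1 != 0 else w2
    return EdgeTest(
        tf=tf,
        crm=crm,
        rmse_wt=rmse_wt,
        null_rmse=null,
        p=p,
        sign="activator" if w_eff > 0 else "repressor",
    )


def build_network(
    model: ExpressionModel,
    S: pd.DataFrame,
    concentrations,
    targets: Mapping[str, AxisProfile],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    tfs: Sequence[str] | None = None,
) -> list[EdgeTest]:
    """Edge tests for all TF x CRM pairs; returns the significant edges
    (p < alpha) with their regulatory signs."""
    if tfs is None:
        tfs = list(S.columns)
    edges = []
    for crm in S.index:
        s_row = S.loc[crm].to_dict()
        for tf in tfs:
            t = edge_pvalue(
                model, str(crm), tf, s_row, concentrations,
                targets[crm], n_perm=n_perm, seed=seed,
            )
            if t.p < alpha:
                edges.append(t)
    return edges


def edges_to_frame(edges: Sequence[EdgeTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"tf": e.tf, "crm": e.crm, "p": e.p, "sign": e.sign,
             "rmse_wt": e.rmse_wt}
            for e in edges
        ]
    )


def chip_discrimination(bound_scores, random_scores) -> float:
    """One-sided Wilcoxon rank-sum p-value that motif scores of
    ChIP-bound regions are stochastically greater than those of random
    length-matched regions."""
    bound = np.asarray(bound_scores, dtype=float)
    rand = np.asarray(random_scores, dtype=float)
    if bound.size == 0 or rand.size == 0:
        raise ValueError("empty score set")
    return float(
        stats.mannwhitneyu(bound, rand, alternative="greater").pvalue
    )


def positional_motif_summary(
    scores: Mapping[str, float],
    activity: Mapping[str, AxisProfile],
    concentration: AxisProfile,
) -> tuple[np.ndarray, float]:
    """Mean motif score of the CRMs active at each axis position, and
    its Pearson correlation with the TF concentration profile.

    Activators show positive correlation (their sites concentrate in
    CRMs active where the TF is present); repressors show
    anti-correlation.  Bins with no active CRM are NaN; a constant score
    vector has undefined correlation (NaN).
    """
    n_bins = len(concentration.values)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for crm, prof in activity.items():
        on = np.asarray(prof.values) == 1
        sums[on] += float(scores[crm])
        counts[on] += 1
    if not counts.any():
        raise ValueError("no active CRMs in any bin")
    with np.errstate(invalid="ignore"):
        mean_vec = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    ok = counts > 0
    v = mean_vec[ok]
    c = concentration.values[ok]
    if np.std(v) == 0 or np.std(c) == 0:
        return mean_vec, float("nan")
    return mean_vec, float(np.corrcoef(v, c)[0, 1])


def incongruous_occupancy(
    activity: AxisProfile,
    occupancy: Mapping[str, bool],
    motif_z: Mapping[str, float],
    repressor_domains: Mapping[str, list[tuple[int, int]]] | None = None,
) -> dict[str, dict]:
    """Classify repressor occupancy of a CRM as incongruous or not.

    Occupancy of a repressor is "incongruous" when the CRM's activity
    domain overlaps the repressor's own expression domain (where the
    bound repressor should shut the CRM off) AND the ChIP occupancy flag
    is set.  Each case is annotated with the motif support category for
    the repressor (significant z > 2, weak z > 0, absent otherwise).
    """
    if repressor_domains is None:
        repressor_domains = DEFAULT_REPRESSOR_DOMAINS
    if activity.kind != "binary":
        raise ValueError("CRM activity must be a binary profile")
    act = np.asarray(activity.values) == 1
    out = {}
    for tf, flag in occupancy.items():
        if tf not in repressor_domains:
            raise KeyError(f"unknown repressor {tf!r}")
        dom = np.zeros(len(act), dtype=bool)
        for lo, hi in repressor_domains[tf]:
            dom[lo - 1 : hi] = True
        overlap = bool(np.any(act & dom))
        out[tf] = {
            "incongruous": bool(flag) and overlap,
            "overlaps_domain": overlap,
            "motif_support": categorize(float(motif_z[tf])),
        }
    return out
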