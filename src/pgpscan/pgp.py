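"""The pattern generating potential (PGP) score.

PGP measures how well a predicted activity profile (continuous, 100
bins) matches a gene's endogenous binary expression pattern.  The
reward term is the mean predicted activity over expressed bins, the
penalty term the mean over non-expressed bins, and

    PGP = 0.5 + 0.5 * (reward - penalty_weight * penalty),

with the penalty weighted three times as heavily as the reward by
default; the linear rescaling places the score in [-1, 1], with 1 a
perfect match.  For genes with several expression domains, a subset of
domains is selected to best match the prediction, so that a CRM driving
only a sub-domain of the pattern is not penalized for the domains it
does not drive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import AxisProfile

PENALTY_WEIGHT = 3.0


@dataclass
class PGPResult:
    reward: float
    penalty: float
    pgp: float
    selected_domains: list[tuple[int, int]] = field(default_factory=list)


def pgp(
    predicted: AxisProfile,
    endogenous: AxisProfile,
    penalty_weight: float = PENALTY_WEIGHT,
    mask: np.ndarray | None = None,
) -> PGPResult:
    """PGP of a predicted profile against a binary endogenous profile.

    ``mask`` (boolean, optional) restricts the evaluation to a subset of
    bins; masked-out bins count toward neither reward nor penalty.  The
    endogenous profile must contain at least one expressed and one
    non-expressed bin within the mask.
    """
    if endogenous.kind != "binary":
        raise ValueError("endogenous profile must be binary")
    pred = np.asarray(predicted.values, dtype=float)
    e = np.asarray(endogenous.values, dtype=float)
    if len(pred) != len(e):
        raise ValueError("profiles must have equal length")
    if mask is None:
        mask = np.ones(len(e), dtype=bool)
    on = mask & (e == 1)
    off = mask & (e == 0)
    if not on.any():
        raise ValueError("endogenous profile has no expression bins")
    if not off.any():
        raise ValueError("endogenous profile has no non-expression bins")
    reward = float(pred[on].mean())
    penalty = float(pred[off].mean())
    score = 0.5 + 0.5 * (reward - penalty_weight * penalty)
    doms = AxisProfile((e * mask).astype(float), "binary").domains()
    return PGPResult(reward=reward, penalty=penalty, pgp=score,
                     selected_domains=doms)


def select_domains(
    predicted: AxisProfile,
    endogenous: AxisProfile,
    penalty_weight: float = PENALTY_WEIGHT,
    max_exhaustive: int = 12,
) -> tuple[AxisProfile, PGPResult]:
    """Best-matching subset of the endogenous expression domains.

    The endogenous profile is decomposed into maximal runs of expressed
    bins (domains).  For each candidate non-empty subset, PGP is
    evaluated with the *unselected* domains' bins excluded from both
    terms ("don't care"); the subset maximizing PGP is returned
    (exhaustive for up to ``max_exhaustive`` domains, greedy add-one
    beyond).  Ties prefer fewer domains, then the anterior-most.
    Returns the reduced endogenous profile (selected domains only) and
    the winning PGP result.
    """
    doms = endogenous.domains()
    if not doms:
        raise ValueError("endogenous profile has no expression domains")
    e = np.asarray(endogenous.values, dtype=float)

    def eval_subset(subset):
        mask = np.ones(len(e), dtype=bool)
        for k, (lo, hi) in enumerate(doms):
            if k not in subset:
                mask[lo - 1 : hi] = False
        return pgp(predicted, endogenous, penalty_weight, mask=mask)

    def key(subset):
        # tie-break: fewer domains first, then anterior-most start bins
        return (len(subset), tuple(doms[k][0] for k in sorted(subset)))

    if len(doms) <= max_exhaustive:
        candidates = []
        for r in range(1, len(doms) + 1):
            candidates.extend(itertools.combinations(range(len(doms)), r))
        candidates.sort(key=key)
        best, best_res = None, None
        for subset in candidates:
            res = eval_subset(subset)
            if best_res is None or res.pgp > best_res.pgp + 1e-12:
                best, best_res = subset, res
    else:
        # greedy: start from the single best domain, add while improving
        singles = sorted(
            range(len(doms)),
            key=lambda k: (-eval_subset((k,)).pgp, doms[k][0]),
        )
        best = (singles[0],)
        best_res = eval_subset(best)
        remaining = [k for k in singles[1:]]
        improved = True
        while improved and remaining:
            improved = False
            for k in list(remaining):
                trial = tuple(sorted(best + (k,)))
                res = eval_subset(trial)
                if res.pgp > best_res.pgp + 1e-12:
                    best, best_res = trial, res
                    remaining.remove(k)
                    improved = True
                    break
    reduced = np.zeros(len(e))
    for k in best:
        lo, hi = doms[k]
        reduced[lo - 1 : hi] = 1.0
    best_res.selected_domains = [doms[k] for k in sorted(best)]
    return (
        AxisProfile(reduced, "binary", endogenous.label),
        best_res,
    )
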