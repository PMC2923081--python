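"""Probabilistic window scoring of sequences against a PWM.

The scorer follows the two-state construction used by HMM-based motif
cluster programs: a sequence is generated left to right, and at each
decision point the process either emits one base from an order-0
background (probability ``1 - q``) or emits a full motif occurrence of
width W from the PWM on the forward or reverse strand (probability
``q/2`` each).  The window score is the log-likelihood ratio of this
model against the background-only model (``q = 0``); it aggregates both
weak and strong matches rather than counting sites above a threshold.

When ``fit_transition`` is set, the motif-entry probability q is chosen
by maximum likelihood over ``[0, q_max]``; because q = 0 is admissible
the fitted score is always >= 0.  All arithmetic is performed in log
space on likelihood *ratios* relative to the background model, so there
is no underflow for long windows.

N bases are emitted with probability 1 under both states and therefore
contribute nothing to the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenomicInterval, MotifModel

Q_MAX_DEFAULT = 0.1
_CODE = np.full(256, 4, dtype=np.int64)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i


@dataclass
class MotifProfile:
    """Per-window motif scores along a sequence for one TF."""

    tf_name: str
    windows: list[GenomicInterval]
    scores: np.ndarray
    species: str = ""
    z: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.windows):
            raise ValueError("scores and windows must align")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        widths = {len(w) for w in self.windows}
        if len(widths) > 1:
            raise ValueError("windows must have uniform width")
        starts = [w.start for w in self.windows]
        if starts != sorted(starts):
            raise ValueError("windows must be sorted")


def encode_sequence(sequence: str) -> np.ndarray:
    """Map A,C,G,T,N -> 0..4 (anything else rejected upstream)."""
    return _CODE[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]


def _site_logodds(codes: np.ndarray, motif: MotifModel) -> np.ndarray:
    """log-sum of forward+reverse site likelihood ratios at each start.

    Returns ``lm`` of length L-W+1 with
    ``lm[s] = log( LR_fwd(s) + LR_rev(s) )`` where LR is the PWM/background
    likelihood ratio of the W-mer starting at s.  N positions contribute 0.
    """
    W = motif.width
    L = len(codes)
    with np.errstate(divide="ignore"):
        lf = np.log(motif.freq_matrix) - np.log(motif.background)[None, :]
        lr = np.log(motif.reverse_complement()) - np.log(motif.background)[None, :]
    # pad with a zero row for N (code 4)
    Mf = np.vstack([lf.T, np.zeros((1, W))])  # (5, W)
    Mr = np.vstack([lr.T, np.zeros((1, W))])
    wins = np.lib.stride_tricks.sliding_window_view(codes, W)  # (L-W+1, W)
    cols = np.arange(W)
    sf = Mf[wins, cols].sum(axis=1)
    sr = Mr[wins, cols].sum(axis=1)
    return np.logaddexp(sf, sr)


def _forward_llr(lm: np.ndarray, L: int, W: int, qs: np.ndarray) -> np.ndarray:
    """Forward-algorithm log-likelihood ratio at each q, vectorized over q.

    ``g[j]`` is log P(first j bases | model with entry prob q) minus
    log P(first j bases | background only); recursion:
    ``g[j] = logaddexp(g[j-1] + log(1-q), g[j-W] + log(q/2) + lm[j-W])``.
    """
    qs = np.asarray(qs, dtype=float)
    with np.errstate(divide="ignore"):
        log1mq = np.log1p(-qs)
        lq2 = np.log(qs / 2.0)
    g = np.zeros((L + 1, len(qs)))
    for j in range(1, L + 1):
        bg = g[j - 1] + log1mq
        if j >= W:
            g[j] = np.logaddexp(bg, g[j - W] + lq2 + lm[j - W])
        else:
            g[j] = bg
    return g[L]


def window_hmm_score(
    sequence: str,
    motif: MotifModel,
    fit_transition: bool = True,
    q: float | None = None,
    q_max: float = Q_MAX_DEFAULT,
    n_grid: int = 32,
    refine: int = 2,
) -> float:
    """Log-likelihood-ratio motif score of one sequence window.

    With ``fit_transition`` (default) q is profiled out by maximum
    likelihood over ``[0, q_max]`` (coarse log grid plus local
    refinement); since q=0 reproduces the null, the score is >= 0.
    With ``fit_transition=False`` the score is evaluated at the given q
    and may be negative.
    """
    W = motif.width
    L = len(sequence)
    if L < W:
        raise ValueError(
            f"sequence length {L} is shorter than motif width {W}"
        )
    codes = encode_sequence(sequence)
    lm = _site_logodds(codes, motif)
    if not fit_transition:
        if q is None:
            raise ValueError("fixed-q scoring requires q")
        if not (0 <= q < 1):
            raise ValueError("q must lie in [0, 1)")
        return float(_forward_llr(lm, L, W, np.array([q]))[0])
    qs = np.concatenate([[0.0], np.geomspace(1e-4, q_max, n_grid - 1)])
    ll = _forward_llr(lm, L, W, qs)
    for _ in range(refine):
        k = int(np.argmax(ll))
        lo = qs[max(k - 1, 0)]
        hi = qs[min(k + 1, len(qs) - 1)]
        if hi <= lo:
            break
        sub = np.linspace(lo, hi, 11)[1:-1]
        ll_sub = _forward_llr(lm, L, W, sub)
        qs = np.concatenate([qs, sub])
        ll = np.concatenate([ll, ll_sub])
        order = np.argsort(qs)
        qs, ll = qs[order], ll[order]
    return float(max(ll.max(), 0.0))


def profile_sequence(
    sequence: str,
    motif: MotifModel,
    window: int = 500,
    shift: int = 250,
    seq_id: str = "seq",
    species: str = "",
    fit_transition: bool = True,
    q: float | None = None,
) -> MotifProfile:
    """Tile a sequence with fixed windows and score each one.

    The final partial window is dropped; a 2,000 bp sequence at
    window=500, shift=250 yields 7 windows.
    """
    if window < motif.width:
        raise ValueError("window must be at least the motif width")
    if shift < 1:
        raise ValueError("shift must be positive")
    L = len(sequence)
    if L < window:
        raise ValueError("sequence shorter than one window")
    windows, scores = [], []
    for start in range(0, L - window + 1, shift):
        sub = sequence[start : start + window]
        windows.append(GenomicInterval(seq_id, start, start + window))
        scores.append(
            window_hmm_score(sub, motif, fit_transition=fit_transition, q=q)
        )
    return MotifProfile(
        tf_name=motif.name or "motif",
        windows=windows,
        scores=np.array(scores),
        species=species,
    )


def crm_motif_score(crm_sequence: str, motif: MotifModel, **kwargs) -> float:
    """Whole-window motif score of a CRM (the S_{i,l} of the expression
    model): the ML-fitted HMM score of the entire CRM sequence."""
    if len(crm_sequence) == 0:
        raise ValueError("empty CRM sequence")
    return window_hmm_score(crm_sequence, motif, fit_transition=True, **kwargs)


def standardize_scores(profile: MotifProfile) -> MotifProfile:
    """Z-score a profile against its own (genome-wide) mean and SD.

    Uses the population SD over all windows.  Categories derived from z:
    significant (z > 2), weak (0 < z <= 2), absent (z <= 0).
    """
    if len(profile.scores) < 2:
        raise ValueError("need at least 2 windows to standardize")
    mu = profile.scores.mean()
    sd = profile.scores.std()
    if sd == 0:
        raise ValueError("zero variance across windows")
    return MotifProfile(
        tf_name=profile.tf_name,
        windows=list(profile.windows),
        scores=profile.scores.copy(),
        species=profile.species,
        z=(profile.scores - mu) / sd,
    )


def categorize(z: float) -> str:
    """Motif-support category from a genomic z-score."""
    if z > 2:
        return "significant"
    if z > 0:
        return "weak"
    return "absent"
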