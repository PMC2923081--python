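"""Core domain types for axis profiles, motifs and genomic intervals.

The anterior-posterior (A/P) axis of the embryo is discretized into 100
equal bins, bin 1 being the most anterior.  Expression patterns (binary),
predicted CRM activities (continuous in (0,1)) and TF concentration
profiles (continuous in [0,1]) all live on this axis and are represented
by :class:`AxisProfile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

N_BINS = 100

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class AxisProfile:
    """A vector of values along the A/P axis.

    Parameters
    ----------
    values : array-like, length ``n_bins`` (default 100)
        Bin 1 (index 0) is the most anterior position.
    kind : {"binary", "continuous"}
        Binary profiles hold endogenous expression domains (0/1);
        continuous profiles hold concentrations or predicted activity
        in [0, 1].
    label : str
        Free-text identifier (gene, CRM or TF name).
    """

    values: np.ndarray
    kind: str
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("AxisProfile values must be 1-D")
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.kind == "binary":
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                raise ValueError("binary profile may contain only 0/1 values")
        else:
            if not np.all(np.isfinite(self.values)):
                raise ValueError("continuous profile must be finite")
            if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
                raise ValueError("continuous profile values must lie in [0, 1]")

    def __len__(self):
        return len(self.values)

    def domains(self) -> list[tuple[int, int]]:
        """Maximal runs of 1s, as 1-based inclusive ``(start_bin, end_bin)``.

        Only meaningful for binary profiles.
        """
        if self.kind != "binary":
            raise ValueError("domains are defined for binary profiles only")
        out = []
        v = self.values.astype(int)
        start = None
        for i, x in enumerate(v):
            if x and start is None:
                start = i
            elif not x and start is not None:
                out.append((start + 1, i))
                start = None
        if start is not None:
            out.append((start + 1, len(v)))
        return out


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self):
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class MotifModel:
    """A position weight matrix with an order-0 background model.

    ``freq_matrix`` has shape (width, 4); row ``k`` is the base
    distribution (A, C, G, T) at motif position ``k`` and sums to 1.
    """

    freq_matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0
    name: str = ""

    def __post_init__(self):
        self.freq_matrix = np.asarray(self.freq_matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.freq_matrix.ndim != 2 or self.freq_matrix.shape[1] != 4:
            raise ValueError("freq_matrix must have shape (width, 4)")
        if np.any(self.freq_matrix < 0) or np.any(self.background < 0):
            raise ValueError("negative probabilities")
        if not np.allclose(self.freq_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each motif position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.freq_matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 1.0,
        background: Sequence[float] | None = None,
        name: str = "",
    ) -> "MotifModel":
        """Build a motif from a JASPAR-style (4, width) count matrix.

        The pseudocount is added to every cell before per-position
        normalization; a matrix whose positions already sum to 1 passes
        through unchanged when ``pseudocount=0``.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("count matrix must have 4 rows (A, C, G, T)")
        if np.any(counts < 0):
            raise ValueError("count matrix contains negative entries")
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        m = counts.T + pseudocount
        sums = m.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("motif position with zero total count")
        if background is None:
            background = np.full(4, 0.25)
        return cls(
            freq_matrix=m / sums,
            background=np.asarray(background, dtype=float),
            pseudocount=pseudocount,
            name=name,
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq_matrix.argmax(axis=1))

    def reverse_complement(self) -> np.ndarray:
        """(width, 4) frequency matrix of the reverse-complement motif."""
        return self.freq_matrix[::-1, ::-1]

    def information_content(self) -> float:
        """Mean per-position relative entropy vs background, in bits."""
        with np.errstate(divide="ignore", invalid="ignore"):
            term = self.freq_matrix * np.log2(
                self.freq_matrix / self.background[None, :]
            )
        return float(np.nansum(term) / self.width)


def binarize_profile(
    intensity: Sequence[float],
    n_bins: int = N_BINS,
    threshold_frac: float = 0.25,
    label: str = "",
) -> AxisProfile:
    """Discretize a raw A/P intensity trace into a binary 100-bin profile.

    The trace (length L >= n_bins, e.g. 320 points from a standardized
    embryo image) is averaged into ``n_bins`` equal-width bins, fractional
    positions weighted by overlap.  A bin is called expressed iff its mean
    exceeds ``threshold_frac`` times the maximum bin mean.  An all-zero
    trace yields an all-zero profile.
    """
    x = np.asarray(intensity, dtype=float)
    if x.ndim != 1:
        raise ValueError("intensity must be a 1-D vector")
    L = len(x)
    if L < n_bins:
        raise ValueError(f"need at least {n_bins} intensity points, got {L}")
    if np.any(x < 0):
        raise ValueError("intensities must be nonnegative")
    # cumulative integral of the step function (position i covers [i, i+1))
    cum = np.concatenate([[0.0], np.cumsum(x)])
    grid = np.arange(L + 1, dtype=float)
    edges = np.linspace(0.0, L, n_bins + 1)
    F = np.interp(edges, grid, cum)
    means = np.diff(F) / np.diff(edges)
    peak = means.max()
    if peak <= 0:
        binary = np.zeros(n_bins)
    else:
        binary = (means > threshold_frac * peak).astype(float)
    return AxisProfile(values=binary, kind="binary", label=label)
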