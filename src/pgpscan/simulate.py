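"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the segmentation
study system: ~10 TFs with experimentally determined binding motifs,
concentration profiles shaped like the classic anterior/posterior
morphogen gradients, interior repressor stripes and terminal-system
factors, a training collection of 46 CRMs with binary expression
patterns on the 100-bin A/P axis, and multi-kilobase loci with planted
CRMs for discovery tests.  Everything is deterministic under a master
seed, and planted ground truth (site positions, true weights, clean
expression) is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core import AxisProfile, GenomicInterval, MotifModel, N_BINS
from .hmm import crm_motif_score
from .model import default_covariate_spec, sigmoid, term_name

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------- motifs

def make_motif(
    seed: int,
    width: int = 8,
    strength: float = 1.2,
    background: Sequence[float] | None = None,
    name: str = "",
) -> MotifModel:
    """Random PWM with a target mean per-position information content.

    Each position is a mixture ``lam * delta(consensus) + (1 - lam) *
    background`` with ``lam`` solved by bisection so the relative
    entropy vs background equals ``strength`` bits; ``strength = 0``
    returns the background itself at every position.
    """
    if width < 4:
        raise ValueError("width must be >= 4")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(width):
        cons = int(rng.integers(4))
        max_ic = -np.log2(bg[cons])
        if strength > max_ic + 1e-12 or strength > 2.0 + 1e-12:
            raise ValueError(
                f"strength {strength} bits/position exceeds the maximum "
                f"{min(max_ic, 2.0):.3f} achievable"
            )

        def ic(lam):
            col = (1 - lam) * bg
            col[cons] += lam
            with np.errstate(divide="ignore", invalid="ignore"):
                t = col * np.log2(col / bg)
            return float(np.nansum(t))

        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if ic(mid) < strength:
                lo = mid
            else:
                hi = mid
        lam = 0.5 * (lo + hi)
        col = (1 - lam) * bg
        col[cons] += lam
        cols.append(col / col.sum())
    return MotifModel(np.array(cols), background=bg, name=name)


def sample_site(motif: MotifModel, rng: np.random.Generator) -> str:
    """One site drawn position-wise from the PWM."""
    out = []
    for row in motif.freq_matrix:
        out.append(BASES[rng.choice(4, p=row / row.sum())])
    return "".join(out)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def random_sequence(
    length: int, rng: np.random.Generator,
    background: Sequence[float] | None = None,
) -> str:
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return "".join(BASES[rng.choice(4, size=length, p=bg / bg.sum())])


# ----------------------------------------------------------------- loci

@dataclass
class Plant:
    """A CRM planted in a locus: start coordinate and per-TF site counts."""
    start: int
    sites: dict[str, int]
    length: int = 1000


def plant_sites(
    sequence: str,
    sites: Mapping[str, int],
    motifs: Mapping[str, MotifModel],
    rng: np.random.Generator,
) -> str:
    """Overwrite non-overlapping stretches of a sequence with PWM-sampled
    sites (random strand); returns the modified sequence."""
    seq = list(sequence)
    occupied: list[tuple[int, int]] = []
    for tf, count in sites.items():
        W = motifs[tf].width
        for _ in range(count):
            for _attempt in range(200):
                pos = int(rng.integers(0, len(seq) - W + 1))
                if all(pos + W <= a or pos >= b for a, b in occupied):
                    break
            else:
                raise ValueError("could not place non-overlapping sites")
            site = sample_site(motifs[tf], rng)
            if rng.random() < 0.5:
                site = _revcomp(site)
            seq[pos : pos + W] = list(site)
            occupied.append((pos, pos + W))
    return "".join(seq)


def make_locus(
    seed: int,
    length: int,
    plants: Sequence[Plant],
    motifs: Mapping[str, MotifModel],
    background: Sequence[float] | None = None,
    seq_id: str = "locus",
) -> tuple[str, list[GenomicInterval], pd.DataFrame]:
    """Background locus with planted CRMs.

    Returns the sequence, the plant coordinates, and the true motif
    score matrix S (plants x TFs) computed on the planted segments.
    """
    rng = np.random.default_rng(seed)
    spans = sorted((p.start, p.start + p.length) for p in plants)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 < b1:
            raise ValueError("planted CRMs overlap")
    if spans and (spans[0][0] < 0 or spans[-1][1] > length):
        raise ValueError("planted CRM outside locus")
    seq = random_sequence(length, rng, background)
    intervals = []
    rows = {}
    for k, plant in enumerate(plants):
        lo, hi = plant.start, plant.start + plant.length
        crm_seq = plant_sites(seq[lo:hi], plant.sites, motifs, rng)
        seq = seq[:lo] + crm_seq + seq[hi:]
        intervals.append(GenomicInterval(seq_id, lo, hi))
        rows[f"plant{k}"] = {
            tf: crm_motif_score(crm_seq, m) for tf, m in motifs.items()
        }
    S = pd.DataFrame(rows).T if rows else pd.DataFrame()
    return seq, intervals, S


# --------------------------------------------------------- concentrations

def concentration_shape(shape: str, n_bins: int = N_BINS) -> np.ndarray:
    """One of the canonical A/P concentration shapes, values in [0, 1].

    Shapes: ``anterior`` (strictly decreasing morphogen gradient),
    ``posterior`` (mirror), ``stripe:LO:HI`` (interior domain with
    support exactly on bins LO..HI), ``terminal_high`` (high at both
    poles), ``terminal_low`` (its exact per-bin complement).
    """
    b = np.arange(1, n_bins + 1, dtype=float)
    x = (b - 1) / (n_bins - 1)
    if shape == "anterior":
        return np.exp(-3.0 * x)
    if shape == "posterior":
        return np.exp(-3.0 * (1 - x))
    if shape.startswith("stripe:"):
        _, lo, hi = shape.split(":")
        lo, hi = int(lo), int(hi)
        if not (1 <= lo <= hi <= n_bins):
            raise ValueError(f"bad stripe bounds {lo}:{hi}")
        v = np.zeros(n_bins)
        width = hi - lo + 1
        v[lo - 1 : hi] = np.sin(np.pi * (np.arange(width) + 0.5) / width)
        return v
    if shape == "terminal_high":
        return np.maximum(np.exp(-8.0 * x), np.exp(-8.0 * (1 - x)))
    if shape == "terminal_low":
        return 1.0 - concentration_shape("terminal_high", n_bins)
    raise ValueError(f"unknown concentration shape {shape!r}")


def make_concentrations(
    shapes: Mapping[str, str], n_bins: int = N_BINS
) -> pd.DataFrame:
    """TF concentration profiles (rows TFs, columns the 100 axis bins)."""
    df = pd.DataFrame(
        {tf: concentration_shape(s, n_bins) for tf, s in shapes.items()}
    ).T
    df.columns = [f"bin{i+1}" for i in range(n_bins)]
    return df


# ------------------------------------------------------------ expression

def simulate_expression(
    S: pd.DataFrame,
    concentrations: pd.DataFrame,
    weights: Mapping[str, float],
    baselines: Mapping[str, float],
    covariate_spec: Sequence[Mapping] | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-simulate binary expression patterns from the model.

    The continuous activity is thresholded at 0.5 (>= 0.5 maps to 1);
    ``noise`` then flips each bin independently with that probability.
    Returns (clean, noisy) CRM x bin 0/1 frames.
    """
    if covariate_spec is None:
        covariate_spec = default_covariate_spec(list(S.columns))
    rng = np.random.default_rng(seed)
    conc = concentrations
    clean = {}
    for crm in S.index:
        eta = np.full(conc.shape[1], float(baselines[crm]))
        for t in covariate_spec:
            tf, order = t["tf"], t.get("order", 1)
            cov = conc.loc[tf].to_numpy() * float(S.loc[crm, tf])
            eta += float(weights[term_name(tf, order)]) * cov**order
        clean[crm] = (sigmoid(eta) >= 0.5).astype(float)
    clean_df = pd.DataFrame(clean).T
    clean_df.columns = conc.columns
    flips = rng.random(clean_df.shape) < noise
    noisy_df = clean_df.where(~flips, 1 - clean_df)
    return clean_df, noisy_df


def constructive_baselines(
    S: pd.DataFrame,
    concentrations: pd.DataFrame,
    weights: Mapping[str, float],
    covariate_spec: Sequence[Mapping] | None = None,
) -> dict[str, float]:
    """Baselines that place each CRM's activity boundary mid-axis:
    alpha_l = -median_b of the summed covariate contribution, so the
    clean binary pattern has both expressed and silent bins."""
    if covariate_spec is None:
        covariate_spec = default_covariate_spec(list(S.columns))
    out = {}
    for crm in S.index:
        eta = np.zeros(concentrations.shape[1])
        for t in covariate_spec:
            tf, order = t["tf"], t.get("order", 1)
            cov = concentrations.loc[tf].to_numpy() * float(S.loc[crm, tf])
            eta += float(weights[term_name(tf, order)]) * cov**order
        out[crm] = float(-np.median(eta))
    return out


# ------------------------------------------------------- training dataset

DEFAULT_SHAPES = {
    "BCDx": "anterior",
    "CADx": "posterior",
    "FKHx": "terminal_high",
    "HBx": "anterior",
    "KRx": "stripe:40:60",
    "KNIx": "stripe:60:70",
    "GTx": "stripe:20:40",
    "HKBx": "terminal_high",
    "TLLx": "terminal_high",
    "CICx": "terminal_low",
}

DEFAULT_ACTIVATORS = ("BCDx", "CADx", "FKHx")


@dataclass
class TrainingData:
    S: pd.DataFrame
    concentrations: pd.DataFrame
    weights: dict[str, float]
    baselines: dict[str, float]
    targets_clean: pd.DataFrame
    targets_noisy: pd.DataFrame
    covariate_spec: list[dict]
    activators: tuple[str, ...]


def simulate_training_data(
    seed: int,
    n_crms: int = 46,
    n_bins: int = N_BINS,
    shapes: Mapping[str, str] | None = None,
    activators: Sequence[str] = DEFAULT_ACTIVATORS,
    noise: float = 0.0,
    weight_scale: float = 2.0,
    site_sparsity: float = 0.35,
) -> TrainingData:
    """Standard training collection: a CRM x TF motif-score matrix with
    planted activator/repressor weights and forward-simulated binary
    patterns (10 TFs x 46 CRMs x 100 bins by default, mirroring the
    dimensions of the training compendium)."""
    if shapes is None:
        shapes = DEFAULT_SHAPES
    rng = np.random.default_rng(seed)
    tfs = list(shapes)
    conc = make_concentrations(shapes, n_bins)
    # nonnegative motif scores with a sparse zero fraction
    Sm = rng.lognormal(mean=0.5, sigma=0.5, size=(n_crms, len(tfs)))
    Sm[rng.random(Sm.shape) < site_sparsity] = 0.0
    empty = ~Sm.any(axis=1)
    Sm[empty, 0] = rng.lognormal(mean=0.5, sigma=0.5, size=int(empty.sum()))
    S = pd.DataFrame(
        Sm, index=[f"crm{i+1}" for i in range(n_crms)], columns=tfs
    )
    weights = {}
    for tf in tfs:
        mag = weight_scale * float(rng.uniform(0.5, 1.5))
        weights[tf] = mag if tf in activators else -mag
    spec = default_covariate_spec(tfs)
    baselines = constructive_baselines(S, conc, weights, spec)
    clean, noisy = simulate_expression(
        S, conc, weights, baselines, spec, noise=noise, seed=seed + 1
    )
    # guard against degenerate all-on/all-off patterns: center the
    # linear predictor between its extremes instead of at its median
    redo = False
    for crm in list(S.index):
        v = clean.loc[crm].to_numpy()
        if v.min() == v.max():
            eta = np.zeros(conc.shape[1])
            for t in spec:
                tf, order = t["tf"], t.get("order", 1)
                cov = conc.loc[tf].to_numpy() * float(S.loc[crm, tf])
                eta += float(weights[term_name(tf, order)]) * cov**order
            baselines[crm] = float(-(eta.min() + eta.max()) / 2.0)
            redo = True
    if redo:
        clean, noisy = simulate_expression(
            S, conc, weights, baselines, spec, noise=noise, seed=seed + 1
        )
    return TrainingData(
        S=S,
        concentrations=conc,
        weights=weights,
        baselines=baselines,
        targets_clean=clean,
        targets_noisy=noisy,
        covariate_spec=spec,
        activators=tuple(activators),
    )


# -------------------------------------------------------------- orthologs

def evolve_orthologs(
    tree: dendropy.Tree,
    ancestral: str,
    rate: float,
    seed: int = 0,
) -> dict[str, str]:
    """Jukes-Cantor evolution of an ancestral sequence down a phylogeny.

    Independent sites, no indels (orthology maps stay positional).  The
    probability that a site differs across a branch of length tau is
    ``3/4 (1 - exp(-4 rate tau / 3))``.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    codes = {b: i for i, b in enumerate("ACGT")}
    anc = np.array([codes[b] for b in ancestral], dtype=np.int64)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): anc}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tau = node.edge.length or 0.0
        p_diff = 0.75 * (1.0 - np.exp(-4.0 * rate * tau / 3.0))
        parent = seqs[id(node.parent_node)]
        child = parent.copy()
        hit = rng.random(len(child)) < p_diff
        if hit.any():
            shift = rng.integers(1, 4, size=int(hit.sum()))
            child[hit] = (child[hit] + shift) % 4
        seqs[id(node)] = child
        if node.is_leaf():
            label = node.taxon.label if node.taxon else (node.label or "")
            out[label] = "".join(BASES[child])
    return out


def positional_orthology(
    n_windows: int, species: Sequence[str]
) -> dict[int, dict[str, int]]:
    """Identity orthology map for indel-free alignments."""
    return {i: {sp: i for sp in species} for i in range(n_windows)}
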