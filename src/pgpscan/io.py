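"""Readers and writers for the standard file formats the pipeline consumes.

FASTA via Biopython, Newick via dendropy, JASPAR-like 4-row motif text,
BED intervals, and TSV axis-profile tables (column 1 = label, columns
2..n_bins+1 = bin values).
"""

from __future__ import annotations

import re
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import AxisProfile, GenomicInterval, MotifModel

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


class ParseError(ValueError):
    pass


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (header, sequence) pairs.

    Sequences are uppercased and restricted to the {A, C, G, T, N}
    alphabet; record order is preserved.
    """
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if not _VALID_SEQ.match(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ParseError(
                    f"record {rec.description!r} contains illegal "
                    f"character(s) {bad}"
                )
            records.append((rec.description, seq))
    except ValueError as e:  # Biopython raises ValueError on bad headers
        if isinstance(e, ParseError):
            raise
        raise ParseError(str(e)) from e
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(path, records: Sequence[tuple[str, str]], width: int = 60):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_newick(path) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths.

    Every non-root branch must carry a finite nonnegative length
    (required by the Brownian-motion averaging); unnamed internal nodes
    are allowed.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return validate_tree(tree)


def read_newick_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return validate_tree(tree)


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ParseError("tree must have at least 2 leaves")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # root pseudo-edge
            continue
        if edge.length is None:
            raise ParseError(
                "branch without a length (branch lengths are required)"
            )
        if not np.isfinite(edge.length) or edge.length < 0:
            raise ParseError(f"invalid branch length {edge.length}")
    return tree


def load_motif(
    path,
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
    name: str = "",
) -> MotifModel:
    """Load a JASPAR-like 4-row motif matrix (counts or frequencies).

    Lines may look like ``A  [ 9  0 ]`` or be bare whitespace-separated
    numbers; an optional ``>`` header line is ignored.  Counts are turned
    into frequencies with the pseudocount added to every cell before
    per-position normalization.
    """
    rows = []
    header = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()[0] if line[1:].split() else ""
                continue
            cleaned = re.sub(r"^[ACGTacgt][\s:|]", " ", line)
            cleaned = cleaned.replace("[", " ").replace("]", " ")
            vals = [float(tok) for tok in cleaned.split()]
            if vals:
                rows.append(vals)
    if len(rows) != 4:
        raise ParseError(f"motif file must have 4 rows (A,C,G,T), got {len(rows)}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError("motif rows have unequal lengths")
    counts = np.array(rows, dtype=float)
    if np.any(counts < 0):
        raise ParseError("motif matrix contains negative entries")
    return MotifModel.from_counts(
        counts, pseudocount=pseudocount, background=background,
        name=name or header,
    )


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(path, intervals: Sequence[GenomicInterval], names=None,
              scores=None):
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.seq_id, str(iv.start), str(iv.end)]
            if names is not None or scores is not None or iv.strand != ".":
                fields.append(str(names[i]) if names is not None else ".")
                fields.append(f"{scores[i]:g}" if scores is not None else "0")
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_profile_table(path) -> pd.DataFrame:
    """Read a TSV of axis profiles: column 1 label, columns 2.. bin values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_profile_table(path, profiles) -> None:
    """Write profiles (DataFrame, or mapping label -> AxisProfile) as TSV."""
    if isinstance(profiles, pd.DataFrame):
        df = profiles
    else:
        df = profiles_to_frame(profiles)
    df.to_csv(path, sep="\t", float_format="%.10g")


def profiles_to_frame(profiles: dict) -> pd.DataFrame:
    rows = {}
    for label, prof in profiles.items():
        values = prof.values if isinstance(prof, AxisProfile) else np.asarray(prof)
        rows[label] = values
    df = pd.DataFrame(rows).T
    df.columns = [f"bin{i+1}" for i in range(df.shape[1])]
    df.index.name = "label"
    return df


def frame_to_profiles(df: pd.DataFrame, kind: str) -> dict[str, AxisProfile]:
    return {
        str(label): AxisProfile(row.to_numpy(dtype=float), kind, str(label))
        for label, row in df.iterrows()
    }
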