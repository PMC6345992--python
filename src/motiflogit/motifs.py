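"""Position probability matrices: parsing, similarity, alignment and merging.

A motif library drawn from a public database is typically redundant: many
entries describe near-identical binding preferences, which makes downstream
regression features collinear.  This module reduces a library to a
non-redundant one by scoring every pair of position probability matrices
(PPMs) with the Pearson correlation of their optimal gapless alignment and
merging groups whose correlation reaches a threshold (0.9 by default) into a
single averaged PPM.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from Bio import motifs as bio_motifs

NUCLEOTIDES = "ACGT"
#: Uniform background, the default when no genome is supplied.
UNIFORM_BACKGROUND = np.full(4, 0.25)

_ROW_SUM_TOL = 1e-6


class MotifParseError(ValueError):
    """Raised when a motif file block cannot be turned into a valid PPM."""


def as_background(freqs: Sequence[float]) -> np.ndarray:
    """Validate background nucleotide frequencies (A, C, G, T)."""
    bg = np.asarray(freqs, dtype=float)
    if bg.shape != (4,):
        raise ValueError("background frequencies must have exactly 4 entries")
    if np.any(bg < 0):
        raise ValueError("background frequencies must be non-negative")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background frequencies must sum to 1")
    return bg


@dataclass(frozen=True)
class PositionProbabilityMatrix:
    """Per-position nucleotide probabilities of one DNA motif.

    ``probs`` has one row per motif position and columns in A, C, G, T order;
    every row sums to one.  ``source_ids`` records which library entries the
    matrix descends from (itself, for an unmerged motif).
    """

    name: str
    probs: np.ndarray
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"motif {self.name!r}: probs must be an L x 4 matrix with L >= 1")
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValueError(f"motif {self.name!r}: probabilities must lie in [0, 1]")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
            raise ValueError(f"motif {self.name!r}: rows must sum to 1 within {_ROW_SUM_TOL}")
        object.__setattr__(self, "probs", probs)
        if not self.source_ids:
            object.__setattr__(self, "source_ids", (self.name,))

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PositionProbabilityMatrix":
        """PPM describing the same motif read on the opposite strand."""
        rc = self.probs[::-1, ::-1]
        return PositionProbabilityMatrix(self.name, rc, self.source_ids)

    def is_uniform(self, tol: float = 1e-12) -> bool:
        """True when every entry equals its row mean (zero variance)."""
        centered = self.probs - self.probs.mean(axis=1, keepdims=True)
        return bool(np.all(np.abs(centered) <= tol))


@dataclass(frozen=True)
class PpmAlignment:
    """Best gapless alignment of motif B against motif A.

    ``offset`` is the position of B's first column relative to A's first
    column (after reverse-complementing B when ``orientation`` is
    ``"reverse"``); ``correlation`` is the Pearson correlation of the
    background-padded pair over the union span of the two matrices.
    """

    offset: int
    orientation: str  # "forward" | "reverse"
    correlation: float
    aligned_length: int


@dataclass(frozen=True)
class MotifCluster:
    member_names: tuple[str, ...]
    merged: PositionProbabilityMatrix


def _counts_to_probs(name: str, counts: np.ndarray, pseudocount: float) -> np.ndarray:
    if np.any(counts < 0):
        raise MotifParseError(f"motif {name!r}: negative matrix entries")
    padded = counts + pseudocount
    row_sums = padded.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise MotifParseError(f"motif {name!r}: a row has zero total count and zero pseudocount")
    return padded / row_sums


def _parse_jaspar_block(block: str, name_hint: str) -> tuple[str, np.ndarray]:
    try:
        parsed = bio_motifs.parse(io.StringIO(block), "jaspar")
        if len(parsed) != 1:
            raise MotifParseError(f"motif {name_hint!r}: malformed block")
        motif = parsed[0]
        counts = np.column_stack([np.asarray(motif.counts[base], float) for base in NUCLEOTIDES])
    except MotifParseError:
        raise
    except Exception as exc:  # Bio raises a mix of ValueError/KeyError/IndexError
        raise MotifParseError(f"motif {name_hint!r}: {exc}") from exc
    name = motif.name or motif.matrix_id or name_hint
    if motif.matrix_id and motif.name and motif.name != motif.matrix_id:
        name = f"{motif.matrix_id} {motif.name}".strip()
    return name, counts


def parse_motif_file(
    path,
    pseudocount: float = 0.001,
    as_counts: bool | None = None,
) -> list[PositionProbabilityMatrix]:
    """Read a JASPAR-style plain-text motif file into PPMs.

    Each record is a ``>`` header followed by four nucleotide rows (bare
    numbers or ``A [ ... ]`` style).  Count matrices are converted to
    probabilities as ``(c + pseudocount) / (row_sum + 4 * pseudocount)``.
    When ``as_counts`` is None each matrix is auto-detected: rows that already
    sum to ~1 are treated as probabilities (the pseudocount still applies, so
    zero probabilities can be lifted off the floor).
    """
    with open(path) as handle:
        text = handle.read()
    blocks: list[str] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if current:
                blocks.append("\n".join(current))
            current = [line]
        elif line.strip():
            if not current:
                raise MotifParseError(f"{path}: matrix rows before the first '>' header")
            current.append(line)
    if current:
        blocks.append("\n".join(current))
    if not blocks:
        raise MotifParseError(f"{path}: no motif records found")

    ppms = []
    for i, block in enumerate(blocks):
        hint = block.splitlines()[0][1:].strip() or f"motif_{i}"
        name, counts = _parse_jaspar_block(block, hint)
        probs = _counts_to_probs(name, counts, pseudocount)
        ppms.append(PositionProbabilityMatrix(name, probs))
    return ppms


def write_motif_file(ppms: Iterable[PositionProbabilityMatrix], path) -> None:
    """Write PPMs in JASPAR plain-text layout (probability matrices)."""
    with open(path, "w") as handle:
        for ppm in ppms:
            handle.write(f">{ppm.name}\n")
            for j, base in enumerate(NUCLEOTIDES):
                row = " ".join(f"{v:.6f}" for v in ppm.probs[:, j])
                handle.write(f"{base} [ {row} ]\n")


def ppm_correlation(a, b) -> float:
    """Pearson correlation of two equal-length PPMs.

    Entries are centered on their per-position row mean (0.25 for rows that
    sum to one) and correlated across all positions and the four nucleotides.
    Returns NaN when either matrix has zero variance (a uniform matrix);
    callers that cluster treat NaN as no similarity.
    """
    pa = a.probs if isinstance(a, PositionProbabilityMatrix) else np.asarray(a, float)
    pb = b.probs if isinstance(b, PositionProbabilityMatrix) else np.asarray(b, float)
    if pa.shape != pb.shape:
        raise ValueError("ppm_correlation requires matrices of equal shape; align them first")
    ca = pa - pa.mean(axis=1, keepdims=True)
    cb = pb - pb.mean(axis=1, keepdims=True)
    denom = np.sqrt((ca * ca).sum()) * np.sqrt((cb * cb).sum())
    if denom == 0.0:
        return float("nan")
    return float((ca * cb).sum() / denom)


def _pad_to_span(probs: np.ndarray, start: int, span: int, bg: np.ndarray) -> np.ndarray:
    out = np.tile(bg, (span, 1))
    out[start : start + probs.shape[0]] = probs
    return out


def _score_offset(pa: np.ndarray, pb: np.ndarray, offset: int, bg: np.ndarray) -> tuple[float, int]:
    lo = min(0, offset)
    hi = max(pa.shape[0], offset + pb.shape[0])
    span = hi - lo
    a_pad = _pad_to_span(pa, -lo, span, bg)
    b_pad = _pad_to_span(pb, offset - lo, span, bg)
    corr = ppm_correlation(a_pad, b_pad)
    return corr, span


def align_ppms(
    a: PositionProbabilityMatrix,
    b: PositionProbabilityMatrix,
    bg: Sequence[float] = UNIFORM_BACKGROUND,
    both_orientations: bool = True,
) -> PpmAlignment:
    """Optimal gapless alignment of ``b`` against ``a``.

    Exhaustively slides ``b`` (and, by default, its reverse complement)
    across ``a`` over every offset with at least one overlapping position,
    padding overhangs with background frequencies, and returns the offset and
    orientation maximizing the Pearson correlation of the padded pair.  Ties
    are broken by smaller ``|offset|``, then forward orientation.
    """
    bg = as_background(bg)
    orientations = [("forward", b.probs)]
    if both_orientations:
        orientations.append(("reverse", b.reverse_complement().probs))

    best: tuple[float, int, int, str, float, int] | None = None
    for orient_rank, (orient, pb) in enumerate(orientations):
        for offset in range(-(pb.shape[0] - 1), a.length):
            corr, span = _score_offset(a.probs, pb, offset, bg)
            score = 0.0 if np.isnan(corr) else corr
            key = (-score, abs(offset), orient_rank, offset)
            if best is None or key < best[:4]:
                best = (*key, corr, span)
    assert best is not None
    _, _, orient_rank, offset, corr, span = best
    return PpmAlignment(
        offset=offset,
        orientation="reverse" if orient_rank else "forward",
        correlation=0.0 if np.isnan(corr) else float(corr),
        aligned_length=span,
    )


def pairwise_alignment_correlations(
    library: Sequence[PositionProbabilityMatrix],
    bg: Sequence[float] = UNIFORM_BACKGROUND,
    both_orientations: bool = True,
) -> np.ndarray:
    """Symmetric matrix of best aligned correlations for every motif pair."""
    n = len(library)
    corr = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        c = align_ppms(library[i], library[j], bg, both_orientations).correlation
        corr[i, j] = corr[j, i] = c
    for i in range(n):
        if library[i].is_uniform():
            corr[i, i] = 0.0  # uninformative motifs never seed clusters
    return corr


def _cluster_labels(corr: np.ndarray, threshold: float, linkage: str) -> np.ndarray:
    n = corr.shape[0]
    if linkage == "single":
        adjacency = csr_matrix((corr >= threshold).astype(int))
        _, labels = connected_components(adjacency, directed=False)
        return labels
    if linkage == "average":
        dist = 1.0 - np.clip(corr, -1.0, 1.0)
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        tree = scipy_linkage(condensed, method="average")
        return fcluster(tree, t=1.0 - threshold, criterion="distance") - 1
    raise ValueError(f"unknown linkage {linkage!r}")


def merge_cluster(
    members: Sequence[PositionProbabilityMatrix],
    bg: Sequence[float] = UNIFORM_BACKGROUND,
    both_orientations: bool = True,
) -> PositionProbabilityMatrix:
    """Average a set of PPMs after aligning each member to the cluster seed.

    The seed is the longest member (ties broken by lexicographically first
    name).  Member columns outside the union span contribute background
    frequencies; averaged rows are renormalized to sum to one.
    """
    bg = as_background(bg)
    if len(members) == 1:
        return members[0]
    seed = min(members, key=lambda p: (-p.length, p.name))
    placements = []
    for member in members:
        if member is seed:
            placements.append((0, seed.probs))
            continue
        aln = align_ppms(seed, member, bg, both_orientations)
        probs = member.reverse_complement().probs if aln.orientation == "reverse" else member.probs
        placements.append((aln.offset, probs))

    lo = min(0, *(off for off, _ in placements))
    hi = max(seed.length, *(off + p.shape[0] for off, p in placements))
    span = hi - lo
    stacked = np.stack([_pad_to_span(p, off - lo, span, bg) for off, p in placements])
    averaged = stacked.mean(axis=0)
    averaged /= averaged.sum(axis=1, keepdims=True)
    name = "+".join(sorted(m.name for m in members))
    sources = tuple(s for m in members for s in m.source_ids)
    return PositionProbabilityMatrix(name, averaged, sources)


def cluster_and_merge(
    library: Sequence[PositionProbabilityMatrix],
    threshold: float = 0.9,
    bg: Sequence[float] = UNIFORM_BACKGROUND,
    both_orientations: bool = True,
    linkage: str = "single",
) -> list[MotifCluster]:
    """Group motifs whose aligned correlation reaches ``threshold`` and merge.

    With ``linkage="single"`` clusters are connected components of the graph
    with an edge wherever the aligned correlation is at least the threshold;
    ``linkage="average"`` cuts an average-linkage dendrogram at the same
    level.  Singleton motifs pass through unchanged.
    """
    if not library:
        raise ValueError("cluster_and_merge requires a non-empty library")
    corr = pairwise_alignment_correlations(library, bg, both_orientations)
    labels = _cluster_labels(corr, threshold, linkage)
    clusters = []
    for label in sorted(set(labels), key=lambda l: int(np.argmax(labels == l))):
        members = [library[i] for i in np.flatnonzero(labels == label)]
        merged = merge_cluster(members, bg, both_orientations)
        clusters.append(MotifCluster(tuple(m.name for m in members), merged))
    return clusters


def merged_library(clusters: Sequence[MotifCluster]) -> list[PositionProbabilityMatrix]:
    return [c.merged for c in clusters]


def merge_report(
    clusters: Sequence[MotifCluster],
    library: Sequence[PositionProbabilityMatrix] | None = None,
    bg: Sequence[float] = UNIFORM_BACKGROUND,
    both_orientations: bool = True,
):
    """Tabular account of the merge: one row per cluster.

    Columns: cluster id, merged name, seed, member names, number of members,
    and the minimum pairwise aligned correlation among members (1.0 for
    singletons).
    """
    import pandas as pd

    by_name: Mapping[str, PositionProbabilityMatrix] = (
        {p.name: p for p in library} if library is not None else {}
    )
    rows = []
    for cid, cluster in enumerate(clusters):
        min_corr = 1.0
        if library is not None and len(cluster.member_names) > 1:
            members = [by_name[n] for n in cluster.member_names]
            min_corr = min(
                align_ppms(x, y, bg, both_orientations).correlation
                for x, y in itertools.combinations(members, 2)
            )
        seed = min(
            (by_name[n] for n in cluster.member_names),
            key=lambda p: (-p.length, p.name),
        ).name if library is not None else cluster.member_names[0]
        rows.append(
            {
                "cluster": cid,
                "merged_name": cluster.merged.name,
                "seed": seed,
                "members": ",".join(cluster.member_names),
                "n_members": len(cluster.member_names),
                "min_pairwise_correlation": min_corr,
            }
        )
    return pd.DataFrame(rows)
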