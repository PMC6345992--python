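"""Genomic loci: BED/FASTA handling and GC-matched background sampling.

The negative class for the binding model is a set of random genomic loci
whose GC-content distribution matches the binding sites bin-for-bin, that
contain no ambiguous (N) bases, and that are equal in number to the binding
sites.  Coordinates follow the BED convention (0-based, half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta


@dataclass
class Locus:
    """One genomic interval with its extracted sequence and class label."""

    chrom: str
    start: int
    end: int
    label: int = 1  # 1 = binding site, 0 = background
    sequence: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (3+ columns); extra columns beyond name are ignored."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    names = pd.read_csv(path, sep="\t", header=None, comment="#")
    if names.shape[1] >= 4:
        df["name"] = names.iloc[:, 3].astype(str)
    else:
        df["name"] = [f"{c}:{s}-{e}" for c, s, e in zip(df.chrom, df.start, df.end)]
    return df


class GenomeView:
    """Uniform access to a genome from a FASTA path or an in-memory mapping."""

    def __init__(self, genome):
        if isinstance(genome, GenomeView):
            self._contigs = genome._contigs
            self._fasta = genome._fasta
        elif isinstance(genome, (str, Path)):
            self._fasta = Fasta(str(genome), sequence_always_upper=True)
            self._contigs = None
        elif isinstance(genome, Mapping):
            self._contigs = {k: v.upper() for k, v in genome.items()}
            self._fasta = None
        else:
            raise TypeError("genome must be a FASTA path or a mapping of contig -> sequence")

    def contig_names(self) -> list[str]:
        if self._contigs is not None:
            return list(self._contigs)
        return list(self._fasta.keys())

    def contig_length(self, chrom: str) -> int:
        if chrom not in self.contig_names():
            raise KeyError(f"unknown contig {chrom!r}")
        if self._contigs is not None:
            return len(self._contigs[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.contig_names():
            raise KeyError(f"unknown contig {chrom!r} for interval {chrom}:{start}-{end}")
        if start < 0 or end > self.contig_length(chrom):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside contig bounds "
                f"(length {self.contig_length(chrom)})"
            )
        if self._contigs is not None:
            return self._contigs[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()


def extract_sequences(bed, genome) -> list[Locus]:
    """Extract uppercased sequences for BED intervals from a genome.

    ``bed`` may be a BED path or a DataFrame with chrom/start/end[/name]
    columns.  The BED strand column is ignored: motif scoring downstream is
    strand-symmetric.
    """
    view = GenomeView(genome)
    df = read_bed(bed) if isinstance(bed, (str, Path)) else bed
    loci = []
    for row in df.itertuples(index=False):
        seq = view.fetch(row.chrom, row.start, row.end)
        name = getattr(row, "name", "") or f"{row.chrom}:{row.start}-{row.end}"
        loci.append(Locus(row.chrom, int(row.start), int(row.end), 1, seq, name))
    return loci


def gc_fraction(sequence: str) -> float:
    if not sequence:
        return 0.0
    seq = sequence.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def background_frequencies_from_genome(genome) -> np.ndarray:
    """Mononucleotide frequencies (A, C, G, T) of a genome, ignoring N."""
    view = GenomeView(genome)
    counts = np.zeros(4)
    for chrom in view.contig_names():
        seq = view.fetch(chrom, 0, view.contig_length(chrom))
        for i, base in enumerate("ACGT"):
            counts[i] += seq.count(base)
    if counts.sum() == 0:
        raise ValueError("genome contains no unambiguous bases")
    return counts / counts.sum()


def gc_matched_background(
    loci: Sequence[Locus],
    genome,
    seed: int,
    gc_bins: int = 20,
    max_attempts_per_locus: int = 20000,
) -> list[Locus]:
    """Sample one GC-matched random background locus per foreground locus.

    Each background locus has the length of its matched foreground locus and
    falls in the same GC bin (``gc_bins`` equal-width bins on [0, 1]), so the
    per-bin GC histograms agree exactly.  Candidates containing N or
    overlapping any foreground locus are rejected.  Sampling is reproducible
    under ``seed``.
    """
    if not loci:
        raise ValueError("gc_matched_background requires at least one foreground locus")
    view = GenomeView(genome)
    rng = np.random.default_rng(seed)

    forbidden: dict[str, IntervalTree] = {}
    for locus in loci:
        forbidden.setdefault(locus.chrom, IntervalTree()).addi(locus.start, locus.end)

    contigs = view.contig_names()
    lengths = np.array([view.contig_length(c) for c in contigs], dtype=float)
    weights = lengths / lengths.sum()

    def gc_bin(seq: str) -> int:
        return min(int(gc_fraction(seq) * gc_bins), gc_bins - 1)

    background = []
    for i, locus in enumerate(loci):
        target_bin = gc_bin(locus.sequence)
        size = locus.length
        for _ in range(max_attempts_per_locus):
            ci = rng.choice(len(contigs), p=weights)
            chrom = contigs[ci]
            max_start = view.contig_length(chrom) - size
            if max_start < 0:
                continue
            start = int(rng.integers(0, max_start + 1))
            end = start + size
            if chrom in forbidden and forbidden[chrom].overlap(start, end):
                continue
            seq = view.fetch(chrom, start, end)
            if "N" in seq:
                continue
            if gc_bin(seq) != target_bin:
                continue
            background.append(Locus(chrom, start, end, 0, seq, f"bg_{i}"))
            break
        else:
            raise RuntimeError(
                f"could not sample a background locus for GC bin {target_bin} "
                f"(locus {locus.name or i}, length {size}) after "
                f"{max_attempts_per_locus} attempts; genome may be too small"
            )
    return background


def write_bed(loci: Sequence[Locus], path) -> None:
    with open(path, "w") as handle:
        for locus in loci:
            name = locus.name or f"{locus.chrom}:{locus.start}-{locus.end}"
            handle.write(f"{locus.chrom}\t{locus.start}\t{locus.end}\t{name}\t{locus.label}\n")


def write_fasta(contigs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for name, seq in contigs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
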