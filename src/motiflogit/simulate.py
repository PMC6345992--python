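"""Synthetic motif libraries, genomes, peak sets and strain pairs.

Every generator plants known ground truth so the rest of the package is
testable without any external download: labels are drawn from the exact
generative model the classifier assumes (a logistic function of standardized
motif scores), duplicate motifs are constructed with aligned correlation at
or above the merge threshold, and strain-B sequences are strain-A sequences
mutated at controlled SNP/indel rates with binding ratios tied linearly to
the induced motif-score differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix, build_feature_matrix
from .motifs import PositionProbabilityMatrix, UNIFORM_BACKGROUND, align_ppms
from .sequences import Locus, write_bed, write_fasta
from .twostrain import StrainPairFeatures, build_strain_features

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic generators.

    Defaults emulate a desk-scale ChIP-seq peak analysis: 200-bp loci (the
    conventional fixed peak size), mammalian-like 41% GC background, a
    20-motif library with 5 causal motifs of mixed-sign weights, and mouse
    strain-pair mutation rates scaled so a few variants hit each locus.
    """

    n_motifs: int = 20
    motif_length_range: tuple[int, int] = (8, 12)
    n_causal: int = 5
    true_weights: tuple[float, ...] = (1.0, -1.0, 2.0, -2.0, 3.0)
    n_loci: int = 2000
    locus_length: int = 200
    gc_content: float = 0.41
    snp_rate: float = 0.02
    indel_rate: float = 0.002
    noise_sd: float = 0.5
    seed: int = 0
    intercept: float = 0.0
    plant_prob: float = 0.5
    n_duplicate_groups: int = 0
    duplicates_per_group: int = 1
    duplicate_min_correlation: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.n_causal <= self.n_motifs:
            raise ValueError("need 0 < n_causal <= n_motifs")
        if len(self.true_weights) != self.n_causal:
            raise ValueError("true_weights must have n_causal entries")
        for rate in (self.gc_content, self.snp_rate, self.indel_rate, self.plant_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_sequences(rng: np.random.Generator, n: int, length: int, gc: float) -> list[str]:
    codes = rng.choice(4, size=(n, length), p=_base_probs(gc))
    return ["".join(NUCLEOTIDES[row]) for row in codes]


def _sharp_ppm(rng: np.random.Generator, name: str, length: int) -> PositionProbabilityMatrix:
    # information-rich columns: one dominant base per position
    probs = np.empty((length, 4))
    for i in range(length):
        dominant = rng.integers(0, 4)
        p_dom = rng.uniform(0.75, 0.97)
        rest = rng.dirichlet(np.ones(3)) * (1 - p_dom)
        row = np.insert(rest, dominant, p_dom)
        probs[i] = row
    probs /= probs.sum(axis=1, keepdims=True)
    return PositionProbabilityMatrix(name, probs)


def _jittered_duplicate(
    rng: np.random.Generator,
    base: PositionProbabilityMatrix,
    name: str,
    min_correlation: float,
) -> PositionProbabilityMatrix:
    for _ in range(100):
        noise = rng.dirichlet(np.ones(4), size=base.length)
        probs = 0.9 * base.probs + 0.1 * noise
        probs /= probs.sum(axis=1, keepdims=True)
        dup = PositionProbabilityMatrix(name, probs)
        if align_ppms(base, dup).correlation >= min_correlation:
            return dup
    raise RuntimeError("failed to build a near-duplicate motif")


def generate_library(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> list[PositionProbabilityMatrix]:
    """Random information-rich PPM library; optional planted duplicate groups.

    The first ``n_duplicate_groups`` motifs each receive
    ``duplicates_per_group`` jittered copies (aligned correlation at least
    ``duplicate_min_correlation`` by construction, named ``<base>_dupK``) so
    library merging has known ground truth to recover.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    lo, hi = spec.motif_length_range
    library = [
        _sharp_ppm(rng, f"M{i:03d}", int(rng.integers(lo, hi + 1)))
        for i in range(spec.n_motifs)
    ]
    for g in range(spec.n_duplicate_groups):
        base = library[g]
        for k in range(spec.duplicates_per_group):
            library.append(
                _jittered_duplicate(
                    rng, base, f"{base.name}_dup{k}", spec.duplicate_min_correlation
                )
            )
    return library


def sample_motif_instance(rng: np.random.Generator, ppm: PositionProbabilityMatrix) -> str:
    codes = [rng.choice(4, p=ppm.probs[i]) for i in range(ppm.length)]
    return "".join(NUCLEOTIDES[codes])


def _plant(rng: np.random.Generator, sequence: str, instance: str) -> str:
    pos = int(rng.integers(0, len(sequence) - len(instance) + 1))
    return sequence[:pos] + instance + sequence[pos + len(instance) :]


@dataclass
class SyntheticBindingDataset:
    """Loci with planted motifs, logistic labels, and the generating truth."""

    genome: dict[str, str]
    loci: list[Locus]
    labels: np.ndarray
    features: FeatureMatrix
    library: list[PositionProbabilityMatrix]
    true_weights: np.ndarray  # aligned to library order; zeros for non-causal
    intercept: float
    causal_names: list[str]

    def binding_loci(self) -> list[Locus]:
        return [l for l, y in zip(self.loci, self.labels) if y == 1]

    def write(self, outdir) -> None:
        from pathlib import Path

        from .motifs import write_motif_file

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_bed(self.binding_loci(), outdir / "peaks.bed")
        write_bed(self.loci, outdir / "all_loci.bed")
        write_motif_file(self.library, outdir / "motifs.jaspar")
        pd.DataFrame(
            {
                "locus_id": [l.name for l in self.loci],
                "label": self.labels,
            }
        ).to_csv(outdir / "labels.tsv", sep="\t", index=False)


def generate_binding_dataset(
    spec: SyntheticSpec,
    library: Sequence[PositionProbabilityMatrix] | None = None,
    spacer: int = 100,
) -> SyntheticBindingDataset:
    """Peak-like loci with planted causal motifs and logistic labels.

    Background sequence is i.i.d. at ``spec.gc_content``.  Each of the first
    ``n_causal`` motifs is planted (one sampled instance, uniform random
    position) into each locus independently with probability
    ``plant_prob``.  Labels are Bernoulli with success probability
    logistic(intercept + Z . w_true) over the standardized motif scores, so
    the classifier's generative assumption holds exactly.  All loci are laid
    out on one synthetic contig separated by spacer sequence, so BED/FASTA
    round-trips work end-to-end.
    """
    rng = np.random.default_rng(spec.seed)
    if library is None:
        library = generate_library(spec, rng)
    causal = list(library[: spec.n_causal])
    sequences = _random_sequences(rng, spec.n_loci, spec.locus_length, spec.gc_content)
    for ppm in causal:
        planted = rng.random(spec.n_loci) < spec.plant_prob
        for i in np.flatnonzero(planted):
            sequences[i] = _plant(rng, sequences[i], sample_motif_instance(rng, ppm))

    features = build_feature_matrix(sequences, library)
    true_weights = np.zeros(len(library))
    true_weights[: spec.n_causal] = np.asarray(spec.true_weights)
    eta = spec.intercept + features.standardized @ true_weights
    labels = (rng.random(spec.n_loci) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    # lay loci on one contig with spacers for a self-consistent genome
    spacers = _random_sequences(rng, spec.n_loci + 1, spacer, spec.gc_content)
    parts, loci, cursor = [spacers[0]], [], spacer
    for i, seq in enumerate(sequences):
        loci.append(
            Locus("chrS1", cursor, cursor + len(seq), int(labels[i]), seq, f"locus_{i}")
        )
        parts.append(seq)
        parts.append(spacers[i + 1])
        cursor += len(seq) + spacer
    genome = {"chrS1": "".join(parts)}

    fm = FeatureMatrix(
        [l.name for l in loci],
        features.motif_names,
        features.raw,
        features.standardized,
        features.col_means,
        features.col_sds,
        features.constant_mask,
    )
    return SyntheticBindingDataset(
        genome, loci, labels, fm, list(library), true_weights, spec.intercept,
        [p.name for p in causal],
    )


def _mutate_sequence(rng: np.random.Generator, sequence: str, snp_rate: float, indel_rate: float) -> str:
    bases = list(sequence)
    snp_positions = np.flatnonzero(rng.random(len(bases)) < snp_rate)
    for pos in snp_positions:
        alternatives = [b for b in "ACGT" if b != bases[pos]]
        bases[pos] = alternatives[rng.integers(0, 3)]
    n_indels = rng.binomial(len(bases), indel_rate)
    for _ in range(n_indels):
        if not bases:
            break
        pos = int(rng.integers(0, len(bases)))
        size = int(rng.integers(1, 4))  # indels of length 1-3
        if rng.random() < 0.5:
            del bases[pos : pos + size]
        else:
            insert = "".join(NUCLEOTIDES[rng.choice(4, size=size)])
            bases[pos:pos] = list(insert)
    return "".join(bases)


@dataclass
class SyntheticStrainDataset:
    """Paired two-genome loci with binding ratios tied to score differences."""

    pairs: pd.DataFrame  # locus_id, seq_strainA, seq_strainB, reads_strainA, reads_strainB
    library: list[PositionProbabilityMatrix]
    true_weights: np.ndarray  # aligned to library order
    mutated_ids: list[str]
    true_log2_ratio: np.ndarray  # noiseless Z . w component per mutated locus
    strain_features: StrainPairFeatures

    def write(self, outdir) -> None:
        from pathlib import Path

        from .motifs import write_motif_file

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(outdir / "strain_pairs.tsv", sep="\t", index=False)
        write_motif_file(self.library, outdir / "motifs.jaspar")


def generate_strain_pairs(
    spec: SyntheticSpec,
    library: Sequence[PositionProbabilityMatrix] | None = None,
    weights: Sequence[float] | None = None,
    baseline_reads: float = 1e9,
    pseudo_reads: float = 1.0,
) -> SyntheticStrainDataset:
    """Strain pairs: strain B mutates strain A; binding ratio follows Z . w.

    Strain-A loci carry planted causal motif instances; strain B applies
    point mutations at ``snp_rate`` per base and insertion/deletion events
    (length 1-3, insertion and deletion equiprobable) at ``indel_rate``.
    Read counts are constructed so that
    log2((reads_A + pseudo) / (reads_B + pseudo)) = Z . weights + N(0,
    noise_sd) over the mutated loci.  Unmutated loci are retained in the
    output (with equal read counts) so the mutated-loci filter is exercised.
    """
    if spec.snp_rate + spec.indel_rate <= 0:
        raise ValueError("strain pairs require snp_rate + indel_rate > 0")
    rng = np.random.default_rng(spec.seed)
    if library is None:
        library = generate_library(spec, rng)
    if weights is None:
        weights = np.zeros(len(library))
        weights[: spec.n_causal] = np.asarray(spec.true_weights)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != len(library):
        raise ValueError("weights must align with the library")

    seq_a = _random_sequences(rng, spec.n_loci, spec.locus_length, spec.gc_content)
    causal = np.flatnonzero(weights != 0)
    for j in causal:
        planted = rng.random(spec.n_loci) < spec.plant_prob
        for i in np.flatnonzero(planted):
            seq_a[i] = _plant(rng, seq_a[i], sample_motif_instance(rng, library[j]))
    seq_b = [_mutate_sequence(rng, s, spec.snp_rate, spec.indel_rate) for s in seq_a]

    ids = [f"locus_{i}" for i in range(spec.n_loci)]
    reads_a = np.full(spec.n_loci, baseline_reads)
    reads_b = np.full(spec.n_loci, baseline_reads)

    provisional = build_strain_features(
        list(zip(ids, seq_a, seq_b)),
        library,
        binding_a=reads_a,
        binding_b=reads_b,
        pseudo_reads=pseudo_reads,
    )
    clean = provisional.standardized @ weights
    noise = rng.normal(0.0, spec.noise_sd, size=provisional.n_loci) if spec.noise_sd > 0 else 0.0
    target = clean + noise
    # split the exponent across the strains so neither count underflows zero
    index = {lid: k for k, lid in enumerate(provisional.locus_ids)}
    for i, lid in enumerate(ids):
        if lid in index:
            t = target[index[lid]]
            reads_a[i] = (baseline_reads + pseudo_reads) * 2.0 ** (t / 2.0) - pseudo_reads
            reads_b[i] = (baseline_reads + pseudo_reads) * 2.0 ** (-t / 2.0) - pseudo_reads

    pairs = pd.DataFrame(
        {
            "locus_id": ids,
            "seq_strainA": seq_a,
            "seq_strainB": seq_b,
            "reads_strainA": reads_a,
            "reads_strainB": reads_b,
        }
    )
    sp = build_strain_features(
        pairs, library, pseudo_reads=pseudo_reads
    )
    return SyntheticStrainDataset(
        pairs, list(library), weights, list(provisional.locus_ids), clean, sp
    )


def generate_genome(
    seed: int,
    n_contigs: int = 3,
    contig_length: int = 100_000,
    gc_content: float = 0.41,
    n_block_rate: float = 5e-5,
    n_block_length: int = 50,
) -> dict[str, str]:
    """Random genome with occasional N blocks (unmappable-like stretches)."""
    rng = np.random.default_rng(seed)
    genome = {}
    for c in range(n_contigs):
        seq = list(_random_sequences(rng, 1, contig_length, gc_content)[0])
        n_blocks = rng.binomial(contig_length, n_block_rate)
        for _ in range(n_blocks):
            start = int(rng.integers(0, max(1, contig_length - n_block_length)))
            seq[start : start + n_block_length] = "N" * n_block_length
        genome[f"chr{c + 1}"] = "".join(seq)
    return genome
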