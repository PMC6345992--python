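"""Motif log-odds scoring, standardized feature matrices, and collinearity.

For every locus and motif we take the best-matching window on either strand
and quantify it as the log-odds score sum_i ln(p_i(base) / bg(base)); scores
below zero are floored at zero so degenerate partial matches still register
while non-matches contribute nothing.  Per-motif score columns are then
standardized (mean 0, variance 1 over all supplied loci) before model
training, and the variance inflation factor diagnoses residual redundancy
among motifs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from .motifs import PositionProbabilityMatrix, UNIFORM_BACKGROUND, as_background
from .sequences import Locus

_BASE_TO_INDEX = np.full(256, 4, dtype=np.int8)  # 4 = N / anything else
for _i, _b in enumerate("ACGT"):
    _BASE_TO_INDEX[ord(_b)] = _i
    _BASE_TO_INDEX[ord(_b.lower())] = _i

_VIF_CAP_R2 = 1.0 - 1e-12
VIF_CAP = 1e12


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0, C=1, G=2, T=3, other=4."""
    return _BASE_TO_INDEX[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _log_odds_table(ppm: PositionProbabilityMatrix, bg: np.ndarray) -> np.ndarray:
    # L x 5 lookup; column 4 (N) scores -inf so windows with ambiguity drop out
    with np.errstate(divide="ignore"):
        table = np.log(ppm.probs / bg)
    return np.hstack([table, np.full((ppm.length, 1), -np.inf)])


def score_sequences(
    sequences: Sequence[str],
    ppm: PositionProbabilityMatrix,
    bg: Sequence[float] = UNIFORM_BACKGROUND,
) -> np.ndarray:
    """Best-match motif score for each sequence (vectorized over loci).

    Scans every ungapped window of the motif's length on the forward and
    reverse-complement strand, returns max(0, best window log-odds score).
    Sequences shorter than the motif score 0.  N-containing windows are
    excluded (they score -inf before the floor).
    """
    bg = as_background(bg)
    if len(sequences) == 0:
        return np.zeros(0)
    L = ppm.length
    max_len = max(len(s) for s in sequences)
    encoded = np.full((len(sequences), max_len), 4, dtype=np.int8)
    for i, seq in enumerate(sequences):
        if seq:
            encoded[i, : len(seq)] = encode_sequence(seq)

    n_windows = max_len - L + 1
    if n_windows <= 0:
        return np.zeros(len(sequences))

    best = np.full(len(sequences), -np.inf)
    for table in (
        _log_odds_table(ppm, bg),
        _log_odds_table(ppm.reverse_complement(), bg),
    ):
        window_scores = np.zeros((len(sequences), n_windows))
        for i in range(L):
            window_scores += table[i, encoded[:, i : i + n_windows]]
        np.maximum(best, window_scores.max(axis=1), out=best)
    return np.maximum(best, 0.0)


def best_motif_score(
    sequence: str,
    ppm: PositionProbabilityMatrix,
    bg: Sequence[float] = UNIFORM_BACKGROUND,
) -> float:
    """Best-match log-odds score of one motif on one sequence (either strand)."""
    return float(score_sequences([sequence], ppm, bg)[0])


@dataclass
class FeatureMatrix:
    """Loci x motifs best-match scores with stored standardization.

    ``raw`` holds the zero-floored log-odds scores; ``standardized`` the
    per-column z-scores using the population standard deviation over all
    supplied loci.  Columns with zero variance are flagged in
    ``constant_mask`` and set to zero.
    """

    locus_ids: list[str]
    motif_names: list[str]
    raw: np.ndarray
    standardized: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    constant_mask: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.raw.shape[0]

    @property
    def n_motifs(self) -> int:
        return self.raw.shape[1]

    def column(self, motif_name: str) -> np.ndarray:
        return self.standardized[:, self.motif_names.index(motif_name)]

    def drop_motif(self, motif_name: str) -> "FeatureMatrix":
        if motif_name not in self.motif_names:
            raise KeyError(f"motif {motif_name!r} not in feature matrix")
        keep = [i for i, n in enumerate(self.motif_names) if n != motif_name]
        return FeatureMatrix(
            self.locus_ids,
            [self.motif_names[i] for i in keep],
            self.raw[:, keep],
            self.standardized[:, keep],
            self.col_means[keep],
            self.col_sds[keep],
            self.constant_mask[keep],
        )

    def to_tsv(self, path, sidecar_path=None) -> None:
        """Write raw scores as TSV plus a JSON sidecar with the scaling."""
        df = pd.DataFrame(self.raw, index=self.locus_ids, columns=self.motif_names)
        df.index.name = "locus_id"
        df.to_csv(path, sep="\t")
        sidecar = sidecar_path or str(path) + ".json"
        with open(sidecar, "w") as handle:
            json.dump(
                {
                    "motif_names": self.motif_names,
                    "col_means": self.col_means.tolist(),
                    "col_sds": self.col_sds.tolist(),
                    "constant_mask": self.constant_mask.astype(bool).tolist(),
                },
                handle,
                indent=1,
            )

    @classmethod
    def from_tsv(cls, path, sidecar_path=None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = sidecar_path or str(path) + ".json"
        with open(sidecar) as handle:
            meta = json.load(handle)
        raw = df.to_numpy(float)
        means = np.asarray(meta["col_means"])
        sds = np.asarray(meta["col_sds"])
        mask = np.asarray(meta["constant_mask"], dtype=bool)
        standardized = standardize_with(raw, means, sds, mask)
        return cls(
            [str(i) for i in df.index],
            list(df.columns),
            raw,
            standardized,
            means,
            sds,
            mask,
        )


def standardize_with(
    raw: np.ndarray, means: np.ndarray, sds: np.ndarray, constant_mask: np.ndarray
) -> np.ndarray:
    """Apply stored standardization; constant columns map to zero."""
    safe_sds = np.where(constant_mask, 1.0, sds)
    z = (raw - means) / safe_sds
    z[:, constant_mask] = 0.0
    return z


def build_feature_matrix(
    loci: Sequence[Locus] | Sequence[str],
    library: Sequence[PositionProbabilityMatrix],
    bg: Sequence[float] = UNIFORM_BACKGROUND,
) -> FeatureMatrix:
    """Score every locus against every motif and standardize per column.

    Standardization parameters (mean, population sd) are computed over all
    supplied loci jointly — binding sites and background together — so the
    matrix fed to the classifier has mean-0, variance-1 columns.
    """
    if len(loci) == 0 or len(library) == 0:
        raise ValueError("build_feature_matrix requires loci and a motif library")
    if isinstance(loci[0], Locus):
        sequences = [l.sequence for l in loci]
        locus_ids = [l.name or f"locus_{i}" for i, l in enumerate(loci)]
    else:
        sequences = list(loci)
        locus_ids = [f"locus_{i}" for i in range(len(sequences))]

    raw = np.column_stack([score_sequences(sequences, ppm, bg) for ppm in library])
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)  # population sd (divisor m)
    constant = sds < 1e-12
    standardized = standardize_with(raw, means, sds, constant)
    return FeatureMatrix(
        locus_ids,
        [p.name for p in library],
        raw,
        standardized,
        means,
        sds,
        constant,
    )


@dataclass
class VifReport:
    """Variance inflation factors: 1 / (1 - R^2) per motif.

    R^2 comes from ordinary least squares of one motif's scores on all the
    others.  Near-singular fits (R^2 within 1e-12 of 1) are capped at 1e12
    and flagged.  VIF above 10 conventionally marks problematic collinearity.
    """

    motif_names: list[str]
    r_squared: np.ndarray
    vif: np.ndarray
    capped: np.ndarray

    @property
    def max_vif(self) -> float:
        return float(self.vif.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif": self.motif_names,
                "r_squared": self.r_squared,
                "vif": self.vif,
                "capped": self.capped,
            }
        )


def compute_vif(features: FeatureMatrix) -> VifReport:
    """VIF for each motif from regressing its scores on the remaining motifs."""
    X = features.standardized
    m, n = X.shape
    if n < 2:
        raise ValueError("VIF requires at least two motifs")
    if m <= n + 1:
        warnings.warn(
            f"only {m} loci for {n} motifs; VIF estimates will be unstable",
            stacklevel=2,
        )
    r2 = np.zeros(n)
    for j in range(n):
        others = np.delete(X, j, axis=1)
        target = X[:, j]
        if features.constant_mask[j]:
            r2[j] = 0.0
            continue
        fit = LinearRegression().fit(others, target)
        r2[j] = max(0.0, fit.score(others, target))
    capped = r2 >= _VIF_CAP_R2
    vif = np.where(capped, VIF_CAP, 1.0 / (1.0 - np.minimum(r2, _VIF_CAP_R2)))
    return VifReport([str(n_) for n_ in features.motif_names], r2, vif, capped)
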