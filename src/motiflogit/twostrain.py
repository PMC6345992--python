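"""Condition-delta predictions and the two-strain variant-effect model.

Two complementary ways to predict changes in binding from motif scores:

* delta between conditions — with binding models trained separately on two
  treatment conditions, the predicted change in binding at a locus is the
  difference of the weighted sums, (W_a - W_b) . S_k, over its standardized
  motif scores.

* two-strain model — for loci whose sequence differs between two genomes
  (SNPs/indels), the standardized per-motif difference of best-match scores
  is regressed linearly on the observed log2 ratio of binding strength, so a
  motif's weight measures how much mutations in it shift binding between the
  strains.  Per-motif significance comes from a partial F-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .features import FeatureMatrix, score_sequences, standardize_with
from .model import BindingModel
from .motifs import PositionProbabilityMatrix, UNIFORM_BACKGROUND


@dataclass
class DeltaPrediction:
    locus_ids: list[str]
    delta: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"locus_id": self.locus_ids, "predicted_delta": self.delta})


def _weights_in_order(model: BindingModel, motif_names: Sequence[str]) -> np.ndarray:
    if set(model.motif_names) != set(motif_names):
        missing = sorted(set(motif_names) - set(model.motif_names))
        extra = sorted(set(model.motif_names) - set(motif_names))
        raise ValueError(
            f"motif mismatch; model lacks {missing}; model has unexpected {extra}"
        )
    index = {name: i for i, name in enumerate(model.motif_names)}
    return model.weights[[index[name] for name in motif_names]]


def predict_delta(
    model_a: BindingModel, model_b: BindingModel, features: FeatureMatrix
) -> DeltaPrediction:
    """Predicted change in binding between conditions a and b per locus.

    delta_k = W_a . S_k - W_b . S_k = (W_a - W_b) . S_k, where S_k is the
    standardized motif score vector of locus k from the supplied features.
    """
    wa = _weights_in_order(model_a, features.motif_names)
    wb = _weights_in_order(model_b, features.motif_names)
    delta = features.standardized @ (wa - wb)
    if not np.all(np.isfinite(delta)):
        raise ValueError("non-finite delta predictions")
    return DeltaPrediction(list(features.locus_ids), delta)


def single_motif_delta_correlation(
    features: FeatureMatrix,
    observed_delta,
    model_a: BindingModel | None = None,
    model_b: BindingModel | None = None,
) -> tuple[pd.Series, float | None]:
    """Correlation of each motif's score — and of the model delta — with an
    observed change in binding.

    Returns (per-motif Pearson correlations, correlation of the
    two-model delta prediction or None when models are not supplied).
    A constant ``observed_delta`` is undefined and raises.
    """
    observed = np.asarray(observed_delta, dtype=float)
    if observed.shape[0] != features.n_loci:
        raise ValueError("observed_delta length must match the number of loci")
    if observed.shape[0] < 3:
        raise ValueError("need at least 3 loci to correlate")
    if np.std(observed) == 0:
        raise ValueError("observed_delta is constant; correlation undefined")

    per_motif = {}
    for j, name in enumerate(features.motif_names):
        col = features.standardized[:, j]
        per_motif[name] = (
            float(np.corrcoef(col, observed)[0, 1]) if np.std(col) > 0 else np.nan
        )
    series = pd.Series(per_motif, name="correlation")

    model_corr = None
    if model_a is not None and model_b is not None:
        delta = predict_delta(model_a, model_b, features).delta
        model_corr = float(np.corrcoef(delta, observed)[0, 1])
    return series, model_corr


@dataclass
class StrainPairFeatures:
    """Per-locus motif score differences between two genomes, mutated loci only.

    ``score_diff`` (D) is strain-A minus strain-B best-match score per motif;
    ``standardized`` (Z) is D standardized per column over the retained loci;
    ``log2_ratio`` is log2 of (strain-A reads + pseudo) / (strain-B reads +
    pseudo).
    """

    locus_ids: list[str]
    motif_names: list[str]
    score_diff: np.ndarray
    standardized: np.ndarray
    log2_ratio: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    constant_mask: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.score_diff.shape[0]


def build_strain_features(
    pairs,
    library: Sequence[PositionProbabilityMatrix],
    bg=UNIFORM_BACKGROUND,
    binding_a=None,
    binding_b=None,
    pseudo_reads: float = 1.0,
) -> StrainPairFeatures:
    """Score paired per-locus sequences from two genomes.

    ``pairs`` is either a DataFrame with columns locus_id, seq_strainA,
    seq_strainB (and optionally reads_strainA / reads_strainB) or a sequence
    of (locus_id, seq_a, seq_b) tuples with read counts passed separately.
    Loci whose sequences are identical in the two strains carry no variant
    signal and are dropped.  Sequences of unequal length (indels) are scored
    natively.
    """
    if isinstance(pairs, pd.DataFrame):
        ids = [str(x) for x in pairs["locus_id"]]
        seq_a = [s.upper() for s in pairs["seq_strainA"]]
        seq_b = [s.upper() for s in pairs["seq_strainB"]]
        if binding_a is None and "reads_strainA" in pairs:
            binding_a = pairs["reads_strainA"].to_numpy(float)
        if binding_b is None and "reads_strainB" in pairs:
            binding_b = pairs["reads_strainB"].to_numpy(float)
    else:
        ids = [str(p[0]) for p in pairs]
        seq_a = [p[1].upper() for p in pairs]
        seq_b = [p[2].upper() for p in pairs]
    if binding_a is None or binding_b is None:
        raise ValueError("read counts for both strains are required")
    binding_a = np.asarray(binding_a, dtype=float)
    binding_b = np.asarray(binding_b, dtype=float)
    if not (len(ids) == len(seq_a) == len(seq_b) == len(binding_a) == len(binding_b)):
        raise ValueError("pair lists and read counts must have equal length")
    if np.any(binding_a < 0) or np.any(binding_b < 0):
        raise ValueError("read counts must be non-negative")

    mutated = [i for i in range(len(ids)) if seq_a[i] != seq_b[i]]
    motif_names = [p.name for p in library]
    if not mutated:
        warnings.warn("no locus differs between the strains; empty feature set", stacklevel=2)
        empty = np.zeros((0, len(library)))
        zeros = np.zeros(len(library))
        return StrainPairFeatures(
            [], motif_names, empty, empty.copy(), np.zeros(0), zeros, zeros.copy(),
            np.ones(len(library), dtype=bool),
        )

    sa = [seq_a[i] for i in mutated]
    sb = [seq_b[i] for i in mutated]
    scores_a = np.column_stack([score_sequences(sa, ppm, bg) for ppm in library])
    scores_b = np.column_stack([score_sequences(sb, ppm, bg) for ppm in library])
    diff = scores_a - scores_b
    means = diff.mean(axis=0)
    sds = diff.std(axis=0)
    constant = sds < 1e-12
    z = standardize_with(diff, means, sds, constant)
    log2_ratio = np.log2(
        (binding_a[mutated] + pseudo_reads) / (binding_b[mutated] + pseudo_reads)
    )
    return StrainPairFeatures(
        [ids[i] for i in mutated], motif_names, diff, z, log2_ratio, means, sds, constant
    )


def read_strain_pairs_tsv(path) -> pd.DataFrame:
    """Read the two-strain input TSV (locus_id, seq_strainA, seq_strainB,
    reads_strainA, reads_strainB)."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
    required = {"locus_id", "seq_strainA", "seq_strainB", "reads_strainA", "reads_strainB"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"strain pair TSV missing columns: {sorted(missing)}")
    return df


@dataclass
class TwoStrainModel:
    """Linear model of strain-specific binding from motif score differences."""

    motif_names: list[str]
    weights: np.ndarray  # fold means
    intercept: float
    fold_weights: np.ndarray
    fold_intercepts: np.ndarray
    p_values: np.ndarray  # per-motif partial F-test, full-data fit

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"motif": self.motif_names, "weight": self.weights, "p_value": self.p_values}
        )


def _partial_f_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Drop-one-column partial F-test p-values from a full-data OLS fit."""
    m, n = X.shape
    design = np.hstack([np.ones((m, 1)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss_full = float(np.sum((y - design @ beta) ** 2))
    df_resid = m - n - 1
    pvals = np.ones(n)
    for j in range(n):
        reduced = np.delete(design, j + 1, axis=1)
        beta_r, *_ = np.linalg.lstsq(reduced, y, rcond=None)
        rss_reduced = float(np.sum((y - reduced @ beta_r) ** 2))
        if df_resid <= 0:
            pvals[j] = np.nan
            continue
        if rss_full <= 1e-300:
            # perfect fit: any motif whose removal breaks it is maximally significant
            pvals[j] = 0.0 if rss_reduced > 1e-12 else 1.0
            continue
        f_stat = max(0.0, (rss_reduced - rss_full)) / (rss_full / df_resid)
        pvals[j] = float(f_dist.sf(f_stat, 1, df_resid))
    return pvals


def train_two_strain(
    sp: StrainPairFeatures, n_folds: int = 5, seed: int = 0
) -> TwoStrainModel:
    """Fit the two-strain linear model under cross-validation.

    Ordinary least squares of log2 binding ratio on standardized score
    differences per fold (80/20 splits); reported weights are fold means.
    Per-motif significance is a partial F-test on the full-data fit.
    """
    if sp.n_loci == 0:
        raise ValueError("no mutated loci to train on")
    X, y = sp.standardized, sp.log2_ratio
    if sp.n_loci <= len(sp.motif_names):
        warnings.warn(
            f"only {sp.n_loci} mutated loci for {len(sp.motif_names)} motifs; "
            "fit may be rank-deficient",
            stacklevel=2,
        )
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_weights, fold_intercepts = [], []
    for train_idx, _ in splitter.split(X):
        fit = LinearRegression().fit(X[train_idx], y[train_idx])
        fold_weights.append(fit.coef_.copy())
        fold_intercepts.append(float(fit.intercept_))
    fold_weights = np.vstack(fold_weights)
    fold_intercepts = np.asarray(fold_intercepts)
    return TwoStrainModel(
        motif_names=list(sp.motif_names),
        weights=fold_weights.mean(axis=0),
        intercept=float(fold_intercepts.mean()),
        fold_weights=fold_weights,
        fold_intercepts=fold_intercepts,
        p_values=_partial_f_pvalues(X, y),
    )


def predict_strain_specific(model, sp: StrainPairFeatures) -> np.ndarray:
    """Predicted strain-specific binding (log2 scale) per mutated locus.

    Accepts either a ``TwoStrainModel`` (weights . Z + intercept) or a
    single-strain ``BindingModel`` whose weights are applied directly to the
    standardized score differences (no intercept) — both read-outs predict
    which strain binds more strongly at a mutated locus.
    """
    if set(model.motif_names) != set(sp.motif_names):
        missing = sorted(set(sp.motif_names) - set(model.motif_names))
        extra = sorted(set(model.motif_names) - set(sp.motif_names))
        raise ValueError(f"motif mismatch; model lacks {missing}; extra {extra}")
    index = {name: i for i, name in enumerate(model.motif_names)}
    weights = np.asarray(model.weights)[[index[n] for n in sp.motif_names]]
    intercept = model.intercept if isinstance(model, TwoStrainModel) else 0.0
    return sp.standardized @ weights + intercept
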