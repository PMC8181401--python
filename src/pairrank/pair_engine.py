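"""Core gene-pair machinery: filtering, binarization, risk scoring.

The central transform converts a genes x samples expression matrix into a
binary pairs x samples indicator matrix: indicator(a, b, s) = 1 exactly
when gene *a* out-expresses gene *b* within sample *s* (ties score 0).
Because the indicator depends only on the within-sample ordering, it is
invariant under any strictly increasing per-sample transform of the
expression values — the property that lets a signature trained on one
platform score samples from another without normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GenePairSignature
from .errors import ValidationError

logger = logging.getLogger(__name__)

PAIR_SEP = "|"


@dataclass
class PipelineConfig:
    """Tunable thresholds of the pair pipeline with their conventional defaults.

    mad_threshold
        Genes with median absolute deviation (no consistency constant)
        at or below this value are dropped before pairing.
    prevalence_min
        A pair whose indicator is 1 (or 0) in less than this fraction of
        samples is uninformative and dropped; exactly the boundary is kept.
    cutoff_horizon, validation_horizon
        Months at which the risk-score cutoff is chosen (time-dependent
        ROC) and at which validation AUC is reported.
    n_iterations
        Subsample-refit repetitions of the penalized Cox selection.
    mad_log2
        Compute MAD on log2(x+1) values (recommended for counts) rather
        than the native scale (intensities).
    """

    mad_threshold: float = 0.5
    prevalence_min: float = 0.20
    cutoff_horizon: float = 36.0
    validation_horizon: float = 60.0
    n_iterations: int = 1000
    subsample_frac: float = 0.8
    seed: int = 0
    mad_log2: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_min < 0.5:
            raise ValidationError("prevalence_min must lie in (0, 0.5)")
        for name in ("mad_threshold", "cutoff_horizon", "validation_horizon"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def pair_id(gene_a: str, gene_b: str) -> str:
    return f"{gene_a}{PAIR_SEP}{gene_b}"


def split_pair_id(pid: str) -> tuple[str, str]:
    a, b = pid.split(PAIR_SEP)
    return a, b


def median_absolute_deviation(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Raw MAD: median of absolute deviations from the median, unscaled."""
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


def mad_filter(
    expr: pd.DataFrame, threshold: float = 0.5, log2_transform: bool = False
) -> pd.DataFrame:
    """Keep genes whose MAD across samples is strictly greater than ``threshold``.

    ``log2_transform`` computes the MAD on log2(x+1) values, the sensible
    scale for RNA-seq counts; intensities are filtered on the native scale.
    Gene order is preserved.
    """
    if expr.shape[1] < 2:
        raise ValidationError("MAD filter needs at least 2 samples")
    values = expr.to_numpy(dtype=float)
    if log2_transform:
        values = np.log2(values + 1.0)
    mads = median_absolute_deviation(values, axis=1)
    keep = mads > threshold
    logger.info("MAD filter: %d of %d genes retained", int(keep.sum()), len(expr))
    return expr.loc[keep]


def restrict_to_genes(expr: pd.DataFrame, genes: set[str]) -> pd.DataFrame:
    """Subset the matrix to a gene list (e.g. immune-related genes)."""
    keep = expr.index.isin(genes)
    n = int(keep.sum())
    if n == 0:
        raise ValidationError("gene list shares no symbols with the matrix")
    logger.info("gene-list intersection: %d of %d genes retained", n, len(expr))
    return expr.loc[keep]


def binarize_pairs(expr: pd.DataFrame) -> pd.DataFrame:
    """All-pairs within-sample comparison.

    For G genes, returns a G*(G-1)/2 x samples binary matrix with one row
    per unordered pair in canonical direction (gene_a precedes gene_b in
    the input row order); entry 1 iff expr(gene_a) > expr(gene_b) in that
    sample, ties 0. The reverse direction is the complement on tie-free
    data and is never emitted.
    """
    if expr.index.has_duplicates or expr.columns.has_duplicates:
        raise ValidationError("duplicate gene or sample ids")
    if len(expr) < 2:
        raise ValidationError("pairing needs at least 2 genes")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("non-finite expression values")
    ii, jj = np.triu_indices(len(expr), k=1)
    indicators = (values[ii] > values[jj]).astype(np.int8)
    genes = expr.index.to_numpy()
    index = pd.Index(
        [pair_id(genes[i], genes[j]) for i, j in zip(ii, jj)], name="pair"
    )
    return pd.DataFrame(indicators, index=index, columns=expr.columns)


def prevalence_filter(ind: pd.DataFrame, min_frac: float = 0.20) -> pd.DataFrame:
    """Drop pairs whose minority score fraction is below ``min_frac``.

    A pair that is 1 (or 0) in almost every sample carries no ranking
    information; "less than" is read literally, so a pair exactly at the
    boundary is kept. Order preserved.
    """
    if ind.shape[1] < 1:
        raise ValidationError("prevalence filter needs at least 1 sample")
    frac_ones = ind.to_numpy(dtype=float).mean(axis=1)
    keep = np.minimum(frac_ones, 1.0 - frac_ones) >= min_frac
    logger.info(
        "prevalence filter: %d of %d pairs retained", int(keep.sum()), len(ind)
    )
    return ind.loc[keep]


def resolve_signature_indicators(
    ind: pd.DataFrame, sig: GenePairSignature
) -> pd.DataFrame:
    """Indicator rows for each signature pair, complementing reversed pairs.

    A signature pair (a, b) stored in the matrix as (b, a) is recovered as
    1 - indicator(b, a); on tie-free data this equals indicator(a, b).
    """
    available = set(ind.index)
    rows = []
    missing: list[str] = []
    for a, b in sig.pairs:
        fwd, rev = pair_id(a, b), pair_id(b, a)
        if fwd in available:
            rows.append(ind.loc[fwd].to_numpy(dtype=float))
        elif rev in available:
            rows.append(1.0 - ind.loc[rev].to_numpy(dtype=float))
        else:
            missing.append(fwd)
    if missing:
        raise ValidationError(
            f"signature pairs unresolvable in indicator matrix: {missing}"
        )
    index = pd.Index([pair_id(a, b) for a, b in sig.pairs], name="pair")
    return pd.DataFrame(np.asarray(rows), index=index, columns=ind.columns)


def risk_score(ind: pd.DataFrame, sig: GenePairSignature) -> pd.Series:
    """Per-sample risk score: the coefficient-weighted sum of pair indicators."""
    resolved = resolve_signature_indicators(ind, sig)
    scores = sig.coefficients @ resolved.to_numpy(dtype=float)
    return pd.Series(scores, index=ind.columns, name="risk_score")


def assign_groups(scores: pd.Series, cutoff: float) -> pd.Series:
    """Dichotomize scores at a cutoff: strictly above -> ``high``, else ``low``."""
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    labels = np.where(scores.to_numpy(dtype=float) > cutoff, "high", "low")
    return pd.Series(labels, index=scores.index, name="group")
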