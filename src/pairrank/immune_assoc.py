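"""Immune-cell fraction estimation and association with the risk score.

Cell composition is estimated from bulk expression by non-negative least
squares against a user-supplied cell-type signature (basis) matrix, with
the fitted mixing weights normalized to fractions. The module also accepts
externally computed fraction tables (e.g. output of a dedicated
deconvolution service) for the downstream association tests: rank-sum
group differences and Pearson correlation with the risk score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError


def deconvolve(mixture: pd.DataFrame, basis: pd.DataFrame) -> pd.DataFrame:
    """Estimate cell-type fractions per sample by NNLS.

    ``mixture`` is genes x samples bulk expression; ``basis`` is genes x
    cell-types reference profiles. Fitting uses the genes shared by both;
    fitted non-negative weights are normalized to sum to 1 per sample.
    """
    shared = basis.index.intersection(mixture.index)
    if len(shared) == 0:
        raise ValidationError("basis and mixture share no genes")
    B = basis.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(B) < basis.shape[1]:
        raise ValidationError("basis matrix is rank-deficient on the shared genes")
    M = mixture.loc[shared].to_numpy(dtype=float)
    fractions = np.zeros((mixture.shape[1], basis.shape[1]))
    for s in range(M.shape[1]):
        weights, _ = optimize.nnls(B, M[:, s])
        total = weights.sum()
        if total <= 0:
            raise ValidationError(
                f"all-zero deconvolution for sample {mixture.columns[s]!r}"
            )
        fractions[s] = weights / total
    return pd.DataFrame(fractions, index=mixture.columns, columns=basis.columns)


def validate_fractions(fractions: pd.DataFrame, atol: float = 1e-9) -> pd.DataFrame:
    values = fractions.to_numpy(dtype=float)
    if (values < -atol).any():
        raise ValidationError("negative cell fractions")
    if not np.allclose(values.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("cell fractions do not sum to 1 per sample")
    return fractions


def compare_groups(fractions: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Two-sided rank-sum test of each cell type between two groups.

    Returns per cell type the group medians and the Mann-Whitney p-value;
    a cell type constant across all samples is flagged with p = 1.
    """
    groups = groups.loc[fractions.index]
    levels = [str(g) for g in pd.unique(groups)]
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 groups required, got {levels}")
    a_mask = (groups == pd.unique(groups)[0]).to_numpy()
    if a_mask.sum() < 3 or (~a_mask).sum() < 3:
        raise ValidationError("each group needs at least 3 samples")
    rows = []
    for cell in fractions.columns:
        xa = fractions.loc[a_mask, cell].to_numpy(dtype=float)
        xb = fractions.loc[~a_mask, cell].to_numpy(dtype=float)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            p, degenerate = 1.0, True
        else:
            _, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            degenerate = False
        rows.append(
            {
                "cell_type": cell,
                f"median_{levels[0]}": float(np.median(xa)),
                f"median_{levels[1]}": float(np.median(xb)),
                "p_value": float(p),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


def correlate_with_score(fractions: pd.DataFrame, scores: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each cell-type fraction with the risk score."""
    common = fractions.index.intersection(scores.index)
    if len(common) < 3:
        raise ValidationError("need at least 3 aligned samples")
    x = scores.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("risk score has zero variance")
    rows = []
    for cell in fractions.columns:
        y = fractions.loc[common, cell].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValidationError(f"cell type {cell!r} has zero variance")
        r, p = stats.pearsonr(x, y)
        rows.append({"cell_type": cell, "pearson_r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows).set_index("cell_type")
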