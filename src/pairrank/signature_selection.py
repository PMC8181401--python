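"""Signature construction: stability-style resampled LASSO-Cox selection.

The selection repeatedly subsamples the cohort, fits an L1-penalized Cox
proportional-hazards model on the pair indicators with the penalty chosen
by internal cross-validation (partial-likelihood loss, Breslow ties), and
records which pairs receive nonzero coefficients. Pairs that are selected
in a large fraction of repetitions form the signature; their final
coefficients come from a single penalized fit on the full training data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .data_io import GenePairSignature
from .errors import FitError, ValidationError
from .pair_engine import split_pair_id

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of the resampled selection.

    ``pair_frequencies`` maps each candidate pair to the fraction of
    iterations in which its penalized coefficient was nonzero.
    """

    pair_frequencies: pd.Series
    n_iterations: int
    seed: int
    selected_pairs: list[str] = field(default_factory=list)


def _align(ind: pd.DataFrame, surv: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    common = ind.columns.intersection(surv.index)
    if len(common) < len(ind.columns) or len(common) < len(surv.index):
        logger.info("aligning on %d shared samples", len(common))
    if len(common) == 0:
        raise ValidationError("indicator matrix and survival table share no samples")
    X = ind[common].to_numpy(dtype=float).T
    sub = surv.loc[common]
    return X, sub["time"].to_numpy(dtype=float), sub["status"].to_numpy(dtype=int)


def breslow_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                   beta: np.ndarray) -> float:
    """Breslow-tie Cox partial log-likelihood at a fixed coefficient vector."""
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    eta = X[order] @ beta
    # risk set of subject i (ascending time) = subjects i..n-1
    exp_eta = np.exp(eta - eta.max())
    risk = np.cumsum(exp_eta[::-1])[::-1]
    ll = 0.0
    for t in np.unique(time[event == 1]):
        at = (time == t) & (event == 1)
        d = int(at.sum())
        first = np.searchsorted(time, t, side="left")
        ll += eta[at].sum() - d * (np.log(risk[first]) + eta.max())
    return float(ll)


def _cv_alpha(X: np.ndarray, time: np.ndarray, event: np.ndarray,
              alphas: np.ndarray, cv_folds: int, rng: np.random.Generator) -> float:
    """Pick the penalty maximizing cross-validated test partial likelihood."""
    n = len(time)
    idx = rng.permutation(n)
    folds = np.array_split(idx, cv_folds)
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    y_all = Surv.from_arrays(event=event.astype(bool), time=time)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        if event[mask].sum() == 0 or event[~mask].sum() == 0:
            continue
        est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, tol=1e-6)
        try:
            with warnings.catch_warnings():
                # early termination at extreme penalties is expected in CV
                warnings.simplefilter("ignore")
                est.fit(X[mask], y_all[mask])
        except (ValueError, ArithmeticError):
            continue
        fitted = {a: k for k, a in enumerate(est.alphas_)}
        for k, a in enumerate(alphas):
            if a not in fitted:
                continue
            beta = est.coef_[:, fitted[a]]
            scores[k] += breslow_loglik(X[~mask], time[~mask], event[~mask], beta)
            counts[k] += 1
    valid = counts == counts.max()
    if counts.max() == 0:
        raise FitError("cross-validation failed in every fold")
    best = np.flatnonzero(valid)[np.argmax(scores[valid])]
    return float(alphas[best])


def _fit_path(X: np.ndarray, time: np.ndarray, event: np.ndarray,
              n_alphas: int = 30) -> tuple[CoxnetSurvivalAnalysis, np.ndarray]:
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    est = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.05, tol=1e-6
    )
    est.fit(X, y)
    return est, np.asarray(est.alphas_)


def resampled_lasso(
    ind: pd.DataFrame,
    surv: pd.DataFrame,
    n_iter: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    cv_folds: int = 3,
    max_retries: int = 25,
) -> SelectionResult:
    """Subsample-refit frequency selection of prognostic pairs.

    Each iteration draws ``subsample_frac`` of the samples without
    replacement, fits the penalized Cox path, picks the penalty by
    ``cv_folds``-fold cross-validated partial likelihood, and records the
    pairs with nonzero coefficients at that penalty. Deterministic given
    ``seed``; per-iteration generators are spawned from one master seed.
    """
    X, time, event = _align(ind, surv)
    n, p = X.shape
    if n < 30 or event.sum() < 10:
        raise ValidationError(
            f"selection needs >=30 samples with >=10 events (got n={n}, "
            f"events={int(event.sum())})"
        )
    n_sub = max(2, int(round(subsample_frac * n)))
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_iter)
    counts = np.zeros(p)
    for it in range(n_iter):
        rng = np.random.default_rng(child_seeds[it])
        for attempt in range(max_retries + 1):
            pick = rng.choice(n, size=n_sub, replace=False)
            if event[pick].sum() >= 2:
                break
        else:
            raise FitError(
                f"iteration {it}: no events in subsample after {max_retries} redraws"
            )
        Xs, ts, es = X[pick], time[pick], event[pick]
        try:
            est, alphas = _fit_path(Xs, ts, es)
            alpha = _cv_alpha(Xs, ts, es, alphas, cv_folds, rng)
            k = int(np.argmin(np.abs(np.asarray(est.alphas_) - alpha)))
            beta = est.coef_[:, k]
        except FitError:
            continue
        counts += beta != 0.0
    freqs = pd.Series(counts / n_iter, index=ind.index, name="frequency")
    return SelectionResult(pair_frequencies=freqs, n_iterations=n_iter, seed=seed)


def select_top(
    result: SelectionResult,
    min_frequency: float | None = None,
    top_k: int | None = None,
) -> list[str]:
    """Pairs passing a frequency threshold or the top-k, highest first.

    Ties in frequency are broken lexicographically by pair id so the
    selection is stable across runs.
    """
    if (min_frequency is None) == (top_k is None):
        raise ValueError("specify exactly one of min_frequency or top_k")
    freqs = result.pair_frequencies
    if freqs.empty:
        raise ValidationError("empty frequency table")
    ordered = freqs.iloc[
        np.lexsort((freqs.index.to_numpy(), -freqs.to_numpy()))
    ]
    if min_frequency is not None:
        chosen = ordered[ordered >= min_frequency]
    else:
        chosen = ordered.iloc[: int(top_k)]
    if chosen.empty:
        raise ValidationError("selection rule matched zero pairs")
    selected = chosen.index.tolist()
    result.selected_pairs = selected
    return selected


def fit_final(
    ind: pd.DataFrame,
    surv: pd.DataFrame,
    pairs: list[str],
    seed: int = 0,
    cv_folds: int = 5,
) -> GenePairSignature:
    """Final coefficients: one penalized Cox fit on the full training data.

    The model is restricted to the selected pairs at the cross-validation
    optimal penalty. Pairs shrunk exactly to zero are dropped (logged).
    """
    if not pairs:
        raise ValidationError("no pairs selected")
    missing = [p for p in pairs if p not in ind.index]
    if missing:
        raise ValidationError(f"selected pairs absent from indicator matrix: {missing}")
    sub = ind.loc[pairs]
    X, time, event = _align(sub, surv)
    rng = np.random.default_rng(seed)
    try:
        est, alphas = _fit_path(X, time, event)
        alpha = _cv_alpha(X, time, event, alphas, cv_folds, rng)
        k = int(np.argmin(np.abs(np.asarray(est.alphas_) - alpha)))
        beta = est.coef_[:, k]
    except (ValueError, ArithmeticError) as exc:
        raise FitError(f"final penalized Cox fit failed: {exc}") from exc
    nonzero = beta != 0.0
    if nonzero.sum() < len(pairs):
        dropped = [p for p, nz in zip(pairs, nonzero) if not nz]
        logger.info("dropping %d zero-coefficient pairs: %s", len(dropped), dropped)
    kept = [p for p, nz in zip(pairs, nonzero) if nz]
    if not kept:
        raise FitError("all selected pairs shrunk to zero in the final fit")
    return GenePairSignature(
        pairs=[split_pair_id(p) for p in kept],
        coefficients=beta[nonzero],
        metadata={"penalty": float(alpha), "n_training_samples": len(time)},
    )
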