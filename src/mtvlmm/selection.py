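"""Chronological splitting, per-taxon (p, q) selection, and the AR(1) baseline.

Each individual's series is cut into contiguous train / validation / test
blocks (default thirds, remainders to the earlier blocks). Candidate
(p, q) models are fitted on the train block, scored by one-step-ahead R^2
on the validation block, and the winner — ties broken toward the simpler
model — is finally scored once on the test block.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .data_io import LongitudinalDataset
from .prediction import fit_predict_block, prediction_r2

__all__ = [
    "ChronoSplit",
    "chrono_split",
    "select_model",
    "SelectionResult",
    "ar1_baseline",
    "compare_methods",
]

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATES: list[tuple[int, int]] = [(0, 1), (1, 1), (0, 3), (1, 3)]


@dataclasses.dataclass
class ChronoSplit:
    """Per-individual contiguous train/validation/test position sets."""

    train: dict[str, np.ndarray]
    validation: dict[str, np.ndarray]
    test: dict[str, np.ndarray]
    fractions: tuple[float, float, float]
    individuals: list[str]


def chrono_split(
    dataset: LongitudinalDataset,
    fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    l_max: int = 0,
) -> ChronoSplit:
    """Cut each individual's time series into ordered thirds (by default).

    Block sizes are floor allocations of ``T_i * fraction`` with the
    remainder given to the earlier blocks, so T=31 under thirds yields
    11/10/10. Individuals too short to support all candidate models
    (``T_i < 3 * l_max``) are dropped with a warning.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("need three positive fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    train, val, test = {}, {}, {}
    kept = []
    for ind in dataset.individuals:
        T = dataset.timepoints(ind)
        if l_max and T < 3 * l_max:
            logger.warning(
                "individual %r dropped from split: T=%d < 3*l_max=%d",
                ind, T, 3 * l_max,
            )
            continue
        sizes = [int(np.floor(T * f)) for f in fractions]
        rem = T - sum(sizes)
        for k in range(rem):
            sizes[k % 3] += 1
        if min(sizes) == 0:
            logger.warning("individual %r dropped from split: empty block", ind)
            continue
        a, b = sizes[0], sizes[0] + sizes[1]
        train[ind] = np.arange(0, a)
        val[ind] = np.arange(a, b)
        test[ind] = np.arange(b, T)
        kept.append(ind)
    if not kept:
        raise ValueError("no individual supports the requested split")
    return ChronoSplit(
        train=train, validation=val, test=test,
        fractions=fractions, individuals=kept,
    )


@dataclasses.dataclass
class SelectionResult:
    focal_taxon: str
    chosen_p: int
    chosen_q: int
    r2_validation: dict[tuple[int, int], float]
    r2_test: float


def select_model(
    dataset: LongitudinalDataset,
    focal_taxon: str,
    split: ChronoSplit,
    candidates: list[tuple[int, int]] | None = None,
    rng_seed: int = 0,
) -> SelectionResult:
    """Choose (p, q) for one taxon by validation-block prediction accuracy.

    Each candidate is fitted on the train block and scored by one-step-ahead
    R^2 on the validation block; the argmax wins, ties broken toward smaller
    q then smaller p. The reported test R^2 is computed once, for the
    selected model only (still fitted on the train block alone). A taxon
    for which no candidate converges is reported as unmodellable.
    """
    candidates = DEFAULT_CANDIDATES if candidates is None else list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    scores: dict[tuple[int, int], float] = {}
    for (p, q) in candidates:
        try:
            obs, pred, _, _, _ = fit_predict_block(
                dataset, focal_taxon, p, q,
                train_positions=split.train,
                target_positions=split.validation,
                rng_seed=rng_seed,
            )
            scores[(p, q)] = prediction_r2(obs, pred)
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            logger.warning(
                "candidate (p=%d, q=%d) failed for %r: %s", p, q, focal_taxon, exc
            )
    if not scores:
        raise RuntimeError(f"taxon {focal_taxon!r} is unmodellable: "
                           "no candidate model converged")
    # argmax with ties toward simpler models: smaller q, then smaller p
    best = min(scores, key=lambda pq: (-scores[pq], pq[1], pq[0]))
    obs, pred, _, _, _ = fit_predict_block(
        dataset, focal_taxon, best[0], best[1],
        train_positions=split.train,
        target_positions=split.test,
        rng_seed=rng_seed,
    )
    return SelectionResult(
        focal_taxon=focal_taxon,
        chosen_p=best[0],
        chosen_q=best[1],
        r2_validation=scores,
        r2_test=prediction_r2(obs, pred),
    )


def ar1_baseline(
    dataset: LongitudinalDataset,
    focal_taxon: str,
    split: ChronoSplit,
) -> float:
    """Pooled test R^2 of a per-individual AR(1) least-squares baseline.

    For each individual, y_t is regressed on [1, y_{t-1}] over the
    train+validation block (the baseline has no hyperparameters to tune),
    then one-step-ahead predictions are made on the test block from
    observed lags; R^2 is computed over the pooled test points. A constant
    training series degenerates to an intercept-only prediction.
    """
    j = dataset.taxon_index(focal_taxon)
    obs_all, pred_all = [], []
    for ind in split.individuals:
        y = dataset.matrices[ind][j]
        fit_pos = np.concatenate([split.train[ind], split.validation[ind]])
        fit_pos = np.sort(fit_pos)
        t_fit = fit_pos[fit_pos >= 1]
        A = np.column_stack([np.ones(len(t_fit)), y[t_fit - 1]])
        coef, *_ = np.linalg.lstsq(A, y[t_fit], rcond=None)
        for t in split.test[ind]:
            if t < 1:
                continue
            obs_all.append(y[t])
            pred_all.append(coef[0] + coef[1] * y[t - 1])
    obs_all = np.asarray(obs_all)
    pred_all = np.asarray(pred_all)
    if np.var(pred_all) == 0 or np.var(obs_all) == 0:
        logger.warning("degenerate AR(1) baseline for %r; R^2 = 0", focal_taxon)
        return 0.0
    return prediction_r2(obs_all, pred_all)


def compare_methods(scores_a, scores_b) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test between two per-taxon R^2 vectors.

    Returns ``(p_value, median paired difference)``; identical vectors give
    p = 1 by convention.
    """
    from scipy import stats

    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be paired (equal length)")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    median_diff = float(np.median(diff))
    if np.all(diff == 0):
        return 1.0, median_diff
    res = stats.wilcoxon(a, b)
    return float(res.pvalue), median_diff
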