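"""BLUP prediction of held-out time points and species-species associations.

Under the fitted model the joint distribution of training responses and a
new observation is multivariate normal, so the best predictor of the new
point is the conditional mean

    mean = x' beta + c' Sigma^{-1} (y - X beta)
    var  = s_new - c' Sigma^{-1} c

with ``Sigma = s_u W~ W~' + s_r H H' + s_eps I`` and ``c`` the covariance
between the new point and the training rows. The community (AR) part of
``c`` is ``s_u * (W~ w_new)``; the individual part has no temporal
information by construction (H is time-scrambled), so its cross-covariance
is taken at the individual-block mean level.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import linalg

from .data_io import LongitudinalDataset
from .design import (
    CommunityCoding,
    LaggedDesign,
    TemporalKinship,
    build_kinship,
    build_lagged_design,
    quantile_bin,
)
from .reml import REMLFit, reml_fit

__all__ = [
    "BlupPrediction",
    "AssociationMatrix",
    "blup_predict",
    "community_cross_cov",
    "sequential_predict",
    "fit_predict_block",
    "prediction_r2",
    "estimate_associations",
    "pca_embedding",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class BlupPrediction:
    predicted: np.ndarray
    conditional_var: np.ndarray
    targets: list[tuple[str, float]]


@dataclasses.dataclass
class AssociationMatrix:
    """BLUP effect matrix U; ``U[i, j]`` is the effect of taxon i on taxon j."""

    U: np.ndarray
    taxa_ids: list[str]
    column_meta: dict


def _sigma_train(fit: REMLFit, design: LaggedDesign, kinship: TemporalKinship):
    n = design.n
    return (
        fit.sigma2_AR * kinship.K1
        + fit.sigma2_ind * kinship.K2
        + fit.sigma2_eps * np.eye(n)
    )


def community_cross_cov(
    fit: REMLFit,
    design: LaggedDesign,
    kinship: TemporalKinship,
    w_new: np.ndarray,
    individual: str | None = None,
) -> np.ndarray:
    """Covariance vector between a new time point and the training rows.

    AR part: ``(s_AR / c) * W~ w_new`` (= ``s_u W~ w_new``). Individual
    part: the scrambled design carries individual identity but no time
    ordering, so the new point's (unknown) scrambled row is replaced by
    its conditional expectation given the block — the mean H row of its
    individual — giving ``s_r * H h_bar_i``. Both parts are inner products
    against training factor rows, so the implied joint covariance stays
    positive semidefinite.
    """
    c = kinship.m_cols
    cc = (fit.sigma2_AR / c) * (design.W_tilde @ np.asarray(w_new, float))
    if individual is not None and fit.sigma2_ind > 0:
        blocks = design.individual_blocks()
        if individual in blocks:
            h_bar = design.H[blocks[individual]].mean(axis=0)
            cc += (fit.sigma2_ind / c) * (design.H @ h_bar)
    return cc


def blup_predict(
    fit: REMLFit,
    design_train: LaggedDesign,
    kinship_train: TemporalKinship,
    x_new: np.ndarray,
    w_new: np.ndarray,
    cross_cov: np.ndarray,
    targets: list[tuple[str, float]] | None = None,
    sigma_cho=None,
) -> BlupPrediction:
    """Conditional-normal (BLUP) prediction of new observations.

    ``x_new`` (k x f), ``w_new`` (k x c) and ``cross_cov`` (k x n) may be
    single rows or stacks. The new point's marginal variance is
    ``s_u ||w_new||^2 + s_ind * mean diag(K2) + s_eps``, mirroring how the
    training covariance is assembled. ``sigma_cho`` optionally carries a
    precomputed Cholesky factor of the training covariance.
    """
    if not fit.converged:
        raise ValueError("blup_predict requires a converged fit")
    x_new = np.atleast_2d(np.asarray(x_new, float))
    w_new = np.atleast_2d(np.asarray(w_new, float))
    cross_cov = np.atleast_2d(np.asarray(cross_cov, float))
    n = design_train.n
    if cross_cov.shape[1] != n:
        raise ValueError("cross_cov length must match the training size")
    if sigma_cho is None:
        Sigma = _sigma_train(fit, design_train, kinship_train)
        try:
            sigma_cho = linalg.cho_factor(Sigma, lower=True)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "training covariance not positive definite; add jitter"
            ) from exc
    resid = design_train.y - design_train.X @ fit.beta
    alpha = linalg.cho_solve(sigma_cho, resid)
    mean = x_new @ fit.beta + cross_cov @ alpha
    c = kinship_train.m_cols
    s_u = fit.sigma2_AR / c
    diag_K2 = float(np.mean(np.diag(kinship_train.K2)))
    marg = (
        s_u * np.sum(w_new**2, axis=1)
        + fit.sigma2_ind * diag_K2
        + fit.sigma2_eps
    )
    Si_c = linalg.cho_solve(sigma_cho, cross_cov.T)
    var = marg - np.sum(cross_cov * Si_c.T, axis=1)
    return BlupPrediction(
        predicted=mean,
        conditional_var=np.maximum(var, 0.0),
        targets=targets or [],
    )


def _subset_times(dataset: LongitudinalDataset, keep: dict[str, np.ndarray]):
    """Dataset restricted per individual to the given time positions."""
    out = dataset.copy()
    out.individuals = [i for i in out.individuals if len(keep.get(i, [])) >= 2]
    out.matrices = {i: out.matrices[i][:, keep[i]] for i in out.individuals}
    out.time_labels = {i: out.time_labels[i][keep[i]] for i in out.individuals}
    out.closed = False
    return out


def fit_predict_block(
    dataset: LongitudinalDataset,
    focal_taxon: str,
    p: int,
    q: int,
    train_positions: dict[str, np.ndarray],
    target_positions: dict[str, np.ndarray],
    binned: CommunityCoding | None = None,
    rng_seed: int = 0,
    bin_low: float = 0.25,
    bin_high: float = 0.75,
):
    """Fit on a training block; one-step-ahead predict given target positions.

    Model parameters (beta, variance components) are estimated once from
    the training block. Each target time is then predicted from *observed*
    history: the self-lags and community lags come from the real samples at
    times t-1, ..., t-L, never from model output; only time t is hidden.
    Targets lacking L prior observations are skipped with a warning.
    Predictions are clipped at zero. Returns (observed, predicted,
    pred_var, targets, fit).
    """
    L = max(p, q)
    train_ds = _subset_times(dataset, train_positions)
    if binned is None:
        # thresholds from the training block only (no information may flow
        # from evaluation blocks into the coding), applied to all samples
        from .design import BinnedDataset, _apply_bins

        thr = quantile_bin(train_ds, low=bin_low, high=bin_high)
        ql, qh = thr.bin_thresholds[:, 0], thr.bin_thresholds[:, 1]
        binned = BinnedDataset(
            matrices={
                ind: _apply_bins(dataset.matrices[ind], ql, qh)
                for ind in dataset.individuals
            },
            taxa_ids=list(dataset.taxa_ids),
            bin_thresholds=thr.bin_thresholds,
            quantile_pair=(bin_low, bin_high),
        )
    binned_train = CommunityCoding(
        matrices={
            i: np.asarray(binned.matrices[i])[:, train_positions[i]]
            for i in train_ds.individuals
        },
        taxa_ids=list(binned.taxa_ids),
    )
    design = build_lagged_design(
        train_ds, binned_train, focal_taxon, p=p, q=q, rng_seed=rng_seed
    )
    kinship = build_kinship(design)
    fit = reml_fit(design, kinship)
    if not fit.converged:
        raise RuntimeError(f"REML did not converge for taxon {focal_taxon!r}")
    Sigma = _sigma_train(fit, design, kinship)
    sigma_cho = linalg.cho_factor(Sigma, lower=True)

    j = dataset.taxon_index(focal_taxon)
    obs, xs, ws, ccs, targets = [], [], [], [], []
    for ind in dataset.individuals:
        M = dataset.matrices[ind]
        B = np.asarray(binned.matrices[ind], dtype=float)
        for t in np.asarray(target_positions.get(ind, []), dtype=int):
            if t < L:
                logger.warning(
                    "target (%r, position %d) lacks %d prior observations; skipped",
                    ind, t, L,
                )
                continue
            x_row = np.ones(p + 1)
            for k in range(1, p + 1):
                x_row[k] = M[j, t - k]
            w_row = np.empty(B.shape[0] * q)
            for a in range(B.shape[0]):
                for lag in range(1, q + 1):
                    w_row[a * q + (lag - 1)] = B[a, t - lag]
            cc = community_cross_cov(fit, design, kinship, w_row, individual=ind)
            obs.append(M[j, t])
            xs.append(x_row)
            ws.append(w_row)
            ccs.append(cc)
            targets.append((ind, float(dataset.time_labels[ind][t])))
    if not obs:
        raise ValueError("no predictable target time points")
    pred = blup_predict(
        fit, design, kinship,
        np.vstack(xs), np.vstack(ws), np.vstack(ccs),
        targets=targets, sigma_cho=sigma_cho,
    )
    predicted = np.maximum(pred.predicted, 0.0)
    return np.asarray(obs), predicted, pred.conditional_var, targets, fit


def sequential_predict(
    dataset: LongitudinalDataset,
    focal_taxon: str,
    p: int,
    q: int,
    split,
    rng_seed: int = 0,
):
    """Sequential out-of-sample prediction of the test block of a split.

    Fits on the train block and produces one-step-ahead predictions for
    every test time, using observed history up to t-1. Returns a
    DataFrame (individual, time, observed, predicted, pred_var).
    """
    import pandas as pd

    obs, predicted, var, targets, _ = fit_predict_block(
        dataset, focal_taxon, p, q,
        train_positions=split.train,
        target_positions=split.test,
        rng_seed=rng_seed,
    )
    return pd.DataFrame(
        {
            "individual": [t[0] for t in targets],
            "time": [t[1] for t in targets],
            "observed": obs,
            "predicted": predicted,
            "pred_var": var,
        }
    )


def prediction_r2(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted values.

    Affine-invariant; a zero-variance input yields 0 (with a warning)
    rather than NaN.
    """
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have the same length")
    if observed.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    vo = np.var(observed)
    vp = np.var(predicted)
    if vo == 0 or vp == 0:
        logger.warning("zero-variance input to prediction_r2; returning 0")
        return 0.0
    cov = np.mean((observed - observed.mean()) * (predicted - predicted.mean()))
    return float(cov**2 / (vo * vp))


def estimate_associations(
    dataset: LongitudinalDataset,
    fits: dict[str, REMLFit],
    designs: dict[str, LaggedDesign],
) -> AssociationMatrix:
    """Per-taxon BLUP of community effects, assembled into the m x m matrix U.

    Column j is ``s_u * W~' Sigma^{-1} (y - X beta)`` from taxon j's fit —
    the conditional expectation of the random effect vector u under the
    model — with lag columns of the same taxon summed for q > 1. Columns
    with ``s_u = 0`` or an unconverged fit are zero (flagged in
    ``column_meta``).
    """
    taxa = list(dataset.taxa_ids)
    first = next(iter(designs.values()))
    kin_taxa = first.kinship_taxa
    m = len(kin_taxa)
    kin_rows = np.array([taxa.index(t) for t in kin_taxa])
    U = np.zeros((len(taxa), len(taxa)))
    meta: dict = {"zero_columns": [], "unconverged": []}
    for jj, taxon in enumerate(taxa):
        if taxon not in fits:
            meta["zero_columns"].append(taxon)
            continue
        fit, design = fits[taxon], designs[taxon]
        if design.kinship_taxa != kin_taxa:
            raise ValueError("designs disagree on the kinship taxon set")
        if not fit.converged:
            meta["unconverged"].append(taxon)
            continue
        kinship = build_kinship(design)
        c = kinship.m_cols
        s_u = fit.sigma2_AR / c
        if s_u == 0:
            meta["zero_columns"].append(taxon)
            continue
        Sigma = _sigma_train(fit, design, kinship)
        resid = design.y - design.X @ fit.beta
        alpha = linalg.cho_solve(linalg.cho_factor(Sigma, lower=True), resid)
        u_hat = s_u * (design.W_tilde.T @ alpha)  # length c = m * q
        U[kin_rows, jj] = u_hat.reshape(m, design.q).sum(axis=1)
    return AssociationMatrix(U=U, taxa_ids=taxa, column_meta=meta)


def pca_embedding(matrix: np.ndarray, n_components: int):
    """Principal components of a kinship or association matrix.

    A symmetric PSD input is eigendecomposed directly (scores are
    eigenvector coordinates scaled by sqrt eigenvalue, variance fractions
    eigenvalue / trace). Any other matrix is column-centered and projected
    through its singular vectors. Returns (scores, explained_fractions).
    """
    A = np.asarray(matrix, float)
    if A.shape[0] == A.shape[1] and np.allclose(A, A.T, atol=1e-10):
        w, Q = np.linalg.eigh(A)
        order = np.argsort(w)[::-1]
        w, Q = w[order], Q[:, order]
        if w[min(n_components, len(w)) - 1] < -1e-8 * max(w[0], 1):
            # not PSD: treat as a generic matrix below
            pass
        else:
            w = np.maximum(w, 0.0)
            total = w.sum()
            k = min(n_components, np.sum(w > 0))
            scores = Q[:, :k] * np.sqrt(w[:k])
            frac = w[:k] / total if total > 0 else np.zeros(k)
            return scores, frac
    Ac = A - A.mean(axis=0, keepdims=True)
    U_, s, _ = np.linalg.svd(Ac, full_matrices=False)
    k = min(n_components, np.sum(s > 1e-12))
    total = float(np.sum(s**2))
    scores = U_[:, :k] * s[:k]
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return scores, frac
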