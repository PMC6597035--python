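"""Validation experiments exercising the whole pipeline on synthetic data.

Each function generates its own data with the package's simulators, runs
the relevant estimator, and measures accuracy against an independent
oracle or the simulator's ground truth. They back both the acceptance
test suite and the reproduction script; problem sizes are chosen so the
full battery runs on a single CPU in minutes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize

from .data_io import screen_taxa
from .design import build_kinship, build_lagged_design
from .downstream import order_permutation_test
from .prediction import blup_predict, community_cross_cov
from .reml import (
    bh_adjust,
    fit_all_taxa,
    reml_fit,
    reml_fit_null,
    restricted_loglik,
    time_explainability,
)
from .selection import ar1_baseline, chrono_split
from .synthetic import simulate_community, simulate_lmm

__all__ = [
    "reml_oracle_gaps",
    "blup_oracle_gaps",
    "chi_recovery",
    "null_calibration",
    "detection_power",
    "nesting_comparison",
]


def _lmm_instance(seed: int, n_individuals=2, timepoints=17, m_taxa=6,
                  chi=None, ind=None):
    rng = np.random.default_rng([seed, 17])
    chi = float(rng.uniform(0.15, 0.55)) if chi is None else chi
    ind = float(rng.uniform(0.05, 0.25)) if ind is None else ind
    ds, truth = simulate_lmm(
        n_individuals=n_individuals, timepoints=timepoints, m_taxa=m_taxa,
        chi=chi, ind_fraction=ind, seed=seed,
    )
    design = build_lagged_design(
        ds, truth.community_coding, truth.focal_taxon, p=0, q=1,
        kinship_taxa=truth.kinship_taxa, rng_seed=seed,
    )
    return design, build_kinship(design), truth


def _direct_maximize(design, kinship) -> float:
    """Derivative-free direct maximization of the restricted likelihood.

    Nelder-Mead on log-variances from several fixed starts, refined by a
    restart from its own best point; independent of the AI-REML path.
    """
    vp = float(np.var(design.y))

    def neg(theta):
        try:
            return -restricted_loglik(design, kinship, tuple(np.exp(theta)))
        except np.linalg.LinAlgError:
            return np.inf

    starts = [
        np.log(vp * np.array(s))
        for s in [(1 / 3, 1 / 3, 1 / 3), (0.6, 0.2, 0.2), (0.1, 0.1, 0.8)]
    ]
    best = np.inf
    best_x = None
    for x0 in starts:
        res = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-12, maxiter=4000, maxfev=8000),
        )
        if res.fun < best:
            best, best_x = res.fun, res.x
    res = optimize.minimize(
        neg, best_x, method="Nelder-Mead",
        options=dict(xatol=1e-11, fatol=1e-13, maxiter=4000, maxfev=8000),
    )
    best = min(best, res.fun)
    return -best


def reml_oracle_gaps(n_instances: int = 25, seed: int = 0) -> np.ndarray:
    """Signed gap (fit - direct search) in restricted log-likelihood over
    random small instances; near-zero gaps mean the AI-REML fitter reaches
    the optimum of :func:`restricted_loglik`."""
    rng = np.random.default_rng(seed)
    gaps = []
    for k in range(n_instances):
        sub_seed = int(rng.integers(1, 2**31 - 1))
        T = int(rng.integers(12, 31))  # n = 2 (T - 1) <= 60
        design, kinship, _ = _lmm_instance(sub_seed, timepoints=T)
        fit = reml_fit(design, kinship, tol=1e-12, param_tol=1e-9,
                       max_iter=300)
        oracle_ll = _direct_maximize(design, kinship)
        gaps.append(fit.loglik_restricted - oracle_ll)
    return np.asarray(gaps)


def blup_oracle_gaps(n_instances: int = 25, seed: int = 0) -> dict:
    """Max |mean| and |variance| discrepancy between blup_predict and
    explicit joint-Gaussian conditioning on random instances (n <= 40)."""
    rng = np.random.default_rng(seed)
    mean_gaps, var_gaps = [], []
    for _ in range(n_instances):
        sub_seed = int(rng.integers(1, 2**31 - 1))
        T = int(rng.integers(8, 12))  # n = 2 (T - 1) <= 22
        design, kinship, _ = _lmm_instance(sub_seed, timepoints=T, m_taxa=5)
        fit = reml_fit(design, kinship)
        if not fit.converged:
            continue
        w_new = rng.choice([0.0, 1.0, 2.0], size=kinship.m_cols)
        x_new = np.ones(1)
        ind0 = design.row_index[0][0]
        cc = community_cross_cov(fit, design, kinship, w_new, individual=ind0)
        pred = blup_predict(fit, design, kinship, x_new, w_new, cc)
        # oracle: form the full (n+1) x (n+1) joint covariance, partition
        n = design.n
        c = kinship.m_cols
        s_u = fit.sigma2_AR / c
        Sigma = (
            fit.sigma2_AR * kinship.K1
            + fit.sigma2_ind * kinship.K2
            + fit.sigma2_eps * np.eye(n)
        )
        s_new = (
            s_u * float(w_new @ w_new)
            + fit.sigma2_ind * float(np.mean(np.diag(kinship.K2)))
            + fit.sigma2_eps
        )
        J = np.empty((n + 1, n + 1))
        J[:n, :n] = Sigma
        J[:n, -1] = J[-1, :n] = cc
        J[-1, -1] = s_new
        Jinv_block = np.linalg.inv(J[:n, :n])
        mu_vec = design.X @ fit.beta
        mean_o = float(x_new @ fit.beta) + J[-1, :n] @ Jinv_block @ (
            design.y - mu_vec
        )
        var_o = J[-1, -1] - J[-1, :n] @ Jinv_block @ J[:n, -1]
        mean_gaps.append(abs(pred.predicted[0] - mean_o))
        var_gaps.append(abs(pred.conditional_var[0] - var_o))
    return dict(
        max_mean_gap=float(np.max(mean_gaps)),
        max_var_gap=float(np.max(var_gaps)),
        n=len(mean_gaps),
    )


def chi_recovery(
    chi_values=(0.1, 0.3, 0.5, 0.7),
    n_replicates: int = 50,
    n_individuals: int = 20,
    timepoints: int = 50,
    m_taxa: int = 100,
    ind_fraction: float = 0.2,
    seed: int = 0,
) -> dict:
    """Recovery of time-explainability from the model's own generator.

    Returns per-chi mean estimate, mean absolute error, and overall 95% CI
    coverage of the true value.
    """
    rng = np.random.default_rng(seed)
    per_chi = {}
    covered = total = 0
    for chi in chi_values:
        ests = []
        for _ in range(n_replicates):
            sub_seed = int(rng.integers(1, 2**31 - 1))
            ds, truth = simulate_lmm(
                n_individuals=n_individuals, timepoints=timepoints,
                m_taxa=m_taxa, chi=chi, ind_fraction=ind_fraction,
                seed=sub_seed,
            )
            design = build_lagged_design(
                ds, truth.community_coding, truth.focal_taxon, p=0, q=1,
                kinship_taxa=truth.kinship_taxa, rng_seed=sub_seed,
            )
            kinship = build_kinship(design)
            fit = reml_fit(design, kinship)
            null = reml_fit_null(design, kinship)
            te = time_explainability(fit, null)
            ests.append(te.chi)
            covered += te.ci_low <= chi <= te.ci_high
            total += 1
        ests = np.asarray(ests)
        per_chi[chi] = dict(
            mean=float(ests.mean()),
            mae=float(np.mean(np.abs(ests - chi))),
        )
    return dict(
        per_chi=per_chi,
        mae=float(np.mean([v["mae"] for v in per_chi.values()])),
        coverage=covered / total,
        n=total,
    )


def null_calibration(
    n_taxa: int = 200,
    n_individuals: int = 10,
    timepoints: int = 30,
    m_taxa: int = 20,
    ind_fraction: float = 0.2,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Boundary-LRT calibration under chi = 0.

    Simulates ``n_taxa`` independent focal taxa with no community signal
    and reports the raw false-positive rate at ``alpha`` plus the
    realized false-discovery proportion after BH (every rejection under
    the global null is false).
    """
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_taxa):
        sub_seed = int(rng.integers(1, 2**31 - 1))
        ds, truth = simulate_lmm(
            n_individuals=n_individuals, timepoints=timepoints,
            m_taxa=m_taxa, chi=0.0, ind_fraction=ind_fraction, seed=sub_seed,
        )
        design = build_lagged_design(
            ds, truth.community_coding, truth.focal_taxon, p=0, q=1,
            kinship_taxa=truth.kinship_taxa, rng_seed=sub_seed,
        )
        kinship = build_kinship(design)
        fit = reml_fit(design, kinship)
        null = reml_fit_null(design, kinship)
        pvals.append(time_explainability(fit, null).p_value)
    pvals = np.asarray(pvals)
    qvals = bh_adjust(pvals)
    rejections = int(np.sum(qvals < alpha))
    fdp = rejections / max(rejections, 1)  # all discoveries are false
    return dict(
        fpr=float(np.mean(pvals < alpha)),
        bh_rejections=rejections,
        fdp=float(fdp),
        n=n_taxa,
    )


def detection_power(
    seed: int = 0,
    n_perm: int = 100_000,
    **community_kwargs,
) -> dict:
    """Sensitivity/specificity of the autoregressive call on the realistic
    simulator, plus the order-structure permutation p-value.

    Taxa that fail the 10% presence screen are not modellable and are
    excluded from both counts (the pipeline never sees them).
    """
    ds, truth = simulate_community(seed=seed, **community_kwargs)
    sub, retained = screen_taxa(ds)
    table = fit_all_taxa(sub, p=0, q=1, rng_seed=seed)
    ar_true = set(truth.autoregressive_taxa)
    calls = dict(zip(table["taxon_id"], table["autoregressive"]))
    tp = sum(calls[t] for t in retained if t in ar_true)
    fp = sum(calls[t] for t in retained if t not in ar_true)
    n_ar = sum(1 for t in retained if t in ar_true)
    n_nar = len(retained) - n_ar
    flags = {t: bool(calls[t]) for t in retained}
    taxonomy = {t: sub.taxonomy[t] for t in retained}
    perm_p, observed = order_permutation_test(
        flags, taxonomy, n_perm=n_perm, seed=seed
    )
    return dict(
        sensitivity=tp / n_ar if n_ar else float("nan"),
        specificity=1 - fp / n_nar if n_nar else float("nan"),
        n_ar_retained=n_ar,
        n_retained=len(retained),
        order_perm_p=perm_p,
        order_perm_observed=observed,
        mean_chi_detected=float(
            table.loc[table["autoregressive"], "chi"].mean()
        ),
    )


@dataclasses.dataclass
class NestingResult:
    r2_mtv: float
    r2_ar1: float


def _one_nesting_rep(seed, chi, ind, beta, n_individuals=5, timepoints=60,
                     m_taxa=8):
    from .prediction import fit_predict_block, prediction_r2

    ds, truth = simulate_lmm(
        n_individuals=n_individuals, timepoints=timepoints, m_taxa=m_taxa,
        chi=chi, ind_fraction=ind, beta=beta, seed=seed,
    )
    split = chrono_split(ds, l_max=1)
    obs, pred, _, _, _ = fit_predict_block(
        ds, truth.focal_taxon, 1, 1,
        train_positions=split.train, target_positions=split.test,
        rng_seed=seed,
    )
    r2_mtv = prediction_r2(obs, pred)
    r2_ar1 = ar1_baseline(ds, truth.focal_taxon, split)
    return NestingResult(r2_mtv=r2_mtv, r2_ar1=r2_ar1)


def nesting_comparison(n_replicates: int = 20, seed: int = 0) -> dict:
    """The full model nests the AR(1) signal and adds community signal.

    Scenario A: pure lag-1 self-dependence (no community effect) — the
    mixed model should match AR(1) up to noise. Scenario B: strong
    community effect, no self-dependence — the mixed model should beat
    AR(1) by a wide margin.
    """
    rng = np.random.default_rng(seed)
    gap_self, mtv_comm, ar1_comm = [], [], []
    # intercepts keep the series well above zero so the nonnegativity
    # clip on predictions never binds in either scenario
    for _ in range(n_replicates):
        s = int(rng.integers(1, 2**31 - 1))
        a = _one_nesting_rep(s, chi=0.0, ind=0.0, beta=(1.0, 0.85))
        gap_self.append(a.r2_mtv - a.r2_ar1)
        b = _one_nesting_rep(s + 1, chi=0.7, ind=0.05, beta=(5.0,))
        mtv_comm.append(b.r2_mtv)
        ar1_comm.append(b.r2_ar1)
    return dict(
        mean_gap_self=float(np.mean(gap_self)),
        mean_r2_mtv_community=float(np.mean(mtv_comm)),
        mean_r2_ar1_community=float(np.mean(ar1_comm)),
        mean_excess_community=float(np.mean(mtv_comm) - np.mean(ar1_comm)),
        n=n_replicates,
    )
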