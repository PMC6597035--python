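"""Restricted maximum likelihood for the two-kinship variance-component model.

The marginal model for one focal taxon is

    y ~ N(X beta, sigma2_AR * K1 + sigma2_ind * K2 + sigma2_eps * I)

with K1 the temporal kinship matrix and K2 its time-scrambled twin. The
variance components are estimated by average-information (AI) REML with
expectation-maximization fallback steps, components constrained nonnegative
by clamping. *Time-explainability* is the share of variance attributable to
the temporal kinship component,

    chi = sigma2_AR / (sigma2_AR + sigma2_ind + sigma2_eps),

with a delta-method confidence interval from the inverse-AI covariance and a
boundary likelihood-ratio test (1/2 chi2_0 + 1/2 chi2_1 mixture) for
sigma2_AR > 0.

Numerics: each kinship is a Gram matrix K_i = F_i F_i' of a known factor
(the scaled community design), so V = s_eps I + sum_i s_i F_i F_i' acts as
identity on the orthogonal complement of span([F_1 F_2]). One QR of the
stacked factors per fit reduces every REML quantity — log-determinants,
GLS solves, traces and the AI matrix — to dense algebra in that span,
making the per-iteration cost O(K^3) for K total factor columns instead of
O(n^3). Correctness is defined by :func:`restricted_loglik` (a direct
dense evaluation), not by the factorization path.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg, stats

from .design import LaggedDesign, TemporalKinship

__all__ = [
    "REMLFit",
    "TimeExplainability",
    "restricted_loglik",
    "reml_fit",
    "reml_fit_null",
    "time_explainability",
    "bh_adjust",
    "fit_all_taxa",
]

_FLOOR_FRACTION = 1e-6  # variance floor relative to var(y), GCTA-style


@dataclasses.dataclass
class REMLFit:
    """Result of a restricted-maximum-likelihood fit."""

    beta: np.ndarray
    sigma2_AR: float
    sigma2_ind: float
    sigma2_eps: float
    vc_cov: np.ndarray  # 3x3, order (AR, ind, eps); zero row/col if fixed
    loglik_restricted: float
    converged: bool
    n_iter: int
    n: int = 0

    @property
    def sigma2(self) -> tuple[float, float, float]:
        return (self.sigma2_AR, self.sigma2_ind, self.sigma2_eps)


@dataclasses.dataclass
class TimeExplainability:
    """Per-taxon time-explainability with uncertainty and significance."""

    chi: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float = float("nan")
    autoregressive: bool | None = None


# ---------------------------------------------------------------------------
# generic AI-REML engine


class _Component:
    """One variance component with Gram structure K = F F'."""

    def __init__(self, F=None, K=None):
        if F is None and K is None:
            raise ValueError("component needs a factor or a dense matrix")
        if F is None:
            # factor a dense PSD matrix once (eigendecomposition)
            w, Q = np.linalg.eigh(K)
            w = np.maximum(w, 0.0)
            F = Q * np.sqrt(w)
        self.F = F


class _ProjectedContext:
    """REML quantities reduced to the span of the stacked factors.

    With Q an orthonormal basis of span([F_1 ... F_c]) (n x Kq) and
    R_i = Q' F_i, the covariance V = s_eps I + sum s_i F_i F_i' equals
    Q M Q' + s_eps (I - Q Q') with M = s_eps I + sum s_i R_i R_i', so all
    determinants, traces and quadratic forms decompose into a dense part in
    the span plus closed-form complement corrections.
    """

    def __init__(self, y, X, factors):
        y = np.asarray(y, float).ravel()
        X = np.atleast_2d(np.asarray(X, float))
        self.n, self.f = X.shape
        self.ncomp = len(factors)
        self.y, self.X = y, X
        self.yy = float(y @ y)
        self.XX = X.T @ X
        self.Xy = X.T @ y
        if factors:
            F_all = np.hstack(factors)
            Q, R_all = np.linalg.qr(F_all)  # reduced: Q is n x min(n, K)
            offs = np.cumsum([0] + [F.shape[1] for F in factors])
            self.R = [R_all[:, offs[i]:offs[i + 1]] for i in range(len(factors))]
            self.RR = [R @ R.T for R in self.R]
            self.Kq = Q.shape[1]
            self.yt = Q.T @ y
            self.Xt = Q.T @ X
        else:
            self.R, self.RR = [], []
            self.Kq = 0
            self.yt = np.zeros(0)
            self.Xt = np.zeros((0, self.f))
        self.comp_XX = self.XX - self.Xt.T @ self.Xt

    def evaluate(self, sigma):
        """Restricted log-likelihood and GLS state at fixed components."""
        s_eps = float(sigma[-1])
        if s_eps <= 0:
            return None
        n, Kq = self.n, self.Kq
        if Kq:
            M = s_eps * np.eye(Kq)
            for s, RR in zip(sigma[:-1], self.RR):
                if s != 0:
                    M += s * RR
            try:
                cf_M = linalg.cho_factor(M, lower=True)
            except linalg.LinAlgError:
                return None
            ld_V = 2.0 * np.sum(np.log(np.diag(cf_M[0]))) + (n - Kq) * np.log(s_eps)
            my = linalg.cho_solve(cf_M, self.yt)
            mX = linalg.cho_solve(cf_M, self.Xt)
            XtViX = self.Xt.T @ mX + self.comp_XX / s_eps
            XtViy = self.Xt.T @ my + (self.Xy - self.Xt.T @ self.yt) / s_eps
            yViy = float(self.yt @ my) + (self.yy - float(self.yt @ self.yt)) / s_eps
        else:
            cf_M, my, mX = None, None, None
            ld_V = n * np.log(s_eps)
            XtViX = self.XX / s_eps
            XtViy = self.Xy / s_eps
            yViy = self.yy / s_eps
        try:
            cf_x = linalg.cho_factor(XtViX)
        except linalg.LinAlgError:
            return None
        ld_x = 2.0 * np.sum(np.log(np.diag(cf_x[0])))
        b = linalg.cho_solve(cf_x, XtViy)
        yPy = yViy - float(XtViy @ b)
        ll = -0.5 * (ld_V + ld_x + yPy)
        if not np.isfinite(ll):
            return None
        return dict(
            ll=ll, b=b, cf_M=cf_M, cf_x=cf_x, mX=mX, s_eps=s_eps,
        )

    def derivatives(self, state):
        """REML score and average-information matrix at the current point."""
        s_eps = state["s_eps"]
        cf_M, cf_x, mX, b = state["cf_M"], state["cf_x"], state["mX"], state["b"]
        n, Kq = self.n, self.Kq
        # GLS residual u = y - X b, in span (ut) and complement (norms only)
        Xu = self.Xy - self.XX @ b
        uu = self.yy - 2 * float(b @ self.Xy) + float(b @ self.XX @ b)
        if Kq:
            ut = self.yt - self.Xt @ b
            mu = linalg.cho_solve(cf_M, ut)
            comp_uu = max(uu - float(ut @ ut), 0.0)
            Linv = linalg.solve_triangular(
                cf_M[0], np.eye(Kq), lower=True
            )
            trM1 = float(np.sum(Linv**2))
            Xtut = self.Xt.T @ ut
        else:
            ut = mu = np.zeros(0)
            comp_uu = uu
            trM1 = 0.0
            Xtut = np.zeros(self.f)

        trPK, quads, ws, tts, Mtts, a_vecs = [], [], [], [], [], []
        for R in self.R:
            MR = linalg.cho_solve(cf_M, R)
            A = R.T @ mX  # F_i' V^-1 X   (k_i x f)
            t1 = float(np.sum(R * MR))
            t2 = float(np.sum(A.T * linalg.cho_solve(cf_x, A.T)))
            trPK.append(t1 - t2)
            w = R.T @ mu
            quads.append(float(w @ w))
            tt = R @ w
            ws.append(w)
            tts.append(tt)
            Mtts.append(linalg.cho_solve(cf_M, tt))
            a_vecs.append(A.T @ w)  # X' V^-1 t_i   (f)
        # residual component
        trVi = trM1 + (n - Kq) / s_eps
        if Kq:
            XV2X = mX.T @ mX + self.comp_XX / s_eps**2
        else:
            XV2X = self.XX / s_eps**2
        trP = trVi - float(np.trace(linalg.cho_solve(cf_x, XV2X)))
        quad_res = float(mu @ mu) + comp_uu / s_eps**2
        trPK.append(trP)
        quads.append(quad_res)
        score = -0.5 * (np.asarray(trPK) - np.asarray(quads))

        k = self.ncomp + 1
        AI = np.empty((k, k))
        # X' V^-2 u (for P-corrections involving v = Py)
        if Kq:
            xvv = mX.T @ mu + (Xu - Xtut) / s_eps**2
            Mmu = linalg.cho_solve(cf_M, mu)
            uV3u = float(mu @ Mmu) + comp_uu / s_eps**3
        else:
            xvv = Xu / s_eps**2
            Mmu = mu
            uV3u = comp_uu / s_eps**3
        Wx_xvv = linalg.cho_solve(cf_x, xvv)
        for i in range(self.ncomp):
            for j in range(i, self.ncomp):
                val = float(tts[i] @ Mtts[j]) - float(
                    a_vecs[i] @ linalg.cho_solve(cf_x, a_vecs[j])
                )
                AI[i, j] = AI[j, i] = 0.5 * val
            val = float(Mtts[i] @ mu) - float(a_vecs[i] @ Wx_xvv)
            AI[i, -1] = AI[-1, i] = 0.5 * val
        AI[-1, -1] = 0.5 * (uV3u - float(xvv @ Wx_xvv))
        return score, AI


@dataclasses.dataclass
class _EngineResult:
    sigma: np.ndarray  # len ncomp + 1, residual last
    beta: np.ndarray
    loglik: float
    ai_cov: np.ndarray  # inverse-AI covariance of the components
    converged: bool
    n_iter: int


def _reml_engine(
    y: np.ndarray,
    X: np.ndarray,
    components: list[_Component],
    max_iter: int = 100,
    tol: float = 1e-6,
    param_tol: float = 1e-4,
    constrain: bool = True,
) -> _EngineResult:
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, f = X.shape
    ncomp = len(components)
    if n <= f + ncomp + 1:
        raise ValueError("not enough observations for the fixed effects")
    vp = float(np.var(y))
    if vp <= 0:
        vp = 1.0
    floor = max(_FLOOR_FRACTION * vp, 1e-12)
    ctx = _ProjectedContext(y, X, [c.F for c in components])

    def clip(sig):
        return np.maximum(sig, floor) if constrain else sig

    def em_step(sigma, score):
        # EM-REML: s_i <- s_i + 2 s_i^2 score_i / n
        return clip(sigma + (sigma**2) * (2.0 * score) / n)

    sigma = np.full(ncomp + 1, vp / (ncomp + 1))
    state = ctx.evaluate(sigma)
    if state is None:
        raise np.linalg.LinAlgError("initial variance matrix is singular")
    converged = False
    n_iter = 0
    score, AI = ctx.derivatives(state)
    for n_iter in range(1, max_iter + 1):
        if n_iter == 1:
            proposal = em_step(sigma, score)
        else:
            # active set: components pinned at the floor whose gradient
            # points outward are held fixed, so they cannot distort the
            # AI step for the free components
            if constrain:
                active = ~((sigma <= floor * (1 + 1e-8)) & (score < 0))
                active[-1] = True
            else:
                active = np.ones(ncomp + 1, dtype=bool)
            delta = np.zeros(ncomp + 1)
            sub_AI = AI[np.ix_(active, active)]
            try:
                delta[active] = np.linalg.solve(sub_AI, score[active])
            except np.linalg.LinAlgError:
                delta[active] = np.linalg.lstsq(
                    sub_AI, score[active], rcond=None
                )[0]
            proposal = clip(sigma + delta)
        new_state = ctx.evaluate(proposal)
        halvings = 0
        while (
            new_state is None or new_state["ll"] < state["ll"] - 1e-10
        ) and halvings < 8:
            proposal = clip(0.5 * (proposal + sigma))
            new_state = ctx.evaluate(proposal)
            halvings += 1
        if new_state is None or new_state["ll"] < state["ll"] - 1e-10:
            proposal = em_step(sigma, score)
            new_state = ctx.evaluate(proposal)
            if new_state is None:
                break
        ll_change = abs(new_state["ll"] - state["ll"])
        denom = np.maximum(np.abs(sigma), floor)
        param_change = float(np.max(np.abs(proposal - sigma) / denom))
        sigma, state = proposal, new_state
        score, AI = ctx.derivatives(state)
        if ll_change < tol and param_change < param_tol:
            converged = True
            break

    if constrain:
        # boundary polish: components held at the small positive floor
        # with an outward gradient belong exactly at zero
        pinned = (sigma <= floor * (1 + 1e-8)) & (score < 0)
        pinned[-1] = False  # the residual variance stays positive
        if pinned.any():
            sigma_zero = sigma.copy()
            sigma_zero[pinned] = 0.0
            state_zero = ctx.evaluate(sigma_zero)
            if state_zero is not None and state_zero["ll"] >= state["ll"]:
                sigma, state = sigma_zero, state_zero
                score, AI = ctx.derivatives(state)

    try:
        ai_cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        ai_cov = np.linalg.pinv(AI)
    # symmetrize and repair tiny negative eigenvalues
    ai_cov = 0.5 * (ai_cov + ai_cov.T)
    w, Q = np.linalg.eigh(ai_cov)
    if w.min() < 0:
        ai_cov = (Q * np.maximum(w, 0)) @ Q.T
    return _EngineResult(
        sigma=sigma,
        beta=state["b"],
        loglik=state["ll"],
        ai_cov=ai_cov,
        converged=converged,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# public operations


def restricted_loglik(
    design: LaggedDesign,
    kinship: TemporalKinship,
    sigma2: tuple[float, float, float],
) -> float:
    """REML log-likelihood at fixed variance components (constants dropped).

    Computes ``-0.5 * (log|V| + log|X' V^-1 X| + y' P y)`` with
    ``V = s_AR K1 + s_ind K2 + s_eps I`` by direct dense factorization; the
    iterative fitter is required to maximize exactly this function.
    """
    s_ar, s_ind, s_eps = sigma2
    n = design.n
    V = s_ar * kinship.K1 + s_ind * kinship.K2 + s_eps * np.eye(n)
    sign, ld_V = np.linalg.slogdet(V)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            "V not positive definite; add jitter or drop collinear columns"
        )
    Vi = np.linalg.inv(V)
    X, y = design.X, design.y
    XtViX = X.T @ Vi @ X
    sign_x, ld_x = np.linalg.slogdet(XtViX)
    if sign_x <= 0:
        raise np.linalg.LinAlgError(
            "X' V^-1 X singular; drop collinear fixed-effect columns"
        )
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return float(-0.5 * (ld_V + ld_x + r @ Vi @ r))


def _components_full(design, kinship):
    c = kinship.m_cols
    return [
        _Component(F=design.W_tilde / np.sqrt(c)),
        _Component(F=design.H / np.sqrt(c)),
    ]


def reml_fit(
    design: LaggedDesign,
    kinship: TemporalKinship,
    max_iter: int = 100,
    tol: float = 1e-6,
    param_tol: float = 1e-4,
    constrain: bool = True,
) -> REMLFit:
    """Fit the full model (AR + individual + residual components) by AI-REML.

    Uses average-information updates with EM fallback when an AI step would
    decrease the restricted likelihood or leave the feasible region;
    components hitting zero are clamped at a small floor. Non-convergence is
    reported through ``converged=False``, never silently accepted.
    """
    res = _reml_engine(
        design.y,
        design.X,
        _components_full(design, kinship),
        max_iter=max_iter,
        tol=tol,
        param_tol=param_tol,
        constrain=constrain,
    )
    return REMLFit(
        beta=res.beta,
        sigma2_AR=float(res.sigma[0]),
        sigma2_ind=float(res.sigma[1]),
        sigma2_eps=float(res.sigma[2]),
        vc_cov=res.ai_cov,
        loglik_restricted=res.loglik,
        converged=res.converged,
        n_iter=res.n_iter,
        n=design.n,
    )


def reml_fit_null(
    design: LaggedDesign,
    kinship: TemporalKinship,
    max_iter: int = 100,
    tol: float = 1e-6,
    param_tol: float = 1e-4,
    constrain: bool = True,
) -> REMLFit:
    """Refit with ``sigma2_AR`` fixed at zero (individual + residual only)."""
    c = kinship.m_cols
    comp = [_Component(F=design.H / np.sqrt(c))]
    res = _reml_engine(
        design.y, design.X, comp,
        max_iter=max_iter, tol=tol, param_tol=param_tol, constrain=constrain,
    )
    vc = np.zeros((3, 3))
    vc[1:, 1:] = res.ai_cov
    return REMLFit(
        beta=res.beta,
        sigma2_AR=0.0,
        sigma2_ind=float(res.sigma[0]),
        sigma2_eps=float(res.sigma[1]),
        vc_cov=vc,
        loglik_restricted=res.loglik,
        converged=res.converged,
        n_iter=res.n_iter,
        n=design.n,
    )


def time_explainability(
    fit: REMLFit,
    null_fit: REMLFit,
    alpha: float = 0.05,
) -> TimeExplainability:
    """Time-explainability chi with a 95% delta-method CI and boundary LRT.

    ``chi = s_AR / (s_AR + s_ind + s_eps)``. The p-value refers the
    restricted likelihood-ratio statistic ``2 (ll_full - ll_null)`` to the
    boundary mixture ``1/2 chi2_0 + 1/2 chi2_1`` (a non-positive statistic
    gives p = 1). The BH-adjusted q-value is filled in at the cohort level.
    """
    if not (fit.converged and null_fit.converged):
        raise ValueError("time_explainability requires converged fits")
    s = np.array(fit.sigma2, dtype=float)
    total = float(s.sum())
    chi = float(s[0] / total) if total > 0 else 0.0
    # delta method: gradient of s0 / (s0 + s1 + s2)
    if total > 0:
        g = np.array([total - s[0], -s[0], -s[0]]) / total**2
        var_chi = float(g @ fit.vc_cov @ g)
        se = np.sqrt(max(var_chi, 0.0))
    else:
        se = 0.0
    z = stats.norm.ppf(1 - 0.05 / 2)
    ci_low = float(np.clip(chi - z * se, 0.0, 1.0))
    ci_high = float(np.clip(chi + z * se, 0.0, 1.0))
    ci_low = min(ci_low, chi)
    ci_high = max(ci_high, chi)
    lrt = 2.0 * (fit.loglik_restricted - null_fit.loglik_restricted)
    p_value = 1.0 if lrt <= 0 else float(0.5 * stats.chi2.sf(lrt, df=1))
    return TimeExplainability(
        chi=chi, ci_low=ci_low, ci_high=ci_high, p_value=p_value
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def fit_all_taxa(
    dataset,
    p: int = 0,
    q: int = 1,
    bin_low: float = 0.25,
    bin_high: float = 0.75,
    alpha: float = 0.05,
    rng_seed: int = 0,
    taxa: list[str] | None = None,
    keep_fits: bool = False,
):
    """Fit the model for every taxon and tabulate time-explainability.

    Binning, the H permutation, and hence K1/K2 are shared across focal
    taxa (one permutation per individual per ``rng_seed``). Returns a
    DataFrame with one row per taxon: variance components, chi with CI,
    boundary-LRT p-value, BH q-value, and the autoregressive call at
    ``alpha``. With ``keep_fits=True`` also returns ``(fits, designs)``
    dictionaries for downstream association estimation.
    """
    import pandas as pd

    from .design import build_kinship, build_lagged_design, quantile_bin

    binned = quantile_bin(dataset, low=bin_low, high=bin_high)
    taxa = list(dataset.taxa_ids) if taxa is None else list(taxa)
    rows = []
    fits: dict[str, REMLFit] = {}
    designs: dict[str, LaggedDesign] = {}
    kinship = None
    for taxon in taxa:
        design = build_lagged_design(
            dataset, binned, taxon, p=p, q=q, rng_seed=rng_seed
        )
        if kinship is None:
            kinship = build_kinship(design)
        fit = reml_fit(design, kinship)
        null_fit = reml_fit_null(design, kinship)
        if fit.converged and null_fit.converged:
            te = time_explainability(fit, null_fit, alpha=alpha)
        else:
            te = TimeExplainability(
                chi=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                p_value=1.0,
            )
        rows.append(
            dict(
                taxon_id=taxon,
                sigma2_AR=fit.sigma2_AR,
                sigma2_ind=fit.sigma2_ind,
                sigma2_eps=fit.sigma2_eps,
                chi=te.chi,
                ci_low=te.ci_low,
                ci_high=te.ci_high,
                p_value=te.p_value,
                converged=fit.converged and null_fit.converged,
                n_iter=fit.n_iter,
            )
        )
        if keep_fits:
            fits[taxon] = fit
            designs[taxon] = design
    table = pd.DataFrame(rows)
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["autoregressive"] = (table["q_value"] < alpha) & table["converged"]
    order = [
        "taxon_id", "sigma2_AR", "sigma2_ind", "sigma2_eps", "chi",
        "ci_low", "ci_high", "p_value", "q_value", "autoregressive",
        "converged", "n_iter",
    ]
    table = table[order]
    if keep_fits:
        return table, fits, designs
    return table
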