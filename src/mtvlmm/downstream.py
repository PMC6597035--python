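"""Order-level summaries, taxonomic permutation test, phylogenetic LMM hook,
and alpha-diversity utilities."""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "OrderSummary",
    "aggregate_by_order",
    "order_permutation_test",
    "phylo_kinship_fit",
    "shannon_diversity",
]

UNASSIGNED = "unassigned"


@dataclasses.dataclass
class OrderSummary:
    order: str
    n_taxa: int
    n_autoregressive: int
    mean_chi: float

    @property
    def fraction_autoregressive(self) -> float:
        return self.n_autoregressive / self.n_taxa


def _order_of(taxonomy, taxon: str) -> str:
    if taxonomy is None:
        return UNASSIGNED
    entry = taxonomy.get(taxon)
    if entry is None:
        return UNASSIGNED
    if isinstance(entry, dict):
        return entry.get("order", UNASSIGNED)
    return str(entry)


def aggregate_by_order(te_table, taxonomy) -> list[OrderSummary]:
    """Summarize per-taxon time-explainability by taxonomic order.

    ``te_table`` is the per-taxon DataFrame from ``fit_all_taxa`` (columns
    ``taxon_id``, ``chi``, ``autoregressive``); ``taxonomy`` maps taxon ->
    order (directly or via an ``{"order": ...}`` dict). Unlabeled taxa go
    to the "unassigned" bucket. Orders with no autoregressive member are
    the *non-autoregressive* orders; the rest are *mixed*.
    """
    groups: dict[str, list[tuple[float, bool]]] = {}
    for _, row in te_table.iterrows():
        order = _order_of(taxonomy, row["taxon_id"])
        groups.setdefault(order, []).append(
            (float(row["chi"]), bool(row["autoregressive"]))
        )
    out = []
    for order in sorted(groups):
        entries = groups[order]
        chis = np.array([c for c, _ in entries])
        n_ar = sum(1 for _, f in entries if f)
        out.append(
            OrderSummary(
                order=order,
                n_taxa=len(entries),
                n_autoregressive=n_ar,
                mean_chi=float(np.nanmean(chis)),
            )
        )
    return out


def order_permutation_test(
    autoregressive_flags: dict[str, bool],
    taxonomy,
    n_perm: int = 100_000,
    seed: int = 0,
) -> tuple[float, int]:
    """Permutation test for concentration of non-autoregressive orders.

    The observed statistic is the number of orders containing zero
    autoregressive taxa. The null shuffles order labels over taxa
    ``n_perm`` times and counts how often at least as many empty orders
    arise; the p-value uses the add-one convention
    ``(1 + #{null >= observed}) / (n_perm + 1)`` and is therefore never
    exactly zero. Returns ``(p_value, observed_statistic)``.
    """
    taxa = list(autoregressive_flags)
    flags = np.array([bool(autoregressive_flags[t]) for t in taxa])
    labels = np.array([_order_of(taxonomy, t) for t in taxa])
    orders, label_codes = np.unique(labels, return_inverse=True)
    if len(orders) < 2:
        raise ValueError("need at least 2 orders")
    n_ar = int(flags.sum())
    if n_ar == 0:
        raise ValueError("need at least one autoregressive taxon")
    n_orders = len(orders)
    observed = n_orders - len(np.unique(label_codes[flags]))
    rng = np.random.default_rng(seed)
    m = len(taxa)
    count = 0
    # shuffling labels over taxa == drawing which taxa are flagged
    for _ in range(n_perm):
        pick = rng.choice(m, size=n_ar, replace=False)
        stat = n_orders - len(np.unique(label_codes[pick]))
        if stat >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return float(p), int(observed)


def phylo_kinship_fit(
    chi_vector,
    phylo_distance: np.ndarray,
    negative_tolerance: float = 0.25,
) -> tuple[float, float]:
    """Variance in time-explainability attributable to phylogeny.

    The distance matrix is converted to a similarity kernel by
    max-distance complement ``(d_max - D) / d_max`` and projected to the
    PSD cone by eigenvalue truncation; if the negative spectrum exceeds
    ``negative_tolerance`` times the leading eigenvalue the kernel is
    rejected rather than silently repaired. A single-kinship REML fit of
    chi on the kernel returns ``(variance_fraction, p_value)`` with the
    boundary-LRT p-value for the kernel component.
    """
    from scipy import stats

    from .reml import _Component, _reml_engine

    chi = np.asarray(chi_vector, float)
    D = np.asarray(phylo_distance, float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    if D.shape[0] != chi.size:
        raise ValueError("chi vector and distance matrix sizes differ")
    d_max = float(D.max())
    if d_max <= 0:
        raise ValueError("degenerate distance matrix")
    Kernel = (d_max - D) / d_max
    w, Q = np.linalg.eigh(Kernel)
    if -w.min() > negative_tolerance * max(w.max(), 1e-12):
        raise ValueError(
            "kernel is negative-definite beyond tolerance; "
            "check the distance matrix"
        )
    w_pos = np.maximum(w, 0.0)
    F = Q * np.sqrt(w_pos)
    K = (F @ F.T)
    X = np.ones((chi.size, 1))
    full = _reml_engine(chi, X, [_Component(F=F, K=K)])
    null = _reml_engine(chi, X, [])
    lrt = 2.0 * (full.loglik - null.loglik)
    if lrt <= 1e-6:
        # kernel adds nothing (e.g. identity kernel, collinear with the
        # residual): attribute the variance to the residual by convention
        return 0.0, 1.0
    s_k, s_e = full.sigma
    frac = float(s_k / (s_k + s_e)) if (s_k + s_e) > 0 else 0.0
    p = float(0.5 * stats.chi2.sf(lrt, df=1))
    return frac, p


def shannon_diversity(proportions) -> tuple[float, float]:
    """Shannon-Wiener index ``H = -sum p ln p`` and its effective number of
    species ``exp(H)`` (zero entries contribute nothing)."""
    p = np.asarray(proportions, float)
    if np.any(p < 0):
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must sum to 1")
    nz = p[p > 0]
    H = float(-np.sum(nz * np.log(nz)))
    return H, float(np.exp(H))
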