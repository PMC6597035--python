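"""Lagged design matrices and the temporal kinship matrices.

The model predicts the relative abundance of a focal taxon at time ``t``
from (a) its own raw abundance at the ``p`` previous time points (fixed
effects) and (b) the quantile-binned abundance of the whole community at the
``q`` previous time points (random effects). The community design ``W~``
yields the temporal kinship matrix ``K1 = W~ W~' / c``; a within-individual
row-scrambled copy ``H`` yields ``K2 = H H' / c``, which carries individual
identity but no temporal ordering and guards the fit against host effects.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .data_io import LongitudinalDataset

__all__ = [
    "BinnedDataset",
    "CommunityCoding",
    "LaggedDesign",
    "TemporalKinship",
    "quantile_bin",
    "quantile_normalize",
    "build_lagged_design",
    "build_kinship",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CommunityCoding:
    """A per-individual recoding of the community matrix used for ``W~``.

    ``matrices`` maps individual -> ``m x T_i`` array of recoded values.
    The default recoding is three-level quantile binning
    (:class:`BinnedDataset`); rank-based quantile normalization is the
    continuous alternative.
    """

    matrices: dict[str, np.ndarray]
    taxa_ids: list[str]


@dataclasses.dataclass
class BinnedDataset(CommunityCoding):
    """Quantile-binned community data with entries in {0, 1, 2}.

    ``bin_thresholds[j] = (q_low, q_high)`` are the per-taxon empirical
    quantiles at ``quantile_pair``; a value bins to 0 if strictly below
    ``q_low``, to 2 if strictly above ``q_high``, and to 1 otherwise. With
    heavy zero inflation ``q_low`` is often exactly 0, in which case zeros
    legally land in the middle bin (neither strict inequality holds).
    """

    bin_thresholds: np.ndarray = None  # m x 2
    quantile_pair: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self):
        for mat in self.matrices.values():
            vals = np.unique(mat)
            if not np.isin(vals, [0, 1, 2]).all():
                raise ValueError("binned entries must be in {0, 1, 2}")


def quantile_bin(
    dataset: LongitudinalDataset,
    low: float = 0.25,
    high: float = 0.75,
    scope: str = "pooled",
) -> BinnedDataset:
    """Bin each taxon's abundances into low/medium/high by its own quantiles.

    Thresholds are the (``low``, ``high``) empirical quantiles (linear
    interpolation between order statistics) of the taxon's values over all
    samples in scope — pooled across individuals by default, matching the
    single shared kinship matrix downstream. A constant taxon maps to all-1.
    """
    if not (0 <= low < high <= 1):
        raise ValueError("need 0 <= low < high <= 1")
    if scope not in {"pooled", "per_individual"}:
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "pooled":
        pooled = dataset.pooled_matrix()
        q_low = np.quantile(pooled, low, axis=1)
        q_high = np.quantile(pooled, high, axis=1)
        thresholds = np.column_stack([q_low, q_high])
        matrices = {
            ind: _apply_bins(dataset.matrices[ind], q_low, q_high)
            for ind in dataset.individuals
        }
    else:
        matrices = {}
        thr_acc = []
        for ind in dataset.individuals:
            mat = dataset.matrices[ind]
            ql = np.quantile(mat, low, axis=1)
            qh = np.quantile(mat, high, axis=1)
            matrices[ind] = _apply_bins(mat, ql, qh)
            thr_acc.append(np.column_stack([ql, qh]))
        thresholds = np.mean(thr_acc, axis=0)
    return BinnedDataset(
        matrices=matrices,
        taxa_ids=list(dataset.taxa_ids),
        bin_thresholds=thresholds,
        quantile_pair=(low, high),
    )


def _apply_bins(mat: np.ndarray, q_low: np.ndarray, q_high: np.ndarray) -> np.ndarray:
    binned = np.ones_like(mat, dtype=np.int8)
    binned[mat < q_low[:, None]] = 0
    binned[mat > q_high[:, None]] = 2
    return binned


def quantile_normalize(dataset: LongitudinalDataset) -> CommunityCoding:
    """Per-taxon rank-based inverse-normal transform of pooled abundances.

    The continuous alternative to three-level binning: each taxon's pooled
    values are mapped through ranks to standard-normal quantiles (ties get
    average ranks, which sends long runs of zeros to a common value).
    """
    from scipy import stats

    pooled = dataset.pooled_matrix()
    n = pooled.shape[1]
    transformed = np.empty_like(pooled, dtype=float)
    for j in range(pooled.shape[0]):
        ranks = stats.rankdata(pooled[j])
        transformed[j] = stats.norm.ppf(ranks / (n + 1))
    matrices = {}
    start = 0
    for ind in dataset.individuals:
        T = dataset.matrices[ind].shape[1]
        matrices[ind] = transformed[:, start:start + T]
        start += T
    return CommunityCoding(matrices=matrices, taxa_ids=list(dataset.taxa_ids))


@dataclasses.dataclass
class LaggedDesign:
    """Stacked response and design matrices for one focal taxon.

    Rows run over individuals (in dataset order) and, within an individual,
    over target times ``t = L+1, ..., T_i`` with ``L = max(p, q)``:

    - ``y[row]``     raw relative abundance of the focal taxon at ``t``
    - ``X[row]``     ``[1, M_{j,t-1}, ..., M_{j,t-p}]`` (raw self-lags)
    - ``W_tilde[row]`` recoded community values, taxon-major:
      (taxon_1 lag 1, ..., taxon_1 lag q, taxon_2 lag 1, ...)
    - ``H``          ``W_tilde`` with rows permuted uniformly at random
      within each individual block (one draw per individual, all columns
      together), seeded by ``rng_seed``.
    """

    focal_taxon: str
    p: int
    q: int
    y: np.ndarray
    X: np.ndarray
    W_tilde: np.ndarray
    H: np.ndarray
    row_index: list[tuple[str, float]]
    kinship_taxa: list[str]
    rng_seed: int
    permutations: dict[str, np.ndarray]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def individual_blocks(self) -> dict[str, np.ndarray]:
        """Row indices of each individual's block."""
        blocks: dict[str, list[int]] = {}
        for r, (ind, _) in enumerate(self.row_index):
            blocks.setdefault(ind, []).append(r)
        return {k: np.asarray(v) for k, v in blocks.items()}


@dataclasses.dataclass
class TemporalKinship:
    """Temporal kinship ``K1 = W~ W~'/c`` and its scrambled twin ``K2 = H H'/c``.

    ``c`` is the number of community columns (``q`` lags x kinship taxa), so
    the scale of ``K1`` does not grow with ``q``.
    """

    K1: np.ndarray
    K2: np.ndarray
    m_cols: int
    kinship_taxa: list[str]
    row_index: list[tuple[str, float]]


def build_lagged_design(
    dataset: LongitudinalDataset,
    binned: CommunityCoding,
    focal_taxon: str,
    p: int,
    q: int,
    kinship_taxa: list[str] | None = None,
    rng_seed: int = 0,
) -> LaggedDesign:
    """Assemble ``y``, ``X``, ``W~`` and ``H`` for one focal taxon.

    Individuals with ``T_i <= max(p, q)`` contribute no usable target time
    and are dropped with a warning; if all are dropped this is an error.
    Every design row depends only on samples strictly earlier than its
    target time (causality), which the tests verify by perturbation.
    """
    if p < 0 or q < 1:
        raise ValueError("need p >= 0 and q >= 1")
    j = dataset.taxon_index(focal_taxon)
    if kinship_taxa is None:
        kinship_taxa = list(binned.taxa_ids)
    kin_idx = [binned.taxa_ids.index(t) for t in kinship_taxa]
    L = max(p, q)
    rng = np.random.default_rng(rng_seed)

    ys, Xs, Ws, Hs, rows = [], [], [], [], []
    permutations: dict[str, np.ndarray] = {}
    for ind in dataset.individuals:
        M = dataset.matrices[ind]
        B = np.asarray(binned.matrices[ind], dtype=float)[kin_idx]
        T = M.shape[1]
        if T <= L:
            logger.warning(
                "individual %r dropped: T=%d <= max(p, q)=%d", ind, T, L
            )
            continue
        n_i = T - L
        targets = np.arange(L, T)  # 0-based target columns
        ys.append(M[j, targets])
        X_i = np.ones((n_i, p + 1))
        for k in range(1, p + 1):
            X_i[:, k] = M[j, targets - k]
        Xs.append(X_i)
        # taxon-major lag layout: columns (taxon, lag) for lag = 1..q
        W_i = np.empty((n_i, len(kin_idx) * q))
        for a in range(len(kin_idx)):
            for lag in range(1, q + 1):
                W_i[:, a * q + (lag - 1)] = B[a, targets - lag]
        Ws.append(W_i)
        perm = rng.permutation(n_i)
        permutations[ind] = perm
        Hs.append(W_i[perm])
        rows.extend((ind, float(dataset.time_labels[ind][t])) for t in targets)

    if not ys:
        raise ValueError(
            f"no individual has more than max(p, q)={L} time points"
        )
    return LaggedDesign(
        focal_taxon=focal_taxon,
        p=p,
        q=q,
        y=np.concatenate(ys),
        X=np.vstack(Xs),
        W_tilde=np.vstack(Ws),
        H=np.vstack(Hs),
        row_index=rows,
        kinship_taxa=list(kinship_taxa),
        rng_seed=rng_seed,
        permutations=permutations,
    )


def build_kinship(design: LaggedDesign) -> TemporalKinship:
    """Gram matrices of the community design, normalized by its column count."""
    c = design.W_tilde.shape[1]
    K1 = design.W_tilde @ design.W_tilde.T / c
    K2 = design.H @ design.H.T / c
    return TemporalKinship(
        K1=K1,
        K2=K2,
        m_cols=c,
        kinship_taxa=list(design.kinship_taxa),
        row_index=list(design.row_index),
    )
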