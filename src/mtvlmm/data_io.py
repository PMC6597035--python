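"""Reading, validation, and screening of longitudinal abundance tables.

The central container is :class:`LongitudinalDataset`: one taxa-by-time
relative-abundance matrix per individual host, with a shared taxon set and
per-individual time grids. Time indices are treated as ordinal (1st, 2nd, ...
sample per host); real-world gaps between collection dates are ignored, which
matches the equally-spaced-sampling assumption of the downstream model.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalDataset",
    "read_dataset",
    "write_dataset",
    "read_taxonomy",
    "close_to_relative",
    "screen_taxa",
]

_CLOSURE_TOL = 1e-8


@dataclasses.dataclass
class LongitudinalDataset:
    """Aligned longitudinal relative-abundance data for ``N`` individuals.

    Parameters
    ----------
    taxa_ids
        Taxon identifiers shared by every per-individual matrix (length ``m``).
    individuals
        Individual (host) identifiers (length ``N``).
    matrices
        Mapping individual -> ``m x T_i`` array. Entry ``[j, t]`` is the
        relative abundance of taxon ``j`` in that individual's ``t``-th sample.
    time_labels
        Mapping individual -> strictly increasing numeric time indices
        (length ``T_i``).
    taxonomy
        Optional mapping taxon id -> ``{"order": ..., ...}``.
    closed
        Whether sample columns are expected to sum to one. Screened or
        model-generated data may legitimately carry non-closed columns.
    """

    taxa_ids: list[str]
    individuals: list[str]
    matrices: dict[str, np.ndarray]
    time_labels: dict[str, np.ndarray]
    taxonomy: dict[str, dict[str, str]] | None = None
    closed: bool = True

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_samples(self) -> int:
        return sum(m.shape[1] for m in self.matrices.values())

    def timepoints(self, individual: str) -> int:
        return self.matrices[individual].shape[1]

    def taxon_index(self, taxon_id: str) -> int:
        try:
            return self.taxa_ids.index(taxon_id)
        except ValueError:
            raise KeyError(f"unknown taxon {taxon_id!r}") from None

    def pooled_matrix(self) -> np.ndarray:
        """All samples side by side, ``m x (sum of T_i)``, individual-major."""
        return np.concatenate(
            [self.matrices[ind] for ind in self.individuals], axis=1
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        m = self.n_taxa
        if len(set(self.taxa_ids)) != m:
            raise ValueError("duplicate taxon ids")
        for ind in self.individuals:
            mat = self.matrices[ind]
            if mat.shape[0] != m:
                raise ValueError(
                    f"individual {ind!r}: {mat.shape[0]} rows, expected {m}"
                )
            if mat.shape[1] < 2:
                raise ValueError(f"individual {ind!r}: fewer than 2 time points")
            if np.any(mat < 0) or not np.all(np.isfinite(mat)):
                raise ValueError(f"individual {ind!r}: negative or non-finite entries")
            t = np.asarray(self.time_labels[ind], dtype=float)
            if t.shape[0] != mat.shape[1]:
                raise ValueError(f"individual {ind!r}: time labels mismatch")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"individual {ind!r}: time labels not increasing")
            if self.closed:
                sums = mat.sum(axis=0)
                bad = np.abs(sums - 1.0) > 1e-6
                if np.any(bad & (sums > 0)):
                    raise ValueError(
                        f"individual {ind!r}: sample columns do not sum to 1 "
                        f"(first offender: column {int(np.nonzero(bad)[0][0])})"
                    )

    def copy(self) -> "LongitudinalDataset":
        return LongitudinalDataset(
            taxa_ids=list(self.taxa_ids),
            individuals=list(self.individuals),
            matrices={k: v.copy() for k, v in self.matrices.items()},
            time_labels={k: np.asarray(v).copy() for k, v in self.time_labels.items()},
            taxonomy=None if self.taxonomy is None else {
                k: dict(v) for k, v in self.taxonomy.items()
            },
            closed=self.closed,
        )


def _read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=index_col)


def read_dataset(
    abundance_path: str | Path,
    metadata_path: str | Path,
    orientation: str = "taxa_by_samples",
    taxonomy_path: str | Path | None = None,
    validate: bool = True,
) -> LongitudinalDataset:
    """Read an abundance table plus sample metadata into a dataset.

    The abundance table is delimited text with a header of sample ids; rows
    are taxa (``orientation="taxa_by_samples"``, the default) or samples
    (``"samples_by_taxa"``). Metadata must provide columns ``sample_id``,
    ``individual_id`` and numeric ``time_index``. Samples are grouped by
    individual and ordered by ``time_index``; duplicated ``(individual,
    time_index)`` pairs are rejected.
    """
    if orientation not in {"taxa_by_samples", "samples_by_taxa"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    abund = _read_table(abundance_path, index_col=0)
    if orientation == "samples_by_taxa":
        abund = abund.T
    meta = _read_table(metadata_path)
    required = {"sample_id", "individual_id", "time_index"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    meta = meta.astype({"sample_id": str, "individual_id": str})
    meta["time_index"] = pd.to_numeric(meta["time_index"], errors="raise")

    for col in abund.columns:
        if str(col) not in set(meta["sample_id"]):
            raise ValueError(f"sample {col!r} absent from metadata")
    values = abund.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(abund.columns):
            colvals = pd.to_numeric(abund[col], errors="coerce")
            bad = colvals.isna() & abund[col].notna()
            if bad.any():
                row = abund.index[int(np.nonzero(bad.to_numpy())[0][0])]
                raise ValueError(
                    f"non-numeric abundance value at row {row!r}, column {col!r}"
                )
        values = abund.apply(pd.to_numeric, errors="raise").to_numpy()
    values = values.astype(float)

    dup = meta.duplicated(subset=["individual_id", "time_index"])
    if dup.any():
        offender = meta[dup].iloc[0]
        raise ValueError(
            "duplicate time point: individual "
            f"{offender['individual_id']!r} at t={offender['time_index']}"
        )

    sample_pos = {str(s): k for k, s in enumerate(abund.columns)}
    meta = meta[meta["sample_id"].isin(sample_pos)]
    individuals = sorted(meta["individual_id"].unique())
    matrices: dict[str, np.ndarray] = {}
    time_labels: dict[str, np.ndarray] = {}
    for ind in individuals:
        sub = meta[meta["individual_id"] == ind].sort_values("time_index")
        cols = [sample_pos[s] for s in sub["sample_id"]]
        matrices[ind] = values[:, cols]
        time_labels[ind] = sub["time_index"].to_numpy(dtype=float)

    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path is not None else None
    sums = values.sum(axis=0)
    closed = bool(np.all(np.abs(sums - 1.0) <= 1e-6))
    ds = LongitudinalDataset(
        taxa_ids=[str(t) for t in abund.index],
        individuals=individuals,
        matrices=matrices,
        time_labels=time_labels,
        taxonomy=taxonomy,
        closed=closed,
    )
    if validate:
        ds.validate()
    return ds


def read_taxonomy(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a taxonomy table with columns ``taxon_id`` and ``order`` (+ extras)."""
    tab = _read_table(path)
    if "taxon_id" not in tab.columns:
        raise ValueError("taxonomy table must have a 'taxon_id' column")
    ranks = [c for c in tab.columns if c != "taxon_id"]
    return {
        str(row["taxon_id"]): {r: str(row[r]) for r in ranks}
        for _, row in tab.iterrows()
    }


def write_dataset(
    dataset: LongitudinalDataset,
    abundance_path: str | Path,
    metadata_path: str | Path,
    float_format: str = "%.10g",
) -> None:
    """Write a dataset back to an abundance TSV/CSV + metadata table.

    Inverse of :func:`read_dataset` on the data model (sample ids are
    regenerated as ``<individual>_t<time>``).
    """
    cols, inds, times = [], [], []
    blocks = []
    for ind in dataset.individuals:
        for k, t in enumerate(dataset.time_labels[ind]):
            label = f"{t:g}" if float(t) == float(t) else str(t)
            cols.append(f"{ind}_t{label}")
            inds.append(ind)
            times.append(float(t))
        blocks.append(dataset.matrices[ind])
    abund = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=dataset.taxa_ids, columns=cols
    )
    sep_a = "\t" if str(abundance_path).endswith((".tsv", ".txt")) else ","
    abund.to_csv(abundance_path, sep=sep_a, index_label="taxon_id",
                 float_format=float_format)
    meta = pd.DataFrame(
        {"sample_id": cols, "individual_id": inds, "time_index": times}
    )
    sep_m = "\t" if str(metadata_path).endswith((".tsv", ".txt")) else ","
    meta.to_csv(metadata_path, sep=sep_m, index=False, float_format=float_format)


def close_to_relative(dataset: LongitudinalDataset) -> LongitudinalDataset:
    """Close each sample column to proportions (divide by its sum).

    Idempotent; preserves the zero pattern. An all-zero sample column is an
    error, since no proportion vector exists for it.
    """
    out = dataset.copy()
    for ind in out.individuals:
        mat = out.matrices[ind]
        sums = mat.sum(axis=0)
        if np.any(sums <= 0):
            t = out.time_labels[ind][int(np.argmin(sums))]
            raise ValueError(
                f"all-zero sample: individual {ind!r} at t={t:g}"
            )
        out.matrices[ind] = mat / sums
    out.closed = True
    return out


def screen_taxa(
    dataset: LongitudinalDataset,
    min_presence_fraction: float = 0.10,
) -> tuple[LongitudinalDataset, list[str]]:
    """Drop taxa with dominant zero abundance before kinship construction.

    A taxon is retained iff it is present (abundance > 0) in at least
    ``min_presence_fraction`` of the time points, pooled over all
    individuals' samples; the comparison is inclusive (``>=``). Retained rows
    are NOT re-closed, so downstream "relative abundance" keeps its original
    whole-community denominator.
    """
    if not 0 <= min_presence_fraction <= 1:
        raise ValueError("min_presence_fraction must be in [0, 1]")
    pooled = dataset.pooled_matrix()
    presence = (pooled > 0).sum(axis=1) / pooled.shape[1]
    if min_presence_fraction == 0:
        keep = (pooled > 0).any(axis=1)
    else:
        keep = presence >= min_presence_fraction
    retained = [t for t, k in zip(dataset.taxa_ids, keep) if k]
    if not retained:
        raise ValueError(
            "no taxa pass the presence screen; lower min_presence_fraction"
        )
    out = dataset.copy()
    idx = np.nonzero(keep)[0]
    out.taxa_ids = retained
    out.matrices = {ind: out.matrices[ind][idx] for ind in out.individuals}
    if out.taxonomy is not None:
        out.taxonomy = {t: out.taxonomy[t] for t in retained if t in out.taxonomy}
    out.closed = False  # rows dropped without re-closure
    return out, retained
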