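"""Core containers and I/O for perturbation expression data.

The central object is :class:`PerturbationDataset`: a samples × genes
expression matrix together with per-sample metadata identifying the
*context* (cell type / cell line), the *action* (perturbation, with a
reserved control value) and optional *location* fields (donor, plate,
row) that capture batch structure in plate-based designs.

Supported on-disk formats are dense TSV/CSV (genes in the header row,
sample ids in the first column) and MatrixMarket coordinate triplets
with companion gene-id and sample-metadata TSVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "PerturbationDataset",
    "ObservedPairSet",
    "PredictionSet",
    "load_expression",
    "save_expression",
    "holdout_split",
]

#: metadata columns recognised as batch/location indicators
LOCATION_COLUMNS = ("donor", "plate", "row")

SCALES = ("counts", "lognorm")


class DataValidationError(ValueError):
    """Raised when a dataset violates its structural contract."""


@dataclass
class PerturbationDataset:
    """Expression matrix (samples × genes) plus per-sample metadata.

    Parameters
    ----------
    matrix
        Dense ``(n_samples, n_genes)`` float array. Entries must be finite;
        non-negative when ``scale == "counts"``.
    gene_ids
        Ordered, unique gene identifiers (length ``n_genes``).
    obs
        Per-sample metadata with at least ``context`` and ``action`` columns;
        optional location columns ``donor``, ``plate``, ``row``. The index
        holds sample ids.
    scale
        ``"counts"`` for raw (summable) counts, ``"lognorm"`` for
        log-normalized expression.
    control_action
        The action value designating the unperturbed control condition
        (default the literal string ``"0"``; plate datasets typically use a
        negative-control compound such as DMSO).
    """

    matrix: np.ndarray
    gene_ids: np.ndarray
    obs: pd.DataFrame
    scale: str = "lognorm"
    control_action: str = "0"
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.matrix.ndim != 2:
            raise DataValidationError("expression matrix must be 2-dimensional")
        if self.scale not in SCALES:
            raise DataValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        n_samples, n_genes = self.matrix.shape
        if len(self.gene_ids) != n_genes:
            raise DataValidationError(
                f"gene id count mismatch: {len(self.gene_ids)} ids vs {n_genes} matrix columns"
            )
        if len(self.obs) != n_samples:
            raise DataValidationError(
                f"metadata/matrix dimension mismatch: {len(self.obs)} vs {n_samples}"
            )
        ids, counts = np.unique(self.gene_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            dups = ids[counts > 1][:5].tolist()
            raise DataValidationError(f"duplicate gene identifiers: {dups}")
        for col in ("context", "action"):
            if col not in self.obs.columns:
                raise DataValidationError(f"metadata is missing required column {col!r}")
        if np.isnan(self.matrix).any():
            raise DataValidationError("expression matrix contains NaN; missing values are not permitted")
        if not np.isfinite(self.matrix).all():
            raise DataValidationError("expression matrix contains non-finite entries")
        if self.scale == "counts" and (self.matrix < 0).any():
            raise DataValidationError("counts-scale matrix has negative entries")
        self.obs = self.obs.copy()
        self.obs.index.name = None
        self.obs["context"] = self.obs["context"].astype(str)
        self.obs["action"] = self.obs["action"].astype(str)
        for col in LOCATION_COLUMNS:
            if col in self.obs.columns:
                self.obs[col] = self.obs[col].astype(str)
        # contexts lacking control samples: recorded as a warning, not an error,
        # because DE against control is not always requested
        missing = [c for c in self.contexts if (c, self.control_action) not in self.pairs()]
        if missing:
            msg = f"contexts without control action {self.control_action!r}: {missing}"
            self.log.append(msg)
            warnings.warn(msg, stacklevel=2)

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def contexts(self) -> list[str]:
        return sorted(self.obs["context"].unique())

    @property
    def actions(self) -> list[str]:
        return sorted(self.obs["action"].unique())

    @property
    def perturbation_actions(self) -> list[str]:
        return [a for a in self.actions if a != self.control_action]

    def pairs(self) -> set[tuple[str, str]]:
        """All observed (context, action) pairs, controls included."""
        return set(map(tuple, self.obs[["context", "action"]].drop_duplicates().itertuples(index=False)))

    def perturbation_pairs(self) -> set[tuple[str, str]]:
        return {(c, a) for c, a in self.pairs() if a != self.control_action}

    def mask(self, context: str | None = None, action: str | None = None) -> np.ndarray:
        m = np.ones(self.n_samples, dtype=bool)
        if context is not None:
            m &= (self.obs["context"] == str(context)).to_numpy()
        if action is not None:
            m &= (self.obs["action"] == str(action)).to_numpy()
        return m

    def subset(self, mask: np.ndarray) -> "PerturbationDataset":
        return PerturbationDataset(
            matrix=self.matrix[mask],
            gene_ids=self.gene_ids,
            obs=self.obs.loc[mask],
            scale=self.scale,
            control_action=self.control_action,
        )

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids.astype(str))


@dataclass(frozen=True)
class ObservedPairSet:
    """A set of (context, action) pairs with a train/test role."""

    pairs: frozenset
    role: str  # "train" | "test"

    def __post_init__(self):
        if self.role not in ("train", "test"):
            raise ValueError(f"role must be 'train' or 'test', got {self.role!r}")
        object.__setattr__(self, "pairs", frozenset(map(tuple, self.pairs)))

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PredictionSet:
    """In silico predictions: per-(context, action) mean expression vectors.

    ``point`` maps ``(context, action)`` to a gene-length vector of predicted
    mean expression. Distribution-predicting models may additionally supply
    ``samples``: per-pair matrices of sampled predicted cells sharing the
    same gene ordering.
    """

    point: dict
    gene_ids: np.ndarray
    samples: dict | None = None
    scale: str = "lognorm"

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        p = len(self.gene_ids)
        self.point = {tuple(k): np.asarray(v, dtype=float) for k, v in self.point.items()}
        for k, v in self.point.items():
            if v.shape != (p,):
                raise DataValidationError(
                    f"prediction for pair {k} has length {v.shape}, expected ({p},)"
                )
        if self.samples is not None:
            self.samples = {tuple(k): np.asarray(v, dtype=float) for k, v in self.samples.items()}
            for k, v in self.samples.items():
                if v.ndim != 2 or v.shape[1] != p:
                    raise DataValidationError(
                        f"sampled predictions for pair {k} have shape {v.shape}, expected (*, {p})"
                    )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"{c}::{a}": v for (c, a), v in sorted(self.point.items())}
        return pd.DataFrame(cols, index=self.gene_ids.astype(str))

    def save_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def load_tsv(cls, path, scale: str = "lognorm") -> "PredictionSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        point = {}
        for col in df.columns:
            if "::" not in col:
                raise DataValidationError(
                    f"prediction column {col!r} is not of the form 'context::action'"
                )
            c, a = col.split("::", 1)
            point[(c, a)] = df[col].to_numpy(dtype=float)
        return cls(point=point, gene_ids=df.index.to_numpy(dtype=object), scale=scale)


# ----------------------------------------------------------------------
# I/O


def _read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    meta.index = meta.index.astype(str)
    return meta


def load_expression(
    path,
    format: str = "dense-tsv",
    metadata_path=None,
    *,
    genes_path=None,
    scale: str = "lognorm",
    control_action: str = "0",
    orientation: str = "auto",
) -> PerturbationDataset:
    """Read an expression matrix plus sample metadata from disk.

    Parameters
    ----------
    path
        Matrix file. For ``mtx+tsv`` this is the ``.mtx`` coordinate file.
    format
        ``"dense-tsv"``, ``"dense-csv"`` or ``"mtx+tsv"``.
    metadata_path
        Sample metadata TSV (columns ``context``, ``action``, optional
        location columns), keyed by sample id. Defaults to a sibling file
        ``<stem>.meta.tsv``.
    genes_path
        For MTX input: one gene id per line. Defaults to ``<stem>.genes.tsv``.
    orientation
        ``"samples-rows"``, ``"genes-rows"`` or ``"auto"`` (detected by
        matching metadata sample ids against row/column labels; dense
        formats only).
    """
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.parent / (path.name.split(".")[0] + ".meta.tsv")
    meta = _read_metadata(metadata_path)

    if format in ("dense-tsv", "dense-csv"):
        sep = "\t" if format == "dense-tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        if orientation == "auto":
            if meta.index.isin(df.index).all():
                pass
            elif meta.index.isin(df.columns).all():
                df = df.T
            elif len(df) != len(meta) and df.shape[1] == len(meta):
                df = df.T  # transposing reconciles the dimensions
        elif orientation == "genes-rows":
            df = df.T
        matrix = df.to_numpy(dtype=float)
        gene_ids = df.columns.to_numpy(dtype=object)
        sample_ids = df.index
    elif format == "mtx+tsv":
        if genes_path is None:
            genes_path = path.parent / (path.name.split(".")[0] + ".genes.tsv")
        mat = scipy.io.mmread(path)
        matrix = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        gene_ids = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy(dtype=object)
        if matrix.shape[0] == len(gene_ids) and matrix.shape[0] != len(meta):
            matrix = matrix.T  # genes-in-rows triplet
        sample_ids = meta.index
    else:
        raise ValueError(f"unknown format {format!r}")

    if matrix.shape[0] != len(meta):
        raise DataValidationError(
            f"metadata/matrix dimension mismatch: {len(meta)} vs {matrix.shape[0]}"
        )
    obs = meta.loc[sample_ids] if list(sample_ids) != list(meta.index) else meta
    ds = PerturbationDataset(
        matrix=matrix,
        gene_ids=gene_ids,
        obs=obs,
        scale=scale,
        control_action=control_action,
    )
    ds.log.append(f"loaded {format} matrix {matrix.shape} from {path} (samples in rows)")
    return ds


def save_expression(dataset: PerturbationDataset, out_dir, format: str = "dense-tsv", stem: str = "matrix") -> dict:
    """Write a dataset to ``out_dir``; returns the paths written.

    Dense formats store samples in rows; MTX stores the same orientation as
    a coordinate triplet. Metadata always goes to ``<stem>.meta.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_path = out_dir / f"{stem}.meta.tsv"
    meta = dataset.obs.rename_axis("sample_id")
    meta.to_csv(meta_path, sep="\t")
    paths = {"metadata": meta_path}
    if format in ("dense-tsv", "dense-csv"):
        sep = "\t" if format == "dense-tsv" else ","
        ext = "tsv" if format == "dense-tsv" else "csv"
        mat_path = out_dir / f"{stem}.{ext}"
        df = pd.DataFrame(
            dataset.matrix,
            index=dataset.obs.index.rename("sample_id"),
            columns=dataset.gene_ids.astype(str),
        )
        df.to_csv(mat_path, sep=sep)
        paths["matrix"] = mat_path
    elif format == "mtx+tsv":
        mat_path = out_dir / f"{stem}.mtx"
        scipy.io.mmwrite(str(mat_path), scipy.sparse.coo_matrix(dataset.matrix))
        genes_path = out_dir / f"{stem}.genes.tsv"
        pd.Series(dataset.gene_ids.astype(str)).to_csv(genes_path, sep="\t", index=False, header=False)
        paths.update(matrix=mat_path, genes=genes_path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return paths


# ----------------------------------------------------------------------
# Train/test partitioning


def holdout_split(
    dataset: PerturbationDataset,
    held_out: Iterable[tuple] | None = None,
    n_random: int | None = None,
    seed: int | None = None,
) -> tuple[ObservedPairSet, ObservedPairSet]:
    """Partition observed (context, action) pairs into train and test sets.

    Either an explicit collection of held-out pairs or a count of randomly
    selected perturbation pairs may be given. Control pairs (action equal to
    the dataset's control token) are never held out; the union of the two
    sets is exactly the observed pair set and they are disjoint.
    """
    all_pairs = dataset.pairs()
    pert_pairs = sorted(dataset.perturbation_pairs())
    if (held_out is None) == (n_random is None):
        raise ValueError("specify exactly one of held_out or n_random")
    if held_out is not None:
        test = {tuple(map(str, p)) for p in held_out}
        for p in test:
            if p not in all_pairs:
                raise ValueError(f"held-out pair {p} is not observed in the dataset")
            if p[1] == dataset.control_action:
                raise ValueError(f"control pair {p} cannot be held out")
    else:
        if n_random < 0 or n_random > len(pert_pairs):
            raise ValueError(
                f"n_random={n_random} out of range: {len(pert_pairs)} perturbation pairs available"
            )
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pert_pairs), size=n_random, replace=False)
        test = {pert_pairs[i] for i in idx}
    train = all_pairs - test
    return (
        ObservedPairSet(pairs=frozenset(train), role="train"),
        ObservedPairSet(pairs=frozenset(test), role="test"),
    )
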