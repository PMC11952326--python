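"""Plate-design-aware pseudo-bulking and population-level DE.

Single-cell counts are aggregated by *sum* within groups defined by cell
type, action and the "location" triple (donor i, plate j, row/library k),
yielding bulk-like replicate profiles. In a fully-crossed plate design
each perturbation pair (cell type, compound) has exactly one well per
donor, hence three pseudobulk replicates, while negative-control columns
provide many control replicates per donor.

Population-level DE fits, per gene, log1p pseudobulk expression on the
action indicator plus donor / plate-within-donor / row covariates — the
same model for the in vitro branch and for model predictions assigned to
the matching locations, so the two branches are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .data_model import PerturbationDataset
from .de_core import DEResult, DEThresholds, linear_model_de

__all__ = [
    "PseudobulkDataset",
    "pseudobulk_sum",
    "filter_complete_pairs",
    "to_count_scale",
    "population_de",
]

GROUP_KEYS = ("context", "action", "donor", "plate", "row")


@dataclass
class PseudobulkDataset:
    """Summed counts per (context, action, donor, plate, row) group."""

    matrix: np.ndarray  # groups × genes, summed counts
    meta: pd.DataFrame  # one row per group: GROUP_KEYS + n_cells
    gene_ids: np.ndarray
    control_action: str = "0"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.matrix.shape[0] != len(self.meta):
            raise ValueError(
                f"group metadata/matrix mismatch: {len(self.meta)} vs {self.matrix.shape[0]}"
            )
        if (self.meta["n_cells"] < 1).any():
            raise ValueError("every pseudobulk group must contain at least one cell")

    @property
    def n_groups(self) -> int:
        return self.matrix.shape[0]

    def pairs(self) -> set:
        return set(map(tuple, self.meta[["context", "action"]].drop_duplicates().itertuples(index=False)))

    def to_dataset(self) -> PerturbationDataset:
        """View the groups as samples of a counts-scale dataset."""
        return PerturbationDataset(
            matrix=self.matrix,
            gene_ids=self.gene_ids,
            obs=self.meta.drop(columns=["n_cells"]),
            scale="counts",
            control_action=self.control_action,
        )


def pseudobulk_sum(
    dataset: PerturbationDataset, group_keys=GROUP_KEYS
) -> PseudobulkDataset:
    """Sum-aggregate cells into pseudobulk groups.

    Requires counts-scale input (sums of log-normalized values are not
    meaningful) and the location metadata named by ``group_keys``. Total
    counts are conserved: the per-gene grand total over groups equals the
    grand total over cells.
    """
    if dataset.scale != "counts":
        raise ValueError(
            "pseudobulk aggregation needs raw counts; supply the counts-scale matrix, "
            "not log-normalized expression"
        )
    missing = [k for k in group_keys if k not in dataset.obs.columns]
    if missing:
        raise ValueError(f"missing location metadata column(s): {missing}")
    keys = dataset.obs[list(group_keys)].astype(str)
    codes, uniques = pd.factorize(pd.MultiIndex.from_frame(keys), sort=True)
    n_groups = len(uniques)
    mat = np.zeros((n_groups, dataset.n_genes))
    np.add.at(mat, codes, dataset.matrix)
    meta = pd.DataFrame(list(uniques), columns=list(group_keys))
    meta["n_cells"] = np.bincount(codes, minlength=n_groups)
    return PseudobulkDataset(
        matrix=mat, meta=meta, gene_ids=dataset.gene_ids, control_action=dataset.control_action
    )


def filter_complete_pairs(pb: PseudobulkDataset, required_donors: int = 3) -> PseudobulkDataset:
    """Drop (context, action) pairs not observed in ``required_donors`` donors.

    Control pairs are subject to the same requirement. The operation is
    idempotent; an empty result is returned with a warning rather than an
    error.
    """
    if "donor" not in pb.meta.columns:
        raise ValueError("donor metadata required for completeness filtering")
    donors_per_pair = pb.meta.groupby(["context", "action"])["donor"].nunique()
    complete = set(donors_per_pair[donors_per_pair >= required_donors].index)
    keep = pb.meta.apply(lambda r: (r["context"], r["action"]) in complete, axis=1).to_numpy()
    if not keep.any():
        warnings.warn("completeness filter removed every pseudobulk group", stacklevel=2)
    return PseudobulkDataset(
        matrix=pb.matrix[keep],
        meta=pb.meta.loc[keep].reset_index(drop=True),
        gene_ids=pb.gene_ids,
        control_action=pb.control_action,
    )


def to_count_scale(
    log_predictions: np.ndarray, size_factors: np.ndarray | float | None = None
) -> np.ndarray:
    """Back-transform log1p-scale predictions to the count scale.

    Applies expm1 elementwise, multiplies by per-group size factors when
    provided (defaulting to 1), and clips at zero. Size factors default to
    the observed totals of the matched in vitro groups in the population
    pipeline, which keeps predicted pseudobulk magnitudes comparable to
    the ground truth.
    """
    vals = np.expm1(np.asarray(log_predictions, dtype=float))
    if size_factors is not None:
        vals = vals * size_factors
    return np.maximum(vals, 0.0)


def nested_plate_codes(donor: pd.Series, plate: pd.Series) -> pd.Series:
    """Recode global plate labels as plate-within-donor indices.

    In the nested design every plate belongs to exactly one donor, so raw
    donor + plate dummies are aliased; the within-donor code keeps the
    design full rank while spanning the same column space.
    """
    frame = pd.DataFrame({"donor": donor.astype(str), "plate": plate.astype(str)})
    per_donor = frame.groupby("donor")["plate"].transform(
        lambda s: s.astype("category").cat.codes.astype(str)
    )
    return per_donor


def population_de(
    pb: PseudobulkDataset,
    context: str,
    action: str,
    *,
    control_action: str | None = None,
    predicted_counts: dict | None = None,
    thresholds: DEThresholds | None = DEThresholds(),
) -> DEResult:
    """Covariate-adjusted linear-model DE for one (context, action) pair.

    Subsets the pseudobulk groups of ``context`` carrying either the
    target action or the (negative) control, fits log1p expression on the
    action indicator + donor, plate-within-donor and row dummies, and
    tests the action coefficient.

    The in silico branch passes ``predicted_counts``: a mapping
    donor -> count-scale predicted gene vector; the perturbation groups'
    rows are then replaced by the predictions *at the same locations*
    while the in vitro control groups are kept, and the identical model is
    fitted — so running this function with the in vitro counts themselves
    reproduces the in vitro branch bitwise.
    """
    control_action = control_action or pb.control_action
    sel = (pb.meta["context"] == str(context)) & pb.meta["action"].isin([str(action), control_action])
    meta = pb.meta.loc[sel].reset_index(drop=True)
    counts = pb.matrix[sel.to_numpy()].copy()
    if (meta["action"] == str(action)).sum() == 0:
        raise ValueError(f"no pseudobulk groups for pair ({context!r}, {action!r})")
    if predicted_counts is not None:
        for i, row in meta.iterrows():
            if row["action"] == str(action):
                donor = row["donor"]
                if donor not in predicted_counts:
                    raise ValueError(f"no prediction supplied for donor {donor!r}")
                counts[i] = np.asarray(predicted_counts[donor], dtype=float)
    design = meta[["action"]].copy()
    design["donor"] = meta["donor"]
    design["plate"] = nested_plate_codes(meta["donor"], meta["plate"])
    design["row"] = meta["row"]
    covariates = [c for c in ("donor", "plate", "row") if design[c].nunique() > 1]
    return linear_model_de(
        np.log1p(counts),
        design,
        str(action),
        control_action=control_action,
        covariates=covariates,
        gene_ids=pb.gene_ids,
        log_base="e",
        thresholds=thresholds,
    )
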