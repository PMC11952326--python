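"""Synthetic perturbation datasets with known DEG ground truth.

Two generators mirror the designs the evaluation framework targets:

* :func:`simulate_single_cell` — a single-cell dataset of C contexts
  (cell types) × (control + perturbations), log-normalized scale, with
  additive context baselines α_gc, sparse perturbation effects β_ga and
  Gaussian cell-level noise. The defaults mirror an interferon-style
  PBMC design: 7 contexts, one stimulation, 6998 genes, ~30 true DEGs,
  context variance dominating effect variance — the regime in which a
  control-mean predictor attains high R² while carrying no DE signal.
* :func:`simulate_plate_design` — a plate-structured counts dataset:
  3 donors × 2 plates × 8 rows, the first three columns of every plate
  reserved for control compounds (negative control first), one well per
  perturbation per donor, every well carrying all cell types, with
  additive log-scale donor/plate/row batch effects and negative-binomial
  counts.

Both return a :class:`~degeval.data_model.PerturbationDataset` plus a
:class:`GroundTruth` holding the generative α, β, per-pair means and the
true DEG support, so every downstream module can be validated without
external data. All randomness flows through one seeded generator; the
same seed reproduces the dataset bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import PerturbationDataset, PredictionSet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "pbmc_like_config",
    "plate_like_config",
    "simulate_single_cell",
    "simulate_plate_design",
    "simulate_null_pseudobulk",
    "corrupt_predictions",
]

NEG_CONTROL = "DMSO"
POS_CONTROLS = ("dabrafenib", "belinostat")
ROWS = tuple("ABCDEFGH")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are set by the two named constructors."""

    n_contexts: int = 7
    n_perturbations: int = 1
    n_genes: int = 6998
    cells_per_pair: int = 200  # per well and cell type in plate mode
    deg_fraction: float = 30 / 6998
    effect_range: tuple = (1.0, 2.5)  # |effect| on the generative log scale
    effect_sign_up: float = 0.75  # probability of up-regulation
    base_range: tuple = (1.0, 4.0)  # baseline expression (single-cell mode)
    base_log_sd: float = 1.0  # baseline log-mean spread (plate mode)
    context_sd: float = 0.4
    noise: str = "gaussian-log"  # or "negative-binomial"
    sigma: float = 0.6
    nb_dispersion: float = 10.0
    batch_sd: float = 0.1
    plate: bool = False
    n_columns: int = 6  # plate columns actually simulated (first 3 = controls)
    control_action: str = "0"

    def __post_init__(self):
        if min(self.n_contexts, self.n_perturbations, self.n_genes, self.cells_per_pair) < 1:
            raise ValueError("all design counts must be positive")
        if not (0.0 <= self.deg_fraction <= 1.0):
            raise ValueError("deg_fraction must lie in [0, 1]")


def pbmc_like_config(**overrides) -> SimConfig:
    """7 cell types × (control, stimulation), 6998 genes, 30 true DEGs."""
    return replace(SimConfig(), **overrides)


def plate_like_config(**overrides) -> SimConfig:
    """3 donors × 2 plates × 8 rows, 6 cell types, NB counts (desk scale)."""
    cfg = SimConfig(
        n_contexts=6,
        n_perturbations=12,
        n_genes=800,
        cells_per_pair=20,
        deg_fraction=0.02,
        effect_range=(0.5, 1.5),
        context_sd=0.5,
        noise="negative-binomial",
        plate=True,
        control_action=NEG_CONTROL,
    )
    return replace(cfg, **overrides)


@dataclass
class GroundTruth:
    """Generative parameters: baselines, sparse effects and DEG support."""

    contexts: list
    actions: list  # perturbation actions, control excluded
    gene_ids: np.ndarray
    alpha: np.ndarray  # (n_contexts, n_genes)
    beta: np.ndarray  # (n_perturbations, n_genes), zero off the DEG support
    control_action: str = "0"

    @property
    def labels(self) -> np.ndarray:
        """True DEG indicator matrix, actions × genes."""
        return (self.beta != 0.0).astype(int)

    def labels_for(self, action: str) -> np.ndarray:
        return self.labels[self.actions.index(action)]

    def mean_for(self, context: str, action: str) -> np.ndarray:
        m = self.alpha[self.contexts.index(context)].copy()
        if action != self.control_action:
            m = m + self.beta[self.actions.index(action)]
        return m

    def n_degs(self, action: str) -> int:
        return int(self.labels_for(action).sum())


def _gene_ids(n: int) -> np.ndarray:
    width = len(str(n - 1))
    return np.array([f"gene{str(i).zfill(width)}" for i in range(n)], dtype=object)


def _draw_effects(cfg: SimConfig, alpha_min: np.ndarray, rng) -> np.ndarray:
    """Sparse per-action effect matrix; zero outside the DEG support.

    Up-regulation adds a uniform draw from ``effect_range``. Down-regulation
    removes a uniform 50–90% fraction of the smallest context baseline, so
    group means stay positive in every context while the fold-change is
    comfortably detectable.
    """
    n_deg = int(round(cfg.deg_fraction * cfg.n_genes))
    if cfg.deg_fraction > 0 and n_deg == 0:
        warnings.warn(
            f"deg_fraction={cfg.deg_fraction} rounds to 0 DEGs at {cfg.n_genes} genes",
            stacklevel=3,
        )
    beta = np.zeros((cfg.n_perturbations, cfg.n_genes))
    for a in range(cfg.n_perturbations):
        support = rng.choice(cfg.n_genes, size=n_deg, replace=False)
        up = rng.random(n_deg) < cfg.effect_sign_up
        lo, hi = cfg.effect_range
        vals = rng.uniform(lo, hi, size=n_deg)
        frac = rng.uniform(0.5, 0.9, size=n_deg)
        beta[a, support] = np.where(up, vals, -frac * alpha_min[support])
    return beta


def simulate_single_cell(cfg: SimConfig, seed: int) -> tuple[PerturbationDataset, GroundTruth]:
    """Generate a log-normalized single-cell dataset plus ground truth.

    Cell means are α_gc + β_ga; cells are i.i.d. Gaussian around them on
    the log-normalized scale (clipped at zero, as normalized expression is
    non-negative), or negative-binomial counts when ``cfg.noise`` is
    ``"negative-binomial"`` (the log-scale mean is then interpreted as
    log1p of the count mean).
    """
    rng = np.random.default_rng(seed)
    contexts = [f"ct{i}" for i in range(cfg.n_contexts)]
    if cfg.n_perturbations == 1:
        actions = ["stim"]
    else:
        actions = [f"p{i}" for i in range(cfg.n_perturbations)]
    genes = _gene_ids(cfg.n_genes)

    base = rng.uniform(*cfg.base_range, size=cfg.n_genes)
    alpha = base[None, :] + rng.normal(0.0, cfg.context_sd, size=(cfg.n_contexts, cfg.n_genes))
    alpha = np.maximum(alpha, 0.05)  # expression baselines stay positive
    beta = _draw_effects(cfg, alpha.min(axis=0), rng)
    truth = GroundTruth(
        contexts=contexts,
        actions=actions,
        gene_ids=genes,
        alpha=alpha,
        beta=beta,
        control_action=cfg.control_action,
    )

    blocks, ctx_col, act_col = [], [], []
    for ci, c in enumerate(contexts):
        for a in [cfg.control_action] + actions:
            mean = truth.mean_for(c, a)
            if cfg.noise == "gaussian-log":
                cells = mean + rng.normal(0.0, cfg.sigma, size=(cfg.cells_per_pair, cfg.n_genes))
                cells = np.maximum(cells, 0.0)
            elif cfg.noise == "negative-binomial":
                mu = np.expm1(np.maximum(mean, 0.0))
                theta = cfg.nb_dispersion
                p = theta / (theta + np.maximum(mu, 1e-12))
                cells = rng.negative_binomial(theta, p, size=(cfg.cells_per_pair, cfg.n_genes)).astype(float)
            else:
                raise ValueError(f"unknown noise model {cfg.noise!r}")
            blocks.append(cells)
            ctx_col += [c] * cfg.cells_per_pair
            act_col += [a] * cfg.cells_per_pair
    matrix = np.vstack(blocks)
    obs = pd.DataFrame(
        {"context": ctx_col, "action": act_col},
        index=[f"cell{i}" for i in range(matrix.shape[0])],
    )
    dataset = PerturbationDataset(
        matrix=matrix,
        gene_ids=genes,
        obs=obs,
        scale="lognorm" if cfg.noise == "gaussian-log" else "counts",
        control_action=cfg.control_action,
    )
    return dataset, truth


# ----------------------------------------------------------------------
# Plate-structured design


def _plate_layout(cfg: SimConfig, rng) -> pd.DataFrame:
    """One row per occupied well: donor, plate, row, column, action.

    Columns 1–3 of every plate hold the control compounds (negative
    control first), giving 16 locations per control action and donor
    (8 rows × 2 plates). Each perturbation occupies one randomly drawn
    free well per donor.
    """
    donors = ["d1", "d2", "d3"]
    controls = [NEG_CONTROL, *POS_CONTROLS]
    pert_actions = [f"drug{str(i).zfill(2)}" for i in range(cfg.n_perturbations)]
    records = []
    for di, donor in enumerate(donors):
        plates = [f"p{2 * di + 1}", f"p{2 * di + 2}"]
        free = [(pl, r, col) for pl in plates for r in ROWS for col in range(4, cfg.n_columns + 1)]
        if cfg.n_perturbations > len(free):
            raise ValueError(
                f"{cfg.n_perturbations} perturbations exceed {len(free)} available wells per donor"
            )
        for pl in plates:
            for r in ROWS:
                for col, act in zip((1, 2, 3), controls):
                    records.append((donor, pl, r, col, act))
        chosen = rng.choice(len(free), size=cfg.n_perturbations, replace=False)
        for act, wi in zip(pert_actions, chosen):
            pl, r, col = free[wi]
            records.append((donor, pl, r, col, act))
    return pd.DataFrame(records, columns=["donor", "plate", "row", "column", "action"])


def simulate_plate_design(cfg: SimConfig, seed: int) -> tuple[PerturbationDataset, GroundTruth]:
    """Generate a plate-structured counts dataset plus ground truth.

    Every occupied well carries all cell types. Per-cell count means are
    exp(b_g + context + action + donor + plate + row effects) with
    negative-binomial sampling; batch effects are additive on the log
    scale (SD ``cfg.batch_sd``) so the population DE model's covariates
    can remove them exactly.
    """
    if not cfg.plate:
        raise ValueError("plate layout flag is not set on this config")
    rng = np.random.default_rng(seed)
    layout = _plate_layout(cfg, rng)
    cell_types = ["Tcell", "Tcd4", "Tcd8", "B", "NK", "Myeloid"][: cfg.n_contexts]
    genes = _gene_ids(cfg.n_genes)

    base = rng.normal(0.0, cfg.base_log_sd, size=cfg.n_genes)
    ctx_eff = rng.normal(0.0, cfg.context_sd, size=(cfg.n_contexts, cfg.n_genes))
    alpha = base[None, :] + ctx_eff
    actions = sorted(a for a in layout["action"].unique() if a != NEG_CONTROL)
    n_actions = len(actions)
    # sparse effects relative to the negative control, positive controls included
    beta = np.zeros((n_actions, cfg.n_genes))
    n_deg = int(round(cfg.deg_fraction * cfg.n_genes))
    lo, hi = cfg.effect_range
    for ai in range(n_actions):
        support = rng.choice(cfg.n_genes, size=n_deg, replace=False)
        sign = np.where(rng.random(n_deg) < cfg.effect_sign_up, 1.0, -1.0)
        beta[ai, support] = sign * rng.uniform(lo, hi, size=n_deg)
    truth = GroundTruth(
        contexts=cell_types,
        actions=actions,
        gene_ids=genes,
        alpha=alpha,
        beta=beta,
        control_action=NEG_CONTROL,
    )

    donor_eff = {d: rng.normal(0.0, cfg.batch_sd, cfg.n_genes) for d in layout["donor"].unique()}
    plate_eff = {p: rng.normal(0.0, cfg.batch_sd, cfg.n_genes) for p in layout["plate"].unique()}
    row_eff = {r: rng.normal(0.0, cfg.batch_sd, cfg.n_genes) for r in ROWS}

    blocks, meta_rows = [], []
    theta = cfg.nb_dispersion
    for rec in layout.itertuples(index=False):
        batch = donor_eff[rec.donor] + plate_eff[rec.plate] + row_eff[rec.row]
        b_action = np.zeros(cfg.n_genes) if rec.action == NEG_CONTROL else beta[actions.index(rec.action)]
        for ci, ct in enumerate(cell_types):
            log_mu = alpha[ci] + b_action + batch
            mu = np.exp(log_mu)
            p = theta / (theta + mu)
            cells = rng.negative_binomial(theta, p, size=(cfg.cells_per_pair, cfg.n_genes)).astype(float)
            blocks.append(cells)
            meta_rows += [
                (ct, rec.action, rec.donor, rec.plate, rec.row)
            ] * cfg.cells_per_pair
    matrix = np.vstack(blocks)
    obs = pd.DataFrame(
        meta_rows,
        columns=["context", "action", "donor", "plate", "row"],
        index=[f"cell{i}" for i in range(matrix.shape[0])],
    )
    dataset = PerturbationDataset(
        matrix=matrix,
        gene_ids=genes,
        obs=obs,
        scale="counts",
        control_action=NEG_CONTROL,
    )
    return dataset, truth


def simulate_null_pseudobulk(
    n_genes: int,
    seed: int,
    *,
    sigma: float = 0.3,
    batch_sd: float = 0.1,
    base_mean: float = 4.0,
    base_sd: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pseudobulk-level null data for DE calibration checks.

    Emits log1p-scale group profiles for one perturbation (3 donors, one
    well each) against a full control block (3 donors × 2 plates × 8 rows)
    with Gaussian noise and additive donor/plate/row batch effects but a
    zero action effect, so a correctly calibrated linear model must return
    uniform p-values. Returns ``(log1p_matrix, group_metadata)``.
    """
    rng = np.random.default_rng(seed)
    donors = ["d1", "d2", "d3"]
    # plate is coded within donor ("1"/"2") so the design stays full rank
    # when donor and plate dummies are used together
    meta_rows = []
    for donor in donors:
        for plate in ("1", "2"):
            for row in ROWS:
                meta_rows.append((donor, plate, row, "0"))
    for donor in donors:
        plate = str(1 + int(rng.integers(0, 2)))
        row = ROWS[int(rng.integers(0, len(ROWS)))]
        meta_rows.append((donor, plate, row, "perturbed"))
    meta = pd.DataFrame(meta_rows, columns=["donor", "plate", "row", "action"])
    base = rng.normal(base_mean, base_sd, size=n_genes)
    donor_eff = {d: rng.normal(0.0, batch_sd, n_genes) for d in donors}
    plate_eff = {p: rng.normal(0.0, batch_sd, n_genes) for p in ("1", "2")}
    row_eff = {r: rng.normal(0.0, batch_sd, n_genes) for r in ROWS}
    mat = np.empty((len(meta), n_genes))
    for i, rec in enumerate(meta.itertuples(index=False)):
        mean = base + donor_eff[rec.donor] + plate_eff[rec.plate] + row_eff[rec.row]
        mat[i] = mean + rng.normal(0.0, sigma, size=n_genes)
    return mat, meta


def corrupt_predictions(
    truth: GroundTruth,
    noise_sd: float,
    seed: int,
    pairs=None,
    scale: str = "lognorm",
) -> PredictionSet:
    """Truth means plus Gaussian log-scale noise, as a PredictionSet.

    ``noise_sd = 0`` returns the exact generative means; increasing it
    degrades the DE ranking smoothly, which is how the R²-vs-AUC-PR
    dissociation is exercised without any trained model.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if pairs is None:
        pairs = [(c, a) for c in truth.contexts for a in truth.actions]
    point = {}
    for c, a in pairs:
        mean = truth.mean_for(c, a)
        if noise_sd > 0:
            # clip at zero: predicted expression must stay non-negative
            point[(c, a)] = np.maximum(mean + rng.normal(0.0, noise_sd, size=mean.shape), 0.0)
        else:
            point[(c, a)] = mean.copy()
    return PredictionSet(point=point, gene_ids=truth.gene_ids, scale=scale)
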