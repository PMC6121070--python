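"""QSAR linear models: the four published scoring equations, MLR fitting,
genetic-algorithm descriptor selection and the validation-statistic suite.

Models map molecular descriptors linearly to pIC50 (the negative decadic log
of the IC50 in molar units).  Model quality is judged by the standard
internal/external battery: R^2 and Q^2_LOO on the training set; Q^2_F1,
Q^2_F2, Q^2_F3 and Lin's concordance correlation coefficient (CCC) on an
external set; RMSE on both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LinearModel", "ValidationReport", "GAConfig",
    "published_models", "predict", "predict_frame", "pretreat",
    "fit_mlr", "q2_loo_press", "ga_select", "validate",
]


class MissingDescriptorError(ValueError):
    """A model input descriptor is absent or flagged missing."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass(frozen=True)
class LinearModel:
    """pIC50 = intercept + sum_k coefficient_k * descriptor_k."""

    name: str
    descriptor_ids: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float

    def __post_init__(self):
        if len(self.descriptor_ids) != len(self.coefficients):
            raise ValueError("one coefficient per descriptor id required")
        if len(set(self.descriptor_ids)) != len(self.descriptor_ids):
            raise ValueError("descriptor ids must be unique")

    @staticmethod
    def from_json(path: str | Path) -> "LinearModel":
        d = json.loads(Path(path).read_text())
        return LinearModel(d["name"], tuple(d["descriptor_ids"]),
                           tuple(d["coefficients"]), d["intercept"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "name": self.name,
            "descriptor_ids": list(self.descriptor_ids),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
        }, indent=2) + "\n")


def published_models() -> list[LinearModel]:
    """The four published scoring equations Y1-Y4, coefficients as printed."""
    out = []
    base = resources.files("arscreen").joinpath("data/models")
    for name in ("y1", "y2", "y3", "y4"):
        d = json.loads(base.joinpath(f"{name}.json").read_text())
        out.append(LinearModel(d["name"], tuple(d["descriptor_ids"]),
                               tuple(d["coefficients"]), d["intercept"]))
    return out


def predict(model: LinearModel, x) -> float:
    """Evaluate a model on one descriptor vector.

    ``x`` maps descriptor id to a float or to a
    :class:`~arscreen.topo.DescriptorValue`.  A missing or flagged entry
    raises :class:`MissingDescriptorError` — never a silent zero-fill.
    """
    total = model.intercept
    for did, coef in zip(model.descriptor_ids, model.coefficients):
        if did not in x:
            raise MissingDescriptorError(f"model {model.name}: descriptor {did!r} absent")
        v = x[did]
        if hasattr(v, "computed"):
            if not v.computed:
                raise MissingDescriptorError(
                    f"model {model.name}: descriptor {did!r} missing ({v.reason})")
            v = v.value
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise MissingDescriptorError(f"model {model.name}: descriptor {did!r} is NaN")
        total += coef * float(v)
    return float(total)


def predict_frame(model: LinearModel, x: pd.DataFrame) -> pd.Series:
    """Vectorized prediction; rows with any missing model input become NaN."""
    cols = list(model.descriptor_ids)
    absent = [c for c in cols if c not in x.columns]
    if absent:
        raise MissingDescriptorError(f"model {model.name}: column(s) {absent} absent")
    sub = x[cols].astype(float)
    return sub.mul(model.coefficients).sum(axis=1, skipna=False) + model.intercept


# ---------------------------------------------------------------------------
# pretreatment

def pretreat(matrix: pd.DataFrame, var_threshold: float = 1.0,
             corr_threshold: float = 0.99) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Remove constant/near-constant and pairwise-redundant descriptor columns.

    Columns with variance below ``var_threshold`` go first; then, for every
    pair with \\|Pearson R\\| above ``corr_threshold``, the later column (in
    input order) is dropped.  Returns the reduced frame and a removal log of
    ``(column, reason)`` tuples.
    """
    if len(matrix) < 2:
        raise ValueError("pretreatment needs at least 2 rows")
    log: list[tuple[str, str]] = []
    keep = []
    for col in matrix.columns:
        if matrix[col].var(ddof=1) < var_threshold:
            log.append((col, "variance"))
        else:
            keep.append(col)
    reduced = matrix[keep]
    if keep:
        corr = reduced.corr().abs().to_numpy()
        drop = set()
        for i in range(len(keep)):
            if i in drop:
                continue
            for j in range(i + 1, len(keep)):
                if j not in drop and corr[i, j] > corr_threshold:
                    drop.add(j)
                    log.append((keep[j], "correlation"))
        keep = [c for k, c in enumerate(keep) if k not in drop]
    if not keep:
        raise ValueError("pretreatment removed every column; review thresholds")
    return matrix[keep], log


# ---------------------------------------------------------------------------
# OLS

def _design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(x)), x])


def _ols(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients [intercept, slopes] with rank check."""
    d = _design(x)
    beta, _, rank, _ = np.linalg.lstsq(d, y, rcond=None)
    if rank < d.shape[1]:
        raise RankDeficiencyError(f"design matrix rank {rank} < {d.shape[1]} columns")
    return beta


def fit_mlr(x: pd.DataFrame | np.ndarray, y, name: str = "mlr") -> LinearModel:
    """Ordinary-least-squares multiple linear regression.

    Requires n > p + 1 and full column rank; a rank-deficient design raises
    :class:`RankDeficiencyError` naming the collinear columns.
    """
    if isinstance(x, pd.DataFrame):
        ids = tuple(str(c) for c in x.columns)
        xv = x.to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        ids = tuple(f"x{i}" for i in range(xv.shape[1]))
    yv = np.asarray(y, dtype=float)
    n, p = xv.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    try:
        beta = _ols(xv, yv)
    except RankDeficiencyError:
        bad = _collinear_columns(xv, ids)
        raise RankDeficiencyError(f"collinear columns: {bad}") from None
    return LinearModel(name, ids, tuple(beta[1:]), float(beta[0]))


def _collinear_columns(xv: np.ndarray, ids: tuple[str, ...]) -> list[str]:
    """Greedy QR-based identification of linearly dependent columns."""
    bad, kept = [], np.ones((len(xv), 1))
    for j, cid in enumerate(ids):
        cand = np.column_stack([kept, xv[:, j]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            kept = cand
        else:
            bad.append(cid)
    return bad


def q2_loo_press(x: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out Q^2 via the PRESS identity e_i / (1 - h_ii).

    Exact for OLS and two orders of magnitude cheaper than refitting; the
    refitting route in :func:`validate` cross-checks it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = _design(x)
    beta, _, rank, _ = np.linalg.lstsq(d, y, rcond=None)
    if rank < d.shape[1]:
        return -np.inf
    resid = y - d @ beta
    # hat diagonal via least-squares solve of D^T D H = D^T, column-wise
    h = np.einsum("ij,ij->i", d, np.linalg.lstsq(d.T @ d, d.T, rcond=None)[0].T)
    denom = 1.0 - h
    if np.any(denom < 1e-10):
        return -np.inf
    press = float(np.sum((resid / denom) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


# ---------------------------------------------------------------------------
# GA descriptor selection

@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for descriptor subset selection.

    Defaults mirror common QSAR-modeling practice: moderate population,
    strong crossover, light mutation, and a hard cap on model size well
    below n/5 to protect against overfitting.
    """

    population_size: int = 100
    generations: int = 200
    mutation_rate: float = 0.05
    crossover_rate: float = 0.8
    max_descriptors: int = 5
    seed: int = 0
    fitness: str = "q2_loo"
    #: Occam penalty subtracted per selected descriptor: without it the GA
    #: pads models to the size cap with noise columns whose spurious
    #: correlation buys a marginal (<0.01) Q2LOO gain
    parsimony: float = 0.01

    def __post_init__(self):
        for r in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.fitness != "q2_loo":
            raise ValueError("only q2_loo fitness is implemented")


def _repair(chrom: np.ndarray, max_on: int, rng: np.random.Generator) -> None:
    """Clamp a chromosome to at most max_on selected columns (in place)."""
    on = np.flatnonzero(chrom)
    if len(on) > max_on:
        off = rng.choice(on, size=len(on) - max_on, replace=False)
        chrom[off] = False


def ga_select(matrix: pd.DataFrame, y, cfg: GAConfig) -> tuple[LinearModel, list[float]]:
    """Select a descriptor subset by a seeded binary-chromosome GA.

    Fitness is Q^2_LOO of the OLS fit on the selected columns; chromosomes
    are capped at ``cfg.max_descriptors`` columns.  Elitism keeps the best
    individual, so the best-so-far fitness trace is non-decreasing.  Returns
    the refitted model on the winning subset and the per-generation trace.
    """
    xv = matrix.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = xv.shape
    if cfg.max_descriptors > n // 5:
        raise ValueError(f"max_descriptors {cfg.max_descriptors} exceeds n/5 = {n // 5}")
    cols = list(matrix.columns)
    if p < cfg.max_descriptors:
        import warnings
        warnings.warn(f"only {p} columns available for cap {cfg.max_descriptors}", stacklevel=2)
    rng = np.random.default_rng(cfg.seed)

    def fitness(chrom: np.ndarray) -> float:
        on = np.flatnonzero(chrom)
        if len(on) == 0:
            return -np.inf
        return q2_loo_press(xv[:, on], yv) - cfg.parsimony * len(on)

    pop = np.zeros((cfg.population_size, p), dtype=bool)
    for i in range(cfg.population_size):
        k = rng.integers(1, max(2, min(cfg.max_descriptors, p) + 1))
        pop[i, rng.choice(p, size=min(k, p), replace=False)] = True
    fits = np.array([fitness(c) for c in pop])

    trace: list[float] = []
    best_idx = int(np.argmax(fits))
    best_chrom, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    trace.append(best_fit)

    for _ in range(cfg.generations):
        new_pop = [best_chrom.copy()]  # elitism
        while len(new_pop) < cfg.population_size:
            # tournament selection, size 2
            a, b = rng.integers(0, cfg.population_size, size=2)
            p1 = pop[a] if fits[a] >= fits[b] else pop[b]
            a, b = rng.integers(0, cfg.population_size, size=2)
            p2 = pop[a] if fits[a] >= fits[b] else pop[b]
            c1, c2 = p1.copy(), p2.copy()
            if rng.random() < cfg.crossover_rate and p > 1:
                cut = int(rng.integers(1, p))
                c1[:cut], c2[:cut] = p2[:cut], p1[:cut]
            for c in (c1, c2):
                flip = rng.random(p) < cfg.mutation_rate
                c[flip] = ~c[flip]
                _repair(c, cfg.max_descriptors, rng)
                new_pop.append(c)
        pop = np.array(new_pop[: cfg.population_size])
        fits = np.array([fitness(c) for c in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_chrom = pop[gen_best].copy()
        trace.append(best_fit)

    on = np.flatnonzero(best_chrom)
    sub = matrix.iloc[:, on]
    model = fit_mlr(sub, yv, name=f"ga[{','.join(str(cols[i]) for i in on)}]")
    return model, trace


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class ValidationReport:
    """Internal and external validation statistics for one model/split."""

    r2: float
    q2_loo: float
    q2_f1: float
    q2_f2: float | None
    q2_f3: float
    ccc: float
    rmse_tr: float
    rmse_pred: float
    n_train: int = 0
    n_ext: int = 0

    def as_row(self) -> dict:
        return {
            "R2": self.r2, "Q2LOO": self.q2_loo, "Q2F1": self.q2_f1,
            "Q2F2": self.q2_f2, "Q2F3": self.q2_f3, "CCC": self.ccc,
            "RMSEtr": self.rmse_tr, "RMSEpred": self.rmse_pred,
        }


def _predict_matrix(model: LinearModel, x: np.ndarray) -> np.ndarray:
    return model.intercept + x @ np.asarray(model.coefficients)


def concordance_ccc(y: np.ndarray, yhat: np.ndarray) -> float:
    """Lin's concordance correlation coefficient."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = len(y)
    dy, dh = y - y.mean(), yhat - yhat.mean()
    denom = float(dy @ dy + dh @ dh + n * (y.mean() - yhat.mean()) ** 2)
    return float(2 * (dy @ dh) / denom)


def validate(model: LinearModel, x_tr, y_tr, x_ext, y_ext,
             loo_refit: bool = True) -> ValidationReport:
    """Full validation battery for a fitted model on a train/external split.

    R^2 = 1 - RSS_tr/TSS_tr; Q^2_LOO by leave-one-out refitting on the
    training set; on the external set Q^2_F1 (training-mean reference),
    Q^2_F2 (external-mean reference; None when the external response has
    zero variance), Q^2_F3 (per-observation variance ratio) and CCC.
    """
    x_tr = np.asarray(x_tr, dtype=float)
    y_tr = np.asarray(y_tr, dtype=float)
    x_ext = np.asarray(x_ext, dtype=float)
    y_ext = np.asarray(y_ext, dtype=float)
    if len(x_ext) < 3:
        raise ValueError("external set needs at least 3 observations")

    yhat_tr = _predict_matrix(model, x_tr)
    rss_tr = float(np.sum((y_tr - yhat_tr) ** 2))
    tss_tr = float(np.sum((y_tr - y_tr.mean()) ** 2))
    r2 = 1.0 - rss_tr / tss_tr

    if loo_refit:
        press = 0.0
        for i in range(len(y_tr)):
            mask = np.arange(len(y_tr)) != i
            beta = _ols(x_tr[mask], y_tr[mask])
            pred_i = beta[0] + x_tr[i] @ beta[1:]
            press += (y_tr[i] - pred_i) ** 2
        q2_loo = 1.0 - press / tss_tr
    else:
        q2_loo = q2_loo_press(x_tr, y_tr)

    yhat_ext = _predict_matrix(model, x_ext)
    rss_ext = float(np.sum((y_ext - yhat_ext) ** 2))
    q2_f1 = 1.0 - rss_ext / float(np.sum((y_ext - y_tr.mean()) ** 2))
    tss_ext = float(np.sum((y_ext - y_ext.mean()) ** 2))
    q2_f2 = None if tss_ext == 0.0 else 1.0 - rss_ext / tss_ext
    q2_f3 = 1.0 - (rss_ext / len(y_ext)) / (tss_tr / len(y_tr))

    return ValidationReport(
        r2=r2, q2_loo=q2_loo, q2_f1=q2_f1, q2_f2=q2_f2, q2_f3=q2_f3,
        ccc=concordance_ccc(y_ext, yhat_ext),
        rmse_tr=float(np.sqrt(rss_tr / len(y_tr))),
        rmse_pred=float(np.sqrt(rss_ext / len(y_ext))),
        n_train=len(y_tr), n_ext=len(y_ext),
    )


def write_validation_csv(reports: dict[str, ValidationReport], path) -> None:
    """One row per model: R2, Q2LOO, Q2F1, Q2F2, Q2F3, CCC, RMSEtr, RMSEpred."""
    pd.DataFrame({k: v.as_row() for k, v in reports.items()}).T.to_csv(path, index_label="model")
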