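"""Ensemble species distribution modelling.

The modelling chain mirrors standard presence/pseudo-absence practice:

* covariate screening by the variance inflation factor (VIF), iteratively
  dropping the most collinear layer until all VIFs are at or below 10;
* pseudo-absences drawn uniformly from cells without presences (balanced
  with the presences by default);
* five algorithm families — logistic GLM, random forest, gradient
  boosting, support-vector machine, and a penalized (maxent-like) logistic
  model — each fitted on a stratified 80% split and evaluated on the held
  out 20% by AUC and the true skill statistic (TSS) at that fit's own
  Max-TSS threshold;
* fits with TSS >= 0.7 are retained; the ensemble suitability is their
  unweighted mean, binarized at the Max-TSS threshold recomputed from the
  ensemble's predictions on the held-out evaluation rows (training-row
  predictions of the tree ensembles are overconfident and would inflate
  the cut);
* future projection onto the mean of the future-climate replicates at the
  same threshold, optionally intersected with the current range under the
  no-dispersal assumption.

:class:`EnsembleSDM` is the model object; :meth:`EnsembleSDM.fit` returns an
:class:`EnsembleSDMResults` carrying the per-algorithm fits and metrics, the
ensemble threshold, and the prediction / binarization methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .grids import BinaryRange, EnvStack, GridSpec

__all__ = [
    "ALGORITHMS",
    "ModelFit",
    "EnsembleSDM",
    "EnsembleSDMResults",
    "UnmodelledSpeciesError",
    "compute_vifs",
    "vif_select",
    "sample_pseudo_absences",
    "presence_cells_from_records",
    "confusion_metrics",
    "auc_score",
    "tss_at_threshold",
    "max_tss_threshold",
    "apply_no_dispersal",
]


class UnmodelledSpeciesError(RuntimeError):
    """Raised when no algorithm reaches the TSS retention bar for a species."""


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------

def confusion_metrics(labels, predicted) -> tuple[float, float, float]:
    """Sensitivity, specificity and TSS from binary labels and predictions."""
    labels = np.asarray(labels, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    tp = int(np.sum(labels & predicted))
    fn = int(np.sum(labels & ~predicted))
    tn = int(np.sum(~labels & ~predicted))
    fp = int(np.sum(~labels & predicted))
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec, sens + spec - 1.0


def auc_score(labels, scores) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Ties receive average ranks, matching the trapezoidal ROC area.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def tss_at_threshold(scores, labels, threshold: float) -> float:
    """TSS of the rule ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    _, _, tss = confusion_metrics(labels, scores >= threshold)
    return tss


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2 if len(u) > 1 else np.empty(0)
    return np.unique(np.concatenate(([0.0], mids, [1.0])))


def max_tss_threshold(scores, labels) -> float:
    """Threshold maximizing TSS; ties broken by the smallest candidate.

    Candidates are the midpoints between consecutive unique scores plus the
    endpoints 0 and 1; presence is predicted where ``score >= threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    cum_pos = np.concatenate(([0], np.cumsum(l_sorted)))
    cum_neg = np.concatenate(([0], np.cumsum(~l_sorted)))
    cands = _candidate_thresholds(scores)
    idx = np.searchsorted(s_sorted, cands, side="left")  # scores < threshold
    tp = n_pos - cum_pos[idx]
    tn = cum_neg[idx]
    tss = tp / n_pos + tn / n_neg - 1.0
    return float(cands[np.argmax(tss)])  # argmax takes the first (smallest)


# ---------------------------------------------------------------------------
# covariate screening and pseudo-absences
# ---------------------------------------------------------------------------

def compute_vifs(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R²_j) of column j regressed on the other columns.

    A perfectly collinear column gets +inf.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 columns")
    Xc = X - X.mean(axis=0)
    vifs = np.empty(p)
    for j in range(p):
        yj = Xc[:, j]
        others = np.delete(Xc, j, axis=1)
        ss_tot = float(yj @ yj)
        if ss_tot == 0:
            vifs[j] = np.inf
            continue
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        r2 = 1 - float(resid @ resid) / ss_tot
        vifs[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return vifs


def vif_select(
    stack: EnvStack,
    sample_cells=None,
    threshold: float = 10.0,
    n_sample: int | None = None,
    seed: int = 0,
) -> list[str]:
    """Iteratively drop the layer with the highest VIF until all are <= threshold.

    Parameters
    ----------
    sample_cells : array of flat cell indices, optional
        Cells on which VIFs are computed; all cells by default.
    n_sample : int, optional
        Alternatively, a uniform random subsample of this size (seeded).
    """
    names = stack.layer_names
    if len(names) < 2:
        raise ValueError("need at least 2 layers")
    X = stack.as_matrix()
    if sample_cells is not None:
        X = X[np.asarray(sample_cells, dtype=int)]
    elif n_sample is not None and n_sample < X.shape[0]:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=n_sample, replace=False)]
    if X.shape[0] <= len(names) + 1:
        raise ValueError("sample size must exceed layer count + 1")
    keep = list(range(len(names)))
    while len(keep) >= 2:
        vifs = compute_vifs(X[:, keep])
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        keep.pop(worst)
    return [names[i] for i in keep]


def presence_cells_from_records(records: pd.DataFrame, grid: GridSpec) -> np.ndarray:
    """Unique flat cell indices of a species' records (input order preserved)."""
    row, col = grid.cell_of(
        records["x"].to_numpy(dtype=float), records["y"].to_numpy(dtype=float)
    )
    flat = row * grid.ncols + col
    _, first = np.unique(flat, return_index=True)
    return flat[np.sort(first)]


def sample_pseudo_absences(
    grid: GridSpec,
    presence_cells,
    n_pa: int,
    seed: int = 0,
) -> np.ndarray:
    """Uniform sample (without replacement) of cells holding no presence."""
    presence_cells = np.asarray(presence_cells, dtype=int)
    available = np.setdiff1d(np.arange(grid.n_cells), presence_cells)
    if n_pa > len(available):
        raise ValueError(
            f"requested {n_pa} pseudo-absences but only {len(available)} "
            "unoccupied cells are available"
        )
    if n_pa == len(available):
        return available
    rng = np.random.default_rng(seed)
    return rng.choice(available, size=n_pa, replace=False)


# ---------------------------------------------------------------------------
# the ensemble model
# ---------------------------------------------------------------------------

def _make_estimator(name: str, random_state: int):
    if name == "logistic_glm":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(C=np.inf, max_iter=2000),  # unpenalized GLM
        )
    if name == "maxent_like":
        # L1-penalized logistic on the presence/background table
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear",
                               random_state=random_state),
        )
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=random_state)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(random_state=random_state)
    if name == "svm":
        # probability calibration wraps the margin classifier
        return make_pipeline(
            StandardScaler(),
            # cv=3 keeps calibration viable at the 5-presence minimum
            CalibratedClassifierCV(SVC(kernel="rbf", random_state=random_state),
                                   cv=3, ensemble=False),
        )
    raise ValueError(f"unknown algorithm {name!r}")


ALGORITHMS = (
    "logistic_glm",
    "random_forest",
    "gradient_boosting",
    "svm",
    "maxent_like",
)


@dataclass
class ModelFit:
    """One algorithm's fit with its hold-out evaluation."""

    species_id: str
    algorithm: str
    estimator: object = field(repr=False)
    eval_scores: np.ndarray = field(repr=False)
    eval_labels: np.ndarray = field(repr=False)
    auc: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    tss: float = np.nan
    threshold: float = np.nan
    retained: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        return proba[:, list(self.estimator.classes_).index(1)]


class EnsembleSDM:
    """Ensemble distribution model for one species.

    Parameters
    ----------
    presence_cells : array of flat cell indices
        Cells with at least one (thinned) occurrence; at least 5.
    stack : EnvStack
        Current-scenario environmental layers (post covariate screening).
    algorithms : sequence of str
        Algorithm families to fit (default: all five).
    n_pseudo_absence : int, optional
        Pseudo-absence count; default equals the presence count (balanced).
    train_fraction : float
        Fraction of the table used for training (stratified); the rest
        evaluates the fits. Default 0.8.
    tss_min : float
        TSS retention bar for the ensemble (default 0.7).
    """

    def __init__(
        self,
        presence_cells,
        stack: EnvStack,
        algorithms=ALGORITHMS,
        n_pseudo_absence: int | None = None,
        train_fraction: float = 0.8,
        tss_min: float = 0.7,
        species_id: str = "species",
    ):
        self.presence_cells = np.asarray(presence_cells, dtype=int)
        if len(self.presence_cells) < 5:
            raise ValueError(
                f"{species_id!r}: need at least 5 presence cells, got "
                f"{len(self.presence_cells)}"
            )
        if not 0 < train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        self.stack = stack
        self.algorithms = tuple(algorithms)
        self.n_pseudo_absence = n_pseudo_absence
        self.train_fraction = train_fraction
        self.tss_min = tss_min
        self.species_id = species_id

    @classmethod
    def from_occurrences(
        cls, records: pd.DataFrame, stack: EnvStack, species_id: str | None = None,
        **kwargs,
    ) -> "EnsembleSDM":
        """Build the model from a (cleaned) occurrence table for one species."""
        species = records["species"].unique()
        if species_id is None:
            if len(species) != 1:
                raise ValueError(
                    "records contain multiple species; pass species_id"
                )
            species_id = str(species[0])
        else:
            records = records[records["species"] == species_id]
        cells = presence_cells_from_records(records, stack.grid)
        return cls(cells, stack, species_id=species_id, **kwargs)

    # -- fitting ----------------------------------------------------------

    def _stratified_split(self, y: np.ndarray, rng: np.random.Generator):
        train = np.zeros(len(y), dtype=bool)
        for cls_val in (0, 1):
            idx = np.flatnonzero(y == cls_val)
            idx = rng.permutation(idx)
            n_train = int(round(self.train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            train[idx[:n_train]] = True
        return train

    def fit(self, seed: int = 0, max_split_retries: int = 10) -> "EnsembleSDMResults":
        """Sample pseudo-absences, split, fit and evaluate every algorithm."""
        rng = np.random.default_rng(seed)
        n_pa = self.n_pseudo_absence or len(self.presence_cells)
        pa_cells = sample_pseudo_absences(
            self.stack.grid, self.presence_cells,
            n_pa, seed=int(rng.integers(2**31)),
        )
        cells = np.concatenate([self.presence_cells, pa_cells])
        y = np.concatenate(
            [np.ones(len(self.presence_cells), dtype=int),
             np.zeros(len(pa_cells), dtype=int)]
        )
        X = self.stack.as_matrix()[cells]

        for attempt in range(max_split_retries):
            train = self._stratified_split(y, rng)
            if len(np.unique(y[train])) == 2 and len(np.unique(y[~train])) == 2:
                break
            warnings.warn(
                f"{self.species_id}: single-class split, resampling "
                f"(attempt {attempt + 1})"
            )
        else:
            raise RuntimeError("could not obtain a two-class train/test split")

        fits: list[ModelFit] = []
        for name in self.algorithms:
            est = _make_estimator(name, random_state=int(rng.integers(2**31)))
            est.fit(X[train], y[train])
            fit = ModelFit(
                species_id=self.species_id, algorithm=name, estimator=est,
                eval_scores=np.empty(0), eval_labels=np.empty(0),
            )
            scores = fit.predict(X[~train])
            labels = y[~train].astype(bool)
            fit.eval_scores, fit.eval_labels = scores, labels
            fit.auc = auc_score(labels, scores)
            fit.threshold = max_tss_threshold(scores, labels)
            fit.sensitivity, fit.specificity, fit.tss = confusion_metrics(
                labels, scores >= fit.threshold
            )
            fit.retained = fit.tss >= self.tss_min
            fits.append(fit)

        return EnsembleSDMResults(self, fits, X, y, cells, train, seed)


class EnsembleSDMResults:
    """Fitted ensemble: per-algorithm metrics, threshold, prediction methods.

    The ensemble suitability is the unweighted mean of the retained fits'
    suitability (so it is bounded by their cell-wise min and max); the binary
    range is its exceedance of ``threshold``, the Max-TSS cut recomputed from
    the ensemble's predictions on the held-out evaluation rows.
    """

    def __init__(self, model: EnsembleSDM, fits: list[ModelFit],
                 X: np.ndarray, y: np.ndarray, cells: np.ndarray,
                 train_mask: np.ndarray, seed: int):
        self.model = model
        self.fits = fits
        self.table_X = X
        self.table_y = y
        self.table_cells = cells
        self.train_mask = np.asarray(train_mask, dtype=bool)
        self.seed = seed
        self.threshold = np.nan
        if self.retained_fits:
            ens_eval = np.mean(
                [f.eval_scores for f in self.retained_fits], axis=0
            )
            self.threshold = max_tss_threshold(
                ens_eval, self.retained_fits[0].eval_labels
            )

    @property
    def species_id(self) -> str:
        return self.model.species_id

    @property
    def retained_fits(self) -> list[ModelFit]:
        return [f for f in self.fits if f.retained]

    @property
    def is_unmodelled(self) -> bool:
        """True when no algorithm reached the TSS retention bar."""
        return not self.retained_fits

    def _ensemble_scores(self, X: np.ndarray) -> np.ndarray:
        fits = self.retained_fits
        if not fits:
            raise UnmodelledSpeciesError(
                f"no fit of {self.species_id!r} reached TSS >= "
                f"{self.model.tss_min}; species excluded from downstream maps"
            )
        return np.mean([f.predict(X) for f in fits], axis=0)

    def predict(self, stack: EnvStack | None = None) -> np.ndarray:
        """Ensemble suitability map on ``stack`` (default: the training stack)."""
        stack = stack or self.model.stack
        if stack.grid != self.model.stack.grid:
            raise ValueError("grid mismatch between stacks")
        X = stack.as_matrix(self.model.stack.layer_names)
        return self._ensemble_scores(X).reshape(stack.grid.shape)

    def binarize(self, stack: EnvStack | None = None,
                 scenario: str | None = None) -> BinaryRange:
        """Binary range: cells whose ensemble suitability >= the Max-TSS cut."""
        stack = stack or self.model.stack
        suit = self.predict(stack)
        return BinaryRange(
            self.species_id,
            scenario or stack.scenario,
            stack.grid,
            suit >= self.threshold,
        )

    def project_future(
        self,
        future: EnvStack | list[EnvStack],
        no_dispersal: bool = False,
        current: BinaryRange | None = None,
    ) -> BinaryRange:
        """Project onto the (mean of the) future replicates at the same threshold.

        With ``no_dispersal=True`` the projection is intersected with
        ``current`` (computed here if not supplied).
        """
        if isinstance(future, list):
            mean_layers = {
                name: np.mean([rep[name] for rep in future], axis=0)
                for name in future[0].layer_names
            }
            future = EnvStack(future[0].grid, mean_layers, "future_mean")
        out = self.binarize(future, scenario=future.scenario)
        if no_dispersal:
            if current is None:
                current = self.binarize()
            out = apply_no_dispersal(current, out)
        return out

    def metrics_frame(self) -> pd.DataFrame:
        """Per-algorithm evaluation metrics as a DataFrame."""
        return pd.DataFrame(
            [
                {
                    "species": f.species_id,
                    "algorithm": f.algorithm,
                    "auc": f.auc,
                    "sensitivity": f.sensitivity,
                    "specificity": f.specificity,
                    "tss": f.tss,
                    "threshold": f.threshold,
                    "retained": f.retained,
                }
                for f in self.fits
            ]
        )

    def summary(self) -> str:
        """Plain-text summary table of the fitted ensemble."""
        lines = [
            f"Ensemble SDM results: {self.species_id}",
            f"  presences: {len(self.model.presence_cells)}   "
            f"pseudo-absences: {int((self.table_y == 0).sum())}   "
            f"TSS retention bar: {self.model.tss_min}",
            "",
            f"  {'algorithm':<18}{'AUC':>8}{'sens':>8}{'spec':>8}"
            f"{'TSS':>8}  retained",
        ]
        for f in self.fits:
            lines.append(
                f"  {f.algorithm:<18}{f.auc:>8.3f}{f.sensitivity:>8.3f}"
                f"{f.specificity:>8.3f}{f.tss:>8.3f}  "
                f"{'yes' if f.retained else 'no'}"
            )
        if self.is_unmodelled:
            lines.append("\n  UNMODELLED: no fit retained; species excluded.")
        else:
            lines.append(
                f"\n  ensemble Max-TSS threshold: {self.threshold:.4f} "
                f"({len(self.retained_fits)} retained fits)"
            )
        return "\n".join(lines)


def apply_no_dispersal(current: BinaryRange, future: BinaryRange) -> BinaryRange:
    """Restrict the future range to cells already occupied now (future ∩ current)."""
    if future.grid != current.grid:
        raise ValueError("grid mismatch")
    return BinaryRange(
        current.species_id, future.scenario, current.grid,
        future.mask & current.mask,
    )
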