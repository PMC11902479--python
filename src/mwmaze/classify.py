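"""Classification experiments over the zone feature table.

Five classifier families (logistic regression, Gaussian naive Bayes,
decision tree, random forest, feed-forward neural network) are compared
by stratified 10-fold cross-validation on trial feature tables built for
six experiment presets:

* E1 — entries and time-in-zone for the four quadrants (8 features);
* E2 — all 32 measures × 4 quadrants (128 features);
* E3 — all 32 measures × K annuli;
* E4 — union of E2 and E3 (480 features when K = 11);
* E5 — E4 with correlation-based feature selection (CFS merit searched
  by best-first with bounded backtracking), re-fit inside each training
  fold;
* E6 — E5 swept over annulus widths of 1, 1.5, 2 and 2.5 platform
  diameters.

Standardization and feature selection are always fit on the training
folds only, so no information leaks from the validation folds.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .features import (
    EXPERIMENT_MEASURES,
    MEASURES,
    build_feature_table,
    feature_columns,
)
from .geometry import make_annuli, make_quadrants

__all__ = [
    "CLASSIFIER_FAMILIES",
    "ExperimentSpec",
    "EXPERIMENTS",
    "SelectionResult",
    "CVResult",
    "CVReport",
    "LabelError",
    "cfs_merit",
    "select_features_bestfirst",
    "cross_validate",
    "run_experiment",
]

CLASSIFIER_FAMILIES = ("LR", "NB", "DT", "RF", "NN")


class LabelError(RuntimeError):
    """Degenerate or non-binary label column."""


def make_classifier(family: str, seed: int = 0):
    """Fixed-hyperparameter classifier instances for the five families."""
    if family == "LR":
        return LogisticRegression(max_iter=2000)
    if family == "NB":
        return GaussianNB()
    if family == "DT":
        return DecisionTreeClassifier(min_samples_leaf=2, random_state=seed)
    if family == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if family == "NN":
        return MLPClassifier(
            hidden_layer_sizes=(64,), max_iter=600, random_state=seed
        )
    raise ValueError(f"unknown classifier family {family!r}")


# ---------------------------------------------------------------------------
# Correlation-based feature selection, best-first search
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of the best-first subset search."""

    selected: list[str]          # admission order into the best subset
    merit: float
    merit_trajectory: list[float]
    n_expanded: int


def cfs_merit(r_cf: np.ndarray, r_ff: np.ndarray, subset) -> float:
    """Correlation-based subset merit
    ``k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)``: high average feature-label
    correlation, penalized by inter-feature redundancy."""
    s = list(subset)
    k = len(s)
    if k == 0:
        return 0.0
    rcf = float(np.mean(r_cf[s]))
    if k == 1:
        return rcf
    sub = r_ff[np.ix_(s, s)]
    rff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    denom = k + k * (k - 1) * rff
    return k * rcf / np.sqrt(max(denom, 1e-12))


def _correlations(X: np.ndarray, y: np.ndarray):
    """Absolute Pearson feature-label and feature-feature correlations;
    constant columns get zero correlation everywhere."""
    n, p = X.shape
    Xs = X - X.mean(axis=0)
    sx = Xs.std(axis=0)
    ok = sx > 1e-12
    ys = y - y.mean()
    sy = ys.std()
    r_cf = np.zeros(p)
    if sy > 1e-12:
        r_cf[ok] = np.abs((Xs[:, ok] * ys[:, None]).mean(axis=0) / (sx[ok] * sy))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.abs(np.nan_to_num(np.atleast_2d(C), nan=0.0))
    np.fill_diagonal(C, 1.0)
    return r_cf, C, ok


def select_features_bestfirst(
    table: pd.DataFrame,
    stale_limit: int = 5,
    label_column: str = "label",
    columns: list[str] | None = None,
) -> SelectionResult:
    """Forward best-first search over feature subsets maximizing CFS merit.

    The open list is a priority queue over evaluated subsets; the best
    unexpanded subset is expanded by adding each unused feature.  The
    search stops after ``stale_limit`` consecutive expansions that fail to
    improve the best merit found so far (bounded backtracking).  Feature
    relevance order is the order of admission into the best subset.
    """
    cols = columns or feature_columns(table)
    if len(cols) < 2:
        if len(cols) == 1:
            y = _binary_labels(table[label_column])
            r_cf, _, _ = _correlations(table[cols].to_numpy(float), y)
            return SelectionResult(list(cols), float(r_cf[0]), [float(r_cf[0])], 0)
        raise ValueError("need at least one feature")
    y = _binary_labels(table[label_column])
    X = table[cols].to_numpy(float)
    r_cf, r_ff, ok = _correlations(X, y)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} constant feature column(s) before search"
        )
    usable = [i for i in range(len(cols)) if ok[i]]

    best_subset: tuple[int, ...] = ()
    best_merit = 0.0
    trajectory: list[float] = []
    # heap of (-merit, counter, subset-tuple-in-admission-order)
    counter = 0
    heap: list = [(0.0, counter, ())]
    seen = {(): True}
    stale = 0
    n_expanded = 0
    while heap and stale < stale_limit:
        neg_m, _, subset = heapq.heappop(heap)
        n_expanded += 1
        improved = False
        in_subset = set(subset)
        for j in usable:
            if j in in_subset:
                continue
            child = subset + (j,)
            key = tuple(sorted(child))
            if key in seen:
                continue
            seen[key] = True
            m = cfs_merit(r_cf, r_ff, child)
            counter += 1
            heapq.heappush(heap, (-m, counter, child))
            if m > best_merit + 1e-12:
                best_merit = m
                best_subset = child
                trajectory.append(m)
                improved = True
        stale = 0 if improved else stale + 1
    if not best_subset:  # no feature helps; fall back to the single best
        j = int(np.argmax(r_cf[usable]))
        best_subset = (usable[j],)
        best_merit = cfs_merit(r_cf, r_ff, best_subset)
        trajectory.append(best_merit)
    return SelectionResult(
        [cols[i] for i in best_subset], best_merit, trajectory, n_expanded
    )


def _binary_labels(labels: pd.Series) -> np.ndarray:
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise LabelError(f"expected 2 classes, found {len(classes)}")
    return (labels.to_numpy() == classes[1]).astype(float)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """One classifier family's cross-validation outcome."""

    family: str
    mean_accuracy: float
    fold_accuracies: list[float]
    confusion: np.ndarray  # pooled 2×2, rows = true class
    classes: list
    seed: int
    selected_features: list[list[str]] | None = None


@dataclass
class CVReport:
    """All families for one experiment configuration."""

    experiment: str
    n_features: int
    results: dict[str, CVResult] = field(default_factory=dict)

    def accuracy_row(self) -> dict[str, float]:
        """One table row of mean accuracies, rounded to 4 decimals."""
        return {
            fam: round(self.results[fam].mean_accuracy, 4)
            for fam in CLASSIFIER_FAMILIES
            if fam in self.results
        }


def cross_validate(
    table: pd.DataFrame,
    classifier_family: str,
    folds: int = 10,
    seed: int = 0,
    selection: bool = False,
    stale_limit: int = 5,
    label_column: str = "label",
    group_by: str | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of one classifier family.

    Features are standardized inside each training fold; when
    ``selection`` is on, CFS best-first selection is re-fit on each
    training fold and only the selected columns are used.  ``group_by``
    may name an id column (e.g. ``animal_id``) to keep a group's trials
    in a single fold.
    """
    cols = feature_columns(table)
    labels = table[label_column]
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise LabelError(f"expected 2 classes, found {len(classes)}")
    y = labels.to_numpy()
    X = table[cols].to_numpy(float)
    n = len(y)

    if group_by is not None:
        splits = _grouped_stratified_splits(
            table[group_by].to_numpy(), y, folds, seed
        )
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))

    accs = []
    pooled = np.zeros((2, 2), dtype=int)
    selected_all = [] if selection else None
    for tr, va in splits:
        use = cols
        if selection:
            sel = select_features_bestfirst(
                table.iloc[tr], stale_limit=stale_limit, label_column=label_column,
                columns=cols,
            )
            use = sel.selected
            selected_all.append(use)
        idx = [cols.index(c) for c in use]
        scaler = StandardScaler().fit(X[np.ix_(tr, idx)])
        clf = make_classifier(classifier_family, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(scaler.transform(X[np.ix_(tr, idx)]), y[tr])
            pred = clf.predict(scaler.transform(X[np.ix_(va, idx)]))
        accs.append(float(np.mean(pred == y[va])))
        pooled += confusion_matrix(y[va], pred, labels=classes)
    assert pooled.sum() == n
    return CVResult(
        family=classifier_family,
        mean_accuracy=float(np.mean(accs)),
        fold_accuracies=accs,
        confusion=pooled,
        classes=classes,
        seed=seed,
        selected_features=selected_all,
    )


def _grouped_stratified_splits(groups, y, folds, seed):
    """Assign whole groups to folds, balancing class counts greedily."""
    rng = np.random.default_rng(seed)
    uniq = pd.unique(groups)
    order = rng.permutation(len(uniq))
    fold_of = {}
    counts = np.zeros(folds)
    for gi in order:
        g = uniq[gi]
        k = int(np.argmin(counts))
        fold_of[g] = k
        counts[k] += np.sum(groups == g)
    assign = np.array([fold_of[g] for g in groups])
    return [
        (np.nonzero(assign != k)[0], np.nonzero(assign == k)[0])
        for k in range(folds)
    ]


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentSpec:
    """One classification experiment preset."""

    id: str
    partitions: tuple[str, ...]
    measures: tuple[str, ...]
    selection: bool = False
    width_multiples: tuple[float, ...] = (1.0,)


EXPERIMENTS: dict[str, ExperimentSpec] = {
    "E1": ExperimentSpec(
        "E1", ("quadrant",), EXPERIMENT_MEASURES["occupancy"]
    ),
    "E2": ExperimentSpec("E2", ("quadrant",), MEASURES),
    "E3": ExperimentSpec("E3", ("annulus",), MEASURES),
    "E4": ExperimentSpec("E4", ("quadrant", "annulus"), MEASURES),
    "E5": ExperimentSpec(
        "E5", ("quadrant", "annulus"), MEASURES, selection=True
    ),
    "E6": ExperimentSpec(
        "E6",
        ("quadrant", "annulus"),
        MEASURES,
        selection=True,
        width_multiples=(1.0, 1.5, 2.0, 2.5),
    ),
}


def experiment_table(
    spec: ExperimentSpec, cohort, width_multiple: float = 1.0
) -> pd.DataFrame:
    """Build the feature table an experiment preset calls for."""
    geom = cohort.geom
    partitions = {}
    if "quadrant" in spec.partitions:
        partitions["quadrant"] = make_quadrants(geom)
    if "annulus" in spec.partitions:
        partitions["annulus"] = make_annuli(geom, width_multiple)
    return build_feature_table(
        cohort.trials, geom, partitions=partitions, measure_subset=spec.measures
    )


def run_experiment(
    spec: ExperimentSpec | str,
    cohort,
    folds: int = 10,
    seed: int = 0,
    families=CLASSIFIER_FAMILIES,
    group_by: str | None = None,
) -> list[CVReport]:
    """Run an experiment preset on a cohort; one report per annulus width."""
    if isinstance(spec, str):
        spec = EXPERIMENTS[spec]
    reports = []
    for w in spec.width_multiples:
        table = experiment_table(spec, cohort, width_multiple=w)
        name = spec.id if len(spec.width_multiples) == 1 else f"{spec.id}[D{w:g}]"
        report = CVReport(experiment=name, n_features=len(feature_columns(table)))
        for fam in families:
            report.results[fam] = cross_validate(
                table,
                fam,
                folds=folds,
                seed=seed,
                selection=spec.selection,
                group_by=group_by,
            )
        reports.append(report)
    return reports


def improvement_table(reports: dict[str, CVReport]) -> pd.DataFrame:
    """Pairwise accuracy deltas between experiments, per classifier."""
    rows = []
    ids = list(reports)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ra, rb = reports[a].accuracy_row(), reports[b].accuracy_row()
            rows.append(
                {"comparison": f"{b} - {a}", **{f: round(rb[f] - ra[f], 4) for f in ra}}
            )
    return pd.DataFrame(rows)
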