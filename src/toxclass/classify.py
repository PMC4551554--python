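"""Linear-SVM toxicant-class classification with compound-level validation.

The classifier works in contrast space (treated minus matched controls).
For every training split it (1) keeps the 100 probe sets with highest
variance within the training columns only, (2) tunes the SVM cost C over
the grid 2^-5 ... 2^2 by stratified cross-validation, (3) fits a linear
soft-margin SVM and (4) maps decision values to class probabilities by a
one-dimensional Platt-style logistic fit along the direction orthogonal to
the decision boundary. Validation leaves out whole compounds (all their
replicates): for every n-subset of compounds a fresh classifier is built
on the rest and the left-out replicates are predicted; a compound is
called CLASS_A when its mean replicate probability exceeds 0.5.

Panel minimization fixes the 100 highest-variance probes of the full
contrast matrix as an ordered list and removes them one at a time from the
low-variance end, re-running leave-one-out and leave-two-out validation at
each size.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatypes import CLASS_A, ContrastMatrix, SampleMetadata, ValidationError
from .preprocess import top_variance_features

DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**i for i in range(-5, 3))
DEFAULT_N_FEATURES = 100


def train_svm(X: np.ndarray, y: np.ndarray, C: float, tol: float = 1e-7):
    """Fit a linear soft-margin SVM; returns (w, b).

    Minimizes 0.5*||w||^2 + C * sum hinge(y_i (w.x_i + b)) with labels
    y in {-1, +1}; decision values f = w.x + b are positive on the +1 side.
    """
    y = np.asarray(y)
    if C <= 0:
        raise ValidationError("C must be positive")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    clf = SVC(kernel="linear", C=C, tol=tol, shrinking=False)
    clf.fit(X, y)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    # libsvm orients the decision function by class order; enforce f > 0 <=> y = +1
    if clf.classes_[1] != 1:
        w, b = -w, -b
    return w, b


def tune_C(
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple[float, ...] = DEFAULT_C_GRID,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Pick the cost with highest stratified-CV accuracy; ties -> smallest C.

    Folds are capped at the smaller class size; when a class has fewer
    than two members per fold the scheme degenerates to leave-one-sample-
    out. Fold assignment is seeded for reproducibility.
    """
    if not grid:
        raise ValidationError("empty C grid")
    y = np.asarray(y)
    class_sizes = np.unique(y, return_counts=True)[1]
    if class_sizes.min() < 2:
        raise ValidationError("need >= 2 samples per class to tune C")
    n_folds = int(min(folds, class_sizes.min()))
    splitter = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=seed % (2**31)
    )
    splits = list(splitter.split(X, y))
    best_C, best_acc = None, -1.0
    for C in sorted(grid):
        correct = 0
        total = 0
        for train_idx, test_idx in splits:
            if len(np.unique(y[train_idx])) < 2:
                continue
            w, b = train_svm(X[train_idx], y[train_idx], C)
            pred = np.sign(X[test_idx] @ w + b)
            pred[pred == 0] = 1
            correct += int((pred == y[test_idx]).sum())
            total += len(test_idx)
        acc = correct / total if total else 0.0
        if acc > best_acc + 1e-12:
            best_acc, best_C = acc, C
    return float(best_C)


def calibrate_probability(f: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt-style logistic calibration of decision values.

    Fits p(y=+1 | f) = 1 / (1 + exp(A*f + B)) by penalized maximum
    likelihood with the standard smoothed targets t+ = (N+ + 1)/(N+ + 2),
    t- = 1/(N- + 2), which keeps (A, B) finite on separable data. Uses the
    Newton method with backtracking (Lin, Lin & Weng). A < 0 after the fit,
    so p increases with f.
    """
    f = np.asarray(f, dtype=float)
    y = np.asarray(y)
    if np.ptp(f) == 0:
        raise ValidationError("decision values are constant; cannot calibrate")
    pos = y > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present among decision values")
    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(pos, hi, lo)

    A = 0.0
    B = np.log((n_neg + 1.0) / (n_pos + 1.0))
    sigma = 1e-12
    min_step = 1e-10

    def objective(A, B):
        # -sum[t*log p + (1-t)*log(1-p)] with p = 1/(1+e^z), z = A*f + B
        z = A * f + B
        return float(
            np.sum(
                np.where(
                    z >= 0,
                    t * z + np.log1p(np.exp(-np.abs(z))),
                    (t - 1.0) * z + np.log1p(np.exp(-np.abs(z))),
                )
            )
        )

    obj = objective(A, B)
    for _ in range(100):
        z = np.clip(A * f + B, -500, 500)
        p = 1.0 / (1.0 + np.exp(z))
        # dObj/dz = t - p; Hessian pieces from d2Obj/dz2 = p(1-p)
        d1 = t - p
        gA = float(np.sum(f * d1))
        gB = float(np.sum(d1))
        if max(abs(gA), abs(gB)) < 1e-10:
            break
        d2 = p * (1.0 - p)
        hAA = float(np.sum(f * f * d2)) + sigma
        hAB = float(np.sum(f * d2))
        hBB = float(np.sum(d2)) + sigma
        det = hAA * hBB - hAB * hAB
        dA = -(hBB * gA - hAB * gB) / det
        dB = -(-hAB * gA + hAA * gB) / det
        step = 1.0
        while step >= min_step:
            new_obj = objective(A + step * dA, B + step * dB)
            if new_obj < obj + 1e-4 * step * (gA * dA + gB * dB):
                A += step * dA
                B += step * dB
                obj = new_obj
                break
            step /= 2.0
        else:
            break
    return float(A), float(B)


def _sigmoid_probability(f: np.ndarray, A: float, B: float) -> np.ndarray:
    z = np.clip(A * np.asarray(f, dtype=float) + B, -500, 500)
    return 1.0 / (1.0 + np.exp(z))


@dataclass
class ClassifierModel:
    """Trained linear classifier: probes, weights, cost and calibration."""

    probe_ids: list[str]
    w: np.ndarray
    b: float
    C: float
    A: float
    B: float
    training_compounds: list[str]

    def decision_values(self, contrasts: ContrastMatrix, sample_ids=None) -> pd.Series:
        cols = sample_ids if sample_ids is not None else contrasts.sample_ids
        X = contrasts.data.loc[self.probe_ids, list(cols)].to_numpy().T
        return pd.Series(X @ self.w + self.b, index=list(cols))

    def predict_probability(self, contrasts: ContrastMatrix, sample_ids=None) -> pd.Series:
        """P(CLASS_A) per replicate column."""
        f = self.decision_values(contrasts, sample_ids)
        return pd.Series(_sigmoid_probability(f.to_numpy(), self.A, self.B), index=f.index)

    def to_json(self) -> str:
        return json.dumps(
            {
                "probe_ids": self.probe_ids,
                "w": list(self.w),
                "b": self.b,
                "C": self.C,
                "A": self.A,
                "B": self.B,
                "training_compounds": self.training_compounds,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        return cls(
            probe_ids=d["probe_ids"],
            w=np.asarray(d["w"], dtype=float),
            b=float(d["b"]),
            C=float(d["C"]),
            A=float(d["A"]),
            B=float(d["B"]),
            training_compounds=d["training_compounds"],
        )


def _labels_for(meta: SampleMetadata, compounds: list[str]) -> dict[str, int]:
    """+1 for CLASS_A compounds, -1 otherwise."""
    return {c: (1 if meta.class_of(c) == CLASS_A else -1) for c in compounds}


def build_classifier(
    contrasts: ContrastMatrix,
    meta: SampleMetadata,
    training_compounds: list[str],
    n_features: int = DEFAULT_N_FEATURES,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    folds: int = 10,
    seed: int = 0,
    fixed_panel: list[str] | None = None,
    fixed_C: float | None = None,
) -> ClassifierModel:
    """Feature selection, C tuning, SVM fit and probability calibration.

    Feature selection sees only the training-compound columns (zero-
    variance probes are never selected). ``fixed_panel`` replaces the
    selection step with a preset probe list; ``fixed_C`` skips tuning.
    """
    label_of = _labels_for(meta, training_compounds)
    if len(set(label_of.values())) < 2:
        raise ValidationError("training compounds must span both classes")
    sample_ids = [
        s for c in training_compounds for s in meta.samples_of(c)
        if s in contrasts.data.columns
    ]
    train = contrasts.subset_samples(sample_ids)
    if fixed_panel is not None:
        probes = list(fixed_panel)
    else:
        var = top_variance_features(train, min(n_features, train.shape[0]))
        # a probe constant across the training columns carries no signal
        ptp = train.data.max(axis=1) - train.data.min(axis=1)
        probes = [p for p in var.index if var[p] > 0 and ptp[p] > 0]
    X = train.data.loc[probes].to_numpy().T
    y = np.asarray(
        [label_of[meta.table.set_index("sample_id").loc[s, "compound"]] for s in sample_ids]
    )
    C = fixed_C if fixed_C is not None else tune_C(X, y, grid=C_grid, folds=folds, seed=seed)
    w, b = train_svm(X, y, C)
    A, B = calibrate_probability(X @ w + b, y)
    return ClassifierModel(
        probe_ids=probes,
        w=w,
        b=b,
        C=float(C),
        A=A,
        B=B,
        training_compounds=list(training_compounds),
    )


@dataclass
class PredictionRecord:
    """Class probabilities for one left-out compound under one split."""

    compound: str
    true_class: str
    left_out: tuple[str, ...]
    replicate_probabilities: dict[str, float]

    @property
    def mean_probability(self) -> float:
        return float(np.mean(list(self.replicate_probabilities.values())))

    @property
    def call(self) -> str:
        """CLASS_A iff mean probability > 0.5; exactly 0.5 -> unclassified."""
        m = self.mean_probability
        if m > 0.5:
            return "CLASS_A"
        if m < 0.5:
            return "CLASS_B"
        return "UNCLASSIFIED"

    @property
    def correct(self) -> bool:
        return self.call == self.true_class


@dataclass
class LeaveNOutResult:
    """All prediction records of a leave-n-out run plus summary rates."""

    n: int
    records: list[PredictionRecord]

    @property
    def n_compound_predictions(self) -> int:
        return len(self.records)

    @property
    def compound_accuracy(self) -> float:
        return float(np.mean([r.correct for r in self.records]))

    @property
    def n_replicate_predictions(self) -> int:
        return sum(len(r.replicate_probabilities) for r in self.records)

    @property
    def replicate_accuracy(self) -> float:
        correct = 0
        total = 0
        for r in self.records:
            want_a = r.true_class == "CLASS_A"
            for p in r.replicate_probabilities.values():
                correct += int((p > 0.5) == want_a and p != 0.5)
                total += 1
        return correct / total

    def records_for(self, compound: str) -> list[PredictionRecord]:
        return [r for r in self.records if r.compound == compound]


def leave_n_out(
    contrasts: ContrastMatrix,
    meta: SampleMetadata,
    n: int = 1,
    n_features: int = DEFAULT_N_FEATURES,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    folds: int = 10,
    seed: int = 0,
    fixed_panel: list[str] | None = None,
    fixed_C: float | None = None,
) -> LeaveNOutResult:
    """Compound-level leave-n-out cross-validation.

    Every n-subset of compounds (lexicographic enumeration) is left out in
    turn; a classifier is built on the remaining compounds and each
    left-out compound's replicates are predicted. Per-split tuning seeds
    are derived deterministically from ``seed``.
    """
    compounds = sorted(meta.compounds)
    if n < 1 or n >= len(compounds) - 1:
        raise ValidationError(f"n must be in 1 .. {len(compounds) - 2}")
    records: list[PredictionRecord] = []
    for si, left_out in enumerate(itertools.combinations(compounds, n)):
        training = [c for c in compounds if c not in left_out]
        split_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(si,)).generate_state(1)[0]
            % (2**31)
        )
        model = build_classifier(
            contrasts,
            meta,
            training,
            n_features=n_features,
            C_grid=C_grid,
            folds=folds,
            seed=split_seed,
            fixed_panel=fixed_panel,
            fixed_C=fixed_C,
        )
        for compound in left_out:
            reps = [
                s for s in meta.samples_of(compound) if s in contrasts.data.columns
            ]
            probs = model.predict_probability(contrasts, reps)
            records.append(
                PredictionRecord(
                    compound=compound,
                    true_class=meta.class_of(compound),
                    left_out=tuple(left_out),
                    replicate_probabilities={s: float(probs[s]) for s in reps},
                )
            )
    return LeaveNOutResult(n=n, records=records)


@dataclass
class PredictivityCurve:
    """Fraction of correct compound calls as the probe panel shrinks."""

    panel: list[str]  # full start panel, descending variance
    table: pd.DataFrame  # columns: panel_size, loo_accuracy, l2o_accuracy

    def panel_at(self, k: int) -> list[str]:
        """The k highest-variance members of the start panel."""
        return self.panel[:k]


def minimize_panel(
    contrasts: ContrastMatrix,
    meta: SampleMetadata,
    start_size: int = DEFAULT_N_FEATURES,
    panel_sizes: list[int] | None = None,
    n_values: tuple[int, ...] = (1, 2),
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    folds: int = 10,
    seed: int = 0,
    fixed_C: float | None = None,
) -> PredictivityCurve:
    """Sequential panel reduction with leave-n-out revalidation.

    The start panel is the ``start_size`` highest-variance probes of the
    full contrast matrix, ordered by descending variance; the panel at
    size k-1 is the panel at size k minus its lowest-variance member. For
    each requested size the classifier is revalidated with the panel fixed
    (no per-split feature selection). The curve need not be monotone in k:
    the weight given to each probe depends on all other probes in the
    respective classifier.
    """
    treated = contrasts.subset_samples(
        [s for s in meta.treated_ids if s in contrasts.data.columns]
    )
    var = top_variance_features(treated, min(start_size, treated.shape[0]))
    panel = [p for p in var.index if var[p] > 0]
    sizes = panel_sizes if panel_sizes is not None else list(range(len(panel), 0, -1))
    rows = []
    for k in sizes:
        if k < 1 or k > len(panel):
            raise ValidationError(f"panel size {k} out of range 1..{len(panel)}")
        sub = panel[:k]
        row = {"panel_size": k}
        for n in n_values:
            res = leave_n_out(
                contrasts,
                meta,
                n=n,
                C_grid=C_grid,
                folds=folds,
                seed=seed,
                fixed_panel=sub,
                fixed_C=fixed_C,
            )
            key = {1: "loo_accuracy", 2: "l2o_accuracy"}.get(n, f"l{n}o_accuracy")
            row[key] = res.compound_accuracy
        rows.append(row)
    return PredictivityCurve(panel=panel, table=pd.DataFrame(rows))
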