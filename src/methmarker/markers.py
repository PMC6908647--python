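"""Cancer-type-specific marker discovery.

The candidate funnel mirrors the marker workflow:

1. ``build_candidates`` -- hypermethylated DMCs lying in promoter regions of
   hypermethylated-downregulated genes;
2. ``specificity_filter`` -- drop any candidate that is a DMC (either
   direction) in at least one other cancer type;
3. ``InformationGainSelector`` -- keep CpGs whose information gain (mutual
   information between the equal-width-binned beta value and the class
   label, in bits) strictly exceeds a threshold, ranked descending;
4. ``SequentialBackwardSelector`` -- sequential backward feature selection
   wrapped around a cross-validated ridge logistic classifier: starting from
   the full filtered set, repeatedly remove the single feature whose removal
   maximizes CV accuracy, and return the best subset seen anywhere along the
   trajectory (ties: smaller subset, then lexicographic probe order).

All tie-breaks are fully specified so a fixed seed reproduces the selection
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, check_X_y

from . import io as mio
from .evaluate import RidgeLogisticRegression

__all__ = [
    "CandidateSet", "build_candidates", "specificity_filter",
    "information_gain", "InformationGainSelector",
    "SequentialBackwardSelector", "sbfs", "MarkerPanel",
]

STAGES = ("initial", "specificity_filtered", "ig_filtered", "final")


@dataclass
class CandidateSet:
    """Candidate CpGs with provenance, tracked through the selection funnel.

    ``stages`` maps stage name to the probe list at that stage; successive
    stages must be nested subsets.
    """

    provenance: pd.DataFrame   # probe_id-indexed: gene, delta, fdr
    stages: dict[str, list[str]] = field(default_factory=dict)

    def add_stage(self, name: str, probes: list[str]) -> None:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}")
        if self.stages:
            last = list(self.stages.values())[-1]
            if not set(probes) <= set(last):
                raise ValueError(f"stage {name!r} is not nested in the previous stage")
        self.stages[name] = list(probes)

    def probes(self, stage: str | None = None) -> list[str]:
        if stage is None:
            stage = list(self.stages)[-1]
        return self.stages[stage]


def build_candidates(
    dmcs: pd.DataFrame,
    hyper_down_genes: set[str],
    ann: pd.DataFrame,
    promoter_regions: tuple[str, ...] = mio.PROMOTER_REGIONS,
) -> CandidateSet:
    """Hyper DMCs in promoter regions of hypermethylated-downregulated genes."""
    hyper = dmcs[dmcs["direction"] == "hyper"]
    rows = []
    sub = ann.loc[ann.index.intersection(hyper.index)]
    for probe, gene, region in mio.iter_gene_links(sub):
        if region in promoter_regions and gene in hyper_down_genes:
            rows.append((probe, gene, hyper.loc[probe, "delta"],
                         hyper.loc[probe, "fdr"]))
    prov = pd.DataFrame(rows, columns=["probe_id", "gene", "delta", "fdr"])
    prov = prov.drop_duplicates("probe_id").set_index("probe_id")
    candidates = CandidateSet(provenance=prov)
    candidates.add_stage("initial", sorted(prov.index))
    return candidates


def specificity_filter(
    candidates: CandidateSet,
    other_cancer_dmcs: dict[str, pd.DataFrame],
) -> CandidateSet:
    """Keep candidates that are a DMC in zero other cancer types.

    ``other_cancer_dmcs`` maps cancer type to its DMC table (indexed by
    probe, both directions count).  Monotone: adding a table can only shrink
    the result.
    """
    current = candidates.probes("initial")
    excluded: set[str] = set()
    for table in other_cancer_dmcs.values():
        excluded |= set(table.index)
    retained = [p for p in current if p not in excluded]
    candidates.add_stage("specificity_filtered", retained)
    return candidates


# ---------------------------------------------------------------------------
# information gain


def information_gain(x, y, n_bins: int = 10) -> float:
    """Mutual information, in bits, between a binned beta vector and labels.

    *x* is discretized into ``n_bins`` equal-width bins on [0, 1];
    IG = H(X) - H(X|Y) >= 0, bounded by min(H(X), H(Y)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels must contain both classes")
    bins = np.minimum((np.clip(x, 0.0, 1.0) * n_bins).astype(int), n_bins - 1)

    def entropy(counts: np.ndarray) -> float:
        p = counts[counts > 0] / counts.sum()
        return float(-(p * np.log2(p)).sum())

    h_x = entropy(np.bincount(bins, minlength=n_bins))
    h_x_given_y = 0.0
    for c in classes:
        mask = y == c
        h_x_given_y += mask.mean() * entropy(np.bincount(bins[mask], minlength=n_bins))
    return max(h_x - h_x_given_y, 0.0)


class InformationGainSelector(SelectorMixin, BaseEstimator):
    """Filter features by information gain against a binary label.

    Attributes (after fit): ``gains_`` per feature (bits), ``support_``
    (gain strictly above ``threshold``), ``ranking_`` (feature indices in
    descending gain order; ties broken by feature index).
    """

    def __init__(self, threshold: float = 0.3, n_bins: int = 10):
        self.threshold = threshold
        self.n_bins = n_bins

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.gains_ = np.array(
            [information_gain(X[:, j], y, n_bins=self.n_bins)
             for j in range(X.shape[1])]
        )
        self.support_ = self.gains_ > self.threshold
        self.ranking_ = np.lexsort((np.arange(X.shape[1]), -self.gains_))
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def ig_filter(
    candidates: CandidateSet,
    beta: pd.DataFrame,
    labels,
    threshold: float = 0.3,
    n_bins: int = 10,
) -> tuple[CandidateSet, dict[str, float]]:
    """Apply the IG filter to the specificity-filtered candidates.

    Returns the candidate set (stage ``ig_filtered`` sorted by descending
    gain) and the per-probe gains.
    """
    stage_in = ("specificity_filtered"
                if "specificity_filtered" in candidates.stages else "initial")
    probes = candidates.probes(stage_in)
    y = np.asarray(labels)
    gains = {
        p: information_gain(beta.loc[p].to_numpy(dtype=float), y, n_bins=n_bins)
        for p in probes
    }
    kept = sorted((p for p in probes if gains[p] > threshold),
                  key=lambda p: (-gains[p], p))
    candidates.add_stage("ig_filtered", kept)
    return candidates, gains


# ---------------------------------------------------------------------------
# sequential backward feature selection


class SequentialBackwardSelector(BaseEstimator):
    """Sequential backward feature selection around CV'd ridge logistic.

    Starting from all features, each step removes the single feature whose
    removal maximizes stratified-CV accuracy (ties: the feature with the
    lowest information gain, then the lexicographically smallest name); the
    returned subset is the global accuracy maximum over every subset on the
    trajectory (ties: fewest features, then lexicographic name order).
    CV folds are fixed from the seed, so selection is deterministic.
    """

    def __init__(self, cv: int = 5, seed: int = 0, l2: float = 1e-4):
        self.cv = cv
        self.seed = seed
        self.l2 = l2

    def fit(self, X, y, feature_names=None, gains=None):
        X, y = check_X_y(X, y, dtype=float)
        n, d = X.shape
        if d < 1:
            raise ValueError("need at least one candidate feature")
        names = (list(feature_names) if feature_names is not None
                 else [f"f{j}" for j in range(d)])
        gains = dict(gains) if gains else {nm: 0.0 for nm in names}
        classes = np.unique(y)
        folds = min(self.cv, min(int(np.sum(y == c)) for c in classes))
        if folds < 2:
            raise ValueError("need at least 2 samples per class for CV")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=self.seed)
        splits = list(skf.split(X, y))

        def accuracy(cols: tuple[int, ...]) -> float:
            Xs = X[:, list(cols)]
            correct = 0
            for train, test in splits:
                try:
                    model = RidgeLogisticRegression(l2=self.l2).fit(Xs[train], y[train])
                except (RuntimeError, ValueError):
                    return float("nan")
                correct += int(np.sum(model.predict(Xs[test]) == y[test]))
            return correct / n

        current = tuple(range(d))
        visited: list[tuple[tuple[int, ...], float]] = []
        acc = accuracy(current)
        if not np.isnan(acc):
            visited.append((current, acc))
        trajectory = [(tuple(names[j] for j in current), acc)]
        while len(current) > 1:
            options = []
            for j in current:
                subset = tuple(k for k in current if k != j)
                a = accuracy(subset)
                if np.isnan(a):
                    continue
                visited.append((subset, a))
                options.append((-a, gains.get(names[j], 0.0), names[j], j, subset))
            if not options:
                break
            options.sort()
            _, _, _, removed, current = options[0]
            trajectory.append((tuple(names[j] for j in current), -options[0][0]))
        if not visited:
            raise RuntimeError("the evaluator failed on every candidate subset")

        def key(item):
            subset, a = item
            return (-a, len(subset), tuple(sorted(names[j] for j in subset)))

        best, best_acc = min(visited, key=key)
        self.support_ = np.zeros(d, dtype=bool)
        self.support_[list(best)] = True
        self.selected_names_ = [names[j] for j in best]
        self.best_score_ = best_acc
        self.trajectory_ = trajectory
        self.n_features_in_ = d
        return self


@dataclass
class MarkerPanel:
    """A selected CpG panel with its frozen classifier."""

    probe_ids: list[str]
    classifier: RidgeLogisticRegression
    cv_accuracy: float
    seed: int
    trajectory: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError("marker panel must be non-empty")
        if not np.all(np.isfinite(self.classifier.coef_)):
            raise ValueError("classifier coefficients must be finite")

    def to_dict(self) -> dict:
        return {
            "probe_ids": list(self.probe_ids),
            "coefficients": dict(zip(self.probe_ids,
                                     self.classifier.coef_.tolist())),
            "intercept": self.classifier.intercept_,
            "classes": [str(c) for c in self.classifier.classes_],
            "cv_accuracy": self.cv_accuracy,
            "seed": self.seed,
        }


def sbfs(
    candidates: CandidateSet | list[str],
    beta: pd.DataFrame,
    labels,
    seed: int = 0,
    cv: int = 5,
    l2: float = 1e-4,
    gains: dict[str, float] | None = None,
) -> MarkerPanel:
    """Run SBFS over the candidate CpGs and freeze the final classifier."""
    probes = (candidates.probes() if isinstance(candidates, CandidateSet)
              else list(candidates))
    if not probes:
        raise ValueError("no candidate probes to select from")
    X = beta.loc[probes].to_numpy(dtype=float).T
    y = np.asarray(labels)
    selector = SequentialBackwardSelector(cv=cv, seed=seed, l2=l2)
    selector.fit(X, y, feature_names=probes, gains=gains)
    chosen = selector.selected_names_
    model = RidgeLogisticRegression(l2=l2).fit(
        beta.loc[chosen].to_numpy(dtype=float).T, y
    )
    if isinstance(candidates, CandidateSet):
        candidates.add_stage("final", chosen)
    return MarkerPanel(probe_ids=list(chosen), classifier=model,
                       cv_accuracy=selector.best_score_, seed=seed,
                       trajectory=selector.trajectory_)
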