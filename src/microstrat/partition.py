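"""Abundant / intermediate / rare partitioning and shared-unique set algebra.

Taxa are classified by their mean relative abundance across all samples:
above the upper threshold (default 0.05%) they are "abundant", below the
lower threshold (default 0.01%) "rare", and "intermediate" otherwise.
Both inequalities are strict, so boundary values are intermediate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator

from .core_io import relative_abundance, validate_feature_table

__all__ = [
    "AbundanceClassifier",
    "classify_abundance",
    "SharedUniqueSummary",
    "shared_unique",
]

LABELS = ("abundant", "intermediate", "rare")


class AbundanceClassifier(BaseEstimator):
    """Classify taxa as abundant/intermediate/rare by mean relative abundance.

    Parameters
    ----------
    upper : float, default 5e-4
        A taxon is abundant iff its mean relative abundance is strictly
        greater than this (0.05% as a proportion).
    lower : float, default 1e-4
        A taxon is rare iff its mean is strictly below this (0.01%).

    The mean is the unweighted mean of per-sample proportions, zeros
    included, so the classification depends on proportions only and is
    invariant to per-sample sequencing depth.

    Attributes
    ----------
    labels_ : pd.Series
        Taxon -> label in {"abundant", "intermediate", "rare"}.
    mean_relative_abundance_ : pd.Series
        Taxon -> mean proportion across samples.
    """

    def __init__(self, upper: float = 5e-4, lower: float = 1e-4):
        self.upper = upper
        self.lower = lower

    def fit(self, X: pd.DataFrame, y=None):
        """Compute labels from a samples x taxa count (or proportion) table."""
        if not self.upper > self.lower > 0:
            raise ValueError(
                f"need upper > lower > 0, got upper={self.upper}, lower={self.lower}"
            )
        validate_feature_table(X)
        mean = relative_abundance(X).mean(axis=0)
        labels = pd.Series("intermediate", index=mean.index, name="label")
        labels[mean > self.upper] = "abundant"
        labels[mean < self.lower] = "rare"
        self.mean_relative_abundance_ = mean.rename("mean_relative_abundance")
        self.labels_ = labels
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Labels for a (possibly new) table under the fitted thresholds."""
        return AbundanceClassifier(self.upper, self.lower).fit(X).labels_

    @property
    def abundant_(self) -> set:
        return set(self.labels_.index[self.labels_ == "abundant"])

    @property
    def rare_(self) -> set:
        return set(self.labels_.index[self.labels_ == "rare"])

    def to_frame(self) -> pd.DataFrame:
        """Taxon table of mean relative abundance, label and thresholds used."""
        out = pd.concat([self.mean_relative_abundance_, self.labels_], axis=1)
        out["upper_threshold"] = self.upper
        out["lower_threshold"] = self.lower
        out.index.name = "taxon_id"
        return out


def classify_abundance(
    table: pd.DataFrame, upper: float = 5e-4, lower: float = 1e-4
) -> pd.DataFrame:
    """Classify taxa by mean relative abundance; thresholds recorded in output.

    Thin wrapper over :class:`AbundanceClassifier`; returns its
    :meth:`~AbundanceClassifier.to_frame` output.
    """
    return AbundanceClassifier(upper=upper, lower=lower).fit(table).to_frame()


@dataclass
class SharedUniqueSummary:
    """Per-group presence sets with their intersections and unique remainders.

    ``unique`` holds, per group, the taxa present in that group and in no
    other; ``core`` is the global intersection; ``pairwise_shared`` maps
    each unordered group pair to its intersection size.
    """

    group_sets: dict[str, set] = field(default_factory=dict)
    core: set = field(default_factory=set)
    unique: dict[str, set] = field(default_factory=dict)
    pairwise_shared: dict[tuple, int] = field(default_factory=dict)

    def counts(self) -> pd.DataFrame:
        rows = {
            g: {
                "present": len(s),
                "unique": len(self.unique[g]),
                "shared_with_any": len(s) - len(self.unique[g]),
                "core": len(self.core),
            }
            for g, s in self.group_sets.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("group")


def shared_unique(tables_by_group: dict[str, pd.DataFrame]) -> SharedUniqueSummary:
    """Shared and unique taxon sets across >= 2 groups of samples.

    A taxon is present in a group when its total count over the group's
    samples is > 0.
    """
    if len(tables_by_group) < 2:
        raise ValueError("need at least 2 groups")
    sets = {}
    for group, table in tables_by_group.items():
        validate_feature_table(table)
        present = set(table.columns[(table.sum(axis=0) > 0)])
        if not present:
            warnings.warn(f"group {group!r} has no present taxa")
        sets[group] = present
    core = set.intersection(*sets.values())
    unique = {
        g: s - set().union(*(o for h, o in sets.items() if h != g))
        for g, s in sets.items()
    }
    pairwise = {
        (a, b): len(sets[a] & sets[b])
        for a, b in itertools.combinations(sorted(sets), 2)
    }
    return SharedUniqueSummary(sets, core, unique, pairwise)
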