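"""Habitat-signature analysis.

Each habitat gets a binary reference profile (1 for every MOTU seen in at
least one of its samples); each water sample gets a sample-specific
profile. Jaccard dissimilarity between a sample profile and each habitat
profile assigns the sample to its nearest habitat, and a rank test
compares own- versus other-habitat dissimilarities.

Note the default construction is circular for classification claims (the
focal sample contributes to its own habitat's profile); a leave-one-out
mode removes the focal sample's presences from its own profile first.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from edna.ecology import MotuTable, common_motu_filter, jaccard_dissimilarity

__all__ = [
    "build_reference_profile", "sample_dissimilarities", "assign_habitat",
    "compare_groups", "HabitatClassifier",
]


def build_reference_profile(
    table: MotuTable, habitat: str, common_only: bool = False
) -> pd.Series:
    """Binary presence profile of a habitat over the full MOTU universe."""
    if habitat not in set(table.meta["habitat"]):
        raise ValueError(f"unknown habitat {habitat!r}")
    universe = table.counts.index
    if common_only:
        filtered = common_motu_filter(table)
        inc = filtered.incidence
    else:
        inc = table.incidence
    cols = [c for c in inc.columns if table.meta.loc[c, "habitat"] == habitat]
    profile = inc[cols].any(axis=1)
    return profile.reindex(universe, fill_value=False).astype(bool)


def sample_dissimilarities(
    table: MotuTable,
    profiles: pd.DataFrame | dict[str, pd.Series] | None = None,
    common_only: bool = False,
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Jaccard dissimilarity of every sample profile to every habitat
    profile.

    With ``leave_one_out``, the focal sample's presences are removed from
    its own habitat's profile before comparison (the profile is rebuilt
    from the habitat's other samples).
    """
    if profiles is None:
        profiles = {
            h: build_reference_profile(table, h, common_only=common_only)
            for h in table.habitats
        }
    profiles = pd.DataFrame(profiles)
    inc = table.incidence
    missing = set(inc.index) - set(profiles.index)
    if missing:
        raise ValueError("profiles do not cover the MOTU universe")
    out = pd.DataFrame(
        index=inc.columns, columns=profiles.columns, dtype=float
    )
    for sample in inc.columns:
        own = table.meta.loc[sample, "habitat"]
        sample_vec = inc[sample].reindex(profiles.index, fill_value=False)
        for habitat in profiles.columns:
            ref = profiles[habitat]
            if leave_one_out and habitat == own:
                others = [
                    c for c in inc.columns
                    if c != sample and table.meta.loc[c, "habitat"] == own
                ]
                sub = MotuTable(counts=table.counts[others + [
                    c for c in inc.columns
                    if table.meta.loc[c, "habitat"] != own
                ]], meta=table.meta)
                ref = build_reference_profile(sub, own, common_only=common_only)
                ref = ref.reindex(profiles.index, fill_value=False)
            out.loc[sample, habitat] = jaccard_dissimilarity(
                sample_vec.to_numpy(), ref.to_numpy()
            )
    return out


def assign_habitat(dissimilarities: pd.Series | pd.DataFrame):
    """Nearest-profile habitat call; exact ties yield ``"ambiguous"``."""
    if isinstance(dissimilarities, pd.DataFrame):
        return dissimilarities.apply(assign_habitat, axis=1)
    row = dissimilarities.astype(float)
    if len(row) < 2:
        raise ValueError("need at least 2 habitats")
    best = row.min()
    winners = row.index[row == best]
    return winners[0] if len(winners) == 1 else "ambiguous"


def compare_groups(own, other):
    """Two-sided Mann-Whitney U comparing own-habitat against
    other-habitat dissimilarities.

    Returns a dict with U, p, and each group's mean and standard error.
    When every value is tied the comparison is uninformative: p = 1 with a
    warning.
    """
    own = np.asarray(own, dtype=float)
    other = np.asarray(other, dtype=float)
    if len(own) == 0 or len(other) == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(own == other[0]) and np.all(other == other[0]):
        warnings.warn("all dissimilarities tied; comparison uninformative")
        u, p = len(own) * len(other) / 2.0, 1.0
    else:
        res = stats.mannwhitneyu(own, other, alternative="two-sided")
        u, p = float(res.statistic), float(res.pvalue)
    def sem(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return {
        "U": u,
        "p": p,
        "own_mean": float(own.mean()),
        "own_sem": sem(own),
        "other_mean": float(other.mean()),
        "other_sem": sem(other),
    }


class HabitatClassifier:
    """Nearest-reference-profile classifier over MOTU incidence vectors.

    Scikit-learn-style: ``fit`` builds one binary reference profile per
    habitat from a :class:`MotuTable`; ``predict`` assigns samples by
    minimum Jaccard dissimilarity.

    Parameters
    ----------
    common_only : bool
        Build profiles from common MOTUs only (>= 4 of 7 samples in some
        habitat x depth stratum).
    leave_one_out : bool
        Exclude the focal sample from its own habitat's profile when
        scoring training samples.
    """

    def __init__(self, common_only: bool = False, leave_one_out: bool = False):
        self.common_only = common_only
        self.leave_one_out = leave_one_out

    def get_params(self, deep: bool = True) -> dict:
        return {"common_only": self.common_only, "leave_one_out": self.leave_one_out}

    def set_params(self, **params) -> "HabitatClassifier":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, table: MotuTable, y=None) -> "HabitatClassifier":
        self.profiles_ = pd.DataFrame(
            {
                h: build_reference_profile(table, h, common_only=self.common_only)
                for h in table.habitats
            }
        )
        self.table_ = table
        return self

    def decision_frame(self) -> pd.DataFrame:
        """Dissimilarity of every fitted sample to every habitat profile."""
        return sample_dissimilarities(
            self.table_, self.profiles_,
            common_only=self.common_only, leave_one_out=self.leave_one_out,
        )

    def predict(self, incidence: pd.DataFrame | None = None):
        """Assign samples (columns of ``incidence``, default the fitted
        table) to habitats."""
        if incidence is None:
            return assign_habitat(self.decision_frame())
        universe = self.profiles_.index
        rows = {}
        for sample in incidence.columns:
            vec = incidence[sample].reindex(universe, fill_value=False)
            rows[sample] = {
                h: jaccard_dissimilarity(vec.to_numpy(), self.profiles_[h].to_numpy())
                for h in self.profiles_.columns
            }
        return assign_habitat(pd.DataFrame(rows).T)

    def score(self, incidence: pd.DataFrame | None = None, y=None) -> float:
        """Fraction of samples assigned to their true habitat."""
        calls = self.predict(incidence)
        truth = self.table_.meta.loc[calls.index, "habitat"]
        return float((calls == truth).mean())
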