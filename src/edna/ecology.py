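"""Community statistics on the MOTU x sample table.

Covers the incidence-based side of a metabarcoding community analysis:
sample-based accumulation curves, the Chao2 and ICE non-parametric
richness estimators, Jaccard / Morisita-Horn / Renkonen (dis)similarities,
non-metric multidimensional scaling, and Spearman rank correlation between
read counts and external abundance surrogates.

The sampling unit throughout is one water sample (site x depth), so a
habitat sampled at seven sites and two depths contributes m = 14 units.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

__all__ = [
    "MotuTable", "IncidenceSummary", "build_motu_table", "common_motu_filter",
    "incidence_summary", "accumulation_curve", "chao2", "ice",
    "jaccard_dissimilarity", "morisita_horn_dissimilarity",
    "renkonen_similarity", "pairwise_dissimilarity", "nmds", "spearman_rho",
]


@dataclass
class MotuTable:
    """MOTU x sample read counts with sample metadata (habitat, site, depth)."""

    counts: pd.DataFrame   # motu x sample, int
    meta: pd.DataFrame     # sample -> habitat / site / depth

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def incidence(self) -> pd.DataFrame:
        return self.counts > 0

    def samples_of(self, habitat: str, depth: str | None = None) -> list[str]:
        sel = self.meta["habitat"] == habitat
        if depth is not None:
            sel &= self.meta["depth"] == depth
        return [s for s in self.counts.columns if s in self.meta.index[sel]]

    @property
    def habitats(self) -> list[str]:
        return sorted(self.meta.loc[self.counts.columns, "habitat"].unique())


def build_motu_table(
    partition, table: pd.DataFrame, meta: pd.DataFrame
) -> MotuTable:
    """Aggregate a unique-sequence x (sample, replicate) count table into a
    MOTU x sample table using a MOTU partition.

    A MOTU's count in a sample is the sum of its member sequences' counts
    across that sample's replicates.
    """
    unknown = [s for s in table.index if s not in partition.labels]
    if unknown:
        raise ValueError(f"{len(unknown)} sequences missing from the partition")
    per_sample = table.T.groupby(level="sample").sum().T
    missing_meta = set(per_sample.columns) - set(meta.index)
    if missing_meta:
        raise ValueError(f"samples without metadata: {sorted(missing_meta)}")
    motu_of = pd.Series({s: partition.labels[s] for s in table.index})
    counts = per_sample.groupby(motu_of).sum()
    counts = counts.sort_index()
    return MotuTable(counts=counts, meta=meta)


def common_motu_filter(
    table: MotuTable, min_samples: int = 4, stratum_size: int = 7
) -> MotuTable:
    """Keep only common MOTUs: detected in at least ``min_samples`` of the
    ``stratum_size`` surface samples, or of the benthic samples, of some
    habitat."""
    inc = table.incidence
    keep = pd.Series(False, index=inc.index)
    for habitat in table.habitats:
        for depth in table.meta["depth"].unique():
            cols = table.samples_of(habitat, depth)
            if not cols:
                continue
            keep |= inc[cols].sum(axis=1) >= min_samples
    return MotuTable(counts=table.counts[keep], meta=table.meta)


@dataclass
class IncidenceSummary:
    """Incidence frequency counts over m sampling units.

    q[k] (k = 1..m) is the number of MOTUs found in exactly k units;
    sum(q) equals the observed richness.
    """

    s_obs: int
    m: int
    q: np.ndarray  # length m, q[k-1] = Q_k

    def __post_init__(self):
        if self.q.sum() != self.s_obs:
            raise ValueError("incidence frequencies do not sum to S_obs")


def incidence_summary(incidence: pd.DataFrame) -> IncidenceSummary:
    """Summarise a MOTU x sampling-unit 0/1 matrix."""
    m = incidence.shape[1]
    freq = incidence.to_numpy().astype(bool).sum(axis=1)
    freq = freq[freq > 0]
    q = np.bincount(freq, minlength=m + 1)[1 : m + 1]
    return IncidenceSummary(s_obs=int(len(freq)), m=m, q=q)


def accumulation_curve(
    incidence: pd.DataFrame,
    n_permutations: int = 100,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Sample-based MOTU accumulation curve.

    Returns per-k mean and sd of the cumulative richness of the first k
    sampling units, over random orderings (or all m! orderings when
    ``exhaustive``). The mean is non-decreasing and reaches the total
    richness at k = m.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    mat = incidence.to_numpy().astype(bool)
    m = mat.shape[1]
    rng = np.random.default_rng(seed)
    orders = (
        list(itertools.permutations(range(m)))
        if exhaustive
        else [rng.permutation(m) for _ in range(n_permutations)]
    )
    rich = np.empty((len(orders), m))
    for i, order in enumerate(orders):
        seen = np.zeros(mat.shape[0], dtype=bool)
        for k, col in enumerate(order):
            seen |= mat[:, col]
            rich[i, k] = seen.sum()
    return pd.DataFrame(
        {"k": np.arange(1, m + 1), "mean": rich.mean(axis=0),
         "sd": rich.std(axis=0, ddof=0)}
    ).set_index("k")


def chao2(summary: IncidenceSummary) -> float:
    """Chao2 incidence-based richness estimate with the (m-1)/m
    small-sample factor; bias-corrected form when Q2 = 0."""
    if summary.m < 2:
        raise ValueError("Chao2 requires at least 2 sampling units")
    q1 = float(summary.q[0])
    q2 = float(summary.q[1]) if summary.m >= 2 else 0.0
    f = (summary.m - 1) / summary.m
    if q2 > 0:
        return summary.s_obs + f * q1 * q1 / (2.0 * q2)
    return summary.s_obs + f * q1 * (q1 - 1.0) / 2.0


def ice(summary: IncidenceSummary, infrequent_cutoff: int = 10) -> float:
    """Incidence-based Coverage Estimator.

    Splits MOTUs at ``infrequent_cutoff`` incidences; estimates the
    coverage of the infrequent group from uniques and inflates the
    infrequent richness accordingly, with a CV correction term. Falls back
    to Chao2 when the coverage estimate is zero (all infrequent MOTUs are
    uniques).
    """
    if summary.m < 2:
        raise ValueError("ICE requires at least 2 sampling units")
    k = np.arange(1, summary.m + 1)
    infreq = k <= infrequent_cutoff
    q = summary.q.astype(float)
    s_infr = q[infreq].sum()
    s_freq = summary.s_obs - s_infr
    n_infr = (k[infreq] * q[infreq]).sum()
    if s_infr == 0 or n_infr == 0:
        return float(summary.s_obs)
    q1 = q[0]
    c_ice = 1.0 - q1 / n_infr
    if c_ice == 0:
        return chao2(summary)
    # number of units containing at least one infrequent MOTU
    m_infr = summary.m
    sum_kk1 = (k[infreq] * (k[infreq] - 1) * q[infreq]).sum()
    gamma2 = max(
        (s_infr / c_ice) * (m_infr / (m_infr - 1)) * sum_kk1 / n_infr**2 - 1.0,
        0.0,
    )
    return float(s_freq + s_infr / c_ice + (q1 / c_ice) * gamma2)


def jaccard_dissimilarity(a, b) -> float:
    """1 - |intersection| / |union| on binary vectors; 0 when both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    union = (a | b).sum()
    if union == 0:
        return 0.0
    return 1.0 - (a & b).sum() / union


def morisita_horn_dissimilarity(x, y) -> float:
    """Morisita-Horn dissimilarity on count vectors; invariant to positive
    rescaling of either vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("count vectors must have positive sums")
    dx = (x * x).sum() / (X * X)
    dy = (y * y).sum() / (Y * Y)
    return 1.0 - 2.0 * (x * y).sum() / ((dx + dy) * X * Y)


def renkonen_similarity(x, y, use_ranks: bool = False) -> float:
    """Renkonen (percentage) similarity: sum of per-taxon minima of
    relative abundances. With ``use_ranks`` the counts are replaced by
    mid-ranks of the non-zero entries before normalising."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if use_ranks:
        x = np.where(x > 0, stats.rankdata(x), 0.0)
        y = np.where(y > 0, stats.rankdata(y), 0.0)
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("count vectors must have positive sums")
    return float(np.minimum(x / X, y / Y).sum())


def pairwise_dissimilarity(
    table: pd.DataFrame, metric: str = "jaccard"
) -> pd.DataFrame:
    """Sample x sample dissimilarity matrix from a MOTU x sample table."""
    funcs = {
        "jaccard": lambda a, b: jaccard_dissimilarity(a > 0, b > 0),
        "morisita_horn": morisita_horn_dissimilarity,
    }
    if metric not in funcs:
        raise ValueError(f"unknown metric {metric!r}")
    cols = list(table.columns)
    n = len(cols)
    out = np.zeros((n, n))
    arr = table.to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = funcs[metric](arr[:, i], arr[:, j])
    return pd.DataFrame(out, index=cols, columns=cols)


def _stress1(d_obs: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities,
    using monotone (isotonic) regression of configuration distances on the
    dissimilarity ranks."""
    n = coords.shape[0]
    iu = np.triu_indices(n, 1)
    d_conf = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))[iu]
    obs = d_obs[iu]
    order = np.argsort(obs, kind="stable")
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(d_conf)
    dhat[order] = iso.fit_transform(np.arange(len(order)), d_conf[order])
    denom = (d_conf**2).sum()
    if denom == 0:
        return 0.0
    return math.sqrt(((d_conf - dhat) ** 2).sum() / denom)


def nmds(
    d: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[pd.DataFrame, float]:
    """Two-dimensional (by default) non-metric multidimensional scaling.

    Minimises stress by SMACOF with monotone regression over
    ``n_restarts`` random starts and reports the Kruskal stress-1 of the
    best configuration. Deterministic given ``seed``.
    """
    index = d.index if isinstance(d, pd.DataFrame) else None
    mat = np.asarray(d, dtype=float)
    if mat.shape[0] < 3:
        raise ValueError("NMDS requires at least 3 samples")
    if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 0):
        raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
    model = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=np.random.RandomState(seed),
        normalized_stress=True,
        eps=1e-7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(mat)
    stress = _stress1(mat, coords)
    frame = pd.DataFrame(
        coords, columns=[f"nmds{i + 1}" for i in range(k)], index=index
    )
    return frame, stress


def spearman_rho(u, v) -> float:
    """Spearman rank correlation (mid-ranks for ties). Raises on constant
    input, where the correlation is undefined."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(u == u[0]) or np.all(v == v[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(u, v).statistic)
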