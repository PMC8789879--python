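"""Compositional transforms, ordination and distance-based permutation tests.

Count tables are compositional: only ratios between features carry
information.  Everything here therefore runs on centred log-ratio (CLR)
transformed data,

    clr_i(x) = ln(x_i + pc) - mean_j ln(x_j + pc),

with the Aitchison distance (Euclidean distance between CLR columns) as the
sample-space metric.  PERMANOVA, the multivariate homogeneity-of-dispersion
test and the single-variable redundancy-analysis (RDA) test are implemented
from first principles on that metric; p-values use label permutations with
the +1 correction, so a reported p is never exactly zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .tables import EnvTable, FeatureTable

__all__ = [
    "ClrTable",
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "DispersionResult",
    "clr_transform",
    "aitchison_distance",
    "pca",
    "permanova",
    "pseudo_f",
    "dispersion_test",
    "rda_marginal_test",
]


@dataclass
class ClrTable:
    """CLR-transformed table; every column sums to zero."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (features, samples), float
    pseudocount: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("CLR matrix shape does not match ids")
        colsums = v.sum(axis=0)
        if v.shape[0] and np.abs(colsums).max() > 1e-9:
            raise ValueError("CLR columns must sum to zero")
        self.values = v

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_matrix(self) -> np.ndarray:
        """Samples x features view (rows are samples)."""
        return self.values.T


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if np.abs(d - d.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if (d < 0).any() or np.abs(np.diag(d)).max(initial=0.0) > 0:
            raise ValueError("distances must be non-negative with zero diagonal")
        self.data = d

    def reorder(self, sample_ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.data[np.ix_(idx, idx)])


@dataclass
class OrdinationResult:
    """Principal-component scores of CLR data."""

    sample_ids: list[str]
    scores: np.ndarray  # (samples, axes)
    variance_fractions: np.ndarray
    loadings: np.ndarray  # (features, axes)
    feature_ids: list[str]

    def __post_init__(self) -> None:
        f = np.asarray(self.variance_fractions, dtype=float)
        if (f < -1e-12).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("variance fractions must be non-negative and sum to 1")
        self.variance_fractions = f


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    ss_total: float
    ss_between: float
    ss_within: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.R2 <= 1.0 + 1e-12):
            raise ValueError("R2 must lie in [0, 1]")
        if abs(self.ss_total - (self.ss_between + self.ss_within)) > 1e-9 * max(1.0, self.ss_total):
            raise ValueError("sums of squares do not decompose")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")


@dataclass
class DispersionResult:
    sample_ids: list[str]
    groups: list[str]
    distances_to_centroid: np.ndarray
    group_means: dict
    F: float
    p: float
    n_permutations: int


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def clr_transform(t: FeatureTable, pseudocount: float = 0.5) -> ClrTable:
    """Centred log-ratio transform with an additive pseudocount.

    ``pseudocount`` may be 0 only for zero-free tables.
    """
    x = t.counts.astype(float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (x <= 0).any():
        raise ValueError("zero counts present: a positive pseudocount is required")
    logs = np.log(x + pseudocount)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return ClrTable(list(t.feature_ids), list(t.sample_ids), clr, pseudocount)


def aitchison_distance(c: ClrTable) -> DistanceMatrix:
    """Pairwise Euclidean distance between CLR columns."""
    d = squareform(pdist(c.samples_matrix(), metric="euclidean"))
    return DistanceMatrix(list(c.sample_ids), d)


def pca(c: ClrTable) -> OrdinationResult:
    """Principal components of sample-centred CLR data.

    Scores are U*S from the SVD of the centred samples x features matrix;
    full-dimensional score distances reproduce the Aitchison distances
    exactly (PCA is an isometry).
    """
    if c.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    X = c.samples_matrix()
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    if total <= 1e-12:
        raise ValueError("constant data: total variance is zero")
    k = int((s > 1e-12 * s[0]).sum())
    scores = U[:, :k] * s[:k]
    fractions = (s[:k] ** 2) / total
    return OrdinationResult(
        sample_ids=list(c.sample_ids),
        scores=scores,
        variance_fractions=fractions,
        loadings=Vt[:k].T,
        feature_ids=list(c.feature_ids),
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _ss_parts(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = float(d2[iu].sum()) / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += float(sub[np.triu_indices(len(idx), k=1)].sum()) / len(idx)
    # floating-point guard: the decomposition is exact in theory
    ss_between = max(ss_total - ss_within, 0.0)
    return ss_total, ss_between, ss_within


def pseudo_f(d: DistanceMatrix, groups) -> tuple[float, float]:
    """PERMANOVA pseudo-F and R^2 for one labelling (no permutations)."""
    labels = np.asarray(list(groups))
    d2 = d.data**2
    uniq, counts = np.unique(labels, return_counts=True)
    a, n = len(uniq), len(labels)
    ss_total, ss_between, ss_within = _ss_parts(d2, labels)
    F = _f_ratio(ss_between, ss_within, a, n)
    return F, ss_between / ss_total


def _f_ratio(ss_between: float, ss_within: float, a: int, n: int) -> float:
    if ss_within <= 0:
        return 0.0 if ss_between <= 0 else np.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``groups`` is a sequence of labels aligned with ``d.sample_ids``.
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    labels = np.asarray(list(groups))
    if len(labels) != len(d.sample_ids):
        raise ValueError("group labels must align with the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        bad = uniq[int(np.argmin(counts))]
        raise ValueError(f"group {bad!r} has a single sample; pseudo-F is undefined")
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    d2 = d.data**2
    a, n = len(uniq), len(labels)
    ss_total, ss_between, ss_within = _ss_parts(d2, labels)
    F_obs = _f_ratio(ss_between, ss_within, a, n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        _, ss_b, ss_w = _ss_parts(d2, perm)
        if _f_ratio(ss_b, ss_w, a, n) >= F_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(F_obs),
        R2=float(min(max(ss_between / ss_total, 0.0), 1.0)),
        p=float(p),
        n_permutations=n_permutations,
        ss_total=float(ss_total),
        ss_between=float(ss_between),
        ss_within=float(ss_within),
    )


def permanova_exhaustive(d: DistanceMatrix, groups) -> float:
    """Exact p over every distinct relabelling that preserves group sizes.

    Feasible only for tiny designs; used as an oracle for the Monte-Carlo p.
    """
    labels = np.asarray(list(groups))
    d2 = d.data**2
    uniq, counts = np.unique(labels, return_counts=True)
    a, n = len(uniq), len(labels)

    def f_for(lab):
        _, ss_b, ss_w = _ss_parts(d2, lab)
        return _f_ratio(ss_b, ss_w, a, n)

    F_obs = f_for(labels)
    if a != 2:
        raise NotImplementedError("exhaustive enumeration implemented for two groups")
    n0 = counts[0]
    hits = total = 0
    for combo in itertools.combinations(range(n), n0):
        lab = np.full(n, uniq[1], dtype=labels.dtype)
        lab[list(combo)] = uniq[0]
        total += 1
        if f_for(lab) >= F_obs - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# dispersion (betadisper-style)
# ---------------------------------------------------------------------------


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_b = ss_w = 0.0
    for g in np.unique(labels):
        v = values[labels == g]
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    a, n = len(np.unique(labels)), len(values)
    if ss_w <= 0:
        return 0.0 if ss_b <= 0 else np.inf
    return (ss_b / (a - 1)) / (ss_w / (n - a))


def dispersion_test(
    data: "ClrTable | DistanceMatrix", groups, n_permutations: int = 999, seed: int = 0
) -> DispersionResult:
    """Homogeneity of multivariate group dispersion.

    Each sample's distance to its own group centroid is computed (directly in
    CLR space, or from squared distances when only a distance matrix is
    available — valid because the Aitchison metric is Euclidean).  A one-way
    ANOVA F on those distances is assessed by permuting group labels over the
    fixed distances.
    """
    labels = np.asarray(list(groups))
    if isinstance(data, ClrTable):
        sample_ids = list(data.sample_ids)
        X = data.samples_matrix()
        if len(labels) != X.shape[0]:
            raise ValueError("group labels must align with samples")
        dists = np.empty(X.shape[0])
        for g in np.unique(labels):
            idx = labels == g
            centroid = X[idx].mean(axis=0)
            dists[idx] = np.linalg.norm(X[idx] - centroid, axis=1)
    else:
        sample_ids = list(data.sample_ids)
        d2 = data.data**2
        if len(labels) != d2.shape[0]:
            raise ValueError("group labels must align with the distance matrix")
        dists = np.empty(d2.shape[0])
        for g in np.unique(labels):
            idx = np.flatnonzero(labels == g)
            ng = len(idx)
            sub = d2[np.ix_(idx, idx)]
            mean_to_members = sub.mean(axis=1)
            within = sub[np.triu_indices(ng, k=1)].sum() / ng**2
            dists[idx] = np.sqrt(np.maximum(mean_to_members - within, 0.0))
    F_obs = _anova_f(dists, labels)
    if np.allclose(dists, dists[0]):
        p = 1.0
    else:
        rng = np.random.default_rng(seed)
        # vectorised permutation: shuffle the distance vector, split by group
        # sizes — equivalent to permuting labels.
        uniq, counts = np.unique(labels, return_counts=True)
        P = n_permutations
        idx = np.argsort(rng.random((P, len(dists))), axis=1)
        permuted = dists[idx]  # (P, n)
        bounds = np.cumsum(counts)[:-1]
        chunks = np.split(permuted, bounds, axis=1)
        grand = dists.mean()
        ss_b = np.zeros(P)
        ss_w = np.zeros(P)
        for chunk in chunks:
            m = chunk.mean(axis=1)
            ss_b += chunk.shape[1] * (m - grand) ** 2
            ss_w += ((chunk - m[:, None]) ** 2).sum(axis=1)
        a, n = len(uniq), len(dists)
        with np.errstate(divide="ignore", invalid="ignore"):
            F_perm = (ss_b / (a - 1)) / (ss_w / (n - a))
        F_perm = np.where(ss_w <= 0, np.where(ss_b <= 0, 0.0, np.inf), F_perm)
        p = float((1 + (F_perm >= F_obs - 1e-12).sum()) / (1 + P))
    group_means = {
        str(g): float(dists[labels == g].mean()) for g in np.unique(labels)
    }
    return DispersionResult(
        sample_ids=sample_ids,
        groups=[str(g) for g in labels],
        distances_to_centroid=dists,
        group_means=group_means,
        F=float(F_obs),
        p=float(p),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# single-variable RDA
# ---------------------------------------------------------------------------


def rda_marginal_test(
    c: ClrTable,
    env: EnvTable,
    variable: str,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """Permutational test of one environmental variable constraining CLR data.

    The standardized variable is regressed onto every (sample-centred) CLR
    feature; constrained inertia is the sum of squared fitted values and the
    F ratio is ``(constrained / 1) / (residual / (n - 2))``.  Significance is
    assessed by permuting the rows of the environmental variable.  For a
    binary variable the constrained-inertia fraction equals the PERMANOVA R^2
    of the same grouping under the Aitchison distance.
    """
    x = env.values_for(variable, c.sample_ids)
    n = len(x)
    if n < 3:
        raise ValueError("need at least three samples")
    if np.std(x) == 0:
        raise ValueError(f"environmental variable {variable!r} is constant")
    x = (x - x.mean()) / x.std()
    Y = c.samples_matrix()
    Y = Y - Y.mean(axis=0, keepdims=True)
    total = float((Y**2).sum())

    def inertia(xv: np.ndarray) -> float:
        beta = xv @ Y / (xv @ xv)
        fitted = np.outer(xv, beta)
        return float((fitted**2).sum())

    constrained = inertia(x)
    residual = total - constrained
    F_obs = constrained / (residual / (n - 2)) if residual > 0 else np.inf
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        xp = rng.permutation(x)
        cst = inertia(xp)
        res = total - cst
        F = cst / (res / (n - 2)) if res > 0 else np.inf
        if F >= F_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return {
        "F": float(F_obs),
        "p": float(p),
        "constrained_inertia": constrained,
        "total_inertia": total,
        "constrained_fraction": constrained / total,
    }
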