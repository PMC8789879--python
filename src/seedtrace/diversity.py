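"""Rarefaction-based alpha diversity and nonparametric group comparison.

Indices are computed per rarefaction draw on relative abundances and averaged
over draws: observed richness, Shannon entropy (nats) and Gini-Simpson
(1 - sum p_i^2).  Rarefaction is exact subsampling without replacement
(multivariate hypergeometric), so a column rarefied to its own total is
returned unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable

__all__ = ["AlphaDiversityResult", "rarefy", "alpha_indices", "kruskal_wallis"]

log = logging.getLogger(__name__)


@dataclass
class AlphaDiversityResult:
    """Per-sample alpha diversity averaged over rarefaction draws."""

    frame: pd.DataFrame  # index: sample id; columns: observed_richness, shannon, simpson
    rarefaction_depth: int
    n_rarefactions: int

    def __post_init__(self) -> None:
        f = self.frame
        if (f["shannon"] < -1e-12).any():
            raise ValueError("Shannon entropy must be non-negative")
        if ((f["simpson"] < -1e-12) | (f["simpson"] >= 1.0)).any():
            raise ValueError("Gini-Simpson index must lie in [0, 1)")


def rarefy(t: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every column to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning (mirroring the removal of shallow field samples).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = t.sample_totals()
    keep_cols, out_cols = [], []
    for j, sid in enumerate(t.sample_ids):
        if totals[j] < depth:
            log.warning("dropping sample %r: total %d < rarefaction depth %d", sid, totals[j], depth)
            continue
        keep_cols.append(sid)
        out_cols.append(rng.multivariate_hypergeometric(t.counts[:, j], depth))
    if not keep_cols:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    return FeatureTable(list(t.feature_ids), keep_cols, np.column_stack(out_cols))


def _indices(col: np.ndarray) -> tuple[float, float, float]:
    total = col.sum()
    p = col[col > 0] / total
    richness = float(p.size)
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    return richness, shannon, simpson


def alpha_indices(
    t: FeatureTable, depth: int, n_rarefactions: int = 10, seed: int = 0
) -> AlphaDiversityResult:
    """Mean observed richness / Shannon / Gini-Simpson over rarefaction draws."""
    if n_rarefactions < 1:
        raise ValueError("n_rarefactions must be >= 1")
    totals = t.sample_totals()
    if (totals == 0).any():
        j = int(np.argmin(totals))
        raise ValueError(f"sample {t.sample_ids[j]!r} is empty")
    acc: dict[str, list[tuple[float, float, float]]] = {}
    kept: list[str] | None = None
    for r in range(n_rarefactions):
        rt = rarefy(t, depth, seed + r)
        if kept is None:
            kept = rt.sample_ids
        for j, sid in enumerate(rt.sample_ids):
            acc.setdefault(sid, []).append(_indices(rt.counts[:, j]))
    rows = {
        sid: np.mean(np.asarray(vals), axis=0) for sid, vals in acc.items()
    }
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["observed_richness", "shannon", "simpson"]
    ).loc[kept]
    return AlphaDiversityResult(frame, rarefaction_depth=depth, n_rarefactions=n_rarefactions)


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Kruskal-Wallis rank-sum test over >= 2 groups.

    Returns ``{"H": statistic, "p": probability}`` with midrank tie
    correction; when every observation is identical the statistic is 0 and
    p = 1 (a degenerate but well-defined answer, not an error).
    """
    vals = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(vals) < 2:
        raise ValueError("need at least two groups")
    if any(v.size < 1 for v in vals):
        raise ValueError("every group needs at least one observation")
    flat = np.concatenate(vals)
    if np.all(flat == flat[0]):
        return {"H": 0.0, "p": 1.0}
    H, p = stats.kruskal(*vals)
    return {"H": float(H), "p": float(p)}
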