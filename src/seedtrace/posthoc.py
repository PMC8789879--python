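"""One-way ANOVA with Tukey HSD post-hoc and compact-letter display.

The compact-letter display follows the insert-and-absorb algorithm: start
from one letter shared by all groups; for every significantly different pair,
split each letter column containing both members; absorb columns that became
subsets of others.  Groups sharing no letter differ at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["AnovaTukeyResult", "anova_tukey", "compact_letter_display"]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class AnovaTukeyResult:
    F: float
    p: float
    pairwise_p: dict  # frozenset({g1, g2}) -> adjusted p
    letters: dict  # group -> letter string
    alpha: float


def compact_letter_display(
    names: Sequence[str], different_pairs: set[frozenset]
) -> dict[str, str]:
    """Assign letters so that two groups share a letter iff not 'different'.

    ``names`` fixes the display order (first group tends to get 'a').
    """
    names = list(names)
    cols: list[set[str]] = [set(names)]
    for pair in different_pairs:
        x, y = tuple(pair)
        new_cols: list[set[str]] = []
        for col in cols:
            if x in col and y in col:
                new_cols.append(col - {y})
                new_cols.append(col - {x})
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another (keep one of duplicates)
        kept: list[set[str]] = []
        for c in new_cols:
            if any(c <= k for k in kept):
                continue
            kept = [k for k in kept if not (k <= c)]
            kept.append(c)
        cols = kept
    cols.sort(key=lambda c: min(names.index(m) for m in c))
    out = {nm: "" for nm in names}
    for letter, col in zip(_LETTERS, cols):
        for nm in names:
            if nm in col:
                out[nm] += letter
    return out


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons.

    Degenerate designs with zero within-group variance everywhere are handled
    by exact separation: pairs with unequal means are declared different.
    """
    names = list(groups.keys())
    vals = [np.asarray(groups[n], dtype=float) for n in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    if any(v.size < 2 for v in vals):
        raise ValueError("every group needs at least two values")
    means = {n: float(v.mean()) for n, v in zip(names, vals)}
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in vals)
    pairwise_p: dict = {}
    if ss_within <= 0:
        # exact separation: no noise, so any mean difference is real
        distinct = len({round(m, 12) for m in means.values()}) > 1
        F = np.inf if distinct else 0.0
        p = 0.0 if distinct else 1.0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                differ = means[names[i]] != means[names[j]]
                pairwise_p[frozenset((names[i], names[j]))] = 0.0 if differ else 1.0
    else:
        F, p = stats.f_oneway(*vals)
        tk = stats.tukey_hsd(*vals)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairwise_p[frozenset((names[i], names[j]))] = float(tk.pvalue[i, j])
    different = {pair for pair, pv in pairwise_p.items() if pv < alpha}
    order = sorted(names, key=lambda n: -means[n])
    letters = compact_letter_display(order, different)
    return AnovaTukeyResult(
        F=float(F), p=float(p), pairwise_p=pairwise_p, letters=letters, alpha=alpha
    )
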