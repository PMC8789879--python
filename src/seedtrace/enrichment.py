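"""Core-microbiome filtering and Dirichlet Monte-Carlo CLR effect sizes.

The differential-abundance machinery works on genus-level tables.  Technical
count variation is propagated by drawing ``n_mc`` compositions per sample
from Dirichlet(counts + prior) and CLR-transforming each draw.  For a
two-group contrast the per-genus effect size in each Monte-Carlo instance is
the median between-group CLR difference over *all* between-group sample
pairs, scaled by the larger of the two groups' median absolute within-pair
differences; the reported effect is the median of that ratio over instances.
|effect| > 1 is the enrichment call.  The sign convention is fixed: positive
means higher in the second group (group B).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata, TaxonomyMap, aggregate_to_rank, merge_tables, subset

__all__ = [
    "CoreSet",
    "core_genera",
    "dirichlet_clr_instances",
    "effect_size",
    "enriched_in_rhizosphere",
    "shared_enrichment",
    "pairwise_species_contrast",
]

WIN_FLOOR = 1e-8


@dataclass
class CoreSet:
    """Genera exceeding a prevalence threshold at a detection floor."""

    rank: str
    prevalence_threshold: float
    detection: float
    members: dict  # genus -> prevalence (fraction of samples)

    @property
    def genera(self) -> list[str]:
        return sorted(self.members)


def core_genera(
    t: FeatureTable, prevalence_threshold: float, detection: float = 0.0, rank: str = "genus"
) -> CoreSet:
    """Core members: relative abundance > ``detection`` in >= ``threshold`` of samples."""
    if not 0.0 < prevalence_threshold <= 1.0:
        raise ValueError("prevalence threshold must lie in (0, 1]")
    if t.shape[0] == 0 or t.shape[1] == 0:
        raise ValueError("empty table")
    rel = t.relative_abundance()
    prev = (rel > detection).mean(axis=1)
    members = {
        f: float(p)
        for f, p in zip(t.feature_ids, prev)
        if p >= prevalence_threshold
    }
    return CoreSet(rank=rank, prevalence_threshold=prevalence_threshold, detection=detection, members=members)


def dirichlet_clr_instances(
    t: FeatureTable, n_mc: int = 128, prior: float = 0.5, seed: int = 0
) -> np.ndarray:
    """``n_mc`` CLR-transformed Dirichlet(counts + prior) draws per sample.

    Returns an array of shape ``(n_mc, features, samples)``; every CLR vector
    sums to zero.
    """
    if n_mc < 16:
        raise ValueError("n_mc must be >= 16")
    rng = np.random.default_rng(seed)
    alpha = t.counts.astype(float) + prior  # (F, S)
    gam = rng.standard_gamma(alpha, size=(n_mc,) + alpha.shape)
    comp = gam / gam.sum(axis=1, keepdims=True)
    logs = np.log(comp)
    return logs - logs.mean(axis=1, keepdims=True)


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu


def effect_size(
    t: FeatureTable,
    groups: Mapping[str, str] | Sequence[str],
    group_order: tuple[str, str] | None = None,
    n_mc: int = 128,
    prior: float = 0.5,
    seed: int = 0,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-genus Dirichlet-MC CLR effect sizes for a two-level contrast.

    ``groups`` maps each sample id to its level (or is a label sequence
    aligned with ``t.sample_ids``); ``group_order = (A, B)`` fixes the sign
    convention (positive = higher in B).  Returns a DataFrame with columns
    ``genus, effect, diff_btw, diff_win, call`` where ``call`` is B's label
    when effect > threshold, A's when effect < -threshold, else ``"none"``.
    """
    if isinstance(groups, Mapping):
        labels = np.array([groups[s] for s in t.sample_ids])
    else:
        labels = np.asarray(list(groups))
        if len(labels) != len(t.sample_ids):
            raise ValueError("labels must align with samples")
    uniq = list(dict.fromkeys(labels))
    if group_order is not None:
        ga, gb = group_order
        if set((ga, gb)) != set(uniq):
            raise ValueError("group_order does not match labels")
    else:
        if len(uniq) != 2:
            raise ValueError("effect_size needs exactly two groups")
        ga, gb = sorted(uniq)
    idx_a = np.flatnonzero(labels == ga)
    idx_b = np.flatnonzero(labels == gb)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("both groups need at least two samples")

    clr = dirichlet_clr_instances(t, n_mc=n_mc, prior=prior, seed=seed)  # (M, F, S)
    A = clr[:, :, idx_a]  # (M, F, nA)
    B = clr[:, :, idx_b]
    # all between-group pairs: (M, F, nB, nA) -> flatten pair axes
    btw_pairs = (B[:, :, :, None] - A[:, :, None, :]).reshape(clr.shape[0], clr.shape[1], -1)
    btw = np.median(btw_pairs, axis=2)  # (M, F)

    ia, ja = _pair_indices(len(idx_a))
    ib, jb = _pair_indices(len(idx_b))
    win_a = np.median(np.abs(A[:, :, ia] - A[:, :, ja]), axis=2)
    win_b = np.median(np.abs(B[:, :, ib] - B[:, :, jb]), axis=2)
    win = np.maximum(np.maximum(win_a, win_b), WIN_FLOOR)

    ratio = btw / win
    eff = np.median(ratio, axis=0)  # (F,)
    diff_btw = np.median(btw, axis=0)
    diff_win = np.median(win, axis=0)
    call = np.where(eff > threshold, gb, np.where(eff < -threshold, ga, "none"))
    return pd.DataFrame(
        {
            "genus": list(t.feature_ids),
            "effect": eff,
            "diff_btw": diff_btw,
            "diff_win": diff_win,
            "call": call,
        }
    )


def _genus_table_for(
    tables: Mapping[str, FeatureTable],
    metadata: SampleMetadata,
    tax: TaxonomyMap,
    selections: list[dict],
) -> tuple[FeatureTable, np.ndarray]:
    """Merge the selected sample groups into one genus-level table + labels."""
    parts = []
    labels: list[str] = []
    for sel in selections:
        label = sel.pop("_label")
        comp = sel["compartment"]
        sub = subset(tables[comp], metadata, sel)
        parts.append(sub)
        labels.extend([label] * len(sub.sample_ids))
    merged = merge_tables(parts, allow_empty=True)
    # canonical sample order so the Monte-Carlo draws (consumed column-wise)
    # are identical however the contrast was phrased
    order = np.argsort(np.asarray(merged.sample_ids, dtype=object))
    merged = merged.select_samples([merged.sample_ids[i] for i in order])
    labels_arr = np.asarray(labels, dtype=object)[order]
    genus_t = aggregate_to_rank(merged, tax, "genus")
    return genus_t, labels_arr


def enriched_in_rhizosphere(
    tables: Mapping[str, FeatureTable],
    metadata: SampleMetadata,
    tax: TaxonomyMap,
    species: str,
    location: str,
    prevalence_threshold: float = 0.85,
    detection: float = 0.0,
    threshold: float = 1.0,
    n_mc: int = 128,
    prior: float = 0.5,
    seed: int = 0,
) -> tuple[set[str], pd.DataFrame]:
    """Core genera with effect > threshold in rhizosphere vs bulk soil.

    Core filtering (prevalence over the contrast's samples) precedes the
    effect-size test.  Returns the enriched genus set and the full effect
    table.
    """
    if hasattr(tables, "tables"):
        ds = tables
        metadata = ds.metadata if metadata is None else metadata
        tax = ds.taxonomy if tax is None else tax
        tables = ds.tables
    genus_t, labels = _genus_table_for(
        tables,
        metadata,
        tax,
        [
            {"_label": "bulk", "compartment": "bulk", "species": species, "location": location},
            {"_label": "rhizosphere", "compartment": "rhizosphere", "species": species, "location": location},
        ],
    )
    core = core_genera(genus_t, prevalence_threshold, detection)
    keep = [i for i, g in enumerate(genus_t.feature_ids) if g in core.members]
    if not keep:
        return set(), pd.DataFrame(columns=["genus", "effect", "diff_btw", "diff_win", "call"])
    core_t = FeatureTable(
        [genus_t.feature_ids[i] for i in keep],
        list(genus_t.sample_ids),
        genus_t.counts[keep],
        allow_empty=True,
    )
    table = effect_size(
        core_t, labels, group_order=("bulk", "rhizosphere"),
        n_mc=n_mc, prior=prior, seed=seed, threshold=threshold,
    )
    enriched = set(table.loc[table["effect"] > threshold, "genus"])
    return enriched, table


def shared_enrichment(set_a: set[str], set_b: set[str]) -> dict[str, set[str]]:
    """Partition two enriched-taxa sets into shared / only_A / only_B."""
    return {
        "shared": set(set_a) & set(set_b),
        "only_a": set(set_a) - set(set_b),
        "only_b": set(set_b) - set(set_a),
    }


def pairwise_species_contrast(
    tables: Mapping[str, FeatureTable],
    metadata: SampleMetadata,
    tax: TaxonomyMap,
    species_a: str,
    species_b: str,
    location: str,
    prevalence_threshold: float = 0.85,
    detection: float = 0.0,
    threshold: float = 1.0,
    n_mc: int = 128,
    prior: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Effect sizes between two species' rhizosphere communities at one site.

    The count of |effect| > threshold genera is the dissimilarity readout;
    it is invariant to the order of the two species.
    """
    if hasattr(tables, "tables"):
        ds = tables
        metadata = ds.metadata if metadata is None else metadata
        tax = ds.taxonomy if tax is None else tax
        tables = ds.tables
    genus_t, labels = _genus_table_for(
        tables,
        metadata,
        tax,
        [
            {"_label": species_a, "compartment": "rhizosphere", "species": species_a, "location": location},
            {"_label": species_b, "compartment": "rhizosphere", "species": species_b, "location": location},
        ],
    )
    core = core_genera(genus_t, prevalence_threshold, detection)
    keep = [i for i, g in enumerate(genus_t.feature_ids) if g in core.members]
    if not keep:
        return pd.DataFrame(columns=["genus", "effect", "diff_btw", "diff_win", "call"])
    core_t = FeatureTable(
        [genus_t.feature_ids[i] for i in keep],
        list(genus_t.sample_ids),
        genus_t.counts[keep],
        allow_empty=True,
    )
    return effect_size(
        core_t, labels, group_order=(species_a, species_b),
        n_mc=n_mc, prior=prior, seed=seed, threshold=threshold,
    )
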