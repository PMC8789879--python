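"""Domain types and tabular I/O for amplicon feature-table pipelines.

The whole pipeline trades in four kinds of tables:

* :class:`FeatureTable` — integer ASV (or genus) count matrix, features x samples;
* :class:`TaxonomyMap` — feature -> ranked lineage, QIIME2 taxonomy dialect;
* :class:`SampleMetadata` — sample -> (species, location, compartment, block);
* :class:`EnvTable` — sample -> numeric soil-chemistry variables.

All on-disk formats are plain TSV.  Seed samples carry no location (the seed
pool comes from a gene bank and is shared across field sites) and seedbed
samples carry no species (seedbed soil is sampled before sowing); both rules
are enforced at validation time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SelectionError",
    "FeatureTable",
    "TaxonomyMap",
    "SampleMetadata",
    "EnvTable",
    "DEFAULT_RANKS",
    "UNCLASSIFIED",
    "COMPARTMENTS",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_env_table",
    "write_env_table",
    "aggregate_to_rank",
    "subset",
]

DEFAULT_RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
)

#: Sentinel for a rank with no assignment.  Distinct unknown clades are kept
#: apart by aggregating on the full lineage prefix, never on the bare sentinel.
UNCLASSIFIED = "unclassified"

COMPARTMENTS: tuple[str, ...] = ("seed", "seedbed", "bulk", "rhizosphere", "endorhiza")

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


class FormatError(ValueError):
    """An input file violates the expected tabular format."""


class SelectionError(ValueError):
    """A metadata predicate selected no samples."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} {x!r}")
        seen.add(x)


@dataclass
class FeatureTable:
    """Non-negative integer count matrix, features (rows) x samples (columns).

    Parameters
    ----------
    feature_ids, sample_ids
        Row and column labels; duplicates are rejected.
    counts
        Integer array of shape ``(len(feature_ids), len(sample_ids))``.
    allow_empty
        Permit all-zero sample columns (default: every sample must carry at
        least one read).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    allow_empty: bool = False

    def __post_init__(self) -> None:
        self.feature_ids = [str(x) for x in self.feature_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {arr.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
                raise FormatError("counts must be integers")
            arr = arr.astype(np.int64)
        else:
            arr = arr.astype(np.int64, copy=True)
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        if not self.allow_empty and arr.shape[0] > 0:
            totals = arr.sum(axis=0)
            if (totals < 1).any():
                j = int(np.argmin(totals))
                raise FormatError(f"sample {self.sample_ids[j]!r} has zero total count")
        self.counts = arr

    # -- conveniences -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        totals = self.counts.sum(axis=0).astype(float)
        totals[totals == 0] = 1.0
        return self.counts / totals

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.feature_ids),
            list(self.sample_ids),
            self.counts.copy(),
            allow_empty=self.allow_empty,
        )

    def select_samples(self, sample_ids: Sequence[str], allow_empty: bool | None = None) -> "FeatureTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return FeatureTable(
            list(self.feature_ids),
            [self.sample_ids[i] for i in idx],
            self.counts[:, idx],
            allow_empty=self.allow_empty if allow_empty is None else allow_empty,
        )

    def drop_empty_features(self) -> "FeatureTable":
        keep = self.counts.sum(axis=1) > 0
        return FeatureTable(
            [f for f, k in zip(self.feature_ids, keep) if k],
            list(self.sample_ids),
            self.counts[keep],
            allow_empty=self.allow_empty,
        )

    def detected_features(self, sample_id: str | None = None) -> set[str]:
        """Features with count >= 1 in the given sample (or in any sample)."""
        if sample_id is None:
            mask = self.counts.sum(axis=1) >= 1
        else:
            mask = self.column(sample_id) >= 1
        return {f for f, m in zip(self.feature_ids, mask) if m}


def merge_tables(tables: Iterable[FeatureTable], allow_empty: bool = False) -> FeatureTable:
    """Union of samples over the union of features (missing counts are zero)."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to merge")
    feats: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for f in t.feature_ids:
            if f not in seen:
                seen.add(f)
                feats.append(f)
    fidx = {f: i for i, f in enumerate(feats)}
    samples: list[str] = []
    cols: list[np.ndarray] = []
    for t in tables:
        rows = np.array([fidx[f] for f in t.feature_ids])
        for j, s in enumerate(t.sample_ids):
            col = np.zeros(len(feats), dtype=np.int64)
            col[rows] = t.counts[:, j]
            samples.append(s)
            cols.append(col)
    return FeatureTable(feats, samples, np.column_stack(cols), allow_empty=allow_empty)


@dataclass
class TaxonomyMap:
    """Feature -> ordered lineage (kingdom ... genus), QIIME2-style.

    Unassigned ranks hold the sentinel :data:`UNCLASSIFIED`.  The
    :meth:`label` method produces aggregation keys: a classified rank value is
    used verbatim, while an unclassified rank yields the full semicolon-joined
    prefix so that distinct unknown clades are never merged.
    """

    lineages: dict[str, tuple[str, ...]]
    ranks: tuple[str, ...] = DEFAULT_RANKS

    def __post_init__(self) -> None:
        self.ranks = tuple(self.ranks)
        clean: dict[str, tuple[str, ...]] = {}
        for fid, lin in self.lineages.items():
            lin = tuple(lin)
            if len(lin) > len(self.ranks):
                lin = lin[: len(self.ranks)]
            if len(lin) < len(self.ranks):
                lin = lin + (UNCLASSIFIED,) * (len(self.ranks) - len(lin))
            clean[str(fid)] = lin
        self.lineages = clean

    def rank_index(self, rank: str) -> int:
        try:
            return self.ranks.index(rank)
        except ValueError:
            raise ValueError(
                f"unknown rank {rank!r}; expected one of {self.ranks}"
            ) from None

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        try:
            return self.lineages[feature_id]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} has no taxonomy entry") from None

    def label(self, feature_id: str, rank: str = "genus") -> str:
        """Aggregation key for ``feature_id`` at ``rank``."""
        k = self.rank_index(rank)
        lin = self.lineage(feature_id)
        if lin[k] != UNCLASSIFIED:
            return lin[k]
        return ";".join(lin[: k + 1])

    def genus(self, feature_id: str) -> str:
        return self.label(feature_id, "genus")

    def covers(self, table: FeatureTable) -> bool:
        return all(f in self.lineages for f in table.feature_ids)


@dataclass
class SampleMetadata:
    """Sample -> (species, location, compartment, block).

    Stored as a DataFrame indexed by sample id.  Missing species/location are
    ``None`` (seed samples have no location; seedbed samples have no species).
    """

    frame: pd.DataFrame

    REQUIRED = ("species", "location", "compartment", "block")

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        df = df[list(self.REQUIRED)].astype(object)
        df = df.where(df.notna(), None)
        df = df.apply(lambda c: c.map(lambda v: None if v in (None, "") else str(v)))
        _check_unique(list(df.index.astype(str)), "sample id")
        for sid, row in df.iterrows():
            comp = row["compartment"]
            if comp not in COMPARTMENTS:
                raise FormatError(
                    f"sample {sid!r}: unknown compartment {comp!r}; "
                    f"expected one of {COMPARTMENTS}"
                )
            if comp == "seed" and row["location"] is not None:
                raise FormatError(f"seed sample {sid!r} must not carry a location")
            if comp == "seedbed" and row["species"] is not None:
                raise FormatError(f"seedbed sample {sid!r} must not carry a species")
        combos = df[list(self.REQUIRED)].apply(tuple, axis=1)
        dup = combos[combos.duplicated()]
        if len(dup):
            raise FormatError(
                f"duplicate (species, location, compartment, block) combination {dup.iloc[0]}"
            )
        df.index = df.index.astype(str)
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def get(self, sample_id: str) -> dict:
        try:
            row = self.frame.loc[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None
        return {k: row[k] for k in self.REQUIRED}

    def select(self, **criteria) -> list[str]:
        """Sample ids matching all criteria (value, or collection of values)."""
        mask = np.ones(len(self.frame), dtype=bool)
        for key, val in criteria.items():
            if key not in self.REQUIRED:
                raise ValueError(f"unknown metadata field {key!r}")
            col = self.frame[key]
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= col.isin(list(val)).to_numpy()
            else:
                mask &= (col == val).to_numpy()
        return list(self.frame.index[mask])

    def levels(self, key: str) -> list[str]:
        vals = [v for v in self.frame[key].unique() if v is not None]
        return sorted(vals)


@dataclass
class EnvTable:
    """Per-sample numeric environmental variables (soil chemistry)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        df.index = df.index.astype(str)
        df = df.apply(pd.to_numeric, errors="raise")
        if not np.all(np.isfinite(df.to_numpy(dtype=float))):
            raise FormatError("environmental variables must be finite numbers")
        _check_unique(list(df.index), "sample id")
        self.frame = df

    @property
    def variables(self) -> list[str]:
        return list(self.frame.columns)

    def values_for(self, variable: str, sample_ids: Sequence[str]) -> np.ndarray:
        if variable not in self.frame.columns:
            raise ValueError(f"unknown environmental variable {variable!r}")
        return self.frame.loc[list(sample_ids), variable].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_feature_table(path, allow_empty: bool = False) -> FeatureTable:
    """Read a features x samples TSV (first header cell ``#FeatureID``)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: feature table needs at least one sample column")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample id")
    df = pd.read_csv(
        path, sep="\t", header=0, index_col=0, dtype=str, keep_default_na=False
    )
    feature_ids = [str(x) for x in df.index]
    _check_unique(feature_ids, "feature id")
    counts = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for j in range(raw.shape[1]):
        col = pd.to_numeric(pd.Series(raw[:, j]), errors="coerce")
        bad = col.isna().to_numpy()
        if bad.any():
            i = int(np.argmax(bad))
            raise FormatError(
                f"{path}: non-numeric cell {raw[i, j]!r} at feature "
                f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        vals = col.to_numpy(dtype=float)
        if np.any(vals != np.floor(vals)):
            i = int(np.argmax(vals != np.floor(vals)))
            raise FormatError(
                f"{path}: non-integer cell {raw[i, j]!r} at feature "
                f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        if np.any(vals < 0):
            i = int(np.argmax(vals < 0))
            raise FormatError(
                f"{path}: negative cell at feature {feature_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            )
        counts[:, j] = vals.astype(np.int64)
    return FeatureTable(feature_ids, sample_ids, counts, allow_empty=allow_empty)


def write_feature_table(t: FeatureTable, path) -> None:
    df = t.to_dataframe()
    df.index.name = "#FeatureID"
    df.to_csv(path, sep="\t")


def _parse_taxon_string(taxon: str, n_ranks: int) -> tuple[str, ...]:
    parts = [p.strip() for p in taxon.split(";")]
    out: list[str] = []
    for p in parts[:n_ranks]:
        p = _RANK_PREFIX.sub("", p).strip()
        out.append(p if p else UNCLASSIFIED)
    while len(out) < n_ranks:
        out.append(UNCLASSIFIED)
    return tuple(out)


def read_taxonomy(path, ranks: tuple[str, ...] = DEFAULT_RANKS) -> TaxonomyMap:
    """Read a QIIME2-dialect taxonomy TSV ('Feature ID', 'Taxon')."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower().replace(" ", ""): c for c in df.columns}
    try:
        fid_col = cols["featureid"]
        tax_col = cols["taxon"]
    except KeyError:
        raise FormatError(
            f"{path}: taxonomy file must have 'Feature ID' and 'Taxon' columns"
        ) from None
    lineages = {
        str(row[fid_col]): _parse_taxon_string(str(row[tax_col]), len(ranks))
        for _, row in df.iterrows()
    }
    _check_unique(list(df[fid_col].astype(str)), "feature id")
    return TaxonomyMap(lineages, ranks=ranks)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    rows = [
        {"Feature ID": fid, "Taxon": "; ".join(lin)}
        for fid, lin in tax.lineages.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, index_col="sample-id"
    )
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.frame.copy()
    df = df.fillna("")
    df.index.name = "sample-id"
    df.to_csv(path, sep="\t")


def read_env_table(path) -> EnvTable:
    df = pd.read_csv(path, sep="\t", index_col="sample-id")
    return EnvTable(df)


def write_env_table(env: EnvTable, path) -> None:
    df = env.frame.copy()
    df.index.name = "sample-id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# table operations
# ---------------------------------------------------------------------------


def aggregate_to_rank(t: FeatureTable, tax: TaxonomyMap, rank: str) -> FeatureTable:
    """Sum ASV counts into distinct lineage labels at ``rank``.

    Unclassified lineages keep their full prefix as the label, so two ASVs
    that are unclassified at ``rank`` but diverge at a higher rank land in
    different rows.  Per-sample totals are conserved exactly.
    """
    tax.rank_index(rank)  # validates the rank name
    labels: list[str] = []
    index: dict[str, int] = {}
    rows: list[list[int]] = []
    for i, fid in enumerate(t.feature_ids):
        lab = tax.label(fid, rank)
        if lab not in index:
            index[lab] = len(labels)
            labels.append(lab)
            rows.append([])
        rows[index[lab]].append(i)
    counts = np.zeros((len(labels), len(t.sample_ids)), dtype=np.int64)
    for k, members in enumerate(rows):
        counts[k] = t.counts[members].sum(axis=0)
    return FeatureTable(labels, list(t.sample_ids), counts, allow_empty=t.allow_empty)


def subset(
    t: FeatureTable,
    meta: SampleMetadata,
    where: Mapping[str, object] | Callable[[dict], bool],
    drop_empty_features: bool = False,
) -> FeatureTable:
    """Select the sample columns whose metadata satisfies ``where``.

    ``where`` is either a mapping of metadata fields to required values (a
    value or a collection of values) or a callable over the metadata record.
    Raises :class:`SelectionError` when nothing matches.
    """
    if callable(where):
        chosen = [s for s in t.sample_ids if s in meta.frame.index and where(meta.get(s))]
        desc = getattr(where, "__name__", repr(where))
    else:
        wanted = set(meta.select(**dict(where)))
        chosen = [s for s in t.sample_ids if s in wanted]
        desc = repr(dict(where))
    if not chosen:
        raise SelectionError(f"no samples match predicate {desc}")
    out = t.select_samples(chosen)
    if drop_empty_features:
        out = out.drop_empty_features()
    return out
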