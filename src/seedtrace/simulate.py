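"""Synthetic multi-compartment community generator with known ground truth.

Emulates the structure of a wheat field trial: one gene-bank seed pool per
species (location-agnostic), seedbed soil sampled per location before sowing,
and bulk soil / rhizosphere / endorhiza samples for every species x location x
block.  Seed ASVs have uniform expected relative abundance, so the expected
seed-transmission proportion has the closed form

    E[proportion] = tau * (1 - seed_seedbed_genus_overlap)

up to detection loss at finite sequencing depth: a fraction ``overlap`` of
seed genera also occurs in the seedbed pool and is therefore struck from the
transmitted set by the background-exclusion rule, while each remaining
(eligible) seed ASV colonizes a given root-compartment replicate independently
with probability ``tau``.

Soil communities are log-normal profiles over a shared ASV pool with additive
per-location shifts on the log scale; the rhizosphere applies per-(species,
genus) log2 fold changes on top of the bulk profile.  Counts are drawn
Dirichlet-multinomial at a fixed depth (``overdispersion = inf`` collapses to
plain multinomial sampling, making column totals exact).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .tables import (
    DEFAULT_RANKS,
    EnvTable,
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    write_env_table,
    write_feature_table,
    write_metadata,
    write_taxonomy,
)

import pandas as pd

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "write_dataset"]

SPECIES_DEFAULT = ("A.tauschii", "T.aestivum", "T.dicoccoides", "T.durum")
LOCATIONS_DEFAULT = ("GG", "WG", "RH")

#: Genetically related couples; used only to build the default enrichment map
#: (related species share most of their enriched genera, mirroring field
#: observations that wild/domesticated relatives recruit similar taxa).
RELATED_COUPLES = (("A.tauschii", "T.aestivum"), ("T.dicoccoides", "T.durum"))


class SpecError(ValueError):
    """The synthetic specification is internally inconsistent."""


def _default_tau(species) -> dict:
    # Endorhiza receives more seed transmission than the rhizosphere, and the
    # wild diploid receives the most — the qualitative pattern the statistic
    # is meant to resolve.
    tau = {}
    for sp in species:
        if sp == "A.tauschii":
            tau[sp] = {"rhizosphere": 0.5, "endorhiza": 0.8}
        else:
            tau[sp] = {"rhizosphere": 0.3, "endorhiza": 0.6}
    return tau


def _default_enrichment(species) -> dict:
    """Five enriched genera per species, three shared within a related couple."""
    lfc: dict[tuple[str, str], float] = {}
    block = 0
    for couple in RELATED_COUPLES:
        present = [sp for sp in couple if sp in species]
        shared = [f"G{block + k:03d}" for k in range(3)]
        for i, sp in enumerate(present):
            own = [f"G{block + 3 + 2 * i + k:03d}" for k in range(2)]
            for g in shared + own:
                lfc[(sp, g)] = 2.5
        block += 10
    leftovers = [sp for sp in species if not any(sp in c for c in RELATED_COUPLES)]
    for i, sp in enumerate(leftovers):
        for k in range(5):
            lfc[(sp, f"G{block + 5 * i + k:03d}")] = 2.5
    return lfc


@dataclass
class SyntheticSpec:
    """Parameters of the generated study.

    Defaults reproduce the field-trial layout: 4 wheat species x 3 locations
    x 3 blocks, 5 compartments, 50,000 reads per sample.
    """

    n_seed_asvs: int = 50
    n_soil_asvs: int = 200
    genus_pool_size: int = 80
    seed_seedbed_genus_overlap: float = 0.2
    tau: Mapping[str, Mapping[str, float]] | None = None
    enrichment_lfc: Mapping[tuple[str, str], float] | None = None
    location_effect_sd: float = 1.0
    depth: int = 50_000
    overdispersion: float = math.inf
    n_blocks: int = 3
    rng_seed: int = 0
    species: tuple[str, ...] = SPECIES_DEFAULT
    locations: tuple[str, ...] = LOCATIONS_DEFAULT
    transmit_rel_abundance: float = 0.002
    soil_lognormal_sd: float = 1.0
    make_env: bool = True

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.locations = tuple(self.locations)
        if not 0.0 <= self.seed_seedbed_genus_overlap <= 1.0:
            raise SpecError("seed_seedbed_genus_overlap must be in [0, 1]")
        if self.depth < 100:
            raise SpecError("depth must be >= 100")
        if self.n_blocks < 2:
            raise SpecError("n_blocks must be >= 2")
        if not 0.0 < self.transmit_rel_abundance < 0.5:
            raise SpecError("transmit_rel_abundance must be a small fraction")
        if self.tau is None:
            self.tau = _default_tau(self.species)
        for sp, comps in self.tau.items():
            if sp not in self.species:
                raise SpecError(f"tau references unknown species {sp!r}")
            for comp, p in comps.items():
                if comp not in ("rhizosphere", "endorhiza"):
                    raise SpecError(f"tau references unknown compartment {comp!r}")
                if not 0.0 <= p <= 1.0:
                    raise SpecError(f"tau[{sp!r}][{comp!r}] = {p} outside [0, 1]")
        for sp in self.species:
            if sp not in self.tau:
                raise SpecError(f"tau missing species {sp!r}")
            for comp in ("rhizosphere", "endorhiza"):
                if comp not in self.tau[sp]:
                    raise SpecError(f"tau[{sp!r}] missing compartment {comp!r}")
        if self.enrichment_lfc is None:
            self.enrichment_lfc = _default_enrichment(self.species)
        for (sp, _g), _v in self.enrichment_lfc.items():
            if sp not in self.species:
                raise SpecError(f"enrichment_lfc references unknown species {sp!r}")


@dataclass
class SyntheticDataset:
    """Generated tables plus the ground truth needed to score the pipeline."""

    tables: dict[str, FeatureTable]
    taxonomy: TaxonomyMap
    metadata: SampleMetadata
    truth: dict
    env: EnvTable | None = None
    spec: SyntheticSpec | None = None

    def all_samples_table(self) -> FeatureTable:
        from .tables import merge_tables

        return merge_tables(self.tables.values(), allow_empty=True)


def _lineage_for(genus: str, gidx: int) -> tuple[str, ...]:
    return (
        "Bacteria",
        f"P{gidx % 7:02d}",
        f"C{gidx % 13:02d}",
        f"O{gidx % 17:02d}",
        f"F{gidx % 23:02d}",
        genus,
    )


def _draw_counts(rng: np.random.Generator, p: np.ndarray, depth: int, overdispersion: float) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    if math.isinf(overdispersion):
        return rng.multinomial(depth, p)
    support = p > 0
    alpha = overdispersion * p[support]
    q = np.zeros_like(p)
    q[support] = rng.dirichlet(alpha)
    return rng.multinomial(depth, q)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full linked dataset; fully reproducible from ``rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)

    n_seed = spec.n_seed_asvs
    n_soil = spec.n_soil_asvs
    n_overlap = int(round(spec.seed_seedbed_genus_overlap * n_seed))

    seed_ids = [f"sasv{i:04d}" for i in range(n_seed)]
    soil_ids = [f"zasv{i:04d}" for i in range(n_soil)]
    seed_genera = [f"SG{i:03d}" for i in range(n_seed)]
    soil_genera = [
        seed_genera[i] if i < n_overlap else f"G{(i - n_overlap) % spec.genus_pool_size:03d}"
        for i in range(n_soil)
    ]

    lineages: dict[str, tuple[str, ...]] = {}
    for fid, g in zip(seed_ids, seed_genera):
        lineages[fid] = _lineage_for(g, 1000 + seed_genera.index(g))
    genus_order: dict[str, int] = {}
    for fid, g in zip(soil_ids, soil_genera):
        gidx = genus_order.setdefault(g, len(genus_order))
        lineages[fid] = lineages.get(
            fid, _lineage_for(g, gidx if not g.startswith("SG") else 1000 + seed_genera.index(g))
        )
    taxonomy = TaxonomyMap(lineages, ranks=DEFAULT_RANKS)

    eligible = seed_ids[n_overlap:]
    ineligible = seed_ids[:n_overlap]

    # log-normal soil profiles: shared base + additive per-location shift
    base = rng.normal(0.0, spec.soil_lognormal_sd, size=n_soil)
    loc_shift = {
        loc: rng.normal(0.0, spec.location_effect_sd, size=n_soil)
        for loc in spec.locations
    }
    lfc_vec: dict[str, np.ndarray] = {}
    for sp in spec.species:
        v = np.zeros(n_soil)
        for i, g in enumerate(soil_genera):
            v[i] = spec.enrichment_lfc.get((sp, g), 0.0) * math.log(2.0)
        lfc_vec[sp] = v

    blocks = [chr(ord("a") + b) for b in range(spec.n_blocks)]
    meta_rows: list[dict] = []
    tables: dict[str, FeatureTable] = {}
    truth: dict = {
        "eligible": list(eligible),
        "ineligible": list(ineligible),
        "transmitted": {"rhizosphere": {}, "endorhiza": {}},
        "detected": {"rhizosphere": {}, "endorhiza": {}},
        "enriched_lfc": {
            sp: {g: v for (s, g), v in spec.enrichment_lfc.items() if s == sp}
            for sp in spec.species
        },
    }

    # --- seed: one pooled sample per species, uniform expected abundance ----
    seed_cols, seed_samples = [], []
    for sp in spec.species:
        sid = f"seed.{sp}"
        seed_cols.append(
            _draw_counts(rng, np.full(n_seed, 1.0 / n_seed), spec.depth, spec.overdispersion)
        )
        seed_samples.append(sid)
        meta_rows.append(
            {"sample-id": sid, "species": sp, "location": None, "compartment": "seed", "block": "pool"}
        )
    tables["seed"] = FeatureTable(seed_ids, seed_samples, np.column_stack(seed_cols))

    # --- seedbed / bulk: location soil profiles ----------------------------
    for comp in ("seedbed", "bulk"):
        cols, samples = [], []
        for loc in spec.locations:
            w = np.exp(base + loc_shift[loc])
            if comp == "seedbed":
                for b in blocks:
                    sid = f"seedbed.{loc}.{b}"
                    cols.append(_draw_counts(rng, w, spec.depth, spec.overdispersion))
                    samples.append(sid)
                    meta_rows.append(
                        {"sample-id": sid, "species": None, "location": loc,
                         "compartment": "seedbed", "block": b}
                    )
            else:
                for sp in spec.species:
                    for b in blocks:
                        sid = f"bulk.{sp}.{loc}.{b}"
                        cols.append(_draw_counts(rng, w, spec.depth, spec.overdispersion))
                        samples.append(sid)
                        meta_rows.append(
                            {"sample-id": sid, "species": sp, "location": loc,
                             "compartment": "bulk", "block": b}
                        )
        tables[comp] = FeatureTable(soil_ids, samples, np.column_stack(cols))

    # --- root compartments: soil background + transmitted seed ASVs --------
    root_feature_ids = soil_ids + eligible
    for comp in ("rhizosphere", "endorhiza"):
        cols, samples = [], []
        for sp in spec.species:
            tau = spec.tau[sp][comp]
            for loc in spec.locations:
                w = np.exp(base + loc_shift[loc] + (lfc_vec[sp] if comp == "rhizosphere" else 0.0))
                w = w / w.sum()
                for b in blocks:
                    sid = f"{comp}.{sp}.{loc}.{b}"
                    mask = rng.random(len(eligible)) < tau
                    q = spec.transmit_rel_abundance
                    spike = mask.astype(float) * q
                    p = np.concatenate([w * (1.0 - spike.sum()), spike])
                    counts = _draw_counts(rng, p, spec.depth, spec.overdispersion)
                    cols.append(counts)
                    samples.append(sid)
                    transmitted = [a for a, m in zip(eligible, mask) if m]
                    detected = [
                        a for a, m, c in zip(eligible, mask, counts[n_soil:]) if m and c >= 1
                    ]
                    truth["transmitted"][comp][sid] = transmitted
                    truth["detected"][comp][sid] = detected
                    meta_rows.append(
                        {"sample-id": sid, "species": sp, "location": loc,
                         "compartment": comp, "block": b}
                    )
        tables[comp] = FeatureTable(root_feature_ids, samples, np.column_stack(cols))

    meta_df = pd.DataFrame(meta_rows).set_index("sample-id")
    metadata = SampleMetadata(meta_df)

    env = None
    if spec.make_env:
        env = _make_env(rng, metadata, spec)

    return SyntheticDataset(
        tables=tables, taxonomy=taxonomy, metadata=metadata, truth=truth,
        env=env, spec=spec,
    )


_ENV_VARS = ("NH4", "NO3", "C", "N", "S", "C:N", "WC")


def _make_env(rng: np.random.Generator, metadata: SampleMetadata, spec: SyntheticSpec) -> EnvTable:
    """Synthetic soil chemistry: location-specific baselines plus noise.

    Covers rhizosphere and bulk samples only (the compartments whose soil is
    assayed in the field).
    """
    baselines = {
        loc: {v: float(rng.normal(10.0, 3.0)) for v in _ENV_VARS}
        for loc in spec.locations
    }
    rows = {}
    for sid in metadata.sample_ids:
        rec = metadata.get(sid)
        if rec["compartment"] not in ("rhizosphere", "bulk"):
            continue
        loc = rec["location"]
        rows[sid] = {
            v: baselines[loc][v] + float(rng.normal(0.0, 1.0)) for v in _ENV_VARS
        }
    return EnvTable(pd.DataFrame.from_dict(rows, orient="index"))


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write all tables, taxonomy, metadata, env and truth.json; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for comp, t in ds.tables.items():
        p = outdir / f"table.{comp}.tsv"
        write_feature_table(t, p)
        paths[f"table.{comp}"] = str(p)
    write_taxonomy(ds.taxonomy, outdir / "taxonomy.tsv")
    paths["taxonomy"] = str(outdir / "taxonomy.tsv")
    write_metadata(ds.metadata, outdir / "metadata.tsv")
    paths["metadata"] = str(outdir / "metadata.tsv")
    if ds.env is not None:
        write_env_table(ds.env, outdir / "env.tsv")
        paths["env"] = str(outdir / "env.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
    paths["truth"] = str(outdir / "truth.json")
    return paths
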