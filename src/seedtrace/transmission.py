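"""Tracing seed ASVs into root compartments with seedbed-background exclusion.

A seed ASV counts as *transmitted* into a root-associated replicate when it is
detected (count >= 1) in the species' seed pool, detected in the target
sample, and its genus is absent from every seedbed replicate of that location
— the background-exclusion rule that keeps ubiquitous soil genera from
masquerading as vertical transmission.  Sharing is assessed at ASV level,
exclusion at genus level.

The per-replicate transmission proportion is the seed-read mass accounted for
by the re-detected ASVs:

    proportion = sum(seed counts of transmitted ASVs) / sum(all seed counts),

a fraction in [0, 1]; the replicate median is the headline statistic.  A
sensitivity variant weighting by target-sample counts is available behind
``numerator="target"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .posthoc import anova_tukey
from .tables import FeatureTable, SampleMetadata, TaxonomyMap, subset

__all__ = [
    "TransmissionResult",
    "transmitted_set",
    "transmission_proportion",
    "transmission_summary",
    "species_specific_transmitted",
]


@dataclass
class TransmissionResult:
    """Transmission outcome for one species x location x target compartment."""

    species: str
    location: str
    target_compartment: str
    replicate_samples: list[str]
    transmitted_asvs: dict  # sample id -> set of ASV ids
    proportion_per_replicate: dict  # sample id -> fraction
    median_proportion: float
    group_letters: str = ""  # across species within location (letters)
    location_letters: str = ""  # across locations within species

    def __post_init__(self) -> None:
        for v in self.proportion_per_replicate.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError("transmission proportions must lie in [0, 1]")


def seedbed_genera(seedbed_t: FeatureTable, tax: TaxonomyMap) -> set[str]:
    """Genus labels detected in any seedbed replicate (union rule)."""
    return {tax.genus(f) for f in seedbed_t.detected_features()}


def transmitted_set_excluding(
    seed_detected: set[str],
    target_detected: set[str],
    excluded_genera: set[str],
    tax: TaxonomyMap,
) -> set[str]:
    """Core set rule: shared ASVs whose genus is not in the excluded set."""
    return {
        a
        for a in seed_detected & target_detected
        if tax.genus(a) not in excluded_genera
    }


def transmitted_set(
    seed_t: FeatureTable,
    target_t: FeatureTable,
    target_sample: str,
    seedbed_t: FeatureTable,
    tax: TaxonomyMap,
) -> set[str]:
    """Seed ASVs re-detected in ``target_sample``, seedbed genera excluded.

    ``seed_t`` holds the seed pool of one species; ``seedbed_t`` holds every
    seedbed replicate of the target sample's location.
    """
    if seedbed_t.shape[1] == 0:
        raise ValueError("no seedbed samples for this location: exclusion rule cannot be applied")
    return transmitted_set_excluding(
        seed_t.detected_features(),
        target_t.detected_features(target_sample),
        seedbed_genera(seedbed_t, tax),
        tax,
    )


def transmission_proportion(
    seed_t: FeatureTable,
    transmitted: Iterable[str],
    target_counts: Mapping[str, int] | None = None,
    numerator: str = "seed",
) -> float:
    """Fraction of seed-read mass carried by re-detected ASVs.

    With ``numerator="seed"`` (default) the numerator sums SEED counts of the
    transmitted ASVs, giving a fraction of the seed community accounted for.
    ``numerator="target"`` sums target-sample counts instead (sensitivity
    analysis; no longer bounded by 1 relative to the seed total, so it is
    normalised by the target total supplied via ``target_counts``).
    """
    transmitted = set(transmitted)
    seed_totals = {
        f: int(c) for f, c in zip(seed_t.feature_ids, seed_t.counts.sum(axis=1))
    }
    detected = {f for f, c in seed_totals.items() if c >= 1}
    extra = transmitted - set(seed_t.feature_ids)
    if extra:
        raise ValueError(f"transmitted ASVs not in seed table: {sorted(extra)[:3]}")
    denom = sum(seed_totals[f] for f in detected)
    if denom == 0:
        raise ValueError("seed table has zero total count")
    if numerator == "seed":
        num = sum(seed_totals[f] for f in transmitted)
        return num / denom
    if numerator == "target":
        if target_counts is None:
            raise ValueError("numerator='target' requires target_counts")
        tot = sum(target_counts.values())
        if tot == 0:
            raise ValueError("target sample has zero total count")
        return sum(target_counts.get(f, 0) for f in transmitted) / tot
    raise ValueError(f"unknown numerator mode {numerator!r}")


def _median(values: list[float]) -> float:
    return float(np.median(values)) if values else 0.0


def transmission_summary(
    tables: Mapping[str, FeatureTable],
    metadata: SampleMetadata,
    tax: TaxonomyMap,
    target_compartments: tuple[str, ...] = ("endorhiza", "rhizosphere"),
    alpha: float = 0.05,
    numerator: str = "seed",
) -> list[TransmissionResult]:
    """Per species x location x target compartment transmission proportions.

    Accepts the dict of compartment tables produced by the generator (or a
    :class:`~seedtrace.simulate.SyntheticDataset`).  Compact-letter displays
    are attached twice: across species within each location x compartment
    (``group_letters``) and across locations within each species x
    compartment (``location_letters``).
    """
    if hasattr(tables, "tables"):  # SyntheticDataset convenience
        ds = tables
        metadata = ds.metadata if metadata is None else metadata
        tax = ds.taxonomy if tax is None else tax
        tables = ds.tables
    for needed in ("seed", "seedbed") + tuple(target_compartments):
        if needed not in tables:
            raise ValueError(f"missing compartment table {needed!r}")

    species = metadata.levels("species")
    locations = metadata.levels("location")
    results: list[TransmissionResult] = []
    for sp in species:
        seed_samples = metadata.select(species=sp, compartment="seed")
        if not seed_samples:
            continue
        seed_t = tables["seed"].select_samples(seed_samples)
        seed_detected = seed_t.detected_features()
        for loc in locations:
            sb_samples = metadata.select(location=loc, compartment="seedbed")
            if not sb_samples:
                raise ValueError(f"no seedbed samples for location {loc!r}")
            sb_t = tables["seedbed"].select_samples(sb_samples)
            excluded = seedbed_genera(sb_t, tax)
            for comp in target_compartments:
                reps = metadata.select(species=sp, location=loc, compartment=comp)
                if not reps:
                    continue
                target_t = tables[comp]
                trans: dict[str, set[str]] = {}
                props: dict[str, float] = {}
                for sid in reps:
                    tset = transmitted_set_excluding(
                        seed_detected,
                        target_t.detected_features(sid),
                        excluded,
                        tax,
                    )
                    trans[sid] = tset
                    tc = None
                    if numerator == "target":
                        tc = dict(zip(target_t.feature_ids, target_t.column(sid)))
                    props[sid] = transmission_proportion(
                        seed_t, tset, target_counts=tc, numerator=numerator
                    )
                results.append(
                    TransmissionResult(
                        species=sp,
                        location=loc,
                        target_compartment=comp,
                        replicate_samples=list(reps),
                        transmitted_asvs=trans,
                        proportion_per_replicate=props,
                        median_proportion=_median(list(props.values())),
                    )
                )

    # compact letters: species within (location, compartment)
    _attach_letters(
        results,
        key=lambda r: (r.location, r.target_compartment),
        group=lambda r: r.species,
        setter=lambda r, s: setattr(r, "group_letters", s),
        alpha=alpha,
    )
    # compact letters: locations within (species, compartment)
    _attach_letters(
        results,
        key=lambda r: (r.species, r.target_compartment),
        group=lambda r: r.location,
        setter=lambda r, s: setattr(r, "location_letters", s),
        alpha=alpha,
    )
    return results


def _attach_letters(results, key, group, setter, alpha) -> None:
    by_key: dict = {}
    for r in results:
        by_key.setdefault(key(r), []).append(r)
    for _, members in by_key.items():
        groups = {
            group(r): list(r.proportion_per_replicate.values()) for r in members
        }
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            for r in members:
                setter(r, "a")
            continue
        res = anova_tukey(groups, alpha=alpha)
        for r in members:
            setter(r, res.letters[group(r)])


def species_specific_transmitted(
    results: list[TransmissionResult],
    tax: TaxonomyMap,
    min_locations: int = 2,
) -> dict[str, dict[str, list[str]]]:
    """Genus-level taxa transmitted for exactly one species in >= 2 locations.

    Returns ``{species: {compartment: [genus, ...]}}``.  A genus qualifies for
    a species (within a compartment) when it appears in that species'
    transmitted sets in at least ``min_locations`` distinct locations and in
    no other species' transmitted sets anywhere.
    """
    locations = {r.location for r in results}
    if len(locations) < min_locations:
        raise ValueError(f"need results for at least {min_locations} locations")
    # genus -> compartment -> species -> set of locations
    seen: dict[str, dict[str, dict[str, set[str]]]] = {}
    for r in results:
        for tset in r.transmitted_asvs.values():
            for a in tset:
                g = tax.genus(a)
                seen.setdefault(g, {}).setdefault(r.target_compartment, {}).setdefault(
                    r.species, set()
                ).add(r.location)
    out: dict[str, dict[str, list[str]]] = {}
    for g, by_comp in seen.items():
        for comp, by_sp in by_comp.items():
            if len(by_sp) != 1:
                continue
            (sp, locs), = by_sp.items()
            if len(locs) >= min_locations:
                out.setdefault(sp, {}).setdefault(comp, []).append(g)
    for sp in out:
        for comp in out[sp]:
            out[sp][comp] = sorted(out[sp][comp])
    return out


def summary_frame(results: list[TransmissionResult]) -> pd.DataFrame:
    """Long-format per-replicate table (for TSV export)."""
    rows = []
    for r in results:
        for sid in r.replicate_samples:
            rows.append(
                {
                    "species": r.species,
                    "location": r.location,
                    "compartment": r.target_compartment,
                    "replicate": sid,
                    "proportion": r.proportion_per_replicate[sid],
                    "n_transmitted_asvs": len(r.transmitted_asvs[sid]),
                }
            )
    return pd.DataFrame(rows)


def medians_frame(results: list[TransmissionResult]) -> pd.DataFrame:
    rows = [
        {
            "species": r.species,
            "location": r.location,
            "compartment": r.target_compartment,
            "median_proportion": r.median_proportion,
            "species_letters": r.group_letters,
            "location_letters": r.location_letters,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
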