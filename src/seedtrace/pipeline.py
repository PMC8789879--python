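"""End-to-end orchestration: simulate -> diversity -> ordination/tests ->
transmission -> enrichment, driven by one config with deterministic seeding.

Stages communicate only through written TSV/JSON artifacts; the run manifest
records every output file with a sha256 checksum plus the config snapshot, so
re-running the same config reproduces the manifest byte for byte.  Bacterial
and fungal datasets are treated as independent runs of the same pipeline
differing only in the core-prevalence default (0.85 vs 0.75).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition, diversity, enrichment, simulate, transmission
from .tables import (
    EnvTable,
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    merge_tables,
    read_env_table,
    read_feature_table,
    read_metadata,
    read_taxonomy,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; serialisable to/from YAML."""

    output_dir: str = "seedtrace_out"
    seed: int = 0
    # either simulate (dict of SyntheticSpec overrides) or input paths
    simulate: dict | None = field(default_factory=dict)
    input_dir: str | None = None
    rank: str = "genus"
    pseudocount: float = 0.5
    rarefaction_depth: int | None = None  # None -> min sample total
    n_rarefactions: int = 10
    n_permutations: int = 999
    n_mc: int = 128
    core_threshold: float = 0.85  # 0.85 bacteria, 0.75 fungi
    detection: float = 0.0
    effect_threshold: float = 1.0
    rda_variable: str | None = "NH4"

    def __post_init__(self) -> None:
        if not 0.0 < self.core_threshold <= 1.0:
            raise ValueError("core_threshold must lie in (0, 1]")
        if self.effect_threshold <= 0:
            raise ValueError("effect_threshold must be positive")
        if self.simulate is None and self.input_dir is None:
            raise ValueError("config needs either a simulate spec or an input_dir")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def snapshot(self) -> dict:
        d = asdict(self)
        d["output_dir"] = "."  # path-independent manifest
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig):
    indir = Path(cfg.input_dir)
    tables = {}
    for comp in ("seed", "seedbed", "bulk", "rhizosphere", "endorhiza"):
        p = indir / f"table.{comp}.tsv"
        if p.exists():
            tables[comp] = read_feature_table(p)
    tax = read_taxonomy(indir / "taxonomy.tsv")
    meta = read_metadata(indir / "metadata.tsv")
    env = None
    if (indir / "env.tsv").exists():
        env = read_env_table(indir / "env.tsv")
    return tables, tax, meta, env


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; return the manifest (also written to manifest.json)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=index, float_format="%.10g")
        files.append(p)

    # -- stage 0: data ------------------------------------------------------
    if cfg.simulate is not None:
        spec_kwargs = dict(cfg.simulate)
        spec_kwargs.setdefault("rng_seed", cfg.seed)
        spec = simulate.SyntheticSpec(**spec_kwargs)
        ds = simulate.generate(spec)
        paths = simulate.write_dataset(ds, out / "data")
        files.extend(Path(p) for p in paths.values())
        tables, tax, meta, env = ds.tables, ds.taxonomy, ds.metadata, ds.env
    else:
        tables, tax, meta, env = _load_inputs(cfg)

    master = merge_tables(tables.values(), allow_empty=True)
    msamples = [s for s in master.sample_ids]
    labels = {s: meta.get(s) for s in msamples}

    # -- stage 1: alpha diversity -------------------------------------------
    totals = master.sample_totals()
    depth = cfg.rarefaction_depth or int(totals[totals > 0].min())
    log.info("rarefaction depth %d", depth)
    alpha = diversity.alpha_indices(
        master, depth=depth, n_rarefactions=cfg.n_rarefactions, seed=cfg.seed
    )
    adf = alpha.frame.copy()
    adf.index.name = "sample-id"
    emit(adf, "alpha_diversity.tsv", index=True)
    kw_rows = []
    for factor in ("compartment", "location", "species"):
        groups: dict[str, list[float]] = {}
        for s in alpha.frame.index:
            lev = labels[s][factor]
            if lev is None:
                continue
            groups.setdefault(lev, []).append(float(alpha.frame.loc[s, "shannon"]))
        if len(groups) >= 2 and all(len(v) >= 1 for v in groups.values()):
            kw = diversity.kruskal_wallis(groups)
            kw_rows.append({"factor": factor, "index": "shannon", **kw})
    emit(pd.DataFrame(kw_rows), "kruskal_wallis.tsv")

    # -- stage 2: composition ------------------------------------------------
    clr = composition.clr_transform(master, pseudocount=cfg.pseudocount)
    dist = composition.aitchison_distance(clr)
    ddf = pd.DataFrame(dist.data, index=dist.sample_ids, columns=dist.sample_ids)
    ddf.index.name = "sample-id"
    emit(ddf, "aitchison_distance.tsv", index=True)
    ord_res = composition.pca(clr)
    sdf = pd.DataFrame(
        ord_res.scores[:, : min(5, ord_res.scores.shape[1])],
        index=ord_res.sample_ids,
        columns=[f"PC{i+1}" for i in range(min(5, ord_res.scores.shape[1]))],
    )
    sdf.index.name = "sample-id"
    emit(sdf, "pca_scores.tsv", index=True)

    perm_rows, disp_rows = [], []
    for factor in ("compartment", "location"):
        lab = [labels[s][factor] for s in msamples]
        keep = [i for i, l in enumerate(lab) if l is not None]
        if len({lab[i] for i in keep}) < 2:
            continue
        sub_ids = [msamples[i] for i in keep]
        sub_d = dist.reorder(sub_ids)
        sub_lab = [lab[i] for i in keep]
        pr = composition.permanova(
            sub_d, sub_lab, n_permutations=cfg.n_permutations, seed=cfg.seed
        )
        perm_rows.append(
            {"factor": factor, "pseudo_F": pr.pseudo_F, "R2": pr.R2, "p": pr.p,
             "n_permutations": pr.n_permutations}
        )
        dr = composition.dispersion_test(
            sub_d, sub_lab, n_permutations=cfg.n_permutations, seed=cfg.seed
        )
        disp_rows.append({"factor": factor, "F": dr.F, "p": dr.p})
    emit(pd.DataFrame(perm_rows), "permanova.tsv")
    emit(pd.DataFrame(disp_rows), "dispersion.tsv")

    if env is not None and cfg.rda_variable:
        env_samples = [s for s in msamples if s in env.frame.index]
        sub = master.select_samples(env_samples)
        sub_clr = composition.clr_transform(sub, pseudocount=cfg.pseudocount)
        rda_rows = []
        for var in env.variables:
            r = composition.rda_marginal_test(
                sub_clr, env, var, n_permutations=cfg.n_permutations, seed=cfg.seed
            )
            rda_rows.append({"variable": var, **r})
        emit(pd.DataFrame(rda_rows), "rda.tsv")

    # -- stage 3: transmission ----------------------------------------------
    results = transmission.transmission_summary(tables, meta, tax)
    emit(transmission.summary_frame(results), "transmission_replicates.tsv")
    emit(transmission.medians_frame(results), "transmission_medians.tsv")
    try:
        specific = transmission.species_specific_transmitted(results, tax)
    except ValueError:
        specific = {}
    spec_rows = [
        {"species": sp, "compartment": comp, "genus": g}
        for sp, by_comp in sorted(specific.items())
        for comp, genera in sorted(by_comp.items())
        for g in genera
    ]
    emit(pd.DataFrame(spec_rows, columns=["species", "compartment", "genus"]),
         "species_specific_transmitted.tsv")

    # -- stage 4: enrichment -------------------------------------------------
    species = meta.levels("species")
    locations = meta.levels("location")
    enr_rows = []
    enriched_sets: dict[tuple[str, str], set[str]] = {}
    for sp in species:
        for loc in locations:
            try:
                eset, table = enrichment.enriched_in_rhizosphere(
                    tables, meta, tax, sp, loc,
                    prevalence_threshold=cfg.core_threshold,
                    detection=cfg.detection,
                    threshold=cfg.effect_threshold,
                    n_mc=cfg.n_mc,
                    seed=cfg.seed,
                )
            except Exception:  # missing compartment for this combination
                continue
            enriched_sets[(sp, loc)] = eset
            for _, row in table.iterrows():
                enr_rows.append({"species": sp, "location": loc, **row.to_dict()})
    emit(pd.DataFrame(enr_rows), "enrichment.tsv")
    share_rows = []
    for couple in simulate.RELATED_COUPLES:
        a, b = couple
        for loc in locations:
            if (a, loc) in enriched_sets and (b, loc) in enriched_sets:
                part = enrichment.shared_enrichment(
                    enriched_sets[(a, loc)], enriched_sets[(b, loc)]
                )
                share_rows.append(
                    {"species_a": a, "species_b": b, "location": loc,
                     "shared": ",".join(sorted(part["shared"])),
                     "only_a": ",".join(sorted(part["only_a"])),
                     "only_b": ",".join(sorted(part["only_b"]))}
                )
    emit(pd.DataFrame(share_rows,
                      columns=["species_a", "species_b", "location",
                               "shared", "only_a", "only_b"]),
         "shared_enrichment.tsv")

    # -- manifest ------------------------------------------------------------
    manifest = {
        "config": cfg.snapshot(),
        "files": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(files))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
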