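"""Config-driven orchestration of the full analysis.

Stages run in dependency order: simulate (or load) inputs -> nucleus QC
-> marker detection -> signatures + spot deconvolution -> FAPs-high/low
region delineation and region DE -> breed contrasts -> secretory screen
-> gene-set enrichment -> random-region correlation.  One global seed
deterministically derives per-stage seeds (stage-name hashing), every
output is written with deterministic bytes, and a machine-readable
manifest records each stage's parameters, seed and outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from .deconv_regions import RegionParams, build_signatures, classify_regions, deconvolve_spots, region_de
from .markers_de import DEParams, de_between_groups, find_markers
from .niche_correlation import (
    CorrelationParams,
    RegionProfiles,
    correlate_gene_sets,
    sample_regions,
    spatial_aggregation_map,
)
from .qc_norm import QCParams, drop_out_of_tissue, filter_matrix, normalize_log_cpm
from .secretome_enrich import LocationTable, annotate_secretory, hypergeom_enrich, screen_comparisons
from .synthdata import ReferenceSpec, SpatialSpec, StudySpec, simulate_study
from .types import CountMatrix, records_to_frame

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "derive_stage_seed"]

logger = logging.getLogger("spatniche")

DEFAULT_TARGETS = ("MYH7", "MYH1", "IRS1", "SLC38A2", "GLUL", "PLPP1")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "spatniche_out"
    log_level: str = "INFO"
    synthetic: dict = field(default_factory=dict)  # StudySpec overrides; {} = defaults
    samples: dict = field(default_factory=lambda: {"TB": "TB", "Duroc": "Duroc"})
    qc: QCParams = field(default_factory=QCParams)
    de: DEParams = field(default_factory=DEParams)
    regions: RegionParams = field(default_factory=RegionParams)
    correlation: CorrelationParams = field(default_factory=CorrelationParams)
    targets: tuple = DEFAULT_TARGETS
    top_k_markers: int = 25

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["targets"] = list(self.targets)
        return d


_SECTION_TYPES = {
    "qc": QCParams,
    "de": DEParams,
    "regions": RegionParams,
    "correlation": CorrelationParams,
}
_SCALAR_KEYS = {"seed", "out_dir", "log_level", "samples", "targets", "top_k_markers", "synthetic"}

_SYNTHETIC_KEYS = {f.name for f in dataclasses.fields(ReferenceSpec)} | {
    "spatial",
    "sample_conditions",
    "secreted_fraction",
    "condition_effects",
}


def _build_section(cls, values: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    return cls(**values)


def validate_config(source) -> PipelineConfig:
    """Load and validate a YAML/JSON config file (or dict); unknown keys error."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _SCALAR_KEYS - set(_SECTION_TYPES)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for key in _SCALAR_KEYS:
        if key in raw:
            kwargs[key] = raw[key]
    if "targets" in kwargs:
        kwargs["targets"] = tuple(kwargs["targets"])
    if "synthetic" in kwargs:
        bad = set(kwargs["synthetic"]) - _SYNTHETIC_KEYS
        if bad:
            raise ConfigError(f"unknown key(s) in section 'synthetic': {sorted(bad)}")
    for key, cls in _SECTION_TYPES.items():
        if key in raw:
            kwargs[key] = _build_section(cls, dict(raw[key]), key)
    try:
        cfg = PipelineConfig(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
    if not isinstance(cfg.seed, int):
        raise ConfigError("seed must be an integer")
    return cfg


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _study_spec_from_config(cfg: PipelineConfig) -> StudySpec:
    synth = dict(cfg.synthetic)
    spatial_over = synth.pop("spatial", {})
    sample_conditions = synth.pop("sample_conditions", None)
    secreted_fraction = synth.pop("secreted_fraction", 0.1)
    condition_effects = synth.pop("condition_effects", None)
    ref_kwargs = {k: v for k, v in synth.items()}
    ref_kwargs["seed"] = 0  # study seed drives everything
    spec_kwargs = {
        "reference": ReferenceSpec(**ref_kwargs),
        "secreted_fraction": secreted_fraction,
        "seed": derive_stage_seed(cfg.seed, "simulate"),
    }
    if condition_effects is not None:
        spec_kwargs["condition_effects"] = condition_effects
    spec = StudySpec(**spec_kwargs)
    if sample_conditions:
        spec.sample_conditions = dict(sample_conditions)
    for sid, over in spatial_over.items():
        base = spec.spatial[sid].__dict__ | dict(over)
        spec.spatial[sid] = SpatialSpec(**base)
    return spec


def _signed_secreted_sets(records) -> dict:
    """Signed secreted DEG sets; genes with conflicting directions (possible
    when records from several samples are pooled) are dropped as non-robust."""
    up = {r.gene_id for r in records if r.passes_filter and r.secreted and r.direction == "up"}
    down = {r.gene_id for r in records if r.passes_filter and r.secreted and r.direction == "down"}
    conflicted = up & down
    return {"up": up - conflicted, "down": down - conflicted}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to out_dir)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": cfg.seed}
    iof.write_json(cfg.to_dict(), out / "config_echo.json")

    def _rel(o):
        try:
            return str(Path(o).relative_to(out))
        except ValueError:
            return str(o)

    def record_stage(name, outputs, params=None, seed=None):
        manifest["stages"].append(
            {
                "name": name,
                "outputs": [_rel(o) for o in outputs],
                "params": params or {},
                "seed": seed,
            }
        )
        iof.write_json(manifest, out / "manifest.json")

    current = "simulate"
    try:
        # ---------------- simulate ----------------------------------
        spec = _study_spec_from_config(cfg)
        study = simulate_study(spec)
        fx = out / "fixtures"
        iof.write_counts_10x(study.reference, fx / "reference")
        iof.write_labels(study.labels, fx / "labels.tsv")
        iof.write_labels(study.conditions, fx / "conditions.tsv")
        iof.write_locations(study.locations, fx / "locations.tsv")
        iof.write_gmt(study.gene_sets, fx / "genesets.gmt")
        for sid, (m, geom, truth) in study.spatial.items():
            iof.write_counts_10x(m, fx / sid)
            iof.write_tissue_positions(geom, fx / sid / "tissue_positions.csv")
            truth.proportions.round(10).to_csv(fx / sid / "true_proportions.tsv", sep="\t")
        iof.write_json(
            {"rho": {f"{a}|{b}": r for (a, b), r in study.truth.rho.items()}},
            fx / "truth.json",
        )
        record_stage("simulate", [fx], params={"seed": spec.seed}, seed=spec.seed)

        # ---------------- qc ----------------------------------------
        current = "qc"
        ref_f, report = filter_matrix(study.reference, cfg.qc)
        labels_f = study.labels.reindex(ref_f.obs_ids)
        cond_f = study.conditions.reindex(ref_f.obs_ids)
        iof.write_json(report.to_dict(), out / "qc_report.json")
        record_stage("qc", [out / "qc_report.json"], params=dataclasses.asdict(cfg.qc))

        # ---------------- markers -----------------------------------
        current = "markers"
        expr = normalize_log_cpm(ref_f)
        marker_records = find_markers(expr, labels_f.to_numpy(), cfg.de, gene_ids=ref_f.gene_ids)
        iof.write_table(records_to_frame(marker_records), out / "markers.tsv", sort_by=["group", "gene_id"])
        record_stage("markers", [out / "markers.tsv"], params=dataclasses.asdict(cfg.de))

        # ---------------- signatures + deconvolution ----------------
        current = "deconvolution"
        sig = build_signatures(ref_f, labels_f, top_k_markers=cfg.top_k_markers, de_params=cfg.de)
        spatial_clean, prop_maps, geoms = {}, {}, {}
        outputs = []
        for sid, (m, geom, _t) in study.spatial.items():
            m2 = drop_out_of_tissue(m, geom)
            pm = deconvolve_spots(m2, sig)
            spatial_clean[sid] = m2
            prop_maps[sid] = pm
            geoms[sid] = geom
            path = out / f"proportions_{sid}.tsv"
            iof.write_table(pm.to_frame(), path, sort_by=["barcode"])
            outputs.append(path)
        record_stage("deconvolution", outputs, params={"top_k_markers": cfg.top_k_markers})

        # ---------------- regions + region DE -----------------------
        current = "regions"
        loc_table = LocationTable(study.locations)
        region_labels, region_des = {}, {}
        outputs = []
        for sid, pm in prop_maps.items():
            lab = classify_regions(pm, geoms[sid], cfg.regions)
            region_labels[sid] = lab
            path = out / f"regions_{sid}.tsv"
            iof.write_labels(lab, path)
            outputs.append(path)
            high = lab.index[lab == "high"]
            low = lab.index[lab == "low"]
            de_params = dataclasses.replace(cfg.de, test="wilcoxon")
            recs = annotate_secretory(
                region_de(spatial_clean[sid], high, low, de_params), loc_table
            )
            region_des[sid] = recs
            path = out / f"de_regions_{sid}.tsv"
            iof.write_table(records_to_frame(recs), path, sort_by=["gene_id"])
            outputs.append(path)
        record_stage("regions", outputs, params=dataclasses.asdict(cfg.regions))

        # ---------------- breed contrasts ----------------------------
        current = "breed_de"
        # (a) spatial: condition contrast restricted to FAPs-high spots
        sids = sorted(spatial_clean)
        # contrast direction follows the config's sample order (first condition
        # listed is the numerator of the fold change)
        conds = list(dict.fromkeys(cfg.samples[s] for s in cfg.samples))
        breed_spatial_recs = []
        if len(conds) == 2:
            import scipy.sparse as sp

            parts, labels_parts = [], []
            for sid in sids:
                lab = region_labels[sid]
                high = lab.index[lab == "high"]
                m2 = spatial_clean[sid]
                pos = {b: i for i, b in enumerate(m2.obs_ids)}
                rows = np.array([pos[b] for b in high if b in pos])
                parts.append(m2.subset_obs(rows))
                labels_parts.extend([cfg.samples[sid]] * len(rows))
            merged = CountMatrix(
                values=sp.vstack([p.values for p in parts]).tocsr(),
                obs_ids=np.concatenate([p.obs_ids for p in parts]),
                gene_ids=parts[0].gene_ids,
                gene_names=parts[0].gene_names,
                obs_kind="spot",
                sample_id="merged_high",
            )
            de_params = dataclasses.replace(cfg.de, test="wilcoxon")
            breed_spatial_recs = annotate_secretory(
                de_between_groups(merged, np.array(labels_parts, dtype=object), de_params,
                                  groups=(conds[0], conds[1])),
                loc_table,
            )
            iof.write_table(
                records_to_frame(breed_spatial_recs), out / "de_breed_faps_high.tsv", sort_by=["gene_id"]
            )
        # (b) snRNA-seq: condition contrast within FAPs nuclei
        breed_snrna_recs = []
        fap_mask = labels_f.to_numpy() == cfg.regions.target_celltype
        if fap_mask.sum() and len(set(cond_f[fap_mask])) == 2:
            fap_m = ref_f.subset_obs(np.where(fap_mask)[0])
            de_params = dataclasses.replace(cfg.de, test="nb_wald")
            breed_snrna_recs = annotate_secretory(
                de_between_groups(fap_m, cond_f[fap_mask].to_numpy(), de_params,
                                  groups=(conds[0], conds[1]) if len(conds) == 2 else None),
                loc_table,
            )
            iof.write_table(
                records_to_frame(breed_snrna_recs), out / "de_breed_faps_snrna.tsv", sort_by=["gene_id"]
            )
        record_stage(
            "breed_de",
            [out / "de_breed_faps_high.tsv", out / "de_breed_faps_snrna.tsv"],
        )

        # ---------------- secretory screen ---------------------------
        current = "screen"
        pooled_region_recs = [r for recs in region_des.values() for r in recs]
        comparisons = {
            "breed_faps_high_region": _signed_secreted_sets(breed_spatial_recs),
            "faps_high_vs_low_region": _signed_secreted_sets(pooled_region_recs),
            "breed_faps_snrna": _signed_secreted_sets(breed_snrna_recs),
        }
        comparisons = {k: v for k, v in comparisons.items() if v["up"] | v["down"]}
        screen = None
        if len(comparisons) >= 2:
            screen = screen_comparisons(comparisons)
            iof.write_json(
                {
                    "counts": screen.counts,
                    "common": sorted(screen.common),
                    "common_direction_consistent": sorted(screen.common_direction_consistent),
                    "unique": {k: sorted(v) for k, v in screen.unique.items()},
                },
                out / "screen.json",
            )
        record_stage("screen", [out / "screen.json"])

        # ---------------- enrichment ---------------------------------
        current = "enrichment"
        universe = [str(g) for g in next(iter(spatial_clean.values())).gene_ids]
        up_region = sorted(
            {r.gene_id for r in pooled_region_recs if r.passes_filter and r.direction == "up"}
        )
        enr = hypergeom_enrich(up_region, universe, study.gene_sets) if up_region else []
        iof.write_table(records_to_frame(enr), out / "enrichment_regions.tsv", sort_by=["set_name"])
        record_stage("enrichment", [out / "enrichment_regions.tsv"])

        # ---------------- niche correlation --------------------------
        current = "nichecorr"
        corr_seed = derive_stage_seed(cfg.seed, "nichecorr")
        parts = []
        for k, sid in enumerate(sids):
            parts.append(
                sample_regions(
                    geoms[sid],
                    spatial_clean[sid],
                    cfg.correlation,
                    sample_id=sid,
                    seed=corr_seed + k,
                )
            )
        profiles = RegionProfiles.concat(parts)
        screened = set()
        for recs in (breed_spatial_recs, pooled_region_recs, breed_snrna_recs):
            screened |= {r.gene_id for r in recs if r.passes_filter and r.secreted}
        set_a = sorted(screened) or sorted(
            g for g, locs in study.locations.items() if any("secreted" in l.lower() for l in locs)
        )
        set_b = [t for t in cfg.targets if t in set(map(str, profiles.gene_ids))]
        corr = correlate_gene_sets(
            profiles, set_a, set_b, cfg.correlation, sample_conditions=cfg.samples
        )
        iof.write_table(records_to_frame(corr), out / "correlations.tsv", sort_by=["gene_a", "gene_b"])
        regions_frame = pd.DataFrame(
            {
                "region_id": [r.region_id for r in profiles.regions],
                "sample": [r.sample_id for r in profiles.regions],
                "seed_spot": [r.seed_spot for r in profiles.regions],
                "members": ["|".join(r.members) for r in profiles.regions],
            }
        )
        iof.write_table(regions_frame, out / "regions_sampled.tsv", sort_by=["region_id"])
        defined = [r for r in corr if r.defined]
        outputs = [out / "correlations.tsv", out / "regions_sampled.tsv"]
        if defined:
            top = max(defined, key=lambda r: abs(r.r))
            for sid in sids:
                agg = spatial_aggregation_map(spatial_clean[sid], geoms[sid], (top.gene_a, top.gene_b))
                path = out / f"aggregation_{sid}.tsv"
                iof.write_table(agg, path, sort_by=["barcode"])
                outputs.append(path)
        record_stage(
            "nichecorr", outputs, params=dataclasses.asdict(cfg.correlation), seed=corr_seed
        )
    except Exception as exc:
        manifest["checkpoint"] = {
            "failed_stage": current,
            "completed_stages": [s["name"] for s in manifest["stages"]],
            "error": str(exc),
        }
        iof.write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest["status"] = "complete"
    iof.write_json(manifest, out / "manifest.json")
    return manifest
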