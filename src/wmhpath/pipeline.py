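"""End-to-end orchestration: generate -> quantify -> score -> analyze.

The pipeline reproduces the study's measurement chain on a synthetic
cohort.  A Gaussian-copula cohort fixes each case's regional ground truth
(tau and amyloid burden, vessel-wall sclerosis, WMH severity); the
generators render per-location IHC montages, per-vessel H&E fields and
regional lesion masks from that truth; the measurement modules then read
the rendered inputs back and the statistics stage runs the group
contrasts, age-controlled partial correlations and stepwise regressions
on the *measured* values.

All randomness descends from one root seed, split deterministically per
stage and per case, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, io_utils, synthgen, wmh_rating
from .cohort_stats import mann_whitney_u, partial_corr, pooled_t_from_samples, route_test, stepwise_forward
from .ihc_quant import DEFAULT_THRESHOLDS, REGION_SECTIONS, aggregate_case, default_sampling_plan, quantify
from .synthgen import CohortConfig, IHCSceneSpec, LesionSceneSpec, VesselSceneSpec, pixel_size_for_field
from .vessel_morphometry import VESSELS_PER_BLOCK, aggregate_si, measure_vessel

log = logging.getLogger("wmhpath")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "make_demo_dataset"]

#: white-matter blocks sampled for vessel morphometry; the two frontal
#: blocks pool into the frontal region downstream
VESSEL_BLOCKS = ("prefrontal", "midfrontal", "temporal", "parietal", "occipital")
_BLOCK_REGION = {"prefrontal": "frontal", "midfrontal": "frontal",
                 "temporal": "temporal", "parietal": "parietal", "occipital": "occipital"}

#: image-generation cap on the per-location positive-area target; keeps the
#: painter inside its packing limit for extreme synthetic burdens
_MAX_TARGET_FRACTION = 0.10


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    outdir: str = "wmhpath_run"
    seed: int = 0
    n_cases: int = 36
    prop_ad: float = 23.0 / 36.0
    tile_px: int = 96                # demo acquisition tile; field area is held at 1.7 mm^2
    markers: tuple[str, ...] = ("AT8", "4G8")
    vessel_pixel_size: float = 2.0   # um/px for rendered vessel fields
    lesion_px_per_mm: float = 4.0
    lesion_field_mm: float = 80.0
    parieto_occipital_mode: str = "max"
    stepwise_entry_p: float = 0.05
    stepwise_removal_p: float = 0.10

    def validate(self) -> None:
        if self.n_cases < 8:
            # the stepwise stage fits up to 4 candidates plus an intercept
            raise ValueError("n_cases must be >= 8 for the statistics stage")
        if not self.markers:
            raise ValueError("config must name at least one marker/threshold spec")
        for m in self.markers:
            if m not in DEFAULT_THRESHOLDS:
                raise ValueError(f"no threshold spec for marker '{m}'")
        if not 0 < self.prop_ad < 1:
            raise ValueError("prop_ad must be strictly between 0 and 1")
        if not self.stepwise_entry_p < self.stepwise_removal_p:
            raise ValueError("stepwise_entry_p must be below stepwise_removal_p")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["markers"] = list(self.markers)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: dict[str, list[str]] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, path: Path) -> None:
        self.stages.setdefault(stage, []).append(str(path))
        self.checksums[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def _stage_seed(root_seed: int, stage: str, item: int = 0) -> int:
    """Deterministic per-stage, per-item seed below 2^31."""
    h = hashlib.sha256(f"{root_seed}:{stage}:{item}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# --------------------------------------------------------------------------
# stage 1: generate


def make_demo_dataset(outdir: str | Path, seed: int = 0, n_cases: int = 36,
                      prop_ad: float = 23.0 / 36.0, tile_px: int = 96,
                      markers: tuple[str, ...] = ("AT8", "4G8"),
                      vessel_pixel_size: float = 2.0,
                      lesion_px_per_mm: float = 4.0,
                      lesion_field_mm: float = 80.0) -> Path:
    """Write a complete synthetic study to ``outdir``.

    Defaults mirror the study cohort: 36 cases, 23 AD / 13 control, 24
    cortical sample locations per case per marker, five white-matter vessel
    blocks of eight vessels each, and one lesion mask per region.  The
    cohort table carries the generating ground truth; the rendered inputs
    are what downstream stages measure.
    """
    outdir = Path(outdir)
    (outdir / "ihc").mkdir(parents=True, exist_ok=True)
    (outdir / "vessels").mkdir(exist_ok=True)
    (outdir / "lesions").mkdir(exist_ok=True)

    cohort = synthgen.make_cohort(CohortConfig(
        n_cases=n_cases, prop_ad=prop_ad, seed=_stage_seed(seed, "cohort")))
    cohort.to_csv(outdir / "cohort.csv", index=False)

    plan = default_sampling_plan()
    pixel_size = pixel_size_for_field(tile_px)
    section_region = {s: r for r, ss in REGION_SECTIONS.items() for s in ss}
    burden_col = {"AT8": "hpt", "4G8": "abeta"}

    rows = []
    for i, case in cohort.iterrows():
        for marker in markers:
            kinds = (("tangle", "thread") if marker == "AT8"
                     else ("plaque", "app_speck"))
            for loc, (section, loc_class) in enumerate(plan):
                region = section_region[section]
                target = float(case[f"{burden_col[marker]}_{region}"]) / 100.0
                target = min(target, _MAX_TARGET_FRACTION)
                spec = IHCSceneSpec(
                    tile_px=tile_px, pixel_size=pixel_size,
                    n_structures=0, structure_kinds=kinds,
                    target_fraction=target, marker=marker,
                    seed=_stage_seed(seed, f"ihc:{marker}", i * 100 + loc),
                )
                truth = synthgen.make_ihc_montage(spec)
                name = f"{case.case_id}_{marker}_{loc:02d}_{section}_{loc_class}.tiff"
                io_utils.write_rgb_tiff(
                    outdir / "ihc" / name, truth.image.rgb, pixel_size,
                    extra={"case_id": case.case_id, "marker": marker,
                           "section": section, "location_class": loc_class,
                           "true_fraction": truth.true_fraction,
                           "true_fraction_filtered": truth.true_fraction_filtered},
                )
        # vessels: 8 per block, SI jittered around the regional truth
        for block in VESSEL_BLOCKS:
            region = _BLOCK_REGION[block]
            si_region = float(case[f"si_{region}"])
            vrng = np.random.default_rng(_stage_seed(seed, f"vessel:{block}", i))
            for v in range(VESSELS_PER_BLOCK):
                si = float(np.clip(si_region + vrng.normal(0, 0.04), 0.05, 0.9))
                d_ext = float(vrng.uniform(70.0, 280.0))
                vspec = VesselSceneSpec(
                    d_int=d_ext * (1.0 - si), d_ext=d_ext,
                    eccentricity=float(vrng.uniform(0, 0.4)),
                    rotation=float(vrng.uniform(0, 180)),
                    pixel_size=vessel_pixel_size,
                    seed=_stage_seed(seed, f"vesselimg:{block}:{v}", i),
                )
                raster, true_si = synthgen.make_vessel_image(vspec)
                name = f"{case.case_id}_{block}_v{v}.tiff"
                io_utils.write_rgb_tiff(
                    outdir / "vessels" / name, raster, vessel_pixel_size,
                    extra={"case_id": case.case_id, "block": block,
                           "vessel_id": v, "true_si": true_si},
                )
        # lesion masks: geometry drawn from the regional ARWMC truth
        for region in synthgen.REGIONS:
            score = int(case[f"arwmc_{region}"])
            lrng = np.random.default_rng(_stage_seed(seed, f"lesion:{region}", i))
            diams: tuple[float, ...]
            if score == 0:
                diams = ()
            elif score == 1:
                diams = tuple(lrng.uniform(3.0, 8.0, size=2))
            elif score == 2:
                diams = (float(lrng.uniform(11.0, 19.0)),)
            else:
                diams = (float(lrng.uniform(22.0, 32.0)),)
            lspec = LesionSceneSpec(
                field_mm=lesion_field_mm, lesion_diameters=diams,
                px_per_mm=lesion_px_per_mm,
                seed=_stage_seed(seed, f"lesionimg:{region}", i),
            )
            lmask, mm_per_px = synthgen.make_lesion_mask(lspec)
            name = f"{case.case_id}_{region}.png"
            io_utils.write_mask_png(outdir / "lesions" / name, lmask, mm_per_px,
                                    extra={"case_id": case.case_id, "region": region,
                                           "true_score": score})
        rows.append(case.case_id)
    log.info("generated %d cases under %s", len(rows), outdir)
    return outdir


# --------------------------------------------------------------------------
# stage 2: quantify IHC


def quantify_ihc_dir(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every montage under ``indir``; per-location and per-case tables."""
    indir = Path(indir)
    recs = []
    for tiff in sorted(indir.glob("*.tiff")):
        image, meta = io_utils.read_montage(tiff)
        spec = DEFAULT_THRESHOLDS[meta["marker"]]
        res = quantify(image, spec)
        recs.append({
            "case_id": meta["case_id"], "section": meta["section"],
            "location_class": meta["location_class"], "marker": meta["marker"],
            "percent_area": res.percent_area, "positive_px": res.positive_px,
            "measured_px": res.measured_px,
        })
    per_location = pd.DataFrame(recs)
    if per_location.empty:
        raise ValueError(f"no montages found under {indir}")
    case_rows = []
    col_prefix = {"AT8": "hpt", "4G8": "abeta"}
    for (case_id, marker), grp in per_location.groupby(["case_id", "marker"]):
        agg = aggregate_case(grp[["section", "percent_area"]])
        case_rows.append({"case_id": case_id, "marker": marker,
                          **{f"{col_prefix[marker]}_{k}": v for k, v in agg.items()}})
    # one row per case with both markers' columns side by side
    per_case = (pd.DataFrame(case_rows).drop(columns="marker")
                .groupby("case_id").max().reset_index())
    return per_location, per_case


# --------------------------------------------------------------------------
# stage 3: vessels


def measure_vessels_dir(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every vessel field; per-vessel and per-case SI tables."""
    indir = Path(indir)
    recs = []
    for tiff in sorted(indir.glob("*.tiff")):
        rgb, meta = io_utils.read_montage(tiff)
        m = measure_vessel(rgb.rgb, rgb.pixel_size)
        recs.append({
            "case_id": meta["case_id"], "block": meta["block"],
            "vessel_id": meta["vessel_id"], "si": m.si,
            "d_int_um": float(np.mean(m.d_int)), "d_ext_um": float(np.mean(m.d_ext)),
        })
    per_vessel = pd.DataFrame(recs)
    if per_vessel.empty:
        raise ValueError(f"no vessel images found under {indir}")
    case_rows = []
    for case_id, grp in per_vessel.groupby("case_id"):
        per_region: dict[str, list[float]] = {}
        for block, bgrp in grp.groupby("block"):
            per_region.setdefault(_BLOCK_REGION[block], []).extend(bgrp["si"])
        agg = aggregate_si(per_region)
        case_rows.append({"case_id": case_id,
                          **{f"si_{k}": v for k, v in agg.items()}})
    return per_vessel, pd.DataFrame(case_rows)


# --------------------------------------------------------------------------
# stage 4: WMH scoring


def score_wmh_dir(indir: str | Path, parieto_occipital_mode: str = "max") -> pd.DataFrame:
    """Rate every regional lesion mask; one row per case with combined scores."""
    indir = Path(indir)
    scores: dict[str, dict[str, int]] = {}
    for png in sorted(indir.glob("*.png")):
        mask, mm_per_px, meta = io_utils.read_mask_png(png)
        census = wmh_rating.census_lesions(mask, mm_per_px)
        scores.setdefault(meta["case_id"], {})[meta["region"]] = wmh_rating.score_region(census)
    if not scores:
        raise ValueError(f"no lesion masks found under {indir}")
    rows = []
    for case_id, s in scores.items():
        combined = wmh_rating.combine_scores(
            s["frontal"], s["temporal"], s["parietal"], s["occipital"],
            parieto_occipital_mode=parieto_occipital_mode,
        )
        rows.append({"case_id": case_id,
                     "arwmc_frontal": s["frontal"], "arwmc_temporal": s["temporal"],
                     "arwmc_parietal": s["parietal"], "arwmc_occipital": s["occipital"],
                     "arwmc_parieto_occipital": combined["parieto_occipital"],
                     "arwmc_total": combined["total"]})
    return pd.DataFrame(rows).sort_values("case_id").reset_index(drop=True)


# --------------------------------------------------------------------------
# stage 5: statistics


def analyze_cohort(table: pd.DataFrame, entry_p: float = 0.05,
                   removal_p: float = 0.10) -> pd.DataFrame:
    """Run the statistical battery on a merged per-case table.

    Group contrasts (normality-routed) on the four total measures,
    age-controlled one-tailed partial correlations of regional/total ARWMC
    with tau, amyloid (Spearman) and SI (Pearson), and a forward stepwise
    regression of ARWMC on tau, amyloid, SI and age per region and in total.
    """
    rows = []
    ad = table[table["group"] == "AD"]
    ctrl = table[table["group"] == "control"]

    for var in ("hpt_total", "abeta_total", "si_total", "arwmc_total"):
        routing = route_test({"AD": ad[var], "control": ctrl[var]})
        if routing.route == "parametric":
            t, df, p = pooled_t_from_samples(ad[var], ctrl[var])
            rows.append({"analysis": "group_contrast", "variable": var,
                         "method": "pooled_t", "estimate": t, "df": df, "p": p,
                         "routing": routing.route})
        else:
            u, p = mann_whitney_u(ad[var], ctrl[var])
            rows.append({"analysis": "group_contrast", "variable": var,
                         "method": "mann_whitney_u", "estimate": u,
                         "df": len(table) - 2, "p": p, "routing": routing.route})
        log.info("routing %s -> %s", var, routing.route)

    scopes = list(synthgen.REGIONS) + ["total"]
    for scope in scopes:
        arwmc = table[f"arwmc_{scope}"] if scope != "total" else table["arwmc_total"]
        for predictor, method in (("hpt", "spearman"), ("abeta", "spearman"), ("si", "pearson")):
            col = f"{predictor}_{scope}"
            sub = pd.DataFrame({"x": table[col], "y": arwmc,
                                "age": table["age_at_death"]}).dropna()
            res = partial_corr(sub["x"], sub["y"], {"age": sub["age"]},
                               method=method, tails=1)
            rows.append({"analysis": "partial_correlation", "variable": col,
                         "region": scope, "method": res.method,
                         "estimate": res.coefficient, "df": res.df,
                         "p": res.p_one_tailed})
        cand = pd.DataFrame({
            "hpt": table[f"hpt_{scope}"], "abeta": table[f"abeta_{scope}"],
            "si": table[f"si_{scope}"], "age": table["age_at_death"],
        }).dropna()
        model = stepwise_forward(arwmc.loc[cand.index], cand,
                                 entry_p=entry_p, removal_p=removal_p,
                                 dependent_name=f"arwmc_{scope}")
        rows.append({"analysis": "stepwise", "variable": f"arwmc_{scope}",
                     "region": scope, "method": "forward_stepwise",
                     "estimate": model.r_squared, "df": model.n,
                     "p": model.f_pvalue,
                     "selected": "+".join(model.selected) or "(none)"})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# driver


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order; returns the run manifest.

    Fails fast with a stage-named error; all outputs (CSV/JSON) land under
    ``config.outdir`` and are checksummed into the manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), seed=config.seed,
                           version=__version__)

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s ...", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    inputs = outdir / "inputs"
    stage("generate", make_demo_dataset, inputs, seed=config.seed,
          n_cases=config.n_cases, prop_ad=config.prop_ad, tile_px=config.tile_px,
          markers=config.markers, vessel_pixel_size=config.vessel_pixel_size,
          lesion_px_per_mm=config.lesion_px_per_mm,
          lesion_field_mm=config.lesion_field_mm)
    manifest.record("generate", inputs / "cohort.csv")

    per_loc, ihc_case = stage("quantify-ihc", quantify_ihc_dir, inputs / "ihc")
    per_loc.to_csv(outdir / "ihc_per_location.csv", index=False)
    ihc_case.to_csv(outdir / "ihc_per_case.csv", index=False)
    manifest.record("quantify-ihc", outdir / "ihc_per_location.csv")
    manifest.record("quantify-ihc", outdir / "ihc_per_case.csv")

    per_vessel, si_case = stage("measure-vessels", measure_vessels_dir, inputs / "vessels")
    per_vessel.to_csv(outdir / "vessels_per_vessel.csv", index=False)
    si_case.to_csv(outdir / "si_per_case.csv", index=False)
    manifest.record("measure-vessels", outdir / "vessels_per_vessel.csv")
    manifest.record("measure-vessels", outdir / "si_per_case.csv")

    wmh_case = stage("score-wmh", score_wmh_dir, inputs / "lesions",
                     config.parieto_occipital_mode)
    wmh_case.to_csv(outdir / "arwmc_per_case.csv", index=False)
    manifest.record("score-wmh", outdir / "arwmc_per_case.csv")

    cohort = pd.read_csv(inputs / "cohort.csv")
    merged = (cohort[["case_id", "group", "age_at_death"]]
              .merge(ihc_case, on="case_id")
              .merge(si_case, on="case_id")
              .merge(wmh_case, on="case_id"))
    results = stage("analyze", analyze_cohort, merged,
                    config.stepwise_entry_p, config.stepwise_removal_p)
    results.to_csv(outdir / "results.csv", index=False)
    manifest.record("analyze", outdir / "results.csv")

    manifest.write(outdir / "manifest.json")
    return manifest
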