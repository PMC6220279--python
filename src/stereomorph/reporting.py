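"""Full study replica: cohort generation → estimation → summary tables.

``run_study`` drives the whole pipeline from one serializable
:class:`RunConfig`: a morphometry cohort (regional volumes, percent
change, correlation matrix), a stereology cohort (Cavalieri volume and
fractionator neuron counts on virtually sectioned phantoms, summarized
with CE²/CV² accounting), a cortical interneuron cohort (layer-resolved
disector densities with a genotype × layer ANOVA), a DEG enrichment
panel, and qPCR marker quantification.  Outputs are tidy TSV files plus a
JSON manifest recording the seed, the config and a checksum per file.

All randomness flows from the single config seed through spawned
generators, so a fixed config reproduces every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import morphometry as morph
from . import qpcr as qpcr_mod
from . import stats as stats_core
from .phantom import (CohortSpec, CountSpec, RegionSpec, VolumeSpec,
                      make_cohort, make_deg_table, make_phantom,
                      make_qpcr_plate, populate_cells, section_phantom,
                      _draw_positive)
from .stereology import (SamplingDesign, cavalieri_volume, density_count,
                         fractionator_count, layer_band_volumes,
                         layerwise_counts, place_disector_stacks)

__all__ = ["RunConfig", "run_study", "summarize_groups",
           "table1_region_geometry", "cpu_region_geometry"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable description of one full study run."""

    seed: int = 0
    out_dir: str = "results/run"
    count_scale: float = 0.1     # scales cell totals (not effects) for speed
    morphometry: bool = True
    stereology: bool = True
    interneurons: bool = True
    enrichment: bool = True
    qpcr: bool = True
    n_wt_mri: int = 9
    n_mut_mri: int = 10
    n_wt_stereo: int = 7
    n_mut_stereo: int = 6
    n_wt_acc: int = 8
    n_mut_acc: int = 6
    section_thickness_um: float = 40.0
    section_period: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# template geometries
# ---------------------------------------------------------------------------

def table1_region_geometry() -> tuple[list[RegionSpec], dict[str, tuple[str, str]]]:
    """A small multi-region brain phantom with a volumetry hierarchy.

    Region means follow reported wild-type averages (mm³); the striatum
    structure rolls up caudate-putamen, fundus and accumbens.
    """
    regs = [
        RegionSpec("CPu", 1, (3000, 3000, 5000), (2000, 1000, 1000),
                   target_volume_mm3=20.5, structure="striatum", group="cerebral_grey"),
        RegionSpec("fundus", 2, (6500, 2500, 2500), (400, 300, 300),
                   target_volume_mm3=0.2, structure="striatum", group="cerebral_grey"),
        RegionSpec("accumbens", 3, (7000, 6500, 2500), (900, 700, 700),
                   target_volume_mm3=4.4, structure="striatum", group="cerebral_grey"),
        RegionSpec("amygdala", 4, (3000, 7000, 9000), (1500, 1100, 1100),
                   target_volume_mm3=16.3, structure="amygdala", group="cerebral_grey"),
        RegionSpec("globus_pallidus", 5, (7500, 7500, 7500), (800, 600, 600),
                   target_volume_mm3=3.2, structure="globus_pallidus", group="cerebral_grey"),
        RegionSpec("thalamus", 6, (8500, 3000, 8500), (1600, 1200, 1200),
                   target_volume_mm3=18.4, structure="thalamus", group="cerebral_grey"),
        RegionSpec("hippocampus", 7, (3000, 9500, 3000), (1800, 1300, 1300),
                   target_volume_mm3=24.0, structure="hippocampus", group="cerebral_grey"),
        RegionSpec("occipital_cortex", 8, (9800, 9800, 3000), (1100, 850, 850),
                   target_volume_mm3=6.5, structure="cerebral_cortex", group="cerebral_grey"),
    ]
    hier = {r.name: (r.structure, r.group) for r in regs}
    return regs, hier


# nominal percent effects on the mutant means, reductions negative
TABLE1_EFFECTS = {"CPu": -0.103, "fundus": 0.009, "accumbens": -0.036,
                  "amygdala": -0.053, "globus_pallidus": -0.069,
                  "thalamus": -0.041, "hippocampus": -0.055,
                  "occipital_cortex": -0.098}


def cpu_region_geometry() -> RegionSpec:
    """Left caudate-putamen template: 10.90 mm³, long axis along z."""
    return RegionSpec("CPu", 1, (3200, 3200, 3200), (1100, 1100, 2200),
                      target_volume_mm3=10.90)


# ---------------------------------------------------------------------------
# group summaries (Table-2-shaped)
# ---------------------------------------------------------------------------

def summarize_groups(per_animal: pd.DataFrame,
                     wt_label: str = "WT",
                     mut_label: str = "MUT") -> pd.DataFrame:
    """Assemble a mean/SD/CV/CE²-CV² summary per quantity and genotype.

    ``per_animal`` needs columns: quantity, animal, genotype, estimate, ce.
    One output row per quantity with both groups' summaries and pooled and
    Welch p-values; singleton groups get absent SD/CV/p.
    """
    rows = []
    for quantity, grp in per_animal.groupby("quantity", sort=False):
        row: dict = {"quantity": quantity}
        samples = {}
        for label, tag in ((wt_label, "wt"), (mut_label, "mut")):
            g = grp[grp["genotype"] == label]
            vals = g["estimate"].to_numpy(dtype=float)
            ces = g["ce"].to_numpy(dtype=float)
            samples[tag] = vals
            row[f"n_{tag}"] = vals.size
            row[f"mean_{tag}"] = vals.mean() if vals.size else np.nan
            if vals.size > 1:
                sd = vals.std(ddof=1)
                cv = sd / vals.mean() if vals.mean() else np.nan
                row[f"sd_{tag}"] = sd
                row[f"cv_{tag}"] = cv
                mean_ce2 = float(np.nanmean(ces ** 2))
                row[f"ce2_over_cv2_{tag}"] = (mean_ce2 / cv ** 2
                                              if cv and not np.isnan(cv) else np.nan)
            else:
                row[f"sd_{tag}"] = row[f"cv_{tag}"] = row[f"ce2_over_cv2_{tag}"] = np.nan
        if len(samples["wt"]) >= 2 and len(samples["mut"]) >= 2:
            pooled = stats_core.two_sample_test(samples["wt"], samples["mut"],
                                                variant="pooled")
            welch = stats_core.two_sample_test(samples["wt"], samples["mut"],
                                               variant="welch")
            row["p_pooled"], row["p_welch"] = pooled.p, welch.p
            row["pct_change"] = (100.0 * (samples["mut"].mean() - samples["wt"].mean())
                                 / samples["wt"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study stages
# ---------------------------------------------------------------------------

def _morphometry_stage(cfg: RunConfig, rng: np.random.Generator,
                       out: Path) -> dict[str, Path]:
    regs, hier = table1_region_geometry()
    spec = CohortSpec(
        n_wt=cfg.n_wt_mri, n_mut=cfg.n_mut_mri,
        volumes=tuple(VolumeSpec(r.name, r.target_volume_mm3, 0.06,
                                 TABLE1_EFFECTS.get(r.name, 0.0))
                      for r in regs),
        shared_factor_sd=0.04,
        seed=int(rng.integers(2 ** 31)),
    )
    cohort = make_cohort(spec, regs, (96, 96, 96), (125.0, 125.0, 125.0),
                         populate=False)
    tables = [morph.region_volumes(a.volume, a.animal_id, a.genotype)
              for a in cohort]
    voltab = pd.concat(tables, ignore_index=True)
    change = morph.percent_change(voltab)
    corr = morph.volume_correlations(voltab)
    paths = {"volumetry": out / "volumetry.tsv",
             "table1_volumetry": out / "table1_volumetry.tsv",
             "correlations": out / "correlations.tsv"}
    voltab.to_csv(paths["volumetry"], sep="\t", index=False)
    change.to_csv(paths["table1_volumetry"], sep="\t", index=False)
    corr.to_csv(paths["correlations"], sep="\t")
    return paths


def _stereology_stage(cfg: RunConfig, rng: np.random.Generator,
                      out: Path) -> dict[str, Path]:
    reg = cpu_region_geometry()
    scale = cfg.count_scale
    # frame grows as counts shrink so each animal still tallies ~300 cells
    frame_side = 44.7 / np.sqrt(scale)
    design = SamplingDesign(section_period=cfg.section_period,
                            section_thickness_um=cfg.section_thickness_um,
                            frame_width_um=frame_side, frame_height_um=frame_side)
    spec = CohortSpec(
        n_wt=cfg.n_wt_stereo, n_mut=cfg.n_mut_stereo,
        volumes=(VolumeSpec("CPu", 10.90, 0.06, -0.11),),
        counts=(CountSpec("CPu", 666016 * scale, 0.14, -0.208),),
        seed=int(rng.integers(2 ** 31)),
    )
    cohort = make_cohort(spec, [reg], (80, 80, 160), (80.0, 80.0, 40.0))
    rows = []
    for a in cohort:
        arng = np.random.default_rng(int(rng.integers(2 ** 31)))
        series = section_phantom(a.volume, a.cells, design.section_thickness_um,
                                 axis=2, rng=arng)
        vol = cavalieri_volume(series, "CPu", design, rng=arng)
        cnt = fractionator_count(series, design, arng, cell_class="neuron")
        rows.append({"quantity": "CPu_volume_mm3", "animal": a.animal_id,
                     "genotype": a.genotype, "estimate": vol.estimate,
                     "ce": vol.ce, "truth": a.truth.volumes_mm3["CPu"]})
        rows.append({"quantity": "CPu_neurons", "animal": a.animal_id,
                     "genotype": a.genotype, "estimate": cnt.estimate,
                     "ce": cnt.ce, "truth": a.truth.counts["CPu", "neuron"]})
    per_animal = pd.DataFrame(rows)
    summary = summarize_groups(per_animal)
    paths = {"stereology_estimates": out / "stereology_estimates.tsv",
             "table2_stereology": out / "table2_stereology.tsv"}
    per_animal.to_csv(paths["stereology_estimates"], sep="\t", index=False)
    summary.to_csv(paths["table2_stereology"], sep="\t", index=False)
    return paths


ACC_LAYERS = {"I-III": (0.0, 0.45), "V": (0.45, 0.80), "VI": (0.80, 1.0)}
ACC_PROFILE = {"I-III": 0.45, "V": 0.40, "VI": 0.15}
# WT means and overall mutant effects per marker category (both = PV ∧ VVA)
ACC_CATEGORIES = {
    "both": {"mean": 9375, "effect": -0.343, "pv": 1.0, "vva": 1.0},
    "pv_only": {"mean": 106, "effect": -0.0, "pv": 1.0, "vva": 0.0},
    "vva_only": {"mean": 462, "effect": -0.0, "pv": 0.0, "vva": 1.0},
}


def _acc_cohort(cfg: RunConfig, rng: np.random.Generator):
    """Cortical-interneuron cohort: the marker deficit concentrated in layer V.

    Each animal carries three neuron sub-populations (PV∧VVA, PV-only,
    VVA-only) with log-normal between-animal variation; the mutant
    reduction of the double-labeled population is applied entirely within
    the layer-V band.
    """
    reg = RegionSpec("aCC", 1, (2000, 1700, 1000), (1200, 1000, 500),
                     target_volume_mm3=2.5)
    vol, truth0 = make_phantom([reg], (50, 44, 25), (80.0, 80.0, 80.0))
    genos = ["WT"] * cfg.n_wt_acc + ["MUT"] * cfg.n_mut_acc
    animals = []
    for i, g in enumerate(genos):
        frames = []
        truth_layers: dict[str, dict[str, int]] = {}
        for cat, par in ACC_CATEGORIES.items():
            cv = 0.17
            draws = {}
            for lay, frac in ACC_PROFILE.items():
                m = par["mean"] * frac
                if g == "MUT":
                    if lay == "V":
                        # whole category effect concentrated in layer V
                        m *= 1.0 + par["effect"] / ACC_PROFILE["V"]
                    m = max(m, 1.0)
                draws[lay] = max(int(round(_draw_positive(m, cv, 1, rng,
                                                          "lognormal")[0])), 0)
            total = sum(draws.values())
            truth_layers[cat] = draws
            prof = {lay: v / total for lay, v in draws.items()} if total else None
            cells = populate_cells(vol, "aCC", total, rng,
                                   class_mixture={"neuron": 1.0},
                                   marker_p={"pv": par["pv"], "vva": par["vva"]},
                                   laminar_profile=prof, layer_axis=1,
                                   layer_bands=ACC_LAYERS)
            frames.append(cells)
        animals.append({"animal": f"{g.lower()}{i:02d}", "genotype": g,
                        "cells": pd.concat(frames, ignore_index=True),
                        "truth": truth_layers})
    return vol, animals


def _interneuron_stage(cfg: RunConfig, rng: np.random.Generator,
                       out: Path) -> dict[str, Path]:
    vol, animals = _acc_cohort(cfg, rng)
    # confocal-style probes: 135 µm field, counting through most of the
    # section depth (guard zones at both faces)
    design = SamplingDesign(section_period=cfg.section_period,
                            section_thickness_um=cfg.section_thickness_um,
                            step_x_um=400.0, step_y_um=400.0,
                            frame_width_um=135.0, frame_height_um=135.0,
                            disector_top_um=5.0, disector_bottom_um=35.0)
    v_ref = vol.region_volume_mm3("aCC")
    band_v = layer_band_volumes(vol, "aCC", ACC_LAYERS, layer_axis=1)
    rows, layer_rows = [], []
    for a in animals:
        arng = np.random.default_rng(int(rng.integers(2 ** 31)))
        series = section_phantom(vol, a["cells"], design.section_thickness_um,
                                 axis=2, rng=arng)
        sampled = [s for s in series.sections if s.voxel_counts.get("aCC", 0)]
        sub = type(series)(sampled[:: max(len(sampled) // 4, 1)][:4],
                           series.thickness_um, series.axis, series.start_um)
        for marker_name, marker in (("PV+", "pv"), ("VVA+", "vva"),
                                    ("PV+VVA+", ("pv", "vva"))):
            stacks = place_disector_stacks(
                sub, vol, "aCC", design, arng,
                stacks_per_layer={"I-III": 6, "V": 6, "VI": 2},
                layer_bands=ACC_LAYERS, layer_axis=1,
                cell_class="neuron", marker=marker)
            est = density_count(stacks, v_ref)
            rows.append({"quantity": f"aCC_{marker_name}", "animal": a["animal"],
                         "genotype": a["genotype"], "estimate": est.estimate,
                         "ce": est.ce})
            if marker == "vva":
                for lay, lest in layerwise_counts(stacks, band_v).items():
                    layer_rows.append({"animal": a["animal"],
                                       "genotype": a["genotype"], "layer": lay,
                                       "estimate": lest.estimate})
    per_animal = pd.DataFrame(rows)
    summary = summarize_groups(per_animal)
    layer_tab = pd.DataFrame(layer_rows)
    aov = stats_core.two_way_anova(layer_tab["estimate"], layer_tab["genotype"],
                                   layer_tab["layer"])
    paths = {"acc_estimates": out / "acc_estimates.tsv",
             "table2_acc": out / "table2_acc.tsv",
             "acc_layers": out / "acc_layerwise.tsv",
             "acc_anova": out / "acc_anova.tsv"}
    per_animal.to_csv(paths["acc_estimates"], sep="\t", index=False)
    summary.to_csv(paths["table2_acc"], sep="\t", index=False)
    layer_tab.to_csv(paths["acc_layers"], sep="\t", index=False)
    aov.table.to_csv(paths["acc_anova"], sep="\t")
    return paths


def _enrichment_stage(cfg: RunConfig, rng: np.random.Generator,
                      out: Path) -> dict[str, Path]:
    degs, sets, universe = make_deg_table(
        rng, enrichment={"celltype_00": 10.0, "celltype_01": 5.0},
        direction_bias={"celltype_00": 1.0, "celltype_01": 1.0})
    signs = dict(zip(degs["gene"], degs["log2fc"]))
    rows = enr.fisher_enrichment(degs["gene"], sets, universe, deg_signs=signs)
    table = enr.enrichment_table(rows)
    paths = {"enrichment": out / "enrichment.tsv"}
    table.to_csv(paths["enrichment"], sep="\t", index=False)
    return paths


QPCR_PANELS = {
    "P0": {"n": 7, "targets": {"Cck": 0.6, "Vip": 1.0, "Pvalb": 1.0}},
    "P21": {"n": 6, "targets": {"Cck": 1.0, "Vip": 0.85, "Pvalb": 0.8}},
}
QPCR_REFS = ["Ref1", "Ref2", "Ref3", "Ref4"]


def _qpcr_stage(cfg: RunConfig, rng: np.random.Generator,
                out: Path) -> dict[str, Path]:
    results = []
    for stage, par in QPCR_PANELS.items():
        genes = list(par["targets"]) + QPCR_REFS
        plate = make_qpcr_plate(rng, genes,
                                {"WT": par["n"], "MUT": par["n"]},
                                fold_changes=par["targets"],
                                stage=stage)
        curves = {g: qpcr_mod.fit_standard_curve(plate, g) for g in genes}
        quant = qpcr_mod.quantify(plate, curves)
        stab = qpcr_mod.stability_rank(quant, QPCR_REFS)
        pair = stab.attrs["best_pair"]
        contrast = qpcr_mod.normalize_and_contrast(quant, pair)
        contrast["stage"] = stage
        results.append(contrast)
    table = pd.concat(results, ignore_index=True)
    paths = {"qpcr_log2fc": out / "qpcr_log2fc.tsv"}
    table.to_csv(paths["qpcr_log2fc"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_study(config: RunConfig) -> dict:
    """Run every enabled stage and write the report bundle + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    stage_rngs = {name: np.random.default_rng(s)
                  for name, s in zip(
                      ["morphometry", "stereology", "interneurons",
                       "enrichment", "qpcr"], seeds)}
    files: dict[str, Path] = {}
    stages = [("morphometry", config.morphometry, _morphometry_stage),
              ("stereology", config.stereology, _stereology_stage),
              ("interneurons", config.interneurons, _interneuron_stage),
              ("enrichment", config.enrichment, _enrichment_stage),
              ("qpcr", config.qpcr, _qpcr_stage)]
    for name, enabled, fn in stages:
        if not enabled:
            continue
        try:
            files.update(fn(config, stage_rngs[name], out))
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    manifest = {"seed": config.seed, "config": config.to_dict(),
                "outputs": {k: {"path": str(p),
                                "sha256": hashlib.sha256(p.read_bytes()).hexdigest()}
                            for k, p in files.items()}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
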