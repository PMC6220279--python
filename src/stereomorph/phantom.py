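"""Synthetic brain phantoms, cell point patterns, cohorts and assay tables.

This module fabricates every input the downstream analyses consume, with a
recorded ground truth so that estimator bias and power can be measured:

* ellipsoid/shell **label volumes** with physical voxel sizes (NIfTI-style),
* **cell populations** — point patterns of neurons and glia with marker
  flags (PV, VVA) and cortical-layer assignments,
* two-genotype **cohorts** with log-normal between-animal variation and
  injected fractional effects on region volumes and cell counts,
* virtual **serial sectioning** into equidistant histological sections,
* **DEG tables** and marker gene-set collections with controlled
  enrichment and direction bias, and
* **qPCR plates** with serial-dilution standards.

Coordinates are continuous µm in a right-handed frame; voxel indexing is
0-based with voxel centers at ``(i + 0.5) * voxel_size``.  All generators
draw from a single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import nibabel as nib

__all__ = [
    "LabelVolume", "GroundTruth", "RegionSpec", "CohortSpec", "VolumeSpec",
    "CountSpec", "Section", "SectionSeries", "AnimalPhantom",
    "make_phantom", "populate_cells", "make_cohort", "section_phantom",
    "make_deg_table", "make_qpcr_plate",
    "write_gmt", "read_gmt", "write_cells_tsv", "read_cells_tsv",
]

MM3_PER_UM3 = 1e-9


# ---------------------------------------------------------------------------
# label volumes
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """A 3D region-labeled voxel grid with physical voxel size in µm."""

    grid: np.ndarray                      # int labels, 0 = background
    voxel_size: tuple[float, float, float]
    label_map: dict[int, str]             # label -> region name
    hierarchy: dict[str, tuple[str, str]] = field(default_factory=dict)
    # region -> (structure, super-group); regions absent are their own structure

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be strictly positive")
        present = set(np.unique(self.grid)) - {0}
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_map")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size))

    def label_of(self, region: str) -> int:
        for lab, name in self.label_map.items():
            if name == region:
                return lab
        raise KeyError(f"region {region!r} not in label_map")

    def region_mask(self, region: str) -> np.ndarray:
        return self.grid == self.label_of(region)

    def region_volume_mm3(self, region: str) -> float:
        """Voxel-counting volume of a region in mm³."""
        return float(self.region_mask(region).sum()) * self.voxel_volume_um3 * MM3_PER_UM3

    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI-1 (µm units) with a JSON voxel-size sidecar."""
        path = Path(path)
        img = nib.Nifti1Image(self.grid.astype(np.int16), affine=np.diag(
            [self.voxel_size[0], self.voxel_size[1], self.voxel_size[2], 1.0]))
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, str(path))
        sidecar = {"voxel_size_um": list(self.voxel_size),
                   "label_map": {str(k): v for k, v in self.label_map.items()},
                   "hierarchy": {k: list(v) for k, v in self.hierarchy.items()}}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelVolume":
        path = Path(path)
        img = nib.load(str(path))
        grid = np.asarray(img.dataobj).astype(int)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar_path.read_text())
        return cls(grid, tuple(meta["voxel_size_um"]),
                   {int(k): v for k, v in meta["label_map"].items()},
                   {k: tuple(v) for k, v in meta.get("hierarchy", {}).items()})


@dataclass
class GroundTruth:
    """The phantom's oracle record: analytic volumes and exact cell counts."""

    volumes_mm3: dict[str, float] = field(default_factory=dict)
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    # (region, class) -> total
    layer_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    # (region, class, layer) -> total

    def validate(self) -> None:
        if any(v < 0 for v in self.volumes_mm3.values()):
            raise ValueError("negative true volume")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative true count")
        per: dict[tuple[str, str], int] = {}
        for (r, c, _l), n in self.layer_counts.items():
            per[r, c] = per.get((r, c), 0) + n
        for key, tot in per.items():
            if key in self.counts and tot != self.counts[key]:
                raise ValueError(f"layer totals for {key} do not sum to region total")


@dataclass(frozen=True)
class RegionSpec:
    """Generating geometry for one region: an ellipsoid or spherical shell.

    ``semi_axes_um`` are the outer semi-axes; a shell sets ``inner_fraction``
    in (0, 1) (inner semi-axes = fraction × outer).  ``target_volume_mm3``
    rescales the semi-axes isotropically so the analytic solid volume hits
    the target.
    """

    name: str
    label: int
    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    inner_fraction: float = 0.0
    target_volume_mm3: float | None = None
    structure: str | None = None
    group: str | None = None

    def scaled_axes(self) -> tuple[float, float, float]:
        a, b, c = self.semi_axes_um
        if self.target_volume_mm3 is None:
            return self.semi_axes_um
        v0 = self.analytic_volume_mm3(self.semi_axes_um, self.inner_fraction)
        s = (self.target_volume_mm3 / v0) ** (1.0 / 3.0)
        return (a * s, b * s, c * s)

    @staticmethod
    def analytic_volume_mm3(axes_um: tuple[float, float, float],
                            inner_fraction: float = 0.0) -> float:
        a, b, c = axes_um
        v = 4.0 / 3.0 * np.pi * a * b * c * (1.0 - inner_fraction ** 3)
        return float(v * MM3_PER_UM3)

    @property
    def true_volume_mm3(self) -> float:
        return self.analytic_volume_mm3(self.scaled_axes(), self.inner_fraction)


def _ellipsoid_mask(shape: tuple[int, int, int],
                    voxel_size: tuple[float, float, float],
                    center: tuple[float, float, float],
                    axes: tuple[float, float, float],
                    inner_fraction: float = 0.0) -> np.ndarray:
    coords = [(np.arange(n) + 0.5) * vs for n, vs in zip(shape, voxel_size)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    q = (((X - center[0]) / axes[0]) ** 2
         + ((Y - center[1]) / axes[1]) ** 2
         + ((Z - center[2]) / axes[2]) ** 2)
    mask = q <= 1.0
    if inner_fraction > 0:
        mask &= q > inner_fraction ** 2
    return mask


def make_phantom(regions: Sequence[RegionSpec],
                 shape: tuple[int, int, int],
                 voxel_size: tuple[float, float, float],
                 hierarchy: Mapping[str, tuple[str, str]] | None = None,
                 ) -> tuple[LabelVolume, GroundTruth]:
    """Rasterize region geometries onto a voxel grid.

    Ground-truth volumes are the analytic solid volumes of the generating
    shapes, not voxel counts.  Overlapping regions are rejected with the
    offending pair named.
    """
    grid = np.zeros(shape, dtype=np.int16)
    label_map: dict[int, str] = {}
    hier: dict[str, tuple[str, str]] = dict(hierarchy or {})
    truth = GroundTruth()
    owner: dict[int, str] = {}
    for spec in regions:
        axes = spec.scaled_axes()
        mask = _ellipsoid_mask(shape, voxel_size, spec.center_um, axes,
                               spec.inner_fraction)
        clash = grid[mask]
        clash = clash[clash != 0]
        if clash.size:
            other = owner[int(clash[0])]
            raise ValueError(f"regions {spec.name!r} and {other!r} overlap")
        grid[mask] = spec.label
        label_map[spec.label] = spec.name
        owner[spec.label] = spec.name
        truth.volumes_mm3[spec.name] = spec.true_volume_mm3
        if spec.structure is not None:
            hier[spec.name] = (spec.structure, spec.group or spec.structure)
    vol = LabelVolume(grid, tuple(voxel_size), label_map, hier)
    return vol, truth


# ---------------------------------------------------------------------------
# cell populations
# ---------------------------------------------------------------------------

def _exact_split(total: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Split ``total`` across keys proportionally, exactly (largest remainder)."""
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    w = w / w.sum()
    raw = w * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return dict(zip(keys, base.tolist()))


def _sample_in_mask(mask: np.ndarray, voxel_size: tuple[float, float, float],
                    n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points (µm) within the labeled voxels of ``mask``."""
    idx = np.flatnonzero(mask)
    if idx.size == 0 and n > 0:
        raise ValueError("cannot place cells: empty region mask")
    pick = rng.choice(idx, size=n, replace=True)
    ijk = np.column_stack(np.unravel_index(pick, mask.shape)).astype(float)
    ijk += rng.random((n, 3))
    return ijk * np.asarray(voxel_size)


def populate_cells(volume: LabelVolume,
                   region: str,
                   total: int,
                   rng: np.random.Generator,
                   class_mixture: Mapping[str, float] | None = None,
                   marker_p: Mapping[str, float] | None = None,
                   laminar_profile: Mapping[str, float] | None = None,
                   layer_axis: int = 2,
                   layer_bands: Mapping[str, tuple[float, float]] | None = None,
                   ) -> pd.DataFrame:
    """Place exactly ``total`` cells uniformly within a labeled region.

    ``class_mixture`` splits the total exactly across classes (default >90%
    neurons, the striatal convention); marker flags (``pv``, ``vva``) are
    binomially thinned on neurons only.  With a ``laminar_profile`` the
    total is split exactly across layers and each layer's cells are placed
    within its depth band (fractions of the region's extent along
    ``layer_axis``); bands default to an equal partition.
    """
    if total < 0:
        raise ValueError("requested total must be >= 0")
    if region not in volume.label_map.values():
        raise KeyError(f"region label {region!r} absent from volume")
    mixture = dict(class_mixture or {"neuron": 0.92, "glia": 0.08})
    markers = dict(marker_p or {})
    cols = ["x_um", "y_um", "z_um", "class", "pv", "vva", "layer", "region"]
    if total == 0:
        return pd.DataFrame(columns=cols)

    mask = volume.region_mask(region)
    frames: list[pd.DataFrame] = []
    if laminar_profile:
        prof = dict(laminar_profile)
        if not np.isclose(sum(prof.values()), 1.0):
            raise ValueError("laminar profile must sum to 1")
        ax_idx = np.nonzero(mask.any(axis=tuple(i for i in range(3) if i != layer_axis)))[0]
        lo = ax_idx.min() * volume.voxel_size[layer_axis]
        hi = (ax_idx.max() + 1) * volume.voxel_size[layer_axis]
        if layer_bands is None:
            edges = np.linspace(0.0, 1.0, len(prof) + 1)
            layer_bands = {lay: (edges[i], edges[i + 1])
                           for i, lay in enumerate(prof)}
        per_layer = _exact_split(total, prof)
        coord = (np.arange(mask.shape[layer_axis]) + 0.5) * volume.voxel_size[layer_axis]
        for lay, n_lay in per_layer.items():
            f0, f1 = layer_bands[lay]
            z0, z1 = lo + f0 * (hi - lo), lo + f1 * (hi - lo)
            band_sel = (coord >= z0) & (coord < z1) if f1 < 1 else (coord >= z0) & (coord <= z1)
            band_mask = mask.copy()
            sl = [slice(None)] * 3
            sl[layer_axis] = ~band_sel
            band_mask[tuple(sl)] = False
            xyz = _sample_in_mask(band_mask, volume.voxel_size, n_lay, rng)
            frames.append(_cells_frame(xyz, n_lay, mixture, markers, lay, region, rng))
    else:
        xyz = _sample_in_mask(mask, volume.voxel_size, total, rng)
        frames.append(_cells_frame(xyz, total, mixture, markers, "", region, rng))
    out = pd.concat(frames, ignore_index=True)
    return out[cols]


def _cells_frame(xyz: np.ndarray, n: int, mixture: Mapping[str, float],
                 markers: Mapping[str, float], layer: str, region: str,
                 rng: np.random.Generator) -> pd.DataFrame:
    split = _exact_split(n, mixture)
    classes = np.concatenate([np.full(k, c, dtype=object) for c, k in split.items()]) \
        if n else np.array([], dtype=object)
    rng.shuffle(classes)
    is_neuron = classes == "neuron"
    pv = np.zeros(n, dtype=bool)
    vva = np.zeros(n, dtype=bool)
    if "pv" in markers:
        pv[is_neuron] = rng.random(is_neuron.sum()) < markers["pv"]
    if "vva" in markers:
        vva[is_neuron] = rng.random(is_neuron.sum()) < markers["vva"]
    return pd.DataFrame({"x_um": xyz[:, 0], "y_um": xyz[:, 1], "z_um": xyz[:, 2],
                         "class": classes, "pv": pv, "vva": vva,
                         "layer": layer, "region": region})


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeSpec:
    """Between-animal model for one region's volume."""
    region: str
    wt_mean_mm3: float
    cv: float
    effect: float = 0.0  # fractional change of the mutant mean


@dataclass(frozen=True)
class CountSpec:
    """Between-animal model for one (region, class) cell total."""
    region: str
    wt_mean: float
    cv: float
    effect: float = 0.0
    cls: str = "neuron"
    class_mixture: tuple[tuple[str, float], ...] = (("neuron", 0.92), ("glia", 0.08))
    marker_p: tuple[tuple[str, float], ...] = ()
    laminar_profile: tuple[tuple[str, float], ...] = ()
    layer_effects: tuple[tuple[str, float], ...] = ()  # extra mutant effect per layer


@dataclass(frozen=True)
class CohortSpec:
    """Two-genotype cohort description with injected effects."""
    n_wt: int
    n_mut: int
    volumes: tuple[VolumeSpec, ...] = ()
    counts: tuple[CountSpec, ...] = ()
    distribution: str = "lognormal"  # or "normal"
    shared_factor_sd: float = 0.0    # optional latent size factor (log-scale SD)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wt < 2 or self.n_mut < 2:
            raise ValueError("group sizes must be >= 2")
        for s in list(self.volumes) + list(self.counts):
            if not (0.0 < s.cv < 1.0):
                raise ValueError(f"CV for {s.region} must lie in (0, 1)")


@dataclass
class AnimalPhantom:
    animal_id: str
    genotype: str  # "WT" or "MUT"
    volume: LabelVolume
    truth: GroundTruth
    cells: pd.DataFrame | None = None


def _draw_positive(mean: float, cv: float, size: int, rng: np.random.Generator,
                   distribution: str) -> np.ndarray:
    """Draws with the requested arithmetic mean and CV (log-normal default)."""
    if cv <= 0:
        return np.full(size, mean)
    if distribution == "lognormal":
        sigma2 = np.log1p(cv ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size)
    if distribution == "normal":
        return rng.normal(mean, cv * mean, size)
    raise ValueError(f"unknown distribution {distribution!r}")


def make_cohort(spec: CohortSpec,
                geometry: Sequence[RegionSpec],
                shape: tuple[int, int, int],
                voxel_size: tuple[float, float, float],
                populate: bool = True) -> list[AnimalPhantom]:
    """Build a two-genotype cohort of phantoms from one template geometry.

    Animal-level true volumes and counts are drawn from a log-normal with
    the requested group mean and CV (mutant means scaled by ``1 + effect``;
    per-layer count effects multiply on top).  Each animal's label volume
    is re-rasterized at its drawn region volumes; cell populations realize
    the drawn counts exactly.  Fixed seed ⇒ identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    genos = ["WT"] * spec.n_wt + ["MUT"] * spec.n_mut
    n = len(genos)
    shared = rng.normal(0.0, spec.shared_factor_sd, n) if spec.shared_factor_sd > 0 \
        else np.zeros(n)

    vol_draws: dict[str, np.ndarray] = {}
    for vs in spec.volumes:
        means = np.where([g == "MUT" for g in genos],
                         vs.wt_mean_mm3 * (1.0 + vs.effect), vs.wt_mean_mm3)
        draws = np.array([_draw_positive(m, vs.cv, 1, rng, spec.distribution)[0]
                          for m in means])
        vol_draws[vs.region] = draws * np.exp(shared)

    count_draws: dict[tuple[str, str], list[dict[str, int]]] = {}
    for cs in spec.counts:
        layer_prof = dict(cs.laminar_profile)
        layer_eff = dict(cs.layer_effects)
        per_animal: list[dict[str, int]] = []
        for a, g in enumerate(genos):
            base = cs.wt_mean * (1.0 + (cs.effect if g == "MUT" else 0.0))
            if layer_prof:
                draws = {}
                for lay, frac in layer_prof.items():
                    m = base * frac
                    if g == "MUT":
                        m *= 1.0 + layer_eff.get(lay, 0.0)
                    draws[lay] = int(round(_draw_positive(m, cs.cv, 1, rng,
                                                          spec.distribution)[0]))
                per_animal.append(draws)
            else:
                tot = int(round(_draw_positive(base, cs.cv, 1, rng,
                                               spec.distribution)[0]))
                per_animal.append({"": tot})
        count_draws[cs.region, cs.cls] = per_animal

    animals: list[AnimalPhantom] = []
    for a, g in enumerate(genos):
        regs = []
        for r in geometry:
            if r.name in vol_draws:
                regs.append(RegionSpec(r.name, r.label, r.center_um,
                                       r.semi_axes_um, r.inner_fraction,
                                       float(vol_draws[r.name][a]),
                                       r.structure, r.group))
            else:
                regs.append(r)
        vol, truth = make_phantom(regs, shape, voxel_size)
        cells_frames = []
        for cs in spec.counts:
            draws = count_draws[cs.region, cs.cls][a]
            total = sum(draws.values())
            truth.counts[cs.region, cs.cls] = total
            prof = None
            if list(draws) != [""]:
                prof = {lay: v / total for lay, v in draws.items()} if total else None
                for lay, v in draws.items():
                    truth.layer_counts[cs.region, cs.cls, lay] = v
            if populate:
                cells_frames.append(populate_cells(
                    vol, cs.region, total, rng,
                    class_mixture=dict(cs.class_mixture),
                    marker_p=dict(cs.marker_p),
                    laminar_profile=prof))
        cells = pd.concat(cells_frames, ignore_index=True) if cells_frames else None
        animals.append(AnimalPhantom(f"{g.lower()}{a:02d}", g, vol, truth, cells))
    return animals


# ---------------------------------------------------------------------------
# virtual sectioning
# ---------------------------------------------------------------------------

@dataclass
class Section:
    """One virtual histological section (a z-slab of the phantom)."""

    index: int
    z0_um: float
    thickness_um: float
    voxel_counts: dict[str, int]          # region -> voxels whose center is in the slab
    layer_range: tuple[int, int]          # [lo, hi) voxel layers along the axis
    cells: pd.DataFrame
    voxel_size: tuple[float, float, float]
    axis: int

    def region_area_um2(self, region: str) -> float:
        """Mean cross-sectional area of the region profile in this section.

        Defined so that area × thickness integrates the voxel volume exactly:
        (slab voxel count × voxel volume) / T.
        """
        n = self.voxel_counts.get(region, 0)
        return n * float(np.prod(self.voxel_size)) / self.thickness_um

    def mask2d(self, volume: LabelVolume, region: str) -> np.ndarray:
        """Representative 2D profile: the central voxel layer of the slab."""
        lo, hi = self.layer_range
        mid = min(max((lo + hi) // 2, 0), volume.grid.shape[self.axis] - 1)
        sl = [slice(None)] * 3
        sl[self.axis] = mid
        return volume.grid[tuple(sl)] == volume.label_of(region)


@dataclass
class SectionSeries:
    sections: list[Section]
    thickness_um: float
    axis: int
    start_um: float
    single_section_warning: bool = False

    def total_cells(self) -> int:
        return sum(len(s.cells) for s in self.sections)


def section_phantom(volume: LabelVolume,
                    cells: pd.DataFrame | None,
                    thickness_um: float,
                    axis: int = 2,
                    rng: np.random.Generator | None = None,
                    start_um: float | None = None,
                    tally_voxels: bool = True) -> SectionSeries:
    """Cut the phantom into serial sections of uniform thickness.

    The first cut falls at a uniform random offset in [0, T) (systematic
    uniform random sectioning); each cell is assigned to exactly one section
    by its reference point (nucleus centroid).  Per-section region tallies
    count voxels whose centers fall inside the slab (skipped when
    ``tally_voxels`` is off, for count-only resampling loops).
    """
    if thickness_um <= 0:
        raise ValueError("section thickness must be > 0")
    if start_um is None:
        if rng is None:
            rng = np.random.default_rng()
        start_um = float(rng.random() * thickness_um)
    if not 0.0 <= start_um < thickness_um:
        raise ValueError("random start must lie in [0, T)")
    vs = volume.voxel_size[axis]
    extent = volume.grid.shape[axis] * vs
    warn = thickness_um >= extent

    axis_cols = {0: "x_um", 1: "y_um", 2: "z_um"}
    zcol = axis_cols[axis]
    if cells is None or len(cells) == 0:
        cells = pd.DataFrame(columns=["x_um", "y_um", "z_um", "class",
                                      "pv", "vva", "layer", "region"])
    cell_sec = np.floor((cells[zcol].to_numpy(dtype=float) - start_um)
                        / thickness_um).astype(int) if len(cells) else np.array([], int)

    centers = (np.arange(volume.grid.shape[axis]) + 0.5) * vs
    vox_sec = np.floor((centers - start_um) / thickness_um).astype(int)
    i_min = int(min(vox_sec.min() if vox_sec.size else 0,
                    cell_sec.min() if cell_sec.size else 0))
    i_max = int(max(vox_sec.max() if vox_sec.size else 0,
                    cell_sec.max() if cell_sec.size else 0))

    labels = sorted(volume.label_map)
    # per-voxel-layer label tallies, binned into slabs
    layer_counts: dict[int, np.ndarray] = {}
    if tally_voxels:
        other_axes = tuple(i for i in range(3) if i != axis)
        for lab in labels:
            layer_counts[lab] = (volume.grid == lab).sum(axis=other_axes)
    # cells binned once: stable sort + searchsorted boundaries
    order = np.argsort(cell_sec, kind="stable") if len(cells) else np.array([], int)
    sorted_sec = cell_sec[order] if len(cells) else cell_sec

    sections: list[Section] = []
    for i in range(i_min, i_max + 1):
        in_slab = vox_sec == i
        layer_idx = np.nonzero(in_slab)[0]
        lo = int(layer_idx.min()) if layer_idx.size else 0
        hi = int(layer_idx.max()) + 1 if layer_idx.size else 0
        counts: dict[str, int] = {}
        if tally_voxels and layer_idx.size:
            for lab in labels:
                n = int(layer_counts[lab][in_slab].sum())
                if n:
                    counts[volume.label_map[lab]] = n
        if len(cells):
            a = np.searchsorted(sorted_sec, i, side="left")
            b = np.searchsorted(sorted_sec, i, side="right")
            sec_cells = cells.iloc[order[a:b]]
        else:
            sec_cells = cells
        sections.append(Section(i, start_um + i * thickness_um, thickness_um,
                                counts, (lo, hi), sec_cells.reset_index(drop=True),
                                volume.voxel_size, axis))
    return SectionSeries(sections, thickness_um, axis, start_um, warn)


# ---------------------------------------------------------------------------
# DEG tables and gene sets
# ---------------------------------------------------------------------------

def make_deg_table(rng: np.random.Generator,
                   universe_size: int = 12000,
                   n_sets: int = 27,
                   set_size: int = 200,
                   n_degs: int = 600,
                   enrichment: Mapping[str, float] | None = None,
                   direction_bias: Mapping[str, float] | None = None,
                   ) -> tuple[pd.DataFrame, dict[str, list[str]], list[str]]:
    """Fabricate a DEG list plus a marker gene-set collection.

    ``enrichment`` maps set name -> sampling weight multiplier for that
    set's genes (>1 enriched, <1 depleted, absent = 1: uniform draws give
    the hypergeometric expectation).  ``direction_bias`` maps set name ->
    probability that an overlapping DEG is down-regulated (1.0 reproduces
    an exclusively-down overlap); other DEGs get random signs.

    Returns (DEG table with gene/log2fc/pvalue, set collection, universe).
    """
    universe = [f"G{i:05d}" for i in range(universe_size)]
    sets: dict[str, list[str]] = {}
    for s in range(n_sets):
        name = f"celltype_{s:02d}"
        sets[name] = sorted(rng.choice(universe, size=set_size, replace=False))
    enr = dict(enrichment or {})
    for name in enr:
        if name not in sets:
            raise KeyError(f"enrichment names unknown set {name!r}")
    weights = np.ones(universe_size)
    index = {g: i for i, g in enumerate(universe)}
    for name, w in enr.items():
        for g in sets[name]:
            weights[index[g]] *= w
    p = weights / weights.sum()
    if n_degs > universe_size:
        raise ValueError("requested DEG count exceeds universe")
    degs = rng.choice(universe, size=n_degs, replace=False, p=p)

    bias = dict(direction_bias or {})
    down = rng.random(n_degs) < 0.5
    for name, b in bias.items():
        members = set(sets[name])
        hit = np.array([g in members for g in degs])
        down[hit] = rng.random(int(hit.sum())) < b
    log2fc = rng.normal(0.8, 0.25, n_degs) * np.where(down, -1.0, 1.0)
    table = pd.DataFrame({"gene": degs, "log2fc": log2fc,
                          "pvalue": rng.uniform(1e-6, 0.05, n_degs)})
    return table, sets, universe


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sets[parts[0]] = parts[2:]
    return sets


def write_cells_tsv(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_cells_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def make_qpcr_plate(rng: np.random.Generator,
                    genes: Sequence[str],
                    group_sizes: Mapping[str, int],
                    fold_changes: Mapping[str, float] | None = None,
                    efficiencies: Mapping[str, float] | None = None,
                    dilutions: Sequence[float] = (1.0, 0.1, 0.01, 0.001, 1e-4),
                    noise_sd: float = 0.2,
                    bio_cv: float = 0.15,
                    stage: str = "P56",
                    mutant_group: str = "MUT") -> pd.DataFrame:
    """Simulate a qPCR plate with serial-dilution standards.

    Cq = intercept − log2(quantity) / log2(1 + efficiency) + N(0, noise_sd).
    Each biological sample's true quantity is the group mean (WT mean 1,
    mutant mean = fold change) with log-normal biological scatter; the
    standard series is built from the pooled mean quantity at the given
    dilutions.  ``fold_changes`` defaults to 1 (reference genes).
    """
    if len(dilutions) < 3:
        raise ValueError("dilution series needs >= 3 points")
    fc = dict(fold_changes or {})
    eff = dict(efficiencies or {})
    for g, e in eff.items():
        if not (0.7 < e <= 1.1):
            raise ValueError(f"efficiency for {g} outside (0.7, 1.1]")
    intercepts = {g: 22.0 + 4.0 * rng.random() for g in genes}
    rows = []
    sample_q: dict[str, dict[str, float]] = {g: {} for g in genes}
    for grp, n in group_sizes.items():
        for i in range(n):
            sid = f"{grp}_{i:02d}"
            for g in genes:
                mean_q = fc.get(g, 1.0) if grp == mutant_group else 1.0
                q = float(_draw_positive(mean_q, bio_cv, 1, rng, "lognormal")[0]) \
                    if bio_cv > 0 else mean_q
                sample_q[g][sid] = q
                e = eff.get(g, 1.0)
                cq = intercepts[g] - np.log2(q) / np.log2(1.0 + e)
                if noise_sd > 0:
                    cq += rng.normal(0.0, noise_sd)
                rows.append({"sample": sid, "group": grp, "stage": stage,
                             "gene": g, "Cq": cq, "is_standard": False,
                             "dilution": np.nan})
    for g in genes:
        pooled = float(np.mean(list(sample_q[g].values())))
        e = eff.get(g, 1.0)
        for d in dilutions:
            cq = intercepts[g] - np.log2(pooled * d) / np.log2(1.0 + e)
            if noise_sd > 0:
                cq += rng.normal(0.0, noise_sd)
            rows.append({"sample": f"std_{d:g}", "group": "standard",
                         "stage": stage, "gene": g, "Cq": cq,
                         "is_standard": True, "dilution": d})
    return pd.DataFrame(rows)
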