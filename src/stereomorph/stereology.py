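"""Design-based stereology: Cavalieri, optical fractionator, disector density.

Implements the three estimators used for striatal volume and neuron number
and for cortical interneuron counts, together with their probe mechanics
and precision accounting:

* ``nucleator_area`` — 2D nucleator area from ray intercepts,
  A = π · mean(lᵢ²), with systematically rotated rays;
* ``cavalieri_volume`` — V = k · T · Σ Area over every k-th section with a
  systematic uniform random start;
* ``apply_counting_frame`` — the unbiased counting frame (left/bottom
  exclusion edges with infinite extensions, top/right inclusion);
* ``optical_disector`` / ``fractionator_count`` —
  N = Σ Q⁻ / (ssf · asf · hsf);
* ``density_count`` / ``layerwise_counts`` —
  N = (Σ Q⁻ / Σ v_dis) · V_ref, per cortical layer band;
* ``precision`` — Gundersen–Jensen (smoothness m = 1) coefficient of error
  for systematic sections, a Poisson + SURS decomposition for counts, and
  the group-level CE²/CV² bookkeeping.

The fractionator's height sampling fraction uses the nominal section
thickness; tissue-shrinkage corrections are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phantom import LabelVolume, Section, SectionSeries

__all__ = [
    "SamplingDesign", "DisectorCount", "StereoEstimate", "GroupSummary",
    "nucleator_area", "cavalieri_volume", "apply_counting_frame",
    "optical_disector", "fractionator_count", "density_count",
    "layerwise_counts", "layer_band_volumes", "place_disector_stacks",
    "gundersen_jensen_ce", "count_ce", "precision", "group_precision",
]


@dataclass(frozen=True)
class SamplingDesign:
    """Full stereological sampling specification.

    Defaults follow the study design for striatal neuron counting:
    every 6th 40 µm section, 400 µm x-y steps, a 2 000 µm² counting frame
    and a 10 µm disector placed 5 µm below the section surface.
    """

    section_period: int = 6
    section_thickness_um: float = 40.0
    step_x_um: float = 400.0
    step_y_um: float = 400.0
    frame_width_um: float = 50.0
    frame_height_um: float = 40.0       # 50 × 40 = 2 000 µm²
    disector_top_um: float = 5.0        # depth below section surface
    disector_bottom_um: float = 15.0
    nucleator_rays: int = 4

    def __post_init__(self) -> None:
        if self.section_period < 1:
            raise ValueError("section period must be >= 1")
        if not (0 <= self.disector_top_um < self.disector_bottom_um):
            raise ValueError("inverted or negative disector window")
        if self.disector_bottom_um > self.section_thickness_um:
            raise ValueError("disector window must lie inside the section slab")
        if self.frame_width_um > self.step_x_um or self.frame_height_um > self.step_y_um:
            raise ValueError("counting frame must fit inside one step cell")

    @property
    def ssf(self) -> float:
        return 1.0 / self.section_period

    @property
    def asf(self) -> float:
        return (self.frame_width_um * self.frame_height_um) / (self.step_x_um * self.step_y_um)

    @property
    def hsf(self) -> float:
        return (self.disector_bottom_um - self.disector_top_um) / self.section_thickness_um

    @property
    def frame_area_um2(self) -> float:
        return self.frame_width_um * self.frame_height_um

    @property
    def disector_height_um(self) -> float:
        return self.disector_bottom_um - self.disector_top_um


@dataclass
class DisectorCount:
    """One optical-disector probe result."""

    x0_um: float
    y0_um: float
    section_index: int
    q: int
    v_dis_um3: float
    layer: str = ""

    def __post_init__(self) -> None:
        if self.q < 0 or self.v_dis_um3 <= 0:
            raise ValueError("invalid disector count")


@dataclass
class StereoEstimate:
    """An estimated total (volume in mm³ or number) with its predicted CE."""

    kind: str                     # "volume" | "number"
    estimate: float
    ce: float
    tallies: np.ndarray           # per-section areas (µm²) or Q⁻ counts
    design: dict = field(default_factory=dict)
    warning: str = ""


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int
    cv: float
    mean_ce2: float
    ce2_over_cv2: float | None


# ---------------------------------------------------------------------------
# 2D nucleator
# ---------------------------------------------------------------------------

def _ray_length(contains: Callable[[float, float], bool],
                seed: tuple[float, float], angle: float,
                r_max: float, tol: float = 1e-9) -> float:
    """First boundary crossing from the seed along a ray, by march + bisection."""
    cx, cy = np.cos(angle), np.sin(angle)
    x0, y0 = seed
    step = r_max / 512.0
    r_in = 0.0
    r = step
    while r <= r_max:
        if not contains(x0 + r * cx, y0 + r * cy):
            break
        r_in, r = r, r + step
    else:
        return r_max
    r_out = r
    while r_out - r_in > tol * max(r_max, 1.0):
        mid = 0.5 * (r_in + r_out)
        if contains(x0 + mid * cx, y0 + mid * cy):
            r_in = mid
        else:
            r_out = mid
    return 0.5 * (r_in + r_out)


def _mask_indicator(mask: np.ndarray, pixel_size: tuple[float, float]
                    ) -> Callable[[float, float], bool]:
    nx, ny = mask.shape
    px, py = pixel_size

    def contains(x: float, y: float) -> bool:
        i, j = int(np.floor(x / px)), int(np.floor(y / py))
        return 0 <= i < nx and 0 <= j < ny and bool(mask[i, j])

    return contains


def nucleator_area(profile: np.ndarray | Callable[[float, float], bool],
                   seed: tuple[float, float],
                   n_rays: int = 4,
                   phase: float | None = None,
                   rng: np.random.Generator | None = None,
                   pixel_size: tuple[float, float] = (1.0, 1.0),
                   r_max: float | None = None) -> float:
    """2D nucleator area estimate: A = π · mean(lᵢ²).

    ``profile`` is a 2D boolean mask (with ``pixel_size`` in µm) or an
    indicator callable over µm coordinates.  Rays are spaced 2π/n with a
    uniform random rotation phase; the estimator is unbiased over the phase
    for profiles star-shaped about the seed.
    """
    if n_rays < 2:
        raise ValueError("need at least 2 rays")
    if callable(profile):
        contains = profile
        if r_max is None:
            raise ValueError("r_max required with a callable profile")
    else:
        contains = _mask_indicator(profile, pixel_size)
        if r_max is None:
            r_max = float(np.hypot(profile.shape[0] * pixel_size[0],
                                   profile.shape[1] * pixel_size[1]))
    if not contains(*seed):
        raise ValueError("nucleator seed lies outside the profile")
    if phase is None:
        phase = float((rng or np.random.default_rng()).random() * 2 * np.pi / n_rays)
    angles = phase + 2.0 * np.pi * np.arange(n_rays) / n_rays
    lengths = np.array([_ray_length(contains, seed, a, r_max) for a in angles])
    return float(np.pi * np.mean(lengths ** 2))


# ---------------------------------------------------------------------------
# Cavalieri volume
# ---------------------------------------------------------------------------

def cavalieri_volume(series: SectionSeries,
                     region: str,
                     design: SamplingDesign,
                     area_method: str = "pixel",
                     volume: LabelVolume | None = None,
                     rng: np.random.Generator | None = None,
                     start: int | None = None) -> StereoEstimate:
    """Cavalieri estimator V = k · T · Σ Area over every k-th section.

    The start section offset is uniform random in {0..k−1} (SURS).  Areas
    come either from the section voxel tally (``pixel``) or from the 2D
    nucleator on the section profile (``nucleator``, seeded at the profile
    centroid).  With k = 1 and pixel areas the estimate reproduces the
    voxelized region volume exactly.
    """
    k = design.section_period
    T = series.thickness_um
    if start is None:
        start = int((rng or np.random.default_rng()).integers(k))
    sampled = [s for s in series.sections if (s.index - start) % k == 0]
    areas = []
    for s in sampled:
        if area_method == "pixel":
            areas.append(s.region_area_um2(region))
        elif area_method == "nucleator":
            if volume is None:
                raise ValueError("nucleator areas need the source LabelVolume")
            mask = s.mask2d(volume, region)
            if not mask.any():
                areas.append(0.0)
                continue
            inplane = [volume.voxel_size[i] for i in range(3) if i != s.axis]
            com = np.array(np.nonzero(mask), dtype=float).mean(axis=1) + 0.5
            seed = (com[0] * inplane[0], com[1] * inplane[1])
            ind = _mask_indicator(mask, tuple(inplane))
            if not ind(*seed):  # non-convex profile: fall back to a mask pixel
                ij = np.argwhere(mask)[0]
                seed = ((ij[0] + 0.5) * inplane[0], (ij[1] + 0.5) * inplane[1])
            areas.append(nucleator_area(mask, seed, design.nucleator_rays,
                                        rng=rng, pixel_size=tuple(inplane)))
        else:
            raise ValueError(f"unknown area method {area_method!r}")
    areas_arr = np.asarray(areas, dtype=float)
    est_um3 = k * T * float(areas_arr.sum())
    warning = "" if areas_arr.sum() > 0 else f"region {region!r} absent from sampled sections"
    ce = gundersen_jensen_ce(areas_arr[areas_arr > 0]) if (areas_arr > 0).sum() >= 3 else np.nan
    return StereoEstimate("volume", est_um3 * 1e-9, ce, areas_arr,
                          {"k": k, "T_um": T, "start": start,
                           "area_method": area_method}, warning)


# ---------------------------------------------------------------------------
# counting frame and optical disector
# ---------------------------------------------------------------------------

def apply_counting_frame(xy: np.ndarray,
                         origin: tuple[float, float],
                         width: float, height: float) -> np.ndarray:
    """Gundersen unbiased counting frame acceptance for reference points.

    Accepts a point iff it lies strictly right of the left (exclusion) edge
    and strictly above the bottom (exclusion) edge, and on or inside the
    right/top (inclusion) edges: x ∈ (x0, x0+w], y ∈ (y0, y0+h].  For point
    references this half-open rule is equivalent to the classical frame
    with infinite exclusion lines, and a complete frame tiling counts every
    point exactly once.  Ties are resolved by exact coordinate comparison.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    x0, y0 = origin
    return ((xy[:, 0] > x0) & (xy[:, 0] <= x0 + width)
            & (xy[:, 1] > y0) & (xy[:, 1] <= y0 + height))


def optical_disector(cells: pd.DataFrame,
                     section: Section,
                     frame_origin: tuple[float, float],
                     frame_width: float, frame_height: float,
                     depth_window: tuple[float, float],
                     layer: str = "") -> DisectorCount:
    """Count reference points inside one optical disector probe.

    ``depth_window`` is (top, bottom) in µm below the section surface, e.g.
    (5, 15) for counts performed 5–15 µm into a 40 µm section; the window
    must leave guard zones at both faces.  Q⁻ counts cells whose reference
    depth lies in [top, bottom) and that pass the counting-frame rule.
    """
    lo, hi = depth_window
    if hi <= lo:
        raise ValueError("inverted disector window")
    zcol = {0: "x_um", 1: "y_um", 2: "z_um"}[section.axis]
    inplane = [c for c in ("x_um", "y_um", "z_um") if c != zcol]
    if len(cells):
        depth = cells[zcol].to_numpy(dtype=float) - section.z0_um
        in_z = (depth >= lo) & (depth < hi)
        xy = cells[inplane].to_numpy(dtype=float)
        acc = apply_counting_frame(xy, frame_origin, frame_width, frame_height)
        q = int((in_z & acc).sum())
    else:
        q = 0
    v_dis = frame_width * frame_height * (hi - lo)
    return DisectorCount(frame_origin[0], frame_origin[1], section.index,
                         q, v_dis, layer)


# ---------------------------------------------------------------------------
# optical fractionator
# ---------------------------------------------------------------------------

def _frame_residue_accept(coord: np.ndarray, phase: float, step: float,
                          extent: float) -> np.ndarray:
    # Residue within the tiling period; a residue of exactly 0 sits on a
    # node and belongs to the left/lower neighbour's inclusion edge, which
    # only exists when the frame spans the full step.
    r = np.mod(coord - phase, step)
    return (r > 0) & (r <= extent) | ((r == 0) & (extent == step))


def fractionator_count(series: SectionSeries,
                       design: SamplingDesign,
                       rng: np.random.Generator,
                       cell_class: str | None = "neuron",
                       marker: str | None = None) -> StereoEstimate:
    """Optical fractionator: N = Σ Q⁻ / (ssf · asf · hsf).

    Sections are subsampled every k-th with a uniform random start; within
    each sampled section the counting-frame grid gets an independent
    uniform random x-y phase and frames tile the plane at the step period
    (each reference point can be captured by exactly one frame).  The
    disector z-window sits at a fixed depth in every section.
    """
    for name, f in (("ssf", design.ssf), ("asf", design.asf), ("hsf", design.hsf)):
        if f <= 0:
            raise ValueError(f"sampling fraction {name} must be > 0")
    k = design.section_period
    start = int(rng.integers(k))
    lo, hi = design.disector_top_um, design.disector_bottom_um
    zcol = {0: "x_um", 1: "y_um", 2: "z_um"}[series.axis]
    inplane = [c for c in ("x_um", "y_um", "z_um") if c != zcol]
    qs = []
    for s in series.sections:
        if (s.index - start) % k != 0:
            continue
        cells = s.cells
        if cell_class is not None and len(cells):
            cells = cells[cells["class"] == cell_class]
        if marker is not None and len(cells):
            cells = cells[cells[marker].astype(bool)]
        if not len(cells):
            qs.append(0)
            continue
        depth = cells[zcol].to_numpy(dtype=float) - s.z0_um
        in_z = (depth >= lo) & (depth < hi)
        px = float(rng.random() * design.step_x_um)
        py = float(rng.random() * design.step_y_um)
        x = cells[inplane[0]].to_numpy(dtype=float)
        y = cells[inplane[1]].to_numpy(dtype=float)
        acc = (_frame_residue_accept(x, px, design.step_x_um, design.frame_width_um)
               & _frame_residue_accept(y, py, design.step_y_um, design.frame_height_um))
        qs.append(int((in_z & acc).sum()))
    q_arr = np.asarray(qs, dtype=float)
    total_q = float(q_arr.sum())
    estimate = total_q / (design.ssf * design.asf * design.hsf)
    return StereoEstimate("number", estimate, count_ce(q_arr), q_arr,
                          {"ssf": design.ssf, "asf": design.asf,
                           "hsf": design.hsf, "start": start})


# ---------------------------------------------------------------------------
# disector density (aCC) estimator
# ---------------------------------------------------------------------------

def density_count(stacks: Sequence[DisectorCount],
                  v_ref_mm3: float) -> StereoEstimate:
    """Disector-density estimator N = (Σ Q⁻ / Σ v_dis) · V_ref."""
    if not stacks:
        raise ValueError("need at least one disector stack")
    if v_ref_mm3 <= 0:
        raise ValueError("reference volume must be > 0")
    q = np.array([s.q for s in stacks], dtype=float)
    v = np.array([s.v_dis_um3 for s in stacks], dtype=float)
    if v.sum() <= 0:
        raise ValueError("total disector volume is zero")
    estimate = q.sum() / v.sum() * (v_ref_mm3 * 1e9)  # density per µm³ × µm³
    return StereoEstimate("number", float(estimate), count_ce(q), q,
                          {"n_stacks": len(stacks), "v_ref_mm3": v_ref_mm3})


def layer_band_volumes(volume: LabelVolume, region: str,
                       layer_bands: Mapping[str, tuple[float, float]],
                       layer_axis: int = 1) -> dict[str, float]:
    """Voxel-counting volume (mm³) of each layer band within a region.

    Bands are fractional depth intervals of the region's extent along
    ``layer_axis`` (the same convention the cell generator uses).
    """
    mask = volume.region_mask(region)
    ax_idx = np.nonzero(mask.any(axis=tuple(i for i in range(3) if i != layer_axis)))[0]
    vs = volume.voxel_size[layer_axis]
    lo, hi = ax_idx.min() * vs, (ax_idx.max() + 1) * vs
    centers = (np.arange(mask.shape[layer_axis]) + 0.5) * vs
    vv = float(np.prod(volume.voxel_size)) * 1e-9
    counts = mask.sum(axis=tuple(i for i in range(3) if i != layer_axis))
    out = {}
    for lay, (f0, f1) in layer_bands.items():
        b0, b1 = lo + f0 * (hi - lo), lo + f1 * (hi - lo)
        sel = (centers >= b0) & ((centers < b1) if f1 < 1 else (centers <= b1))
        out[lay] = float(counts[sel].sum()) * vv
    return out


def layerwise_counts(stacks: Sequence[DisectorCount],
                     v_ref_mm3: Mapping[str, float]) -> dict[str, StereoEstimate]:
    """Apply the density estimator per cortical layer band.

    Every stack must carry a layer assignment with a reference volume.
    Band totals add up to the whole-region estimate exactly when the
    sampled disector volume per band is proportional to the band's
    reference volume (uniform sampling intensity across bands).
    """
    for s in stacks:
        if not s.layer:
            raise ValueError("stack without a layer assignment")
        if s.layer not in v_ref_mm3:
            raise ValueError(f"no reference volume for layer {s.layer!r}")
    out = {}
    for lay, v in v_ref_mm3.items():
        lay_stacks = [s for s in stacks if s.layer == lay]
        if lay_stacks:
            out[lay] = density_count(lay_stacks, v)
    return out


def place_disector_stacks(series: SectionSeries,
                          volume: LabelVolume,
                          region: str,
                          design: SamplingDesign,
                          rng: np.random.Generator,
                          stacks_per_layer: Mapping[str, int],
                          layer_bands: Mapping[str, tuple[float, float]],
                          layer_axis: int = 1,
                          cell_class: str | None = "neuron",
                          marker: str | Sequence[str] | None = None,
                          max_tries: int = 200) -> list[DisectorCount]:
    """Place disector probes at random positions within layer bands.

    Emulates confocal z-stack sampling: in every section, ``stacks_per_layer``
    probes are dropped at uniform random in-plane positions inside the
    region profile (restricted to the layer's depth band, fractions of the
    region extent along ``layer_axis``), rejecting positions whose frame
    would leave the region so that each probe volume lies fully in tissue.
    """
    zcol = {0: "x_um", 1: "y_um", 2: "z_um"}[series.axis]
    inplane_axes = [i for i in range(3) if i != series.axis]
    inplane_cols = [c for c in ("x_um", "y_um", "z_um") if c != zcol]
    if layer_axis == series.axis:
        raise ValueError("layer axis must differ from the sectioning axis")
    lax_pos = inplane_axes.index(layer_axis)
    mask_full = volume.region_mask(region)
    ax_idx = np.nonzero(mask_full.any(axis=tuple(i for i in range(3) if i != layer_axis)))[0]
    lo_um = ax_idx.min() * volume.voxel_size[layer_axis]
    hi_um = (ax_idx.max() + 1) * volume.voxel_size[layer_axis]
    fw, fh = design.frame_width_um, design.frame_height_um
    depth = (design.disector_top_um, design.disector_bottom_um)
    vs_inplane = [volume.voxel_size[i] for i in inplane_axes]

    stacks: list[DisectorCount] = []
    for s in series.sections:
        mask2d = s.mask2d(volume, region)
        if not mask2d.any():
            continue
        cand = np.argwhere(mask2d)
        band_coord = (cand[:, lax_pos] + 0.5) * vs_inplane[lax_pos]
        cells = s.cells
        if cell_class is not None and len(cells):
            cells = cells[cells["class"] == cell_class]
        marker_list = [marker] if isinstance(marker, str) else list(marker or [])
        for m in marker_list:
            if len(cells):
                cells = cells[cells[m].astype(bool)]
        for lay, n_stacks in stacks_per_layer.items():
            f0, f1 = layer_bands[lay]
            b0, b1 = lo_um + f0 * (hi_um - lo_um), lo_um + f1 * (hi_um - lo_um)
            in_band = (band_coord >= b0) & (band_coord < b1)
            band_pix = cand[in_band]
            if not band_pix.size:
                continue
            placed = 0
            tries = 0
            while placed < n_stacks and tries < max_tries * n_stacks:
                tries += 1
                pix = band_pix[rng.integers(len(band_pix))]
                center = (pix + rng.random(2)) * np.asarray(vs_inplane)
                origin = (center[0] - fw / 2.0, center[1] - fh / 2.0)
                corners = [(origin[0], origin[1]), (origin[0] + fw, origin[1]),
                           (origin[0], origin[1] + fh), (origin[0] + fw, origin[1] + fh)]
                ind = _mask_indicator(mask2d, tuple(vs_inplane))
                if not all(ind(cx, cy) for cx, cy in corners):
                    continue
                stacks.append(optical_disector(cells, s, origin, fw, fh, depth, lay))
                placed += 1
    return stacks


# ---------------------------------------------------------------------------
# precision (CE / CV accounting)
# ---------------------------------------------------------------------------

def gundersen_jensen_ce(values: Sequence[float], noise: float = 0.0) -> float:
    """Gundersen–Jensen CE for a systematically sampled sequence (m = 1).

    Var_SURS = (3·(A − noise) − 4B + C) / 240 with A = Σaᵢ², B = Σaᵢaᵢ₊₁,
    C = Σaᵢaᵢ₊₂; CE = √(Var_SURS + noise) / Σaᵢ.  A constant sequence has
    zero SURS variance, leaving only the noise (nugget) term.
    """
    a = np.asarray(values, dtype=float)
    n = a.size
    if n < 3:
        return np.nan
    total = a.sum()
    if total <= 0:
        return np.nan
    if np.ptp(a) == 0.0:
        # degenerate constant sequence: no systematic variation by convention
        return float(np.sqrt(noise) / total)
    A = float(np.sum(a * a))
    B = float(np.sum(a[:-1] * a[1:]))
    C = float(np.sum(a[:-2] * a[2:]))
    var_surs = max((3.0 * (A - noise) - 4.0 * B + C) / 240.0, 0.0)
    return float(np.sqrt(var_surs + noise) / total)


def count_ce(q_per_section: Sequence[float]) -> float:
    """Predicted CE of a fractionator/disector count.

    CE² = 1/ΣQ⁻ (Poisson counting noise) + CE²_SURS of the section-wise Q⁻
    sequence (between-section systematic variation, m = 1).
    """
    q = np.asarray(q_per_section, dtype=float)
    total = q.sum()
    if total <= 0:
        return np.nan
    ce_surs = gundersen_jensen_ce(q) if q.size >= 3 else 0.0
    if np.isnan(ce_surs):
        ce_surs = 0.0
    return float(np.sqrt(1.0 / total + ce_surs ** 2))


def precision(estimate: StereoEstimate) -> float:
    """Predicted CE of an estimate (recomputed from its retained tallies)."""
    if estimate.kind == "volume":
        t = estimate.tallies
        return gundersen_jensen_ce(t[t > 0])
    return count_ce(estimate.tallies)


def group_precision(estimates: Iterable[StereoEstimate]) -> GroupSummary:
    """Group mean, SD, CV and the CE²/CV² variance share (Table-style)."""
    ests = list(estimates)
    vals = np.array([e.estimate for e in ests], dtype=float)
    ces = np.array([e.ce for e in ests], dtype=float)
    n = vals.size
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else np.nan
    cv = sd / mean if (n > 1 and mean != 0) else np.nan
    mean_ce2 = float(np.nanmean(ces ** 2))
    ratio = mean_ce2 / cv ** 2 if (cv and not np.isnan(cv) and cv > 0) else None
    return GroupSummary(mean, sd, n, cv, mean_ce2, ratio)
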