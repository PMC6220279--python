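"""Label-volume morphometry: regional volumes, percent change, correlation
matrices, and Laplace-equation cortical thickness with pointwise t-maps.

Volumes are measured directly on labeled voxel grids (voxel count × voxel
volume) over a region → structure → super-group hierarchy; atlas
registration is out of scope by design.  Cortical thickness solves
Laplace's equation on the cortical ribbon with Dirichlet boundaries (0 at
the inner surface, 1 at the outer) and integrates streamlines along the
normalized potential gradient; group thickness differences are tested
point-by-point with uncorrected two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .phantom import LabelVolume, MM3_PER_UM3
from . import stats as stats_core

__all__ = [
    "ThicknessField", "TMap",
    "region_volumes", "percent_change", "volume_correlations",
    "laplace_thickness", "thickness_tmap",
]


# ---------------------------------------------------------------------------
# regional volumetry
# ---------------------------------------------------------------------------

def region_volumes(volume: LabelVolume,
                   animal_id: str = "a0",
                   genotype: str = "WT",
                   hemisphere_axis: int = 0,
                   hemisphere_split: int | None = None) -> pd.DataFrame:
    """Per-region voxel-counting volumes, split by hemisphere, with roll-ups.

    ``hemisphere_split`` is the voxel index of the mid-plane along
    ``hemisphere_axis`` (defaults to half the grid); voxels below it are
    "left".  Structure rows (and super-group rows, when a hierarchy is
    attached) are sums over their member regions, and left + right = both
    exactly for every row.
    """
    if hemisphere_split is None:
        hemisphere_split = volume.grid.shape[hemisphere_axis] // 2
    idx = np.arange(volume.grid.shape[hemisphere_axis])
    left_sel = idx < hemisphere_split
    vv = volume.voxel_volume_um3 * MM3_PER_UM3

    rows = []
    for lab, region in sorted(volume.label_map.items()):
        mask = volume.grid == lab
        counts = mask.sum(axis=tuple(i for i in range(3) if i != hemisphere_axis))
        left = float(counts[left_sel].sum()) * vv
        right = float(counts[~left_sel].sum()) * vv
        for hemi, v in (("left", left), ("right", right), ("both", left + right)):
            rows.append({"animal": animal_id, "genotype": genotype,
                         "region": region, "level": "region",
                         "hemisphere": hemi, "volume_mm3": v})
    table = pd.DataFrame(rows)

    if volume.hierarchy:
        base = table[table["level"] == "region"]
        hier = pd.DataFrame(
            [{"region": r, "structure": s, "group": g}
             for r, (s, g) in volume.hierarchy.items()])
        merged = base.merge(hier, on="region", how="inner")
        for level, key in (("structure", "structure"), ("group", "group")):
            agg = (merged.groupby([key, "hemisphere"], as_index=False)["volume_mm3"]
                   .sum().rename(columns={key: "region"}))
            agg["animal"], agg["genotype"], agg["level"] = animal_id, genotype, level
            table = pd.concat([table, agg], ignore_index=True)
    return table


def percent_change(table: pd.DataFrame,
                   wt_label: str = "WT",
                   mut_label: str = "MUT",
                   hemisphere: str = "both") -> pd.DataFrame:
    """Per-region percent volume change of the mutant group vs wild type.

    change = 100 · (mean_mut − mean_wt) / mean_wt (reductions negative),
    paired with pooled and Welch two-sample tests.  A zero wild-type mean
    leaves the change undefined and flags the row.
    """
    sub = table[table["hemisphere"] == hemisphere]
    rows = []
    for (region, _level), grp in sub.groupby(["region", "level"], sort=False):
        wt = grp.loc[grp["genotype"] == wt_label, "volume_mm3"].to_numpy()
        mut = grp.loc[grp["genotype"] == mut_label, "volume_mm3"].to_numpy()
        if wt.size == 0 or mut.size == 0:
            raise ValueError(f"region {region!r}: a group is empty")
        row = {"region": region, "level": grp["level"].iloc[0],
               "n_wt": wt.size, "n_mut": mut.size,
               "mean_wt": wt.mean(), "mean_mut": mut.mean(), "flag": ""}
        if wt.mean() == 0:
            row.update({"pct_change": np.nan, "flag": "zero WT mean"})
        else:
            row["pct_change"] = 100.0 * (mut.mean() - wt.mean()) / wt.mean()
        if wt.size >= 2 and mut.size >= 2:
            pooled = stats_core.two_sample_test(wt, mut, variant="pooled")
            welch = stats_core.two_sample_test(wt, mut, variant="welch")
            row.update({"t_pooled": pooled.t, "p_pooled": pooled.p,
                        "t_welch": welch.t, "p_welch": welch.p})
        rows.append(row)
    return pd.DataFrame(rows)


def volume_correlations(table: pd.DataFrame,
                        hemisphere: str = "both",
                        level: str | None = None) -> pd.DataFrame:
    """Region × region Pearson correlation of per-animal volumes.

    Animals from both genotypes are pooled into one matrix (pre-filter the
    table for a per-genotype matrix).  Zero-variance regions yield NaN
    entries rather than silent zeros.
    """
    sub = table[table["hemisphere"] == hemisphere]
    if level is not None:
        sub = sub[sub["level"] == level]
    wide = sub.pivot_table(index="animal", columns="region",
                           values="volume_mm3", observed=False)
    return stats_core.pearson_matrix(wide)


# ---------------------------------------------------------------------------
# Laplace-equation cortical thickness
# ---------------------------------------------------------------------------

@dataclass
class ThicknessField:
    """Thickness sampled at outer cortical boundary voxel centers."""

    points_ijk: np.ndarray      # (N, 3) voxel indices of outer-surface points
    points_um: np.ndarray       # (N, 3) physical coordinates
    thickness_um: np.ndarray    # (N,)
    potential: np.ndarray       # solved Laplace potential on the full grid
    iterations: int
    residual: float


@dataclass
class TMap:
    """Pointwise two-sample t statistics on a shared surface point set."""

    points_ijk: np.ndarray
    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray            # p < alpha (uncorrected by design)
    alpha: float = 0.05


def laplace_thickness(volume: LabelVolume,
                      cortex: str,
                      inner: str,
                      outer: str | None = None,
                      tol: float = 1e-5,
                      max_iter: int = 50000,
                      step_voxels: float = 0.2,
                      omega: float = 1.9) -> ThicknessField:
    """Solve Laplace's equation on the cortical ribbon and trace streamlines.

    The potential is fixed at 0 in the ``inner`` compartment and 1 in
    ``outer`` (``None`` = everything that is neither cortex nor inner,
    including background) and relaxed on cortex voxels (SOR) until the
    maximum update falls below ``tol``.  From each outer-boundary voxel
    center a streamline is integrated with RK4 (step ``step_voxels`` × the
    smallest voxel edge) down the normalized gradient to the inner surface
    and up to the outer surface; the two path lengths are summed.
    """
    grid = volume.grid
    ctx = volume.region_mask(cortex)
    inn = volume.region_mask(inner)
    if outer is not None:
        out = volume.region_mask(outer)
    else:
        out = ~(ctx | inn)
    if not ctx.any():
        raise ValueError("empty cortex ribbon")

    # the ribbon must separate the boundaries: no inner voxel 6-adjacent to outer
    struct = ndimage.generate_binary_structure(3, 1)
    if (ndimage.binary_dilation(inn, struct) & out).any():
        raise ValueError("cortex ribbon does not separate inner and outer surfaces")
    touches_inner = (ndimage.binary_dilation(ctx, struct) & inn).any()
    touches_outer = (ndimage.binary_dilation(ctx, struct) & out).any()
    if not (touches_inner and touches_outer):
        raise ValueError("cortex ribbon must touch both boundary compartments")

    vs = np.asarray(volume.voxel_size, dtype=float)
    w = 1.0 / vs ** 2
    phi = np.where(out, 1.0, 0.0)
    phi[ctx] = 0.5

    it = 0
    residual = np.inf
    # red-black Gauss-Seidel with successive over-relaxation, vectorized
    denom = 2.0 * w.sum()
    ii, jj, kk = np.indices(grid.shape, sparse=True)
    parity = (ii + jj + kk) % 2
    colors = [ctx & (parity == 0), ctx & (parity == 1)]
    while it < max_iter and residual > tol:
        residual = 0.0
        for color in colors:
            nb = (w[0] * (np.roll(phi, 1, 0) + np.roll(phi, -1, 0))
                  + w[1] * (np.roll(phi, 1, 1) + np.roll(phi, -1, 1))
                  + w[2] * (np.roll(phi, 1, 2) + np.roll(phi, -1, 2))) / denom
            new = phi[color] + omega * (nb[color] - phi[color])
            residual = max(residual, float(np.max(np.abs(new - phi[color]))))
            phi[color] = new
        it += 1
    if residual > tol:
        raise RuntimeError(f"Laplace solver did not reach tol {tol} "
                           f"in {max_iter} iterations (residual {residual:.2e})")

    # outer-surface points: cortex voxels with an outer 6-neighbour
    surf = ctx & ndimage.binary_dilation(out, struct)
    pts_ijk = np.argwhere(surf)
    pts_um = (pts_ijk + 0.5) * vs

    # gradient of the potential in physical units
    grads = np.gradient(phi, *vs)

    def g_at(pos_um: np.ndarray) -> np.ndarray:
        coords = (pos_um / vs - 0.5).T
        return np.stack([ndimage.map_coordinates(g, coords, order=1,
                                                 mode="nearest")
                         for g in grads], axis=1)

    def trace(start_um: np.ndarray, sign: float, stop_mask: np.ndarray,
              h: float, max_steps: int) -> np.ndarray:
        pos = start_um.copy()
        length = np.zeros(len(pos))
        active = np.ones(len(pos), dtype=bool)
        shape = np.asarray(grid.shape)
        for _ in range(max_steps):
            if not active.any():
                break
            p = pos[active]

            def unit(v: np.ndarray) -> np.ndarray:
                n = np.linalg.norm(v, axis=1, keepdims=True)
                n[n == 0] = 1.0
                return v / n

            k1 = sign * unit(g_at(p))
            k2 = sign * unit(g_at(p + 0.5 * h * k1))
            k3 = sign * unit(g_at(p + 0.5 * h * k2))
            k4 = sign * unit(g_at(p + h * k3))
            step = h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            pos[active] = p + step
            length[active] += np.linalg.norm(step, axis=1)
            ijk = np.clip((pos[active] / vs).astype(int), 0, shape - 1)
            arrived = stop_mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
            idx = np.flatnonzero(active)
            active[idx[arrived]] = False
        return length

    h = step_voxels * float(vs.min())
    extent = float(np.max(np.asarray(grid.shape) * vs))
    max_steps = int(extent / h)
    len_down = trace(pts_um, -1.0, inn, h, max_steps)
    len_up = trace(pts_um, +1.0, out, h, max_steps)
    thickness = len_down + len_up
    return ThicknessField(pts_ijk, pts_um, thickness, phi, it, residual)


def thickness_tmap(fields: Sequence[ThicknessField],
                   genotypes: Sequence[str],
                   wt_label: str = "WT",
                   alpha: float = 0.05) -> TMap:
    """Point-by-point two-sample t-test of thickness between genotypes.

    All fields must share an identical surface point set (phantoms built on
    one grid).  The threshold mask keeps points with uncorrected p < alpha,
    mirroring an uncorrected-map reporting convention.
    """
    ref = fields[0].points_ijk
    for f in fields[1:]:
        if f.points_ijk.shape != ref.shape or not np.array_equal(f.points_ijk, ref):
            raise ValueError("thickness fields are not on a shared point set")
    geno = np.asarray(genotypes)
    data = np.stack([f.thickness_um for f in fields])
    g1 = data[geno == wt_label]
    g2 = data[geno != wt_label]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 animals per group")
    t, p = sps.ttest_ind(g1, g2, axis=0)
    t = np.asarray(t)
    p = np.asarray(p)
    # identical zero-variance data: t undefined -> not significant
    p = np.where(np.isnan(p), 1.0, p)
    return TMap(ref, t, p, p < alpha, alpha)
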