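"""qPCR relative quantification by the standard-curve method.

A serial dilution of pooled cDNA yields, per gene, a least-squares line of
Cq against log10(relative quantity); unknown samples are read off that
curve.  Reference genes are ranked by a NormFinder-style two-level
variance decomposition on log quantities (intragroup variability plus
intergroup bias), samples are normalized to the geometric mean of the best
reference pair, and per-gene group contrasts are reported as
log2(mean_mut / mean_wt) with a normality-gated t-test.

Fold changes are computed on group means of relative quantities (the
standard-curve convention), not per-sample ΔΔCq.  No Cq outlier filtering
is applied by default; a MAD filter is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as stats_core

__all__ = [
    "StandardCurve", "fit_standard_curve", "quantify",
    "stability_rank", "normalize_quantities", "normalize_and_contrast",
]


@dataclass(frozen=True)
class StandardCurve:
    """Fitted Cq vs log10(relative quantity) line for one assay."""

    gene: str
    slope: float
    intercept: float
    r2: float
    efficiency: float           # 10^(−1/slope) − 1
    rejected: bool = False
    reason: str = ""

    def quantity(self, cq: np.ndarray | float) -> np.ndarray | float:
        """Relative quantity read off the curve."""
        return 10.0 ** ((np.asarray(cq, dtype=float) - self.intercept) / self.slope)


def fit_standard_curve(plate: pd.DataFrame, gene: str,
                       mad_filter: bool = False) -> StandardCurve:
    """Fit one gene's dilution series.

    Requires >= 3 dilution points spanning >= 2 log10 units; a
    non-monotone mean Cq vs dilution relationship flags the curve as
    rejected.  Amplification efficiency is 10^(−1/slope) − 1 (−3.32
    cycles per decade at 100%).
    """
    std = plate[(plate["gene"] == gene) & plate["is_standard"]]
    if std["dilution"].nunique() < 3:
        raise ValueError(f"{gene}: dilution series needs >= 3 points")
    logq = np.log10(std["dilution"].to_numpy(dtype=float))
    if logq.max() - logq.min() < 2.0:
        raise ValueError(f"{gene}: dilution series must span >= 2 log10 units")
    cq = std["Cq"].to_numpy(dtype=float)
    if mad_filter:
        med = np.median(cq)
        mad = np.median(np.abs(cq - med))
        keep = np.abs(cq - med) <= 5 * max(mad, 1e-12)
        logq, cq = logq[keep], cq[keep]
    fit = sps.linregress(logq, cq)
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0 if fit.slope < 0 else np.nan
    rejected, reason = False, ""
    mean_by_dil = std.groupby("dilution")["Cq"].mean().sort_index()
    if not np.all(np.diff(mean_by_dil.to_numpy()) < 0):
        rejected, reason = True, "Cq not monotone decreasing with quantity"
    if fit.slope >= 0:
        rejected, reason = True, "non-negative slope"
    return StandardCurve(gene, float(fit.slope), float(fit.intercept),
                         float(fit.rvalue ** 2), float(eff), rejected, reason)


def quantify(plate: pd.DataFrame,
             curves: dict[str, StandardCurve] | None = None) -> pd.DataFrame:
    """Relative quantities for all non-standard wells via per-gene curves."""
    if curves is None:
        curves = {g: fit_standard_curve(plate, g)
                  for g in plate["gene"].unique()}
    unk = plate[~plate["is_standard"]].copy()
    unk["quantity"] = [curves[g].quantity(c)
                       for g, c in zip(unk["gene"], unk["Cq"])]
    return unk


def stability_rank(quantities: pd.DataFrame,
                   candidates: Sequence[str],
                   group_col: str = "group") -> pd.DataFrame:
    """NormFinder-style reference-gene stability ranking.

    Works on log2 quantities with per-sample centering (removing the
    sample loading effect across the candidate panel), then decomposes
    each gene's residuals into intergroup bias and intragroup variance:

        stability = sqrt(mean_g(bias_g²) + mean_g(var_g / n_g))

    Smaller is more stable.  Returns the ranked table; the best pair is
    the 2-combination minimizing the stability of the averaged pseudo-gene.
    Needs >= 3 candidates and >= 2 groups.
    """
    cand = list(candidates)
    if len(cand) < 3:
        raise ValueError("need >= 3 candidate reference genes")
    sub = quantities[quantities["gene"].isin(cand)]
    wide = sub.pivot_table(index="sample", columns="gene", values="quantity")
    groups = sub.drop_duplicates("sample").set_index("sample")[group_col]
    groups = groups.loc[wide.index]
    if groups.nunique() < 2:
        raise ValueError("need >= 2 experimental groups")
    logq = np.log2(wide)
    centered = logq.sub(logq.mean(axis=1), axis=0)  # remove sample effect

    def _stability(values: pd.Series) -> float:
        bias2, varterm = [], []
        overall = values.mean()
        for _, idx in groups.groupby(groups).groups.items():
            v = values.loc[idx]
            bias2.append((v.mean() - overall) ** 2)
            varterm.append(v.var(ddof=1) / len(v) if len(v) > 1 else 0.0)
        return float(np.sqrt(np.mean(bias2) + np.mean(varterm)))

    table = pd.DataFrame({
        "gene": cand,
        "stability": [_stability(centered[g]) for g in cand],
    }).sort_values("stability", kind="stable").reset_index(drop=True)

    best_pair, best_val = None, np.inf
    for i in range(len(cand)):
        for j in range(i + 1, len(cand)):
            pseudo = (centered[cand[i]] + centered[cand[j]]) / 2.0
            v = _stability(pseudo)
            if v < best_val:
                best_pair, best_val = (cand[i], cand[j]), v
    table.attrs["best_pair"] = best_pair
    table.attrs["best_pair_stability"] = best_val
    return table


def normalize_quantities(quantities: pd.DataFrame,
                         reference_pair: tuple[str, str]) -> pd.DataFrame:
    """Divide each sample's quantities by the geometric mean of the pair.

    Samples missing either reference measurement are dropped (logged in
    the returned frame's ``attrs['dropped']``).  Normalization is exactly
    invariant to a per-sample global scale factor.
    """
    ref = quantities[quantities["gene"].isin(reference_pair)]
    factors = ref.pivot_table(index="sample", columns="gene", values="quantity")
    complete = factors.dropna()
    dropped = sorted(set(factors.index) - set(complete.index))
    norm = np.exp(np.log(complete).mean(axis=1))  # geometric mean
    out = quantities[quantities["sample"].isin(complete.index)].copy()
    out["norm_factor"] = out["sample"].map(norm)
    out["rel_expr"] = out["quantity"] / out["norm_factor"]
    out.attrs["dropped"] = dropped
    return out


def normalize_and_contrast(quantities: pd.DataFrame,
                           reference_pair: tuple[str, str],
                           wt_label: str = "WT",
                           mut_label: str = "MUT",
                           group_col: str = "group") -> pd.DataFrame:
    """Per-gene log2 fold change (mutant vs wild type) after normalization.

    log2FC = log2(mean_mut / mean_wt) on normalized relative quantities,
    with Shapiro-Wilk gating and pooled/Welch t-tests per gene (reference
    genes included, as a control: their fold change should sit near 0).
    """
    norm = normalize_quantities(quantities, reference_pair)
    rows = []
    for gene, grp in norm.groupby("gene", sort=False):
        wt = grp.loc[grp[group_col] == wt_label, "rel_expr"].to_numpy(dtype=float)
        mut = grp.loc[grp[group_col] == mut_label, "rel_expr"].to_numpy(dtype=float)
        if wt.size < 2 or mut.size < 2:
            continue
        gate_wt = stats_core.normality_gate(wt)
        gate_mut = stats_core.normality_gate(mut)
        pooled = stats_core.two_sample_test(wt, mut, variant="pooled")
        welch = stats_core.two_sample_test(wt, mut, variant="welch")
        rows.append({"gene": gene, "stage": grp["stage"].iloc[0],
                     "mean_wt": wt.mean(), "mean_mut": mut.mean(),
                     "log2fc": float(np.log2(mut.mean() / wt.mean())),
                     "normality_ok": gate_wt.passed and gate_mut.passed,
                     "t_pooled": pooled.t, "p_pooled": pooled.p,
                     "t_welch": welch.t, "p_welch": welch.p,
                     "is_reference": gene in reference_pair})
    return pd.DataFrame(rows)
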