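"""Cell-type enrichment of DEG lists against marker gene-set collections.

Each marker set (e.g. a cell type's specificity-thresholded gene list) is
tested for overlap with a differentially-expressed-gene list by a
two-sided Fisher exact test on the 2×2 table over an explicit gene
universe, corrected across sets with Benjamini-Hochberg.  Overlaps are
additionally decomposed by direction of change (the fraction of
overlapping DEGs that are down-regulated), and marker panels can be
contrasted between cell-type classes on their log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as stats_core

__all__ = [
    "EnrichmentRow", "fisher_enrichment", "bh_correct",
    "direction_decomposition", "enrichment_table", "marker_contrast",
]


@dataclass(frozen=True)
class EnrichmentRow:
    """One gene set's overlap statistics with the DEG list."""

    set_name: str
    overlap: int
    deg_only: int
    set_only: int
    neither: int
    p: float
    q: float = np.nan
    frac_down: float = np.nan


def bh_correct(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) · m / j, clipped at 1; monotone
    non-decreasing in p and never below the raw p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_enrichment(degs: Sequence[str],
                      sets: Mapping[str, Sequence[str]],
                      universe: Sequence[str],
                      deg_signs: Mapping[str, float] | None = None,
                      ) -> list[EnrichmentRow]:
    """Two-sided Fisher exact enrichment of the DEG list in each gene set.

    The 2×2 table for a set S is (|DEG∩S|, |DEG∖S|, |S∖DEG|, rest) over the
    supplied universe; p is scipy's point-probability two-sided Fisher
    exact.  Rows come back sorted by BH q.  ``deg_signs`` (gene → log2FC or
    sign) additionally fills the down-regulated overlap fraction.
    """
    uni = set(universe)
    deg_set = set(degs)
    stray = deg_set - uni
    if stray:
        raise ValueError(f"DEG {sorted(stray)[0]!r} is not in the gene universe")
    n_uni = len(uni)
    rows = []
    for name, genes in sets.items():
        s = set(genes) & uni
        a = len(deg_set & s)
        b = len(deg_set) - a
        c = len(s) - a
        d = n_uni - a - b - c
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(EnrichmentRow(name, a, b, c, d, float(p)))
    q = bh_correct([r.p for r in rows])
    rows = [EnrichmentRow(r.set_name, r.overlap, r.deg_only, r.set_only,
                          r.neither, r.p, float(qi)) for r, qi in zip(rows, q)]
    if deg_signs is not None:
        rows = direction_decomposition(rows, sets, deg_signs)
    return sorted(rows, key=lambda r: (r.q, r.p))


def direction_decomposition(rows: Sequence[EnrichmentRow],
                            sets: Mapping[str, Sequence[str]],
                            deg_signs: Mapping[str, float],
                            ) -> list[EnrichmentRow]:
    """Fraction of each set's overlapping DEGs that are down-regulated.

    ``deg_signs`` maps every DEG to its log2 fold change (any negative
    value counts as down).  Sets with zero overlap get NaN (undefined)
    rather than 0.
    """
    out = []
    for r in rows:
        members = set(sets[r.set_name])
        overl = [g for g in deg_signs if g in members]
        if overl:
            frac = float(np.mean([deg_signs[g] < 0 for g in overl]))
        else:
            frac = np.nan
        out.append(EnrichmentRow(r.set_name, r.overlap, r.deg_only, r.set_only,
                                 r.neither, r.p, r.q, frac))
    return out


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tidy TSV-ready table (set, overlap, p, q, frac_down, significance)."""
    return pd.DataFrame([{"set": r.set_name, "overlap": r.overlap,
                          "p": r.p, "q": r.q, "frac_down": r.frac_down,
                          "significant": r.q < 0.05} for r in rows])


def marker_contrast(panel: pd.DataFrame,
                    class_a: str, class_b: str,
                    class_col: str = "cell_class",
                    value_col: str = "log2fc") -> dict:
    """Contrast mean marker log2 fold change between two cell-type classes.

    Treats markers (not animals) as the test units: reports the class
    means, their difference (A − B), and a pooled two-sample t-test.
    Classes with fewer than 2 markers are rejected.
    """
    a = panel.loc[panel[class_col] == class_a, value_col].to_numpy(dtype=float)
    b = panel.loc[panel[class_col] == class_b, value_col].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs >= 2 markers")
    res = stats_core.two_sample_test(a, b, variant="pooled")
    return {"class_a": class_a, "class_b": class_b,
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "difference": float(a.mean() - b.mean()),
            "t": res.t, "df": res.df, "p": res.p}
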