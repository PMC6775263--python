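"""Behavioral indices and behavior-taxon Spearman correlation matrices.

The sucrose-preference index is computed from raw intakes as

    SP (%) = sucrose (g) / (sucrose (g) + water (g)) x 100

Taxon-behavior associations are pairwise-complete Spearman rank
correlations (shared implementation with the network edges), annotated
with significance stars at p < 0.05 / 0.01 / 0.001 on the raw p-values;
Benjamini-Hochberg q-values are an optional extra, off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import spearman
from .diffabund import adjust_bh
from .tables import AbundanceTable, BehaviorTable

__all__ = [
    "sucrose_preference",
    "stars_for_p",
    "correlate_behavior",
    "correlate_time_course",
    "CorrelationMatrix",
]


def sucrose_preference(sucrose_g: float, water_g: float) -> float:
    """Sucrose preference percentage from the two intakes."""
    if sucrose_g < 0 or water_g < 0:
        raise ValueError("intakes must be >= 0")
    total = sucrose_g + water_g
    if total == 0:
        raise ValueError("total intake is zero; SP undefined")
    return 100.0 * sucrose_g / total


def stars_for_p(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ''."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationMatrix:
    """Taxa x behavioral-index matrices of rho, p, stars (and optional q)."""

    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    q: pd.DataFrame | None = None

    def to_long(self) -> pd.DataFrame:
        rows = []
        for taxon in self.rho.index:
            for index in self.rho.columns:
                rows.append({
                    "taxon": taxon,
                    "index": index,
                    "rho": self.rho.loc[taxon, index],
                    "p": self.p.loc[taxon, index],
                    "stars": self.stars.loc[taxon, index],
                    "q": self.q.loc[taxon, index] if self.q is not None else np.nan,
                })
        return pd.DataFrame(rows)


def _correlate(abund_frame: pd.DataFrame, behav_frame: pd.DataFrame,
               fdr: bool, min_pairs: int) -> CorrelationMatrix:
    taxa = list(abund_frame.index)
    indices = list(behav_frame.columns)
    rho = pd.DataFrame(np.nan, index=taxa, columns=indices)
    pmat = pd.DataFrame(np.nan, index=taxa, columns=indices)
    shared = [s for s in abund_frame.columns if s in behav_frame.index]
    for index in indices:
        b_all = behav_frame.loc[shared, index].to_numpy(dtype=float)
        for taxon in taxa:
            a_all = abund_frame.loc[taxon, shared].to_numpy(dtype=float)
            ok = ~(np.isnan(a_all) | np.isnan(b_all))
            if ok.sum() < min_pairs:
                continue
            a, b = a_all[ok], b_all[ok]
            if np.all(a == a[0]) or np.all(b == b[0]):
                continue  # constant vector: correlation undefined, cell missing
            r, p = spearman(a, b)
            rho.loc[taxon, index] = r
            pmat.loc[taxon, index] = p
    stars = pmat.map(stars_for_p)
    q = None
    if fdr:
        q = pmat.copy()
        for index in indices:
            q[index] = adjust_bh(pmat[index].to_numpy())
    return CorrelationMatrix(rho, pmat, stars, q)


def correlate_behavior(t: AbundanceTable, b: BehaviorTable, taxa_subset=None,
                       fdr: bool = False, min_pairs: int = 4) -> CorrelationMatrix:
    """Spearman correlation of each taxon's abundance with each behavioral
    index over pairwise-complete samples (>= ``min_pairs`` required)."""
    frame = t.to_frame()
    if taxa_subset is not None:
        missing = [x for x in taxa_subset if x not in frame.index]
        if missing:
            raise ValueError(f"taxa not in the abundance table: {missing}")
        frame = frame.loc[list(taxa_subset)]
    return _correlate(frame, b.data, fdr, min_pairs)


def correlate_time_course(t: AbundanceTable, sp_by_time: dict, taxa_subset=None,
                          fdr: bool = False, min_pairs: int = 4) -> CorrelationMatrix:
    """Correlate taxa with the sucrose-preference time course: one column
    per timepoint (e.g. "1h", "4h", "16h", "24h").

    ``sp_by_time`` maps a timepoint label to a per-sample SP vector
    (a mapping or pandas Series indexed by sample id)."""
    cols = {}
    for label, vec in sp_by_time.items():
        cols[str(label)] = pd.Series(vec, dtype=float)
    behav = pd.DataFrame(cols)
    frame = t.to_frame()
    if taxa_subset is not None:
        frame = frame.loc[list(taxa_subset)]
    return _correlate(frame, behav, fdr, min_pairs)
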