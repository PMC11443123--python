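"""Corpus-level statistics on predictability.

Three analyses: the paired hemispheric (laterality) t-test on per-map
left/right means, the per-parcel "predictability brain map" (which brain
structures carry highly predictable functions), and its Spearman correlation
with externally supplied gradient vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import ols_slope_t, spearman
from .errors import ZeroVarianceError
from .maps_io import AtlasParcellation, ParcelMatrix, split_hemispheres


@dataclass
class LateralityResult:
    t: float
    df: int
    p: float
    mean_left: float
    mean_right: float
    n_maps: int

    def __post_init__(self):
        if self.df != self.n_maps - 1:
            raise ValueError("paired design requires df = n_maps - 1")


@dataclass
class PredictabilityBrainMap:
    """Per-parcel t statistic of the index coefficient, df = n_maps - 2."""

    t_values: pd.Series
    df: int

    def __post_init__(self):
        if not np.isfinite(self.t_values.to_numpy(dtype=float)).all():
            raise ValueError("brain map contains non-finite t values")


def laterality_ttest(matrix: ParcelMatrix, atlas: AtlasParcellation) -> LateralityResult:
    """Paired two-sided t-test of per-map left vs right hemispheric means.

    Each map contributes one (mean over L parcels, mean over R parcels)
    pair; midline parcels are excluded by :func:`split_hemispheres`.  The
    paired design gives df = n_maps - 1.
    """
    if matrix.n_maps < 3:
        raise ValueError("need at least 3 maps for the paired t-test")
    left, right = [], []
    for map_id in matrix.map_ids:
        s = split_hemispheres(matrix.row(map_id), atlas)
        left.append(s.left_mean)
        right.append(s.right_mean)
    left = np.array(left)
    right = np.array(right)
    n = matrix.n_maps
    if np.all(left == right):
        t_stat, p_val = 0.0, 1.0  # exactly balanced hemispheres
    else:
        res = stats.ttest_rel(left, right)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return LateralityResult(
        t=t_stat, df=n - 1, p=p_val,
        mean_left=float(left.mean()), mean_right=float(right.mean()), n_maps=n,
    )


def predictability_map(matrix: ParcelMatrix, results: pd.DataFrame) -> PredictabilityBrainMap:
    """Regress each parcel's activation across maps on the predictability index.

    For parcel p the measured values over the n maps are the response and the
    per-map index the regressor; the map of slope t statistics highlights
    structures whose activation tracks high predictability.  A constant index
    raises :class:`ZeroVarianceError`.
    """
    idx = results.set_index("map_id")["index"]
    missing = [m for m in matrix.map_ids if m not in idx.index]
    if missing:
        raise ValueError(f"results missing for maps: {missing[:10]}")
    x = idx.loc[matrix.map_ids].to_numpy(dtype=float)
    _, _, t, df = ols_slope_t(x, matrix.values)
    return PredictabilityBrainMap(
        t_values=pd.Series(t, index=matrix.parcel_ids), df=df)


def gradient_correlation(brain_map: PredictabilityBrainMap,
                         gradients: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho (+ two-sided p) between the predictability map and each
    gradient column; parcels are aligned by id, ties get average ranks."""
    t = brain_map.t_values
    missing = [p for p in t.index if p not in gradients.index]
    if missing:
        raise ValueError(f"gradients missing parcels: {missing[:10]}")
    aligned = gradients.loc[t.index]
    rows = []
    for col in aligned.columns:
        rho, p = spearman(t.to_numpy(dtype=float),
                          aligned[col].to_numpy(dtype=float))
        rows.append({"gradient_id": col, "rho": rho, "p": p})
    return pd.DataFrame(rows)
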