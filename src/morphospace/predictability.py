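"""Distance-regression prediction of map anatomy and the predictability index.

Every map in a fitted morphospace can be *predicted* from the remaining
(reference) maps: for each parcel, the reference values are regressed on the
negated embedded distance to the target, so that references closer to the
target weigh in with positive slope where activation rises towards it.  The
t statistic of that slope, converted to a z score and thresholded like the
measured maps, is the predicted activation.  The correlation between
predicted and measured parcel vectors is the map's **predictability index**:
a [-1, 1] coherence score of the map with the corpus.

Leaving each map out in turn gives the corpus-wide index table; projecting
unseen maps with UMAP's transform and scoring them with Spearman extends the
index out of sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from ._stats import ols_slope_t, pearson, spearman, t_to_z
from .embedding import Morphospace, transform_new
from .errors import ZeroVarianceError
from .maps_io import ParcelMatrix, ThresholdPolicy

__all__ = [
    "DistanceRegressionModel", "PredictedMap", "PredictabilityResult",
    "predict_map", "t_to_z", "predictability_index", "loo_predictability",
    "project_and_predict", "knn_index_summary", "covariate_correlation",
]

MIN_REFERENCES = 4


@dataclass
class DistanceRegressionModel:
    """Per-parcel OLS of reference activations on [1, -distance]."""

    target_id: str
    reference_ids: list
    table: pd.DataFrame  # per parcel: intercept, slope, t
    df: int

    def __post_init__(self):
        if self.df < 1:
            raise ValueError("df must be >= 1")


@dataclass
class PredictedMap:
    """A predicted parcel vector in z units.

    ``values`` is thresholded (entries are 0 or >= the threshold);
    ``z_raw`` keeps the unthresholded z scores for scale-sensitive uses.
    """

    target_id: str
    values: pd.Series
    z_raw: pd.Series
    threshold: float
    provenance: str = ""

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if not np.all((v == 0) | (v >= self.threshold)):
            raise ValueError("thresholded values must be 0 or >= threshold")


@dataclass
class PredictabilityResult:
    map_id: str
    index: float
    method: str
    n_parcels: int

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.index <= 1.0 + 1e-12:
            raise ValueError("index must lie in [-1, 1]")


def _distances_to_target(space: Morphospace, target_id: str) -> Tuple[np.ndarray, list]:
    coords = space.coordinates
    if target_id not in coords.index:
        raise KeyError(f"map {target_id!r} is not in the fitted space")
    target = coords.loc[target_id].to_numpy(dtype=float)
    refs = [m for m in coords.index if m != target_id]
    d = np.linalg.norm(coords.loc[refs].to_numpy(dtype=float) - target, axis=1)
    return d, refs


def _regress_from_distances(d: np.ndarray, Y: np.ndarray, target_id: str,
                            refs: list, parcel_ids: list,
                            policy: ThresholdPolicy,
                            provenance: str) -> Tuple[DistanceRegressionModel, PredictedMap]:
    if len(refs) < MIN_REFERENCES:
        raise ValueError(f"need at least {MIN_REFERENCES} reference maps, got {len(refs)}")
    if np.ptp(d) == 0:
        raise ZeroVarianceError("embedded distances to the target have zero variance")
    intercept, slope, t, df = ols_slope_t(-d, Y)
    z = t_to_z(t, df)
    model = DistanceRegressionModel(
        target_id=target_id,
        reference_ids=refs,
        table=pd.DataFrame({"intercept": intercept, "slope": slope, "t": t},
                           index=parcel_ids),
        df=df,
    )
    z_raw = pd.Series(z, index=parcel_ids)
    predicted = PredictedMap(
        target_id=target_id,
        values=pd.Series(policy.apply(z), index=parcel_ids),
        z_raw=z_raw,
        threshold=policy.z_crit,
        provenance=provenance,
    )
    return model, predicted


def predict_map(target_id: str, space: Morphospace, matrix: ParcelMatrix, *,
                policy: ThresholdPolicy = ThresholdPolicy(),
                backend: str = "regression") -> Tuple[Optional[DistanceRegressionModel], PredictedMap]:
    """Predict one map's parcel vector from its embedded distances to the rest.

    ``backend="regression"`` (default): per parcel, OLS of reference values
    on ``[1, -d]`` (d = embedded Euclidean distance reference -> target);
    the prediction is the t statistic of the ``-d`` regressor converted to z
    and thresholded at ``policy.z_crit``.  Parcels constant across references
    get t = 0; exact fits are capped at the value mapping to the z cap.

    ``backend="idw"``: inverse-squared-distance weighted average of reference
    values, thresholded the same way (an interpolation alternative; note its
    output is in measured-map units, not t-derived z units).
    """
    d, refs = _distances_to_target(space, target_id)
    Y = matrix.subset(refs).values
    parcel_ids = matrix.parcel_ids
    if backend == "regression":
        return _regress_from_distances(d, Y, target_id, refs, parcel_ids,
                                       policy, space.training_checksum)
    if backend == "idw":
        if len(refs) < MIN_REFERENCES:
            raise ValueError(f"need at least {MIN_REFERENCES} reference maps")
        w = 1.0 / np.maximum(d, 1e-12) ** 2
        pred = (w @ Y) / w.sum()
        z_raw = pd.Series(pred, index=parcel_ids)
        return None, PredictedMap(
            target_id=target_id,
            values=pd.Series(policy.apply(pred), index=parcel_ids),
            z_raw=z_raw,
            threshold=policy.z_crit,
            provenance=space.training_checksum,
        )
    raise ValueError(f"unknown backend {backend!r}")


def predictability_index(predicted: PredictedMap, measured: pd.Series,
                         method: str = "pearson", *,
                         thresholded: bool = True) -> PredictabilityResult:
    """Correlate a predicted map with the measured one over all parcels.

    With ``thresholded=True`` (default) both sides are thresholded at the
    prediction's z threshold before correlating — zeros included — mirroring
    how the measured maps themselves are cleaned.  ``thresholded=False``
    correlates raw z predictions with raw measured values instead (useful
    when the measured values are not on a calibrated z scale).

    Spearman uses average ranks for ties.  Constant input on either side
    raises :class:`ZeroVarianceError`.
    """
    if not predicted.values.index.equals(measured.index):
        raise ValueError("predicted and measured parcel sets differ")
    if thresholded:
        x = predicted.values.to_numpy(dtype=float)
        y = np.where(measured.to_numpy(dtype=float) >= predicted.threshold,
                     measured.to_numpy(dtype=float), 0.0)
    else:
        x = predicted.z_raw.to_numpy(dtype=float)
        y = measured.to_numpy(dtype=float)
    if method == "pearson":
        r, _ = pearson(x, y)
    elif method == "spearman":
        r, _ = spearman(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PredictabilityResult(map_id=predicted.target_id, index=r,
                                method=method, n_parcels=len(measured))


def _score_rows(space: Morphospace, matrix: ParcelMatrix, coords: pd.DataFrame,
                targets: ParcelMatrix, method: str, thresholded: bool,
                policy: ThresholdPolicy, exclude_self: bool) -> pd.DataFrame:
    """Predict+score each row of ``targets`` located at ``coords``."""
    ref_coords = space.coordinates.to_numpy(dtype=float)
    ref_ids = space.map_ids
    Y_all = matrix.values
    parcel_ids = matrix.parcel_ids
    rows = []
    for map_id in targets.map_ids:
        point = coords.loc[map_id].to_numpy(dtype=float)
        if exclude_self:
            keep = [i for i, m in enumerate(ref_ids) if m != map_id]
        else:
            keep = list(range(len(ref_ids)))
        d = np.linalg.norm(ref_coords[keep] - point, axis=1)
        _, predicted = _regress_from_distances(
            d, Y_all[keep], map_id, [ref_ids[i] for i in keep], parcel_ids,
            policy, space.training_checksum)
        measured = targets.row(map_id)
        res = predictability_index(predicted, measured, method=method,
                                   thresholded=thresholded)
        pred_vals = predicted.values if thresholded else predicted.z_raw
        meas_vals = (np.where(measured >= policy.z_crit, measured, 0.0)
                     if thresholded else measured.to_numpy(dtype=float))
        mae = float(np.mean(np.abs(pred_vals.to_numpy(dtype=float) - meas_vals)))
        rows.append({"map_id": map_id, "index": res.index, "method": method,
                     "n_parcels": res.n_parcels, "mae": mae})
    return pd.DataFrame(rows)


def loo_predictability(space: Morphospace, matrix: ParcelMatrix,
                       method: str = "pearson", *,
                       thresholded: bool = True,
                       policy: ThresholdPolicy = ThresholdPolicy()) -> pd.DataFrame:
    """Leave-one-out predictability index for every map in the space.

    Each map in turn is the target; all remaining maps are references.  The
    result table (map_id, index, method, n_parcels, mae) is independent of
    map ordering.
    """
    if list(space.map_ids) != list(matrix.map_ids):
        raise ValueError("space and matrix must cover the same maps in the same order")
    return _score_rows(space, matrix, space.coordinates, matrix,
                       method, thresholded, policy, exclude_self=True)


def project_and_predict(space: Morphospace, matrix: ParcelMatrix,
                        new_maps: ParcelMatrix, *,
                        method: str = "spearman",
                        thresholded: bool = True,
                        policy: ThresholdPolicy = ThresholdPolicy()
                        ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Project unseen maps into the space and score their predictions.

    New maps are placed by UMAP transform; each is then predicted from *all*
    training references (distance regression as in :func:`predict_map`) and
    scored against its own measured vector — Spearman by default, as rank
    correlation is robust to the unknown scale of out-of-sample maps.

    Returns (result table, projected coordinates).
    """
    coords = transform_new(space, new_maps)
    results = _score_rows(space, matrix, coords, new_maps, method,
                          thresholded, policy, exclude_self=False)
    return results, coords


def knn_index_summary(space: Morphospace, results: pd.DataFrame,
                      query: np.ndarray, k: int = 5) -> float:
    """Mean predictability index of the k training maps nearest to a point.

    Ties in distance are broken by map order (map_id order of the fitted
    space).  ``query`` is a single coordinate vector in embedding space.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(space.map_ids):
        raise ValueError(f"k={k} exceeds the {len(space.map_ids)} training maps")
    query = np.asarray(query, dtype=float).ravel()
    coords = space.coordinates.to_numpy(dtype=float)
    d = np.linalg.norm(coords - query, axis=1)
    order = np.argsort(d, kind="stable")[:k]
    idx = results.set_index("map_id")["index"]
    neighbours = [space.map_ids[i] for i in order]
    return float(idx.loc[neighbours].mean())


@dataclass
class CovariateCorrelation:
    r: float
    p: float
    n: int


def covariate_correlation(results: pd.DataFrame, covariate: pd.Series) -> CovariateCorrelation:
    """Pearson correlation between the index and a per-map covariate
    (e.g. the number of studies behind each meta-analytic map)."""
    idx = results.set_index("map_id")["index"]
    missing = [m for m in idx.index if m not in covariate.index]
    if missing:
        raise ValueError(f"covariate missing for maps: {missing[:10]}")
    cov = covariate.loc[idx.index].to_numpy(dtype=float)
    r, p = pearson(idx.to_numpy(dtype=float), cov)
    return CovariateCorrelation(r=r, p=p, n=len(idx))
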