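"""Reading, thresholding and parcel-level reduction of statistical brain maps.

The module revolves around three containers:

* :class:`VolumeMap` — one statistical volume (z or t per voxel) with its
  affine and term metadata;
* :class:`AtlasParcellation` — an integer label volume plus a parcel table
  (id, name, hemisphere);
* :class:`ParcelMatrix` — the maps x parcels matrix of mean statistics that
  every downstream stage consumes.

Volumes travel as NIfTI-1 through :mod:`nibabel`; parcel tables and matrices
as UTF-8 TSV.  Maps and atlases must live on the same voxel grid: no silent
resampling is ever performed — use :func:`resample_map` /
:func:`resample_labels` explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import (
    EmptyParcelError,
    GridMismatchError,
    ParcelMismatchError,
    StatKindError,
)

HEMISPHERES = ("L", "R", "M")

#: mm tolerance when comparing affines of a map and an atlas.
AFFINE_ATOL = 1e-4


@dataclass
class VolumeMap:
    """A statistical brain volume (z- or t-statistic per voxel).

    Parameters
    ----------
    values : (i, j, k) float array
        Statistic per voxel; must be finite everywhere.
    affine : (4, 4) array
        Voxel -> mm transform; must be invertible.
    stat_kind : {"z", "t"}
    term : str
        The cognitive term (or frame label) the map summarises.
    source : str
        Free-text provenance tag.
    n_studies : int, optional
        Number of studies aggregated in a meta-analytic map.
    """

    values: np.ndarray
    affine: np.ndarray
    stat_kind: str = "z"
    term: str = ""
    source: str = ""
    n_studies: Optional[int] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if not np.isfinite(self.values).all():
            raise ValueError("map contains non-finite values")
        if self.stat_kind not in ("z", "t"):
            raise ValueError(f"stat_kind must be 'z' or 't', got {self.stat_kind!r}")
        if self.n_studies is not None and self.n_studies < 0:
            raise ValueError("n_studies must be nonnegative")

    @property
    def dims(self) -> tuple:
        return self.values.shape

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.values, self.affine), str(path))

    @classmethod
    def from_nifti(cls, path, stat_kind="z", term="", source="", n_studies=None):
        img = nib.load(str(path))
        return cls(
            values=np.asarray(img.get_fdata(), dtype=float),
            affine=img.affine,
            stat_kind=stat_kind,
            term=term or Path(path).stem.replace(".nii", ""),
            source=source,
            n_studies=n_studies,
        )


@dataclass(frozen=True)
class ThresholdPolicy:
    """Cleaning rule for z maps: voxels below ``z_crit`` are set to zero.

    The default 3.4 corresponds to a one-sided normal tail probability of
    about 3.37e-4 and is the customary cut for meta-analytic z maps.
    """

    z_crit: float = 3.4

    def __post_init__(self):
        if not self.z_crit > 0:
            raise ValueError("z_crit must be positive")

    def apply(self, values: np.ndarray) -> np.ndarray:
        return np.where(values >= self.z_crit, values, 0.0)


@dataclass
class AtlasParcellation:
    """Integer label volume plus a parcel table.

    ``label_volume`` holds one integer per voxel, 0 meaning background.
    ``parcels`` is a DataFrame with columns ``parcel_id`` (unique, >= 1),
    ``name``, ``hemisphere`` (L/R/M) and ``atlas`` (source tag).
    """

    label_volume: np.ndarray
    affine: np.ndarray
    parcels: pd.DataFrame

    def __post_init__(self):
        self.label_volume = np.asarray(self.label_volume)
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            rounded = np.rint(self.label_volume)
            if not np.allclose(self.label_volume, rounded):
                raise ValueError("label volume must be integer-valued")
            self.label_volume = rounded.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=float)
        required = {"parcel_id", "name", "hemisphere"}
        if not required.issubset(self.parcels.columns):
            raise ValueError(f"parcel table needs columns {sorted(required)}")
        ids = self.parcels["parcel_id"].to_numpy()
        if len(ids) != len(set(ids)):
            raise ValueError("parcel ids must be unique")
        if (ids < 1).any():
            raise ValueError("parcel ids must be >= 1 (0 is background)")
        bad_hemi = set(self.parcels["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere codes: {sorted(bad_hemi)}")
        present = set(np.unique(self.label_volume)) - {0}
        missing = present - set(ids.tolist())
        if missing:
            raise ValueError(
                f"labels present in volume but absent from parcel table: {sorted(missing)}"
            )

    @property
    def parcel_ids(self) -> np.ndarray:
        return self.parcels["parcel_id"].to_numpy()

    @property
    def dims(self) -> tuple:
        return self.label_volume.shape

    def to_files(self, label_path, table_path) -> None:
        nib.save(nib.Nifti1Image(self.label_volume.astype(np.int32), self.affine), str(label_path))
        self.parcels.to_csv(table_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, label_path, table_path):
        img = nib.load(str(label_path))
        table = pd.read_csv(table_path, sep="\t")
        return cls(
            label_volume=np.asarray(img.get_fdata()),
            affine=img.affine,
            parcels=table,
        )


class ParcelMatrix:
    """Maps x parcels matrix of mean statistics — the universal exchange object.

    Wraps a DataFrame whose index holds map ids (strings) and whose columns
    hold parcel ids (ints).  All entries must be finite.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise ValueError("ParcelMatrix must have at least one map and one parcel")
        if data.index.has_duplicates:
            raise ValueError("duplicate map ids")
        if data.columns.has_duplicates:
            raise ValueError("duplicate parcel ids")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("ParcelMatrix entries must be finite")
        data = data.astype(float)
        data.columns = [int(c) for c in data.columns]
        data.index = data.index.astype(str)
        self._data = data

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def map_ids(self) -> list:
        return list(self._data.index)

    @property
    def parcel_ids(self) -> list:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy(dtype=float)

    @property
    def n_maps(self) -> int:
        return self._data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self._data.shape[1]

    def row(self, map_id: str) -> pd.Series:
        return self._data.loc[str(map_id)]

    def subset(self, map_ids: Sequence[str]) -> "ParcelMatrix":
        return ParcelMatrix(self._data.loc[list(map_ids)].copy())

    def __repr__(self):
        return f"ParcelMatrix({self.n_maps} maps x {self.n_parcels} parcels)"

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self._data.copy()
        out.index.name = "map_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ParcelMatrix":
        data = pd.read_csv(path, sep="\t", index_col="map_id",
                           float_precision="round_trip")
        return cls(data)


class HemisphereSplit(NamedTuple):
    left_mean: float
    right_mean: float
    n_midline_excluded: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def threshold(vol: VolumeMap, policy: ThresholdPolicy = ThresholdPolicy(), *,
              allow_stat_kind_mismatch: bool = False) -> VolumeMap:
    """Zero every voxel whose value falls below ``policy.z_crit``.

    Values exactly at the threshold survive.  The operation is idempotent and
    leaves the grid and affine untouched.  Applying a z threshold to a t map
    is refused unless ``allow_stat_kind_mismatch`` is set.
    """
    if vol.stat_kind != "z" and not allow_stat_kind_mismatch:
        raise StatKindError(
            f"threshold expects a z map, got stat_kind={vol.stat_kind!r}; "
            "convert t->z first or pass allow_stat_kind_mismatch=True"
        )
    return VolumeMap(
        values=policy.apply(vol.values),
        affine=vol.affine,
        stat_kind=vol.stat_kind,
        term=vol.term,
        source=vol.source,
        n_studies=vol.n_studies,
    )


def _check_same_grid(vol: VolumeMap, atlas: AtlasParcellation) -> None:
    if vol.dims != atlas.dims:
        raise GridMismatchError(
            f"map grid {vol.dims} != atlas grid {atlas.dims}; "
            "resample explicitly with resample_map/resample_labels"
        )
    if not np.allclose(vol.affine, atlas.affine, atol=AFFINE_ATOL):
        raise GridMismatchError(
            "map and atlas affines differ beyond 1e-4 mm; "
            "resample explicitly with resample_map/resample_labels"
        )


def parcellate(vol: VolumeMap, atlas: AtlasParcellation, *,
               mode: str = "mean") -> pd.Series:
    """Reduce a volume to one mean statistic per parcel.

    ``mode="mean"`` (default) averages over *all* voxels of the parcel,
    zeros included, so the reduction stays linear in the input volume.
    ``mode="nonzero_mean"`` averages only voxels with nonzero values
    (0.0 if the parcel is entirely zero).

    Returns a Series indexed by parcel id, in parcel-table order.
    """
    if mode not in ("mean", "nonzero_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_same_grid(vol, atlas)
    labels = atlas.label_volume.ravel()
    vals = vol.values.ravel()
    nmax = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=nmax)
    sums = np.bincount(labels, weights=vals, minlength=nmax)
    out = {}
    for pid in atlas.parcel_ids:
        if pid >= nmax or counts[pid] == 0:
            raise EmptyParcelError(f"parcel {pid} has no voxels in the label volume")
        if mode == "mean":
            out[pid] = sums[pid] / counts[pid]
        else:
            mask = (labels == pid) & (vals != 0)
            nz = int(mask.sum())
            out[pid] = float(vals[mask].sum() / nz) if nz else 0.0
    return pd.Series(out, name=vol.term or None, dtype=float)


def stack(vectors: Iterable[pd.Series], map_ids: Optional[Sequence[str]] = None) -> ParcelMatrix:
    """Stack parcel vectors (one per map) into a :class:`ParcelMatrix`.

    Row order follows input order.  All vectors must share the same parcel
    index; map ids come from ``map_ids`` or from each Series' ``name``.
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("cannot stack zero maps")
    ref_index = vectors[0].index
    for i, v in enumerate(vectors[1:], start=1):
        if not v.index.equals(ref_index):
            extra = sorted(set(v.index) - set(ref_index))
            missing = sorted(set(ref_index) - set(v.index))
            raise ParcelMismatchError(
                f"vector {i} parcel set differs from vector 0: "
                f"extra={extra[:10]}, missing={missing[:10]}"
            )
    if map_ids is None:
        map_ids = [str(v.name) if v.name is not None else f"map_{i:04d}"
                   for i, v in enumerate(vectors)]
    if len(map_ids) != len(vectors):
        raise ValueError("map_ids length must match number of vectors")
    data = pd.DataFrame([v.to_numpy(dtype=float) for v in vectors],
                        index=[str(m) for m in map_ids],
                        columns=list(ref_index))
    return ParcelMatrix(data)


def make_uniform_parcellation(mask: VolumeMap, k: int, seed: int = 0) -> AtlasParcellation:
    """Partition the in-mask voxels into ``k`` spatially uniform parcels.

    k-means on voxel mm-coordinates: parcels are Voronoi cells of the fitted
    centroids, hence contiguous and of roughly equal extent.  Deterministic
    given ``seed``.  Hemisphere tags come from the sign of the centroid x
    coordinate (negative = L, positive = R, |x| < 1e-6 = M).
    """
    in_mask = np.argwhere(mask.values > 0)
    n_vox = in_mask.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_vox:
        raise ValueError(f"k={k} exceeds the {n_vox} in-mask voxels")
    mm = nib.affines.apply_affine(mask.affine, in_mask)
    if k == n_vox:
        labels = np.arange(n_vox)
    elif k == 1:
        labels = np.zeros(n_vox, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=4, random_state=seed)
        labels = km.fit_predict(mm)
    label_volume = np.zeros(mask.dims, dtype=np.int32)
    label_volume[tuple(in_mask.T)] = labels + 1
    rows = []
    for pid in range(1, k + 1):
        cx = mm[labels == pid - 1].mean(axis=0)
        hemi = "M" if abs(cx[0]) < 1e-6 else ("L" if cx[0] < 0 else "R")
        rows.append({"parcel_id": pid, "name": f"uniform_{pid:04d}",
                     "hemisphere": hemi, "atlas": f"uniform_k{k}"})
    return AtlasParcellation(label_volume=label_volume, affine=mask.affine,
                             parcels=pd.DataFrame(rows))


def split_hemispheres(vector: pd.Series, atlas: AtlasParcellation) -> HemisphereSplit:
    """Mean statistic over left- and over right-hemisphere parcels.

    Midline (``M``) parcels are excluded; their count is reported in the
    result.  Raises if either hemisphere has no parcel.
    """
    table = atlas.parcels.set_index("parcel_id")["hemisphere"]
    ids = [pid for pid in vector.index if pid in table.index]
    if len(ids) != len(vector):
        missing = sorted(set(vector.index) - set(table.index))
        raise ParcelMismatchError(f"parcels absent from atlas table: {missing[:10]}")
    hemi = table.loc[ids]
    left = vector[hemi[hemi == "L"].index]
    right = vector[hemi[hemi == "R"].index]
    n_mid = int((hemi == "M").sum())
    if len(left) == 0 or len(right) == 0:
        raise ValueError("atlas must contain parcels in both hemispheres")
    return HemisphereSplit(float(left.mean()), float(right.mean()), n_mid)


# ---------------------------------------------------------------------------
# resampling + inverse parcellation utilities
# ---------------------------------------------------------------------------

def resample_map(vol: VolumeMap, target_affine, target_shape) -> VolumeMap:
    """Trilinear resampling of a statistic volume onto a target grid."""
    from nilearn.image import resample_img

    img = resample_img(
        nib.Nifti1Image(vol.values, vol.affine),
        target_affine=np.asarray(target_affine, dtype=float),
        target_shape=tuple(target_shape),
        interpolation="continuous",
        force_resample=True,
        copy_header=True,
    )
    return VolumeMap(np.asarray(img.get_fdata(), dtype=float), img.affine,
                     vol.stat_kind, vol.term, vol.source, vol.n_studies)


def resample_labels(atlas: AtlasParcellation, target_affine, target_shape) -> AtlasParcellation:
    """Nearest-neighbour resampling of a label volume onto a target grid."""
    from nilearn.image import resample_img

    img = resample_img(
        nib.Nifti1Image(atlas.label_volume.astype(np.int32), atlas.affine),
        target_affine=np.asarray(target_affine, dtype=float),
        target_shape=tuple(target_shape),
        interpolation="nearest",
        force_resample=True,
        copy_header=True,
    )
    return AtlasParcellation(np.asarray(img.get_fdata()), img.affine, atlas.parcels.copy())


def unparcellate(vector: pd.Series, atlas: AtlasParcellation, *,
                 stat_kind: str = "z", term: str = "") -> VolumeMap:
    """Paint a parcel vector back into a volume (each voxel takes its parcel value)."""
    lut = np.zeros(int(atlas.label_volume.max()) + 1, dtype=float)
    for pid, val in vector.items():
        lut[int(pid)] = val
    return VolumeMap(lut[atlas.label_volume], atlas.affine, stat_kind=stat_kind, term=term)
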