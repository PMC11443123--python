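"""Synthetic data with known ground truth for every downstream stage.

Four generators:

* :func:`make_toy_atlas` — a small label volume tiling a grid, with parcel
  centroids in mm;
* :func:`make_branch_maps` — a map collection whose latent geometry is a
  star of rays ("branches") in 3D, each map being a smooth nonnegative
  activation bump over parcel space;
* :func:`make_autocorrelated_field` — one draw from a Gaussian field with
  exponential spatial covariance over parcel centroids;
* :func:`make_term_corpus` — a term-document count matrix with planted
  topic blocks.

All generators are bit-for-bit reproducible given their seed, and their
outputs serialize to the same TSV/NIfTI formats :mod:`morphospace.maps_io`
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .maps_io import AtlasParcellation, ParcelMatrix, VolumeMap, make_uniform_parcellation


@dataclass(frozen=True)
class BranchSpec:
    """Study conditions for the branch-structured map collection.

    The latent skeleton is ``n_branches`` rays leaving the origin of a 3D
    latent space; each branch carries ``maps_per_branch`` maps at evenly
    spaced radii between ``hub_gap * branch_separation`` (branches detach
    from the hub with distinct identities) and ``branch_separation``, plus
    optional unlabelled maps near the centre.  Each map's parcel loading is a Gaussian bump (width
    ``smoothness * branch_separation``) around its latent position, scaled to
    a z-like peak ``amplitude``, with optional iid parcel noise.

    ``directions="planar"`` (default) spaces the rays at equal angles within
    a plane, so every branch points away from all others — the star-shaped
    arrangement in which inter-map distance is informative about map
    dissimilarity everywhere.  ``directions="axes"`` uses the +-coordinate
    axes instead, giving an intrinsically 3D star for up to six branches.

    Defaults define a 60-map, noiseless collection over 120 parcels.
    """

    n_branches: int = 3
    maps_per_branch: int = 20
    n_center_maps: int = 0
    n_parcels: int = 120
    branch_separation: float = 10.0
    noise_sd: float = 0.0
    amplitude: float = 8.0
    smoothness: float = 0.6
    anchor_frac: float = 0.3
    hub_gap: float = 0.35
    directions: str = "planar"
    seed: int = 0

    def __post_init__(self):
        if self.n_branches < 2:
            raise ValueError("need at least 2 branches")
        if self.n_parcels < 10:
            raise ValueError("need at least 10 parcels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.directions not in ("planar", "axes"):
            raise ValueError("directions must be 'planar' or 'axes'")
        if self.directions == "axes" and self.n_branches > 6:
            raise ValueError("'axes' supports at most 6 branches")
        if not self.anchor_frac > 0:
            raise ValueError("anchor_frac must be positive")
        if not 0 <= self.hub_gap < 1:
            raise ValueError("hub_gap must lie in [0, 1)")

    @property
    def n_maps(self) -> int:
        return self.n_branches * self.maps_per_branch + self.n_center_maps


@dataclass
class SyntheticDataset:
    """A generated map collection plus its ground truth.

    ``truth`` has one row per map: map_id, branch label (``branch_<b>`` or
    ``center``), and the latent 3D coordinates.  ``centroids`` gives the mm
    coordinates of every parcel.
    """

    parcel_matrix: ParcelMatrix
    truth: pd.DataFrame
    centroids: pd.DataFrame

    def truth_to_tsv(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def centroids_to_tsv(self, path) -> None:
        self.centroids.to_csv(path, sep="\t", index=False)


def make_toy_atlas(grid_dims=(8, 8, 8), n_parcels: int = 8, seed: int = 0,
                   voxel_size: float = 2.0) -> Tuple[AtlasParcellation, pd.DataFrame]:
    """A toy parcellation tiling a full grid, centred on the origin.

    Every voxel of the grid is in-mask; parcels are Voronoi cells of a
    k-means on voxel mm-coordinates, so they are contiguous and tile the
    grid.  The affine centres the grid at mm origin, which puts roughly half
    the parcels in each hemisphere.

    Returns the atlas and a centroid table (parcel_id, x, y, z in mm,
    centroid = mean voxel mm-coordinate).
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    n_vox = int(np.prod(grid_dims))
    if n_parcels > n_vox:
        raise ValueError(f"n_parcels={n_parcels} exceeds the {n_vox} grid voxels")
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = -(np.array(grid_dims) - 1) / 2.0 * voxel_size
    mask = VolumeMap(np.ones(grid_dims), affine, stat_kind="z", term="mask")
    atlas = make_uniform_parcellation(mask, n_parcels, seed=seed)
    centroids = parcel_centroids(atlas)
    return atlas, centroids


def parcel_centroids(atlas: AtlasParcellation) -> pd.DataFrame:
    """Mean mm-coordinate of each parcel's voxels."""
    import nibabel as nib

    rows = []
    for pid in atlas.parcel_ids:
        ijk = np.argwhere(atlas.label_volume == pid)
        mm = nib.affines.apply_affine(atlas.affine, ijk).mean(axis=0)
        rows.append({"parcel_id": int(pid), "x": mm[0], "y": mm[1], "z": mm[2]})
    return pd.DataFrame(rows)


def _branch_directions(spec: BranchSpec) -> np.ndarray:
    """Unit direction per branch.

    "planar": equal angles ``2*pi*b/B`` in the xy-plane, so branches are
    mutually opposed.  "axes": the +-coordinate axes (x, -x, y, -y, z, -z).
    """
    if spec.directions == "axes":
        axes = np.array([
            [1, 0, 0], [-1, 0, 0], [0, 1, 0],
            [0, -1, 0], [0, 0, 1], [0, 0, -1],
        ], dtype=float)
        return axes[:spec.n_branches]
    angles = 2 * np.pi * np.arange(spec.n_branches) / spec.n_branches
    return np.column_stack([np.cos(angles), np.sin(angles), np.zeros_like(angles)])


def make_branch_maps(spec: BranchSpec, centroids: pd.DataFrame) -> SyntheticDataset:
    """Generate the branch-structured map collection.

    Parcels are anchored in the latent space by centring their mm centroids,
    projecting them into the plane of a planar skeleton (anchors live in the
    span of the branches), and rescaling so their root-mean-square radius is
    ``anchor_frac`` of ``branch_separation`` — a compact anchor cloud around
    the skeleton's hub.  Map ``i`` at latent position ``x_i`` loads parcel
    ``p`` with ``amplitude * exp(-||x_i - a_p||^2 / (2 l^2))`` where
    ``l = smoothness * branch_separation``; zero-mean Gaussian noise of sd
    ``noise_sd`` is added in parcel space.
    """
    rng = np.random.default_rng(spec.seed)
    if len(centroids) != spec.n_parcels:
        raise ValueError(
            f"centroid table has {len(centroids)} parcels, spec wants {spec.n_parcels}"
        )
    coords = centroids[["x", "y", "z"]].to_numpy(dtype=float)
    centred = coords - coords.mean(axis=0)
    if spec.directions == "planar":
        centred = centred.copy()
        centred[:, 2] = 0.0
    rms = np.sqrt((centred ** 2).sum(axis=1).mean())
    if rms == 0:
        raise ValueError("degenerate centroids: all at one point")
    anchors = centred * (spec.anchor_frac * spec.branch_separation / rms)

    directions = _branch_directions(spec)
    positions, branches, map_ids = [], [], []
    idx = 0
    r0 = spec.hub_gap * spec.branch_separation
    for b in range(spec.n_branches):
        for i in range(1, spec.maps_per_branch + 1):
            r = r0 + (spec.branch_separation - r0) * i / spec.maps_per_branch
            positions.append(directions[b] * r)
            branches.append(f"branch_{b + 1}")
            map_ids.append(f"m{idx:04d}")
            idx += 1
    for _ in range(spec.n_center_maps):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        positions.append(u * rng.uniform(0, 0.05 * spec.branch_separation))
        branches.append("center")
        map_ids.append(f"m{idx:04d}")
        idx += 1
    positions = np.array(positions)

    length_scale = spec.smoothness * spec.branch_separation
    d2 = cdist(positions, anchors, metric="sqeuclidean")
    loadings = spec.amplitude * np.exp(-d2 / (2 * length_scale ** 2))
    if spec.noise_sd > 0:
        loadings = loadings + rng.normal(0.0, spec.noise_sd, size=loadings.shape)

    matrix = ParcelMatrix(pd.DataFrame(
        loadings, index=map_ids, columns=centroids["parcel_id"].tolist()))
    truth = pd.DataFrame({
        "map_id": map_ids,
        "branch": branches,
        "x": positions[:, 0],
        "y": positions[:, 1],
        "z": positions[:, 2],
    })
    return SyntheticDataset(parcel_matrix=matrix, truth=truth, centroids=centroids)


def make_autocorrelated_field(centroids: pd.DataFrame, correlation_length: float,
                              seed: int = 0) -> pd.Series:
    """One draw from a zero-mean Gaussian field over parcel centroids.

    Covariance between parcels at distance ``d`` is
    ``exp(-d / correlation_length)``.  Tiny lengths approach iid noise (pure
    nugget); lengths much larger than the domain give a near-constant field.
    """
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    rng = np.random.default_rng(seed)
    coords = centroids[["x", "y", "z"]].to_numpy(dtype=float)
    D = cdist(coords, coords)
    C = np.exp(-D / correlation_length)
    L = None
    for jitter in (0.0, 1e-12, 1e-10, 1e-8, 1e-6):
        try:
            L = np.linalg.cholesky(C + jitter * np.eye(len(C)))
            break
        except np.linalg.LinAlgError:
            continue
    if L is None:
        raise ValueError("covariance not positive definite even after jitter")
    field = L @ rng.standard_normal(len(C))
    return pd.Series(field, index=centroids["parcel_id"].tolist(), name="field")


def make_term_corpus(n_terms: int, n_docs: int, n_blocks: int, seed: int = 0, *,
                     terms_per_doc: int = 8,
                     cross_block_prob: float = 0.0) -> Tuple[pd.DataFrame, pd.Series]:
    """Term-document counts with planted topic blocks.

    Terms are partitioned into ``n_blocks`` contiguous blocks.  Each document
    picks one block and samples ``terms_per_doc`` tokens from it; each token
    instead comes from the full vocabulary with probability
    ``cross_block_prob`` (0 by default, which makes the term co-occurrence
    matrix exactly block-diagonal).  Terms that end up unused are given one
    occurrence in a document of their own block so every term has a defined
    document frequency.

    Returns the counts (terms x documents) and the ground-truth block label
    per term.
    """
    if n_blocks > n_terms:
        raise ValueError("n_blocks cannot exceed n_terms")
    rng = np.random.default_rng(seed)
    terms = [f"term_{i:04d}" for i in range(n_terms)]
    block_of = np.repeat(np.arange(n_blocks), -(-n_terms // n_blocks))[:n_terms]
    members = [np.flatnonzero(block_of == b) for b in range(n_blocks)]
    counts = np.zeros((n_terms, n_docs), dtype=int)
    doc_block = rng.integers(0, n_blocks, size=n_docs)
    for d in range(n_docs):
        pool = members[doc_block[d]]
        for _ in range(terms_per_doc):
            if cross_block_prob > 0 and rng.random() < cross_block_prob:
                t = rng.integers(0, n_terms)
            else:
                t = pool[rng.integers(0, len(pool))]
            counts[t, d] += 1
    for t in np.flatnonzero(counts.sum(axis=1) == 0):
        docs = np.flatnonzero(doc_block == block_of[t])
        d = docs[rng.integers(0, len(docs))] if len(docs) else rng.integers(0, n_docs)
        counts[t, d] = 1
    counts_df = pd.DataFrame(counts, index=terms,
                             columns=[f"doc_{d:04d}" for d in range(n_docs)])
    labels = pd.Series(block_of, index=terms, name="block")
    return counts_df, labels
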