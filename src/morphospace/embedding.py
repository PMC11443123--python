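"""Fitting the morphospace embedding and its distance geometry.

A *morphospace* is a low-dimensional UMAP embedding of a map collection in
which each point is one brain map and Euclidean inter-point distance encodes
map similarity.  The module covers fitting, pairwise distances, out-of-sample
projection (UMAP transform), dimensionality selection, and an array-based
persistence format.

Persistence deliberately avoids pickling the fitted UMAP object: a bundle
directory stores the training matrix, the configuration and the coordinates,
and :func:`load_morphospace` refits deterministically from those, verifying
that the recovered coordinates match the stored ones.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Any, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import ParcelMismatchError
from .maps_io import ParcelMatrix

_BUNDLE_FORMAT = 1


@dataclass(frozen=True)
class EmbeddingConfig:
    """UMAP settings for the morphospace.

    ``n_neighbors=15`` balances local manifold detail against global
    structure; ``min_dist=0.1`` is the library default; distances in the
    embedding are Euclidean so that linear statistics downstream remain
    meaningful.  ``standardize`` (off by default) optionally z-scores parcels
    before embedding.
    """

    n_neighbors: int = 15
    min_dist: float = 0.1
    n_dims: int = 3
    metric: str = "euclidean"
    seed: int = 0
    standardize: bool = False

    def __post_init__(self):
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if not (0 <= self.min_dist < 1):
            raise ValueError("min_dist must be in [0, 1)")
        if self.n_dims not in (2, 3, 4, 5):
            raise ValueError("n_dims must be one of {2, 3, 4, 5}")


@dataclass
class Morphospace:
    """A fitted embedding: coordinates, transformer handle, config, checksum.

    ``training_checksum`` fingerprints the (matrix, config) pair; any output
    derived from this space carries it as provenance.
    """

    coordinates: pd.DataFrame
    transformer: Any
    config: EmbeddingConfig
    training_checksum: str
    training_matrix: ParcelMatrix
    _scaler: Optional[Tuple[np.ndarray, np.ndarray]] = None

    @property
    def map_ids(self) -> list:
        return list(self.coordinates.index)

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]

    def coordinates_checksum(self) -> str:
        return hashlib.sha256(
            np.ascontiguousarray(self.coordinates.to_numpy(dtype=float)).tobytes()
        ).hexdigest()


def _checksum(matrix: ParcelMatrix, config: EmbeddingConfig) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(asdict(config), sort_keys=True).encode())
    h.update("\x00".join(matrix.map_ids).encode())
    h.update(",".join(str(p) for p in matrix.parcel_ids).encode())
    h.update(np.ascontiguousarray(matrix.values).tobytes())
    return h.hexdigest()


def _prepare_features(matrix: ParcelMatrix, config: EmbeddingConfig,
                      scaler=None):
    X = matrix.values.astype(np.float64)
    if not config.standardize:
        return X, None
    if scaler is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        scaler = (mean, sd)
    mean, sd = scaler
    return (X - mean) / sd, scaler


def fit_morphospace(matrix: ParcelMatrix, config: Optional[EmbeddingConfig] = None) -> Morphospace:
    """Embed a ParcelMatrix with UMAP; deterministic given (matrix, config).

    Requires at least ``n_neighbors + 1`` maps and finite entries.  The
    returned space carries the fitted transformer for out-of-sample
    projection and a checksum of its training inputs.
    """
    import umap

    config = config or EmbeddingConfig()
    if matrix.n_maps < config.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={config.n_neighbors + 1} maps, "
            f"got {matrix.n_maps}"
        )
    X, scaler = _prepare_features(matrix, config)
    reducer = umap.UMAP(
        n_neighbors=config.n_neighbors,
        min_dist=config.min_dist,
        n_components=config.n_dims,
        metric=config.metric,
        random_state=config.seed,
        transform_seed=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced single-threading
        coords = reducer.fit_transform(X)
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise RuntimeError("embedding produced non-finite coordinates")
    frame = pd.DataFrame(coords, index=matrix.map_ids,
                         columns=[f"dim_{i + 1}" for i in range(config.n_dims)])
    return Morphospace(
        coordinates=frame,
        transformer=reducer,
        config=config,
        training_checksum=_checksum(matrix, config),
        training_matrix=matrix,
        _scaler=scaler,
    )


def pairwise_distances(space: Morphospace) -> pd.DataFrame:
    """Square matrix of Euclidean distances between embedded maps."""
    coords = space.coordinates.to_numpy(dtype=float)
    D = squareform(pdist(coords, metric="euclidean"))
    return pd.DataFrame(D, index=space.map_ids, columns=space.map_ids)


def check_distance_invariants(D: pd.DataFrame, n_triples: int = 200, seed: int = 0) -> None:
    """Assert symmetry, zero diagonal, nonnegativity and the triangle
    inequality (on sampled triples) of a distance matrix."""
    A = D.to_numpy(dtype=float)
    if not np.allclose(A, A.T):
        raise AssertionError("distance matrix is not symmetric")
    if not np.allclose(np.diag(A), 0.0):
        raise AssertionError("distance matrix diagonal is not zero")
    if (A < -1e-12).any():
        raise AssertionError("negative distances")
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    for _ in range(min(n_triples, n ** 3)):
        i, j, k = rng.integers(0, n, size=3)
        if A[i, k] > A[i, j] + A[j, k] + 1e-9:
            raise AssertionError("triangle inequality violated")


def transform_new(space: Morphospace, new_maps: ParcelMatrix) -> pd.DataFrame:
    """Project new maps into a fitted space without altering it.

    The new matrix must share the training parcel set and order.  The
    training coordinates are checksummed before and after the call to
    guarantee the space is untouched.
    """
    if list(new_maps.parcel_ids) != list(space.training_matrix.parcel_ids):
        extra = sorted(set(new_maps.parcel_ids) - set(space.training_matrix.parcel_ids))
        missing = sorted(set(space.training_matrix.parcel_ids) - set(new_maps.parcel_ids))
        raise ParcelMismatchError(
            f"new maps do not share the training parcel set/order "
            f"(extra={extra[:10]}, missing={missing[:10]})"
        )
    before = space.coordinates_checksum()
    X, _ = _prepare_features(new_maps, space.config, scaler=space._scaler)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = space.transformer.transform(X)
    after = space.coordinates_checksum()
    if before != after:
        raise RuntimeError("transform mutated the fitted space")
    return pd.DataFrame(np.asarray(coords, dtype=float), index=new_maps.map_ids,
                        columns=list(space.coordinates.columns))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_morphospace(space: Morphospace, path) -> None:
    """Write a model bundle: manifest.json + training matrix + coordinates.

    No language-native serialization is used; loading refits UMAP from the
    stored inputs (deterministic given the stored seed).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    space.training_matrix.to_tsv(path / "training_matrix.tsv")
    coords = space.coordinates.copy()
    coords.index.name = "map_id"
    coords.to_csv(path / "coordinates.tsv", sep="\t")
    manifest = {
        "format_version": _BUNDLE_FORMAT,
        "config": asdict(space.config),
        "training_checksum": space.training_checksum,
        "coordinates_checksum": space.coordinates_checksum(),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_morphospace(path) -> Morphospace:
    """Reconstruct a space from a bundle by deterministic refit.

    Verifies the training checksum and that the refitted coordinates agree
    with the stored ones to 1e-5.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest["format_version"] != _BUNDLE_FORMAT:
        raise ValueError(f"unsupported bundle format {manifest['format_version']}")
    config = EmbeddingConfig(**manifest["config"])
    matrix = ParcelMatrix.from_tsv(path / "training_matrix.tsv")
    space = fit_morphospace(matrix, config)
    if space.training_checksum != manifest["training_checksum"]:
        raise ValueError("training checksum mismatch: bundle is corrupt")
    stored = pd.read_csv(path / "coordinates.tsv", sep="\t", index_col="map_id")
    if not np.allclose(space.coordinates.to_numpy(), stored.to_numpy(), atol=1e-5):
        raise ValueError("refit coordinates diverge from stored bundle")
    return space


# ---------------------------------------------------------------------------
# dimensionality selection
# ---------------------------------------------------------------------------

@dataclass
class DimensionSelection:
    chosen_dim: int
    mae_table: pd.DataFrame        # maps x dims, per-map MAE
    tests: pd.DataFrame            # pairwise Wilcoxon + Shapiro records
    mean_index: dict               # dim -> mean predictability index
    tie_break_used: bool


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank; exact null for n <= 25 (when free of
    zero differences), normal approximation with continuity correction
    otherwise.  Identical vectors give (nan, 1.0)."""
    diff = a - b
    if np.all(diff == 0):
        return float("nan"), 1.0
    n = len(diff)
    method = "exact" if (n <= 25 and not np.any(diff == 0)) else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", correction=True, method=method)
    return float(res.statistic), float(res.pvalue)


def select_dimension(matrix: ParcelMatrix, dims: Sequence[int] = (2, 3, 4, 5),
                     config: Optional[EmbeddingConfig] = None,
                     alpha: float = 0.05) -> DimensionSelection:
    """Pick the embedding dimensionality by out-of-sample reconstruction error.

    For each candidate dimensionality the full leave-one-out prediction loop
    is run and the per-map mean absolute error (MAE) between predicted and
    measured parcel vectors recorded.  Candidates are compared pairwise with
    the two-sided Wilcoxon signed-rank test (Shapiro-Wilk normality of the
    differences is reported alongside, not enforced).  The lowest-mean-MAE
    dimension wins; if runners-up are statistically indistinguishable from it
    (p > alpha), the tie is broken by the higher mean predictability index.
    """
    from .predictability import loo_predictability

    dims = list(dims)
    if len(dims) < 2:
        raise ValueError("need at least 2 candidate dimensionalities")
    config = config or EmbeddingConfig()
    mae, mean_index = {}, {}
    for d in dims:
        cfg = replace(config, n_dims=d)
        try:
            space = fit_morphospace(matrix, cfg)
            res = loo_predictability(space, matrix, thresholded=False)
        except Exception as exc:  # noqa: BLE001 - reraise with the dim named
            raise RuntimeError(f"embedding failed for n_dims={d}: {exc}") from exc
        mae[d] = res.set_index("map_id")["mae"]
        mean_index[d] = float(res["index"].mean())
    mae_table = pd.DataFrame(mae)
    records = []
    for a, b in combinations(dims, 2):
        diff = mae_table[a].to_numpy() - mae_table[b].to_numpy()
        if np.ptp(diff) == 0:
            sh_p = float("nan")
        else:
            sh_p = float(stats.shapiro(diff).pvalue)
        w_stat, w_p = _paired_wilcoxon(mae_table[a].to_numpy(), mae_table[b].to_numpy())
        records.append({"dim_a": a, "dim_b": b, "shapiro_p": sh_p,
                        "wilcoxon_stat": w_stat, "wilcoxon_p": w_p})
    tests = pd.DataFrame(records)
    best = min(dims, key=lambda d: mae_table[d].mean())
    contenders = [best]
    for d in dims:
        if d == best:
            continue
        row = tests[((tests.dim_a == best) & (tests.dim_b == d)) |
                    ((tests.dim_a == d) & (tests.dim_b == best))]
        if float(row["wilcoxon_p"].iloc[0]) > alpha:
            contenders.append(d)
    tie_break = len(contenders) > 1
    chosen = max(contenders, key=lambda d: mean_index[d]) if tie_break else best
    return DimensionSelection(chosen_dim=int(chosen), mae_table=mae_table,
                              tests=tests, mean_index=mean_index,
                              tie_break_used=tie_break)
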