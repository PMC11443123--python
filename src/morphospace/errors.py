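"""Exception types shared across the toolkit."""


class MorphospaceError(Exception):
    """Base class for all toolkit-specific errors."""


class StatKindError(MorphospaceError):
    """A map with the wrong statistic kind (z vs t) was supplied."""


class GridMismatchError(MorphospaceError):
    """Map and atlas do not share the same voxel grid / affine.

    Resample one of them explicitly (see :func:`morphospace.maps_io.resample_map`)
    rather than relying on silent interpolation.
    """


class EmptyParcelError(MorphospaceError):
    """A parcel listed in the atlas table has no voxels in the label volume."""


class ParcelMismatchError(MorphospaceError):
    """Two parcel-indexed objects do not share the same parcel set/order."""


class ZeroVarianceError(MorphospaceError):
    """A correlation or regression is undefined because an input is constant."""
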