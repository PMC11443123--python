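"""Inventory of the public corpora the toolkit is designed around.

These constants describe the real datasets a production run would consume —
the 2017 Neurosynth meta-analytic collection that defines the reference
space, the out-of-sample map sources used for projection, and the 7T
naturalistic-movie runs used for decoding.  None of the data ships with the
package; the numbers let pipelines size their bookkeeping and let reports
state the corpus composition.
"""

from scipy import stats

#: Meta-analytic z maps (one cognitive term each) in the 2017 reference corpus.
NEUROSYNTH_2017_N_MAPS = 506

#: Parcels obtained from the combined cortical + subcortical parcellation.
N_PARCELS_COMBINED_ATLAS = 440

#: Default z threshold applied to every meta-analytic map.
DEFAULT_Z_THRESHOLD = 3.4

#: Out-of-sample map sources projected into the reference space.
OUT_OF_SAMPLE_SOURCES = {
    "neuroquery": 888,
    "neurosynth_2021": 13,
    "neurovault": 19,
}

#: Per-run frame counts of the four 7T movie-watching runs (1 s sampling).
MOVIE_RUN_FRAMES = {
    "MOVIE1": 921,
    "MOVIE2": 918,
    "MOVIE3": 915,
    "MOVIE4": 901,
}


def total_projected_maps() -> int:
    """Total out-of-sample maps across all projection sources."""
    return sum(OUT_OF_SAMPLE_SOURCES.values())


def total_movie_frames() -> int:
    """Total per-second activation maps across the four movie runs."""
    return sum(MOVIE_RUN_FRAMES.values())


def threshold_tail_probability(z_crit: float = DEFAULT_Z_THRESHOLD) -> float:
    """Upper-tail standard-normal probability of the z threshold."""
    return float(stats.norm.sf(z_crit))
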