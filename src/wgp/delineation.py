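"""Pairwise similarity and species calls from per-genome parameters.

For a dataset of genomes the absolute difference of each parameter is
computed for every (unordered) pair and normalized by that parameter's range
over the whole dataset, giving values in [0, 1].  The distance of a pair is
the unweighted mean of the normalized differences over a chosen parameter
subset, and the percentage similarity is ``s = 100 * (1 - d)``.  Two genomes
are called the same species when their similarity exceeds a threshold
(default 96%).

The normalization makes similarities dataset-dependent by construction:
adding a genome that extends a parameter's range changes all similarities of
that parameter.  The comparison is reciprocal, so only N*(N-1)/2 pairs are
evaluated for N genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import PARAMETER_NAMES, GenomeParameters

__all__ = [
    "SUBSET_PRESETS",
    "ParameterSubset",
    "SimilarityMatrix",
    "DelineationCall",
    "DEFAULT_THRESHOLD",
    "normalized_distance_tables",
    "similarity_matrix",
    "delineate",
]

DEFAULT_THRESHOLD = 96.0

#: Named parameter combinations: s2 averages Tr_CG and Diff_p, s3 adds Tr_0,
#: s4 uses all four descriptors.
SUBSET_PRESETS: dict[str, tuple[str, ...]] = {
    "s2": ("tr_cg", "diff_p"),
    "s3": ("tr_cg", "diff_p", "tr_0"),
    "s4": ("diff_p", "tr_0", "tr_cg", "a_cp"),
}


@dataclass(frozen=True)
class ParameterSubset:
    """An ordered, non-empty subset of the four parameter names."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("parameter subset must be non-empty")
        unknown = [m for m in self.members if m not in PARAMETER_NAMES]
        if unknown:
            raise ValueError(f"unknown parameter(s): {unknown}")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate parameters in subset")

    @classmethod
    def from_spec(cls, spec: str) -> "ParameterSubset":
        """Build from a preset name (s2/s3/s4), a single parameter name, or a
        comma-separated list of parameter names."""
        if spec in SUBSET_PRESETS:
            return cls(SUBSET_PRESETS[spec])
        return cls(tuple(s.strip() for s in spec.split(",")))

    def __iter__(self):
        return iter(self.members)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric percentage-similarity matrix for a dataset of genomes."""

    genome_ids: tuple[str, ...]
    values: np.ndarray
    subset: ParameterSubset
    #: per-parameter (min, max) over the dataset used for normalization
    normalization_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def pair(self, a: str, b: str) -> float:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.genome_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)

    def __len__(self) -> int:
        return len(self.genome_ids)


@dataclass(frozen=True)
class DelineationCall:
    """Same/different-species verdict for one genome pair."""

    genome_pair: tuple[str, str]
    similarity: float
    same_species: bool
    threshold: float


def _check_params(params: list[GenomeParameters]) -> list[GenomeParameters]:
    if len(params) < 2:
        raise ValueError("delineation requires at least 2 genomes")
    ids = [p.genome_id for p in params]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate genome ids: {sorted(dupes)}")
    # deterministic pair enumeration: lexicographic by id
    return sorted(params, key=lambda p: p.genome_id)


def normalized_distance_tables(
    params: list[GenomeParameters],
) -> tuple[dict[str, np.ndarray], dict[str, tuple[float, float]]]:
    """Range-normalized pairwise distance matrix for each parameter.

    Returns
    -------
    distances
        parameter name -> symmetric (N, N) matrix of
        ``|q_A - q_B| / (max q - min q)`` with zero diagonal.  When a
        parameter's range is zero over the dataset all its distances are 0
        (identical values carry no discriminative signal).
    ranges
        parameter name -> (min, max) over the dataset.
    """
    params = _check_params(params)
    distances: dict[str, np.ndarray] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for name in PARAMETER_NAMES:
        q = np.array([getattr(p, name) for p in params], dtype=float)
        lo, hi = float(q.min()), float(q.max())
        ranges[name] = (lo, hi)
        diff = np.abs(q[:, None] - q[None, :])
        span = hi - lo
        distances[name] = diff / span if span > 0 else np.zeros_like(diff)
    return distances, ranges


def similarity_matrix(
    params: list[GenomeParameters],
    subset: ParameterSubset | str = "s4",
) -> SimilarityMatrix:
    """Percentage similarity ``100 * (1 - mean normalized distance)``.

    ``subset`` selects which parameters enter the (unweighted) mean.
    """
    if isinstance(subset, str):
        subset = ParameterSubset.from_spec(subset)
    params = _check_params(params)
    distances, ranges = normalized_distance_tables(params)
    d_bar = np.mean([distances[name] for name in subset], axis=0)
    values = 100.0 * (1.0 - d_bar)
    np.fill_diagonal(values, 100.0)
    return SimilarityMatrix(
        genome_ids=tuple(p.genome_id for p in params),
        values=values,
        subset=subset,
        normalization_ranges={name: ranges[name] for name in subset},
    )


def delineate(
    matrix: SimilarityMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    inclusive: bool = False,
) -> list[DelineationCall]:
    """Same/different-species call for every unordered genome pair.

    A pair is called the same species when its similarity is strictly above
    the threshold (``inclusive=True`` switches to >=; similarities exactly at
    the boundary are rare but the convention is explicit).
    """
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    ids = matrix.genome_ids
    calls = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            s = float(matrix.values[i, j])
            same = s >= threshold if inclusive else s > threshold
            calls.append(
                DelineationCall(
                    genome_pair=(ids[i], ids[j]),
                    similarity=s,
                    same_species=same,
                    threshold=threshold,
                )
            )
    return calls
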