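"""Seeded synthetic genomes with controlled statistical structure.

The four whole-genome descriptors are composition and dinucleotide
statistics, so first-order models are enough to exercise the full pipeline
without downloading real genomes:

* ``generate_genome`` — i.i.d. draws from a base composition;
* ``markov_genome`` — first-order Markov chain with a given transition
  matrix, to stress the dinucleotide parameters independently of
  composition;
* ``gc_skew_ramp_genome`` — two halves with mirrored G-vs-C bias, producing
  the characteristic arrow-shaped cumulated phase with a well-defined
  maximum and minimum for the rearrangement step.  The two halves use exact,
  mirrored base counts so the genome's total phase skew is exactly zero
  (real genomes approximate this through Chargaff's second parity rule); a
  nonzero net skew would make the circular minimum ill-posed.
* ``mutate_genome`` — uniform random substitutions, modelling strain-level
  divergence within a species;
* ``generate_cluster_dataset`` — several species (distinct compositions),
  each an ancestor plus mutated strains, optionally randomly rotated —
  a scaled-down stand-in for a multi-species validation set.

The seven default species compositions span GC content 0.30-0.66 with
purine fractions 0.52-0.70 and G-over-C skews 0.02-0.14, so each of the four
descriptors varies substantially across species (the dataset-range
normalization in the delineation step amplifies noise in any parameter
whose inter-species range is small).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_COMPOSITIONS",
    "OVERLAPPING_TRCG_COMPOSITIONS",
    "SpeciesClusterSpec",
    "generate_genome",
    "markov_genome",
    "gc_skew_ramp_genome",
    "mutate_genome",
    "rotate_genome",
    "generate_cluster_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _composition(comp) -> np.ndarray:
    comp = np.asarray(comp, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
        raise ValueError("composition must be 4 non-negative probabilities summing to 1")
    return comp


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


#: (pA, pC, pG, pT) per species: GC 0.30-0.66, purines 0.52-0.70,
#: G-C skew 0.02-0.14.
DEFAULT_COMPOSITIONS: tuple[tuple[float, float, float, float], ...] = (
    (0.36, 0.14, 0.16, 0.34),
    (0.35, 0.16, 0.20, 0.29),
    (0.34, 0.18, 0.24, 0.24),
    (0.33, 0.20, 0.28, 0.19),
    (0.32, 0.22, 0.32, 0.14),
    (0.31, 0.24, 0.36, 0.09),
    (0.30, 0.26, 0.40, 0.04),
)

#: Like the defaults, but species 3 and 4 share their GC content (hence the
#: same expected Tr_CG ~ g^2) while differing in purine fraction and skew —
#: a single-parameter Tr_CG delineation cannot separate them.
OVERLAPPING_TRCG_COMPOSITIONS: tuple[tuple[float, float, float, float], ...] = (
    (0.36, 0.14, 0.16, 0.34),
    (0.35, 0.16, 0.20, 0.29),
    (0.34, 0.18, 0.24, 0.24),
    (0.36, 0.17, 0.25, 0.22),
    (0.32, 0.22, 0.32, 0.14),
    (0.31, 0.24, 0.36, 0.09),
    (0.30, 0.26, 0.40, 0.04),
)


def generate_genome(length: int, composition, seed: int | np.random.Generator) -> str:
    """i.i.d. A/C/G/T sequence of ``length`` drawn from ``composition``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    comp = _composition(composition)
    rng = np.random.default_rng(seed)
    return _to_str(rng.choice(4, size=length, p=comp))


def markov_genome(
    length: int, transition: np.ndarray, seed: int | np.random.Generator, start=None
) -> str:
    """First-order Markov sequence with 4x4 ``transition`` (rows A,C,G,T).

    ``start`` is the initial-state distribution (default: the transition
    matrix's stationary distribution).
    """
    transition = np.asarray(transition, dtype=float)
    if transition.shape != (4, 4) or (transition < 0).any():
        raise ValueError("transition must be a non-negative 4x4 matrix")
    if not np.allclose(transition.sum(axis=1), 1.0):
        raise ValueError("transition rows must sum to 1")
    rng = np.random.default_rng(seed)
    if start is None:
        w, v = np.linalg.eig(transition.T)
        stat = np.real(v[:, np.argmin(np.abs(w - 1))])
        start = stat / stat.sum()
    codes = np.empty(length, dtype=np.uint8)
    # cumulative transition rows let each step be a single searchsorted
    cum = np.cumsum(transition, axis=1)
    u = rng.random(length)
    codes[0] = rng.choice(4, p=_composition(start))
    for k in range(1, length):
        codes[k] = np.searchsorted(cum[codes[k - 1]], u[k])
    return _to_str(codes)


def gc_skew_ramp_genome(
    length: int,
    seed: int | np.random.Generator,
    gc: float = 0.5,
    skew: float = 0.06,
) -> str:
    """Genome whose cumulated phase has the arrow shape of real chromosomes.

    The first half is G-rich and the second C-rich by ``skew`` (absolute
    difference of the G and C fractions), with A/T balanced.  Each half is a
    random permutation of an exact base multiset and the second half mirrors
    the first's G/C counts, so the total phase skew is exactly zero and the
    rotation to the signal's true minimum is well-posed.
    """
    if length < 4:
        raise ValueError("length must be >= 4")
    if not 0 < gc < 1 or skew < 0 or skew > gc:
        raise ValueError("require 0 < gc < 1 and 0 <= skew <= gc")
    rng = np.random.default_rng(seed)
    h = length // 2
    n_g = int(round(h * (gc + skew) / 2))
    n_c = int(round(h * (gc - skew) / 2))
    rem = h - n_g - n_c
    n_a, n_t = rem // 2, rem - rem // 2
    half1 = np.repeat(np.array([0, 1, 2, 3], dtype=np.uint8), [n_a, n_c, n_g, n_t])
    # mirror G/C, swap the (possibly unequal) A/T counts to cancel A-T skew;
    # an odd-length leftover residue goes to G so the net skew stays >= 0
    h2 = length - h
    half2 = np.repeat(
        np.array([0, 1, 2, 3], dtype=np.uint8), [n_t, n_g, n_c + (h2 - h), n_a]
    )
    rng.shuffle(half1)
    rng.shuffle(half2)
    return _to_str(np.concatenate([half1, half2]))


def mutate_genome(seq: str, rate: float, seed: int | np.random.Generator) -> str:
    """Substitute each position with probability ``rate`` by a different base."""
    if not 0 <= rate < 0.5:
        raise ValueError("substitution rate must be in [0, 0.5)")
    if rate == 0:
        return seq
    rng = np.random.default_rng(seed)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    base_idx = np.full(256, 255, dtype=np.uint8)
    base_idx[_BASES] = np.arange(4)
    idx = base_idx[codes]
    if (idx == 255).any():
        raise ValueError("mutate_genome requires an A/C/G/T sequence")
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    # shift by 1..3 mod 4: uniform over the three other bases
    idx[hit] = (idx[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return _to_str(idx.astype(np.uint8))


def rotate_genome(seq: str, offset: int) -> str:
    """Circularly rotate ``seq`` to start at 0-based position ``offset``."""
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


@dataclass(frozen=True)
class SpeciesClusterSpec:
    """Recipe for a multi-species strain-cluster dataset.

    Defaults: 7 species x 5 strains of 200 kb with 1% strain-level
    substitution, using the spread default compositions.
    """

    n_species: int = 7
    strains_per_species: int = 5
    genome_length: int = 200_000
    compositions: tuple[tuple[float, float, float, float], ...] = DEFAULT_COMPOSITIONS
    intra_species_substitution_rate: float = 0.01
    random_rotation: bool = False
    seed: int = 0
    #: warn when two species compositions are closer than this in total
    #: variation distance
    min_composition_tv: float = 0.02

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.strains_per_species < 1:
            raise ValueError("counts must be >= 1")
        if self.n_species > len(self.compositions):
            raise ValueError("not enough compositions for n_species")
        if not 0 <= self.intra_species_substitution_rate < 0.5:
            raise ValueError("substitution rate must be in [0, 0.5)")
        for comp in self.compositions[: self.n_species]:
            _composition(comp)


def generate_cluster_dataset(
    spec: SpeciesClusterSpec,
) -> tuple[dict[str, str], dict[str, str]]:
    """Generate genomes and species labels from a :class:`SpeciesClusterSpec`.

    Each species gets one ancestor genome drawn from its composition and
    ``strains_per_species - 1`` mutated derivatives; with
    ``spec.random_rotation`` every strain is additionally rotated by a random
    offset (exercising the rearrangement step).

    Returns
    -------
    genomes
        genome_id -> sequence, ids like ``sp03_strain2``.
    labels
        genome_id -> species name (``species_3``).
    """
    import warnings

    comps = [np.asarray(c, float) for c in spec.compositions[: spec.n_species]]
    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            tv = 0.5 * np.abs(comps[i] - comps[j]).sum()
            if tv < spec.min_composition_tv:
                warnings.warn(
                    f"species compositions {i + 1} and {j + 1} are within total "
                    f"variation {tv:.3f}; delineation may legitimately fail",
                    stacklevel=2,
                )
    rng = np.random.default_rng(spec.seed)
    genomes: dict[str, str] = {}
    labels: dict[str, str] = {}
    for s, comp in enumerate(comps, start=1):
        ancestor = generate_genome(spec.genome_length, comp, rng)
        for k in range(1, spec.strains_per_species + 1):
            gid = f"sp{s:02d}_strain{k}"
            seq = ancestor if k == 1 else mutate_genome(
                ancestor, spec.intra_species_substitution_rate, rng
            )
            if spec.random_rotation:
                seq = rotate_genome(seq, int(rng.integers(0, len(seq))))
            genomes[gid] = seq
            labels[gid] = f"species_{s}"
    return genomes, labels
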