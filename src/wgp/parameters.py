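"""The four whole-genome parameters (WGP descriptors).

Each genome is summarized by four numbers computed from its phase and
cumulated-phase signals after the record has been rotated to its canonical
start:

``diff_p``
    mean absolute difference of adjacent phase values,
    ``(1/L) * sum_k |p_k - p_{k+1}|`` — order-sensitive: permuting residues
    changes it even at fixed base composition.
``tr_0``
    fraction of the L-1 adjacent pairs whose phases have strictly opposite
    signs; for unambiguous sequences this equals the fraction of
    dinucleotides in {AC, AT, CA, CG, GC, GT, TA, TG}.
``tr_cg``
    fraction of adjacent pairs whose phases both belong to C or G
    (+-3*pi/4); equals the fraction of dinucleotides in {CC, CG, GC, GG}.
``a_cp``
    average growth angle of the cumulated phase: ``(1/N) * sum_k
    atan(c_i / i)`` with ``i = round(k * i_max / N)``, k = 1..N, where i_max
    is the 1-based position of the signal's global maximum.  N defaults
    to 10; averaging over several positions smooths local irregularities of
    the signal's rise.

The four descriptors are computed once per genome and are independent of any
other genome, so they can be stored in a parameter table and reused across
delineation datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

import numpy as np

from .rearrangement import rearrange
from .signals import PHASE_MAP, CumulatedPhase, phase_signal

__all__ = [
    "PARAMETER_NAMES",
    "AcpSettings",
    "GenomeParameters",
    "diff_p",
    "tr_0",
    "tr_cg",
    "a_cp",
    "compute_parameters",
]

#: Canonical parameter order used throughout tables and matrices.
PARAMETER_NAMES = ("diff_p", "tr_0", "tr_cg", "a_cp")

_CG_PHASES = (PHASE_MAP["C"], PHASE_MAP["G"])  # +-3*pi/4


@dataclass(frozen=True)
class AcpSettings:
    """Sampling settings for the average growth angle.

    ``n_positions`` sampled indices are spread evenly from the start of the
    signal to its global maximum.
    """

    n_positions: int = 10

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")


@dataclass(frozen=True)
class GenomeParameters:
    """The four descriptors of one genome plus identifying metadata."""

    genome_id: str
    length: int
    diff_p: float
    tr_0: float
    tr_cg: float
    a_cp: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.diff_p, self.tr_0, self.tr_cg, self.a_cp])


def _check_pairs(phase: np.ndarray) -> None:
    if phase.size < 2:
        raise ValueError("parameter computation requires length >= 2")


def diff_p(phase: np.ndarray) -> float:
    """Mean absolute difference of adjacent phase values (divided by L)."""
    phase = np.asarray(phase)
    _check_pairs(phase)
    return float(np.abs(np.diff(phase)).sum() / phase.size)


def tr_0(phase: np.ndarray) -> float:
    """Fraction of adjacent pairs with strictly opposite phase signs.

    Zero phases (W and fully ambiguous codes) are neither positive nor
    negative, so pairs involving them contribute no transition.
    """
    phase = np.asarray(phase)
    _check_pairs(phase)
    sign = np.sign(phase)
    crossings = np.count_nonzero(sign[:-1] * sign[1:] < 0)
    return crossings / (phase.size - 1)


def tr_cg(phase: np.ndarray) -> float:
    """Fraction of adjacent pairs whose phases both correspond to C or G."""
    phase = np.asarray(phase)
    _check_pairs(phase)
    is_cg = np.abs(np.abs(phase) - abs(_CG_PHASES[0])) < 1e-12
    return int(np.count_nonzero(is_cg[:-1] & is_cg[1:])) / (phase.size - 1)


def a_cp(signal: CumulatedPhase | np.ndarray, settings: AcpSettings = AcpSettings()) -> float:
    """Average growth angle of a (rearranged) cumulated-phase signal.

    Samples N positions ``i = round(k * i_max / N)`` for k = 1..N (clamped to
    [1, i_max]) and averages ``atan(c_i / i)``, where positions are 1-based
    and i_max is the position of the signal's global maximum.

    Raises
    ------
    ValueError
        If the maximum lies before position N (degenerate tiny signals);
        choose a smaller ``n_positions``.
    """
    if not isinstance(signal, CumulatedPhase):
        signal = CumulatedPhase(np.asarray(signal, dtype=float))
    n = settings.n_positions
    i_max = signal.i_max
    if i_max < n:
        raise ValueError(
            f"signal maximum at position {i_max} < N={n}; use a smaller n_positions"
        )
    k = np.arange(1, n + 1)
    idx = np.clip(np.rint(k * i_max / n).astype(int), 1, i_max)
    angles = np.arctan(signal.values[idx - 1] / idx)
    return float(angles.mean())


def compute_parameters(
    seq: str,
    *,
    genome_id: str = "",
    settings: AcpSettings = AcpSettings(),
    rearrangement: bool = True,
) -> GenomeParameters:
    """Compute all four descriptors for one genome.

    The genome is first rotated to its canonical (cumulated-phase minimum)
    start; the phase signal is recomputed from the rotated sequence and all
    four parameters derive from it.  Set ``rearrangement=False`` to skip the
    rotation (ablation: the descriptors then depend on where the deposited
    record happens to start, which degrades delineation).
    """
    if isinstance(seq, bytes):
        seq = seq.decode("ascii")
    if len(seq) < max(2, settings.n_positions):
        raise ValueError(
            f"genome {genome_id!r} too short (L={len(seq)}) for parameter computation"
        )
    if rearrangement:
        rg = rearrange(seq, id=genome_id)
        sequence, signal = rg.sequence, rg.signal
    else:
        from .signals import cumulated_phase

        sequence = seq
        signal = cumulated_phase(seq, id=genome_id)
    phase = phase_signal(sequence, id=genome_id)
    return GenomeParameters(
        genome_id=genome_id,
        length=len(sequence),
        diff_p=diff_p(phase),
        tr_0=tr_0(phase),
        tr_cg=tr_cg(phase),
        a_cp=a_cp(signal, settings),
    )
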