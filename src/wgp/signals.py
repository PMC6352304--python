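"""Phase and cumulated-phase representations of nucleotide sequences.

A DNA sequence is mapped to the complex plane by projecting the nucleotide
tetrahedron: A = 1+j, C = -1-j, G = -1+j, T = 1-j, with the partially
determined IUPAC codes landing on the axes (R = j, Y = -j, S = -1, W = 1) and
the fully ambiguous codes at the origin.  The *phase signal* keeps only the
phases of these complex values, one per residue; the *cumulated phase* is its
running sum.  For an A/C/G/T-only prefix of length k the cumulated phase has
the closed form

    c_k = pi/4 * (3*(n_G - n_C) + (n_A - n_T)),

where n_X counts residues of type X in the prefix, so the signal's global
trend tracks strand-composition (GC and AT) skew across a genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

import numpy as np

__all__ = [
    "PHASE_MAP",
    "CumulatedPhase",
    "phase_of_symbol",
    "phase_signal",
    "cumulated_phase",
    "closed_form_cumulated_phase",
    "sequence_from_phases",
]

#: Phase (radians) assigned to each IUPAC nucleotide symbol.  W is 0 (the
#: alternative 2*pi reading would inject an arbitrary jump into the running
#: sum); B/D/H/V follow the fully ambiguous codes to 0.
PHASE_MAP: dict[str, float] = {
    "A": pi / 4,
    "C": -3 * pi / 4,
    "G": 3 * pi / 4,
    "T": -pi / 4,
    "R": pi / 2,
    "Y": -pi / 2,
    "S": pi,
    "W": 0.0,
    "M": 0.0,
    "K": 0.0,
    "N": 0.0,
    "B": 0.0,
    "D": 0.0,
    "H": 0.0,
    "V": 0.0,
}

# byte -> phase lookup (NaN marks unrecognized symbols), upper and lower case
_LUT = np.full(256, np.nan)
for _sym, _val in PHASE_MAP.items():
    _LUT[ord(_sym)] = _val
    _LUT[ord(_sym.lower())] = _val

# Every phase is an integer multiple of pi/4 (A:1, C:-3, G:3, T:-1, R:2,
# Y:-2, S:4, rest 0), so running sums are kept as exact integers and only
# scaled to radians at the end — extremum locations and ties are then exact
# and independent of summation order.
_ICOEF = np.zeros(256, dtype=np.int64)
for _sym, _val in PHASE_MAP.items():
    _ICOEF[ord(_sym)] = _ICOEF[ord(_sym.lower())] = round(_val / (pi / 4))

# exact inverse for the four unambiguous bases (distinct phases)
_INVERSE = {PHASE_MAP[b]: b for b in "ACGT"}


def _as_bytes(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii", errors="surrogateescape")
    return np.frombuffer(seq, dtype=np.uint8)


def phase_of_symbol(symbol: str) -> float:
    """Phase (radians) of a single IUPAC nucleotide symbol, case-insensitive.

    Raises
    ------
    ValueError
        If the symbol is not a recognized IUPAC nucleotide code.
    """
    try:
        return PHASE_MAP[symbol.upper()]
    except KeyError:
        raise ValueError(f"unrecognized nucleotide symbol {symbol!r}") from None


def phase_signal(seq: str | bytes, *, id: str = "") -> np.ndarray:
    """Map a sequence to its phase signal (one value per residue).

    Parameters
    ----------
    seq
        Nucleotide sequence (IUPAC codes, case-insensitive).
    id
        Optional identifier used in error messages.

    Returns
    -------
    numpy.ndarray
        Float array of length ``len(seq)`` with values in the eight-element
        phase alphabet.
    """
    codes = _as_bytes(seq)
    if codes.size == 0:
        raise ValueError(f"empty sequence{' ' + id if id else ''}")
    values = _LUT[codes]
    bad = np.flatnonzero(np.isnan(values))
    if bad.size:
        pos = int(bad[0])
        sym = chr(codes[pos])
        raise ValueError(
            f"invalid nucleotide symbol {sym!r} at position {pos + 1}"
            + (f" in {id}" if id else "")
        )
    return values


@dataclass(frozen=True)
class CumulatedPhase:
    """Cumulated (running-sum) phase signal of a sequence.

    Attributes
    ----------
    values
        Running sum of the phase signal, same length as the sequence.
    argmax, argmin
        0-based positions of the global maximum/minimum (first occurrence);
        derived from ``values`` when not given explicitly.
    """

    values: np.ndarray
    argmax: int | None = None
    argmin: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size == 0:
            raise ValueError("empty signal")
        object.__setattr__(self, "values", values)
        if self.argmax is None:
            object.__setattr__(self, "argmax", int(np.argmax(values)))
        if self.argmin is None:
            object.__setattr__(self, "argmin", int(np.argmin(values)))
        if not (0 <= self.argmax < values.size and 0 <= self.argmin < values.size):
            raise ValueError("argmax/argmin out of range")

    @property
    def i_max(self) -> int:
        """1-based position of the global maximum."""
        return self.argmax + 1

    def __len__(self) -> int:
        return len(self.values)


def _int_cumsum(seq: str | bytes, *, id: str = "") -> np.ndarray:
    """Exact integer running sum of the phase coefficients (units of pi/4)."""
    codes = _as_bytes(seq)
    if codes.size == 0:
        raise ValueError(f"empty sequence{' ' + id if id else ''}")
    bad = np.flatnonzero(np.isnan(_LUT[codes]))
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"invalid nucleotide symbol {chr(codes[pos])!r} at position {pos + 1}"
            + (f" in {id}" if id else "")
        )
    return np.cumsum(_ICOEF[codes])


def cumulated_phase(seq: str | bytes, *, id: str = "") -> CumulatedPhase:
    """Cumulative sum of the phase signal of ``seq``.

    Computed in exact integer units of pi/4 and scaled to radians, so the
    positions of the global extrema are exact.
    """
    return CumulatedPhase(pi / 4 * _int_cumsum(seq, id=id))


def closed_form_cumulated_phase(seq: str | bytes) -> np.ndarray:
    """Cumulated phase via prefix nucleotide counts (A/C/G/T-only closed form).

    Evaluates ``pi/4 * (3*(n_G,k - n_C,k) + (n_A,k - n_T,k))`` at every prefix
    length k.  Only meaningful for unambiguous sequences; ambiguity codes
    contribute zero, which coincides with the phase-sum definition for all
    zero-phase codes but not for R/Y/S.
    """
    codes = _as_bytes(seq)
    coef = np.zeros(256)
    coef[ord("A")] = coef[ord("a")] = 1.0
    coef[ord("T")] = coef[ord("t")] = -1.0
    coef[ord("G")] = coef[ord("g")] = 3.0
    coef[ord("C")] = coef[ord("c")] = -3.0
    return pi / 4 * np.cumsum(coef[codes])


def sequence_from_phases(values: np.ndarray) -> str:
    """Invert a phase signal back to its A/C/G/T sequence.

    Only the four unambiguous bases are invertible (their phases are
    distinct); any other phase value raises ``ValueError``.
    """
    out = []
    for v in np.asarray(values):
        for phase, base in _INVERSE.items():
            if abs(v - phase) < 1e-12:
                out.append(base)
                break
        else:
            raise ValueError(f"phase value {v!r} does not map to an unambiguous base")
    return "".join(out)
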