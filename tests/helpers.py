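"""Shared independent oracles and generators for the test suite."""

from __future__ import annotations

import numpy as np

#: Dinucleotides whose phase pair crosses zero / stays on C,G.
TR0_DINUCS = {"AC", "AT", "CA", "CG", "GC", "GT", "TA", "TG"}
TRCG_DINUCS = {"CC", "CG", "GC", "GG"}


def dinucleotide_fraction(seq: str, dinucs: set[str]) -> float:
    """Brute-force symbolic count of adjacent pairs in ``dinucs``."""
    hits = sum(seq[i : i + 2] in dinucs for i in range(len(seq) - 1))
    return hits / (len(seq) - 1)


def prefix_count_cumulated(seq: str) -> np.ndarray:
    """Independent closed-form oracle: pi/4*(3*(nG-nC) + (nA-nT)) per prefix,
    via explicit per-base prefix counting."""
    counts = {b: np.cumsum([c == b for c in seq]) for b in "ACGT"}
    return (np.pi / 4) * (
        3 * (counts["G"] - counts["C"]) + (counts["A"] - counts["T"])
    )


def random_acgt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
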