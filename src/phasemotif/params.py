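"""Sequence parameters for disordered regions: FCR, NCPR, kappa, mean
hydropathy and the fraction of disorder-promoting residues.

These are the five classic charge/patterning metrics used to characterise
intrinsically disordered sequence.  Kappa measures charge patterning on a
0-1 scale (0 = charges well mixed along the chain, 1 = maximally segregated
for the composition): local charge asymmetry ``sigma = (f+ - f-)^2 /
(f+ + f-)`` is computed in sliding blobs of 5 and 6 residues, its mean
squared deviation from the global asymmetry (``delta``) is normalised by
the maximum ``delta`` attainable by any rearrangement of the same charges
(``delta_max``).  For short sequences delta_max is found by exhaustive
enumeration of all distinct charge-pattern arrangements; beyond an
enumeration budget a documented family of extremal block arrangements is
used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

#: Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

#: Disorder-promoting residues: Ala, Arg, Gly, Gln, Ser, Pro, Glu, Lys.
DISORDER_PROMOTING = frozenset("ARGQSPEK")

DEFAULT_BLOB_SIZES = (5, 6)

#: Above this many distinct charge-pattern arrangements, delta_max falls
#: back to constructed extremal arrangements instead of full enumeration.
ENUMERATION_LIMIT = 100_000


class _NotApplicable:
    """Sentinel for kappa on sequences where it is undefined."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_APPLICABLE"

    def __bool__(self) -> bool:
        return False


NOT_APPLICABLE = _NotApplicable()


@dataclass(frozen=True)
class ChargePattern:
    labels: tuple[int, ...]  # +1, -1, 0 per residue
    f_plus: float
    f_minus: float


@dataclass(frozen=True)
class SequenceParameters:
    fcr: float
    ncpr: float
    kappa: "float | _NotApplicable"
    mean_hydropathy: float
    disorder_fraction: float
    kappa_exact: bool = True


def charge_pattern(sequence: str, his_charged: bool = False) -> ChargePattern:
    """Label each residue +1 (K, R), -1 (D, E) or 0; His neutral by default."""
    if not sequence:
        raise ValueError("empty sequence")
    positive = "KRH" if his_charged else "KR"
    labels = tuple(
        1 if ch in positive else (-1 if ch in "DE" else 0) for ch in sequence
    )
    n = len(labels)
    return ChargePattern(
        labels,
        f_plus=sum(1 for v in labels if v > 0) / n,
        f_minus=sum(1 for v in labels if v < 0) / n,
    )


def compute_fcr_ncpr(sequence: str, his_charged: bool = False) -> tuple[float, float]:
    cp = charge_pattern(sequence, his_charged)
    return cp.f_plus + cp.f_minus, cp.f_plus - cp.f_minus


def _sigma(labels: Sequence[int]) -> float:
    n = len(labels)
    fp = sum(1 for v in labels if v > 0) / n
    fm = sum(1 for v in labels if v < 0) / n
    if fp + fm == 0:
        return 0.0
    return (fp - fm) ** 2 / (fp + fm)


def _delta(labels: Sequence[int], g: int) -> float:
    """Mean squared deviation of blob asymmetry from global asymmetry.

    Blobs are fully contained windows of size g (no partial edge blobs).
    """
    sig_global = _sigma(labels)
    n = len(labels)
    total = 0.0
    for i in range(n - g + 1):
        total += (_sigma(labels[i : i + g]) - sig_global) ** 2
    return total / (n - g + 1)


def _n_arrangements(labels: Sequence[int]) -> int:
    n = len(labels)
    n_pos = sum(1 for v in labels if v > 0)
    n_neg = sum(1 for v in labels if v < 0)
    return math.comb(n, n_pos) * math.comb(n - n_pos, n_neg)


def _multiset_arrangements(labels: Sequence[int]) -> Iterator[tuple[int, ...]]:
    """All distinct arrangements of the charge-label multiset."""
    counts = {v: 0 for v in (1, -1, 0)}
    for v in labels:
        counts[v] += 1
    n = len(labels)
    buf: list[int] = []

    def rec() -> Iterator[tuple[int, ...]]:
        if len(buf) == n:
            yield tuple(buf)
            return
        for v in (1, -1, 0):
            if counts[v] > 0:
                counts[v] -= 1
                buf.append(v)
                yield from rec()
                buf.pop()
                counts[v] += 1

    yield from rec()


def _extremal_arrangements(labels: Sequence[int]) -> list[tuple[int, ...]]:
    """Block arrangements expected to maximise charge segregation."""
    n_pos = sum(1 for v in labels if v > 0)
    n_neg = sum(1 for v in labels if v < 0)
    n_zero = len(labels) - n_pos - n_neg
    pos, neg, zero = [1] * n_pos, [-1] * n_neg, [0] * n_zero
    half = n_zero // 2
    candidates = [
        pos + zero + neg,                      # charges split to opposite ends
        pos + neg + zero,                      # adjacent blocks at one end
        zero + pos + neg,                      # ... at the other end
        zero[:half] + pos + neg + zero[half:], # adjacent blocks centred
        neg + zero + pos,
    ]
    return [tuple(c) for c in candidates]


def compute_kappa(
    sequence: str,
    blob_sizes: Sequence[int] = DEFAULT_BLOB_SIZES,
    his_charged: bool = False,
    return_exact: bool = False,
):
    """Kappa charge-patterning parameter, or NOT_APPLICABLE when undefined.

    Undefined when the sequence has no charged residues, is shorter than
    every blob size, or every usable blob size is degenerate (delta_max 0,
    e.g. a fully charged single-sign sequence).  With ``return_exact`` a
    ``(kappa, exact)`` pair is returned, ``exact`` saying whether delta_max
    came from exhaustive enumeration.
    """
    if any(g < 2 for g in blob_sizes):
        raise ValueError("blob sizes must be >= 2")
    cp = charge_pattern(sequence, his_charged)
    usable = [g for g in blob_sizes if g <= len(cp.labels)]
    if cp.f_plus + cp.f_minus == 0 or not usable:
        return (NOT_APPLICABLE, True) if return_exact else NOT_APPLICABLE

    exact = _n_arrangements(cp.labels) <= ENUMERATION_LIMIT
    ratios = []
    for g in usable:
        delta = _delta(cp.labels, g)
        if exact:
            delta_max = max(_delta(arr, g) for arr in _multiset_arrangements(cp.labels))
        else:
            delta_max = max(_delta(arr, g) for arr in _extremal_arrangements(cp.labels))
        if delta_max == 0:
            continue
        ratios.append(delta / delta_max)
    if not ratios:
        return (NOT_APPLICABLE, True) if return_exact else NOT_APPLICABLE
    kappa = sum(ratios) / len(ratios)
    return (kappa, exact) if return_exact else kappa


def compute_hydropathy(sequence: str, raw: bool = False) -> float:
    """Mean Kyte-Doolittle hydropathy; shifted to the 0-9 scale by default."""
    if not sequence:
        raise ValueError("empty sequence")
    values = [KYTE_DOOLITTLE[ch] for ch in sequence if ch in KYTE_DOOLITTLE]
    if not values:
        raise ValueError("no canonical residues in sequence")
    mean = sum(values) / len(values)
    return mean if raw else mean + 4.5


def compute_disorder_fraction(
    sequence: str, promoting: frozenset[str] = DISORDER_PROMOTING
) -> float:
    if not sequence:
        raise ValueError("empty sequence")
    return sum(1 for ch in sequence if ch in promoting) / len(sequence)


def compute_all(sequence: str, his_charged: bool = False) -> SequenceParameters:
    """All five parameters in one record."""
    fcr, ncpr = compute_fcr_ncpr(sequence, his_charged)
    kappa, exact = compute_kappa(sequence, his_charged=his_charged, return_exact=True)
    return SequenceParameters(
        fcr=fcr,
        ncpr=ncpr,
        kappa=kappa,
        mean_hydropathy=compute_hydropathy(sequence),
        disorder_fraction=compute_disorder_fraction(sequence),
        kappa_exact=exact,
    )
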