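"""Motif-trio co-occurrence scoring and minimal peptide assembly.

For a trio of enriched motifs (A, B, C) we count, over the DPR universe,
the regions containing each pair and all three.  Two ratios summarise the
trio: *coverage*, the fraction of the least-present motif's regions in
which all three coexist, and *symmetry*, the min/max ratio of the three
pairwise counts (1 when A co-occurs with B exactly as often as with C and
B with C).  The final score averages them on a 0-100 scale::

    FS = 100 * (0.5 * coverage + 0.5 * symmetry)

so FS = 100 means all three motifs appear together in every DPR where any
of them appears, in equal pairwise proportions, and FS near 0 means the
motifs essentially never co-occur.  The formula is isolated here so an
alternative scoring rule can be swapped in.

Peptide assembly evaluates all six orderings of a trio, drops motifs that
are substrings of another member, merges adjacent motifs with maximal
suffix-prefix overlap (skipping a motif already contained in the running
merge), and keeps candidates under 20 residues.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .params import NOT_APPLICABLE, SequenceParameters, compute_all

MAX_PEPTIDE_LENGTH = 20  # designs must stay strictly below this

#: Default parameter windows for filtering designed peptides.  These are
#: package defaults standing in for published human-IDR ranges (hydropathy
#: on the shifted 0-9 scale); edit to taste via `filter_candidates(ranges=...)`.
DEFAULT_FILTER_RANGES: dict[str, tuple[float, float]] = {
    "fcr": (0.0, 0.7),
    "ncpr": (-0.35, 0.35),
    "kappa": (0.0, 0.5),
    "mean_hydropathy": (0.0, 4.8),
    "disorder_fraction": (0.55, 1.0),
}


@dataclass(frozen=True)
class TrioScore:
    motifs: tuple[str, str, str]  # canonical lexicographic storage order
    n_ab: int
    n_ac: int
    n_bc: int
    n_abc: int
    coverage: float
    symmetry: float
    fs: float

    @property
    def vs_sum(self) -> int:
        return self.n_ab + self.n_ac + self.n_bc


@dataclass
class DesignedPeptide:
    sequence: str
    source_motifs: tuple[str, str, str]
    ordering: tuple[str, ...]
    fs: float = 0.0
    params: SequenceParameters | None = None
    passes_filter: bool = True
    filter_failures: list[str] = field(default_factory=list)
    is_minimal: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def _presence_bitset(motif: str, dpr_sequences: Sequence[str]) -> int:
    bits = 0
    for i, seq in enumerate(dpr_sequences):
        if motif in seq:
            bits |= 1 << i
    return bits


def pair_cooccurrence(
    motif_a: str, motif_b: str, dpr_sequences: Sequence[str]
) -> int:
    """Number of DPRs containing at least one occurrence of each motif."""
    if not motif_a or not motif_b:
        raise ValueError("empty motif")
    return (
        _presence_bitset(motif_a, dpr_sequences)
        & _presence_bitset(motif_b, dpr_sequences)
    ).bit_count()


def _score_from_bitsets(
    trio: tuple[str, str, str], bits: Mapping[str, int]
) -> TrioScore:
    a, b, c = trio
    ba, bb, bc = bits[a], bits[b], bits[c]
    n_ab = (ba & bb).bit_count()
    n_ac = (ba & bc).bit_count()
    n_bc = (bb & bc).bit_count()
    n_abc = (ba & bb & bc).bit_count()
    min_presence = min(ba.bit_count(), bb.bit_count(), bc.bit_count())
    coverage = n_abc / min_presence if min_presence else 0.0
    mx = max(n_ab, n_ac, n_bc)
    symmetry = min(n_ab, n_ac, n_bc) / mx if mx else 0.0
    return TrioScore(
        motifs=trio,
        n_ab=n_ab, n_ac=n_ac, n_bc=n_bc, n_abc=n_abc,
        coverage=coverage, symmetry=symmetry,
        fs=100.0 * (0.5 * coverage + 0.5 * symmetry),
    )


def score_trio(
    motif_a: str, motif_b: str, motif_c: str, dpr_sequences: Sequence[str]
) -> TrioScore:
    """Score one trio; invariant under argument permutation."""
    if len({motif_a, motif_b, motif_c}) != 3:
        raise ValueError("trio motifs must be distinct")
    trio = tuple(sorted((motif_a, motif_b, motif_c)))
    bits = {m: _presence_bitset(m, dpr_sequences) for m in trio}
    return _score_from_bitsets(trio, bits)


def score_all_trios(
    motifs: Sequence[str], dpr_sequences: Sequence[str]
) -> list[TrioScore]:
    """Score every C(m,3) trio, ranked FS-descending then canonical order.

    Region membership is held as per-motif bitsets; pairwise intersections
    are cached so the triple loop costs one AND + popcount per trio.
    """
    motifs = sorted(set(motifs))
    if len(motifs) < 3:
        raise ValueError("need at least 3 distinct motifs")
    bits = {m: _presence_bitset(m, dpr_sequences) for m in motifs}
    presence = {m: bits[m].bit_count() for m in motifs}
    pair_bits: dict[tuple[str, str], int] = {}
    pair_count: dict[tuple[str, str], int] = {}
    for a, b in itertools.combinations(motifs, 2):
        pb = bits[a] & bits[b]
        pair_bits[(a, b)] = pb
        pair_count[(a, b)] = pb.bit_count()
    scores = []
    for a, b, c in itertools.combinations(motifs, 3):
        n_ab = pair_count[(a, b)]
        n_ac = pair_count[(a, c)]
        n_bc = pair_count[(b, c)]
        n_abc = (pair_bits[(a, b)] & bits[c]).bit_count()
        min_presence = min(presence[a], presence[b], presence[c])
        coverage = n_abc / min_presence if min_presence else 0.0
        mx = max(n_ab, n_ac, n_bc)
        symmetry = min(n_ab, n_ac, n_bc) / mx if mx else 0.0
        scores.append(
            TrioScore(
                motifs=(a, b, c),
                n_ab=n_ab, n_ac=n_ac, n_bc=n_bc, n_abc=n_abc,
                coverage=coverage, symmetry=symmetry,
                fs=100.0 * (0.5 * coverage + 0.5 * symmetry),
            )
        )
    scores.sort(key=lambda s: (-s.fs, s.motifs))
    return scores


def _overlap(left: str, right: str) -> int:
    """Length of the maximal suffix of ``left`` equal to a prefix of ``right``."""
    for k in range(min(len(left), len(right)), 0, -1):
        if left.endswith(right[:k]):
            return k
    return 0


def merge_ordered(motifs: Sequence[str]) -> str:
    """Merge motifs left-to-right with maximal suffix-prefix overlaps.

    A motif already contained in the running merge is skipped.
    """
    merged = motifs[0]
    for nxt in motifs[1:]:
        if nxt in merged:
            continue
        merged = merged + nxt[_overlap(merged, nxt):]
    return merged


def build_peptides(trio: Sequence[str]) -> list[DesignedPeptide]:
    """All deduplicated merge candidates for a trio, shortest flagged minimal.

    Motifs that are substrings of another trio member are dropped first;
    every surviving motif occurs as a substring of every candidate.
    Candidates of length >= 20 are discarded; output is sorted by length
    then lexicographically.
    """
    motifs = list(dict.fromkeys(trio))
    survivors = [m for m in motifs if not any(m != h and m in h for h in motifs)]
    seen: set[str] = set()
    candidates: list[DesignedPeptide] = []
    for ordering in itertools.permutations(survivors):
        seq = merge_ordered(ordering)
        if len(seq) >= MAX_PEPTIDE_LENGTH or seq in seen:
            continue
        seen.add(seq)
        candidates.append(
            DesignedPeptide(sequence=seq, source_motifs=tuple(sorted(set(trio))),
                            ordering=ordering)
        )
    candidates.sort(key=lambda p: (len(p.sequence), p.sequence))
    if candidates:
        candidates[0].is_minimal = True
    return candidates


def filter_candidates(
    candidates: Iterable[DesignedPeptide],
    ranges: Mapping[str, tuple[float, float]] | None = None,
    kappa_na_policy: str = "pass",
) -> list[DesignedPeptide]:
    """Annotate each candidate with its parameter-filter verdict.

    Nothing is deleted: ``passes_filter`` and ``filter_failures`` are set
    per candidate.  A kappa of NOT_APPLICABLE counts as a pass or a failure
    according to ``kappa_na_policy`` ("pass" or "fail").
    """
    ranges = dict(ranges or DEFAULT_FILTER_RANGES)
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"range for {name!r} has lo > hi")
    if kappa_na_policy not in ("pass", "fail"):
        raise ValueError(f"unknown kappa_na_policy {kappa_na_policy!r}")
    out = []
    for cand in candidates:
        if cand.params is None:
            cand.params = compute_all(cand.sequence)
        failures = []
        for name, (lo, hi) in ranges.items():
            value = getattr(cand.params, name)
            if name == "kappa" and value is NOT_APPLICABLE:
                if kappa_na_policy == "fail":
                    failures.append(name)
                continue
            if not (lo <= value <= hi):
                failures.append(name)
        cand.filter_failures = failures
        cand.passes_filter = not failures
        out.append(cand)
    return out


def rank_designs(peptides: Iterable[DesignedPeptide]) -> list[DesignedPeptide]:
    """Passing candidates first, FS descending, then length, then sequence."""
    return sorted(
        peptides,
        key=lambda p: (not p.passes_filter, -p.fs, len(p.sequence), p.sequence),
    )
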