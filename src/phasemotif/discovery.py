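"""Enrichment-based short-motif discovery in droplet-promoting regions.

Every contiguous 3-6-mer occurring in at least one positive DPR is a
candidate.  For each candidate we count *presence* (number of distinct
sequences in a universe containing at least one occurrence) and *frequency*
(total occurrences, overlapping matches included) in three universes:
positive DPR subsequences, full negative protein sequences, and NODPR
subsequences.  Raw presence/frequency folds against the negative universe
are min-max normalised to [0,1] (PF, FF) and combined with equal weight,
CF = 0.5 PF + 0.5 FF; motifs with CF at or above the selection threshold
(default 0.2) are reported as enriched.

Overlapping occurrences count toward frequency: homorepeat motifs (QQQQ in
QQQQQ) only make sense with step-1 window counting.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import ProteinRecord, RegionAnnotation, SENTINEL

log = logging.getLogger(__name__)

DEFAULT_K_MIN = 3
DEFAULT_K_MAX = 6
DEFAULT_CF_THRESHOLD = 0.2


@dataclass(frozen=True)
class MotifStats:
    motif: str
    presence_pos: int
    frequency_pos: int
    presence_neg: int
    frequency_neg: int
    presence_nodpr: int = 0
    frequency_nodpr: int = 0
    pf_raw: float = 0.0
    ff_raw: float = 0.0
    pf: float = 0.0
    ff: float = 0.0
    cf: float = 0.0
    neg_floored: bool = False  # denominator floored at 1 occurrence


@dataclass(frozen=True)
class PerRegionMotifCounts:
    motif: str
    region_id: str
    count: int


def enumerate_candidates(
    dpr_sequences: Iterable[str],
    k_min: int = DEFAULT_K_MIN,
    k_max: int = DEFAULT_K_MAX,
) -> set[str]:
    """Distinct k-mers (k_min <= k <= k_max) occurring in any positive DPR.

    Windows containing a sanitization sentinel are excluded.
    """
    if k_min < 1 or k_max < k_min:
        raise ValueError(f"bad k range [{k_min},{k_max}]")
    candidates: set[str] = set()
    for seq in dpr_sequences:
        for k in range(k_min, k_max + 1):
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if SENTINEL not in window:
                    candidates.add(window)
    return candidates


def count_occurrences(motif: str, sequence: str) -> int:
    """Occurrences of motif in sequence, overlapping matches counted."""
    if not motif:
        raise ValueError("empty motif")
    count = 0
    pos = sequence.find(motif)
    while pos != -1:
        count += 1
        pos = sequence.find(motif, pos + 1)
    return count


def count_presence_frequency(
    motif: str, sequences: Iterable[str]
) -> tuple[int, int]:
    """(presence, frequency) of one motif over a sequence universe."""
    presence = frequency = 0
    for seq in sequences:
        n = count_occurrences(motif, seq)
        if n:
            presence += 1
            frequency += n
    return presence, frequency


def count_universe(
    sequences: Iterable[str],
    ks: Iterable[int],
    restrict: set[str] | None = None,
) -> tuple[Counter, Counter]:
    """Presence and frequency counters for all k-mers over a universe.

    One pass per sequence and window length; with ``restrict`` only the
    given motifs are tallied (used for negative/NODPR universes so that
    counters stay bounded by the candidate set).
    """
    ks = sorted(set(ks))
    presence: Counter = Counter()
    frequency: Counter = Counter()
    for seq in sequences:
        seen: set[str] = set()
        for k in ks:
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if restrict is not None and window not in restrict:
                    continue
                frequency[window] += 1
                seen.add(window)
        presence.update(seen)
    return presence, frequency


def compute_fold_scores(
    candidates: Iterable[str],
    pos_counts: tuple[Mapping[str, int], Mapping[str, int]],
    neg_counts: tuple[Mapping[str, int], Mapping[str, int]],
    nodpr_counts: tuple[Mapping[str, int], Mapping[str, int]] | None = None,
) -> list[MotifStats]:
    """Raw folds against the negative universe, min-max normalised PF/FF, CF.

    The fold denominator is floored at one occurrence so motifs absent from
    negatives keep a finite, order-preserving fold (flagged per motif).
    Degenerate normalisation (all raw folds equal) maps everything to 0.
    """
    candidates = sorted(set(candidates))
    if not candidates:
        return []
    p_pos, f_pos = pos_counts
    p_neg, f_neg = neg_counts
    p_nod, f_nod = nodpr_counts if nodpr_counts else ({}, {})

    pf_raws = []
    ff_raws = []
    for m in candidates:
        pf_raws.append(p_pos.get(m, 0) / max(p_neg.get(m, 0), 1))
        ff_raws.append(f_pos.get(m, 0) / max(f_neg.get(m, 0), 1))

    def minmax(values: list[float]) -> list[float]:
        lo, hi = min(values), max(values)
        if hi == lo:
            log.info("degenerate min-max normalization (all folds equal); all set to 0")
            return [0.0] * len(values)
        return [(v - lo) / (hi - lo) for v in values]

    pfs, ffs = minmax(pf_raws), minmax(ff_raws)
    stats = []
    for m, pf_raw, ff_raw, pf, ff in zip(candidates, pf_raws, ff_raws, pfs, ffs):
        stats.append(
            MotifStats(
                motif=m,
                presence_pos=p_pos.get(m, 0),
                frequency_pos=f_pos.get(m, 0),
                presence_neg=p_neg.get(m, 0),
                frequency_neg=f_neg.get(m, 0),
                presence_nodpr=p_nod.get(m, 0),
                frequency_nodpr=f_nod.get(m, 0),
                pf_raw=pf_raw,
                ff_raw=ff_raw,
                pf=pf,
                ff=ff,
                cf=0.5 * pf + 0.5 * ff,
                neg_floored=p_neg.get(m, 0) == 0 or f_neg.get(m, 0) == 0,
            )
        )
    return stats


def select_enriched(
    stats: Iterable[MotifStats], cf_threshold: float = DEFAULT_CF_THRESHOLD
) -> list[MotifStats]:
    """Motifs with CF >= threshold, CF-descending, lexicographic tie-break."""
    if not (0.0 <= cf_threshold <= 1.0):
        raise ValueError(f"cf_threshold {cf_threshold} outside [0,1]")
    kept = [s for s in stats if s.cf >= cf_threshold]
    return sorted(kept, key=lambda s: (-s.cf, s.motif))


def embedded_fraction(
    motifs: Iterable[str],
) -> tuple[float, dict[str, list[str]]]:
    """Fraction of motifs that are proper substrings of another motif in the set.

    Also returns, per embedded motif, the list of its host motifs.
    """
    motifs = sorted(set(motifs))
    hosts: dict[str, list[str]] = {}
    for m in motifs:
        found = [h for h in motifs if h != m and m in h]
        if found:
            hosts[m] = found
    fraction = len(hosts) / len(motifs) if motifs else 0.0
    return fraction, hosts


def motif_set_summary(
    motifs: Iterable[str],
) -> tuple[dict[int, float], dict[str, float]]:
    """(length distribution in percent, residue membership in percent of motifs).

    Membership counts each motif once per residue type it contains.
    """
    motifs = sorted(set(motifs))
    if not motifs:
        raise ValueError("empty motif set")
    n = len(motifs)
    lengths = Counter(len(m) for m in motifs)
    length_pct = {k: 100.0 * v / n for k, v in sorted(lengths.items())}
    membership: Counter = Counter()
    for m in motifs:
        for a in set(m):
            membership[a] += 1
    membership_pct = {a: 100.0 * membership[a] / n for a in sorted(membership)}
    return length_pct, membership_pct


def per_region_counts(
    motifs: Iterable[str], regions: Sequence[RegionAnnotation]
) -> list[PerRegionMotifCounts]:
    """One row per (motif, region) with at least one occurrence."""
    rows = []
    for m in sorted(set(motifs)):
        for r in regions:
            n = count_occurrences(m, r.subsequence)
            if n:
                rows.append(PerRegionMotifCounts(m, r.region_id, n))
    return rows


def discover(
    dpr_sequences: Sequence[str],
    negative_sequences: Sequence[str],
    nodpr_sequences: Sequence[str] = (),
    k_min: int = DEFAULT_K_MIN,
    k_max: int = DEFAULT_K_MAX,
    cf_threshold: float = DEFAULT_CF_THRESHOLD,
) -> tuple[list[MotifStats], list[MotifStats]]:
    """Full discovery pass: candidates, counts, folds, selection.

    Returns ``(all_stats, selected)``.
    """
    ks = range(k_min, k_max + 1)
    candidates = enumerate_candidates(dpr_sequences, k_min, k_max)
    pos = count_universe(dpr_sequences, ks, restrict=candidates)
    neg = count_universe(negative_sequences, ks, restrict=candidates)
    nod = count_universe(nodpr_sequences, ks, restrict=candidates) if nodpr_sequences else None
    stats = compute_fold_scores(candidates, pos, neg, nod)
    return stats, select_enriched(stats, cf_threshold)


def discover_per_family(
    records: Sequence[ProteinRecord],
    regions: Sequence[RegionAnnotation],
    negative_sequences: Sequence[str],
    k_min: int = DEFAULT_K_MIN,
    k_max: int = DEFAULT_K_MAX,
    cf_threshold: float = DEFAULT_CF_THRESHOLD,
) -> dict[str, list[MotifStats]]:
    """Discovery restricted to each family's DPRs; negative universe unchanged.

    Normalisation is min-max within each family's own candidate set.
    Families without DPRs are omitted with a warning.
    """
    by_protein_family = {rec.id: rec.family for rec in records}
    out: dict[str, list[MotifStats]] = {}
    families = sorted({rec.family for rec in records if rec.source_set == "positive"})
    for family in families:
        dprs = [
            r.subsequence
            for r in regions
            if r.kind == "DPR" and by_protein_family.get(r.protein_id) == family
        ]
        if not dprs:
            log.warning("family %s has no DPRs; omitted", family)
            continue
        _, selected = discover(
            dprs, negative_sequences, k_min=k_min, k_max=k_max, cf_threshold=cf_threshold
        )
        out[family] = selected
    return out


def family_unique_motifs(
    per_family: Mapping[str, Sequence[MotifStats]],
) -> dict[str, set[str]]:
    """Motifs selected in exactly one family (set difference across families)."""
    sets = {fam: {s.motif for s in stats} for fam, stats in per_family.items()}
    return {
        fam: motifs - set().union(*(m for f, m in sets.items() if f != fam))
        if len(sets) > 1 else set(motifs)
        for fam, motifs in sets.items()
    }
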