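"""Amino-acid composition profiles for full sequences, DPRs and NODPRs.

Counts are exact tallies pooled over a group of sequences; percentages are
carried at full precision and printed at one decimal.  Residue-character
classes are a configurable partition of the 20-letter alphabet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import CANONICAL, ProteinRecord, RegionAnnotation, extract_region_sequences

# Default residue-character partition (standard biochemistry; His counted as
# positively charged here, configurable by passing another partition).
DEFAULT_CLASSES: dict[str, frozenset[str]] = {
    "positively charged": frozenset("KRH"),
    "negatively charged": frozenset("DE"),
    "aromatic": frozenset("FWY"),
    "polar uncharged": frozenset("STNQC"),
    "hydrophobic aliphatic": frozenset("AVLIM"),
    "special": frozenset("GP"),
}


@dataclass
class CompositionProfile:
    group_label: str
    counts: dict[str, int]
    n_residues: int
    class_percentages: dict[str, float] = field(default_factory=dict)

    @property
    def percentages(self) -> dict[str, float]:
        if self.n_residues == 0:
            return {a: float("nan") for a in CANONICAL}
        return {a: 100.0 * self.counts[a] / self.n_residues for a in CANONICAL}


def profile_sequences(
    seqs: Iterable[str],
    group_label: str = "",
    classes: Mapping[str, frozenset[str]] | None = None,
) -> CompositionProfile:
    """Pool residue counts across sequences into one profile.

    Sanitization sentinels (and any other non-canonical character) are
    ignored.  An empty pool yields a profile with ``n_residues == 0`` and
    NaN percentages, flagged with a warning.
    """
    classes = dict(classes or DEFAULT_CLASSES)
    counts = {a: 0 for a in CANONICAL}
    for seq in seqs:
        for ch in seq:
            if ch in counts:
                counts[ch] += 1
    n = sum(counts.values())
    if n == 0:
        warnings.warn(f"profile {group_label!r}: empty residue pool", stacklevel=2)
        return CompositionProfile(group_label, counts, 0)
    class_pct = {
        name: 100.0 * sum(counts[a] for a in members) / n
        for name, members in classes.items()
    }
    return CompositionProfile(group_label, counts, n, class_pct)


def profile_by_family(
    records: Sequence[ProteinRecord],
    regions: Sequence[RegionAnnotation] = (),
    kind: str = "full",
    classes: Mapping[str, frozenset[str]] | None = None,
) -> list[CompositionProfile]:
    """One profile per family present in the input, pooling within family.

    ``kind`` selects the residue pool: ``full`` protein sequences, or the
    ``DPR`` / ``NODPR`` subsequences of each family's proteins.  Families
    with no sequences of the requested kind are omitted with a warning.
    """
    if kind not in ("full", "DPR", "NODPR"):
        raise ValueError(f"unknown kind {kind!r}")
    if kind != "full":
        filled = extract_region_sequences(records, [r for r in regions if r.kind == kind])
        by_protein: dict[str, list[str]] = {}
        for r in filled:
            by_protein.setdefault(r.protein_id, []).append(r.subsequence)
    profiles = []
    for family in sorted({rec.family for rec in records}):
        fam_records = [rec for rec in records if rec.family == family]
        if kind == "full":
            pool = [rec.sequence for rec in fam_records]
        else:
            pool = [s for rec in fam_records for s in by_protein.get(rec.id, [])]
        if not pool:
            warnings.warn(f"family {family!r}: no {kind} sequences; omitted", stacklevel=2)
            continue
        profiles.append(profile_sequences(pool, f"{kind}/{family}", classes))
    return profiles


def rank_top_residues(
    profile: CompositionProfile, k: int
) -> list[tuple[str, float]]:
    """Top-k residues by percentage, descending, ties broken lexicographically."""
    if k <= 0:
        raise ValueError("k must be positive")
    if profile.n_residues == 0:
        raise ValueError("empty profile")
    ranked = sorted(profile.percentages.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[: min(k, len(ranked))]
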