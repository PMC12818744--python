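"""Seedable synthetic protein databases with annotated regions and planted motifs.

The generator emulates the structure of the curated study data so every
downstream stage can be exercised without downloads: 178 positive
(phase-separating) proteins of 400-800 residues carrying droplet-promoting
regions (DPRs, mean length 72.1) and non-droplet-promoting regions (NODPRs,
mean length 90.2) with distinct residue compositions, plus 208 negative
proteins drawn whole from a Leu-enriched composition.  Short motifs can be
planted into a controlled fraction of DPRs (or negatives) by overwriting an
in-region window, so enrichment is known by construction.

What this emulates: compositional contrast between region classes and
presence/frequency enrichment of specific k-mers.  What it does not: real
protein grammar, domain structure, or the positional statistics of real
intrinsically disordered regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import CANONICAL, ProteinRecord, RegionAnnotation

# Per-residue composition tables.  The leading entries of the DPR and
# negative tables are pinned to the study's reported top enrichments
# (DPRs: Gly 11.5%, Ser 11.7%, Pro 10.6%, Ala 7.6%, Glu 6.4%;
# negatives: Leu 11.1%, Ser 6.8%, Val 6.9%, Ala 6.6%, Glu 6.3%); the
# remaining mass is spread over the other residues in proportions typical
# of disordered (DPR), mildly hydrophobic (NODPR) and globular (negative)
# sequence.
DPR_COMPOSITION: dict[str, float] = {
    "G": 0.115, "S": 0.117, "P": 0.106, "A": 0.076, "E": 0.064,
    "Q": 0.060, "R": 0.055, "N": 0.047, "T": 0.052, "D": 0.049,
    "K": 0.049, "L": 0.040, "V": 0.034, "F": 0.030, "Y": 0.027,
    "I": 0.024, "H": 0.022, "M": 0.015, "C": 0.010, "W": 0.008,
}

NODPR_COMPOSITION: dict[str, float] = {
    "L": 0.095, "V": 0.070, "I": 0.055, "A": 0.075, "F": 0.045,
    "G": 0.060, "S": 0.070, "P": 0.050, "T": 0.060, "E": 0.065,
    "D": 0.050, "K": 0.063, "R": 0.048, "N": 0.040, "Q": 0.040,
    "Y": 0.030, "H": 0.023, "M": 0.025, "W": 0.012, "C": 0.024,
}

NEGATIVE_COMPOSITION: dict[str, float] = {
    "L": 0.111, "S": 0.068, "V": 0.069, "A": 0.066, "E": 0.063,
    "G": 0.068, "K": 0.058, "T": 0.056, "D": 0.053, "I": 0.051,
    "R": 0.053, "P": 0.047, "N": 0.042, "F": 0.042, "Q": 0.042,
    "Y": 0.030, "H": 0.024, "M": 0.023, "C": 0.021, "W": 0.013,
}

# Family labels are assigned to positives in the study's observed
# proportions (79, 42, 21, 27, 17, 10 of 178).
FAMILY_WEIGHTS: dict[str, float] = {
    "RNA-binding": 79 / 178,
    "DNA-binding": 42 / 178,
    "chromatin-binding": 21 / 178,
    "regulation": 27 / 178,
    "hydrolase": 17 / 178,
    "structure": 10 / 178,
}

MIN_REGION_LENGTH = 10


def _validate_table(table: dict[str, float], name: str) -> None:
    if sorted(table) != sorted(CANONICAL):
        raise ValueError(f"{name}: composition table must cover the 20 canonical residues")
    total = sum(table.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name}: composition sums to {total}, not 1")
    if any(not (0.0 <= p <= 1.0) for p in table.values()):
        raise ValueError(f"{name}: probabilities outside [0,1]")


@dataclass(frozen=True)
class PlantSpec:
    """A motif to plant at a controlled enrichment level.

    ``presence_fraction`` is the fraction of eligible targets (DPRs for
    ``positive_dpr``, negative proteins for ``negative``) that receive at
    least one copy; ``copies_per_region`` is an inclusive integer range.
    """

    motif: str
    presence_fraction: float
    copies_per_region: tuple[int, int] = (1, 1)
    target_set: str = "positive_dpr"

    def __post_init__(self) -> None:
        if not (3 <= len(self.motif) <= 6):
            raise ValueError(f"plant motif {self.motif!r}: length must be 3-6")
        if any(ch not in CANONICAL for ch in self.motif):
            raise ValueError(f"plant motif {self.motif!r}: non-canonical letters")
        if not (0.0 <= self.presence_fraction <= 1.0):
            raise ValueError("presence_fraction outside [0,1]")
        if self.target_set not in ("positive_dpr", "negative"):
            raise ValueError(f"unknown target_set {self.target_set!r}")
        lo, hi = self.copies_per_region
        if not (1 <= lo <= hi):
            raise ValueError("copies_per_region must be an ordered range >= 1")


@dataclass
class GeneratorConfig:
    """Study-scale defaults: 178 positives, 208 negatives, 400-800 residues,
    DPR mean length 72.1, NODPR mean length 90.2, 0.92 mean DPRs per negative."""

    n_positive: int = 178
    n_negative: int = 208
    protein_length_range: tuple[int, int] = (400, 800)
    dpr_length_mean: float = 72.1
    nodpr_length_mean: float = 90.2
    dprs_per_protein_range: tuple[int, int] = (1, 6)
    nodprs_per_protein_range: tuple[int, int] = (1, 6)
    negative_dpr_mean: float = 0.92
    composition_dpr: dict[str, float] = field(default_factory=lambda: dict(DPR_COMPOSITION))
    composition_nodpr: dict[str, float] = field(default_factory=lambda: dict(NODPR_COMPOSITION))
    composition_negative: dict[str, float] = field(default_factory=lambda: dict(NEGATIVE_COMPOSITION))
    planted_motifs: list[PlantSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        _validate_table(self.composition_dpr, "composition_dpr")
        _validate_table(self.composition_nodpr, "composition_nodpr")
        _validate_table(self.composition_negative, "composition_negative")
        lo, hi = self.protein_length_range
        if not (0 < lo <= hi):
            raise ValueError("protein_length_range must be positive and ordered")
        for spec in self.planted_motifs:
            if len(spec.motif) > MIN_REGION_LENGTH:
                raise ValueError(
                    f"plant motif {spec.motif!r} longer than the shortest possible region"
                )
        if self.dpr_length_mean <= MIN_REGION_LENGTH or self.nodpr_length_mean <= MIN_REGION_LENGTH:
            raise ValueError(f"region length means must exceed {MIN_REGION_LENGTH}")


def sample_composition(
    table: dict[str, float], length: int, rng: np.random.Generator
) -> str:
    """Draw ``length`` residues i.i.d. from a composition table."""
    if length < 0:
        raise ValueError("negative length")
    if length == 0:
        return ""
    _validate_table(table, "table")
    letters = sorted(table)
    probs = np.array([table[a] for a in letters])
    probs = probs / probs.sum()  # exact renormalization against float drift
    idx = rng.choice(len(letters), size=length, p=probs)
    letter_arr = np.array(list(letters))
    return "".join(letter_arr[idx])


def _region_length(mean: float, cap: int, rng: np.random.Generator) -> int:
    """Geometric-like length with the configured mean, truncated to [10, cap].

    Heavy right tail mimics real disordered-region length distributions;
    the floor keeps every region long enough to host a planted motif.
    """
    p = 1.0 / max(mean - (MIN_REGION_LENGTH - 1), 1.0)
    length = (MIN_REGION_LENGTH - 1) + int(rng.geometric(p))
    return int(min(max(length, MIN_REGION_LENGTH), cap))


def generate_database(
    config: GeneratorConfig | None = None,
) -> tuple[list[ProteinRecord], list[RegionAnnotation]]:
    """Generate positive and negative protein records with region annotations.

    Deterministic given ``config.seed``: a single random stream is consumed
    in fixed order (positives in id order, then negatives, then plant specs
    in list order).  Positives are assembled as spacer/region blocks whose
    residues come from the DPR and NODPR composition tables (spacers use the
    NODPR table); negatives are whole-sequence draws from the negative
    table.  Planting overwrites a random window fully inside the target
    region so lengths and boundaries are preserved.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    families = sorted(FAMILY_WEIGHTS)
    fam_probs = np.array([FAMILY_WEIGHTS[f] for f in families])
    fam_probs = fam_probs / fam_probs.sum()

    sequences: dict[str, list[str]] = {}   # mutable char arrays until freeze
    meta: dict[str, tuple[str, str]] = {}  # id -> (family, source_set)
    regions: list[RegionAnnotation] = []

    lo_len, hi_len = config.protein_length_range
    for i in range(config.n_positive):
        pid = f"POS{i + 1:04d}"
        family = families[int(rng.choice(len(families), p=fam_probs))]
        length = int(rng.integers(lo_len, hi_len + 1))
        cap = length // 2
        n_dpr = int(rng.integers(config.dprs_per_protein_range[0],
                                 config.dprs_per_protein_range[1] + 1))
        n_nodpr = int(rng.integers(config.nodprs_per_protein_range[0],
                                   config.nodprs_per_protein_range[1] + 1))
        blocks = [("DPR", _region_length(config.dpr_length_mean, cap, rng))
                  for _ in range(n_dpr)]
        blocks += [("NODPR", _region_length(config.nodpr_length_mean, cap, rng))
                   for _ in range(n_nodpr)]
        order = rng.permutation(len(blocks))
        blocks = [blocks[j] for j in order]
        # drop the longest blocks until regions + 1-residue spacers fit
        while sum(b[1] for b in blocks) + len(blocks) + 1 > length and len(blocks) > 1:
            longest = max(range(len(blocks)), key=lambda j: blocks[j][1])
            blocks.pop(longest)
        leftover = length - sum(b[1] for b in blocks)
        spacers = rng.multinomial(leftover - (len(blocks) + 1),
                                  [1.0 / (len(blocks) + 1)] * (len(blocks) + 1))
        spacers = spacers + 1  # every spacer at least one residue
        chars: list[str] = []
        pos = 0
        for j, (kind, blen) in enumerate(blocks):
            spacer = sample_composition(config.composition_nodpr, int(spacers[j]), rng)
            chars.extend(spacer)
            pos += len(spacer)
            table = config.composition_dpr if kind == "DPR" else config.composition_nodpr
            chars.extend(sample_composition(table, blen, rng))
            regions.append(RegionAnnotation(pid, pos, pos + blen, kind))
            pos += blen
        chars.extend(sample_composition(config.composition_nodpr, int(spacers[-1]), rng))
        sequences[pid] = chars
        meta[pid] = (family, "positive")

    for i in range(config.n_negative):
        pid = f"NEG{i + 1:04d}"
        length = int(rng.integers(lo_len, hi_len + 1))
        sequences[pid] = list(sample_composition(config.composition_negative, length, rng))
        meta[pid] = ("none", "negative")

    for spec in config.planted_motifs:
        _plant(spec, sequences, regions, meta, rng)

    records = [
        ProteinRecord(pid, "".join(chars), family=meta[pid][0], source_set=meta[pid][1])
        for pid, chars in sequences.items()
    ]
    seq_by_id = {r.id: r.sequence for r in records}
    regions = [
        RegionAnnotation(r.protein_id, r.start, r.end, r.kind,
                         seq_by_id[r.protein_id][r.start : r.end])
        for r in regions
    ]
    return records, regions


def _plant(
    spec: PlantSpec,
    sequences: dict[str, list[str]],
    regions: list[RegionAnnotation],
    meta: dict[str, tuple[str, str]],
    rng: np.random.Generator,
) -> None:
    m = len(spec.motif)
    if spec.target_set == "positive_dpr":
        targets = [(r.protein_id, r.start, r.end) for r in regions
                   if r.kind == "DPR" and len(r) >= m]
    else:
        targets = [(pid, 0, len(sequences[pid])) for pid in sorted(sequences)
                   if meta[pid][1] == "negative"]
    n_plant = int(round(spec.presence_fraction * len(targets)))
    if n_plant == 0:
        return
    chosen = rng.choice(len(targets), size=n_plant, replace=False)
    lo, hi = spec.copies_per_region
    for idx in chosen:
        pid, start, end = targets[int(idx)]
        copies = int(rng.integers(lo, hi + 1))
        # non-overlapping slots, as many as fit (always >= 1)
        slots = (end - start) // m
        copies = max(1, min(copies, slots))
        slot_idx = rng.choice(slots, size=copies, replace=False)
        for s in slot_idx:
            offset = start + int(s) * m
            sequences[pid][offset : offset + m] = list(spec.motif)
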