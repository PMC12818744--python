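"""Reading and writing protein sequences, region annotations and motif tables.

Sequences travel as FASTA (via Biopython); region annotations and motif
statistics travel as tab-separated text.  Internally every interval is
0-based half-open; readers translate from the file's declared coordinate
dialect at the boundary.

FASTA headers may carry record metadata as ``key=value`` tokens after the
accession, e.g. ``>P12345 family=RNA-binding set=positive pdp=0.85``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
#: replacement for non-canonical letters (B, J, O, U, X, Z); any k-mer window
#: containing it is excluded from motif counting downstream.
SENTINEL = "x"

FAMILIES = frozenset(
    {"RNA-binding", "DNA-binding", "chromatin-binding", "regulation",
     "hydrolase", "structure", "none"}
)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, sequence and study metadata.

    ``pdp`` is the droplet-promoting probability supplied by an upstream
    predictor; it is an input annotation, never computed here.
    """

    id: str
    sequence: str
    family: str = "none"
    source_set: str = "positive"
    pdp: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.family not in FAMILIES:
            raise ValueError(f"record {self.id!r}: unknown family {self.family!r}")
        if self.source_set not in ("positive", "negative"):
            raise ValueError(f"record {self.id!r}: bad set {self.source_set!r}")
        if self.pdp is not None and not (0.0 <= self.pdp <= 1.0):
            raise ValueError(f"record {self.id!r}: pdp {self.pdp} outside [0,1]")


@dataclass(frozen=True)
class RegionAnnotation:
    """A DPR or NODPR interval on a protein, 0-based half-open."""

    protein_id: str
    start: int
    end: int
    kind: str  # "DPR" or "NODPR"
    subsequence: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("DPR", "NODPR"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad interval [{self.start},{self.end}) on {self.protein_id}"
            )

    @property
    def region_id(self) -> str:
        return f"{self.protein_id}:{self.start}-{self.end}:{self.kind}"

    def __len__(self) -> int:
        return self.end - self.start


def sanitize(sequence: str) -> str:
    """Uppercase and replace non-canonical letters with the sentinel."""
    out = []
    for ch in sequence.upper():
        if ch in CANONICAL:
            out.append(ch)
        elif ch in "-* \t":
            continue
        else:
            out.append(SENTINEL)
    return "".join(out)


def _parse_header(description: str) -> tuple[str, dict[str, str]]:
    tokens = description.split()
    acc = tokens[0]
    meta: dict[str, str] = {}
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, val = tok.partition("=")
            meta[key] = val
    return acc, meta


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA; header tokens family=/set=/pdp= are parsed."""
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        acc, meta = _parse_header(entry.description)
        pdp = float(meta["pdp"]) if "pdp" in meta else None
        records.append(
            ProteinRecord(
                id=acc,
                sequence=sanitize(str(entry.seq)),
                family=meta.get("family", "none"),
                source_set=meta.get("set", "positive"),
                pdp=pdp,
            )
        )
    if not records:
        log.warning("no FASTA entries in %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = []
    for rec in records:
        desc = f"family={rec.family} set={rec.source_set}"
        if rec.pdp is not None:
            desc += f" pdp={rec.pdp:g}"
        entries.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    SeqIO.write(entries, str(path), "fasta")


def read_regions(
    path: str | Path, convention: str = "zero_half_open"
) -> list[RegionAnnotation]:
    """Read a region TSV (protein_id, start, end, kind) in the given dialect.

    ``zero_half_open`` rows pass through; ``one_inclusive`` rows are shifted
    to the internal 0-based half-open convention (start-1, end).
    """
    if convention not in ("zero_half_open", "one_inclusive"):
        raise ValueError(f"unknown coordinate convention {convention!r}")
    regions: list[RegionAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "protein_id":  # header row
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            pid, start_s, end_s, kind = fields[:4]
            start, end = int(start_s), int(end_s)
            if convention == "one_inclusive":
                start -= 1
            regions.append(RegionAnnotation(pid, start, end, kind))
    return regions


def write_regions(regions: Iterable[RegionAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tstart\tend\tkind\n")
        for r in regions:
            fh.write(f"{r.protein_id}\t{r.start}\t{r.end}\t{r.kind}\n")


def extract_region_sequences(
    records: Sequence[ProteinRecord], regions: Sequence[RegionAnnotation]
) -> list[RegionAnnotation]:
    """Fill each region's subsequence by slicing its parent record.

    Raises ``KeyError`` listing dangling protein ids, ``ValueError`` for
    out-of-bounds intervals.
    """
    by_id = {rec.id: rec for rec in records}
    dangling = sorted({r.protein_id for r in regions} - by_id.keys())
    if dangling:
        raise KeyError(f"regions reference unknown proteins: {', '.join(dangling)}")
    out = []
    for r in regions:
        seq = by_id[r.protein_id].sequence
        if r.end > len(seq):
            raise ValueError(
                f"region [{r.start},{r.end}) exceeds length {len(seq)} of {r.protein_id}"
            )
        out.append(replace(r, subsequence=seq[r.start : r.end]))
    return out


def filter_by_pdp(
    records: Iterable[ProteinRecord],
    threshold: float = 0.2,
    missing: str = "skip",
) -> list[ProteinRecord]:
    """Keep records whose droplet-promoting probability is strictly below threshold.

    Records lacking a pdp annotation are skipped with a warning by default
    (``missing="skip"``) or rejected (``missing="error"``).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside (0,1]")
    kept = []
    for rec in records:
        if rec.pdp is None:
            if missing == "error":
                raise ValueError(f"record {rec.id} lacks a pdp annotation")
            warnings.warn(f"record {rec.id} lacks pdp; skipped", stacklevel=2)
            continue
        if rec.pdp < threshold:
            kept.append(rec)
    return kept


MOTIF_TABLE_COLUMNS = [
    "motif", "length",
    "presence_pos", "frequency_pos",
    "presence_neg", "frequency_neg",
    "presence_nodpr", "frequency_nodpr",
    "PF", "FF", "CF",
]


def write_motif_table(stats, path: str | Path) -> None:
    """Write motif statistics as TSV, ordered CF-descending then lexicographic."""
    rows = sorted(stats, key=lambda s: (-s.cf, s.motif))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MOTIF_TABLE_COLUMNS) + "\n")
        for s in rows:
            fh.write(
                f"{s.motif}\t{len(s.motif)}\t"
                f"{s.presence_pos}\t{s.frequency_pos}\t"
                f"{s.presence_neg}\t{s.frequency_neg}\t"
                f"{s.presence_nodpr}\t{s.frequency_nodpr}\t"
                f"{s.pf:.6f}\t{s.ff:.6f}\t{s.cf:.6f}\n"
            )


def read_motif_list(path: str | Path) -> list[str]:
    """Read a motif list TSV: one motif per row, first column, '#' comments ignored."""
    motifs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split("\t")[0]
            if tok == "motif":
                continue
            motifs.append(tok)
    return motifs
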