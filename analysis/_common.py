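"""Shared setup for the analysis drivers: one study-scale synthetic database,
generated once (seed 2024) and cached under results/synthetic/."""

from pathlib import Path

from phasemotif.io import (
    extract_region_sequences, read_fasta, read_regions, write_fasta, write_regions,
)
from phasemotif.synthetic import GeneratorConfig, PlantSpec, generate_database

RESULTS = Path(__file__).resolve().parent.parent / "results"
SYNTHETIC = RESULTS / "synthetic"
SEED = 2024

#: Motifs planted into positive DPRs at 10x the negative rate, so the
#: discovery and design stages have known ground truth to recover.
PLANTED = ["GGDR", "SRGG", "GRGGY", "YGPG", "QPNS"]


def study_config() -> GeneratorConfig:
    specs = [PlantSpec(m, presence_fraction=0.4) for m in PLANTED]
    specs += [PlantSpec(m, presence_fraction=0.04, target_set="negative") for m in PLANTED]
    return GeneratorConfig(planted_motifs=specs, seed=SEED)


def load_database():
    """Load the cached synthetic database, generating it if absent."""
    fasta, regions_tsv = SYNTHETIC / "database.fasta", SYNTHETIC / "regions.tsv"
    if not fasta.exists():
        SYNTHETIC.mkdir(parents=True, exist_ok=True)
        records, regions = generate_database(study_config())
        write_fasta(records, fasta)
        write_regions(regions, regions_tsv)
    records = read_fasta(fasta)
    regions = extract_region_sequences(records, read_regions(regions_tsv))
    return records, regions
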