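"""phasemotif: short-motif enrichment in droplet-promoting regions of
phase-separating proteins, and co-occurrence-based design of minimal
LLPS-prone peptides."""

from importlib import resources

__version__ = "0.1.0"


def enriched_motif_list() -> list[str]:
    """The packaged 129-motif enriched set (synthetic reconstruction).

    Motifs named in the source study's prose are included verbatim; the
    remainder are constructed so the set's aggregate statistics (length
    distribution, residue membership, embedded fraction) match the
    published values.
    """
    from .io import read_motif_list

    path = resources.files("phasemotif") / "data" / "enriched_motifs_synthetic.tsv"
    with resources.as_file(path) as p:
        return read_motif_list(p)
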