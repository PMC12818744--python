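"""Characterize the packaged 129-motif enriched set: embeddedness, length
distribution, and residue membership.

The packaged list is a synthetic reconstruction of the published set;
its aggregate statistics (36% embedded, 54% tetrapeptides, Gly in 59% of
motifs, ...) are recomputed here from scratch.  Writes a summary TSV
under results/motif_set/.
"""

from _common import RESULTS

from phasemotif import enriched_motif_list
from phasemotif.discovery import embedded_fraction, motif_set_summary

OUT = RESULTS / "motif_set"


def main() -> None:
    motifs = enriched_motif_list()
    frac, hosts = embedded_fraction(motifs)
    length_pct, membership_pct = motif_set_summary(motifs)

    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "summary.tsv", "w") as fh:
        fh.write("kind\tkey\tpercent\n")
        fh.write(f"embedded\tfraction\t{100 * frac:.2f}\n")
        for k, v in length_pct.items():
            fh.write(f"length\t{k}\t{v:.2f}\n")
        for a, v in membership_pct.items():
            fh.write(f"membership\t{a}\t{v:.2f}\n")
    with open(OUT / "embeddings.tsv", "w") as fh:
        fh.write("motif\thosts\n")
        for motif in sorted(hosts):
            fh.write(f"{motif}\t{','.join(hosts[motif])}\n")

    print(f"{len(motifs)} motifs; {100 * frac:.0f}% embedded in another motif")
    print("length distribution: " +
          ", ".join(f"{k}-mers {v:.0f}%" for k, v in length_pct.items()))
    top = sorted(membership_pct.items(), key=lambda kv: -kv[1])[:6]
    print("most shared residues: " +
          ", ".join(f"{a} {v:.0f}%" for a, v in top))
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    main()
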