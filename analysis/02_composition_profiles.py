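"""Amino-acid composition of DPRs, NODPRs and negatives, overall and by family.

DPRs should echo their generating composition (Gly/Ser/Pro-rich), negatives
their Leu-enriched table — the compositional contrast that separates
droplet-promoting regions from ordinary sequence.  Writes residue and
residue-class percentage tables under results/composition/.
"""

from _common import RESULTS, load_database

from phasemotif.composition import profile_by_family, profile_sequences, rank_top_residues

OUT = RESULTS / "composition"


def main() -> None:
    records, regions = load_database()
    pools = {
        "DPR": [r.subsequence for r in regions if r.kind == "DPR"],
        "NODPR": [r.subsequence for r in regions if r.kind == "NODPR"],
        "negative": [r.sequence for r in records if r.source_set == "negative"],
    }
    profiles = [profile_sequences(seqs, label) for label, seqs in pools.items()]
    positives = [r for r in records if r.source_set == "positive"]
    profiles += profile_by_family(positives, regions, kind="DPR")

    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "residue_percentages.tsv", "w") as fh:
        fh.write("group\tresidue\tcount\tpercent\n")
        for profile in profiles:
            for residue, pct in sorted(profile.percentages.items()):
                fh.write(f"{profile.group_label}\t{residue}\t"
                         f"{profile.counts[residue]}\t{pct:.4f}\n")
    with open(OUT / "class_percentages.tsv", "w") as fh:
        fh.write("group\tclass\tpercent\n")
        for profile in profiles:
            for cls, pct in profile.class_percentages.items():
                fh.write(f"{profile.group_label}\t{cls}\t{pct:.4f}\n")

    for profile in profiles[:3]:
        top = ", ".join(f"{a} {p:.1f}%" for a, p in rank_top_residues(profile, 5))
        print(f"{profile.group_label:>9}: {top}")
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    main()
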