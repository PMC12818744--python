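"""Charge/patterning parameters (FCR, NCPR, kappa, hydropathy, disorder
fraction) for every DPR and NODPR.

NODPRs drawn from the hydrophobic table should show higher mean hydropathy
and a lower disorder-promoting fraction than DPRs — the two metrics that
separate the region classes.  Writes a per-region table under
results/params/.
"""

from statistics import mean

from _common import RESULTS, load_database

from phasemotif.params import NOT_APPLICABLE, compute_all

OUT = RESULTS / "params"


def main() -> None:
    _, regions = load_database()
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in regions:
        p = compute_all(r.subsequence)
        rows.append((r.region_id, r.kind, p))
    with open(OUT / "region_parameters.tsv", "w") as fh:
        fh.write("region_id\tkind\tfcr\tncpr\tkappa\tkappa_exact\t"
                 "mean_hydropathy\tdisorder_fraction\n")
        for region_id, kind, p in rows:
            kappa = "NA" if p.kappa is NOT_APPLICABLE else f"{p.kappa:.4f}"
            fh.write(f"{region_id}\t{kind}\t{p.fcr:.4f}\t{p.ncpr:.4f}\t{kappa}\t"
                     f"{int(p.kappa_exact)}\t{p.mean_hydropathy:.4f}\t"
                     f"{p.disorder_fraction:.4f}\n")

    for kind in ("DPR", "NODPR"):
        sub = [p for _, k, p in rows if k == kind]
        kappas = [p.kappa for p in sub if p.kappa is not NOT_APPLICABLE]
        print(f"{kind:>6}: n={len(sub)}  FCR {mean(p.fcr for p in sub):.3f}  "
              f"NCPR {mean(p.ncpr for p in sub):+.3f}  "
              f"kappa {mean(kappas):.3f}  "
              f"hydropathy {mean(p.mean_hydropathy for p in sub):.2f}  "
              f"disorder {mean(p.disorder_fraction for p in sub):.3f}")
    print(f"table written to {OUT}/region_parameters.tsv")


if __name__ == "__main__":
    main()
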