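"""Process a demonstration plate of assay readings with the closed-form
readout formulas.

Relative turbidity converts A600 absorbance to percent (a proxy for
condensate formation); encapsulation efficiency converts total vs
supernatant fluorophore concentrations to the percent taken up by the
droplet phase.  Writes computed tables under results/assays/.
"""

from _common import RESULTS

from phasemotif.assays import encapsulation_efficiency, relative_turbidity

OUT = RESULTS / "assays"

# demonstration readings: (sample, A600) and (sample, c_total, c_sup)
TURBIDITY_READINGS = [
    ("peptide-1mg", 0.05), ("peptide-5mg", 0.30), ("peptide-10mg", 1.00),
    ("buffer-blank", 0.00),
]
PARTITIONING_READINGS = [
    ("peptide-A", 10.0, 6.44), ("peptide-B", 10.0, 7.93), ("peptide-C", 10.0, 8.49),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "turbidity.tsv", "w") as fh:
        fh.write("sample\ta600\trelative_turbidity\n")
        for sample, a600 in TURBIDITY_READINGS:
            tau = relative_turbidity(a600)
            fh.write(f"{sample}\t{a600:.2f}\t{tau:.2f}\n")
            print(f"{sample:>13}: A600 {a600:.2f} -> relative turbidity {tau:.1f}%")
    with open(OUT / "encapsulation.tsv", "w") as fh:
        fh.write("sample\tc_total\tc_sup\tee_percent\n")
        for sample, c_total, c_sup in PARTITIONING_READINGS:
            ee = encapsulation_efficiency(c_total, c_sup)
            fh.write(f"{sample}\t{c_total:.2f}\t{c_sup:.2f}\t{ee:.1f}\n")
            print(f"{sample:>13}: EE {ee:.1f}%")
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    main()
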