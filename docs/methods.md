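# Methods

## Scope and data model

The package analyses protein sequence only. Proteins are records with an
accession, a sanitized 20-letter sequence, a functional family label
(RNA-binding, DNA-binding, chromatin-binding, regulation, hydrolase,
structure), a positive/negative set label, and optionally a
droplet-promoting probability (pDP) supplied by an upstream predictor —
pDP is never computed here, only used to select negatives (strictly below
a threshold, default 0.2). Regions (DPR or NODPR intervals) are 0-based
half-open everywhere internally; file readers translate from a declared
dialect (`zero_half_open` or `one_inclusive`), which keeps all slicing
arithmetic uniform and makes the conversion an involution. Non-canonical
letters (B, J, O, U, X, Z) are replaced by a lowercase sentinel during
sanitization; any k-mer window containing a sentinel is excluded from
motif counting, so the motif space is exactly the canonical alphabet.

## Motif discovery

Candidates are all distinct 3–6-mers occurring in at least one positive
DPR. This asymmetry is deliberate: a motif occurring only in negatives is
not a candidate and can never be reported.

Counting conventions, chosen once and used everywhere:

- *Presence* counts sequences (DPRs, or negative proteins) containing at
  least one occurrence; *frequency* counts occurrences with overlapping
  matches included (step-1 sliding window). Overlap counting is required
  for homorepeat motifs to behave sensibly (QQQQ occurs twice in QQQQQ).
- The negative universe is the full negative protein sequences, not
  negative DPRs: negatives average less than one droplet-promoting region
  each, so restricting them would leave almost no counting material.
- Fold denominators are floored at one occurrence, so motifs absent from
  negatives keep a finite fold that preserves ordering; such motifs are
  flagged (`neg_floored`).

Raw presence/frequency folds are min–max normalised across the candidate
set being scored (the minimal-assumption reading of "normalised to 0–1");
if all raw folds are equal the normalisation is degenerate and everything
maps to 0, which is logged. CF = 0.5 PF + 0.5 FF, and selection keeps
CF ≥ threshold (default 0.2, inclusive). Per-family discovery reruns the
whole pipeline on one family's DPRs with the negative universe unchanged
and normalisation within the family's own candidate set. Embedded motifs
(proper substrings of another selected motif) are reported but never
removed. All orderings break ties lexicographically so outputs are
deterministic.

## Trio scoring

For motifs A, B, C over the DPR universe, per-motif region membership is
a bitset; pairwise and triple co-occurrence counts are popcounts of bitset
intersections, which is what makes all C(129,3) = 349,504 trios over
~600–700 regions a seconds-scale computation. With n_AB, n_AC, n_BC the
pairwise counts and n_ABC the triple count:

- coverage = n_ABC / min(presence_A, presence_B, presence_C), 0 if the
  minimum presence is 0;
- symmetry = min(n_AB, n_AC, n_BC) / max(...), 0 if the maximum is 0;
- FS = 100 · (0.5·coverage + 0.5·symmetry).

The published account of this score states its anchors but not its
algebra; this formula is the simplest one reproducing all three anchors
(100 = all three motifs in all DPRs in equal proportions; ~50 =
asymmetric pairs or limited joint presence; ~0 = no co-occurrence) and is
isolated in one place so an alternative rule can be swapped in. FS is
invariant under argument permutation, bounded in [0, 100], and adding a
region containing all three motifs never decreases it.

## Peptide assembly and filtering

For each trio, motifs that are substrings of another member are dropped,
then every ordering of the survivors is merged left-to-right with maximal
suffix–prefix overlap, skipping a motif already contained in the running
merge. Candidates of length ≥ 20 are discarded, duplicates removed, and
the shortest candidate flagged minimal. For three motifs of length ≤ 6,
exhausting the orderings with maximal pairwise overlaps attains the
global shortest-superstring optimum (verified in the tests against a
search over all orderings *and all overlap amounts*).

Designed peptides are annotated with the five sequence parameters and a
filter verdict; filtering annotates, never deletes. The default windows
(FCR [0, 0.7], NCPR [−0.35, 0.35], kappa [0, 0.5], hydropathy [0, 4.8] on
the shifted scale, disorder fraction [0.55, 1]) are package defaults
standing in for published human-IDR ranges that are not printed anywhere
re-derivable; they are plain config values. A kappa of NOT_APPLICABLE
passes by default (policy configurable). Ranking puts passing candidates
first, then FS descending, length ascending, lexicographic.

## Sequence parameters

- Charge labels: K, R → +1; D, E → −1; everything else 0. Histidine is
  neutral by default (common practice near neutral pH), togglable.
- FCR = f+ + f−, NCPR = f+ − f−, so |NCPR| ≤ FCR always.
- Kappa: blob asymmetry σ = (f+ − f−)²/(f+ + f−) (0 for uncharged blobs)
  over fully-contained windows of 5 and 6 residues; δ_g is the mean
  squared deviation of blob σ from global σ; κ_g = δ_g / δ_max,g; κ is
  the mean over usable blob sizes. δ_max is found by exhaustive
  enumeration of all distinct arrangements of the charge-label multiset
  when their number is ≤ 100,000 — which covers every designed peptide —
  and otherwise by a documented family of extremal block constructions
  (charges at opposite ends; adjacent blocks at either end or centred);
  the fallback is flagged (`kappa_exact=False`). κ is NOT_APPLICABLE (a
  distinct sentinel, never a number, so it cannot silently pass a filter)
  when the sequence has no charges, is shorter than every blob, or every
  usable blob size is degenerate (δ_max = 0, e.g. a fully charged
  single-sign sequence). Edge blobs are not partially included; a
  sequence shorter than a blob size skips that size.
- Mean hydropathy is the Kyte–Doolittle mean shifted by +4.5 to the 0–9
  scale (raw mean available via flag).
- Disorder-promoting fraction over {A, R, G, Q, S, P, E, K}, configurable.

## Synthetic data generator

The generator emulates the study conditions as its defaults: 178
positives and 208 negatives, protein lengths uniform in 400–800, DPR
lengths geometric-like with mean 72.1 and NODPR lengths with mean 90.2
(heavy right tail, as real disordered-region lengths have), truncated to
[10, protein_length/2] — truncation pulls the realized means ~10% below
the configured values, which is accepted rather than compensated. Each
positive carries 1–6 DPRs and 1–6 NODPRs placed disjointly with at least
one spacer residue between blocks; spacers use the NODPR composition.
DPR composition pins the published top enrichments (Gly 11.5%, Ser 11.7%,
Pro 10.6%, Ala 7.6%, Glu 6.4%); the negative table pins Leu 11.1% with a
globular remainder; the NODPR table is mildly hydrophobic. Negatives are
whole-sequence draws. Planting overwrites a random window fully inside a
chosen region (never straddling a boundary), preserving all lengths;
exactly round(presence_fraction · n_targets) targets receive at least one
copy, and multi-copy plants go into disjoint slots. A single RNG stream
seeded from the config is consumed in documented order (positives, then
negatives, then plant specs), so outputs are byte-reproducible.

What the generator does **not** emulate: real protein grammar, domain
architecture, positional autocorrelation, or charge clustering — residues
are i.i.d. within a block, so kappa does not separate DPRs from NODPRs in
synthetic data even though hydropathy and disorder fraction do. Passing
tests therefore demonstrate correctness of the counting, scoring and
design machinery under known enrichment, not recovery of the real
databases' motif list.

## Packaged 129-motif set

`data/enriched_motifs_synthetic.tsv` is a synthetic reconstruction, not
the original supplementary table: every motif the source study names in
prose as a member of the global enriched set (78 motifs) is included
verbatim, and the remainder are constructed so the set's aggregate
statistics match the published values exactly under nearest-integer
rounding — 129 motifs; lengths 3/70/40/16 across 3/4/5/6-mers (the
published 2/54/31/13% is the largest-remainder rounding of this split);
residue membership Gly 59%, Pro 47%, Ser 29%, Arg 23%, Gln 20%, Tyr 19%;
36% of motifs embedded in another. Analyses of *individual* filler motifs
are meaningless; analyses of the set's aggregate structure are faithful.

## Numerical and testing choices

Tolerances: composition tables must sum to 1 within 1e-9; kappa oracle
agreement is asserted to 1e-12; published-statistic recomputation is
asserted at the printed (integer-percent) precision. Problem sizes in the
test suite follow the study conditions (178/208 proteins) where the
property under test is scale-dependent (planted-motif recovery, full
trio-matrix scoring) and use small constructed fixtures everywhere else.
Independent oracles are kept independent: counting is checked against a
character-by-character scan, kappa against a sympy-based multiset
enumeration, and superstring minimality against a search over all
orderings and overlap amounts — none of which share code with the
production paths.

Known limitations: the FS algebra is this package's own calibration of
the published anchors, so absolute FS values for real trios are not
comparable to the published peptide table; the CF normalisation scope
(global vs per-family) is a config choice; no statistical testing is
attached to composition differences or motif selection (selection is the
CF threshold, by design); FRAP curve fitting and any predictor of droplet
propensity are out of scope.
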