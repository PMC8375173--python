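# Methods

This note documents the models, rules and numerical choices behind
`zfsurvey`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Finger model and scanner

A C2H2 zinc finger is modelled as four ligand positions
`C-X(a)-C-X(s)-H-X(b)-H` with residues-between bounds `a ∈ [2, 4]`
(`cc_gap_min/max`), `s ∈ [7, 30]` (`spacing_min/max`; the Cys2→His1 spacing)
and `b ∈ [3, 5]` (`hh_gap_min/max`). The plant-specific QALGGH hexapeptide is
anchored to *end at the first histidine ligand*: that choice makes the intact
Q-type pattern `X2-C-X2-C-X7-QALGGH-X3-H` and the spacing-12 rule two views
of the same geometry. The general consensus also names an F and an L between
the cysteines and histidines; they are not enforced by default
(`require_FL=False`) because the Q-type pattern itself omits them — a strict
mode checks F at Cys2+4 and L at Cys2+10.

Scanning is two-pass and greedy. Pass 1 enumerates all ligand quadruples
satisfying the bounds, sorted lexicographically by `(c1, c2, h1, h2)`, and
accepts each candidate whose span `[c1, h2]` does not overlap an accepted
span; fingers never share a residue. Pass 2 revisits residues not covered by
pass 1 and emits single-histidine (D-type) fingers: a `C..C` pair followed by
*exactly one* histidine within `d_tail_max = 30` residues of Cys2, that
histidine being the QALGGH-terminal one. The tail inspection stops at the
first pass-1-covered residue so a D finger closely followed by a full finger
is still found. A `C..C` pair with no downstream histidine at all is not
reported — without the window histidine neither a type nor a QALGGH window
can be assigned. `X` never matches a ligand or window position: ligand
identity must be certain.

Greedy leftmost-first resolution was chosen because it is deterministic and
identical to the exhaustive-enumeration oracle used in the tests; the test
suite checks equality on thousands of random sequences over a C/H-rich
alphabet.

## Typing cascade

1. no second histidine → **D**;
2. window == QALGGH and spacing == 12 → **Q**;
3. 1–4 substitutions among the first five window residues → **M1–M4**
   (the subclass index *is* the substitution count; the ceiling
   `m_max_mismatch` is configurable);
4. otherwise **Z1** (spacing ≥ 12) or **Z2** (spacing < 12).

Two boundary conventions are deliberate. A fully substituted window (5/5)
routes to Z rather than M5 (`five_mismatch_to_z=True`): a window sharing
nothing with QALGGH is treated as fully degenerate. A degenerate window at
spacing exactly 12 goes to Z1: assigning the boundary upward keeps spacing-12
fingers distinct from the short-spacing Z2 class while Q already owns the
intact-window case.

## Architecture and subsets

Adjacent fingers are *linked* when at most `TANDEM_MAX_GAP = 11` residues
separate them (the "< 12 linker" convention); maximal linked runs form
tandem arrays, and a protein is tandem iff some array holds ≥ 2 fingers.
Subset labels: isolated proteins by finger count and collapsed type (M1–M4 →
M, Z1/Z2 → Z); two-finger proteins whose collapsed types differ — including
the D;D case, for which no named subset exists — are 2i-Mix; proteins with
five or more dispersed fingers are binned into Ta-4i-SF with a logged
warning. Tandem proteins are **t1** when a single array covers every finger
and **t2** otherwise (several arrays, or an array plus isolated extras);
t1/t2 have no standard published definition, so this single-array criterion
is the package's own and is configurable at the call sites. A protein with
both an array and isolated fingers counts as tandem: the tandem definition
keys on the existence of linked pairs.

Splice variants group by gene id (`Traes_…` ids parse into chromosome 1–7,
sub-genome A/B/D, arm S/L; foreign ids are accepted locus-less and skipped
in placement tables with a logged count). The per-gene representative is the
lowest variant index; genes whose variants disagree in their finger
type-string are flagged architecture-divergent.

Percentages are exact-rational, half-up: one decimal for protein-level
shares, two decimals for sub-genome and arm shares (survey reports
conventionally mix these precisions). Gene-level denominators count unique
genes with a parsed locus; protein-level denominators count proteins.

## Accessory boxes

Box patterns are degenerate strings (`x` = any residue) matched exactly;
within one pattern only the leftmost non-overlapping matches are kept, while
overlapping matches of different patterns are all reported. The shipped
library carries concrete patterns only for the EAR family (DLNxxP, LxLxL,
LDLNL, LDLSL, FDLNI); the L-, EK-, PL-, R-, NPL- and SFP1-boxes are known
only from sequence logos, so they ship pattern-less with their declared
finger-relative location and accept user patterns via a TSV library.
Inventing consensus strings for them was rejected. "N-/C-terminal of a
finger" means strictly outside the finger span; a zero-residue gap still
counts as outside.

## Ka/Ks (NG86) and the clock

Site counts: each codon position contributes (synonymous single-base
changes)/3; mutations into stop codons count as nonsynonymous sites.
Difference counts average the synonymous/nonsynonymous composition over all
minimal mutational pathways (1, 2 or 6 orderings), excluding pathways through
stop codons; when every ordering is blocked the codon pair contributes its
raw differences as nonsynonymous. Proportions use site counts averaged over
the two sequences and are Jukes–Cantor corrected,
`K = -(3/4) ln(1 - (4/3) p)`; `p ≥ 3/4` is reported as a saturation flag, not
an exception. NG86 was chosen over maximum-likelihood codon models because it
is fully specified, closed-form and checkable against a brute-force pathway
oracle (the tests compare the whole 61×61 sense-codon grid).

Selection: ω = Ka/Ks with a neutrality band |ω − 1| ≤ 0.05 (exact ω = 1 is
measure-zero; the half-width is configurable); Ks = 0 with Ka > 0 reports
ω = ∞, positive. Divergence time `T = Ks / (2λ × 10⁶)` Mya with
λ = 6.5 × 10⁻⁹ synonymous substitutions/site/year (grass clade), λ
configurable. Aligned pairs drop gapped codon columns and a shared terminal
stop; internal stops are errors.

## Expression

TPM matrices are transformed as log₂(TPM+1) — the pseudocount handles zeros.
Expressed genes: TPM ≥ 0.5 in ≥ 1 sample (boundary inclusive); both
thresholds configurable. Grouping: agglomerative clustering, average linkage,
Euclidean distance on the log rows, cut to k = 5 and relabelled 1..k by
ascending cluster mean (linkage and distance for published heatmap
dendrograms are rarely stated; average/Euclidean is the declared default).
Organ-level calls average the log values of each organ's three stages (the
15 stage codes map onto root/stem/leaf/spike/grain) and call low ≤ 1.0,
high ≥ 5.0, moderate between — declared defaults on the log₂ scale for the
qualitative words "lowly/moderately/highly expressed". qPCR fold change is
2^−ΔΔCT from target/reference CT in treated vs control.

## Synthetic data

`make_protein` writes finger blocks from fixed templates (Q: intact window,
spacing 12; M_k: k window substitutions drawn from letters disjoint from
QALGG; Z1/Z2: fully degenerate windows at spacings 14 and 9; D: a Q-like
block without the terminal histidine pair) joined by filler drawn from a
16-letter alphabet free of C, H, F and L, so no spurious fingers or EAR-like
matches can arise and scan+classify provably inverts the spec. The seed
varies only filler residues, never structure. One family of layouts is
rejected as unrealisable rather than generated: a D finger followed too
closely by a full finger (gap < 2 before Q/M, < 5 before Z2, < 1 before
another D), because the follower's histidines would pair with the D's
cysteines into a single chimeric unit that any consensus-driven scanner
would report instead of two fingers.

`make_codon_pair` draws a random stop-free CDS and applies Poisson numbers
of synonymous and nonsynonymous single-base changes, each at a distinct
(codon, position) slot, with means `p·S` and `p·N` where `p` inverts the
Jukes–Cantor map at the target rate — so the NG86 estimate is centred on the
target; across the tested range (Ks 0.05–0.6, 300 codons) the median
absolute Ks error is ≈ 0.03. `make_expression` adds Gaussian noise
(σ = 0.3 on the log₂ scale by default) to per-group mean profiles and
back-transforms to TPM.

**The paper-counts fixture** plants a complete family: 457 proteins over 204
genes (84 genes × 3 splice variants + 85 × 2 + 35 × 1; the 253 extra
variants reuse the representative's architecture except that the third
variant of multi-finger dispersed genes drops its first finger, mirroring
real variant series with reduced finger counts), with exactly 214 tandem and
243 isolated proteins. Genes are placed so chromosome 5 holds 54 (48 long-arm),
chromosome 2 holds 38 (14 long-arm), chromosomes 3/4/7 hold 27/33/13 (7 of
chromosome 7 long-arm), sub-genome B holds 85 and long arms 115 overall;
chromosomes 1 and 6 (20 and 19 genes) and the remaining arm quotas are free
margins chosen once. Gene models give 104 genes zero introns and the rest
one to ten. The TPM matrix plants five expression groups among the 198
expressed genes — 44 low, 35 root-preferential (9 moderate / 26 low outside
the root), 8 high, 37 broadly moderate with low root, 74 uniformly
moderate — plus 6 unexpressed genes (all-sample TPM < 0.5) drawn from the
broadly-moderate group, so the five recovered clusters sum to the expressed
count. Group profiles are spaced so that, at noise σ = 0.3, the smallest
between-group separation (the two root-preferential sub-profiles) still
merges before any other pair of groups; the root level of the
root-preferential group is set high (log₂ ≈ 6) because with a plain
Euclidean metric root *preference* must be encoded as a large root offset to
keep that group separable from the uniformly moderate one. Any slack
quantity not pinned by a planted tally is filled deterministically,
independent of the seed; the manifest records every planted truth and is the
single source for the round-trip tests.

What the generator does **not** emulate: realistic amino-acid composition,
homology between variants beyond architecture sharing, linkage between
chromosomal placement and expression, read-level noise, or length/GC
structure of real wheat genes. Passing round-trips therefore demonstrate
that the analysis code inverts its own declared rules on inputs satisfying
them — not that the rules recover every finger a profile-HMM search would
find in a real proteome.

## Problem sizes and determinism

The test suite and the acceptance script run the full 457-protein fixture
(sub-second), exhaustive scanner checks on ~1500 random sequences up to 40
residues plus 1000 planted proteins, the complete 61×61 sense-codon grid,
and 200 simulated codon pairs of 300 codons — all single-core and seeded.
Every random draw flows from an explicit integer seed; reruns with the same
seed are byte-identical.

## Known limitations

* Detection is consensus-driven, not probabilistic: no profile-HMM scores or
  E-values, and no C2HC/CCCH or other zinc-finger classes.
* The M-subclass rule (substitution count) is a declared stand-in for a
  convention that is not precisely published.
* NG86 underestimates rates at high divergence relative to ML codon models;
  results near the Jukes–Cantor bound are flagged saturated rather than
  extrapolated.
* The five-group clustering assumes groups separable in Euclidean
  log-expression space; root-*preference* as such is not a metric the
  clustering optimises.
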