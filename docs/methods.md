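# Methods

## Domain model and segmentation

CtBP-family proteins are treated as NTD + dehydrogenase core + CTD, with the
core operationalized as the anchored window `RPLVALL … NCVN`.  `NCVN` is the
final motif of the core, so the CTD starts strictly after it; the sequences
immediately downstream (`KEY` + aromatic in arthropods, `KEYL`/`KEFF` in
vertebrate paralogs) are therefore the first CTD residues.  The alternative
convention — treating `NCVNKEY` as the CTD start — appears in some
comparative figures; we keep the exclusive boundary so that composition
statistics describe only the disordered region, and the choice is
configurable at display level only.

Anchors are matched by leftmost exact occurrence, falling back to the
leftmost window at minimal Hamming distance within a budget (default 1
substitution), because divergent lineages vary anchor residues.  Coordinates
are 0-based half-open; the three intervals always tile `[0, L)`.  A missing
NTD anchor empties the NTD; a missing CTD anchor empties the CTD; both
missing is an error, not a guess.

Isoform typing: `short` means CTD < 40 residues.  Real short forms end
within ~10 residues of the core and long forms add a ~90-residue extension,
so 40 separates the regimes with margin on both sides.  Terminal motifs are
assigned by longest-suffix match against an editable catalogue (ancestral
`PEPSEVH`/`SEVH`, dipteran `APECARP`/`SNQEK`/`ESTEAP`, hymenopteran
`RLSSRC`, plus `DNTAR`, `AKK`, and the vertebrate family termini `PADQ`,
`LTEQ`).  NTDs of ≥ 300 residues are flagged RIBEYE-like; documented
extensions run 550–620 residues, and ordinary NTDs are well under 300.

## Pairwise identity

Global (end-to-end) Needleman–Wunsch with match +1, mismatch −1, linear gap
−2, and a fixed traceback preference (diagonal > up > left) for byte-stable
output.  Percent identity divides identical residue columns by the full
alignment length — gap columns count as differences, because "completely
conserved" positions are residue matches only.  Window identity locates the
reference's anchored core, maps those residue positions to alignment
columns, and computes identity over that column span (gaps inside the
window count as mismatches).  The scoring scheme is a package choice: only
percent identity, not score, is the comparative quantity, and published
core/CTD identity contrasts (~90% vs ~50% between mammalian paralogs) are
insensitive to reasonable scheme changes at the few-percent level.  A
substitution-matrix option is deliberately not the default.

## IDR composition and charge phase

Fractions are exact counts over non-X residues: P/G/A (structure-breaking),
hydrophobic {M, I, V, L, F, Y, W}, f⁺ = {K, R}, f⁻ = {D, E}; histidine is
treated as uncharged.  FCR = f⁺ + f⁻ and NCPR = f⁺ − f⁻ (stored signed;
thresholds use the magnitude).  The ambiguity code X is excluded from both
numerator and denominator so it cannot dilute fractions; an all-X sequence
is an error rather than a zero.

Two classifications are reported side by side because they answer different
questions.  The full Das–Pappu regions use the standard boundaries:
R1 (FCR < 0.25), R2 (0.25 ≤ FCR ≤ 0.35), R3 (FCR > 0.35, |NCPR| ≤ 0.35),
R4/R5 (FCR > 0.35 with signed NCPR beyond ∓0.35).  The simplified
weak-polyampholyte flag (FCR < 0.3 and |NCPR| < 0.25) follows the coarser
two-threshold rule used in comparative CtBP surveys; note its FCR cut
(0.3) is not the canonical R1/R2 boundary (0.25), so flag and region can
disagree (e.g. FCR 0.29, NCPR 0.20 is region R2 but flagged weak) — both
are reported, neither is given precedence.

Per-species aggregation picks the longest CTD (ties broken by smallest
record id, logged), excludes species with only tailless records, and
averages species unweighted within user-supplied groups (clades).

## Conservation classes

Per alignment column, among non-gap rows: one residue above 50% →
`conserved`; failing that, one chemical group (aliphatic M/V/I/L, aromatic
W/Y/F, acidic D/E, basic K/R, hydroxyl S/T) pooled above 50% → `chemical`;
independently, a distinct second residue in the closed interval [25%, 50%]
is recorded as secondary.  Columns under 50% occupancy are classed `none`.
Two conventions here are ours, stated explicitly because the source scheme
leaves them open: denominators exclude gaps, and chemical conservation
reuses the same >50% quota as the primary class.  Conserved blocks are
maximal runs of conserved/chemical columns tolerating at most one
interruption (both configurable) and at least 5 columns long; a simple
gap-fraction filter (default 0.8) stands in for heavier alignment trimming,
which is out of scope.

## Paralog classification

Calls combine two signals computed per query: core-window identity to
designated CtBP1 and CtBP2 reference proteins, and the CTD boundary motifs
characteristic of each duplicate family — `KEYL…PADQ` (CtBP1 side) and
`KEFF…LTEQ` (CtBP2 side), matched within one substitution per 4-mer because
lineages vary them (KDYL, KDYF, KEFL are attested variants).  Concordant
signals give the family; conflicting signals give `unresolved` with both
rule firings in the evidence trail — the classifier never silently
overrides one signal with the other.

Distinguishing the canonical gene from its `-like` duplicate for a lone
query is genuinely open; we use a ≥ 98% core-identity threshold to the
nearer reference for the canonical call, everything else concordant being
`-like`.  Within one species, the second-ranked CtBP1-side duplicate (by
core identity) is demoted to CtBP1a, implementing the observation that
1-like and 1a are distinguished by relative similarity rather than by any
motif of their own.

SUMO scanning reports every ψKxα window (ψ ∈ hydrophobic set, α ∈ {D, E}),
overlaps included; ψ's membership reuses the hydrophobic set above, since
no separate definition exists.  Site audits globally align query to
reference and read the query residue in the column of each named reference
site (CtBP1 numbering: S422, K428; CtBP2 numbering: S128, A129, R190, G216,
L221, S365, T414, S428); the tables are editable config, and reference
sequences are user-supplied, not bundled.

## Synthetic families

The generator assembles an ancestor as NTD template + core template
(`RPLVALL` … `NCVN`, 330 residues) + CTD, where the CTD is four conserved
blocks (`KEYW`, `PELNGAIYRY`, `AHSTT`, `PEPSEVH`) separated by three
22-residue spacers sampled from residue weights tuned to disordered-linker
composition: expected P+G+A 0.45, expected charge 0.14, hydrophobics rare.
This gives a 92-residue CTD, inside the 90–100 range typical of the family.
The fixed NTD/core templates are sampled once (package constants) from
folded-domain weights (~33% hydrophobic, ~22% P/G/A), so core-vs-CTD
composition contrasts behave like the real protein's.

Descendants arise by independent per-site substitution (default p = 0.05
per branch; star or balanced tree), uniform over the 19 alternative
residues — the simplest model with closed-form expectations.  Conserved
blocks and both anchors mutate at a 0.1 multiplier, mimicking purifying
selection.  Optional short isoforms (default probability 0.3 per species)
truncate after the core and append `SNQEK` or `APECARP`; optional paralog
families overwrite the CTD start/end 4-mers.  Indels, when enabled, are
spacer-only deletions so the true alignment stays trivially constructible;
they default off.  All sampling flows from one integer seed, and identical
spec + seed reproduces the family byte for byte.

Closed-form oracles: expected spacer class fractions are the normalized
weights; expected per-site identity between two star-tree leaves is
(1−p)² + p²/19.  A paralog benchmark derives two reference lineages from a
common ancestor (one 0.05-substitution branch each, putting their cores at
~90% identity, the observed mammalian CtBP1–CtBP2 contrast) and queries
one further 0.08 branch away (~92% to their own reference — clearly below
the 98% canonical threshold and clearly above the ~83% cross-family
identity), with motifs assigned concordantly or deliberately crossed.

What the generator does **not** emulate: rate heterogeneity beyond block
protection, realistic substitution matrices (LG/WAG), insertions, splice-
graph structure, lineage-specific CTD replacements (mites, nematodes,
tardigrades), or compositional drift of long branches.  Passing tests on
synthetic data therefore demonstrate correctness of the implementations
and recoverability of planted signal under an idealized substitution
process — not robustness to every form of real sequence divergence.

## Numerical and degenerate-input choices

Tie-breaks are fixed everywhere (alignment traceback diagonal>up>left;
longest-motif-wins for endings; smallest-id for equal-length CTDs;
leftmost for equal-distance anchor matches).  TSV floats print to 4
decimals and report column order is frozen, so outputs diff cleanly.
Terminal `*` (stop) is stripped on input with a log note.  Empty sequences,
all-X sequences, ragged alignments, duplicate ids, unmapped species, and
out-of-range audit sites all raise typed errors naming the offender.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
500 alignment-oracle pairs (length ≤ 6), 1,000-string counting and
SUMO-scan oracles, 50 single-species replicate families for composition
recovery (independent ancestors, so spacer sampling noise averages out),
3 × 12-species families (~88,000 site comparisons) for the substitution-
rate check, a 200-query concordant and 50-query conflicting paralog
benchmark, and 10 two-species replicate families for the composition
panel.  These sizes put Monte-Carlo noise well inside each check's
tolerance while the whole run stays in the seconds range.
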