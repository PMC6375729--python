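# Methods

`betrewire` implements the computational core of a BET-protein interactome
rewiring analysis: how an acetyl-lysine–competitive bromodomain inhibitor
(JQ1) reshapes the interaction landscape of the BET family (BRD2, BRD3,
BRD4, BRDT), and which sequence features — di-acetyl-lysine motifs read by
the bromodomains (BRDs) and basic/hydrophobic short linear motifs (SLiMs)
read by the extra-terminal (ET) domain — explain the inhibitor-sensitive and
-insensitive halves of that landscape. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Rewiring classification

The unit of observation is a bait–prey pair scored by AP-MS at a series of
treatment time points (0, 10, 60, 240 min), with spectral counts per
replicate and a SAINT false-discovery rate per pair and time point.

For a comparison of a reference time point `t0` against a treated time point
`t1`:

* Replicate spectral counts are **summed**, not averaged (spectral-count
  sums are the field's working currency, and sums preserve the count nature
  of the data).
* The log2 fold change is `LFC = log2((c1 + p) / (c0 + p))` with pseudocount
  `p = 1` by default. The pseudocount keeps LFC finite for the frequent
  gain-from-zero and loss-to-zero pairs; it is a configuration parameter so
  alternative zero-handling conventions can be explored, since published
  totals are sensitive to this choice.
* Categories: **decreased** (`LFC ≤ −T`), **increased** (`LFC ≥ +T`),
  **sustained** otherwise, with threshold `T = 2` (a four-fold change) —
  the threshold used throughout the source analysis.
* The classified universe is the union of pairs passing the FDR cut
  (default 0.01, i.e. FDR ≤ 1 %) at **either** compared time point.
  Pairs with zero summed counts at both time points are excluded: they are
  unobserved in the comparison, not "sustained at zero". Rows without an
  FDR value are treated as passing, on the assumption that FDR-free tables
  have been pre-filtered upstream.
* **Below-detection** preys — passing FDR at reference with counts > 0, and
  zero total counts after treatment — form the candidate pool for
  acetylation-dependent binding and feed the enrichment analysis.

Invariants enforced by construction and tests: category counts are conserved
(every classified pair gets exactly one category), the category is monotone
in the treated count for fixed reference count, and swapping the two time
points exactly exchanges the decreased and increased totals.

SAINT scoring itself, and control subtraction, are out of scope: the FDR in
the input table is trusted as the specificity filter.

## Motif scanning

All scanners report **overlapping** occurrences: the quantity of interest is
the number of candidate binding sites, not a maximal non-overlapping
matching, so a lysine may terminate one motif and begin the next. Positions
are 1-based throughout, following PTM-database convention.

* `scan_k_linker_k` enumerates K–X{n}–K for a linker-length window
  (default n = 2, the geometry a single BET BRD cavity accommodates; up to
  n = 6 for the longer-linker binding modes). Over the 20-letter alphabet
  there are 20² = 400 distinct XX linkers; exactly 13 of them occur in the
  four core histones (GG, GS, DG, AA, AP, AV, AQ, AR, SA, VL, LN, TA, TP)
  and define the "histone-like" subset.
* `scan_ky` and `scan_kyxk` cover the Kac–Y mode, where a tyrosine at +1
  substitutes for the second acetyl-lysine in the BRD cavity.
* `scan_et_slim` matches positional-alphabet patterns built from
  Φ = {M, L, V, I} (hydrophobic; `include_phe` adds F, the second-round
  extension that recovers F-containing motifs) and [+] = {K, R} (basic).
  The library comprises the minimal motif [+]Φ(Φ/[+]), a BRD9-like and a
  WHSC1/L1-like pattern, and three common motifs CM1–CM3. Two readings were
  genuinely open:
  * the BRD9-like LOGO string has four constrained positions, but the
    reference peptide LKLVLKV must contain exactly one site; the
    implemented 5-position pattern (Φ/[+])ΦΦ(Φ/[+])Φ — the conserved
    C-terminal hydrophobic included — is the unique natural reading with
    that property;
  * CM2's "(H)" is implemented as a literal histidine and flagged
    "interpretation uncertain" in the pattern's notes.
  Flank residues (up to 5 per side) are captured for display but never
  constrain matching.

Acetylation overlay (`overlay_kac`) classifies each di-K hit as unmodified,
mono-acetylated (first or second anchor) or di-acetylated from a
PhosphoSitePlus-style site table. Window deduplication is at the
window-string level, so identical peptides from splice variants collapse to
one entry with recorded multiplicity.

Every scanner is tested for exact agreement with an independent
regular-expression oracle (lookahead for overlap) on 1,000 random sequences.

## Positional enrichment

For a protein set of interest (typically one bait's below-detection preys),
15-mer windows are extracted around each annotated acetyl-K, gap-padded at
sequence termini. For each offset −7…+7 (0 = the central Kac, excluded as
fixed by construction):

* `percent(r, o)` = share of windows carrying residue `r` at offset `o`,
  among windows with a non-gap residue there. Gaps reduce the denominator
  rather than acting as a 21st symbol, so per-offset percentages sum to 100.
* `ratio(r, o)` = `percent(r, o) / (100 · bg(r))`. The default background is
  the pooled non-center, non-gap window residues of the same set (matching
  a per-set normalization); whole-proteome frequencies and user-supplied
  tables are options, since the original normalization is not fully
  specified. With the pooled background, the occupancy-weighted mean of
  each residue's ratios is exactly 1 — a structural identity used as a test.

No significance testing is attached to the ratios; the statistic is
descriptive, as in the source analysis.

## SPOT-array quantification

Spot intensities are normalized per array to the **maximum** hexa-His
control spot (percent of control maximum). Normalized values may exceed 100
(a spot brighter than the controls) and are capped only on request, since
saturation is handled by exposure, not clipping. Binding tiers are nested
with ≥ semantics: moderate ≥ 50 %, strong ≥ 75 %, very strong ≥ 85 %.

For two-domain (BD1/BD2) profiling the preference rule set is: `BD1_only`
iff BD1 ≥ 75 and BD1 ≥ 2·BD2 (symmetrically `BD2_only`); otherwise `both`
when both domains reach the moderate tier (the stricter ≥ 75 reading is a
config option, as the original category definition is ambiguous); `none`
otherwise.

Alanine scans report `retained(i) = 100·mutant(i)/wt` (100 = no change,
0 = total loss) and a derived contribution score
`max(0, 100 − retained)` normalized to sum 100 — this package's concrete
definition of "relative residue contribution", chosen because it is monotone
in binding loss and ignores gain-of-binding mutants; the formula is
configurable in the sense that the raw retained profile is always available.

## Synthetic data: what it emulates and what it does not

The generators produce every input format with recorded ground truth:

* **Interaction tables**: negative-binomial spectral counts
  (variance `m + αm²`, dispersion α = 0.2, the standard over-dispersion
  regime for spectral counting), base mean 50 per replicate, 4 baits,
  2 replicates, the 0/10/60/240 min design, planted per-pair categories
  with LFC ∈ {−4, 0, +4}, a configurable fraction of decreased pairs forced
  to exact zero (below-detection truth), SAINT-like FDR values, and an
  optional presence probability that plants a bait-sharing structure.
  Truth records both the *forced* zero-outs and the *realized* ones
  (chance all-zero draws included), so recovery tests compare against what
  is actually in the data.
* **Proteomes**: i.i.d. background residues with planted motif instances at
  recorded positions; the finished proteome is re-scanned and the full hit
  list recorded as truth, so accidental background matches can never make a
  test flaky. A census helper concatenates all 400 K-XX-K units with
  lysine-free 3-residue separators, guaranteeing exactly 400 scanner hits.
* **Acetyl-site tables**: per-lysine independent acetylation; a contextual
  bias can up-weight acetylation near a chosen residue. Because that bias
  saturates (the induced positional ratio is mathematically smaller than
  the multiplier), `simulate_acetylome` co-generates proteome and sites so
  that the conditional residue frequency at the biased offset is *exactly*
  `multiplier × background` — the generator whose planted 10× tyrosine(+1)
  signal the enrichment stage must recover.
* **SPOT arrays**: multiplicative log-normal noise (unit mean, CV 0.05 by
  default) on planted binding strengths, controls at strength 100.
  Normalizing to the *maximum* of several noisy controls biases all values
  slightly downward; this is faithful to the control-maximum definition and
  is the main reason tier concordance sits near, not at, 100 %.

What the generators do **not** emulate: peptide-level detectability and
shared-peptide inference, correlated noise between preys of one complex,
compositional competition between abundant preys, batch effects between
arrays, and real proteome residue composition (backgrounds are uniform by
default). Passing recovery tests therefore demonstrates correctness of the
computations under the stated noise models, not robustness to every
pathology of real AP-MS or densitometry data.

## Problem sizes and numerical choices

Test and acceptance runs use 1,000 bait–prey pairs for category recovery,
1,000 random sequences for scanner/oracle equivalence, 10,000 acetyl-K
windows for enrichment recovery, and 500 peptides for SPOT tier recovery —
sizes at which the binomial standard errors of the measured rates are well
below the margins being asserted. Per-offset percentage sums are checked to
1e−9; matrix round-trips are bit-exact for integers and 12 significant
digits for floats. Ties in enrichment rankings break alphabetically;
zero-background residues yield an explicit +inf sentinel with a warning
rather than silent NaN.

## Known limitations

* The published headline totals that derive from the deposited
  supplementary tables can only be reproduced with those tables on disk;
  the pipeline exposes every convention knob involved (FDR cut, threshold,
  pseudocount, time-point choice, column mapping) but ships no third-party
  data.
* The classified universe convention (union-of-time-points FDR pass,
  0-vs-0 exclusion) is one of several defensible readings; totals under
  other conventions are reachable through the exposed parameters.
* CM2 and the BRD9-like pattern width encode interpretation choices
  (flagged in the pattern metadata) that structural or binding data, not
  sequence alone, would settle.
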