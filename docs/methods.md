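# Methods

This note documents the models behind `aptatrigger`: the folding engine,
the variant-scoring conventions, the two-state dose-response model, the
switch-activation score, and the synthetic fixture generators, together
with every numerical choice a user might want to question.

## Nearest-neighbor folding engine

Secondary-structure free energies use a nearest-neighbor decomposition at
37 C, 1.0 M Na+, 0 M Mg2+ (RT = 0.61633 kcal/mol). The parameter table is
shipped as versioned package data (`data/rna_nn_params_v1.tsv`):
Watson-Crick stack energies follow the Xia/Turner measurements; wobble
(G:U) stacks are set within the published range, including the
destabilizing 5'GU/3'UG motif (+0.5 kcal/mol). Loop initiations
(hairpin >= 3 nt, bulge, internal) are tabulated and extended beyond the
tabulated sizes by a Jacobson-Stockmayer term `1.75 RT ln(n/n_max)`.
Single-nucleotide bulges retain the stack of their flanking pairs; larger
bulges and internal loops pay a 0.5 kcal/mol helix-end penalty per
adjacent A:U/G:U closing pair; internal-loop asymmetry costs
0.6 kcal/mol per unpaired-count difference, capped at 3.0. Multiloops are
affine: 3.4 kcal/mol closing + 0.4 per branch + 0.0 per unpaired base.

Deliberate simplifications, chosen for tractability and documented as a
known systematic offset: no dangling ends, no coaxial stacking, no
terminal-mismatch or special-hairpin (tri/tetraloop) terms, no pseudoknots,
no temperature or Mg2+ dependence. Absolute energies therefore differ from
NUPACK/ViennaRNA outputs; only orderings and signs are treated as
reproducible, and the test-suite checks rank agreement (Spearman > 0.8)
against an independent predictor rather than numeric equality.

All arithmetic is integer decacalories (1 unit = 0.01 kcal/mol). This
makes the dynamic program, its traceback, the explicit loop-decomposition
evaluator and the exhaustive enumeration oracle agree *exactly* - the
engine's core correctness property, verified on hundreds of random
sequences up to length 22 (the enumeration guard; beyond that the
structure count explodes).

MFE folding is a Zuker dynamic program (`V`/`WM`/suffix matrices,
two-loop span capped at 30 unpaired bases, minimum hairpin loop 3, G:U
allowed, lonely pairs allowed). Traceback is deterministic: candidates
are scanned pairing-first by smallest 5' index, then smallest partner,
with hairpin, two-loop and multiloop decompositions tried in that order,
so repeated calls are bit-identical. The open chain scores exactly 0 and
is always available, hence MFE <= 0.

Intermolecular duplexes (`duplex_mfe`) consider only inter-strand pairs,
with the same stack/bulge/internal terms, a 4.09 kcal/mol initiation
penalty and helix-end penalties at both duplex ends; the function returns
(0.0, no pairs) when no duplex has negative free energy. Because the
stack table is symmetrized under strand reversal, the duplex energy is
independent of argument order.

Ligand binding is a *soft constraint*: `fold_with_aptamer_bonus` adds a
(negative) bonus to every structure that forms the aptamer span's closing
lower-stem pair, implemented by injecting the bonus into that single DP
cell. A dominating bonus yields the best stem-closed structure, which is
how the competent-conformation penalty below is computed; explicit
ternary-complex folding is out of scope.

## Stem-variant scoring (ddG)

`compute_ddg(variant, original)` folds each aptamer flanked by 3-nt
neutral linkers (`AAA`, chosen to minimize spurious pairing; the linker
composition is a package convention) and reports
`ddG = dG_modified - dG_original`; positive means destabilized. MFE
rather than ensemble free energy is used - the two differ by a roughly
variant-independent entropy term at these sizes, and MFE keeps the
engine's exact-oracle property available for every reported number.

The stability window (3, 7) kcal/mol is exclusive at both ends:
`ddg <= 3` is `too_strong` (constitutively competent, leaky), `ddg >= 7`
is `too_weak` (ligand cannot pay the closure cost).

Because ddG is a *global* MFE difference, stem arms can base-pair with
the aptamer core, so GC-count orderings hold as a trend, not pairwise:
across the exhaustive length 2-4 variant sets of the theophylline
aptamer, the per-GC-count *median* ddG is strictly decreasing in GC
count at every length, while individual wobble-containing arms can beat
all-GC arms by recruiting core sequence (e.g. the GGCU/GGCC arm). Tests
and the acceptance checks therefore assert the median trend and
GC-richness of the global minimizer.

## Two-state dose-response model

The aptamer interconverts between a non-binding and a binding-competent
state; only the competent one binds ligand:

    f(L) = K (1 + L/Kd) / (1 + K (1 + L/Kd)),   K = exp(-ddg_conf / RT).

`ddg_conf` defaults to the stem variant's ddG (identity calibration,
exposed as a parameter since no experimental mapping is available);
`Kd` is user configuration - the packaged values are literature
placeholders and flagged as such. Reporter output is affine in the
competent fraction, `r(L) = basal + span (f - f0)/(1 - f0)`, which is
algebraically a one-site binding curve in `L` with midpoint

    EC50 = Kd (1 + K) / K,

strictly decreasing in K, i.e. weaker stems shift the operational range
upward. The closed form is cross-checked against numeric bisection to
1e-9 relative. Models with `f(0) > 0.99` are flagged as degenerate
(nothing left to switch).

**Identifiability.** Since the curve depends on (Kd, K) only through
`Kd (1+K)/K`, a single dose-response curve cannot determine both.
`fit_two_state` (seeded multi-start Levenberg-Marquardt on log
parameters) accepts one of them as fixed; the parameter-recovery study
(8 concentrations over 4 decades, 5% multiplicative log-normal noise,
100 seeded replicates) recovers Kd with K fixed and K with Kd fixed,
each to a median relative error comfortably within 20%. A joint fit is
permitted but its diagnostics flag the degeneracy. Hill coefficients
other than 1, kinetics, and high-ligand growth inhibition are out of
model scope.

## Switch-activation score

`score_activation(design, switch)` is the product of three factors, each
in (0, 1):

* **competence** `P = exp(-penalty/RT)`, where `penalty` is the cost of
  the trigger's stem-closed conformation relative to its ground state
  (0 when the competent state is the MFE). A ligand applies a saturating
  bonus of -20 kcal/mol to the closing pair, driving the penalty to 0;
  triggers without an aptamer (positive controls) have P = 1 in both
  states, making them ligand-independent by construction.
* **toehold access** `sigma(-(g_toe + 7.0)/1.5)`: a logistic in the
  trigger:toehold hybridization energy. Strand displacement nucleates at
  the single-stranded toehold; this factor suppresses triggers (or AND
  half-strands) that bind the stem region without a toehold foothold.
* **drive** `sigma(-(g_duplex - g_switch + 8.0 - RT ln d)/4.0)`: a
  logistic in the net free energy of unwinding the switch hairpin and
  forming the trigger:switch duplex, with an 8 kcal/mol offset lumping
  association entropy and the invasion barrier, and trigger dosage `d`
  entering as a chemical-potential shift (raising dosage raises both
  leak and activated scores). For an apta-trigger the duplex is computed
  with the *presented* domains b*+a* - in the competent conformation the
  aptamer folds compactly and co-localizes them - while the competence
  factor is computed on the full strand.

The logistic scale of 4.0 kcal/mol (about 6.5 RT) keeps score
differences resolvable across the design space; a scale as sharp as RT
collapses the score to a step function and erases the trim/dosage
orderings the model is meant to expose. Only orderings of these scores
are asserted anywhere - there is no quantitative activation data to
calibrate against.

`on_score` uses the saturating bonus, `leak_score` bonus 0. Crosstalk
matrices evaluate every trigger x switch pair and normalize each column
by its cognate diagonal (which is therefore exactly 1); with all ligands
absent the entries are leak-based instead.

**Gates.** OR gates share identical b*/a* domains across one
apta-trigger per ligand (combined score: best strand). AND gates split
the trigger across two strands, b*-aptamer1-c and c*-aptamer2-a*
(c chosen deterministically, 8 nt by default, rejected if it
cross-reacts with the switch below -8 kcal/mol); the gate score is the
product of both competence factors, a c:c* assembly factor and the
drive of the joined domains. NOT gates target a repressor-type switch
(translation ON by default); output is 1 minus the repression score, so
ligand turns expression OFF. Gate designers validate their products -
an AND half-strand that drives the switch alone, or a strand whose
aptamer is constitutively competent in its strand context (closure
penalty < 0.5 kcal/mol), is rejected with a design error rather than
silently mis-gating. Composite gates (NOR/NAND) are explicitly
unsupported. Truth tables threshold the score at 0.5 by default; scores
are strictly inside (0, 1), so thresholds 0 and 1 give all-ON / all-OFF.

## Synthetic fixture generators

The generators exist so every downstream module is testable offline, and
they *construct* the properties the circuit layer assumes:

* **Toy switches** (seeded): 12-nt A/U-biased toehold, 12-nt stem with
  the start codon sequestered at the stem top, RBS in the loop.
  Accepted only if the MFE structure forms the hairpin with the toehold
  single-stranded, the cognate trigger duplex is below -25 kcal/mol and
  beats the hairpin by at least 12 kcal/mol, the trigger:toehold duplex
  is below -9 kcal/mol, and all non-cognate duplexes against previously
  accepted switches stay above -8 kcal/mol (orthogonality by
  construction).
* **Toy aptamers** (seeded): a 3-5 nt lower stem of A/U pairs with one
  G, closed through a wobble G:U; the core contains a decoy segment that
  is the *strict* Watson-Crick complement of the 5' arm, so the
  non-binding (decoy-paired) state outcompetes the competent state by
  the G:C vs G:U margin. Accepted only if the closure penalty lies in
  [0.5, 9] kcal/mol. This mirrors the empirical recipe that functional
  lower stems have 3-5 mostly-A/U pairs.
* **Matched sets** co-select switches and aptamers: the aptamer's
  closure penalty must be invariant (within 0.02 kcal/mol) to the
  flanking trigger domains, including trimmed variants - i.e. the
  trigger tails must not fold onto the aptamer. This yields the clean
  monotonicity of leak under partial-trigger trimming that the tests
  assert; a switch with no compatible aptamer is redrawn.

What the toy parts do **not** emulate: real aptamer tertiary contacts
and ligand-binding geometry, pseudoknots/G-quadruplexes, cellular
context (RNase turnover, ribosome occupancy, growth effects), and
kinetics. Passing tests therefore demonstrate internal consistency of
the thermodynamic design rules, not wet-lab performance; the packaged
literature parts carry provenance strings and placeholder Kd values for
the same reason.

## Numerical conventions and degenerate inputs

* Energies: integer decacalories internally, kcal/mol floats at the API;
  reports print 4 decimals; coordinates are 0-based half-open; sequences
  are sense-strand RNA (T transliterated to U on input).
* Tie-breaking: first-match traceback in a fixed scan order (documented
  above); variant enumeration breaks ddG ties lexicographically on the
  5' arm; all generators are `numpy.random.default_rng`-seeded and
  byte-deterministic.
* Degenerate inputs: empty grids, unsorted grids, negative
  concentrations, non-complementary stem arms, over-trimming, empty
  partial-trigger domains, non-cognate cis fusions and unknown part
  names all raise typed errors naming the offending value; flat
  dose-response data raises a fit error rather than returning a
  meaningless model.

## Problem sizes

Default study sizes keep every check exact or well-sampled: 200 random
sequences (length 8-22) for oracle equivalence; exhaustive stem variants
at lengths <= 4 (1548 folds); 1000 random models for the EC50 closed
form; 100 noise replicates for parameter recovery; libraries of 4
switches for crosstalk; 20 seeded instances per gate type. These are the
package's standard verification sizes and scale linearly if enlarged.

## Known limitations

Absolute free energies are not comparable to NUPACK/ViennaRNA outputs
(no dangles/coaxial/terminal mismatches); the activation score is an
ordering device, not a fluorescence predictor; the identity
ddG -> ddg_conf calibration is a default, not a fitted mapping, so
predicted EC50 *shifts* between stem variants are qualitative; MS2-style
protein ligands are treated with the same one-site binding algebra as
small molecules; and trimming-induced leak increases seen for some real
aptamers (an unexplained empirical effect) have no model term here.
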