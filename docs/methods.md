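# Methods

## Problem setting

Parallel dimeric coiled-coils follow a seven-residue repeat
`abcdefg`: `a`/`d` residues pack into the hydrophobic core of the dimer
interface, `e`/`g` form flanking inter-helical electrostatic contacts,
and `b`/`c`/`f` face solvent.  `ccortho` implements the computational
cycle around a barcode-sequencing bacterial two-hybrid screen of such
designs: enumerate a restricted sequence space, predict pairwise
interaction strength with a learned linear model, quantify measured
interaction scores from barcode counts, fit the model to those scores,
and select the largest subsets of proteins whose intended pairings are
orthogonal — every on-target interaction stronger than every off-target
interaction by a chosen margin.

## Sequence space (`ccgen`)

A library coil consists of whole heptads starting on an `a` position.
The default design space is four heptads with Ile or Asn at `a`, Glu or
Lys at `e` and `g`, a fixed `d` residue, and a constant surface
*background* at `b`/`c`/`f`; it contains (2·2·2)⁴ = 4,096 coils.
Backgrounds modulate helicity and solubility but not the interface, so
coil identifiers are the concatenated `a`/`d`/`e`/`g` residues
("interfacial signature") plus the background name.  The fixed `d`
residue defaults to Leu — the canonical core residue in parallel
dimers — and is configurable, since the design space itself constrains
only `a`/`e`/`g`.  Partial heptads are rejected rather than padded.

## Interaction model (`scoring`)

The score of a chain pair at a given alignment is a sum of weights over
interface residue pairs plus an intercept:

* `aa` — `a_i`–`a'_i` core contacts; optionally the first a-contact of
  the interface is scored by a separate N-terminal class (`aa_nterm`),
  reflecting end fraying.
* `dd` — `d_i`–`d'_i` core contacts.
* `ge` — `g_i`–`e'_(i+1)` and `e_(i+1)`–`g'_i` electrostatic contacts;
  both orientations share one weight class.  The i→i+1 indexing is the
  standard canonical-dimer geometry; the package fixes this convention
  explicitly since alternative conventions appear in the literature.
* optionally, within-chain weights for consecutive `a` residues
  (`aconsec`).

Weights are symmetric in the residue pair (keys are sorted two-letter
strings).  Chains may interact displaced by whole heptads (a *heptad
shift*), leaving a shorter overlapping interface; the pair score is the
maximum over all alignments with at least `min_overlap` (default 1)
heptads of interface.  Equal-scoring alignments resolve to the smallest
|offset|, negative before positive, which keeps in-register alignments
preferred and makes scores exactly symmetric under operand exchange.
Sub-heptad (3/4-stutter) displacements and antiparallel orientations
are out of scope.

A residue pair with no weight raises an error by default to surface
alphabet mismatches; a treat-as-zero mode exists for inference with
partially trained models.

All-against-all scoring is vectorized: for each candidate offset the
contact-weight lookups broadcast over the whole library at once, so the
full 4,096-coil space (16.7 million ordered pairs) scores in well under
a minute on one core.

## Measured interaction scores (`quant`)

Each cloned protein pair carries one or more unique 20-nt DNA barcodes
inside the reporter transcript.  The pipeline truncates reads to the
barcode window, counts unique sequences, collapses sequencing errors by
greedy Levenshtein clustering (descending-count centroids, distance ≤ 1
by default; total counts are conserved exactly), and maps barcodes to
designed pairs by exact-match plurality voting with a 75% purity rule
(ambiguous barcodes are excluded).  A barcode is retained only with at
least `min_dna_reads` (default 10, compared with ≥) in *every* DNA
replicate; each pair's score is then

    interaction score = ln( median over barcodes of RNA reads / DNA reads )

with counts summed across replicates by default (a per-replicate-ratio
mode is provided; which pooling the original assay used is ambiguous,
and at matched depths both agree closely).  A pseudocount of 0 is the
default, faithful to the formula; all-zero-RNA pairs yield a flagged
−∞ rather than being dropped silently.  Greedy sphere clustering
replaces message-passing approaches: at distance 1 with strongly skewed
count distributions the partitions coincide in practice, and exact
count conservation holds regardless.  Exact-match plurality mapping
replaces read-mapping pipelines because designed libraries make exact
matching well-posed.

Replicate agreement is summarized by the Pearson correlation and the
maximum absolute score delta; the latter bounds measurement uncertainty
and motivates choosing an orthogonality-gap threshold safely above it.

## Model fitting (`training`)

Measured scores are regressed on contact counts.  Because off-target
pairs need not bind in register, the alignment of each pair is latent:
the fit alternates ordinary least squares at the current alignment
assignment with re-assigning every off-target pair to its best-scoring
alignment under the fitted model (on-target pairs stay pinned at offset
0 by default; a flag releases them).  Convergence is a fixed point of
the assignment, typically reached within a handful of rounds; if
`max_iter` (default 20) passes without one, `converged=False` is
reported rather than raising.  Realignment maximizes predicted score,
not residual, so the training RSS can tick up by a fraction of a
percent in a late round even on self-consistent data; descent holds
overall.  With adversarially degenerate generating weights (most pairs
selecting one-heptad interfaces) the assignment can oscillate with
period 2 — the linear model cannot represent such data and the loop
terminates by `max_iter`.

Least squares is solved in closed form; ridge regularization (never on
the intercept) is optional with λ = 0 the default, as the fitting
procedure of the original analysis is not specified and OLS is the
minimal choice.  Rank-deficient designs fall back to the minimum-norm
solution with a warning.

**Identifiability.**  Contact counts obey structural identities on
every alignment of equal-length chains: a-total = d-total = overlap,
ge-total = 2·(overlap − 1) (likewise consecutive-a), and exactly one
N-terminal a-contact per row.  Adding a constant to all weights of one
class is therefore absorbed by other classes and the intercept without
changing any prediction: raw weights are identifiable only up to a
three-dimensional gauge (four with consecutive-a), and with an
invariant `d` position the `dd` class is entirely confounded with the
intercept.  `gauge_fix` canonicalizes models — centering `ge`,
`aconsec` and `dd` at zero mean and aligning the N-terminal mean with
the core a-weight mean — without changing predictions, so that a fit
and the generator it recovered become comparable weight by weight.
Parameter-recovery results are always stated on gauge-fixed weights.

Bootstrap evaluation resamples rows with replacement, refits from
scratch, and records per-resample R² — on the resampled rows by default
(for comparing candidate model families) or on a held-out set.
Held-out evaluation is also available directly (`evaluate_r2`), with
pairs re-aligned under the evaluated model at inference time; shifting
is applied uniformly at inference by default, with the feature-config
flag restricting it if desired.

## Orthogonal subsets (`orthosets`)

For a pairing (hetero- and homodimers; each member in exactly one
pair), the *orthogonality gap* is the weakest on-target score minus the
strongest off-target score among the members; non-designated
homodimers count as off-target.  A pairing with no off-target
interactions — a lone homodimer — has an unbounded (+∞) gap and
therefore meets any finite threshold; callers can detect this via the
`unbounded` flag.

Two-orientation measurements are symmetrized by `mean`, `min`, `max`,
or the `conservative` policy (orientation minimum for on-target
evaluation, maximum for off-target), which can only shrink reported
gaps.  Missing orientations fall back to the present one; a pair
measured in neither orientation raises when needed.  Exact search
requires complete matrices; the original analysis likewise filtered to
complete, quality data.

The finder reduces subset selection to maximum independent sets.
Because the global gap condition couples every off-target interaction
to the *weakest* on-target score of the set, a single pairwise conflict
test is not exact; the search instead guesses that weakest score `v`
over all candidate on-target values.  At fixed `v` the condition
becomes a uniform off-target ceiling `v − gap`, the conflict graph
(vertices: candidate pairs with on-score ≥ v; edges: shared protein or
any cross off-target above the ceiling) encodes the problem exactly,
and a maximum independent set — computed as an exact branch-and-bound
maximum clique on the complement graph — is the largest valid pairing
with min-on ≥ v.  The best solution over all `v` is returned,
preferring size, then recomputed gap, then lexicographic pair ids; a
size-preserving local-swap pass further improves the gap, and a final
recomputation from raw scores guarantees the returned set satisfies its
own invariants.  This is exact up to 40 proteins; above that a greedy
heuristic with local search is used, with a warning (the returned set
is always valid, possibly not maximum).  Agreement with brute-force
enumeration of all partial pairings is tested on random 6-protein
instances.

`design_orthogonal_sets` applies the finder to model-predicted score
matrices: it repeatedly pools the strongest-interacting remaining
proteins (up to `max_proteins_per_set`), solves the pool exactly, and
removes chosen members — a scaled-down, deterministic reconstruction of
the original design search whose exact reduction was not published.
The default design threshold is 0.0 (predicted-orthogonal); the
experimental-selection default is 1.0, with 0.0/0.5 presets, matching
the margins used to tolerate measurement uncertainty below 0.8 score
units.

## Synthetic data (`synth`)

Generators are deterministic under their seed and produce inputs for
every other module:

* `make_true_model` — symmetric pair weights and intercept i.i.d.
  N(0, 1).
* `random_coils` — distinct random coils over per-position alphabets;
  unlike library enumeration the `d` position may vary, keeping the
  `dd` class identifiable in recovery fixtures.
* `simulate_interactions` — observed = true score + N(0, σ).  A
  `shift_fraction` of off-target rows is scored at the best alignment
  under the true model (the self-consistent notion of an injected
  shift: the recoverable offset is the one the generative model itself
  prefers); the rest are scored in register.
* `simulate_barcode_data` — per pair, `barcodes_per_pair` distinct
  random 20-mers; DNA counts negative-binomial around `dna_depth`, RNA
  counts negative-binomial with mean DNA·exp(score), so the ln-median
  statistic recovers the planted score by construction.  Emitted reads
  carry independent per-base substitution errors.  Negative-binomial
  (not Poisson) counts let replicate-agreement tests exercise
  overdispersion.
* `plant_orthogonal_matrix` — a complete matrix whose planted pairing
  exceeds all other interactions by at least `gap + 4σ` before noise;
  non-planted scores sit in a band narrower than the requested gap so
  the planted solution is uniquely optimal.

Defaults: noise σ = 0.15 (consistent with replicate correlations above
0.98 over a multi-log-unit range and worst-case score uncertainty below
0.8), 8 barcodes per pair, DNA depth 100, dispersion 20, per-base error
rate 0.5%, two replicates.  The `cc0-like` preset emulates a 16-protein
all-against-all control (256 ordered interactions).

What the simulations do **not** emulate: PCR chimeras beyond a simple
chimeric-read fraction, index hopping, cloning bottlenecks, qPCR
normalization, competition between pairs in a single pot, and any
sequence-dependent expression artifacts.  Passing tests therefore
demonstrate correctness of the computational procedures under the
stated generative assumptions, not predictive accuracy on real
screens — measured R² values of fitted models on experimental libraries
cannot be reproduced without the deposited data and are out of scope.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path: the full 4,096-coil enumeration and its vectorized score
matrix; 2,000-row training sets over 40-coil registries; 100-instance
oracle comparisons on 6-protein matrices; 100-seed planted-recovery
sweeps on 8-protein matrices; and quantification of 256-pair assays at
depth 100–1,000.  Score ties break deterministically everywhere
(alignment: smallest |offset|, negative first; subset selection: size,
then gap, then lexicographic ids).  Floating-point comparisons in the
subset search use strict inequalities on raw scores; degenerate inputs
(empty libraries, empty alphabets, unmeasured pairs, infeasible
alignments, all-zero RNA) raise typed errors or flagged sentinels as
documented on each function.
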