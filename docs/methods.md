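# Methods

`stramtf` analyses the repertoire of transcription factors (TFs,
sequence-specific DNA binders) and other transcription regulators (TRs,
chromatin remodellers and protein-interaction regulators) across a set of
related species — the motivating system is the Stramenopiles, a lineage
spanning autotrophic diatoms and brown algae and heterotrophic oomycetes.
The pipeline has four stages: rule-based classification of proteins into
TF/TR families from protein-domain hits; family-size and
relative-importance statistics; correlation of family sizes with
organismal traits under phylogenetic independent contrasts (PIC) and FDR
control; and parsimony mapping of family gains and losses with group-wise
abundance tests.

## Domain-hit filtering and classification

Inputs are per-domain bit-score tables from profile-HMM searches (HMMER3
`--domtblout`, or a simplified TSV with an explicit species column).  A
hit is trusted when its *per-domain* bit score clears the model's
*gathering cutoff* (GA), the curated per-model threshold above which
matches are considered true family members.  The comparison defaults to
inclusive (score ≥ GA), matching HMMER's `--cut_ga` convention; a strict
mode (score > GA) is available and the chosen mode is recorded in the
run's provenance file.  The domain-level, not full-sequence, score and GA
are used throughout, because classification is per-domain.

A family rule is a conjunction of *required clauses* — each clause an OR
over alternative domains, so one rule can accept alternative DNA-binding
domains — plus a set of *forbidden* domains whose presence vetoes
membership regardless of the required clauses.  In the rule file, `should`
rows sharing a `clause_id` form one OR-clause; a file without a
`clause_id` column treats every required domain as its own clause (pure
AND, the strictest reading of "must appear").  Classification is by the
*set* of GA-passing domains on each protein; domain copy number is
recorded for reporting but never consulted, and overlap resolution between
hits is not attempted — any GA-passing domain counts as present.

A protein can satisfy several rules.  The default policy reports every
satisfied family and flags the protein ambiguous (so a protein assigned to
k families increments k matrix cells); a `most_specific` policy keeps only
the satisfied rule(s) with the most required clauses.  Families with zero
members everywhere are retained in the size matrix so that downstream
gain/loss mapping can see absences.  Relative importance of family f in
species s is `100 · n_{sf} / Σ_f n_{sf}` — the family's percentage of all
TF+TR assignments in that species; each species row sums to 100 by
construction.

## Phylogenetic independent contrasts

Species inherit family sizes from common ancestors, so cross-species
values are not independent observations.  Under Brownian-motion (BM)
evolution, Felsenstein's pruning recursion converts n tip values on a
rooted bifurcating tree with branch lengths into n−1 standardized
contrasts: at each internal node with children carrying working values
x_i, x_j and working lengths v_i, v_j,

    c = (x_i − x_j) / √(v_i + v_j)
    x_node = (x_i/v_i + x_j/v_j) / (1/v_i + 1/v_j)
    v_parent-edge += v_i·v_j / (v_i + v_j)

The contrasts are i.i.d. N(0, σ²) when BM holds, so ordinary correlation
machinery applies to them.  The implementation propagates the weighted
average in the algebraically equivalent form `x_j + w_i (x_i − x_j)` so a
constant trait yields an exactly zero contrast vector, which is then
flagged undefined rather than correlated.

Correlation of two contrast sets defaults to the *through-origin* form
`r = Σ c_x c_y / √(Σ c_x² Σ c_y²)` with `t = r √((k−1)/(1−r²))` on k−1
degrees of freedom — contrasts have mean zero by construction, so fitting
an intercept wastes information.  A `centered` mode (ordinary Pearson on
the contrast vectors, k−2 df) reproduces the common practice of calling a
stock correlation function on contrasts.  Both modes are recorded per run.

The trait screen contrasts every continuous trait (genome size in Mb,
predicted protein count, flagella count, cell-type count) and every
family's size on the same tree, collects two-sided p-values, and applies
Benjamini–Hochberg step-up FDR *within each trait across families* (one
batch per trait; a joint batch is a defensible alternative, but per-trait
batches keep a poorly behaved trait from dragging the others).  BH was
chosen over empirical-null q-value estimation because it is deterministic
and assumption-light at these batch sizes (~60 tests).  Raw counts are
correlated by default — no transformation is applied — with an optional
log10 transform for scale-heavy traits like genome size.

Numerical choices: trees must be strictly bifurcating (polytomies are
rejected, or arbitrarily resolved on request with epsilon-length edges);
zero-length branches are replaced by ε = 1e−8 with a warning, since
contrasts divide by branch length; negative trait values are allowed
(contrasts are differences).

## Gain/loss mapping and group tests

Family presence (count > threshold; default threshold 0, raise to guard
against single-gene annotation noise) is mapped by unordered binary
parsimony, which permits regain after loss — a pattern these repertoires
actually show (a protein-interaction family lost in one clade and
regained in a nested subclade) and which Dollo parsimony would forbid.
The implementation is a unit-cost Sankoff dynamic programme (equivalent
to Fitch scoring for binary characters): a bottom-up pass computes each
node's minimal subtree change count conditional on its state, and a
top-down pass assigns states given the parent, so the per-edge optimal
sets are exact.  Ties are broken by DELTRAN (keep the parent's state
when optimal, delaying changes toward the tips) by default, ACCTRAN
optionally; edges with more than one optimal state are listed as
ambiguous rather than silently resolved, and a tied root is resolved to
*present* and flagged.  The parsimony score is tie-break independent.
Dollo parsimony (single gain at the connecting subtree of present tips,
losses below) is provided for single-origin analyses.

Family-size differences between ecological groups (autotrophs vs
heterotrophs, each needing ≥ 2 species) are screened with a two-sample
t-test — pooled-variance Student by default, Welch optionally — with BH
correction across families.  Identical group values give t = 0, p = 1;
zero variance with unequal means is flagged undefined rather than
reported as infinitely significant.  The t-test treats species as
exchangeable units; when groups coincide with clades this assumption is
optimistic, which is why the trait analysis proper goes through
contrasts and the group test is a secondary screen.

## Synthetic data: what it emulates, what it does not

The generator produces every input with known ground truth, under one
hierarchically split seed (per-tree / per-trait / per-family / per-hits
streams, so adding a family does not perturb the others; artifacts are
byte-identical across runs).

* **Trees** are pure-birth (Yule): waiting time to the next split among k
  lineages is Exp(k·λ), cut just before the (n+1)-th birth, so expected
  root-to-tip depth is Σ_{k=2..n} 1/(kλ).  Defaults: 11 tips, λ = 1.
  Pure birth gives the branch-length heterogeneity the statistics need;
  extinction realism is not attempted.
* **Traits** evolve by BM with per-trait rates (defaults: genome size
  root 100 Mb, σ = 30; predicted proteins root 15,000, σ = 3,000;
  flagella root 1, σ = 0.8; cell types root 3, σ = 1.5 — per unit branch
  length, giving paper-scale spreads over a depth-≈2 tree).  Binary
  mapping traits follow the autotroph group (chloroplast, pigments) or
  are random.
* **Family sizes** are log-normal-via-BM: a log-scale latent with root
  log 5 and σ = 0.6 per unit length, exponentiated and rounded, clipped
  to ≥ 1 so zeros arise only from planted losses.  These conditions give
  a few hundred TF/TR proteins per species across 63 families (mean ~5–8
  per family, range ~1–40), the scale observed in real repertoires of
  this kind.  A planted (family, trait, ρ) triple shares standardized BM
  increments between the trait and the family latent at correlation ρ;
  the ledger records the continuous latent, because rounding small
  counts attenuates the correlation observable from integer sizes
  (≈ 0.83 realized for ρ = 0.9 at these sizes) while detection power is
  essentially unaffected.  Planted gain/loss events flip presence on
  named edges; planted group shifts add a multiple of the family's count
  standard deviation to one group.
* **Domain hits** realize the size matrix exactly: each planted protein
  carries one domain per required clause at GA + U(1, 20) bits; decoys
  (default 20% of proteins) either miss one required clause or carry the
  family's forbidden domain at GA-passing scores, so they must be
  rejected by rule logic, not by the score filter; sub-GA noise hits
  (GA − U(1, 10)) land on real and on otherwise-empty proteins and must
  vanish at the filtering stage.  Scores only straddle GA; no attempt is
  made to mimic real HMM score distributions or sequences.

Because rules are synthetic with family-unique domains, classification on
generated data is exactly invertible; real rule files with shared domains
across families will produce genuine multi-family ambiguity, which the
pipeline reports but the synthetic tests do not exercise.  Passing tests
therefore demonstrate the correctness of the machinery, not the adequacy
of any particular real rule set.

## Verification and problem sizes

The calibration suite (`stramtf.validation`, exercised by the test suite
and `scripts/acceptance.py`) measures: exact 2- and 3-tip PIC closed
forms; whitening of the BM covariance (A V Aᵀ = I to 1e−8 over 500 random
trees ≤ 16 tips, with independent cross-checks against a dendropy-derived
covariance and against R's `ape::pic` in the unit tests); type-I error of
the through-origin contrast test at 32 tips over 10,000 independent BM
trait pairs (nominal 5% ± 1%); recovery of a planted ρ = 0.9 within
± 0.05 over 500 replicates at 64 tips; detection of the planted family at
q < 0.05 in ≥ 80% of 200 replicate screens (49 null families, 32 tips)
with null families flagged at ≤ 5%; exact inversion of an 11-species ×
63-family bundle (~5,000 proteins, 20% decoys, sub-GA noise) with zero
decoys assigned; parsimony-score agreement with exhaustive enumeration
(all 2⁶ patterns on a 6-tip tree, 100 random 8-tip instances) and planted
single-loss / loss-regain costs of 1 and 2; BH agreement with the
brute-force step-up definition on 1,000 random vectors; and the pooled
t-test closed form (t = −3.674, df = 4 for (1,2,3) vs (4,5,6)) plus its
calibration on exchangeable null counts.  These problem sizes were chosen
so the Monte-Carlo standard errors are well inside the stated bands while
the whole suite runs in a few minutes on one CPU.

## Known limitations

* The rule engine ships no curated rule content; real analyses must
  supply the family rule file, and results are only as good as the rules.
* BH-FDR assumes independent or positively dependent tests; family sizes
  within a species are compositionally coupled, which the per-trait
  batching mitigates but does not remove.
* The group t-test ignores phylogeny (see above).
* Parsimony mapping reports one most-parsimonious reconstruction plus the
  ambiguous edges; it does not enumerate all MPRs, and rate-based
  probabilistic gain/loss models are out of scope.
* Phylogenetic logistic regression for binary traits is not implemented;
  binary traits are carried through I/O for mapping only.
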