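# Methods

## Scope and model of the problem

`screeneval` evaluates receptor binding-site models — typically GPCR
homology models — for structure-based virtual screening. A model is judged
on two axes: whether retrospective docking against it retrieves known
ligands ahead of property-matched decoys (ligand enrichment), and how close
its coordinates are to an experimental reference structure
(region-restricted RMSD). The package also covers the derived analyses
that go with a template benchmark: best-score ensemble enrichment,
chemotype-subset enrichment, region-restricted sequence identity between
target and template, geometric binding-mode classification of docked
poses, and the summary statistics (distributions, OLS/Pearson
correlations) that relate these quantities.

## Semi-log ROC enrichment

Docked compounds are ranked by predicted binding energy (lower = better).
The ROC curve plots the ligand fraction retrieved (TPR) against the decoy
fraction retrieved (FPR). Ordinary AUC weights all of the curve equally,
but in a prospective screen only the extreme early ranks matter, so the
curve is integrated against `log10(FPR)` over `[lambda, 1]`:

    logAUC = 100 * (integral_lambda^1 TPR(x) dlog10 x) / log10(1/lambda)
    aLogAUC = logAUC - 100*(1 - lambda)/ln(1/lambda)

The subtracted term is the same integral for the random diagonal
`TPR(x) = x`, so aLogAUC is 0 for random ranking; at `lambda = 0.001` the
random baseline is 14.47 and a perfect screen scores 85.53. A screen that
retrieves twice the random ligand fraction at every decoy fraction
(`TPR = min(2x, 1)`) scores ~10.0, which anchors the qualitative bands:
`< 10` poor, `10–15` fair, `15–20` good, `20–25` very good, `> 25`
excellent (interior band edges upper-inclusive).

Numerical choices:

* **lambda = 0.001** by default (the established convention for this
  metric family), exposed in configuration. The normalized integral is
  insensitive to lambda at first order near that value.
* **Exact segment integration.** The empirical ROC is piecewise linear;
  `integral (a + bx) dln x = a ln(x2/x1) + b (x2 - x1)` is applied per
  segment with the curve clamped at `FPR = lambda` on the left. This is
  the limit of trapezoidal quadrature on the log axis and is verified in
  the tests against an independent dense-grid midpoint quadrature to
  1e-6 on a thousand random tables.
* **Ties** (identical scores) form one block that advances FPR and TPR
  simultaneously — a diagonal jump — making the curve deterministic and
  invariant to record order.
* **Undocked compounds** stay in both denominators and are appended as a
  single final tied block: a ligand that fails to dock costs enrichment
  rather than disappearing. The alternative (dropping failures from the
  denominators) is a legitimate convention but silently rewards models
  that cannot dock difficult actives.

## Ensembles and chemotype subsets

Ensemble enrichment merges member screens of the same compound universe by
giving each compound its best (minimum) docked energy over members where
it docked, then scores the merged table as one screen. The merge is
invariant to member order and duplication, and a member that supplies
every best score determines the result exactly.

Subset enrichment rescoreds one screen counting only a declared ligand
subset (a chemotype) against the full decoy background. Ligands outside
the subset are removed from both numerator and denominator, not recast as
decoys: they are known actives and would contaminate the negative set.
Chemotype membership always enters as an explicit id list; similarity
clustering is out of scope.

## Structural accuracy

All comparisons pair atoms strictly by `(chain, residue number, atom
name)`; residues or atoms missing on either side are skipped symmetrically.
The protocol is one deterministic convention:

1. a single least-squares (Kabsch) superposition on the transmembrane
   (TM) backbone atoms N, CA, C, O — no outlier-rejection cycles;
2. `RMSD_TMBB` (TM backbone), `RMSD_BSBB` (binding-site backbone) and
   `RMSD_BSSC` (binding-site side-chain heavy atoms, CB included) computed
   in that frame without refitting.

Side-chain RMSD accounts for chemical symmetry: for Asp (OD1/OD2), Glu
(OE1/OE2), Phe/Tyr (CD1/CD2 + CE1/CE2 jointly), Arg (NH1/NH2), Leu
(CD1/CD2) and Val (CG1/CG2), the labelling minimizing that residue's
squared deviation is chosen independently per residue. This is exact and
linear-time because the equivalent labellings within a residue are
independent of every other residue; symmetry-aware RMSD is therefore never
larger than the naive value and equals it when no symmetric residues are
present.

Pairwise model diversity superposes every model pair on the TM backbone
and reports the mean off-diagonal region RMSD. Improvement fractions count
candidates (e.g. refined snapshots) whose region RMSD to the reference is
*strictly* lower than a baseline model's.

Structures are read from PDB text through Biopython (first model only;
alternate locations resolve to the highest-occupancy conformer; waters and
hydrogens excluded). Printed RMSDs from any specific external tool are not
bit-reproducible targets because superposition protocols differ; the
convention above is documented so results are reproducible within this
package.

## Sequence identity

Region-restricted identity is computed from a two-sequence alignment
(FASTA or Clustal). The denominator is the number of *target* region
positions, so a region residue aligned opposite a template gap counts as a
mismatch — identity is framed per target region, and gaps penalize.
Comparison is case-insensitive and `X` never matches. Regions may be
given as residue numbers or as generic helix.position labels resolved
through a user-supplied numbering map; binding-site definitions enter as
configuration, never hard-coded.

## Binding-mode classification

A docked pose is "Good" iff it (a) places a declared cation atom within
4.0 A of either carboxylate oxygen of the anchor aspartate (generic
position 3.32) and (b) places an aromatic-ring centroid within 6.0 A of a
configured TM5/TM6 anchor heavy atom; otherwise "Bad". The cutoffs follow
common interaction-geometry conventions (salt bridge: N+ to carboxylate O
~<4 A; ring engagement: centroid to heavy atom ~<6 A) and are
configurable, since any published tally based on visual inspection is
threshold-sensitive. A pose with no declared cations or rings raises an
error rather than silently scoring "Bad". Verdicts are invariant under
rigid motion applied jointly to pose and receptor, and enlarging either
cutoff can only turn "Bad" into "Good".

## Synthetic data: what it emulates, and what it does not

The generators provide inputs whose correct answers are known in advance:

* **`gen_screen`** — ligand and decoy energies are Gaussians with common
  sigma. This is the minimal family with a closed-form ROC,
  `TPR(x) = Phi(Phi^-1(x) + d)` with `d = (mu_decoy - mu_ligand)/sigma`,
  which `binormal_logauc_oracle` integrates numerically (20,001-point
  trapezoid on the log axis, stable to 1e-4 under grid halving). Defaults
  are one large screen: 822 ligands vs 55,146 decoys, `d = 1` sigma
  (aLogAUC ~17, the "good" band), no docking failures. Failures, when
  enabled, strike independently of score — the simplest null for the
  undocked-handling policy, though real docking failures correlate with
  molecular properties.
* **`gen_ensemble`** — per-compound latent score plus a scalar per-model
  bias (`sd` 0.5) and per-compound noise (`sd` 1.0), giving inter-model
  rank correlation `sigma^2/(sigma^2 + noise^2)` = 0.8 at the defaults,
  emulating same-template model sets.
* **`gen_perturbed_structure`** — iid Gaussian coordinate noise (RMSD
  concentrates on `sqrt(3)*sigma`) and/or pure symmetric-label swaps that
  move no atom.
* **`gen_toy_complex`** — places cation and ring at exactly requested
  anchor distances, with all competing anchor atoms strictly farther.
* **`gen_toy_alignment`** — region identity is `100*n_matches/region_size`
  by construction, with optional template-gap columns counted as
  mismatches.

Passing tests on these inputs shows the metrics are computed correctly and
calibrated; it does not show that any real docking program's score
distributions are binormal, that real model errors are isotropic Gaussian
noise, or that real chemotype bias is an additive mean shift. Real screens
have heavier-tailed scores, correlated failures and non-spherical
structural error; conclusions about a particular receptor still require
real ligands, decoys and structures.

## Analysis scenario (analysis/)

The numbered analyses re-create the shape of a template benchmark at
reduced scale: 12 synthetic templates with binding-site identities 10–90%,
20 models per template, 200 ligands vs 10,000 decoys per screen (the
package defaults model a single full-scale screen; the benchmark trades
library size for template coverage). Identity drives both the score
separation (`d = 0.25 + 1.75*identity/100`) and the structural noise
(`sigma = 2.2 - 1.8*identity/100` A), so enrichment, accuracy and identity
are genuinely correlated in the synthetic world — the regressions in
`analysis/06_report.py` recover that construction (R ~ +1 for enrichment
vs identity, R ~ -1 for enrichment vs RMSD_BSSC). These are properties of
the scenario, not empirical claims about receptors.

## Known limitations

* Enrichment assumes exactly two classes; compounds of unknown activity
  are not modelled.
* Atom pairing requires identical residue numbering in both structures;
  sequence-based structural alignment is out of scope.
* The symmetry table covers the standard ambiguous side chains only
  (His ND1/CD2–CE1/NE2 flips are excluded because the atoms are not
  chemically equivalent).
* Binding-mode classification is binary geometry; it does not grade pose
  quality continuously and depends on the configured anchors and cutoffs.
* Quantiles use linear interpolation between order statistics; other
  quantile conventions will differ at small n.
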