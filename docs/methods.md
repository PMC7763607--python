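# Methods

## The modeling problem

Blood–brain barrier (BBB) permeation is commonly summarized by
LogBB = log10(C_brain / C_plasma), the log ratio of a compound's total
concentration in brain versus plasma. `fragbb` builds regression models of
LogBB from *fragmental (substructural) descriptors*: integer occurrence
counts of small labeled subgraphs of the heavy-atom molecular graph.
Active transport (e.g. P-glycoprotein efflux) is not modeled explicitly;
its structural correlates are left to be captured implicitly by the
nonlinear model.

## Molecular graphs and structure keys

Structures are parsed with RDKit from SMILES or SDF (V2000). Hydrogens are
folded into per-atom counts; only the largest connected component is kept
(salt stripping); stereochemistry is discarded (all fragments are 2D
topological); formal charges are retained without neutralization.
Aromaticity is perceived once, by RDKit's default model, for training and
prediction inputs alike — mixing perception schemes between training and
prediction would silently change descriptor meanings and is therefore not
supported. The canonical structure key (duplicate detection, dataset
overlap analysis) is the RDKit canonical non-isomeric SMILES of the
normalized graph.

## Fragment descriptors

A fragment is an **induced** connected subgraph of the heavy-atom graph
with at most `max_atoms` atoms (default 8; 6/8/10 are the searched
options), classified by topology:

* **path** — induced tree with maximum degree 2 (single atoms included);
* **cycle** — induced subgraph with all degrees exactly 2 (a simple,
  chordless ring);
* **branch** — induced tree with exactly one vertex of degree ≥ 3
  (a star whose rays are paths).

Because the subgraph is induced, each atom subset realizes at most one
fragment, and the occurrence number of a fragment is simply the number of
atom subsets realizing it — independent of traversal direction or starting
atom. The induced rule also keeps ring counting sane in fused systems: the
perimeter of naphthalene is not an induced cycle (the bridgehead bond is a
chord), so only the two six-membered rings are counted. Trees with two or
more branching vertices are deliberately not enumerated; they are the next
complexity class beyond paths/cycles/branches and would inflate the catalog
without adding interpretable descriptors.

Atoms are labeled at three refinement levels that coexist in one pooled
catalog: level 1 is the element alone; level 2 adds aromaticity and the
sorted pattern of incident heavy-atom bond orders; level 3 adds the valence
state (total bond-order sum) and the hydrogen count (and the formal charge
when nonzero). Each finer label determines the coarser ones, so level-3
counts aggregate exactly to level-2 and level-1 counts — a property the
test suite asserts. Bond orders inside the fragment are part of its
canonical key at every level. Canonical keys minimize over the symmetry of
each topology (reversal for paths; rotation and reflection for cycles;
ray sorting for branches).

Fragments occurring in fewer than `min_support` compounds (default 5, i.e.
fragments present in four or fewer compounds) are removed from the catalog:
such rare substructures cannot support generalizable relationships.
Columns whose [0, 1]-scaled variance falls below 1e-6 are removed next.
Both filters run once, globally, before cross-validation; the relevance
selection below runs locally inside the resampling loop.

## Preprocessing and descriptor selection

Descriptors and the endpoint are min-max scaled to [0, 1] per column,
fitted on training rows only. Counts are non-negative, strongly non-normal,
and small differences near zero are chemically meaningful, which is why
linear [0, 1] scaling is preferred over standardization; z-score, robust
(median/IQR) and quantile scalers are available as alternatives. A constant
column maps to 0 by convention. Scaled prediction inputs may fall outside
[0, 1] and are deliberately not clipped.

Selection methods, all deterministic given a seed, with ties broken by
ascending column (canonical-key) order:

* univariate top-k by F-statistic or by nearest-neighbor mutual information
  (3 neighbors, seeded);
* recursive feature elimination over PLS, random-forest, linear-SVM,
  elastic-net or lasso base models;
* **stepwise PLS** (the default): starting from the empty subset, fit a
  partial least squares regression (at most 5 components) on the current
  subset, form the residual endpoint, and add the descriptor with the
  highest relevance score against that residual; stop at k descriptors or
  when the residual variance degenerates.

The stepwise working model is linear while the final model is a neural
network; that structural mismatch is a guard against selection-induced
overfitting leaking into the final model family.

Local selection runs once per outer fold on the outer-training rows
(configurable to once per inner member); scalers are always fitted per
member on its inner-training rows.

## The network

A feed-forward regressor with one hidden layer by default, hidden width a
fraction (0.2–0.6) of the input width, SELU activations, a single linear
output unit, and optional alpha dropout (the SELU-compatible variant that
preserves self-normalization) between hidden layers. Weights use
LeCun-normal initialization (variance 1/fan-in). Training minimizes mean
squared error with Adam (learning rate 1e-3, batch 32) on scaled inputs and
endpoint; a disjoint stop set is evaluated every epoch and the weights of
the best stop-set epoch are restored when no improvement is seen for
`patience` epochs (default 20; epoch cap 1000). The forward pass,
backpropagation and the analytic input gradient are implemented in NumPy;
the gradient is verified against central finite differences in the tests.
The epoch cap matters: on clean low-noise fixtures the best stop-set epoch
can exceed 500, so truncating training dominates every other
hyperparameter.

## Double cross-validation

The NO×NI scheme (default 5×4): the outer loop partitions the dataset into
NO near-equal folds by plain random shuffle (no endpoint stratification);
for each outer fold, the remaining compounds are partitioned into NI inner
folds, and NI networks are trained each using NI−1 inner folds for weight
updates and the held-out inner fold for early stopping. The outer fold —
never seen by scaler, selector or network — receives the mean prediction of
its NI inner networks, inverse-scaled to log units. Repetitions (NR)
re-shuffle everything; out-of-fold predictions are averaged over
repetitions per compound before error sums, so that

    Q²     = 1 − PRESS/SS,    RMSEcv = sqrt(PRESS/N)

keep N equal to the compound count. PRESS is computed on the original
LogBB scale so RMSEcv is directly comparable to the ~0.3 log-unit
experimental error of the endpoint. The NR×NO×NI trained members, with
their scalers and selected subsets, form the prediction ensemble. A run
aborts unless at least 80% of members train successfully.

## Guarded prediction and applicability control

Per compound: each member predicts and is inverse-scaled; values outside
the sanity range [−2.5, 2.5] (wider than any realistic training span) are
discarded as applicability-domain violations; if strictly more than 50% of
members are discarded the prediction fails; survivors are clipped to the
acceptable range [−2, 2]; the mean and the population standard deviation of
the clipped survivors are reported, unless the SD strictly exceeds 30% of
the acceptable-range width (1.2 log units), which also fails the
prediction. The SD threshold uses the acceptable (clip) range width, not
the sanity width, and both comparisons are strict, matching the protocol's
"more than" wording. Members that fail featurization count toward the fail
fraction. The ensemble SD correlates only loosely with the eventual
prediction error, so it serves as a warning signal rather than a strict
filter; batch prediction reports that correlation alongside N, Pearson R,
RMSE and the counts of absolute errors above 1.0 and 1.5 log units.

## Fragment contributions

For interpretation, the gradient of the *scaled* output with respect to the
*scaled* inputs is computed analytically per member, multiplied elementwise
by that member's scaled inputs, mapped back to the full catalog (fragments
outside a member's selected subset contribute zero for that member), and
averaged over members, then over a compound set. A fragment absent from a
compound contributes exactly zero whenever the member's training minimum
for that column is zero (always true in practice for count data). Reports
are ranked from the most negative (permeability-lowering) to the most
positive contribution.

## Hyperparameter search

Trials draw configurations uniformly at random (seeded) from the space:
fragment size cap {6, 8, 10}, selected descriptor count 100–1000, hidden
ratio 0.2–0.6, dropout 0–0.5, selection and scaler method. Each trial runs
a full double-CV evaluation and is scored by Loss = −Q² + log(Time)/100
with Time the double-CV wall-clock seconds (floored at 1 s); the log base
defaults to natural and is configurable, since the penalty's base is a
convention rather than a derived quantity. Trials that fail or exceed a
configured time limit are discarded. The trial log is append-only
JSON-lines; each record stores the per-trial seed from which its
hyperparameters can be re-sampled exactly. For tests, a time-injection
hook makes the loss hardware-independent.

## Synthetic data with planted truth

The generator assembles molecules by concatenating valid SMILES building
blocks (alkyl/ether/amine/amide chain tokens plus terminal groups:
carboxylic acid, trifluoromethyl, halogens, nitrile, dimethylamino, ...),
guaranteeing parseable structures. The endpoint is a linear combination of
the counts of seven active level-1 fragments — carbon (+0.10/atom), oxygen
(−0.40), nitrogen (−0.30), fluorine (+0.25), chlorine (+0.20), carbonyl
C=O (−0.35) and the aromatic C:C bond (+0.05) — plus an intercept of
−0.70, optionally squashed by a mild tanh nonlinearity, plus Gaussian noise
(default sd 0.3, the experimental-error scale), clipped to [−2.2, 1.8] to
emulate a realistic LogBB span. The default conditions give a continuous,
mildly right-skewed endpoint spanning the full four log units with about
7% of values at the clip boundaries. Coefficient signs follow the known
structure–permeability trends so that interpretation tests are chemically
meaningful.

What the generator does *not* emulate: real pharmacokinetic mechanisms,
activity cliffs, measurement heteroscedasticity, correlated literature
errors, or the chemical space of marketed CNS drugs. Passing the recovery
tests therefore demonstrates that the pipeline's machinery (enumeration,
selection, training, guarded prediction, interpretation) is correct and
well-calibrated at realistic noise — not that the same accuracy would be
reached on any particular experimental dataset.

## Study conditions of the recovery experiments

The planted-recovery study uses n = 500 compounds at noise sd 0.3 with the
standard featurization (fragments up to 8 atoms, levels 1–3 pooled,
support ≥ 5), 5×4 double CV, and **20 locally selected descriptors** —
roughly three per planted effect. The planted signal is sparse (7 active
fragments), so a compact selected subset is the scientifically appropriate
regime; with hundreds of selected descriptors the selection step itself
starts to overfit its training folds and the cross-validated error degrades
even though the in-sample fit does not, which is the behavior the
hyperparameter search is designed to penalize (its own test demonstrates
that small subsets win on sparse synthetic signals). The irreducible error
floor of the study is the noise sd (0.3); the double-CV RMSEcv lands
modestly above it (the cost of selection and finite training data), and
y-scrambling collapses Q² to ≈ 0, confirming that the headroom above the
floor is signal, not leakage. The y-scrambling control reuses the same
feature matrix and settings with a permuted endpoint.

## Numerical and degenerate-input conventions

Constant scaled columns map to 0; constant endpoints make SS = 0 and raise
an error rather than produce an undefined Q²; a constant prediction vector
yields an undefined Pearson R, reported as NaN with an explicit flag; ties
in every selection method break by ascending canonical key; fold sizes
differ by at most one; the guarded protocol's comparisons are strict
inequalities. All randomness flows from explicit integer seeds through
NumPy Generators; derived per-member and per-trial seeds stay below 2^31.

## Known limitations

* The original fragment-typing software's atom-type table is unpublished;
  the three-level classification here is a documented reconstruction, and
  absolute descriptor counts will differ from that software even where the
  enumeration semantics agree.
* Branch fragments are restricted to single-branching-vertex trees, and
  cycles to induced (chordless) rings; exotic cage hydrocarbons could
  expose differences against a smallest-ring convention.
* The curated 529-compound experimental LogBB dataset and the external
  validation set are distributed as journal supplementary material and are
  not bundled; the headline-statistics check runs only when the user places
  the dataset at `data/bbb_logbb_529.csv` (columns id, smiles, logbb).
* Training is plain NumPy on CPU; it is sized for hundreds of compounds and
  a few hundred descriptors, not for datasets orders of magnitude larger.
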