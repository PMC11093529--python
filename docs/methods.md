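# Methods

## The generative model

`abmix` models a numbered antibody variable region as a fixed-length
categorical vector. After IMGT numbering, every sequence occupies the same
`L` coordinates (canonical positions 1–128 plus a capped set of CDR3
insertion codes), with the gap symbol filling unoccupied positions. A
repertoire is then an `N × L` matrix over a 21-symbol alphabet, and the
model is a finite mixture of product-categorical components:

    p(x) = Σₖ πₖ ∏ᵢ θ[k, i, xᵢ],   Σₖ πₖ = 1,   Σⱼ θ[k, i, j] = 1.

Each component is a position-independent profile; dependence between
positions — the signal that separates species — is carried entirely by the
mixture structure. The model is fully interpretable: any component can be
inspected as a per-position probability table, any scored sequence can be
traced to the component that dominates its likelihood, and generation is
plain ancestral sampling. The gap symbol is a modeled category: indel
structure (e.g. CDR length) is part of what a component describes, and the
BIC parameter count treats it as a free dimension, `p = (K−1) + K·L·20`.

### Fitting

Expectation-maximization on integer-encoded repertoires. The E-step
computes responsibilities in log space with log-sum-exp; the M-step sets
`πₖ ∝ Σₙ rₙₖ` and `θ[k,i,j] ∝ Σₙ rₙₖ·[xₙᵢ = j] + s` with smoothing
pseudocount `s` (default 1e−6). Smoothing keeps every emission strictly
positive so that a single residue never seen in training yields a very low
— rather than infinitely low — sequence score; `s = 0` is allowed and
makes the single-component fit the exact closed-form frequency MLE.

Sufficient statistics are accumulated with unbuffered indexed addition in
row order, so E-step results are bitwise identical for any shard size;
sharding (default 65536 rows) only bounds peak memory.

Convergence: relative log-likelihood change below `tol = 1e-5` or
`max_iter = 300`. The likelihood trajectory is recorded and is
nondecreasing (within 1e−8 relative, the slack covering the tiny M-step
regularization by `s`).

**Initialization.** The default (`init="points"`) seeds each component
from a data row chosen by farthest-point traversal: a random first row,
then repeatedly the row maximizing the minimum Hamming distance to the
seeds already chosen; emissions start at 0.6 on each seed's observed
symbol with the remainder uniform. We also provide `init="random"`
(per-row Dirichlet(1) responsibilities followed by one M-step). The
farthest-point default exists because random-responsibility starts start
every component near the global frequency profile, and greedy EM then
sometimes converges with two components splitting one true cluster while
another cluster goes unmodeled; distance-weighted (k-means++ style)
seeding is not enough here because within-cluster and between-cluster
Hamming distances differ only by a factor of about two for realistic
emission entropies, whereas the max-min traversal picks one row per
distinct cluster essentially always. Three restarts (different seeds, best
final log-likelihood kept) are the default belt-and-braces.

### Model selection and pruning

`grid_select` fits each candidate `K` and keeps the BIC minimizer
(`BIC = p·ln N − 2·log L̂`), ties going to the smallest `K`. After
fitting, components with weight below 1e−12 are removed and the remaining
weights renormalized; the pruning threshold is part of the method, not a
tunable.

### Scoring, masking, classification

Scores are natural-log probabilities, computed with log-sum-exp
throughout; `log 0 = −inf` is propagated, never trapped. A mask is a set
of position labels *excluded* from the product; masking every position
leaves the empty product, which is exactly 1 — the implementation returns
0.0 exactly rather than `log Σπ`, which differs from zero only by the
float error of the simplex. Masked scores are monotone: enlarging the mask
can only remove sub-unity factors, so the score can only rise.

The species classifier applies Bayes' rule across per-species mixtures
sharing one position set, in log space, with user priors (uniform by
default). It resolves species present in its training set sharply but — by
construction — says nothing trustworthy about species it has never seen,
which is why the single-model generative score is the primary humanness
readout and the classifier a secondary mode.

## Numbering

A chain profile is built from a gapped reference alignment over the
canonical positions: per-column log-odds scores
`log((count + 0.1) / (total + 2)) − log(1/20)` against a uniform
background (pseudocount 0.1), all-gap columns dropped. Template-gap
(deletion) penalties are two-tier — high (8.0, log-odds units) at
conserved framework columns (gap fraction < 1%, majority residue > 95%)
and everywhere else in the frameworks, low (0.5) in and adjacent to the
CDRs — and scaled by column occupancy, so skipping a column that most
reference sequences also skip is nearly free. Query-insertion penalties
are low only in slots bordering CDR columns. The net effect is the
intended one: indels are funneled into the CDRs.

Alignment is semi-global dynamic programming (terminal gaps free by
default, configurable), deterministic tie-break match > deletion >
insertion. `X` scores 0 against every column and encodes as gap with a
warning. Chain type is chosen by the highest length-normalized score
across the supplied profiles (ties prefer H > K > L); a best score below a
configurable floor raises "not an antibody variable region".

Path-to-label conversion assigns matched residues their column labels.
Residues inserted within the CDR3 111/112 window are pooled with any
matched insertion-code columns and relabeled by the IMGT convention —
letters ascending from 111 (111A, 111B, …) then descending into 112
(…, 112B, 112A). Insertions elsewhere get ascending letters on the
preceding position (with a warning); the two spots where no monotone
letter scheme exists (before position 1, between 112 and 113) raise an
error rather than emit an ill-ordered label. Conserved-anchor validation
flags missing cysteines at IMGT 23/104 and tryptophan at 41. Terminal
query overhang beyond the profile is trimmed with a warning, so the
numbered sequence always round-trips: residues concatenated in label
order reproduce it exactly.

Region tables: IMGT regions partition 1–128 identically for all chains
(FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65, FR3 66–104, CDR3 105–117,
FR4 118–128); Kabat CDRs are expressed in IMGT coordinates through a
packaged translation table (heavy 36–40 / 55–74 / 107–117; light 24–40 /
56–69 / 105–117) derived from the standard anchor correspondences. The
eight key residues and the Vernier-zone lists ship as editable CSVs
(`abmix/data/`): the literature does not agree on a single canonical set,
so the packaged defaults express the concept — framework positions
adjacent to or structurally supporting the CDR loops, in IMGT coordinates
— and every consumer accepts an override.

## Humanization

`humanize` numbers and encodes the parent, finds its closest cluster
(argmax of per-component log-probability, ties to the lowest index), and
grafts: every position outside the Kabat-defined CDRs and outside the
preserved set takes the cluster's most probable symbol (emission argmax,
ties alphabetical). If the argmax at a framework position is the gap
symbol the parent residue is kept, with a warning — silently deleting
framework residues would be worse than a slightly less probable graft.

Back-mutation is greedy with full rescoring: at each step every remaining
grafted position is trialed with its parent residue restored and the
full-mixture score recomputed; the best-scoring candidate (ties to the
lowest position label) is applied if that score stays at or above the
threshold, and the search stops otherwise — no other candidate can clear
a bound the maximum missed. Rescoring each step, rather than freezing
per-position deltas at the graft, is deliberate: restoring one residue
changes the responsibilities and hence every other candidate's effect.
The trajectory itself does not depend on the threshold, which only decides
where it stops; a looser threshold therefore restores a superset of what a
tighter one restores, giving the monotone preservation ordering
straight graft ≤ 110% ≤ 125% by construction.

Threshold semantics: `threshold = fraction × score(graft)` on the
natural-log scale. Graft scores are negative, so fraction 1.10 tolerates a
10% log-probability decrease; `None` skips back-mutation entirely.

## Synthetic study conditions

The default scenario (`SyntheticScenario()`) is the condition under which
everything is tested: `K_true = 5` components, `L = 50` positions,
`n_train = 20000`, `n_test = 2000` per arm, mixture weights from
Dirichlet(5) (sizable clusters, none near-empty), emission rows from a
symmetric Dirichlet with concentration `1/separation = 0.05`
(near-one-hot, well-separated components standing in for germline-driven
sequence families), divergence 0.3 for the shifted species, no added
substitution noise. The shifted species redraws a random ~30% of each
component's emission rows — a deliberate simplification of cross-species
germline divergence that reproduces the qualitative score separation
between species, not any particular dataset's axis values.

What the generator does **not** emulate: VDJ recombination mechanics,
somatic hypermutation lineage structure, clonal abundance skew, sequencing
error profiles, or the scale (tens of millions of sequences, K in the
thousands) of real repertoire models. Passing tests therefore demonstrate
that the algorithms are correct and well-behaved under controlled truth,
not that any particular accuracy will transfer to a real repertoire.

The toy reference alignments for numbering are built from a per-chain
consensus with the conserved anchors planted (Cys 23/104, Trp 41),
CDR-typical unoccupied positions, seeded substitutions (3% default,
anchors exempt) and up to two CDR-localized indel events per row; the true
labels ride alongside every row.

Scaled problem sizes in the test-suite and acceptance-script runs
(10–20 seeds for recovery, 5–10 for BIC selection, 100–200 humanization
parents, 2000 + 2000 scored test sequences) were chosen as the smallest
sizes at which the measured quantities are stable across seed families.

## Known limitations

* Chain profiles must be built from a reference alignment; the packaged
  toy profiles demonstrate the machinery but are not germline references.
  Numbering real antibodies well requires building profiles from a curated
  germline alignment.
* Insertion codes outside the CDR3 window are labeled on the preceding
  position, which is a convention, not IMGT doctrine; sequences with
  insertions immediately after position 112 are rejected.
* Kappa and lambda chains use separate profiles for numbering but nothing
  prevents (or requires) fitting them jointly in one light-chain mixture.
* The Bayes classifier is only as broad as its model set; sequences from
  species outside it are assigned to whichever known species they least
  disresemble. Use the generative score when provenance is open.
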