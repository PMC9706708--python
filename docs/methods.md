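# Methods

## The question the pipeline answers

Amino-acid recoding replaces the 20 residues by a small number of bin
labels (Dayhoff-6: {AGPST}, {DENQ}, {HKR}, {ILMV}, {FWY}, {C}), masking
substitutions between residues of the same bin.  Whether this "loses
information" or "removes misleading signal" depends on the fit of the
inference model: when the model cannot describe the across-site
compositional heterogeneity of the amino-acid alignment, the masked
within-bin substitutions are precisely the ones that drive long-branch
attraction; when the model already fits, recoding only discards signal.
The package quantifies this trade-off on simulated data: accuracy
(Total Accuracy, TA), model adequacy (posterior-predictive Z-scores of
the per-site state diversity, PPA-Div), saturation, and
parsimony-based information loss.

## Generative model

Sequences evolve under a profile-mixture (CAT-style) model: a site
draws a category `c` with weight `w_c`, a rate `r` from a discrete
Gamma(α) with mean 1, and then evolves by the reversible generator

    Q_c(i,j) = ρ_ij π_c(j),   i ≠ j,

normalized so that −Σ_i π_c(i) Q_c(i,i) = 1 — branch lengths are
expected substitutions per site at each category's own stationary
profile.  Exchangeabilities ρ default to LG; "poisson" (all equal,
F81-type) and free GTR are available.  Gamma rates use the standard
equal-probability discretization with conditional category means
(`G = 4` by default for simulation, exact mean 1 by construction); a
continuous-Gamma flag exists for simulation.

### Site profiles of the default study generator

CAT profiles estimated from real superalignments concentrate their mass
on small clusters of biochemically similar, frequently exchanging amino
acids.  A symmetric Dirichlet draw does not have this property: its
sparse support scatters across Dayhoff bins, which breaks the empirical
association between "frequently exchanging" and "same bin" that
recoding exploits, and with such profiles Dayhoff-6 behaves like a
random recoding.  `default_study_model` therefore draws each profile as
`Dirichlet(20 · p_a(t))`, where `p_a(t)` is the row of the LG
transition matrix from a random seed residue `a` (chosen by LG
frequency) at diffusion time `t = 0.4`: the profile concentrates on the
LG neighborhood of `a`, emulating empirical CAT profiles.  The
diffusion time controls how tightly profiles align with Dayhoff bins —
very small values (≤ 0.25) make profiles nearly bin-pure, an extreme in
which Dayhoff-6 recoding itself *merges* near-convergent residues into
identical states and random schemes look artificially good; very large
values (≥ 0.5) wash out the compositional heterogeneity and with it the
long-branch artifact.  The default sits between those failure modes.
Generator defaults: 32 categories, uniform weights, α = 0.5, LG
exchangeabilities.  The literal symmetric-Dirichlet generator remains
available (`profile_mode="dirichlet"`).

What the generator does **not** emulate: across-lineage compositional
heterogeneity (all taxa share the mixture), indels (missing data only
enters via masking), and the 97-taxon scale of the original simulated
datasets.  Passing tests therefore demonstrate the behavior of
recoding under across-site heterogeneity only.

## Zone trees

`zone_tree` builds 4-, 10- or 20-taxon trees from four clade slots: two
long stems (outgroup-analog `OUT`, ctenophore-analog `CTE`) and two
short stems (sponge-analog `POR`, other-animals `BIL`).
`ctenophora_sister` places both long stems on one side of the internal
branch (Farris zone, attraction helps); `porifera_sister` separates
them (Felsenstein zone, attraction misleads).  Defaults: long 1.2,
short 0.1, internal 0.2, within-clade 0.1 expected substitutions/site
— chosen (and exposed as parameters) so that the Felsenstein-zone
artifact is consistently present for amino-acid data under
low-category mixtures while the recoded data remain recoverable.
Simulation roots at the internal-branch midpoint; under reversibility
the choice is immaterial.

## Recoding schemes and similarity

Built-ins: Dayhoff-6, SR6, KGB6 (packaged data files).  Random schemes
are uniform permutations of the 20 residues into the Dayhoff-6 size
template {5,4,4,3,3,1}.  Similarity between two schemes with equal
bin-size multisets is the size-constrained optimal bin matching: bins
may only pair with equal-size bins, the total intersection cardinality
is maximized (optimal assignment per size class), and the score is
100·matched/20 — always a multiple of 5, 100 iff the partitions are
identical up to relabeling, and 0 is attainable.  Searching for schemes
at a target similarity uses rejection sampling (0% hits occur at rate
~10⁻³ under uniform draws); 90% schemes are rare under uniform
sampling, so a constructive shortcut displaces exactly two residues
between two bins and verifies by re-scoring.

## Likelihood engine

Felsenstein pruning over unique site patterns, summed over categories
and Gamma classes; missing symbols contribute all-ones leaf partials.
Equal-exchangeability categories use the F81 closed form
`P(t) = e^{−t/(1−Σπ²)} I + (1−e^{−t/(1−Σπ²)}) 1πᵀ` in an O(S·k)
numba kernel (the numpy eigendecomposition path covers general ρ and
is cross-checked against the kernel in the tests).  Per-node scaling
guards underflow.

`ml_fit` is coordinate ascent: per-branch bounded 1-D optimization
(bracket [1e-9, 30]), Gamma shape on a log scale in [0.02, 50], GTR
rates by cyclic 1-D updates, and mixture parameters by a
generalized-EM step — the weight update is the exact mixture M-step,
the profile update is a responsibility-weighted state-count heuristic
accepted only if the log-likelihood improves.  Every update is guarded,
so the trajectory is monotone; convergence at Δlog L < 1e-4, with a
`converged=False` flag (not an exception) on round exhaustion.
Mixture profiles initialize from k-means on per-site frequency vectors
(seeded, ties to the lowest category index).  Bootstrap topology
support refits each candidate on site-resampled replicates from a warm
start; ties for the best score split uniformly at random.

## Bayesian sampler

Metropolis-Hastings over an explicit candidate-topology list with
marginalized category allocation.  One cycle sweeps: per-branch
multiplier moves, a Gamma-shape multiplier, a Dirichlet proposal on the
weights, one Dirichlet proposal per profile, a GTR-rates proposal when
applicable, and a uniform topology proposal.  Branch lengths live in a
slot vector shared across candidates — leaf edges map by taxon label,
internal edges by preorder slot — so a topology jump keeps each tip's
fitted length (mapping by node index instead provably freezes the
topology chain).  Priors: Exp(mean 0.1) branch lengths, Exp(mean 1)
shape, flat Dirichlet on all simplex parameters, uniform topologies.
Defaults mirror the study's chain settings (2,000 cycles, burn-in
1,000, subsample 10); the desk-scale experiment uses 250/120/4.
Posterior probabilities are occupancy fractions of the post-burn-in
trace; acceptance rates are recorded per move class, and
`convergence_check` compares two chains (flag at PP difference > 0.1)
with a Geweke-style mean comparison available for traces.

## Posterior-predictive adequacy

PPA-Div = mean number of distinct non-missing states per column;
PPA-Mean = mean over taxa of Σ_states |f_taxon − f_global| (non-missing
cells only).  For each posterior draw, a replicate alignment of the
observed dimensions is simulated under the drawn parameters; observed
missing cells are masked at the same positions in every replicate so
observed and predictive statistics use identical cell sets.
Z = (observed − predictive mean)/predictive SD, signed; interpretation
bands at |z| ≤ 2 (adequate), 3, 5, 10.  Note that with this sign
convention a model that *over*-predicts diversity (the typical misfit
here) yields negative z; all comparative quantities (δPPA-Div, bands)
use |z|.

## Parsimony and saturation

Fitch counts use bit-mask state sets over unique patterns on binary
trees (a basal trifurcation representing an unrooted root is handled
exactly).  The heuristic search is random stepwise addition (insertion
minimizing the Fitch count, ties to the lowest edge index) refined by
first-improvement NNI to a local optimum, keeping a single best tree;
it matches exhaustive topology enumeration on ≤7 taxa in the tests.
Information loss = 100·(L_AA − L_rec)/L_AA.  The per-branch loss map
uses one deterministic minimal reconstruction (parent state when it is
in the Fitch set, otherwise the lowest-index state), whose per-branch
steps sum to the Fitch length.  Saturation: NJ (scikit-bio) on
p-distances with pairwise deletion; M = Σxy/Σx² regressing NJ
tip-to-tip distances (y) on model-tree patristic distances (x) through
the origin, Sat = 1 − M — axes chosen so that saturation compresses
observed distances and Sat ≥ 0.

## Desk-scale experiment design

The directional replication runs 4-taxon zone trees, 10,000 sites, 5-6
replicates per arm, one fixed generating parameterization per
experiment (as in a study that estimates its simulation model once
from real data; 32 profile categories), and the model ladder
nCAT1/nCAT4/nCAT8 (finite F81+G mixtures with empirical-frequency
initialization, inference with G = 2 Gamma classes, chains of 220
cycles).  Pilots located the full-scale study's regimes on this
ladder: nCAT1 and nCAT4 misfit both data types (the artifact persists
on both, as for GTR at full scale), while nCAT8 is still misfit for
the 20-state data but adequate for 6-state recoded data — the nCAT10
situation, where recoding rescues the Felsenstein zone.  The nCAT8 row
supplies the headline TA comparison including the 0%- and
90%-similarity random recodings; each replicate is paired with two
independent scheme draws per random class to average over
scheme-sampling noise.  Quantities reported: per-arm accuracy, TA,
mean PPA-Div Z per (model, data type), δPPA-Div = |Z_AA| − |Z_Rec|,
δTA = TA_Rec − TA_AA, and the OLS of δTA on δPPA-Div.  The
tree-length/saturation comparison runs separately on 20-taxon,
3,000-site fixtures where parsimony and NJ are cheap.

## Known limitations

- Quartet-scale inference: PPA-Div on 4 taxa is a weak statistic
  (column diversity ∈ {1..4}), and a free Gamma shape absorbs part of
  the profile-induced heterogeneity, so desk-scale |Z| magnitudes are
  single-digit, far from the full-scale study's 17-44; only signs,
  orderings and deltas are meaningful here.
- The sampler explores a fixed candidate list, not tree space, and its
  priors are simple defaults; posterior probabilities are comparable
  across conditions, not calibrated against any external sampler.
- The GTR fit uses cyclic 1-D rate updates and is practical only for
  small state spaces or short alignments.
- Random-recoding TA differences (90% vs 0%) are small by construction
  and need the paired design (same alignments across data types) to be
  resolvable at desk replicate counts; at these alignment lengths the
  0%-similarity schemes, which mask the fewest substitutions, can tie
  with or slightly exceed Dayhoff-6 in accuracy.
- The saturation index compares data types only roughly: 6-state and
  20-state alphabets have different observed-distance ceilings, and on
  these simulations Dayhoff-6 recoding does not measurably reduce Sat.
  Likewise the parsimony information loss of Dayhoff-6 here (~20%) is
  a property of this generator, not a universal constant.
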