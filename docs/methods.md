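# Methods

## Scope and model of the problem

`ximine` treats enzyme-family mining as a deterministic pipeline over
protein sequences: screen by length, collapse redundancy by pairwise
identity, keep only sequences whose catalytic machinery is intact in a
reference coordinate frame, place the survivors on a phylogeny, choose
candidates from that phylogeny, diagnose and repair terminal defects, and
resurrect ancestors at internal nodes. The package's contract is that every
stage is a pure function of its inputs and a seed: rerunning a pipeline
reproduces every artifact byte for byte.

## Alignment

Global pairwise alignment is Needleman–Wunsch with affine gaps (Gotoh's
three-state recurrence). The first residue of a gap run costs `gap_open`,
each further residue `gap_extend`; defaults are BLOSUM62 with −11/−1, the
standard protein setting. The ambiguity residue `X` scores 0 against
everything and never counts toward identity. Traceback is fully specified —
ties resolve diagonal > up > left — because downstream coordinate maps,
terminal diagnoses and repair scripts must not depend on incidental DP
ordering. The DP fill is a numba-compiled kernel; the test suite checks the
score against an exhaustive edit-operation recursion on short pairs and
against Biopython's global aligner on longer ones.

Percent identity divides identical non-gap columns by the shorter ungapped
sequence length by default (the convention of identity-threshold clustering
tools); the full-column denominator is available as an option since
published identity tables do not always state their convention.

The multiple alignment is center-star: every sequence is aligned to one
center (the reference, in the pipeline) and the pairwise alignments are
merged under "once a gap, always a gap". This is O(k·n²), deterministic, and
adequate for the small post-dereplication sets the pipeline produces; it is
not a progressive MSA and makes no claim of joint optimality.

## Screening stages

* **Length window.** 370–470 residues (inclusive) family-wide; the
  per-type windows 380–390 and 440–460 and the type boundary (type II
  strictly above 400 residues) are exposed separately. Inclusive bounds are
  a documented choice so boundary behavior is exact.
* **Dereplication.** Greedy incremental clustering: sequences sorted
  longest-first (ties by id), each joining the first representative matched
  at identity ≥ the threshold (default 73%, inclusive), else founding a new
  cluster. Identical residue strings merge unconditionally. This mirrors
  the greedy longest-first strategy of CD-HIT but performs full DP
  alignments instead of word filters — collections at this stage are
  desk-scale, and exactness is worth more than speed.
* **Conserved sites.** The candidate is globally aligned to the reference;
  each site is read through the resulting coordinate map, so terminal
  truncations/extensions that leave site columns aligned do not shift the
  sites. Default profile: the 15 catalytic/pocket residues of PirXI in
  PirXI numbering; default tolerance 0 missed sites (configurable), since
  the biological rationale is that a single lost metal ligand abolishes
  catalysis.

## Phylogenetics

Tree construction is neighbor joining (Saitou–Nei) on p-distances or
Poisson-corrected distances (`d = −ln(1−p)`, `p` capped at 0.95 to keep the
correction finite). NJ is used deliberately instead of a maximum-likelihood
topology search: it is exact on additive matrices (verified on random trees
to 1e−9), fully deterministic with lexicographic tie-breaks, and sufficient
to drive selection, diagnosis and reconstruction; `tree_likelihood` is
available for scoring fixed topologies. Negative NJ branch-length estimates
are clamped to zero without redistribution. Midpoint rooting places the
root halfway along the longest leaf-to-leaf path; when the midpoint falls
exactly on an internal node, that node becomes the root, which makes the
operation idempotent.

The substitution model is reversible, built from symmetric
exchangeabilities and equilibrium frequencies, normalized to one expected
substitution per site per unit branch length. The default is the Poisson
model (uniform exchangeabilities and frequencies) because it admits
closed-form spot checks; an empirical matrix can be loaded from a text file
(frequency line plus square exchangeability table). Transition matrices
come from an eigendecomposition of the symmetrized rate matrix — stable for
reversible models — with rows summing to 1 within 1e−10; tiny negative
entries from round-off are clipped at zero.

Likelihood is Felsenstein pruning with per-node rescaling; gaps and
residues outside the model alphabet are missing data (partial vector of
ones). Under the reversible default the log-likelihood is invariant to
root placement (pulley principle), which the tests check numerically at
1e−8.

Candidate selection mixes two motivations seen in enzyme-mining practice:
`n_near` picks closest (patristic distance) to any verified enzyme — likely
to be active — and `n_spread` greedy max-min picks that maximize coverage of
the tree — likely to be novel. All ties break on leaf labels.

## Ancestral reconstruction

Marginal reconstruction only: per node and site the posterior is
proportional to inside × outside partial likelihoods, computed by one
downward and one upward pruning pass; posteriors are exact under the model
and independent of root placement for reversible models. MAP ties break by
alphabet order. Joint reconstruction is out of scope, matching the common
usage of resurrection studies where per-site posteriors guide synthesis.

"Surviving sites": a site is written into a node's MAP sequence only when
at most half of the node's descendant leaves are gapped there (threshold
configurable); other sites are emitted as gaps. Branch lengths are taken
as given from tree construction and are not re-optimized — a deliberate
scope boundary; with short branches the posterior is dominated by the data,
not the branch lengths.

## Terminal diagnosis and repair

Diagnosis reads the maximal leading/trailing gap runs of the global
alignment candidate-vs-reference: reference residues over candidate gaps
are a deficit (truncation), candidate residues over reference gaps an
overhang (extension). Runs below 5 residues are classified "complete" —
indel noise rather than a terminal defect — because the family's observed
real defects are 11, 22 and 37 residues; the threshold is configurable,
and repair round-trip tests run it at 1 to exercise every size. Plans are
explicit edit scripts (graft, trim, internal motif deletion, point
mutation) validated fail-fast against the current sequence state at every
step, since silent coordinate drift is the classic failure of manual
sequence surgery. The donor fragment for a graft is the donor's first (or
last) `deficit` residues, i.e. the donor is assumed to share the reference
coordinate frame; point-mutation coordinates refer to the post-graft
sequence. Consensus comparison reports candidate positions where a column
of the active-sequence MSA is conserved at ≥ `min_conservation` (default
0.8) and the candidate disagrees.

## Simulator: what it does and does not emulate

The generator produces a family by sampling a tree (pure-birth with
exponential waiting times, or a user-fixed Newick), scaling branch lengths
by `branch_scale` (expected substitutions per site per branch; Yule trees
are rescaled so the *mean* branch length equals it), sampling a root from
the model frequencies with catalytic sites forced to the profile residues,
evolving sites independently down the tree, and finally injecting at most
one anomaly per leaf: N-terminal truncation (size default 15–40, covering
the observed 22 and 37), N-terminal extension (8–15, covering the observed
11), or an internal motif insertion (default "NTSIPFD"). Every event is
logged and replayable; replaying the log on the pre-event sequence must
reproduce the emitted sequence exactly, and the tests enforce this.

Deliberate simplifications: substitution is site-independent with no rate
heterogeneity; no indels occur during descent (indels exist only as leaf
events); at most one event per leaf. These keep likelihood and
reconstruction checks exact and keep the event-log ↔ diagnosis
correspondence unambiguous. Consequently, passing tests demonstrate
correctness of the algorithms under the model, not robustness to real-data
phenomena such as alignment ambiguity in low-complexity regions,
heterotachy, or compositional bias.

Default study conditions used by the tests and the acceptance script:
12–18 leaves, sequence length 200–390 residues, 0.05–0.12 expected
substitutions/site/branch — small enough to run in seconds, large enough
that identity spreads straddle the 73% dereplication threshold and
reconstruction accuracy is a meaningful statistic.

## Fermentation metrics

Pure arithmetic on time series: generations per transfer
`log2(OD_final/OD_initial)` (additive over consecutive transfers);
xylose utilization rate `(c_0h − c_24h)/24` g/liter/h; fractional product
yield `product/(consumed glucose + consumed xylose)/0.51` with 0.51 g/g
the theoretical ethanol yield on sugar; dry cell weight `0.34 × OD600`
g/liter. The biomass denominator of the specific rate is the time-weighted
mean DCW over the window (trapezoidal), with an endpoint-mean option —
the underlying literature formula is not fully specified, so the default
is documented rather than claimed canonical. Rates are reported positive
for consumption.

## Numerical and determinism choices

* Integer substitution scores and gap penalties; DP in int64 with a large
  negative sentinel, so alignment scores are exact.
* Distance, NJ and likelihood computations in float64; additive-recovery
  tolerance 1e−9, likelihood-vs-enumeration tolerance 1e−10, root-invariance
  tolerance 1e−8.
* Every stochastic component draws from one `numpy.random.default_rng`
  seeded from the configuration; all order-dependent choices (cluster
  founding, NJ agglomeration, MAP ties, selection ties) break ties
  lexicographically.
* Newick writing canonicalizes child order by smallest descendant leaf
  label and prints branch lengths with 10 significant digits, so
  read∘write is the identity for the package's own files.

## Known limitations

* No maximum-likelihood or Bayesian topology search; tree quality is bounded
  by the distance estimates.
* Center-star MSA quality degrades for deep divergences; the pipeline
  mitigates this by aligning post-dereplication survivors only.
* The conserved-site filter depends on the pairwise alignment being correct
  around the site columns; extreme divergence can misplace sites.
* Ancestral reconstruction ignores rate variation across sites and
  alignment uncertainty.
* The screening counts of any particular public-database snapshot are not
  reproducible and are not a target of this package.
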