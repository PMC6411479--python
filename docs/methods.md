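# Methods

This note records the models, defaults, and numerical choices behind
egt-screen, and what the synthetic validation does and does not show.

## Profile HMMs

**Architecture.** Plan-style match/insert/delete profile: begin node 0,
match states M₁..M_M, insert states I₀..I_M emitting background
frequencies, delete states D₁..D_M, and an end state.  Allowed moves are
M→{M,I,D}, I→{I,M}, D→{D,M} plus begin/end; there are no I↔D transitions.
With all emission and transition vectors normalized the glocal model is a
proper generative distribution over sequences — which is what makes the
probability-conservation check meaningful (total forward mass over an
exhaustively enumerable sequence space equals 1 within 1e-9).

**Estimation.** Match columns are alignment columns with gap fraction
< 0.5 (configurable).  Match emissions are observed counts plus
background-proportional pseudocounts of total weight 1.0 (Robinson &
Robinson background); X residues are ignored in counts and score zero
log-odds everywhere.  Transitions are counted from each row's state path
through the column classification with Laplace (+1) smoothing over each
state's allowed moves, so no transition is ever exactly zero in an
estimated profile.

**Scoring.** Scores are log₂-odds (bits) against an i.i.d. background null
with no length correction.  Local mode permits entry into and exit from any
match state, both weighted 1/M, with unaligned flanking residues scored by
the null; it is the search default because transcriptome-derived protein
models are frequently fragmentary.  Glocal mode traverses the whole model.
Viterbi runs in log space; forward runs in linear odds space with per-row
rescaling (no per-cell transcendentals), which keeps the two scorers within
1e-9 of the brute-force path enumeration on small instances — the
correctness oracle for both.

**Significance.** Each profile is calibrated by drawing 200 background
decoys (length = the median target-protein length) and fitting a Gumbel
location/scale by maximum likelihood to their local Viterbi scores
(`scipy.stats.gumbel_r.fit`).  E-value = database size × Gumbel tail.  The
accuracy target is modest — a factor of ~2 in the tail is ample against a
10⁻⁵ reporting threshold — and is verified by the uniformity check (count
of E ≤ 100 among 1000 fresh decoys within the central 99% binomial
interval around 100).

**Search shortcuts (exact in effect).** The pipeline's searcher first
computes an ungapped match-only local score — a lower bound on the Viterbi
score — and skips the full dynamic program when that bound sits more than
15 bits below the reporting threshold; indel excursions cannot close a gap
that large.  Family assignment computes forward scores only for the top-3
profiles ranked by Viterbi; inter-family gaps are hundreds of bits, so the
shortlist does not change the assignment or margin in practice.  The public
`search_proteomes`/`assign_family` operations score exhaustively.

## Trees

Pairwise distances use pairwise deletion of gap/X columns and the Kimura
protein correction d = −ln(1 − p − p²/5) by default (p-distance and Poisson
available); pairs at p ≥ 0.85 are capped at distance 10.0 with a warning.
Neighbor joining is the classic Q-criterion algorithm, deterministic with
lowest-index tie-breaking; negative branch lengths are clamped to zero with
the deficit moved to the sibling edge.  Edge confidence is a nonparametric
bootstrap over alignment columns (default 100 replicates; the support of an
edge is the percentage of replicate trees containing its bipartition).
Midpoint rooting places the root halfway along the longest leaf-to-leaf
path; supports are re-attached by bipartition, so re-rooting never changes
the support of a split.  Distance-NJ is a deliberate desk-scale stand-in
for maximum-likelihood inference: the downstream classifier consumes only
topology and supports, and externally computed Newick trees can be
imported in their place.

## Provenance classification

For each query-role leaf of a rooted, support-annotated gene tree, the
maximal clade consisting entirely of query-role leaves is collapsed into a
unit; walking rootward, the first ancestor contributing reference leaves
defines the sister composition.  The call is host_related (algal_related)
when host-outgroup (algal) leaves make up ≥ 80% of those reference leaves
and the joining node's support is strictly greater than 70; otherwise
ambiguous.  The purity tolerance admits a single contaminant leaf in an
otherwise clean sister group; the support is read at the node that joins
the query unit to its sister because that edge carries the claim being
tested.  A node with unknown support (e.g., the root) demotes to ambiguous
— the conservative direction.

**Paralog purge.** Up to three cycles: build a bootstrapped tree, remove
the hit leaves inside maximal clades where more than half of the
family-annotated leaves carry a different best-profile assignment and the
clade support exceeds 70, re-insert survivors via their profile paths,
stop when a cycle removes nothing.  Two details matter in practice:
(1) clades are scanned on the midpoint-rooted tree — on an arbitrarily
rooted NJ tree the complement of the paralog clade can masquerade as a
clade and sweep in adjacent true orthologs; (2) a single intruding leaf is
treated as a trivial clade with support 100 (its leaf-versus-rest split
holds in every replicate by construction) — otherwise singleton paralogs
are unpurgeable.  After purging, a hit is accepted as a true ortholog if
its sister context contains at least one reference leaf, or if its
best-profile assignment matches the family with a margin of ≥ 2 bits.

## Targeting evidence

The signal-peptide heuristic examines the first 40 residues and requires:
(a) nonnegative net charge over residues 1–5 (K/R = +1, D/E = −1);
(b) some 8-residue window within residues 3–20 with mean Kyte–Doolittle
hydropathy ≥ 2.0; and (c) a cleavage motif — for some signal length
ℓ ∈ [14, 34) (0-based mature start), residues ℓ−1 and ℓ−3 are small
(A/G/S/C/T).  The hydropathy threshold of 2.0 was set from the analytic
false-positive estimate: at 1.6 roughly 10% of background-composition
proteins pass all three rules, while hydrophobic cores drawn from
{L,V,A,F,I} average KD ≈ 3.4, so 2.0 cuts the false-positive rate to ~3%
at no sensitivity cost.  All constants are config-exposed, and the
heuristic is explicitly not equivalent to a neural-network predictor —
an import path accepts external predictions (which still respect the
refusal rule below).

SP verdicts are only emitted for proteins with complete N-termini
(upstream ORF-caller metadata when present, otherwise an initial
methionine aligned within 15 columns of the modal reference start);
truncated models get no verdict in either direction, matching the known
failure modes of SP prediction on incomplete protein models.

FG-repeat scanning counts FG dimer starts in the best window of ≤ 200
residues; the flag requires ≥ 5 dimers and density ≥ 1.5 per 100 residues
(values chosen to separate FG-Nup-like clustering from shuffled
composition controls at < 5% flag rate); FXFG and GLFG motifs are counted
separately.

## Inventory

The matrix holds one cell per (registry family, query taxon) with the
retained copies' affinity, SP and N-terminus flags.  Data-set completeness
is proxied by the fraction of control families (those detected in ≥ 80% of
reference taxa) with at least one hit in the taxon.  An absence is
corroborated when every taxon of the role group with completeness ≥ 0.5 —
and at least 3 of them — lacks the family.  The subcomplex summary reports
presence per compartment group: `host` from host-related copies and
`nucleomorph` from algal-related copies, a subcomplex being present when
any of its families has any such copy.

## Synthetic scenarios

The generator emulates the statistical structure the inference assumes,
not sequence biology in detail:

- **Species tree.** Fixed shape (((query₆, host₄), algal₆), other₄) with
  slightly varied pendant lengths, scaled so the deepest pairwise
  divergences stay below the Kimura-correction saturation regime — beyond
  it the corrected-distance variance (∝ 1/(1−p−p²/5)) swamps the 0.2–0.3
  backbone edges and bootstrap supports collapse for short families.
- **Evolution.** Per-branch jump process: each site substitutes once per
  branch with probability 1 − e^(−rate·t) and is replaced by a background
  draw excluding the current residue (optional Gamma site-rate
  multipliers).  This admits a closed-form two-leaf divergence expectation
  used as the model's own statistical test.  The initiator methionine is
  held invariant.  No indels are simulated, so reference alignments are
  exact by construction — alignment inference is not the system under
  test.
- **EGT.** A single transfer: a donor lineage leaves the algal stem at a
  dedicated junction node (placing the donor exactly at the crown would
  create a polytomy that distance methods resolve arbitrarily), and the
  transferred gene then descends vertically along the query subtree —
  one algal-affinity copy per query taxon, with a signal-peptide prefix
  (M + 2 basic + 8–10 hydrophobics from {L,V,A,F,I} + A-x-A) when enabled.
  The SP model and the targeting heuristic are co-designed; SP metrics on
  generator output are internal-consistency checks, not biological claims.
- **Decoys, losses, duplications, truncation.** Decoy paralog families
  branch 0.25 expected substitutions/site off the family root and evolve
  down the same species tree, getting their own reference alignment and
  registry entry — deep enough to be assigned to their own profile,
  shallow enough to intrude into the target family's search at E ≤ 10⁻⁵.
  Losses remove (family, taxon) genes; duplications add a shallowly
  diverged within-taxon copy; truncation removes 10–50% of the N-terminus
  of a configurable fraction of query transcripts and marks them
  incomplete.

Default study conditions: 12 families (lengths drawn uniformly from
200–600 residues), 20 taxa, two EGT families (the Nup98/Rae1 analogs) with
signal peptides, rate 1.0, no losses/duplications/decoys/truncation unless
the scenario asks for them.  The classifier study runs 25 seed-varied
default scenarios plus 5 pure-host control scenarios; purge and targeting
use dedicated decoy and truncation scenarios.  These sizes keep the whole
validation within a few minutes on one CPU while leaving large margins on
the recovery criteria.

## Determinism

Every stochastic stage draws its seed from the master seed and a stage
label via a BLAKE2 hash (`derive_seed`), so toggling one stage never
perturbs another, identical configurations produce byte-identical output
files, and results are independent of thread count (all kernels are
single-threaded).

## Known limitations

- For short families (~200 columns) the bootstrap support of the deepest
  backbone split occasionally dips below the strict > 70 rule, demoting an
  entire family's (correct) host calls to ambiguous in a small fraction of
  seeds.  This is the conservative direction and mirrors the low-support
  ambiguity class real analyses report; it is why recovery criteria are
  stated as ≥ 90% rather than 100%.
- The classifier assumes reference sampling polarizes provenance; with no
  reference leaves in a tree it reports unclassifiable rather than
  guessing.  Long-branch-attraction artifacts are not detected or
  corrected — supports are recorded and interpretation is left to the
  user.
- NJ on corrected distances is not maximum likelihood; for published
  analyses the external-tree import path should carry ML topologies and
  supports into the same classification machinery.
- The generator's no-indel assumption means augmented-alignment handling
  of real indel-rich families is exercised only through the SP-prefix and
  truncation paths (N-terminal inserts and deletes), not internal indels.
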