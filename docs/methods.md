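# Methods

## Model and state space

A secondary structure on a fixed sequence σ (alphabet ACGU, length n ≥ 1)
is a set of base pairs (i, j), 1-based with i < j, such that each position
pairs at most once, pair intervals are nested or disjoint (no pseudoknots),
every pair is canonical (AU/UA, GC/CG, GU/UG) and every hairpin encloses at
least three unpaired bases (j − i ≥ 4).  The move set connects structures
differing by exactly one pair; this neighbourhood is symmetric and connects
all of Ω through the open chain.

Energies are pair-additive with a stacking term.  The built-in `bpstack`
model assigns −3.0 (GC), −2.0 (AU), −1.0 (GU) kcal/mol per pair and
−1.0 kcal/mol per stacked adjacency ((i, j) and (i+1, j−1) both paired).
These constants are this package's design choice — deliberately simple so
that every downstream quantity can be verified by brute force — not
measured thermodynamic parameters.  The open chain has energy 0 exactly.
Temperature defaults to 310.15 K (37 °C), giving kT = R·T ≈ 0.6163 kcal/mol
with R = 1.98717×10⁻³ kcal/(mol·K).

Model energies are stored as integers in units of 10⁻² kcal/mol (inputs
rounded half away from zero), so energy comparisons — and therefore
gradient-walk and flooding tie-breaks — are exact and platform-independent.
Guiding-potential entries are kept as exact rationals
(`fractions.Fraction`): the per-pair update α/|s′| rarely lands on a cent
grid, and exact rationals make the closed-form identity below hold
bit-for-bit while preserving exact comparability.  The two representations
mix losslessly (cents are rationals).

## Soft-constrained thermodynamics

The DP uses three interval tables — all structures on [i, j], structures
with (i, j) paired, and structures without it — so that the stacking term
and the per-pair pseudo-energy E_ij both attach exactly where pair (i, j)
is formed.  That keeps the guiding potential decomposable and the sampler
exact under any E_ij.  MFE folding runs the same recursion in min-plus
form over integer cents; among co-optimal structures the lexicographically
smallest dot-bracket (byte order, so '(' < ')' < '.') is reconstructed by
memoised comparison of optimal substrings, making folds deterministic.
Hard constraints (forbidden pairs) simply remove entries from the pair
tables; the constrained fold that prohibits all MFE pairs yields the second
projection reference.

The partition function is computed in a scaled linear domain: Boltzmann
weights are multiplied by f^(interval length) with
f = exp(β·E_MFE/n), the standard per-nucleotide rescaling, so Z remains
representable for sequences of several hundred nucleotides (log Z is always
finite; Z itself may overflow to inf only in extreme synthetic cases).
Sampling probabilities are ratios in which f cancels.  Stochastic
backtracking precomputes, per DP cell, the cumulative weights of its
decompositions, so each draw is a cheap root-to-leaves descent
(O(n log n)-ish per sample in practice); draws are i.i.d. and reproduce
exactly for a fixed (tables, count, seed).  Uniform sampling runs the same
machinery at β = 0, which makes every structure weight exactly 1.

Exhaustive enumeration recurses on the leftmost position and is guarded by
a structure-count ceiling (default 5×10⁶); with an energy band only
structures within the band above the minimum are returned.  Enumeration is
the oracle substrate: partition sums, exact distributions, gradient basins
and barrier trees on short sequences are all checked against it (the test
suite re-derives these quantities with independent code).

## Gradient walks, basins, barrier trees

A gradient walk repeatedly moves to the strictly lowest-energy neighbour,
breaking energy ties by lexicographically smallest dot-bracket, and stops
when no neighbour is strictly lower; plateaus therefore count as local
minima.  Walk endpoints define the gradient-basin partition of Ω.  Inside
the sampling loop walks always use the unmodified energy E: local minima
are features of the true landscape, the potential only shapes sampling.
One consequence of the tie-break worth knowing: walks can end in shallow
dead ends (e.g. from the open chain of GGGAAACCC the first tie resolves to
pair (1,7), which admits no further additions), which is faithful to the
definition and confirmed by the brute-force oracle.

Barrier trees are built by flooding a complete enumeration in increasing
(energy, dot-bracket) order: a structure with no processed neighbour opens
a basin (leaf); with processed neighbours in one basin it joins it; with
several it is the saddle merging them at its energy (deepest basin kept,
equal energies resolved lexicographically, so the construction is
deterministic).  Coarse graining absorbs any minimum whose barrier
(saddle − own energy) is below a threshold (default 3.0 kcal/mol) into the
deeper neighbour basin; because merges are processed in increasing saddle
order, only single-leaf basins can ever be absorbed, so recorded merges
stay consistent.  Band-limited enumerations produce trees flagged
incomplete (with a warning): saddles above the band are missing by
construction.  Coverage of a found-minima set reports (a) the fraction of
the top-k saddles (default k = 100, ranked by height) whose two deepest
side-minima were both found and (b) the fraction of leaves found.  With no
merges the saddle fraction is vacuously 1.

## The adaptive sampling loop

Parameters (defaults): total samples N = 10⁵, round size g = 100, weight
α = kT, saturation threshold μ = 0.1, master seed.  Per round: recompute
the partition function only if the potential changed (rounds without an
update reuse the cached tables); draw g structures; gradient-walk each to
its minimum and update the cumulative basin map; select this round's
most-sampled minimum (ties to lexicographic smallest); if the cumulative
ratio |M1|/|M>1| of singleton to repeat minima does not exceed μ, apply the
repellent update — add α/|s′| to every pair of s′ and append to the
potential's history.  Open-chain targets are skipped (the penalty is
undefined at |s′| = 0).  Per-round RNG streams are spawned from the master
seed, so runs are exactly reproducible and the potential is reconstructible
by replaying its history.

The gate direction is implemented literally (update only while the ratio
is *small*, i.e. when sampling depth at the current distribution is
saturated by collisions).  Empirically this gate is conservative: once the
accumulated potential flattens the distribution, fresh singleton minima
keep the ratio above μ and updates become rare.  A configuration flag
(`invert_gate`) exposes the opposite convention for experimentation;
nothing in the tests relies on it.  α should stay near kT: much larger
weights make consecutive sampling distributions nearly disjoint.

Attractive guidance is the same machinery with α < 0 applied to
user-chosen reference structures.

## Quality measures

2D projection assigns each structure to the class (d₁, d₂) of base-pair
distances to two references — by default the MFE structure and the most
stable structure sharing none of its pairs (via the constrained fold; an
open-chain MFE has no such pair and raises).  Classes record the minimum
energy, its structure, the Boltzmann mass Σe^(−βE) (so the class free
energy G = −ln(Z_cell)/β) and a count.  Coverage of a sampled grid against
an exhaustive truth grid counts truth classes whose sampled minimum lies
within ϑ of the true class minimum (reporting defaults ϑ = 0 and
5 kcal/mol; denominator = occupied truth classes; a free-energy variant
applies the same margin to G).  Density of states bins unique structures
into half-open energy bins anchored at the minimum (default width
1 kcal/mol).  The weighted mean base-pair distance uses Boltzmann weights
renormalised over the given set and is evaluated through the pair-frequency
identity Σ_(i,j) 2q_ij(1−q_ij), which equals the quadratic double sum
exactly and is linear in input size.

## Synthetic data

`generate_random_sequences` draws i.i.d. uniform ACGU sequences.
`generate_bistable_fixture` emulates the two-state-switch scenario in which
plain Boltzmann sampling fails: layout X A³ M A³ T with arm X = GACA, core
M = UGUC (its reverse complement) and tail T = GAUA (X with its C weakened
to a wobble U).  M pairs upstream with X (the stable helix, −13, −15 with
its AU decoration) or downstream with T (the metastable helix, −11); the
shared core makes the helices mutually exclusive, mixtures would cross, and
the mixed arm locks both registers.  The design was selected, by exhaustive
evaluation of candidate arm/tail/linker layouts under the bpstack model,
to satisfy the properties the fixture exists to provide: the constrained
reference pair recovers exactly the two designed helices; the metastable
basin carries ≈6.5×10⁻⁴ of the Boltzmann mass (exact, from enumeration), so
a plain sample of N = 1000 misses it with probability (1−p)^N ≈ 0.52 while
the adaptive sampler at N = 2000 discovers both states in ≥49/50 seeded
runs under the literal saturation gate.

What the fixtures do *not* emulate: real loop-dependent Turner energetics,
dangles and coaxial stacking, longer-range multiloop architecture, and the
sequence lengths (>100 nt) where sampling methods are actually needed.
Passing tests demonstrate algorithmic correctness (DP vs enumeration,
walks and trees vs oracles, distributional fidelity of the sampler) and
the qualitative metastable-discovery behaviour — not quantitative accuracy
on natural RNAs.

## Numerical and scale choices

Desk-scale problem sizes keep every oracle exact: enumeration fixtures use
n ≤ 18 (|Ω| ≤ ~4000), sampling fidelity uses 10⁵ draws against exact
distributions (TV < 0.01; χ² with expected-count pooling at 5, accepted at
p > 0.001 in ≥9/10 seeds), and the discovery benchmark uses N = 2000 over
10 seeds.  Partition-function accuracy is held to 10⁻⁹ relative against
brute force (measured ~10⁻¹⁴).  Degenerate inputs are defined, not special
cases: the open chain is always a valid structure; sequences with no
canonical pair have |Ω| = 1 and Z = 1; an empty repellent reference is an
error; an all-counts-singleton basin map has saturation ratio +∞, and an
empty one 0.

## Known limitations

The Turner adapter evaluates, folds and samples through ViennaRNA but
cannot feed the in-repo DP (Turner terms are not pair+stack decomposable),
so the adaptive loop itself runs on the built-in model.  Barrier trees
require complete enumeration and are thus limited to short sequences; no
heuristic saddle search is provided.  Exact base-pair probability matrices
(inside–outside) are not computed; empirical pair frequencies from samples
stand in where needed.
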