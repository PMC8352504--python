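# rnaxplore

Adaptive Boltzmann sampling of RNA secondary-structure energy landscapes
with repellent guiding potentials, plus the landscape quality measures
needed to validate samples against brute-force enumeration.

## The problem

An RNA sequence σ of length *n* folds into a conformation space Ω of
pseudoknot-free secondary structures (canonical pairs AU/GC/GU, at least
three unpaired bases per hairpin).  Together with the single base-pair move
set M and an energy function E, the triple (Ω, M, E) is the energy
landscape.  Folding kinetics are governed not by the minimum free energy
(MFE) structure alone but by metastable basins and the saddles between
them — yet plain Boltzmann sampling, drawing s with probability
p(s) = e^(−βE(s))/Z, almost never visits basins whose total mass is small,
no matter how kinetically important they are.

`rnaxplore` implements a metadynamics-style fix.  Sampling proceeds in
rounds of *g* draws from the soft-constrained distribution

    p̂(s) = e^(−β(E(s)+E_Ψ(s))) / Ẑ,   E_Ψ(s) = Σ_(i,j)∈s E_ij .

After each round, every draw is mapped by gradient (steepest-descent) walk
to its local minimum; the round's most-sampled minimum s′ is penalised by
spreading a weight α (default kT) over its base pairs,

    E_ij ← E_ij + α·δ_ij(s′)/|s′| ,

so that E_Ψ accumulates exactly the per-structure penalty
E_c(s′, s) = α·|s ∩ s′|/|s′|.  A saturation gate applies the update only
while the ratio |M1|/|M>1| of once-observed to multiply-observed minima
stays below a threshold μ (default 0.1), which also avoids needless
recomputation of the O(n³) partition function.  Repeated over m = N/g
rounds this pushes probability mass out of already well-explored basins and
surfaces rare, metastable states; the *reported* minima always refer to the
unmodified landscape E.

Everything is verifiable on short sequences: exhaustive enumeration,
gradient-basin partitions, barrier trees by flooding (with 3 kcal/mol
coarse graining and basin/barrier coverage of the 100 highest saddles), 2D
distance-class projections against the MFE and the constrained-MFE
references with coverage margins ϑ ∈ {0, 5} kcal/mol, density of states and
the weighted mean base-pair distance.

The energy backend is pluggable.  The built-in `bpstack` model
(GC −3.0, AU −2.0, GU −1.0, stacked adjacency −1.0 kcal/mol; integer
centi-kcal arithmetic internally) keeps the repository self-contained and
enumerable; an optional adapter (`rnaxplore.turner`) drives the Turner
model through the ViennaRNA bindings, including per-pair soft constraints.

## Worked example

```python
from rnaxplore import *

seq = generate_bistable_fixture()          # GACAAAAUGUCAAAGAUA
model = BpStackModel()

s1, s2 = reference_pair(seq, model)        # MFE + constrained MFE
res = run_xplorer(seq, model, XplorerConfig(N=2000, g=100, seed=1))

enum = enumerate_structures(seq, model)
truth = project(enum, s1, s2, model.beta, source="exhaustive")
items = [(s, structure_energy(model, seq, s)) for s in res.samples.unique()]
cov = class_coverage(project(items, s1, s2, model.beta), truth, theta=0.0)
```

prints (via the obvious `print` statements):

```
sequence    GACAAAAUGUCAAAGAUA
reference 1 ((((...))))(....). -15.00 kcal/mol
reference 2 .......((((...)))) -11.00 kcal/mol
adaptive sampling: 2000 draws, 12 distinct local minima, 1 potential updates
  ((((...)))).(...).  -15.00  x867
  ((((...))))(....).  -15.00  x772
  .(((...))((...))).  -14.00  x249
  (.((...))((...))).  -13.00  x52
distance-class coverage (theta=0): 0.52
```

The fixture is a designed two-state switch: the central tract pairs either
upstream (stable helix, −15 kcal/mol with decorations) or downstream
(metastable helix, −11 kcal/mol).  The metastable basin holds ~7·10⁻⁴ of
the Boltzmann mass, so a plain sample of a thousand structures usually
misses it; the repellent potential finds it reliably at N = 2000 while also
discovering ~40 % more distinct minima than plain sampling.

A command-line interface mirrors the library:

```bash
xplorer gen --bistable -o seq.fa
xplorer sample -i seq.fa -N 2000 -g 100 --seed 1 -o out/
xplorer coverage -i seq.fa -s out/bistable-h4-l3.samples.txt --theta 0 --theta 5 -o out/
xplorer barriers -i seq.fa --minh 3.0 -o out/
```

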