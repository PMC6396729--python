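# Methods

## Models

All four models share the mainland–island structure: discrete
generations, an effectively infinite island population, and one-way
migration replacing a fraction *m* of the island each generation with
mainland individuals.  The pure strains (island: index-1 alleles and the
mt₁ cytotype; mainland: index-2 and mt₂) are equally fit; only mixed
genotypes lose viability, according to the model's fitness table:

* **Model A** (haploid MtNI): hybrids mt₁N₂ and mt₂N₁ have viability
  1−s₁ and 1−s₂.
* **Model B** (haploid NNI): hybrids A₂B₁ and A₁B₂ have viability 1−s_A
  and 1−s_B.
* **Model C** (diploid MtNI): N-locus heterozygotes have viability
  1−h₁s₁ on the mt₁ background and 1−h₂s₂ on mt₂; the mismatched
  homozygotes (mt₁N₂N₂, mt₂N₁N₁) have 1−s₁ and 1−s₂.
* **Model D** (diploid NNI), two variants.  *Asymmetric*: only
  combinations of A₂ with B₁ are deleterious — the A₁A₁ row of the
  fitness table is all 1, A₂A₂B₁B₁ has 1−s_A, and every genotype
  carrying A₂ together with B₁ in heterozygous combination has 1−h_A s_A
  (the classic two-locus Dobzhansky–Muller configuration).  *Symmetric*:
  both double homozygous hybrids (A₁A₁B₂B₂, A₂A₂B₁B₁) have 1−s and every
  genotype heterozygous at either locus has 1−hs.

Fitness is sex-independent everywhere.  The MtNI models are sexed solely
because the cytotype is maternally inherited; the NNI models need no sex
distinction, and the migrant sex ratio m_f (fraction of females) can
only affect the MtNI models.

Assumptions adopted throughout, chosen to keep the genetics canonical:

* free recombination (r = 1/2) between all nuclear loci, including the
  neutral marker — the two-locus Mendelian shares are equiprobable;
* strictly maternal cytotype inheritance, no paternal leakage;
* 1:1 offspring sex ratio, each Mendelian class split equally;
* viability selection on offspring ("adult offspring" counting); a
  fertility reading of the same coefficients is mathematically
  identical here and not separately implemented;
* diploid genotypes are unordered and parental origin is not tracked
  (no imprinting appears in any fitness table).

## Fitness-graph method

Under weak migration, migrants and all their descendants mate only with
residents.  The genetic classes reachable from the migrant genotype(s)
under repeated backcrossing form a directed graph; the edge X→Y carries
the *fitness component* — the Mendelian fraction of Y among X's
backcross offspring times Y's viability.  The reproductive value of a
class (its long-term contribution to the island gene pool at the neutral
marker, residents ≡ 1) satisfies v(X) = Σ_Y w(X→Y) v(Y).  The migrant
average, (1−m_f)v♂ + m_f v♀ for sexed models, equals the gene flow
factor m_e/m in the m → 0 limit.

Implementation choices:

* Nodes are discovered by breadth-first closure over *Mendelian-possible*
  offspring, ignoring the viability weights.  A class that becomes
  unreachable only because a fitness hits zero at a parameter corner
  (e.g. mt₂N₁ females at s₂ = 1) is therefore retained, with a
  well-defined solved value; this does not affect the migrant average.
  The graphs have 8 (A), 4 (B), 10 (C) and 5 (D) classes.  For Model D
  the double homozygous hybrids A₁A₁B₂B₂ and A₂A₂B₁B₁ can never descend
  from the migrant — after the F1, each backcross lineage carries at
  most one migrant allele per locus — which is why fully recessive NNI
  (h = h_A = 0) produces no barrier at all: the only selected genotypes
  never occur in the migrant lineage.  The same argument removes
  A₁A₂B₂B₂ and A₂A₂B₁B₂ from the migrant-reachable set.
* The resident boundary is imposed as v = 1 directly rather than as an
  equation row (avoiding the degenerate 1 = 1·1 row); the remaining
  system is ≤ 10×10 and solved by dense LU factorisation.  Its diagonal
  dominance for coefficients in [0, 1] keeps it nonsingular; a singular
  solve raises `GraphSolveError` carrying the offending parameters.
* The hand-written per-model equation systems are kept in the test suite
  as independent regression oracles, not used by the implementation.

## Closed forms

`closed_form` implements the analytic solutions of the four systems with
no code shared with the graph solver, so each route checks the other:

* Model A: v♂ = 1/(1+s₁); v♀ = (3+2s₁−s₂−2s₁s₂)/(3(1+s₁)(1+s₂)).
* Model B: v_{A₁B₂} = 1/(1+s_B); v_{A₂B₁} = 1/(1+s_A);
  v_{A₂B₂} = (3+s_A+s_B−s_As_B)/(3(1+s_A+s_B+s_As_B)).
* Model C: v♂ = (1−h₁s₁)/(1+h₁s₁);
  v♀ = (1−h₂s₂)(3+s₂+h₁s₁(1−s₂)) / ((1+h₁s₁)(1+s₂)(3+h₂s₂)).
* Model D: asymmetric v = (1−h_As_A)/(1+h_As_A);
  symmetric v = (1−hs)(3−hs)/((1+hs)(3+hs)).

The Model D attributions were fixed by deriving both variants
symbolically from their fitness tables and confirming against the graph
solver on a parameter grid: the asymmetric (Dobzhansky–Muller) table
yields the (1−hs)/(1+hs) form — which also equals the male-migrant value
of the diploid MtNI model, as it must, since a male migrant's lineage
sees exactly the same heterozygote penalties — and the symmetric table
yields the (1−hs)(3−hs)/((1+hs)(3+hs)) form.  Both depend on the
parameters only through the product h·s, and both equal 1 at h = 0:
recessive NNI is no barrier.  At h = s = 1 (dominant lethal F1) both are
0: the migrant lineage is severed in the first generation.

## Forward recursion and the numerical m_e

`recursion` advances the exact joint frequency distribution over
(incompatibility genotype × marker dosage × sex) — at most
2 cytotypes × 3 N-genotypes × 3 marker dosages × 2 sexes = 36 classes —
through migration, random union of gametes, viability selection and
renormalisation.  The sexed pools are tracked separately and each sums
to 1; a migrant stream with female fraction m_f replaces 2·m·m_f of the
female pool and 2·m·(1−m_f) of the male pool (total fraction m).  The
mainland is fixed: pure index-2 genotype, marker allele at frequency q
(Hardy–Weinberg within diploid migrants).

Defaults: p₀ = 0, q = 1, tolerance 10⁻¹⁰, t_max = 10⁶, life-cycle order
migration → mating → selection → census.  The order is not uniquely
determined by the model description; a mating → selection → migration
variant is exposed via `SimConfig(order="mate_first")`, and the m → 0
limit is insensitive to the choice (tested).

The estimator iterates r(t) = (p(t+1)−p(t))/(q−p(t)).  Two regimes
matter:

* When the island's divergence is stable under migration, r(t) contracts
  geometrically onto m_e and iteration stops when the relative change in
  r drops below the tolerance.  With no incompatibility, r(t) = m
  exactly from the first generation.
* When the divergence erodes — e.g. asymmetric MtNI of type I, where N₂
  is neutral on the mt₁ background and slowly swamps the island's
  nuclear locus — r(t) first settles onto a quasi-stationary plateau
  (the barrier as measured while the island is still diverged, the
  quantity the weak-migration theory predicts) and then drifts towards m
  on the O(1/m) swamping timescale.  The estimator reports the plateau,
  detected as the generation at which the ratio increments stop
  contracting while already below 1% of r.  Long-run stability of the
  island polymorphism itself is deliberately out of scope.

A run in which the resident genotype has lost its majority by the stop
generation is flagged `barrier_lost`; such runs are excluded from
validation pass/fail decisions.

At m = 10⁻⁴ the numerical factor agrees with the analytic one to well
under 1% across random parameter draws of all four models (the
`validate` subcommand and the acceptance suite check 20 draws per model);
the residual discrepancy is O(m) and shrinks with the migration rate.

## Problem sizes and validation scale

All analytic computations are ≤ 10×10 linear solves (microseconds).  The
test suite checks graph-vs-closed-form agreement to 10⁻¹² on 1000 random
draws per model, and recursion-vs-analytic agreement to 1% on 20 draws
per model at m = 10⁻⁴ (each run converges in well under a thousand
generations of a ≤ 36-class recursion); the full suite runs in seconds.

## Known limitations

* The reproductive-value route is exact only in the m → 0 limit; at
  finite m the numerical factor carries an O(m) bias (visible in the
  worked example: 0.3334 vs 1/3 at m = 10⁻⁴).
* Two alleles per locus, unlinked loci only, no haplodiploidy, no
  X-linkage, no cytoplasmic symbionts; the marker is strictly neutral
  and unlinked.
* The recursion's DOT-exported graphs label edges with numeric weights
  at the given parameters, not symbolic expressions.
* Stability of the island polymorphism under migration is not analysed;
  heavy-migration runs are only flagged, not characterised.
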