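# Methods

## The distorter model

The population is censused at birth in non-overlapping generations and
partitioned into six classes: uninfected XY males (g1), uninfected YY males
(g3), uninfected XX females (g2), and infected XX / XY / YY females
(g4 / g6 / g8). Infection feminizes, so every carrier is female; an
uninfected XX individual is also female. Class indices 5 and 7 are unused
by construction (no uninfected XY/YY females exist only as labels — an
uninfected XY individual is the male class g1).

Reproduction is panmictic. Sperm pools: P1 (Y) = (g1/2 + g3)/F_M,
P3 (X) = (g1/2)/F_M. Egg pools mix Mendelian segregation with maternal
transmission: an infected mother of genotype g transmits the symbiont to
each egg independently with probability t_g, so e.g. infected XY mothers
contribute (1−t_XY)/2 of their eggs to each uninfected pool and t_XY/2 to
each infected pool. Offspring classes are the products of the normalized
pools (an infected egg yields an infected female whatever the sperm), so
the next generation sums to one without renormalization.

Assumptions: no fecundity or viability differences among classes, no
paternal or horizontal transmission, no drift (the stochastic analogue
lives in `synth`), infinite population. The two scalar parameterizations
are *blocked* (t_X = t_XY = α, t_Y = 0: YY mothers cannot transmit) and
*uniform* (all three = α).

### Numerical choices

* Equilibrium iteration: convergence when the maximum per-class change in
  one generation falls below `tol` (default 1e−12); cap `max_gen` = 1e6.
* Extinction clamp: when the infected frequency drops below 1e−9 the
  infected classes are set to exactly zero (and the state renormalized), so
  a numerically dying infection is never reported as persistence.
* Chromosome frequencies are counted among the sex-chromosome copies of
  individuals (each diploid carries two), not among gametes:
  x = (g1 + 2g2 + 2g4 + g6)/2. Under this copy counting the standard
  XY/XX population has X at 75% and Y at 25%. (The literature sometimes
  prints the same pair with the labels exchanged; the unordered pair is
  what the model pins down, and this package always reports both labels.)
* Dose summary: expected copies contributed by one male plus one female
  drawn from the current class distributions; autosome dose fixed at 4 per
  pair. The standard population gives Y:X:A = 1:3:4. A per-individual
  variant is available behind a flag.
* Invasion threshold: the infected subsystem (g4, g6, g8) linearized at the
  distorter-free equilibrium (sperm pools ½/½, eggs all uninfected X) has
  Jacobian rows (t_X, t_XY/2, 0), (t_X, t_XY, t_Y), (0, t_XY/2, t_Y). The
  threshold is the α where its spectral radius crosses 1, found by
  bisection on [0, 1] (tolerance 1e−9). Uniform mode: radius 2α, threshold
  exactly 1/2. Blocked mode: radius α(1 + 1/√2), threshold 2 − √2 ≈ 0.5858.
* Persistence vs invasion: iterating from low-frequency infected starts
  shows loss below the linear threshold and persistence above it in both
  modes; a bisection utility (`persistence_threshold`) confirms no
  detectable bistability in blocked mode (boundary within 0.01 of 2 − √2).
  Reports of a persistence boundary near α ≈ 0.55 for this model appear to
  reflect a coarser numerical convention; this package reports the linear
  threshold and the iterated boundary separately.
* Singular limit α = 1, uniform mode: every egg is infected, males are no
  longer produced, and the population tends to all-infected females with X
  frozen at 50% of copies among the survivors. X loss and YY fixation are
  the correct description only for threshold < α < 1; the package reports
  the degenerate limit as computed rather than forcing the idealized
  answer.
* Default introduction scenario: the distorter-free equilibrium with a
  fraction ε (default 0.01) of females converted to infected XX — an
  infection arriving in a standard population.

## Y-contig detection

Depth is measured by exact canonical k-mer matching (default k = 21): a
contig's depth in a read set is the mean count of its k-mers in that set,
scaled per million read bases so libraries of different size are
comparable. This is deterministic and alignment-free; externally computed
(e.g. BAM-derived) depth tables can be substituted. CQ = female/male depth;
contigs with male depth under 0.1× the genome-wide male median get an
undefined CQ (ratio blow-up guard) and are excluded from calling.

YGS uses a separate, shorter k (default 15) to keep the single-copy k-mer
sets dense: single-copy = occurring exactly once in the assembly (canonical
counting); matched = present in the female read set with count ≥ 2, which
absorbs isolated sequencing errors; YGS = 100 × unmatched/single-copy.
Candidates require both CQ ≤ 0.35 and YGS ≥ 35 (configurable; these are the
standard permissive thresholds for repeat-rich genomes).

SNP densities count heterozygous biallelic SNVs per kb of unmasked length;
mask intervals are BED-style 0-based half-open, VCF positions 1-based.
Group comparisons report per-group medians and the Mann-Whitney U in both
orientations (U1, U2 and the minimum), since published U values do not
always state the orientation.

## Pedigree inference

Observable layers: Y-marker PCR (amplification ⇒ XY or YY; none ⇒ XX),
infection status (an uninfected female must be XX under the feminization
rule; males are never carriers), and qPCR dose ratio 2^−ΔCt with band cuts
at 0.25 / 0.75 / 1.5 — midpoints around the expected 0 / 0.5 / 1 — values
beyond 1.5 are flagged rather than called.

Inference runs constraint propagation to a fixed point: children are
narrowed to genotypes producible from some pair of parental gametes, and
parents to genotypes compatible with every child given the co-parent's
candidates. An empty candidate set is reported as a Mendelian
inconsistency naming the parent-offspring triangle. Parents still
ambiguous between XY and YY are then scored by a segregation likelihood
over their offspring's marker classes (XX vs Y-bearing), with the
co-parent *profiled out* — the likelihood is maximized over the co-parent's
candidates per mate — so a definite call is made only when no co-parent
configuration could explain the data, and only when the best candidate
beats the runner-up by a Bayes factor ≥ 100 (configurable). The classic
case — 32 of 32 Y-bearing offspring under an XY father — rejects an XY
mother at (3/4)^32, Bayes factor ≈ 10^4. Every call carries a plain-text
derivation trace.

The weighted transmission frequency of a family is
(females/brood size) × (infected/tested females); all-male broods are 0 by
construction and broods with no tested females are undefined. Display
rounding is round-half-to-even to the integer percent (reproducing 62.4 →
62, 24.36 → 24 and 6.25 → 6); exact fractions are kept internally. Group
tests use the tie-corrected Kruskal-Wallis H (chi-square p, k−1 df — the
convention used for small published family sets) and Dunn pairwise z tests
(tie-corrected pooled variance, unadjusted two-sided p by default,
Bonferroni optional, since published analyses rarely state an adjustment).

## Synthetic data: what it emulates, what it does not

* `simulate_population`: multinomial sampling of N offspring per generation
  from the recursion's class probabilities — drift, but no selection or
  mating structure. The correct noise scale for a generation-by-generation
  comparison with the recursion is the binomial SE of a *one-step*
  prediction (sampled generation t+1 vs the deterministic update of the
  sampled generation t). Deviations from the full deterministic trajectory
  also contain early-transient fluctuations amplified by the invasion
  dynamics and are not binomially scaled; the test suite therefore asserts
  the one-step condition (3 SE per comparison with the standard ≤1%
  multiplicity allowance across ~300 comparisons).
* `synth_genome_and_reads`: autosomes ×2, X, and a Y that is an identical X
  homolog plus novel Y-specific contigs totaling `y_specific_fraction`
  (default 0.1%) of the assembly — a young, undifferentiated sex-chromosome
  pair. Novel (not diverged-copy) Y sequence keeps k-mer uniqueness
  unambiguous. Reads are uniform, fixed-length, substitution-only
  (default error 0.001), with overhanging starts clipped so contig termini
  are covered; no indels, no coverage or GC bias, no paired-end structure.
  Default assembly 2 Mb; tests use 60–300 kb so the full scan runs in
  seconds to tens of seconds.
* `synth_pedigree`: Mendelian segregation, maternal infection with
  genotype-dependent rates, feminization, negative-binomial brood sizes
  (mean 40, dispersion 12, loosely matching observed broods of 13–68),
  partial testing and Gaussian qPCR noise (σ = 0.05). No death,
  no mis-scored PCR, no paternity errors — so inference soundness results
  bound logical errors, not robustness to typing error.
* `synth_snp_table`: Poisson SNP counts at group-specific rates, placed
  outside mask intervals.

Passing tests on these generators demonstrate correctness of the
algorithms against planted truth under idealized noise; they do not certify
performance on real libraries with alignment artefacts, repeat-induced
multi-mapping or hemizygous regions.

## Known limitations

* The dynamics module is deterministic and haploid-locus-free: no
  autosomal suppressors, no fecundity costs, no ZZ/ZW variant.
* Kruskal-Wallis p-values use the chi-square approximation; for the 20- and
  16-family tables this matches the published convention but is approximate
  at such sizes.
* The 20-family statistics recomputed from the printed family table give
  H = 9.76 (transmission) and H = 0.34 (brood size); published values for
  these two analyses (8.84 and 0.18) could not be reproduced from the
  printed per-family numbers under any rank/tie convention we tried,
  whereas the 16-family transmission statistic (7.91) and the full Dunn
  significance pattern reproduce exactly. The recomputed values are the
  ones this package stands behind.
* The exact-enumeration Mann-Whitney p is used only when the assignment
  count is small (≤ 20,000); larger samples use the tie-corrected normal
  approximation with continuity correction.
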