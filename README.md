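# wolbsex

Tools for studying how host sex chromosomes control the spread of
**feminizing *Wolbachia*** endosymbionts in species with XY/XX sex
determination, modelled on the terrestrial isopod *Armadillidium nasatum*.
Feminizing symbionts convert genetic males into phenotypic females and are
inherited maternally; in an XY/XX host their spread is expected to eliminate
the X chromosome and fix the (often inviable) YY genotype — unless something
interrupts transmission. This package implements the computational core of
that question for population geneticists and symbiosis researchers:

* **`wolbsex.dynamics`** — a deterministic recursion over six genotype
  classes (XY and YY males; uninfected XX females; infected XX, XY and YY
  females). An infected mother of genotype *g* transmits the symbiont to
  each offspring with probability *t_g*; carriers develop as females.
  Gamete pools are formed from the genotype frequencies, e.g. sperm
  P(Y) = (G_XY/2 + G_YY)/F_M, and offspring classes are products of the
  normalized sperm and egg pools. The module solves equilibria, sweeps the
  scalar rate α (blocked mode: t_X = t_XY = α, t_Y = 0; uniform mode:
  all three = α), computes invasion thresholds from the leading eigenvalue
  of the infected-class linearization, and summarizes X/Y/autosome dose
  ratios per mating pair.
* **`wolbsex.sexlink`** — detection of Y-specific contigs in a male genome
  assembly from male/female sequencing data: the chromosome quotient
  CQ = female/male normalized depth (≈0 Y-specific, ≈1 autosomal, ≈2
  X-specific) and the Y-genome-scan score YGS = % of a contig's single-copy
  k-mers absent from female reads (≈100 for Y-specific sequence), with
  candidate calling at CQ ≤ 0.35 and YGS ≥ 35%, plus per-contig
  heterozygous-SNP densities and Mann-Whitney group comparisons.
* **`wolbsex.pedigree`** — XX/XY/YY genotype inference over pedigrees from
  Y-marker PCR, qPCR dose ratios (2^−ΔCt ≈ 0 / 0.5 / 1) and Mendelian
  constraint propagation with a Bayes-factor-gated segregation likelihood;
  and the weighted per-family transmission frequency
  (females/brood) × (infected/tested females) with Kruskal-Wallis/Dunn
  group tests.
* **`wolbsex.rank_stats`** — the tie-corrected Kruskal-Wallis H, Dunn
  pairwise z and Mann-Whitney U tests used above.
* **`wolbsex.synth`** — seeded generators with ground truth for every input:
  an individual-based multinomial population simulator, synthetic XY-male
  genomes with a planted Y-specific region plus read sets, pedigrees, and
  SNP tables.

A 20-family summary table and a three-generation pedigree are packaged as
fixtures, so all in-literature analyses run without downloads.

## Worked example

```sh
python examples/distorter_dynamics.py
```

```
alpha=0.4 blocked: X=0.750 Y=0.250 distorter=0.000 lost=True
blocked sweep:   min X frequency      = 0.1250  (never below 1/8)
blocked sweep:   max distorter freq   = 0.5000  (never above 1/2)
blocked sweep:   female freq range    = [0.5000, 0.5000]  (sex ratio stays balanced)
uniform  invasion threshold alpha* = 0.500000
blocked  invasion threshold alpha* = 0.585786
```

Below the invasion threshold the distorter is lost and the standard
population returns (X at 75% of sex-chromosome copies, Y at 25%). When YY
females block transmission, the X chromosome can never fall below 12.5% of
copies, the distorter never exceeds half the population, and the population
sex ratio stays balanced — in sharp contrast with uniform transmission,
where any α > 1/2 drives the X toward loss and biases the sex ratio toward
females. The other example scripts exercise the contig scan
(`scan_for_y_contigs.py`), pedigree inference (`pedigree_genotypes.py`), the
family statistics (`transmission_statistics.py`) and the stochastic oracle
(`stochastic_oracle.py`).

A thin CLI mirrors the library:
`wolbsex sweep --mode blocked`, `wolbsex threshold --mode uniform`,
`wolbsex scan --contigs … --male-reads … --female-reads …`,
`wolbsex pedigree-infer`, `wolbsex transmit-stats --min-tested 10`,
`wolbsex rank {kw,dunn,mwu}` and `wolbsex synth {population,genome,pedigree,snps}`.

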