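# Methods

## Data model and haplodiploid conventions

Microsatellite calls are stored per sample × locus as tuples of positive
integer allele codes: two for diploid females, one for haploid males, with
missing data an explicit null (never a zero code). Allele identity is the
integer code at face value — the package targets trinucleotide panels
where stutter does not merge neighbouring alleles, so no binning is
applied. Any missing call removes that sample at that locus only
(pairwise-available analysis), matching the default behaviour of the
standard tools in this field.

The sex of a sample decides which statistics it can enter:

* **Heterozygote-based statistics** — H_O, F_IS, F_ST, and the
  Hardy–Weinberg deficit test — use **females only**. A haploid male has
  no heterozygosity and would bias these estimators.
* **Allele-frequency statistics** — allele counts, Nei gene diversity,
  rarefied allelic richness, and the shared/private inventories — count
  **every gene copy**: two per female, one per male.

GenePop has no haploid encoding, so males are written as
duplicated-allele homozygotes and their sex travels in a metadata sidecar
(`<file>.meta.tsv`); on reading, a male's duplicated (or single-width)
token collapses back to one stored copy, and a male coded as a
heterozygote is a hard error. Alignment coordinates are 0-based
internally and 1-based in anything user-facing.

## Diversity and differentiation statistics

* **Expected heterozygosity / gene diversity** use the small-sample
  unbiased form (N/(N−1))(1 − Σpᵢ²) over the relevant gene copies (2n
  female copies for H_E; all copies for gene diversity). The choice of
  the unbiased form is a convention; at the sample sizes typical of this
  design the correction is a few percent.
* **Allelic richness** is the hypergeometric rarefaction estimator
  R_g = Σₐ [1 − C(N−Nₐ, g)/C(N, g)], the expected number of distinct
  alleles among g gene copies drawn without replacement. When units are
  compared, g defaults to the smallest per-unit gene-copy count.
* **F-statistics** are Weir & Cockerham's variance-component estimators.
  Per locus and per allele the among-population (a), among-individual
  (b) and within-individual (c) components are computed from sample
  sizes, allele frequencies and heterozygote frequencies; estimates are
  ratios of components summed over alleles and loci
  (f = 1 − Σc/Σ(b+c), θ = Σa/Σ(a+b+c)), never means of per-locus ratios.
  With a single population the among-population terms vanish and only f
  is defined; a single diploid individual leaves f undefined (reported as
  null, not zero).
* **Hardy–Weinberg deficit test**: a one-sided Monte-Carlo test whose
  statistic is the population's single-locus f; the null is generated by
  shuffling the population's female gene copies into random diploids,
  with p = (1 + #{f_null ≥ f_obs})/(n_perm + 1). This is a permutation
  analogue of the exact tests used by the standard tools — simpler, seed-
  controlled, and asymptotically calibrated. Because f at fixed allele
  frequencies is a monotone function of the heterozygote count, the null
  statistic is discrete; with small samples the +1-smoothed test is
  conservative. Calibration checks therefore use fixtures large enough
  (≈150 diploids, ≈8 alleles) for the null to be near-continuous, where
  the measured type-I error at nominal 0.05 is ≈0.05. Monomorphic loci
  return p = 1 by convention.
* **mtDNA summaries**: haplotypes are exact string-equality classes of
  the aligned sequences. Segregating sites count positions with ≥2
  distinct unambiguous bases. Haplotype diversity is
  (n/(n−1))(1 − Σpᵢ²) over haplotype frequencies. Nucleotide diversity is
  the mean pairwise proportion of differing sites with pairwise deletion:
  a site enters a pair's comparison only when both members carry an
  unambiguous base (A/C/G/T), mirroring the exclusion of undetermined
  nucleotides in chromatogram-derived data.

## The divergence-time estimator

The model treats each locus as a Bernoulli trial along a single line of
descent: with per-locus per-generation mutation rate μ, a locus escapes
mutation over t generations with probability (1−μ)ᵗ, so

P = 1 − (1−μ)ᵗ and t̂ = ln(1−P)/ln(1−μ).

The exact compound form is the default; the small-μ exponential
approximation t ≈ −ln(1−P)/μ is available behind a flag and agrees to
first order in μ. (A linearised reading of the accumulation model,
1−P = 1−μt, would give t = P/μ ≈ 4.6 × 10² at P = 0.455, μ = 10⁻³; only
the compound form reproduces the 6.1 × 10² / 6.1 × 10⁴ envelope, and it
is the mathematically coherent survival form.) Implementation uses
`expm1`/`log1p` to avoid cancellation; beyond P ≈ 1 − 10⁻⁶ the inversion
is numerically meaningless in double precision and the round-trip
property is only asserted below that saturation.

Because literature microsatellite rates span orders of magnitude,
estimates are reported as an envelope over a μ bracket (default
10⁻⁵…10⁻³); higher μ explains the same P in fewer generations, so the
envelope is (t̂(μ_high), t̂(μ_low)). Display rounding is two significant
figures in scientific notation. Years are generations divided by a
generations-per-year rate (default 6, a multivoltine wasp in a temperate
climate). Uncertainty on P = k/n is the Clopper–Pearson binomial
interval, mapped through the inversion; k = n maps to an unbounded upper
time, flagged as infinite.

**Known bias.** P is measured as the proportion of loci where the focal
group shows a private allele. Under stepwise mutation a ±1 step can
re-create an allele present in the other group (homoplasy), and drift can
lose the mutant again, so observable-P underestimates mutational-P and t̂
from observable data is biased low. The simulator quantifies this
(see below); the package exposes both definitions rather than hiding the
assumption.

## Shared/private allele accounting

An allele is shared iff present (≥1 gene copy — no frequency floor) in
both groups at a locus; otherwise private to the group carrying it. Two
bases are kept distinct because they answer different questions:

* **amplified** — all loci with data in both groups (flag-switchable to
  either-group amplification); locus-level proportions on this basis feed
  the dating model.
* **analyzed** — a designated analysis panel (by default the polymorphic
  amplified loci); allele-class fractions (shared / private-A /
  private-B, each as a fraction of the locus's distinct alleles) are
  averaged over this panel as an unweighted per-locus mean, which is the
  natural reading of "average over loci" (pooled-count averaging is easy
  to compute from the same classification if wanted).

## The forward simulator

One generation of a deme of `n_broods` host patches:

1. each patch's foundresses (up to `foundresses_per_brood`, chosen from
   the females that settled there; an empty patch is reseeded from the
   deme pool and the event logged) produce `brood_size` offspring,
   mothers drawn uniformly per offspring;
2. an offspring is female with probability `offspring_sex_ratio`
   (fertilised egg: one maternal allele at random plus the stored sperm
   allele per locus) and male otherwise (haploid, maternal allele only);
3. microsatellites mutate per gene copy per transmission at rate `mu_ms`
   by ±1 repeat (equal probability); mtDNA is copied from the mother and
   mutates per sequence per transmission at rate `mu_mt` at a uniform
   random site;
4. daughters mate within the natal patch; with probability
   `sib_mating_preference` a daughter mates a full brother when one is
   available, otherwise any male of the patch (kin aggregation at the
   emergence site — the driver of the strong heterozygote deficit);
   daughters in patches without males remain unmated and are dropped;
   a deme-wide random-mating mode exists for calibration work;
5. a `disperser_fraction` of mated daughters moves to a random other
   patch; the rest stay home.

A `brood_failure_rate` can remove whole patches per generation
(host-finding failure) with recolonisation from the pool; it is off by
default — at the deliberately small deme sizes used here it collapses
nuclear diversity — but is the knob for studying patch-turnover regimes.

The invasive deme is founded at generation `t_burnin` by `n_founders`
mated females copied from the native deme (default 1: a single inseminated
foundress, the canonical invasion scenario); both demes then evolve
`t_split` further generations. Sampling takes at most one individual per
patch (mirroring one-individual-per-trap field sampling), by default 10
invasive and 32 native females (the study design sampled the native
region roughly three times as deeply).

**Ground truth.** Every gene copy carries a flag recording whether any
post-founding mutation occurred on its ancestral copy lineage. The truth
statistic `mutated_loci` reads the flag on a single reference copy (the
maternal copy of the first final-generation invasive female). That
lineage spans exactly `t_split` transmissions, so the indicator is
Bernoulli(1 − (1−μ)ᵗ) per locus — the estimator's idealised P, realised
mechanically inside the simulation. Pooling flags across all sampled
copies would instead count μ × (total genealogy length) opportunities and
would not correspond to any quantity the estimator models. The
observable counterpart is computed from the sampled datasets exactly as a
field study would: the fraction of loci where the invasive sample carries
an allele absent from the native sample.

### Demographic defaults and what they emulate

The demographic parameters are not field estimates; they were chosen to
make the default simulation reproduce the study system's statistical
fingerprint at desk scale, and then frozen:

| parameter | default | role |
|---|---|---|
| `n_broods` (invasive) | 20 | matriline count; mtDNA sorting speed |
| `n_broods_native` | 40 | native allele retention and richness |
| `foundresses_per_brood` | 4 | nuclear Ne at fixed matriline count |
| `brood_size` | 20 | offspring per patch |
| `offspring_sex_ratio` | 0.8 | female-biased, as in gregarious parasitoids |
| `disperser_fraction` | 0.06 | patch takeover / lineage mixing |
| `sib_mating_preference` | 0.9 | inbreeding level (F_IS) |
| `t_burnin` | 100 | native standing variation at founding |
| `mu_ms` | 10⁻³ | upper literature microsatellite rate |
| `mu_mt` | 7.4 × 10⁻⁵ | COI rate estimated in a related parasitoid |
| `mt_length` | 532 bp | analysed COI fragment length |
| `n_loci` | 53 | analysis panel size |

Under these defaults (measured over fresh-seed replicate panels):
sampled native F_IS ≈ 0.55–0.75; invasive/native mean gene-diversity
ratio ≈ 0.69 ± 0.08; a single invasive mtDNA haplotype in ≈ 95 % of
replicates (mean sampled mitochondrial mutations ≈ 0.03–0.06, consistent
with the single-matriline expectation t·μ_mt ≈ 0.044); idealised P within
binomial noise of 1 − (1−μ)ᵗ; observable P below idealised P in ~90 % of
replicates. Three structural choices matter and were found, not assumed:

* **A native deme larger than the invasive one** (40 vs 20 patches, and
  deeper sampling). With a native deme as small as the invasive one,
  native allele turnover over 600 generations deletes ancestral alleles
  that the invasive deme still carries, manufacturing false "invasive
  private" alleles and reversing the homoplasy bias. The native region
  in the motivating system is an established multi-island area; holding
  more of the regional allele pool is the faithful scaled-down rendering.
* **Several co-foundress sisters per patch** decouple nuclear diversity
  from mtDNA monomorphism: sisters share a matriline (so the
  mitochondrial effective size stays ≈ patch count) while their
  offspring and sperm lineages keep the nuclear effective size several
  times higher.
* **Sib-mating preference** decouples F_IS from dispersal: dispersal can
  then be high enough for patch takeover to sort matrilines quickly
  (the founder-event mitochondrial sweep) without eroding the
  heterozygote deficit.

### What the simulator does not emulate

Real microsatellite mutation is length- and locus-heterogeneous; the
simulator uses one symmetric single-step rate for all loci. The native
"region" is one deme, not three island populations (no within-native
structure, no F_CT hierarchy). mtDNA has no transition bias or rate
variation among sites. Genotyping error, allelic dropout and null alleles
do not exist. Passing the validation suite therefore shows that the
estimator behaves as analysed *under the model's own assumptions plus
stepwise homoplasy and realistic inbreeding demography* — not that real
data meet those assumptions.

## Numerical and reproducibility conventions

* All randomness flows from `numpy.random.default_rng`; replicate seeds
  derive deterministically from a base seed via `SeedSequence` and stay
  below 2³¹. Same config + seed ⇒ bit-identical results.
* Undefined statistics raise (library) or render as nulls (reports);
  they are never silently zero.
* Allelic richness uses exact integer binomial coefficients
  (`math.comb`), not lognormal approximations.
* The permutation test adds-one to numerator and denominator; ties count
  toward the tail (conservative).
* Reported problem sizes for the validation suite — 50 replicates,
  100 loci, a 600-generation split, demes of 20/40 patches — were chosen
  as the package's standard desk-scale validation conditions; the same
  machinery runs at any scale through `SimConfig`.

## Known limitations

* The dating model ignores lineage structure entirely: it is a
  single-lineage survival argument, and its idealised P is only
  realisable in simulation. On observable data it inherits the
  homoplasy/drift downward bias quantified here, plus any ascertainment
  in the locus panel.
* The Weir–Cockerham machinery assumes diploid females; the package
  enforces that by construction rather than offering haploid-inclusive
  F-statistics.
* GenePop digit-width inference requires consistent token widths within
  a file; mixed-width files are rejected rather than guessed at.
* The simulator's brood scheduling is synchronous (non-overlapping
  generations) and patch count is fixed; demographic growth of the
  invasive region beyond patch saturation is not modelled.
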