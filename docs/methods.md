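# Methods

This note documents the statistical and computational choices behind
`scatdiet`: what each stage assumes, which knobs matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## The data model

The central object is the MOTU table: one row per dereplicated unique
sequence (MOTU), one integer read-count column per PCR. Each scat sample is
amplified in three PCR replicates named `<sample>.R1/.R2/.R3`; the
sample/replicate index is derived from the column names. Sample metadata
(site, season, coordinates, field species guess) and the reference database
(FASTA, `>taxon_name|rank` headers, strict A/C/G/T) travel alongside. All
I/O is plain text (TSV/FASTA).

## Curation cascade

Stages run in a fixed order; every stage only removes rows, zeroes cells or
merges rows, so MOTU and read totals are non-increasing (merging conserves
reads exactly), which the per-stage attrition log makes auditable.

- **Singletons** are sequences whose *dataset-wide* total is one read —
  not sequences confined to one PCR. A sequence with one read in each of
  two PCRs is kept.
- **Length bounds** 60 and 130 bp are inclusive: the filter removes
  strictly shorter or longer sequences.
- **Minimum evidence**: a MOTU must reach 10 reads in at least one PCR;
  the criterion is the per-MOTU maximum over PCRs, evaluated on the
  dataset-wide table.
- **Annotation** uses global (end-to-end) alignment with unit
  mismatch/indel costs; identity = matches / alignment columns, i.e.
  100·(1 − d/L) for edit distance d over L columns (alignment via `edlib`;
  among co-optimal alignments the reported path's column count is used,
  the standard aligner-dependent convention). Hits below 95 % are dropped.
  Ties at equal identity resolve to the shared genus when all tied
  references belong to one genus; cross-genus ties are dropped as
  ambiguous. Reference sequences with ambiguity codes are rejected at load:
  degenerate-base handling applies to MOTUs only, which keeps the identity
  computation unambiguous.
- **Tag jumps** (reads mis-assigned across PCRs during multiplexed
  sequencing) appear as trace counts of a sequence outside its true PCRs.
  The cure is the conventional per-sequence relative-abundance cut: any
  per-PCR count below `tagjump_fraction` of the sequence's dataset-wide
  total is zeroed. The default is 1e-4. The threshold must separate two
  scale-free quantities: the expected share of a jumped trace (jump rate /
  number of PCRs, ~1e-6 at realistic rates) and the smallest genuine
  per-PCR share (~1/n_PCR ≈ 5e-4 for a taxon present throughout a
  2000-PCR dataset). A cut at 1e-3 sits *above* the genuine-share floor of
  large surveys and measurably erases true host counts, so the default is
  one order of magnitude below the floor and three above the trace level.
  The fraction is an explicit parameter because the right value depends on
  the survey's jump rate and size.
- **Merging** combines MOTUs assigned to the same taxon (per-PCR sums). A
  genus-level annotation folds into its species when exactly one species of
  that genus is in the table; with zero or several species it stays at
  genus. The representative sequence is the highest-read member.

## Host assignment and diet detection

The voting rule compares read counts *among configured host taxa only* —
an abundant prey cannot outvote a host. A vote requires a strict maximum
(ties abstain) that also holds ≥ 1 % of the replicate's total reads;
assignment requires two votes, so a sample with a single informative
replicate is always unassigned. Abstention (UNASSIGNED) is the designed
response to weak or failed samples; accordingly the package reports
host-assignment *accuracy over assigned samples* and the *assignment rate*
separately, the usual decomposition for an abstaining classifier.

Diet detection averages a taxon's relative read frequency across
replicates and detects at ≥ 1 % (threshold configurable). Two documented
switches cover readings the detection rule leaves open:

- **Denominator**: per-PCR shares are computed against all reads of the
  PCR (host included; default) or against non-host reads only
  (`denominator="diet"`). %FO is insensitive to this choice in practice
  because host and diet reads rescale all taxa equally within a PCR; RRA
  is not, so both modes are exposed.
- **Failed PCRs** (zero total reads) are excluded from the average rather
  than contributing zeros: a failed amplification is missing data, not
  evidence of absence.

%FO and RRA are rounded half-up to two decimals for reporting; all
internal computation is unrounded.

## Occurrence models

The three main models are aggregated binomials (k of n per site × season
cell) with logit link: dog occurrence over season, vole occurrence over
season, and dog occurrence over vole %FO (season and vole %FO are collinear
by construction, hence separate models). Fitting is IRLS via
`statsmodels` GLM (deviance tolerance 1e-10, ≤ 100 iterations), standard
errors from the observed information, and response-scale 95 % intervals by
back-transforming logit-scale Wald intervals — profile likelihood is not
implemented. The vole covariate enters internally as a proportion in [0,1]
for coefficient-scale stability and is reported as a percentage. Possible
complete separation is flagged (|β| > 15 or SE > 10³) with a warning rather
than an error. A sample-level random-intercept (GLMM) variant is out of
scope; site cells are treated as independent after the spatial check below.

**Residual diagnostics** simulate `n_sim` (default 250, minimum 20)
datasets from the fitted model and compute per-observation randomized
quantile residuals — the rank of the observed count among simulated ones
with uniform jitter across ties — which are U(0,1) under a correctly
specified model. Reported: a Kolmogorov–Smirnov uniformity p, the
dispersion ratio var(observed Pearson residuals)/mean var(simulated), and
the count of observations outside the simulated envelope. Residuals of the
very data the model was fitted to are slightly conservative (the fit has
adapted to them); passing fresh counts via `observed=` gives exactly
calibrated residuals, which is how the calibration tests are run.

**Spatial autocorrelation** uses Moran's I with inverse-Euclidean-distance
weights, zero diagonal, row-standardized (the test names no canonical
weights; inverse distance is the common default). Expected value
−1/(m−1); two-sided p from the normal approximation. Duplicate locations
are collapsed by averaging their residuals.

## Artifact diagnostics

Sequence "differences" are generalized Levenshtein distances (unit costs),
summarised over all host × target MOTU pairs. Read-structure plots use
log₁₀(count + 1) throughout. The upper-quantile regression minimizes the
pinball loss Σ ρ_τ(y − a − bx) exactly via its linear-programming
formulation (HiGHS); τ defaults to 0.90. The "nonzero component" defaults
to target-positive PCRs (host may be zero, matching the inclusion of the
target-only quadrant); `nonzero="both"` restricts to doubly positive pairs.

## Energetics

Combustion replicates are accepted when 100·sd/mean < 1.5 (strict). Energy
conversion uses the thermochemical calorie (4.184 kJ/kcal) by default with
the international-table constant (4.1868) selectable; published kcal
figures derive from per-dog conversion-then-averaging, so cross-checks use
0.5–1.5 % relative tolerance rather than exact equality. Wet-basis values
apply the *study-average* water fraction uniformly (as bench practice
back-transforms), not per-dog fractions. Mineral fractions are
residue/dry-mass and residue/wet-mass; when the residue column is missing
the profile marks mineral fields unavailable. Budget arithmetic uses an
adult fox's 400–800 kcal/day bracket, 20 g rodents at 137–170 kcal/100 g;
the faeces requirement rounds to the nearest hundred grams and the rodent
count to the nearest ten by default (rounding modes are explicit
parameters; unrounded quotients are available).

## Synthetic generator

The generator emulates the survey design the analysis assumes: scats from
`n_sites` sites (default 5) across four seasonal windows (default labels
winter2018…spring2019), ~34 scats per cell (≈ 680 samples, the order of
the emulated survey), each amplified in triplicate.

- **Occurrence truth.** Vole availability per site × season is
  logit⁻¹(season intercept + site noise); a sample's vole presence is
  Bernoulli at that availability. Dog presence is Bernoulli at
  logit⁻¹(0.3 − 2.5·availability) — the negative default slope encodes
  dog faeces as an alternative resource. Other diet taxa occur at a flat
  0.3. Season intercepts default to (2.6, 0.75, −1.45, −0.55), producing
  the high-winter, collapsing-vole trajectory typical of a cyclic vole
  population's low phase.
- **Reads.** Depth per PCR is negative binomial (mean 5000, dispersion 2 —
  a heavy right tail). Shares over present taxa are a symmetric Dirichlet
  draw (concentration 1) with the host's weight multiplied by 10 before
  blocking: a scat is mostly depositor DNA, which is exactly why blocking
  oligonucleotides are used. Blocking then removes a fraction (default
  0.7) of the host share. Any truly ingested taxon that multinomial
  sampling left with zero reads in all three replicates is bumped to one
  read in a random replicate, preserving the invariant that eaten taxa
  leave DNA.
- **Artifacts**, injected after the truth snapshot: single-substitution
  error variants (per-read probability 0.002), Poisson(2) one-read junk
  sequences of random length 40–140 per PCR, tag jumps moving a
  Binomial(total, 0.002) subset of each sequence's reads to uniform other
  PCRs (per-sequence totals conserved), and human-contamination blocks
  (~50 reads) in 2 % of PCRs. Field species guesses are mislabelled at
  rate 0.2.
- **Determinism**: one `numpy` PCG64 generator seeds everything; identical
  config + seed reproduces every output file byte-for-byte.

What the generator does *not* emulate: read-level FASTQ/quality structure,
chimeras, primer/adapter artifacts, multi-host scats, true taxonomic
mixtures below the marker's resolution, or spatially autocorrelated
occurrence. Passing tests therefore validate the *computational* pipeline
against a known truth of matching statistical shape — they do not certify
performance on any particular real dataset, whose artifact rates and
compositional structure must be assessed with the diagnostics module.

The calorimetry generator emits 2–4 combustion replicates per dog with
within-dog noise at 0.4 % of the mean, safely inside the 1.5 % RSD
acceptance rule, and wet/dry weights exactly consistent with the requested
water fraction (default 60.5 %).

## Test and acceptance problem sizes

The validation suite exercises the pipeline at sizes chosen to keep the
whole suite fast while leaving Monte-Carlo error well below the margins
being asserted: oracle-equivalence checks on 1,000 random MOTUs × 60 PCRs
and 1,000 random voting samples; GLM parameter recovery over 500
replicates of 19 site × season cells (10–60 samples each); diagnostic
calibration over 200 replicates with 250 simulations each; and one full
end-to-end run at the default ~680-sample survey.

## Known limitations

- Identity ties and co-optimal alignments make percent identity mildly
  aligner-dependent near the 95 % boundary (documented above).
- The GLM layer offers no random effects and no model selection; with few
  site cells the Wald intervals are approximate.
- The tag-jump and contamination rules are conventional stand-ins for the
  (unpublished) lab-specific criteria of any given study; both are
  parameters, not claims.
- RRA depends on the share-denominator convention; comparisons across
  studies should state which is used.
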