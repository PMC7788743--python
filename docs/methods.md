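# Methods

## Scope

`rohscan` implements a complete runs-of-homozygosity (ROH) analysis for
biallelic SNP-array genotypes of a multi-breed livestock panel: quality
control, consecutive-runs ROH detection, length-class binning, genomic
inbreeding (F_ROH and F_HOM), per-marker incidence of common runs,
ROH-island calling with population-sharing classification, and a one-way
breed-effect model on per-sample island SNP proportions. Because real
multi-breed sheep genotypes are access-restricted, validation rests on a
synthetic panel generator that plants identical-by-descent segments with
known per-animal true autozygosity.

Genotypes are reduced to per-marker *status* (homozygous / heterozygous /
missing) immediately on input; no downstream quantity depends on allele
identity, so the arbitrary choice of which homozygote is coded `HOM_A`
is irrelevant by construction. Coordinates are 1-based inclusive
everywhere (matching PLINK MAP positions); an interval's length is
`end − start + 1`. The BED export converts to 0-based half-open by
`start − 1`.

## Quality control

Filters and defaults (all configurable):

| filter | default | removal rule |
|---|---|---|
| autosome restriction | chromosomes 1–26 | non-numeric / out-of-range chromosome labels dropped at read |
| marker call rate | 0.95 | removed iff call rate **<** threshold |
| marker MAF | 0.01 | removed iff MAF **<** threshold (monomorphic always removed) |
| animal missingness | 0.02 | removed iff missing fraction **>** threshold |

Boundary semantics are deliberately strict-inequality removals, i.e.
equality retains (a 95.0% call-rate marker stays; a 2.0%-missing animal
stays). MAF is computed from non-missing calls only. The order —
autosomes, call rate, MAF, then animal missingness on the post-marker
panel — follows common practice; it is configurable and echoed in the
report because marginal removal counts depend on it. No LD pruning is
performed anywhere; short chance ROH from LD are instead excluded by the
1 Mb minimum run length.

Half-missing genotypes (`A 0`) have no standard interpretation; they are
treated as missing and counted, never guessed.

## Run detection

A run of homozygosity is a maximal stretch of markers in one animal on
one chromosome satisfying, jointly (defaults in `RohParams`):

* ≥ 30 markers and a span of ≥ 1 Mb;
* at most 1 heterozygous and at most 1 missing call, as *independent*
  budgets (one of each may co-occur in a run);
* mean density of at least one marker per 100 kb, assessed over the
  whole run (`span / n_markers ≤ 100 kb`), not locally;
* no gap above 250 kb between consecutive *genotyped* member markers —
  a missing member marker does not split the distance, so the gap clock
  runs between its genotyped neighbours;
* homozygous, non-missing terminal markers (het/missing only strictly
  inside).

Detection is a greedy left-to-right scan over consecutive markers: the
leftmost marker from which any compliant window starts opens a run, the
run extends to the largest compliant end, and the scan resumes after it.
This yields maximal, non-overlapping runs and makes the definition
testable: an independent brute-force enumeration of all compliant
windows plus the same leftmost/longest selection must return the
identical set, and does, on 100 random chromosomes per suite run
(`tests/_utils.py::bruteforce_runs` is coded separately from the
scanner). A post-hoc validator (`validate_segments`) re-derives every
criterion for every emitted segment from the raw genotypes; the test
suite runs it with zero tolerance.

Length classes are half-open, lower-inclusive bins 1–6, 6–12, 12–24,
24–48 and > 48 Mb (exactly 6 Mb falls in 6–12 Mb; the bin labels alone
do not fix the boundary side, so this is declared as the convention).
Runs below 1 Mb can only exist under a relaxed `min_length_bp` and are
labelled `<1Mb`, outside the standard bins.

## Inbreeding

**F_ROH** = L_ROH / L_AUTO, per animal, where L_ROH is the summed length
of autosomal runs and L_AUTO the SNP-covered autosome length. L_AUTO is
either the constant 2 453 Mb conventionally used for the ovine autosomes
or computed from the post-QC map as Σ per chromosome of
(max − min position + 1); outputs record which mode was used. Synthetic
genomes use the map mode since their covered span (26 × 94 Mb ≈
2 444 Mb) is deliberately close to, but not exactly, the constant.

**F_HOM** is the method-of-moments excess-homozygosity estimator

    F_HOM = (O_hom − E_hom) / (N − E_hom),  E_hom = Σ_j (1 − 2 p_j q_j),

summed over the animal's N non-missing markers, with allele frequencies
p_j estimated from the full post-QC panel. No small-sample correction is
applied to E_hom; the resulting O(1/2N) downward bias is about −0.005 at
100 animals and is visible, and acceptably small, in the calibration
experiment. When every contributing marker is monomorphic the estimator
is undefined and reported as missing. Note that in a differentiated
multi-breed panel, pooled-panel frequencies make F_HOM systematically
higher than F_ROH (a Wahlund effect): within-breed genotypes are more
homozygous than the pooled Hardy–Weinberg expectation. The two
estimators nevertheless rank animals nearly identically (r ≈ 0.999 on
the default synthetic design).

Breed summaries report means with sample SD (n−1); single-animal breeds
get a missing SD.

## Islands

The incidence of common runs at a marker is the number of distinct
animals with ≥ 1 run covering its position (overlapping runs of one
animal are merged first). An island is a maximal stretch of consecutive
markers with incidence **strictly greater than** 20 animals, spanning
**more than** 1 Mb with ≥ 30 markers. Optionally, above-threshold
stretches separated by sub-threshold gaps no wider than `max_gap_bp`
may be merged; the default is 0 (off), so adjacent clusters are never
joined implicitly. Islands are numbered ROH1, ROH2, … in (chromosome,
start) order.

A population *contributes* to an island iff at least one of its animals
has a run covering at least one member marker — deliberately a weak
overlap rule, since requiring whole-island coverage would make sharing
depend on island width. Classes partition the island set: unique (1
population), shared (2–3), common (> 3).

Per island and sample, the proportion of member markers covered by the
sample's runs (0–1) is modelled as

    proportion = μ + B_i + e,

a one-way fixed-effects ANOVA with sum-to-zero breed effects B_i
(statsmodels OLS; μ is then the unweighted mean of breed means), with an
F-test for the breed term. The model is skipped, with a note, for
islands observable in fewer than two breeds with two samples each. Raw
p-values are emitted; no multiple-testing correction is applied across
islands.

## Synthetic panels

The generator emulates a medium-density array on a sheep-like genome.
Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| genome | 26 autosomes × 94 Mb | total 2 444 Mb, matching the SNP-covered autosome scale |
| marker spacing | uniform 20–80 kb (mean 50 kb) | typical 50k-chip mean gap |
| oversized gaps | 2 per chromosome, 300–500 kb | exercises the 250 kb gap rule |
| ancestral frequencies | uniform 0.2–0.8 | array ascertainment toward intermediate MAF |
| breed differentiation | Balding–Nichols, F_ST 0.1 | moderate among-breed drift |
| planted lengths | mixture over the five bins, weights (0.882, 0.08, 0.025, 0.01, 0.003) | short-dominated, as in real panels |
| error / missing rates | 0 (per-experiment) | each experiment states its own |

Animals are two independent haplotypes drawn from breed frequencies;
autozygosity is planted by copying haplotype 1 over haplotype 2 in
non-overlapping intervals until the summed length reaches
F_target × genome (the construction stops within half a minimum segment
of the target, < 0.001 in F on the full genome). Genotyping errors flip
one allele of a call — inside planted segments this creates exactly the
heterozygotes that stress the ≤ 1-het budget. Optional per-breed
*hotspots* plant a segment overlapping a fixed locus with given
probability, creating the run pile-ups needed to test island calling and
sharing. Everything derives from a single mandatory seed through one RNG
in fixed draw order, so a seed reproduces the panel byte for byte.

What the generator does **not** model: linkage disequilibrium (markers
are exchangeable given the planted intervals, so chance short runs are
rarer than on a real chip and the 1 Mb minimum is less load-bearing than
in practice), recombination-map heterogeneity, pedigree structure, sex
chromosomes, and allele-calling artefacts. Passing tests therefore
demonstrate correctness of the algorithms against their definitions and
calibration under the stated generative model — not robustness to
LD-driven false runs on real data.

## Validation experiment design

All experiments live in `rohscan.experiments`, seeded, and are run both
by the test suite and by `scripts/acceptance.py`. Problem sizes are
chosen so each experiment finishes in well under a minute on one core
while Monte Carlo noise stays an order of magnitude inside the checked
tolerances.

* **Detector vs enumeration** — 100 random chromosomes of 60–500
  markers with heterozygosity 2–40%, missingness 0–6%, jittered spacing
  and occasional oversized gaps; exact set equality required.
* **Planted recovery** — 3 breeds × 20 animals, 2 chromosomes × ~2 000
  markers at 50 kb. With zero error/missingness, every planted interval
  holding ≥ 30 markers over ≥ 1 Mb must lie *inside* a detected run.
  Containment, not exact boundary equality, is the correct oracle here:
  chance homozygosity in the outbred flanks legitimately extends a
  maximal run a few markers past the planted end (measured: ~8 markers
  in total, i.e. ~0.2 Mb per side), and any detector honouring
  maximality must show this. Oversized gaps are disabled in this design
  — an interval straddling a > 250 kb gap is unrecoverable as one run by
  definition — and the gap rule is covered by dedicated unit tests.
  With a 0.1% error rate, sensitivity is measured for ≥ 2 Mb segments
  (an interior error plus a flank het can split a covering run, which
  bounds attainable whole-segment sensitivity near 0.95–0.97).
* **F_ROH recovery** — breeds planted at F_true 0.05 / 0.15 / 0.30,
  full 26-chromosome genome at 50 kb spacing, long segments (uniform
  10–20 Mb). The long-segment design is deliberate: each planted segment
  contributes a fixed edge bias (boundary quantisation to the marker
  grid plus the chance extension above, a few markers per edge), so the
  total bias scales with the *number* of segments. With the
  short-dominated default mixture, F = 0.3 means ~150 segments and an
  a-priori bias of +0.02–0.04 — outside a ±0.01 check for any faithful
  maximal-run detector — whereas ~50 long segments keep it near +0.004.
  Mean breed F_ROH must match F_true within ±0.01 with breed ranking
  preserved.
* **F_HOM calibration** — 100 animals, ~40 000 markers (26 × 77 Mb at
  50 kb), no planting, F_ST 0: mean F_HOM within ±0.02 of zero. The
  F_ROH–F_HOM agreement uses nine planted levels spanning F_true 0–0.4
  (8 animals each, F_ST 0 so pooled frequencies are unbiased).
* **Invariant sweep** — a 75-animal, 4-chromosome design with two
  hotspots, 0.2% error and 1% missingness; zero tolerance on segment and
  island invariants and on the sharing-class partition.
* **ANOVA calibration** — the island model is simulated directly at the
  model's own level (normal residuals, SD 0.1): 500 null islands
  (4 breeds × 15) must give uniform F-test p-values (KS p > 0.01); a
  +0.3 two-breed effect at n = 20/breed is estimated as the fitted
  breed contrast averaged over 100 replicate islands (a single
  replicate's contrast SE is 0.032, so averaging is what makes ±0.05 a
  test of bias rather than of one draw).
* **Determinism** — one seed, two simulations and writes: byte-identical
  PED/MAP.

## Known limitations

* The consecutive-runs internals (scan order, terminal-marker rule,
  whether het and missing budgets may co-occur) vary between published
  implementations; the choices here are declared above and enforced by
  the validator, but other tools may emit slightly different run sets on
  the same data.
* `f_hom` with pooled frequencies is confounded by population structure
  (Wahlund); for within-breed inference, supply within-breed
  frequencies.
* The island sample threshold (> 20 animals) is an absolute count, as
  is conventional; on panels much smaller or larger than ~1 000 animals
  it corresponds to a very different population fraction and should be
  reconsidered via `min_samples`.
* Island ANOVA treats proportions as unbounded responses; with many
  zero-proportion samples the F-test is approximate.
* The O(n·k) scan (k = markers until a budget/gap violation) is pure
  Python/NumPy; a ~50k-marker, ~100-animal panel takes seconds, but
  million-marker panels would warrant a compiled inner loop.
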