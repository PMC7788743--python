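# rohscan

Runs-of-homozygosity (ROH) analysis for biallelic SNP-array genotypes of
multi-breed livestock panels: quality control, consecutive-runs ROH
detection, genomic inbreeding, ROH islands, and a breed-effect model on
island SNP proportions — plus a synthetic genotype simulator with
planted identical-by-descent segments that provides ground truth for
every step.

It is written for population geneticists and breed-conservation
researchers who have PLINK text PED/MAP genotypes (OvineSNP50-style
chips and similar) with a breed/production-system table per animal, and
who want the full ROH workflow as a tested, scriptable Python library
rather than a chain of GUI tools.

## What it computes

A **run of homozygosity** is a contiguous stretch of homozygous
genotypes in one individual, evidence of identity by descent. Runs are
detected per animal per chromosome by scanning consecutive markers
against joint criteria (defaults): ≥ 30 SNPs, ≥ 1 Mb, ≤ 1 heterozygous
and ≤ 1 missing call, ≥ 1 SNP per 100 kb, inter-marker gaps ≤ 250 kb,
homozygous terminals. Detected runs are binned into 1–6, 6–12, 12–24,
24–48 and > 48 Mb classes and summarised per breed (mean number MN_ROH
and mean length AL_ROH of runs).

Genomic inbreeding per animal:

    F_ROH = L_ROH / L_AUTO
    F_HOM = (O_hom − E_hom) / (N − E_hom),   E_hom = Σ_j (1 − 2 p_j q_j)

with L_ROH the summed autosomal run length, L_AUTO the SNP-covered
autosome length (2453 Mb default for sheep, or computed from the map),
and F_HOM the method-of-moments excess-homozygosity estimator over the
animal's N non-missing markers.

**ROH islands** are genomic regions where runs from many individuals
pile up: maximal stretches of consecutive SNPs each covered by runs in
more than 20 animals, spanning > 1 Mb with ≥ 30 SNPs. Islands are
classified by contributing populations (unique = 1, shared = 2–3,
common = > 3), and per island the proportion of member SNPs each sample
covers is analysed with a one-way fixed-effects model
`proportion = μ + B_i + e` (sum-to-zero breed effects, F-test).

The **simulator** builds multi-breed panels (26 autosomes, ~50 kb marker
spacing, Balding–Nichols breed differentiation) and plants autozygous
segments by haplotype copying until each animal reaches its target
inbreeding, recording every planted interval and true F per animal —
the oracle the test suite measures recovery against.

## Worked example

The `analysis/` scripts run the whole study on a default five-breed
synthetic design (98 animals, breed inbreeding targets 0.05–0.25, three
hotspot regions, 0.1% genotyping error, 0.5% missingness):

```
python analysis/01_simulate_panel.py 1   # seed 1
python analysis/02_quality_control.py
python analysis/03_detect_roh.py
python analysis/04_inbreeding.py
python analysis/05_roh_islands.py
```

which prints, among other things:

```
markers: 48764 -> 48762 (call rate -2, MAF -0)
animals: 98 -> 98 (missingness -0)

9496 runs detected; validator violations: 0
88.2% of runs fall in the 1-6 Mb class (mean length 4.17 Mb)
population  n_animals  n_roh  mn_roh  al_roh_mb  sum_roh_mb
   Dualkop         15   1774  118.27       4.25      502.47
   Lowveld         15    442   29.47       4.25      125.36
Muttonvale         20   1194   59.70       4.21      251.19
  Pelthill         28   4346  155.21       4.05      628.87
  Woolford         20   1740   87.00       4.32      375.46

breed means (planted truth vs estimates):
            f_true   f_roh   f_hom
Dualkop       0.20  0.2058  0.2573
Lowveld       0.05  0.0513  0.1212
Muttonvale    0.10  0.1029  0.1658
Pelthill      0.25  0.2576  0.3052
Woolford      0.15  0.1538  0.2129
per-animal corr(F_ROH, F_true) = 1.000; corr(F_ROH, F_HOM) = 0.998

peak incidence 88 animals at chr1:19990544
86 islands called; sharing classes: {'common': 85, 'shared': 1}
```

Reading this: QC barely touches the clean synthetic panel; the detected
run-length histogram reproduces the planted short-dominated mixture
(88.2% in 1–6 Mb); mean F_ROH recovers each breed's planted F within a
few thousandths, while F_HOM sits systematically higher because pooled
allele frequencies in a differentiated panel overstate expected
heterozygosity (a Wahlund effect — the ranking still matches F_ROH at
r ≈ 0.998); and the incidence peak at chr1:20 Mb is the hotspot region
planted in all five breeds, called as island ROH1.

The same workflow runs from the shell against real files:

```
rohscan detect --ped panel.ped --map panel.map --meta metadata.tsv --out-dir roh/
rohscan inbreeding --ped ... --roh roh/roh.tsv --l-auto 2453000000 --out-dir inb/
rohscan islands --map ... --meta ... --roh roh/roh.tsv --out-dir islands/
```

(`rohscan simulate`, `qc` and `run-all` complete the set; see `--help`.)

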