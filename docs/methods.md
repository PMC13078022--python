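# Methods

## The problem

Multifocal hepatocellular carcinoma (mfHCC) — two or more tumor nodules in
one liver — arises by two mechanisms with different biology and prognosis:
**intrahepatic metastasis (IM)**, where one clone disseminates within the
liver, and **multicentric occurrence (MO)**, where chronically damaged
liver ("field effect") spawns independent de novo tumors. Distinguishing
the two requires deciding, for every pair of tumor nodules of a patient,
whether the nodules are clonally related. This package implements that
decision as a statistical test on somatic variants, the patient-level
classification built on it, the construction of tumor units for
downstream comparison, and the similarity analyses that contrast clonal,
non-clonal and inter-patient biopsy pairs.

## Clonality test

Two biopsies of common clonal origin share "trunk" somatic variants
acquired before dissemination. The evidence carried by a shared variant
depends on how unusual sharing it by chance would be: recurrent hotspot
mutations (e.g. *CTNNB1*, *TERT* promoter) co-occur in unrelated tumors,
whereas a shared passenger variant seen in one patient of the cohort is
near-proof of common origin. For biopsy variant sets $A$ and $B$ the
statistic is a rarity-weighted cosine overlap

$$S(A,B) \;=\; \frac{\sum_{v \in A \cap B} w(v)}
  {\sqrt{\left(\sum_{v \in A} w(v)\right)\left(\sum_{v \in B} w(v)\right)}},
  \qquad w(v) = -\log_{10}\!\big(\max(f_v, f_{\min})\big),$$

where $f_v$ is the fraction of cohort **patients** carrying $v$ (a variant
is counted once per patient, so multiply-biopsied clones do not inflate
their own frequencies) and $f_{\min} = 1/(2\,n_{\text{patients}})$ keeps
weights finite. $S \in [0,1]$, is symmetric, equals 0 iff the sets are
disjoint and 1 iff they are equal, never decreases when a shared variant
is added, and never increases when a private one is added.

**Null distribution.** Under the null hypothesis of independent origin,
the two variant sets are exchangeable with random draws from the cohort
variant pool. Each permutation redraws sets of the observed sizes $|A|$
and $|B|$ with probability proportional to variant frequency, **without
replacement** within a replicate, and rescores. Frequency-proportional
draws make the null frequency-matched: hotspot-rich profiles get
hotspot-rich nulls. The p-value uses the add-one rule
$p = (1 + \#\{S_{\text{perm}} \ge S_{\text{obs}}\})/(n_{\text{perm}} + 1)$
with ties counted against the observed score (conservative). A pair is
called **clonal** iff $p \le \alpha$ with $\alpha = 0.05$, boundary
inclusive, matching the study's global significance rule. Defaults:
$n_{\text{perm}} = 999$, so the smallest attainable p is 0.001.

Sampling without replacement is implemented as vectorized sequential
draws with per-element rejection: drawing from the full distribution and
redrawing any index already present in its replicate is exactly a draw
from the renormalized distribution over the remaining variants. This is
$O(k^2)$ per replicate in the set size $k$ rather than $O(\text{pool})$,
which is what makes the calibration study (1,000 pairs × 999
permutations) run in well under a minute.

**Reproducibility.** Each pair's RNG stream is seeded by a BLAKE2 hash of
(master seed, canonical pair key), so per-pair results are independent of
iteration order and stable across platforms.

## Patient classification and tumor units

Biopsy-pair calls are aggregated to nodule pairs by the **any-clonal
rule**: one confident clonal biopsy pair marks the nodule pair clonal,
because variant dropout (sampling, coverage, calling) can mask sharing in
other biopsies, while a significant shared-variant excess is positive
evidence. Conflicting biopsy-pair calls within a nodule pair are flagged.

A patient is **IM** iff all nodule pairs are clonal, **MO** iff all are
non-clonal, **mixed** otherwise. Tumor units are the connected components
of the clonal-relation graph: a component with ≥ 2 nodules is a **TMP**
(tumor with metastatic potential), a singleton is a **TNEM** (tumor with
no evidence of metastasis). Components treat clonality as transitive;
intransitive triangles are absorbed into one component and are detectable
in the relation table. Note the label and the partition are not mutually
redundant on arbitrary call patterns: a mixed patient can yield two TMPs
and no TNEM (two disjoint clonal pairs), and an intransitive triangle is
labeled mixed yet forms a single all-covering TMP. On transitively
consistent call sets the correspondence is exact: IM ⇔ one all-covering
TMP, MO ⇔ all TNEM, mixed ⇔ ≥ 2 units including a TMP.

Unit-level aggregation follows the study's rules:

* **Mutations** — the exact union over member biopsies.
* **Copy number** — per genome bin, the member state with the largest
  deviation from neutral ploidy (2), so deep losses survive neutral
  co-members; a gain/loss tie of equal magnitude resolves to the gain and
  is flagged.
* **Representative biopsies** — the earliest-timepoint biopsy of each
  member nodule (ties broken to the smallest biopsy id, flagged); used
  for per-biopsy quantities such as TMB and expression scores.
* **Clinical status** — taken from the nodule holding the unit's globally
  earliest biopsy.

## Similarity framework and statistics

Pairs fall into three classes: clonal and non-clonal (intra-patient,
inter-nodule) and inter-patient (default 50 pairs sampled uniformly
without replacement from all cross-patient tumor biopsy pairs,
seed-deterministic, matching the study's n = 50). Per pair we compute
Spearman correlations (the study's default; Pearson available) of
copy-number state vectors, signature-activity vectors and expression
profiles, and same/different/missing concordance of grade, growth
pattern and liver segment (identical **or neighboring** Couinaud
segments count as concordant; the adjacency is configurable).

Scalar metrics: fraction of genome altered (length-weighted fraction of
bins with non-neutral state; invariant to bin refinement), tumor
mutational burden (variants per callable megabase, default 35 Mb),
driver alteration count (driver genes with ≥ 1 alteration, gene counted
once, computed on the unit union), and a gene-set score (mean over set
genes of z-scores against a reference collection, e.g. NTL biopsies).
The shared-driver-mutation statistic pools variant occurrences across
all clonal pairs (primary) and also reports the mean of per-pair
fractions, plus, for non-clonal/inter-patient pairs, the count of pairs
carrying different variants of the same driver gene.

Group comparisons are two-sided throughout: Mann-Whitney U for two
numeric groups (exact enumeration when pooled n ≤ 10 — handled
in-package because it must be tie-safe — otherwise scipy's tie-corrected
normal approximation), Kruskal-Wallis for more, Fisher's exact test
(probability-mass rule) for 2×2 tables and chi-squared without
continuity correction for larger ones. No multiple-testing correction by
default; a Benjamini-Hochberg helper exists for exploratory tables.

## Synthetic cohort generator

Real mfHCC multi-omics data are controlled-access, so every stage is
exercised on generated cohorts with known ground truth. The generator
emulates the study's design: 22 patients by default (10 IM / 9 MO / 3
mixed), 2–4 nodules each (mixed patients ≥ 3), 1–2 biopsies per nodule at
serial timepoints, 1–2 NTL biopsies per patient.

* **Variant pool** — 10,000 variants with power-law rank-frequency
  $f_i = 0.3\, i^{-1}$ (many rare, few common). Every 50th rank is a
  hotspot assigned round-robin to a 20-gene HCC driver panel
  (*CTNNB1*, *TP53*, *ALB*, *ARID1A*, …), so recurrent driver mutations
  span the spectrum.
* **Mutations** — each clonal component draws Poisson(20) trunk variants
  from the rare tail ($f \le 0.01$): clonality evidence in this framework
  rests on rare sharing. Each nodule adds Poisson(30) private variants
  drawn frequency-proportionally from the whole pool, so hotspots recur
  independently across patients and common-variant sharing is
  uninformative by construction. Biopsies drop each nodule variant with
  probability 0.05 (dropout) and add Poisson(1) biopsy-private variants.
* **Copy number** — 500 bins of 1 Mb over 10 synthetic chromosomes; 40
  candidate events (3–25 bins, states 0/1/3/4/5); each component takes
  each event with p = 0.30 (co-segregating in clonal sets), each nodule
  privately with p = 0.15.
* **Expression** — 2,000 genes, baseline N(5, 2) log2(TPM+1); random
  component (SD 0.6) and nodule (SD 0.3) programs plus biopsy noise
  (SD 0.5). Tumors in multi-nodule components gain +1 log2 on a 50-gene
  cell-cycle set (*TTK*, *BUB1*, *NUF2*, …) — the metastatic phenotype.
  NTL of MO/mixed patients gains +1 log2 on a 50-gene fibrosis set
  (*COL1A1*, *MMP9*, *NFKB1*, …) — IM-NTL has the least fibrotic
  microenvironment, mirroring the study's fibroblast-score contrast.
* **Signatures** — one Dirichlet(1) exposure vector per clone over five
  signatures, biopsies mix in 10% fresh Dirichlet noise.
* Clinical covariates (Couinaud segment, Edmondson grade, growth
  pattern) are correlated within clonal components (same or neighboring
  segment with probability 0.8, same grade/pattern with 0.85).

Everything is a deterministic function of the seed via named
`numpy.random.default_rng` substreams.

**What the generator does not emulate:** realistic mutational signature
profiles, subclonal structure or cancer-cell fractions, purity/coverage
variation, genome-wide LD of copy-number events, or proteomes. Passing
tests therefore demonstrate the correctness and calibration of the
*methods* under the stated generative assumptions, not performance on
real sequencing data. The generator's defaults were chosen once for
testability (clear trunk signal, honest null), not tuned to reproduce
the study's printed effect sizes; e.g. the pooled shared-driver fraction
of clonal pairs on synthetic cohorts (~50%) is below the study's 83%,
because synthetic driver hits are mostly private frequency-proportional
draws rather than truncal events.

## Numerical choices and degenerate inputs

* Empty mutation profiles are an error for scoring (the score is
  undefined); the generator guarantees non-empty profiles.
* If every variant of both profiles has weight 0 (all at frequency 1),
  the score degenerates to set equality (1 if equal, else 0).
* Permutation tie comparison uses a 1e-12 float tolerance so that exact
  ties count as ≥ (conservative).
* Correlations of zero-variance profiles are reported missing with a
  warning, never imputed.
* Uncovered copy-number bins default to neutral ploidy with a logged
  count; a bin takes the state of the segment covering its midpoint.
* Cohort frequencies lie in $[f_{\min}, 1]$ and are invariant to biopsy
  ordering; `unit_summaries` reports mean/range as absent (not 0) when
  there are no TMPs.
* Problem sizes in the test and acceptance studies: calibration uses
  1,000 independent pairs at 999 permutations; sensitivity 200 clonal
  pairs with ≥ 5 rare trunk variants; end-to-end recovery five cohorts
  of 25 patients; the exhaustive classification check enumerates all
  relation graphs on ≤ 5 nodules. These match the property-suite scales
  stated in the analysis plan and run on one CPU in a few minutes.

## Known limitations

* Cohort-internal variant frequencies (not an external population
  reference) define rarity; in very small cohorts the weights are
  coarse. The open question of reference choice is resolved in favor of
  self-contained cohort frequencies.
* The clonality call is mutation-only; copy-number evidence is used for
  similarity description, not calling.
* Copy number is consumed as integer absolute states; log-ratio segment
  means are rounded at ingest.
* The any-clonal nodule aggregation rule and the transitive component
  rule are policies chosen here (flagged when they matter); the source
  study does not state how it would resolve conflicting or intransitive
  calls.
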