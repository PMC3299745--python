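# Methods

## Setting

`clonediv` reanalyses a common small-scale design in host–microbiome
ecotoxicology: a crustacean host (the brackish-water harpacticoid copepod
*Nitocra spinipes*) is exposed to antibiotics alongside solvent controls;
the bacterial community associated with the animals is characterised by a
16S rRNA clone library per treatment (30 Sanger-sequenced clones each), and
host development is scored per replicate well. The analysis links the two
sides: does lower symbiont diversity accompany poorer juvenile development?

The six libraries are ciprofloxacin (Cipr), sulfamethoxazole (Sulf) and
trimethoprim (Trim) treatments, and their solvent controls — synthetic
seawater (SS), acetone (Ac) and DMSO. The antibiotic-to-control pairing
follows the solvent each stock was prepared in: Cipr/SS, Sulf/Ac, Trim/DMSO.

## Diversity of censored clone libraries

A clone library is not a random sample of the community: PCR and cloning
are selective. The Brillouin index is the appropriate diversity measure for
such fully enumerated ("censored") collections:

    H_B = (ln N! − Σ_i ln N_i!) / N

with N_i clones in phylotype i and N total clones, in nats per individual.
Relative evenness rescales it between the extremes attainable at the
observed N and phylotype count S:

    V = (H_B − H_min) / (H_max − H_min)

H_min comes from the most uneven composition (one phylotype with N − S + 1
clones, the rest singletons); H_max from the most even one, with parts
X = ⌊N/S⌋ and Y = X + 1 (r = N − S·X parts of size Y). Both closed forms are
verified in the test suite against brute-force enumeration over every
composition of N ≤ 15, and the inequality H_min ≤ H_B ≤ H_max is property-
tested on random count vectors.

Numerical choices: log-factorials use the exact big-integer product up to
n = 170 and lgamma beyond, so the N = 30 golden values carry no accumulation
error. Natural log is the reporting base; V is base-invariant because the
scale cancels. Zero counts are dropped before S is computed. For S = 1 the
evenness is undefined (0/0) and is reported as an explicit `None`/NaN
marker rather than a silent 0 or 1, so degenerate libraries cannot distort
downstream correlations.

A reproducibility caveat found while validating: from the fixture counts,
the computed V matches the printed record for both S = 5 libraries (SS 0.74,
Ac 0.60) and H_B matches for all six libraries, but the printed V values of
the four S = 4 libraries (0.26/0.51/0.40/0.57) are not reproduced by the
evenness formula with these standard bounds (we obtain 0.29/0.58/0.45/0.63).
No alternative min/max form we are aware of reproduces both groups at once.
The package computes the formula as defined and documents the discrepancy
instead of imitating it.

### The fixture count table

The shipped table (`clonediv/data/table1_counts.tsv`) reproduces the
published per-library clone counts with one reconciliation: three cells
printed as "(14)" clones contradict both the stated 30-clones-per-library
design and their own printed frequencies (13%). Wherever a library column
did not sum to 30, those cells were replaced by round(frequency × 30 / 100)
= 4 clones. After reconciliation every column sums to 30 and the diversity
stage reproduces all six printed H_B values at 2 dp — the unreconciled
counts do not, which is strong evidence the reconciliation recovers the
data actually analysed.

## Phylotype binning

Sequences sharing ≥ 97% identity — the classical 16S species-level cutoff —
are one phylotype. Identity is computed on a global alignment with affine
internal gap costs (match +1, mismatch −1, open −2, extend −0.5) and
cost-free terminal gaps; terminal-gap columns are excluded from the identity
denominator because clone inserts are partial genes with ragged ends. Two
guards make the measure robust: the ambiguity code N never counts as a
match, and the denominator is floored at the shorter sequence's length so a
spurious micro-overlap between unrelated sequences cannot score high.

Binning is greedy centroid clustering with a deterministic visiting order
(descending length, then id): a sequence joins the first cluster whose
representative it matches at ≥ threshold, else founds a new cluster. At
clone-library scale — tens of clones, references ≥ 4% apart, read error
~0.5% — the greedy partition provably coincides with the planted one (each
clone is within ~1% of its own reference and ≥ 3% from any other), and the
tests confirm exact recovery. Cluster naming is best-identity assignment
against a user-supplied reference FASTA (ties to the lexicographically
smaller id), with the achieved identity recorded so sub-threshold names can
be flagged — the local stand-in for naming by closest database hit.

Frequencies are reported as whole-number percentages (rounded half away
from zero), absent phylotypes as "nd"; per-library percentage sums may
drift from 100 by up to S/2 through rounding.

## Development endpoints

Each replicate well starts with `n_start` = 50 nauplii and is censused at
termination. Endpoints per replicate:

* survivorship (%) = 100 · survivors / n_start;
* %Copepodites = 100 · n_copepodites / survivors (undefined marker when
  nothing survived);
* development index DI = Σ k_i n_i / NS with stage values k = 1 (nauplius)
  and k = 2 (copepodite).

The DI is meant to fold survival and metamorphosis into one score, which
requires a convention for dead animals. Default: NS = n_start and the dead
score 0, so E[DI] = p_survive · (1 + p_metamorphose) and DI = 2 only under
full survival with full metamorphosis; excluding the dead would remove
survival from the index entirely. The survivor-only convention
(NS = survivors, DI ∈ [1, 2]) is available as a switch since the original
definition leaves the choice open.

## Statistics

All tests are tuned to the design's very small n (three replicates per
treatment, six libraries):

* **t-test** — pooled-variance Student form, df = n₁ + n₂ − 2 (the reported
  df = 4 at 3 + 3 replicates forces pooled rather than Welch), two-sided.
  Zero pooled variance is resolved explicitly (t = 0/p = 1 for equal means;
  an infinite-t marker otherwise).
* **ANOVA + Tukey HSD** — standard one-way F with df (k − 1, N − k);
  pairwise p-values from the studentized-range distribution at the error df
  (scipy's implementation).
* **Box-Cox** — applied to endpoint data before t/F tests to stabilise
  distributions. λ = 0 is ln; otherwise (x^λ − 1)/λ; "auto" maximises the
  profile log-likelihood over λ ∈ [−5, 5]. Zero-containing endpoints are
  shifted by half the smallest positive value (recorded). In the pipeline a
  single λ is fitted on the pooled data of each comparison so both groups
  are transformed on one scale; an all-constant endpoint (e.g. a fully
  arrested treatment) passes through untransformed and the degenerate-
  variance rules above take over.
* **Spearman** — r is the Pearson correlation of average ranks (ties
  averaged). For n ≤ 8 the two-sided p is exact by full enumeration of the
  n! rank permutations; the t-approximation is unreliable at the design's
  n = 6 and is reported alongside (`details["p_asymptotic"]`). The
  correlation links treatment-level mean DI to each library's H_B and V.

## Synthetic data

The generator emulates the study design so the whole pipeline is testable
offline: 8 reference ribotypes of 900 bp, rejection-sampled so all pairs
sit at ≤ 96% identity (i.e. ≥ 4% divergence, matching sub-species-level
separation); per-library clone compositions defaulting to the six published
count vectors (fixed-count mode for exact golden tests, multinomial mode
for sampling noise); independent per-base substitutions at 0.5% per clone
(Sanger-scale error, kept below half the reference divergence so binning is
identifiable — the scenario validates min_divergence > 2 · per_base_error);
and stage censuses with survivors ~ Binomial(n_start, p_survive) and
copepodites ~ Binomial(survivors, p_metamorphose). Default stage
probabilities mirror the reported outcome qualitatively: good survival
everywhere except trimethoprim (p_survive 0.60), metamorphosis arrested
under trimethoprim (p = 0), and the acetone control metamorphosing fastest
(p = 0.85) among controls (SS 0.60, DMSO 0.50; Cipr 0.40, Sulf 0.65).

What the generator does **not** emulate: chimeras and indel sequencing
errors (substitution-only by default), primer bias, within-treatment
compositional variation between replicates (one library per treatment, as
in the study), and any pharmacodynamics of the antibiotics. Passing tests
therefore show that the analysis recovers planted structure under clean
amplicon noise, not that it is robust to every artefact of real Sanger
libraries.

Determinism: every generator derives its numpy stream from the scenario
seed through a fixed spawn key, so outputs are bit-reproducible per seed
and streams never alias across generators.

## Problem sizes

Routine tests run the sequence stages at 200–300 bp and few references;
the end-to-end check uses the full 900 bp × 180 clone design, the
Monte-Carlo expectation checks use 500 replicates, and the λ-recovery
checks use n = 2000 draws — sizes at which each check's sampling error is
comfortably inside its asserted tolerance.

## Known limitations

* Greedy centroid binning is order-dependent in principle; it is exact only
  when clusters are separated well beyond the threshold, as here. Dense
  identity landscapes would need average-linkage or exact methods.
* The exact Spearman permutation p is O(n!) and capped at n = 8.
* The printed S = 4 evenness values remain unexplained (above).
* Endpoint replicate data are not printed in the original record, so the
  development-side statistics are validated by parameter recovery on
  synthetic data, not against published statistics.
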