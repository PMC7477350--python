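# Methods

## Mutant-proteoform database construction

A single amino acid variant (accession, 1-based position, ref → alt) is
applied to its canonical protein, and the **mutated** sequence is digested
in silico with trypsin specificity: cleavage C-terminal to K or R,
suppressed before proline (the Keil rule, on by default and configurable).
The database entry is the fully-cleaved peptide containing the variant
plus up to two fully-cleaved peptides on each side, truncated at the
protein termini. Digesting the mutated rather than the canonical sequence
matters when the substitution creates or destroys a K/R site: the
searchable peptides are mutated-sequence peptides, so their boundaries
define the context. Two cleavage-unit flanks guarantee that any peptide
with up to two missed cleavages containing the variant lies inside the
entry. Entry headers carry `parent=` and `offset=` (1-based start of the
entry on the full mutated protein) so downstream tools recover coordinates
without a sidecar file.

Batch builds are deterministic (input variant order, duplicates collapsed
to one entry), skip-and-report reference mismatches rather than aborting —
public variant catalogs are noisy — and support an accession exclusion
list for pathological cases such as titin, which alone carries tens of
thousands of catalogued substitutions. The build report satisfies
`variants_in = written + excluded + mismatched + duplicates + unresolvable`
on every run.

## PSM filtering

A PSM is kept only if, in this fixed order, it is

1. **fully tryptic** — N-terminus preceded by K/R (under the proline rule,
   a peptide starting with P after K/R is not a cleavage product) or the
   protein start; C-terminus ending in K/R or the protein end; at most
   `max_missed` (default 2) internal missed cleavages, with K/R–P bonds
   not counted as sites;
2. **variant-covering** — some occurrence of the peptide in the matched
   entry spans the substituted residue;
3. **mutant-specific** — absent from an exact-membership index of every
   tryptic peptide (≤ 2 missed cleavages) of the canonical proteome.
   With `il_equivalence` (default on) membership is tested after mapping
   I and L to one symbol, since those residues are isobaric and standard
   fragmentation cannot separate them;
4. **unambiguous** — matched to one entry, or to isoform entries of one
   parent (accession root before the isoform suffix, overridable with an
   isoform map) carrying the same exchange, which merge into one entry
   group. Matches across different parents or exchanges are rejected.

An I↔L substitution can never pass the collapsed specificity test — its
collapsed sequence *is* the canonical peptide — yet such matches carry
real information and are conventionally registered for later targeted
verification. They are therefore held to exact-sequence specificity only
and kept with a distinct `kept_isobaric_flagged` decision rather than
being silently rejected or silently trusted. This also preserves
monotonicity: relaxing `max_missed` or disabling `il_equivalence` never
shrinks the kept set.

The fixed rejection order makes reason codes deterministic; each PSM's
verdict is independent of all others, so filtering is order-independent
and parallelisable. Technical replicates are combined by **summing**
spectral counts (replicates are searched together, not averaged), with
per-replicate presence recorded.

An open caveat: deamidation of N/Q, a common variable search
modification, is mass-identical to N→D / Q→E substitutions. The filter
exposes an optional warning flag for such variants
(`warn_deamidation_mimics`) and makes no correction.

## Quantification

Spectral counts are assembled into a complete entry-group × sample
integer matrix (zeros for absent pairs, lexicographic ordering for
determinism). Group comparison uses the pseudocount-corrected log2
spectral-count ratio

    Rsc = log2((n2 + f)/(n1 + f)) + log2((t1 − n1 + f)/(t2 − n2 + f))

with f = 0.5 by default — the value used in the original formulation of
this estimator — and t the grand total of counts over a trait's samples,
so the second term corrects for unequal sampling depth. The function is
antisymmetric under swapping groups and monotone in n2. Proteins with
zero counts in both compared groups are dropped rather than reported as
Rsc = 0. The upregulation flag uses |Rsc| > 1 (more than two-fold) by
default.

Percentages in partition and cohort summaries are rounded **half-up** to
one decimal, matching printed-table convention (121/1100 → 11.0,
24/36 → 66.7). Quantile normalisation forces every column onto the
distribution of row-wise sorted-column means; tied values within a
column receive the mean of the quantile values they span, which makes
the operation idempotent.

## Coexpression modules and screening

Protein profiles are correlated pairwise (Pearson; zero-variance rows
are excluded with a warning). The default adjacency is the **signed**
soft threshold `a = ((1 + r)/2)^β`. The literal transform `(1 − r)/2` —
sometimes quoted as the similarity — is a *dissimilarity*: raising it to
a power inverts the network, clustering anti-correlated proteins. It is
deliberately still available as `similarity_convention="literal_paper"`
so the literal recipe can be reproduced, but it is not the default. The
default power is β = 15 with minimum module size 30 and deepSplit 4;
all are configurable.

Topological overlap is computed as
`TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
`l_ij = Σ_u a_iu a_uj`, `k_i = Σ_u a_iu`, unit diagonal; `1 − TOM` feeds
average-linkage hierarchical clustering. Tree cutting is a simplified
dynamic-hybrid cut: the dendrogram is cut at a fixed fraction of its
maximum merge height, mapped from the deepSplit sensitivity ladder
(0 → 0.90, 1 → 0.93, 2 → 0.95, 3 → 0.97, 4 → 0.99), and clusters below
`min_module_size` remain unassigned. Higher sensitivity cuts nearer the
top, so branches that separate only at the final merges still come apart
into modules and fewer proteins are left unassigned; lower settings
demand tighter branches. The full upstream hybrid algorithm (adaptive
per-branch height criteria and PAM-like relabelling) is intentionally
not replicated; at the block-structured scale this package targets the
static cut recovers planted modules essentially exactly, and the cut is
deterministic and permutation-equivariant. Modules are labelled WM1,
WM2, … in decreasing size order.

Each module is summarised by its **eigen-protein**, defined here as the
top hub: the member with the highest intramodular connectivity
`k_i^in = Σ_{j∈module} a_ij` (ties broken lexicographically). This is a
deliberate design choice over the first-principal-component eigengene:
the hub is an actual protein, directly interpretable and directly
measurable in follow-up assays. Module–trait association is the
point-biserial Pearson correlation of the hub profile with a 0/1 trait
indicator, with a two-sided p from the t-transform; each trait is tested
as its own indicator.

Module screening against protein groups (trait-unique sets,
Rsc-upregulated sets, …) uses the one-sided hypergeometric
upper tail `P(X ≥ overlap)` with population = universe, successes =
group, draws = module. Benjamini–Hochberg q-values are computed across
all module × group cells as a single family (the standard convention
when no method is named), and a module is screened in when its
**maximum** q across the groups is below the threshold (default 0.05) —
a conservative rule requiring over-representation in *every* group
tested. The full ranked table is always emitted; any further manual cut
is left to the user.

## Synthetic data

The generator emulates, at desk scale, the statistical shape of an
FFPE-cohort mutant-proteomics study:

- **Proteome**: uniform residues with K/R boosted to 8% each, so
  tryptic digestion yields many peptides; proteins are regenerated until
  they digest into ≥ 3 peptides. Default 50 proteins of 100–400 residues.
- **Variants**: reference-consistent by construction, positions sampled
  without replacement; a configurable fraction (default 10%) are I↔L.
- **PSMs**: the default design is 36 samples in three traits (9/9/18,
  mirroring the cohort split of a two-mutation-plus-negative study) in
  technical triplicate. Counts per detected entry are negative binomial
  (mean 3, dispersion 0.5 — overdispersed small integers with natural
  zeros, as spectral counts are), split multinomially across replicates.
  Violations of each filtering rule are planted at 5% each by
  deterministic construction: trimmed N-termini (non-tryptic), flanking
  peptides (non-covering), multi-parent matched lists (ambiguous), and
  canonical-shared peptides planted by adding "shadow" canonical
  proteins carrying a copy of a variant peptide, the way a paralog
  would (not-specific).
- **Expression matrices**: module members are
  `√w · latent + √(1−w) · σ · ε`, giving expected within-module
  correlation `w/(w + (1−w)σ²)` — exactly `within_r` at the default
  σ = 1 and 1 at σ = 0. Background proteins are pure noise. Module 1's
  latent factor is shifted (default 1.5) in the first trait's samples
  and half its members form that trait's planted "unique" group for
  ORA-recovery checks.

One seeded generator drives every artifact, so a seed reproduces a study
byte for byte. What the simulation does *not* emulate: spectrum-level
properties (m/z, intensity, retention time, chimeric spectra), search
engine score distributions, FDR behaviour, shared-peptide protein
inference, or realistic protein homology families. Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical assumptions, not end-to-end performance on real LC-MS/MS
data.

## Problem sizes and numerical choices

The test and acceptance workloads use 30–50 proteins, 200–1,000
variants, and 36-sample expression matrices with three 40-protein
modules — large enough to exercise every code path and small enough to
run the whole suite in seconds. Oracle comparisons use strict
tolerances: 1e-10 for the topological overlap triple-sum oracle, 1e-12
for hypergeometric p against exhaustive subset enumeration (universe
≤ 12), 1e-9 for the closed-form Rsc example. Correlations are clipped to
[−1, 1] before powering; TOM denominators are guarded against the
all-zero-adjacency case (overlap defined as 0). Ties are broken
deterministically everywhere (lexicographic names for hubs and module
labels, stable sorts in ranking).

## Known limitations

- The dynamic tree cut is a simplified static-height variant (above);
  very unbalanced dendrograms may split differently from the full
  hybrid algorithm.
- Spectral counting ignores peptide detectability and protein length;
  Rsc is a semiquantitative screen, not an abundance estimate.
- The mutant-specificity test is exact-membership only; it does not
  model near-isobaric modification mimics beyond the optional N→D/Q→E
  warning.
- The `peaks_csv` PSM dialect is a best-effort column mapping; the
  `generic_tsv` dialect is the stable contract.
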