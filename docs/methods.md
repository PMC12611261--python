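# Methods

## The experiment being modelled

MM-TPP measures ligand-induced thermal stabilization on membrane proteomes
held water-soluble in Peptidisc scaffolds. Aliquots of the library, with
and without ligand, are heated in parallel to a series of temperatures;
denatured protein aggregates and is removed, and the soluble remainder is
quantified by label-free LC–MS/MS. A ligand that binds a protein raises
(or, for destabilizers, lowers) the temperature at which the soluble
fraction collapses, so at intermediate temperatures the treatment/control
intensity ratio departs from 1. The package analyzes the resulting
protein × sample intensity table; everything upstream of the
protein-groups table (sample preparation, database search) is out of scope
and consumed as input.

## Preprocessing

Operations run in a fixed order enforced by a transform-state tag on the
matrix; calling out of order raises. The order is: identification filters
→ log2 → scaffold normalization → per-temperature valid-value filter →
imputation.

**Identification filters.** Rows flagged as reverse-database decoys
(id prefix `REV__` or flag column), contaminants (`CON__` or flag), or
identified only by a modification site are removed. Scaffold-peptide rows
(matched by a configurable id/gene regex, default matching Peptidisc
scaffold entries) are retained for normalization but excluded from testing
and from enrichment backgrounds. Intensity 0 or an empty cell is an
explicit missing value (the MaxQuant convention), never a measurement.

**Normalization.** Each sample is shifted additively in log2 space so that
the mean scaffold-peptide intensity is equal across samples. Because the
scaffold peptide is added in constant proportion during reconstitution and
does not denature in the gradient, it serves as an internal loading
standard. The shift preserves all within-sample differences. If the
scaffold is missing in a sample the run aborts unless the median-fallback
flag is set, in which case per-sample medians are equalized instead (a
weaker assumption, logged as a warning).

**Valid-value filter.** Each temperature is analyzed as its own
treatment-vs-control contrast; a protein enters the contrast when it has
at least `min_valid` (default 3, i.e. a complete triplicate) observed
values in the treatment group **or** the control group at that
temperature. The one-sided "either" rule deliberately admits on/off
proteins — fully observed in one arm, fully dropped out in the other —
which are the strongest stabilization signals. The alternative reading
(≥ 3 valid anywhere in an arm across all temperatures) was evaluated and
rejected: it admits heavily-imputed contrasts that raise the false-call
rate among unshifted proteins roughly twofold and can invert the direction
of a call.

**Unique peptides.** Proteins need ≥ 2 unique peptides (the highest count
over the table's unique-peptide columns); records with no count are
dropped with a warning.

**Imputation.** Missing values in sample *j* are drawn from
N(μ_j − 1.8·σ_j, (0.3·σ_j)²), where μ_j and σ_j are the mean and standard
deviation of the observed values of that sample within the analyzed slice.
This is the standard column-wise downshifted-normal treatment for
missing-not-at-random dropout: missing cells are assumed to sit below the
detection limit, in the lower tail of the sample's intensity
distribution. Imputation runs after row filtering, so every imputed row
has at least `min_valid` real observations in one group, and each
temperature slice is imputed independently. A single RNG stream seeded
from the run config is consumed in row-major order over missing cells,
making reruns byte-identical. Observed values are never altered.

## Differential testing and calling

The s0-moderated t-statistic divides the mean log2 difference by
`s_p·sqrt(1/n_t + 1/n_c) + s0` with the equal-variance pooled s_p and
s0 = 0.1. The s0 constant damps the significance of tiny fold changes
backed by tiny variances — the classic volcano artifact. p-values are
two-sided from the ordinary t distribution with n_t + n_c − 2 degrees of
freedom evaluated at |t|. This analytic convention is documented and
fixed: it reduces exactly to the textbook pooled test at s0 = 0 and is
conservative for s0 > 0 (|t| shrinks monotonically in s0). A
permutation-based alternative (as in SAM) was not adopted; with n = 3 + 3
the permutation distribution has too few distinct values to resolve
p < 0.05.

Calls use strict joint cutoffs: stabilized iff log2 FC > 1 **and**
−log10 p > 1.3; destabilized mirrored. No multiple-testing correction is
applied to stability calls — the procedure is a fixed-threshold volcano,
not an FDR analysis; BH correction is used only inside enrichment. Values
exactly at a cutoff are not called, a documented resolution of the
boundary ambiguity.

Melting profiles are per-temperature replicate means ± sd over *observed*
values only (imputed values never enter a curve), smoothed with
monotonicity-preserving piecewise-cubic Hermite interpolation (PCHIP,
Fritsch–Carlson construction) on a 0.1 °C grid; the interpolant passes
through the knots exactly and cannot overshoot between them. Relative
abundance at T is 2^(mean_log2(T) − mean_log2(T_ref)) per protein and arm.

## Annotation, enrichment, binder fractions

Classification follows the GO-then-topology route: proteins with a
membrane GO annotation (default GO:0016020; annotation tables are expected
pre-expanded, no ontology traversal in-package) are split by their
externally predicted transmembrane-segment count into IMP (≥ 1 TMS) and
membrane-associated (0 TMS); all others are soluble. A consequence worth
knowing: a protein with predicted TMS but no membrane GO term is labelled
soluble, because topology is only evaluated for GO-membrane proteins.
Membrane-annotated proteins without a TMS count are an error rather than a
guess.

Enrichment uses the EASE score: the one-tailed hypergeometric upper tail
of the 2×2 query/term table with the overlap cell decremented by one
(shrinking each margin it contributes to), so a single-protein overlap can
never be significant. Terms are reported with BH-adjusted q-values;
significance requires both p < 0.05 and q < 0.05. Redundancy reduction is
a simple grouping of terms whose query hits are the identical protein set
(the best-scoring term represents the group) — deliberately simpler than
graph-based tools, and flagged as such. The background is the set of
proteins tested at that analysis, scaffold excluded.

The binder-fraction summary reports, per temperature and overall, the
percentage of tag-annotated proteins (e.g. "ATP binding") among all tested
proteins versus among proteins called stabilized or destabilized; an
excess in the shifted set is the expected signature of genuine target
engagement.

## Structure-based ligand-fit score

AlphaFold-family predictions store per-atom pLDDT (0–100) in the B-factor
field. The score is the unweighted mean over contact residues of the
per-residue mean heavy-atom pLDDT, where a contact residue has ≥ 1 heavy
atom within `cutoff_A` of ≥ 1 ligand heavy atom. The cutoff is **not**
specified by upstream conventions, so it is an explicit parameter
(default 5.0 Å, a common heavy-atom contact definition) and is carried in
the score object; scores computed at different cutoffs are not
comparable. Two-stage averaging (atoms → residue → score) prevents large
residues from dominating. The score is invariant under rigid-body motion
and monotone in the cutoff (enlarging it never removes residues).

## Synthetic data: what it emulates, what it does not

The generator produces a complete experiment: a MaxQuant-dialect
protein-groups table (linear intensities, 0 = missing), design, annotation
and ground-truth tables. Per protein, the expected log2 intensity is

    base + log2( (1−plateau) / (1 + exp((T − Tm)/scale)) + plateau )

a two-state denaturation sigmoid; binders shift Tm by ΔTm in the treatment
arm only. Replicate noise is Gaussian in log2 space (sd 0.2); each noisy
value is then observed with probability logistic((value − 21)/1.5) —
dropout acting on the measured value, the simplest missing-not-at-random
mechanism and the one downshifted-normal imputation is built for.
Defaults: 5 temperatures (37 reference + 51–64 gradient), triplicates,
Tm ~ N(54, 4) °C, scale ~ U(1, 3) °C, plateau ~ U(0, 0.2),
base ~ N(25, 2) log2 units, ΔTm = ±6 °C for 5%/2% of proteins. These
values are calibrated so that a +6 °C shift drives log2 fold differences
past the volcano cutoff at intermediate temperatures, mirroring the
stabilization window of a well-behaved ABC-transporter positive control.
Unique-peptide counts are 1 + Poisson(max(0, base − 20)), so the
≥ 2-peptide filter removes a known, abundance-dependent subset. Decoy,
contaminant and site-only rows draw intensities from the same base
distribution — the flags, not abundance, must remove them. A constant
scaffold row (sd 0.05 log2 units, never missing) anchors normalization.
Annotations plant membrane GO terms/TMS counts and functional tags with
higher probability in binder classes (defaults: "ATP binding" at 60% in
binders vs 9% in non-binders; membrane annotation at 90% vs 50%).

Not emulated: peptide-level quantification and roll-up, batch effects,
retention-time or run-order drift, correlated noise between replicates,
ratio compression, co-aggregation. Passing recovery tests therefore shows
the pipeline correctly inverts *this* generative model, not that real
MM-TPP data are this clean.

## Operating characteristics at the reference conditions

Under the default generator (1000 proteins, seed 42) and default analysis
parameters, the pipeline recovers 68% of planted stabilized binders at
one or more temperatures (70 ± 4% across seeds), calls ≤ 2% of
non-binders at any temperature, and (at this seed) never calls a
destabilized binder stabilized. The misses are structural, not bugs: a
few binders fall to the ≥ 2-peptide/valid-value filters by construction
(low base abundance), some lose their single informative temperature to
partial dropout (neither arm keeps a complete triplicate), and some reach
fold changes > 1 whose p-values stay above 0.05 because groups mixing
observed and imputed values carry inflated within-group variance at 4
degrees of freedom. These are the known failure modes of the
Perseus-style workflow on missing-not-at-random data, and the synthetic
benchmark reproduces them faithfully rather than hiding them. The
"destabilized never called stabilized" property is likewise stochastic:
at other seeds, rare dropout configurations can invert a call's
direction.

## Numerical and design choices

- Problem sizes in tests and the acceptance script (10⁴ null proteins,
  10⁵ imputation draws, 10³-protein reference simulation) are chosen so
  every check resolves its tolerance with comfortable margin while the
  whole suite runs in well under a minute of compute.
- Sample columns are kept in a canonical design order (temperature, arm,
  replicate); all operations address samples by id, never by position.
- Result tables are written with 17 significant digits; write→read round
  trips are exact to double precision. Manifests contain no timestamps,
  so reruns are byte-comparable; the output directory is not part of the
  config hash.
- `s0_t_test` returns t = 0, p = 1 exactly when the mean difference is 0
  (covering the identical-groups case where the pooled sd is also 0).
- BH adjustment is *not* idempotent in general (re-adjusting an adjusted
  vector re-multiplies by m/i); the tested guarantees are rank
  monotonicity, the cap at 1, permutation equivariance, and fixed points
  on flat vectors.
- Degenerate inputs fail loudly: non-positive raw intensities, columns
  with < 2 observed values at imputation, duplicate PCHIP knots,
  inconsistent 2×2 margins, ligands absent from a structure (the error
  lists available components), membrane proteins without TMS counts.

## Known limitations

- The s0 p-value convention is analytic, not permutation-based; p-values
  for s0 > 0 are interpretable as calibrated thresholds, not exact tail
  probabilities of a null distribution.
- No Tm fitting or TPP-TR curve analysis: calls are per-temperature, as
  in the fixed-threshold volcano procedure the package implements.
- No GO DAG handling; annotation tables must be pre-expanded to the terms
  used for classification and enrichment.
- The ligand-fit score depends on the contact cutoff, which upstream
  practice leaves unspecified; absolute values should not be compared
  across cutoffs or prediction tools.
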