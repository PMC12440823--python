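# Methods

## Data model and filtering

Intensity data are long-format tables: one row per analyte (LiP peptide or
tryptic-control protein) × fraction/condition × replicate, positive peak
areas in arbitrary units. Zero, negative or missing intensities are treated
as missing and never imputed. The detection filter keeps an analyte only if
it was measured in ≥3 replicates in ≥2 groups; a LiP peptide additionally
requires its parent protein to pass the same rule in the tryptic control,
and group cells below the replicate floor are removed, so every surviving
cell is testable. Peptides are located on the proteome by exact substring
match (first occurrence, ambiguity flagged) and classified fully tryptic
when both termini are trypsin-consistent (preceded by K/R or a protein
terminus, ending in K/R or the C-terminus). The "no cleavage before
proline" refinement is off by default and switchable; the simpler rule is
stated explicitly rather than guessed per dataset.

## Normalisation and protein correction

Each sample (sample type × group × replicate) is rescaled multiplicatively
so its median intensity matches the median of sample medians, either across
all samples of a sample type (`global`) or only within one fraction
(`per_group`, appropriate when every fraction was searched separately, as
in a library experiment). The peptide signal is then the ratio R =
I_pep / I_prot formed per (group, replicate); in library mode the ratios are
median-equalised across samples once more, because systematic
peptide/protein ratio offsets between fractions would otherwise dominate.

## The error-propagated one-way ANOVA

Per group: n, the mean ratio, and a propagated standard deviation
`sd = mean * sqrt(CV_pep^2 + CV_prot^2)`, where the CVs are sample
(n−1-denominator) coefficients of variation of the raw peptide and protein
intensities in that group. The protein CV uses all control replicates of the
protein in the group, which may exceed the peptide's replicate count.
MS_within pools `(n−1)·sd²` over groups with N−C degrees of freedom. For
MS_between two variants exist:

* `as_printed` (default): the grand term is `Σ_c Mean_c / N` and the
  divisor is C. This form is kept verbatim for fidelity with the original
  pipeline. Note that whenever replicates exist (N > C) the grand term is
  smaller than the grand mean by roughly a factor C/N, so MS_between is
  inflated for *every* peptide — including the null-identical case — and
  p-values from F(C−1, N−C) are not calibrated (in our null benchmark the
  raw-p < 0.05 fraction is ≈ 1).
* `textbook`: weighted grand mean `Σ_c n_c·Mean_c / N`, divisor C−1 — the
  classical between mean square. All calibration and recovery benchmarks
  use this variant.

Degenerate cases are flagged, not fudged: MS_within = 0 with MS_between > 0
gives p = 0 and a `degenerate` flag; both zero gives p = 1; N−C ≤ 0 skips
the peptide with a reason. A between term at floating-point rounding level
relative to the squared grand mean is treated as zero so that exact
zero-noise inputs land in the correct degenerate branch.

Even with the textbook numerator the test is *mildly conservative*: the
propagated denominator pools two 3-df CV estimates per group (≈ 2(N−C)
effective df) yet is referred to F(C−1, N−C), and the protein noise enters
both mean squares. Under the study conditions (4 fractions × 4 replicates,
10% CVs) the measured null type-I error at 0.05 is ≈ 0.029 (mean over 12
independent 2,000-peptide simulations), versus exactly 0.050 for a classic
ANOVA on the same ratios. Users who need exact calibration can test the
ratios directly; the propagated form is retained because it is the method
this package implements.

Multiple testing uses Benjamini–Hochberg throughout. Pairwise fraction
differences use the Tukey–Kramer studentized-range statistic per peptide,
then BH across the pooled peptide × pair family (Tukey already controls the
within-peptide family; peptides are the remaining multiplicity). The
studentized-range upper tail is evaluated with fixed Gauss–Hermite (inner
normal location integral, 80 nodes) × Gauss–Legendre (outer chi scale
integral, 72 nodes over (0, 1 + 12/√df]) quadrature, vectorised over all
peptides sharing (k, df); agreement with adaptive quadrature is ~1e-13,
and the two-group case reduces to the pooled t-test.

Overlapping peptides are merged to the longest identified fully tryptic
parent among the tested peptides of the protein; the region q is the median
of member q-values, and a peptide with no identified parent becomes its own
flagged region.

## Marker library

A region with q_median < 0.05 becomes a marker. Elution plausibility uses
the half-molecular-weight rule: the retentate of cutoff k is expected to
hold species below the next-larger cutoff (unbounded for the 100-kDa
membrane), and a monomer may elute there iff MW/2 ≤ that bound, boundary
inclusive — the reading fixed by the worked 80-kDa example (allowed down to
30 K, not 10 K), which is a regression test. A marker is low confidence iff
every significant fraction pair (Tukey, BH-adjusted, < 0.05) involves a
disallowed fraction; a single fully allowed pair makes it high confidence.
MW is computed from sequence (average residue masses), since the rule
reasons about the monomer. Evidence flags record overlap (≥1 residue) with
protein-binding / RNA-binding domain annotations and mean interface
distance strictly below 2.6 Å.

## Overlay on perturbation experiments

A peptide from any protein-abundance-corrected LiP–MS experiment is a
marker hit iff it is significant and at least 50% of *its own* length
(denominator = the peptide, boundary inclusive) overlaps a library marker
of its protein; the hit inherits the marker's confidence class. Protein
abundance changes are called separately from the tryptic control by classic
one-way ANOVA with |log2FC| strictly > 0.5 and q < 0.05 (both
configurable; a relaxed q of 0.1 suits smaller mutant comparisons).

## Structural arm

SASA is computed by Shrake–Rupley sphere sampling with a deterministic
golden-spiral point set (default 960 points/atom, probe 1.4 Å) and
normalised per residue by theoretical maximum accessibilities (Tien-style
table, configurable; values above 100% are not clipped). Interface
residues are those whose rSASA rises by strictly more than 25 percentage
points when their chain is computed in isolation versus in the full
oligomer. Peptides are mapped onto chains by exact sequence match (multiple
copies resolved by a seeded uniform choice, so runs are reproducible);
each peptide residue takes its minimum Cα–Cα distance to any interface
residue and the peptide score is the mean, with interface association at
2.6 Å (or the stringent 0.3 Å). When several structures cover a protein the
selection policy is `biggest` (most subunits), `random` (seeded), or
`best` — the structure maximising markers-inside + non-markers-outside the
cutoff, a deliberately simple agreement score isolated behind the policy
interface. ROC AUC treats interface association as the label and −log10 q
as the score, ties counting one half; confusion counts additionally use the
marker/interface mapping (marker at interface = TP, etc.).

## Network arm

The complex table induces an undirected, unweighted co-membership graph
(one clique per complex, deduplicated, no self-loops). Proteins with
changing interface markers seed a personalized PageRank: damping 0.9 is the
probability of following an edge, restart is uniform over the seeds, and
dangling mass returns to the restart vector, keeping the scores a
distribution. Nodes at or above the 60th score percentile are kept (top
40%, ties retained — deterministic and conservative), clustered with
walktrap at 4 steps cut at maximal modularity (isolated nodes become
singletons), and clusters with ≥4 subunits are named after the complex
contributing the most changing-marker proteins; co-equal complexes produce
a joined name, clusters with no marker-bearing complex fall back to largest
member overlap, else "unassigned". Condition comparison restricts both
datasets to regions detected in both, then classifies each cluster's marker
sets as shared / gain in either condition / divergent / none.

## Evidence analyses

Domain enrichment: peptides are assigned terms by interval overlap and each
term gets a one-sided Fisher exact test of markers versus the non-marker
background, BH across terms. Disorder: any-overlap flag per peptide,
percentages for significant vs nonsignificant sets, one-sided Fisher.
Mutation overlap: the fraction of curated interaction-disrupting mutation
sites inside markers extended by a 0- or 10-residue window; the null places
the same number of sites uniformly over the pooled residues of the same
proteins (length-weighted — the natural uniform model; the source data do
not specify a weighting). With the procedure's ten draws the smallest
empirical p is 1/11, so a normal-approximation p over the null draws is
reported alongside, and the draw count is configurable.

## AP–MS arm

Candidate interactors are filtered on externally supplied SAINT
probabilities (≥1.0), detection in 4/4 pull-down replicates, and mean
spectral count ≥4.5 — all boundaries inclusive. Intensities are normalised
jointly by total area sums. Per prey the statistic is the double ratio
(prey FLAG/non-FLAG over bait FLAG/non-FLAG), its error propagated from the
four replicate-level CVs, and the two treatments compared with
t = ΔR / sqrt((sd₁² + sd₂²)/3) referred to Student's t with four degrees of
freedom — the /3 pooling and the fixed df are implemented exactly as the
method defines them. Because the propagated sds use replicate-level CVs
(about twice the standard error of the underlying means at n = 4), the test
is strongly conservative: in a 4,000-prey null simulation at 10% CV no p
falls below 0.05 (minimum ≈ 0.07). p-values are two-sided with direction
carried by the sign of t; the bait's own row is the identity (R = 1, t = 0).

## Synthetic-data generator

The generator emulates the library experiment's structure: 4 fractions × 4
replicates (defaults), per-protein log-normal abundance (median 10⁶ area
units, ~0.3 log10 spread) with per-fraction log-normal offsets (0.2 log10),
peptide yields log-normal around 5% of protein signal, multiplicative
log-normal replicate noise with mean exactly 1 at 10% CV for both peptide
and protein channels, optional uniform missingness, and planted markers
that multiply the peptide/protein ratio by 2^log2FC in one named fraction —
exactly the signal the ratio statistic isolates, leaving protein abundance
untouched. Proteomes are uniform-composition random sequences (~10% K/R, so
tryptic peptides average ~10 residues); the digest cuts after every K/R (no
missed cleavages), adds semi-tryptic fragments at random PK sites nested in
their tryptic parents, and enforces the 6-residue floor.

Toy dimers are two Cα + pseudo-side-chain sphere traces (uniform 1.9 Å
radii, 3.8 Å spacing; side chains offset 3 Å toward the partner) running
parallel at 40 Å except over a central contact patch approached to 7 Å,
which buries ≈35 rSASA points per patch residue — comfortably above the
25-point threshold with a wide margin on both sides. Because the residues
are uniform spheres, toy structures use a uniform reference accessibility
(100 Å², the exposure of a fully solvent-facing mid-chain toy residue)
rather than residue-type maxima. Planted networks are one clique per
complex plus seeded random bridge edges.

What passing synthetic benchmarks does **not** show: real LiP data have
peptide-specific detectability, correlated missingness, fraction
cross-contamination, shared-peptide ambiguity and imperfect structural
ground truth (the original study's PDB-wide interface ROC AUCs were
0.54–0.71, far from the clean separation of planted dimers). The benchmarks
demonstrate correctness of the computations and recoverability of planted
signal under the stated noise model, not expected performance on biological
data.

## Benchmark problem sizes

Null calibration uses 2,000 peptides over a 160-protein proteome; marker
recovery plants 50 regions over 120 proteins; the structural benchmark uses
64-residue chains tiled by length-8 tryptic blocks (so the 12-residue patch
is always covered by legal digest products); network references use ≤10-node
graphs for the linear solve and 5-clique plantings for walktrap. These
sizes make every check a few seconds on one CPU while keeping the Monte
Carlo error of the measured rates well inside the asserted margins.
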