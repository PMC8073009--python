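# Methods

## Fitness from pooled competitions

Model: strains in a shared pool grow exponentially without interaction, so
the log2 ratio of two strains' UMI-collapsed barcode counts is linear in
the number of generations, with slope equal to the relative fitness
coefficient `s = λ_mut/λ_WT − 1`. Generations are counted on the wild-type
clock as `−log2(dilution factor)` per transfer (7.8 for the standard 70 µl
→ 16 ml protocol), summed over transfers; this approximation is good when
most strains grow near the wild-type rate.

Estimator: ordinary least squares on `(Tgen, log2 ratio)`. Timepoints with
a zero count in either strain are dropped and flagged rather than
pseudocounted. The per-point counting error is the Poisson propagation
`σ_r = (1/ln2)·√(1/N₁ + 1/N₂)`. Two interval summaries are reported: a
t-based 95% CI on the slope (default), and the min–max slope over 200
timepoint bootstrap resamples (resampling timepoints with replacement
respects the regression structure; degenerate resamples with a single
distinct timepoint are discarded). Both are exposed because the dashed
confidence bands in this kind of assay are sometimes drawn from either
convention; the t-based interval is the one whose coverage we verify
(95 ± 3% over 500 simulated pools).

Design precision: for `n_t` evenly spaced samplings spanning `Tgen_tot`
generations with iid log2-ratio noise `σ_log2r`, the exact OLS slope
standard error is

    σ_sLS = σ_log2r · sqrt(12 (n_t − 1) / (n_t (n_t + 1))) / Tgen_tot.

At (0.2, 5, 31.2) this gives 0.81%, i.e. sub-1% resolution — the design
point of the five-harvest, ~30-generation protocol. The precision audit
(`isogenic_precision`) estimates the realized σ_s from same-genotype
barcode pairs and defines the resolution as ±2σ_s. Control backgrounds are
removed by subtracting the mean control-genotype fitness per experiment.

The rescue-significance test draws `n_focal` values with replacement from
the background set and from the focal set, compares medians, and reports
the fraction of draws where the background median is more extreme — a
bootstrap-subsampling analogue of a one-sided location test for small,
unbalanced comparisons (e.g. 12 focal vs. 96 background pairwise
differences).

Cross-talk: spike-in count matrices over (PCR1 index × PCR2 index) are
split into inter-pool misassignment (reads in columns that never received
the spike-in, over total reads) and intra-pool misassignment (reads at
wrong rows within expected columns, over reads in those columns).

## Expression quantification and sectors

Per-gene density is the mean of the per-position track over the gene body
with 20 nt trimmed from each end (start/stop-proximal artifacts), strand
aware; rpkm normalizes by reads not mapping to rRNA/tRNA (the exclusion
list is configurable). Synthesis fractions are read shares
`d_i·L_i/Σ d_j·L_j`, which equal proteome mass fractions for a stable
proteome; stop-codon usage is the synthesis-fraction sum per stop (or stop
tetranucleotide), a flux-weighted usage rather than a gene count.

Sector calibrations are linear maps from transcriptome fraction ψ to
proteome fraction φ: `φ_R = α·ψ_R` with α ≈ 1.1 for translation proteins
(the regulon sum should exclude the perturbed release factors themselves),
and `φ = α·(ψ − ψ°) + φ°` with α ≈ 1.41 for the general-stress (sigB)
regulon, reflecting the higher average translation efficiency of induced
regulon mRNAs. Ectopic-construct proteome fractions multiply the wild-type
fraction by the measured mRNA fold-change and the construct's TE
fold-change (defaults 3.0 for RF2, 0.66 for RF1, 1.0 for PrmC — the
parsimonious assumption for a construct without its own TE calibration).

ΔCt quantification: technical replicates further than 0.2 Ct from their
nearest companion are dropped (nearest-neighbour rule, so one outlier
cannot drag down its consistent companions); a −RT minus +RT gap of ≤ 7 Ct
flags genomic-DNA contamination; levels are `2^(Ct_ref − Ct_target)` with
gyrA as the default loading reference and primer efficiency taken as 2.

Growth laws are fitted on relative growth rate (wild type = 1) against the
translation-sector fraction: translation line `λ = κ_t(φ_R − φ°)`,
nutrition line `λ = κ_n(φ_R^max − φ_R)`; the trajectory's slope sign
classifies which line a perturbation follows. Gratuitous expression of a
fraction φ_U is predicted under (i) the proportional model — all other
fractions compress by `1 − φ_U` and `Δs = −φ_U` — and (ii) a reconstructed
two-line growth-law model in which φ_U is subtracted from the allocatable
proteome (`φ_R^max → φ_R^max − φ_U`) and the new steady state is the
intersection of the two lines. The linear intersection is solved in closed
form and cross-checked against a numeric root find to < 1e−10; outputs are
labelled "growth-law model (reconstructed)". For typical fitted
parameters the growth-law prediction exceeds the proportional one in
magnitude, which is why an observed one-to-one (`Δs = −φ_U`) response is
the milder of the two.

## Termination stress metrics

Metagene traces: genes with mean footprint density ≥ 0.5 reads/nt and at
least twice the upstream window long are normalized by their mean density
over the first half of the gene (positions `[start, start + L/2)` in
transcription sense), aligned at the stop (offset 0 = last nt of the stop
codon), and summarized by the per-offset median — robust to any single
gene's rescaling, and to corruption of a minority of genes at an offset.
The window default is [−150, +60] nt (configurable; wide enough for ~5
queue periods).

Queue counting: successive local maxima on the ~25 nt period grid
(tolerance ±5 nt) count as stalled ribosomes while they exceed 2× the
baseline (median of the most-upstream third of the window); counting stops
at the first missing peak. This makes "queue length" a reproducible
integer; an excess-density integral is not reported because peak counting
proved sufficient and is easier to calibrate on synthetic tracks.

Readthrough: score = mean density over +5..+45 nt past the stop divided by
the edge-trimmed body density, computed only for isolated genes (nearest
co-directional neighbours > 55 bp away on both sides, overlaps counted as
negative distances) above 0.1 reads/nt. Scores > 1 are retained but
flagged (unannotated ORFs and repeats can inflate the window). Group
summaries are medians with interquartile ranges, by stop codon or stop
tetranucleotide; groups under 5 genes are flagged.

## Pair stoichiometry and the reshuffling null

Adjacent co-directional genes form pairs with signed transcription-sense
distance `d = right start − left end` (identical on either strand);
`d = −4` with an upstream UGA and the junction motif AUGA is the shared
start/stop punctuation class enabling translational coupling. Distance
stratification treats "within 30 bp" as `d ≤ 30` including overlaps.
Stoichiometry fold-changes `FC = (down/up)_perturbed / (down/up)_reference`
require strictly more than 10 reads in both genes in both conditions.

The reshuffling test permutes stop-codon labels across the analyzed pairs
(the natural exchangeable set is the distance- and coverage-filtered
subset, not the genome-wide list). The effect size is the ratio of the
focal class median FC to the UAA median FC; the p-value is the add-one
fraction of permutations with a strictly smaller (more pronounced) effect,
so exactly separated inputs give `p = 1/(1+n_perm)` and null p-values are
uniform on the permutation grid. The default permutation count is 1e5
(configurable upward when resolving very small p-values). The same test
applies to per-gene fold-changes normalized by the global median FC and
grouped by the gene's own stop.

Candidate operon calls cluster homolog hits by single linkage with a
permissive 100 bp start-to-end gap, require the full label set, optionally
enforce co-orientation and conserved transcription-sense order, and keep
one best call per species.

## Ribosome-traffic simulator

An open-boundary exclusion process with extended particles: ribosomes of
footprint ℓ = 10 codons (~30 nt, matching the observed ~25–30 nt queue
spacing) initiate at rate α when the entry window is clear (α is the
per-mRNA translation-efficiency proxy), advance at rate k when the site a
footprint ahead is clear, and terminate at the stop at rate β; an optional
competing reaction at rate γ carries the ribosome past the stop
(readthrough, default off). Events are simulated exactly
(continuous-time Gillespie); occupancy, queue length (contiguous ribosomes
stacked at the stop) and fluxes through the entry, midpoint and stop are
time-averaged after burn-in, and an absorbing configuration (e.g. β = 0
with a full lattice) is propagated to the end of the simulated window.
Only rate ratios matter; times are arbitrary units.

Two regimes matter for interpretation. While β stays above the
initiation-limited current, completion flux is unchanged by a termination
slowdown and queues stay short — the regime consistent with unchanged
expression of the stalled genes themselves (queues of a few ribosomes).
Occlusion of a downstream ORF is measured as the change in
downstream/upstream completion-flux ratio between the slow-β and
reference conditions; it falls below 1 only when the terminating
ribosome's footprint overlaps the downstream initiation window (e.g. the
−4 nt overlap, which maps to a 1-codon overlap after nt→codon rounding),
and it deepens with upstream initiation rate.

## Synthetic data: what it emulates, and what it does not

The generators produce every input format the analyzers consume, with
ground truth recorded: annotations with controlled stop-codon frequencies,
intergenic spacing (including a configurable fraction of −4 nt A-UGA
junctions written consistently into the genome sequence), strand runs and
lengths; competition count tables from exponential growth with Poisson
sampling, per-(strain, timepoint) lognormal technical noise (log2-s.d.
`σ_log2r/√2` so a pair's ratio has s.d. σ_log2r, matching the iid
assumption of the precision formula), and index cross-talk by uniform
reallocation within or across pools; footprint pileups with
phenomenological queue peaks (25 nt period, amplitude ∝ TE × (slowdown−1))
and downstream readthrough plateaus — or, mechanistically, occupancy
profiles from the traffic simulator; and condition series where a regulon
is induced along a φ_U grid under either proportional compression (all
other fractions × (1−φ_U)) or one-to-one compression (the translation
sector alone absorbs φ_U).

Inoculation is exactly 1:1 (optional jitter via the noise term); the
stated defaults are the study conditions: 7.8 generations per transfer,
5 harvests (~31 generations), σ_log2r = 0.2, ~1e5 UMIs per strain per
timepoint, basal sectors of 2% (general stress) and 35% (translation).

Not emulated: raw reads, PCR chemistry and sequencing errors, UMI
sequencing errors (collapse is exact-string), mRNA secondary structure or
codon-specific elongation, ribosome drop-off and collision-triggered
cleavage, transcription-unit structure beyond adjacent-gene spacing, and
growth-condition-dependent changes in total library composition. Passing
round-trip tests therefore demonstrates estimator correctness under the
declared noise model, not robustness to every artifact of real libraries.

## Numerical conventions and problem sizes

Coordinates are 0-based half-open internally; GFF3 I/O is 1-based closed;
bedGraph is 0-based half-open, one file per strand. Minus-strand genes are
processed on the reverse-complement axis so "first half", "downstream of
stop" and metagene offsets are always in transcription sense; a
reverse-complement involution test guards this. The center of an
even-length footprint is length/2 rounded down. Footprint-length filtering
(14–44 nt) and center mapping are upstream of this package and carried as
track metadata.

Test and acceptance problem sizes are chosen to keep the default suite in
the tens of seconds while leaving Monte-Carlo error well inside each
tolerance: 10,000 replicates for the design-precision check, 500 pools for
slope-scatter and CI coverage, 2,000 simulated pair sets (199 permutations
each, exact-test rejection at p ≤ α) for null calibration, 10 replicate
datasets of 300 pairs for the injected-effect recovery, 300-gene
annotations for expression/termination round trips, and traffic
simulations of 300–3,000 time units. Larger sizes change none of the
conclusions, only the Monte-Carlo error.
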