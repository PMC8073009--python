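# ribofit

Analyses for bacterial expression–fitness landscape studies: high-precision
relative fitness from pooled barcoded competitions, proteome-sector
quantification with growth-law compression predictions, and
translation-termination stress metrics from ribosome profiling — together
with synthetic-data generators and a stochastic ribosome-traffic simulator
so every stage can be validated offline against known ground truth.

## Who this is for

Groups measuring how perturbing a gene's expression level propagates to
growth rate in bacteria: pooled Bar-seq-style competitions read out by
UMI-collapsed barcode amplicon counts, matched RNA-seq / ribosome-profiling
expression quantification, and mechanistic follow-up on translation
termination (release-factor depletion, stop-codon-specific ribosome queues,
readthrough, operon stoichiometry).

## The statistics at the core

- **Relative fitness.** In exponential pooled growth the log2 barcode-count
  ratio of a strain pair obeys `log2 R_mut/R_WT = const + s·Tgen`, with
  `Tgen = −log2(dilution factor)` accumulated per transfer. `s` is the OLS
  slope; per-point Poisson error is `σ_r = (1/ln2)·√(1/N₁+1/N₂)`; a
  timepoint bootstrap gives `(s_min, s_max)`. For `n_t` even samplings over
  `Tgen_tot` generations with iid log2-ratio noise `σ`, the slope s.d. is
  `σ_sLS = σ·√(12(n_t−1)/(n_t(n_t+1)))/Tgen_tot` — about 0.8% for
  (σ=0.2, n_t=5, ≈31 generations), i.e. sub-1% fitness resolution.
- **Sectors and growth laws.** Per-gene synthesis fractions
  `f_i = d_i·L_i/Σd_j·L_j` from edge-trimmed footprint density; regulon
  fractions by summation; transcriptome→proteome calibrations
  `φ_R = 1.1·ψ_R` and `φ = 1.41·(ψ−ψ°)+φ°` (general-stress regulon);
  translation line `λ = κ_t(φ_R−φ°)` and nutrition line
  `λ = κ_n(φ_R^max−φ_R)`, with gratuitous-expression predictions
  `φ_R → φ_R(1−φ_U)`, `Δs = −φ_U` (proportional) or the two-line steady
  state with `φ_R^max → φ_R^max−φ_U` (growth-law model, reconstructed).
- **Termination stress.** Stop-aligned metagene traces (median of
  first-half-normalized density), queue counting on a ~25 nt period grid,
  readthrough score = density(+5..+45 nt past stop)/body density, and the
  stop-codon reshuffling test on downstream/upstream stoichiometry
  fold-changes: effect = median FC(focal)/median FC(UAA),
  `p = (1+#{perm < obs})/(1+n_perm)`.
- **Ribosome traffic.** An open-boundary exclusion process (footprint 10
  codons) reproduces stop-specific queues, their growth with translation
  efficiency, and occlusion of downstream initiation at overlapping
  start/stop junctions.

## Worked example

```python
import ribofit as rf

design = rf.SimDesign(n_strains=3, true_s=[0.0, -0.03, 0.01], depth=1e5,
                      sigma_log2r=0.2, seed=7)
counts, truth = rf.gen_competition_counts(design)
for bc, s_true in zip(truth["barcode"], truth["true_s"]):
    if bc == "bc000":
        continue
    traj = rf.ratio_trajectory(counts, bc, "bc000")
    est = rf.fit_relative_fitness(traj, n_boot=200, seed=0)
    print(f"{bc}: s = {est.s:+.4f}  (true {s_true:+.3f}), "
          f"bootstrap range [{est.boot_range[0]:+.4f}, {est.boot_range[1]:+.4f}]")
print(f"design precision: {rf.design_precision(rf.DesignParams(0.2, 5, 31.2)):.4f}")
```

prints

```
bc001: s = -0.0368  (true -0.030), bootstrap range [-0.0907, -0.0023]
bc002: s = +0.0030  (true +0.010), bootstrap range [-0.0137, +0.0322]
design precision: 0.0081
```

Each strain is compared with the wild-type barcode over five harvests
(~31 generations); the fitted slopes recover the injected fitness within
the expected single-pool scatter, and the closed-form design precision
(0.81% per pair) says how much scatter to expect.

A command-line layer mirrors the library:
`ribofit simulate | fitness | expression | qpcr | sectors | termination |
pairs | operonscan | queuesim` (see `--help` on each).

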