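"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (fitness inference, expression
quantification, sector physiology, termination metrics, pair stoichiometry)
can be exercised offline on data produced here: gene annotations with
controlled stop codons and intergenic spacing, barcoded pooled-competition
count tables from exponential growth, ribosome-footprint pileups with
stop-proximal queues and readthrough, and condition series with regulon
induction and proteome compression. Each generator records the injected
truth alongside its output and is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation, STOP_CODONS, _rna_to_dna
from .pileup import PileupTrack

_NT = np.array(list("ACGT"))


# ============================================================ configurations
@dataclass
class SimDesign:
    """Design of a pooled-competition experiment.

    ``sigma_log2r`` is the s.d. of the log2 ratio of a strain pair; it is
    realized as independent lognormal multiplicative noise per
    (strain, timepoint) with log2-s.d. sigma_log2r / sqrt(2), so that the
    difference of two strains' log-counts has the stated s.d. (the iid
    assumption behind the closed-form design precision).
    """

    n_strains: int
    true_s: np.ndarray | list
    generations_per_transfer: float = 7.8
    n_timepoints: int = 5
    depth: float = 1e5  # expected UMI count per strain per timepoint
    sigma_log2r: float = 0.2
    crosstalk_intra: float = 0.0
    crosstalk_inter: float = 0.0
    poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_s = np.asarray(self.true_s, dtype=float)
        if len(self.true_s) != self.n_strains:
            raise ValueError("true_s must have one entry per strain")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_timepoints < 2:
            raise ValueError("need at least two timepoints")
        for p in (self.crosstalk_intra, self.crosstalk_inter):
            if not (0 <= p < 1):
                raise ValueError("cross-talk probabilities must be in [0, 1)")


@dataclass
class SimAnnotationConfig:
    n_genes: int = 200
    mean_length: float = 900.0  # nt; lognormal spread around this
    length_sigma: float = 0.35  # s.d. of log length
    min_length: int = 60
    stop_freqs: dict = field(default_factory=lambda: {"UAA": 0.888, "UAG": 0.064, "UGA": 0.049})
    mean_gap: float = 80.0
    sd_gap: float = 50.0
    min_gap: int = 1
    frac_codirectional: float = 0.75
    frac_a_uga: float = 0.07  # among co-directional pairs
    frac_other_overlap: float = 0.0  # among co-directional pairs
    chrom: str = "chrSim"
    chrom_length: int | None = None  # declared cap; error if packing exceeds
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.stop_freqs.get(c, 0.0) for c in STOP_CODONS)
        if abs(total - 1.0) > 0.01:
            raise ValueError("stop-codon frequencies must sum to 1")
        self.stop_freqs = {c: self.stop_freqs.get(c, 0.0) / total for c in STOP_CODONS}
        if self.min_length < 60:
            raise ValueError("gene lengths must be at least 60 nt")


@dataclass
class SimProfileConfig:
    """Phenomenological footprint-pileup model.

    Per-gene mean density is proportional to translation efficiency (TE).
    Stops whose termination ``slowdown`` exceeds 1 get periodic queue peaks
    (spacing ``queue_period`` nt, amplitude (slowdown - 1) x TE) upstream of
    the stop; a readthrough plateau of the stated fraction of the body
    density extends downstream of the stop.
    """

    te_mean: float = 3.0  # reads/nt at TE = 1 scale
    te_sigma: float = 0.8  # lognormal s.d. of log TE
    slowdown: dict = field(default_factory=lambda: {c: 1.0 for c in STOP_CODONS})
    readthrough: dict = field(default_factory=lambda: {c: 0.0 for c in STOP_CODONS})
    queue_period: float = 25.0
    n_queue_peaks: int = 3
    peak_width: int = 5
    readthrough_window: int = 45
    noise: str | None = "poisson"  # None for noiseless densities
    seed: int = 0

    def __post_init__(self) -> None:
        if self.queue_period <= 0:
            raise ValueError("queue period must be positive")
        for c, f in self.readthrough.items():
            if not (0 <= f <= 1):
                raise ValueError(f"readthrough fraction for {c} must be in [0, 1]")
        for c, sl in self.slowdown.items():
            if sl < 1:
                raise ValueError(f"termination slowdown for {c} must be >= 1")


# =========================================================== gen_annotation
def gen_annotation(config: SimAnnotationConfig) -> tuple[GeneAnnotation, dict]:
    """Generate a strand-aware annotation plus a consistent genome sequence.

    Genes are placed left to right along one chromosome; adjacent genes are
    co-directional with probability ``frac_codirectional``. Among
    co-directional pairs, a fraction ``frac_a_uga`` is placed in the -4 nt
    start/stop overlap configuration (upstream stop forced to UGA, junction
    motif ATGA) and ``frac_other_overlap`` at other negative spacings;
    remaining gaps are drawn from a truncated normal. Returns
    ``(annotation, genome)`` where genome maps chromosome -> DNA string with
    the annotated stop codons written in.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    stops = rng.choice(
        STOP_CODONS, size=n, p=[config.stop_freqs.get(c, 0.0) for c in STOP_CODONS]
    )
    lengths = np.exp(rng.normal(np.log(config.mean_length), config.length_sigma, size=n))
    lengths = np.maximum((lengths // 3).astype(int) * 3, config.min_length)

    strands = np.empty(n, dtype="<U1")
    strands[0] = rng.choice(["+", "-"])
    for i in range(1, n):
        if rng.random() < config.frac_codirectional:
            strands[i] = strands[i - 1]
        else:
            strands[i] = "-" if strands[i - 1] == "+" else "+"

    # genomic gap between gene i-1 end and gene i start (transcription-sense
    # spacing equals this genomic gap for co-directional pairs on either strand)
    gaps = np.empty(n, dtype=int)
    gaps[0] = 200  # left flank
    a_uga_pair = np.zeros(n, dtype=bool)
    overlap_choices = [d for d in range(-20, 0) if d != -4]
    for i in range(1, n):
        codir = strands[i] == strands[i - 1]
        u = rng.random()
        if codir and u < config.frac_a_uga:
            gaps[i] = -4
            a_uga_pair[i] = True
            # upstream gene in transcription sense: left gene on "+", right on "-"
            if strands[i] == "+":
                stops[i - 1] = "UGA"
            else:
                stops[i] = "UGA"
        elif codir and u < config.frac_a_uga + config.frac_other_overlap:
            gaps[i] = int(rng.choice(overlap_choices))
        else:
            g = int(round(rng.normal(config.mean_gap, config.sd_gap)))
            gaps[i] = max(g, config.min_gap if codir else max(config.min_gap, 1))

    starts = np.empty(n, dtype=int)
    ends = np.empty(n, dtype=int)
    pos = 0
    for i in range(n):
        pos += gaps[i]
        starts[i] = pos
        ends[i] = pos + lengths[i]
        pos = ends[i]
    chrom_len = int(ends[-1] + 200)
    if config.chrom_length is not None:
        if chrom_len > config.chrom_length:
            raise ValueError(
                f"cannot pack {n} genes into declared chromosome length "
                f"{config.chrom_length} (need {chrom_len})"
            )
        chrom_len = config.chrom_length

    seq = rng.choice(_NT, size=chrom_len)
    for i in range(n):
        codon_dna = _rna_to_dna(stops[i])
        if strands[i] == "+":
            seq[ends[i] - 3 : ends[i]] = list(codon_dna)
        else:
            rc = codon_dna[::-1].translate(str.maketrans("ACGT", "TGCA"))
            seq[starts[i] : starts[i] + 3] = list(rc)
    # write the overlapping ATG start for A-UGA junctions (consistent with
    # the already-written UGA stop: motif ATGA / reverse complement TCAT)
    for i in np.flatnonzero(a_uga_pair):
        if strands[i] == "+":
            seq[starts[i]] = "A"  # downstream ATG; stop TGA occupies the next 3 nt
        else:
            seq[ends[i - 1] - 1] = "T"  # reverse-complement junction (motif TCAT)
    genome = {config.chrom: "".join(seq)}

    df = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n)],
            "chrom": config.chrom,
            "strand": strands,
            "start": starts,
            "end": ends,
            "gene_class": "mRNA",
            "stop_codon": stops,
            "stop_tetra": "",
            "regulons": "",
        }
    )
    ann = GeneAnnotation(df, chrom_sizes={config.chrom: chrom_len})
    ann.verify_stop_codons(genome)  # fills in stop tetranucleotides
    return ann, genome


# ==================================================== gen_competition_counts
def gen_competition_counts(design: SimDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate UMI-collapsed barcode counts for one pooled competition.

    Strain frequencies follow exponential pooled growth,
    f_i(t) proportional to f_i(0) * 2**(s_i * Tgen(t)), renormalized to the
    pool; counts are Poisson around depth-scaled frequencies (or exact
    expectations when ``poisson=False``), then multiplied by lognormal
    technical noise and optionally reallocated by index cross-talk.
    Returns ``(counts, truth)``.
    """
    d = design
    rng = np.random.default_rng(d.seed)
    tgen = np.arange(d.n_timepoints) * d.generations_per_transfer
    f0 = np.full(d.n_strains, 1.0 / d.n_strains)
    total_depth = d.depth * d.n_strains

    rows = []
    for ti, t in enumerate(tgen):
        w = f0 * np.power(2.0, d.true_s * t)
        f = w / w.sum()
        mean = total_depth * f
        if d.sigma_log2r > 0:
            log2_noise = rng.normal(0.0, d.sigma_log2r / np.sqrt(2.0), size=d.n_strains)
            mean = mean * np.power(2.0, log2_noise)
        if d.poisson:
            counts = rng.poisson(mean).astype(float)
        else:
            counts = mean
        rows.append(counts)
    mat = np.array(rows)  # (timepoint, strain)

    if d.crosstalk_intra > 0 and d.poisson:
        mat = _reallocate(mat, d.crosstalk_intra, axis=1, rng=rng)
    if d.crosstalk_inter > 0 and d.poisson:
        mat = _reallocate(mat, d.crosstalk_inter, axis=0, rng=rng)

    recs = []
    for ti in range(d.n_timepoints):
        for i in range(d.n_strains):
            recs.append(
                {
                    "experiment": "sim",
                    "condition": "c0",
                    "timepoint": ti,
                    "generations": tgen[ti],
                    "barcode": f"bc{i:03d}",
                    "genotype": f"geno{i:03d}",
                    "count": mat[ti, i],
                }
            )
    counts = pd.DataFrame(recs)
    truth = pd.DataFrame(
        {"barcode": [f"bc{i:03d}" for i in range(d.n_strains)], "true_s": d.true_s}
    )
    return counts, truth


def _reallocate(mat: np.ndarray, p: float, axis: int, rng) -> np.ndarray:
    """Move a Binomial(count, p) share of each cell to uniformly random other
    cells along ``axis`` (index misassignment); totals are conserved."""
    out = mat.copy()
    n_t, n_s = mat.shape
    if axis == 1:  # within a timepoint (intra-pool): to other barcodes
        for ti in range(n_t):
            for i in range(n_s):
                moved = rng.binomial(int(out[ti, i]), p)
                if moved:
                    out[ti, i] -= moved
                    targets = rng.integers(0, n_s - 1, size=moved)
                    targets[targets >= i] += 1
                    np.add.at(out[ti], targets, 1.0)
    else:  # across timepoints/pools (inter-pool)
        for ti in range(n_t):
            for i in range(n_s):
                moved = rng.binomial(int(out[ti, i]), p)
                if moved:
                    out[ti, i] -= moved
                    targets = rng.integers(0, n_t - 1, size=moved)
                    targets[targets >= ti] += 1
                    np.add.at(out[:, i], targets, 1.0)
    return out


# ================================================================ gen_pileup
def gen_pileup(
    ann: GeneAnnotation,
    profile: SimProfileConfig,
    te: dict | None = None,
) -> tuple[PileupTrack, pd.DataFrame]:
    """Footprint pileup with injected queues and readthrough (peak injection).

    ``te`` optionally fixes per-gene translation efficiencies (gene_id ->
    reads/nt); otherwise TEs are drawn lognormally. For a mechanistic
    alternative see :mod:`ribofit.tasep`, which produces occupancy profiles
    from an exclusion process instead of injected peaks.
    """
    rng = np.random.default_rng(profile.seed)
    counts = {
        (chrom, strand): np.zeros(size)
        for chrom, size in ann.chrom_sizes.items()
        for strand in "+-"
    }
    truth_rows = []
    for row in ann.genes.itertuples():
        L = row.end - row.start
        gene_te = (
            te[row.gene_id]
            if te is not None
            else float(np.exp(rng.normal(np.log(profile.te_mean), profile.te_sigma)))
        )
        dens = np.zeros(L + profile.readthrough_window)  # transcription sense
        dens[:L] = gene_te
        slow = profile.slowdown.get(row.stop_codon, 1.0)
        n_peaks = 0
        if slow > 1:
            n_peaks = profile.n_queue_peaks
            half = profile.peak_width // 2
            for k in range(n_peaks):
                c = L - 2 - int(round(k * profile.queue_period))  # middle nt of stop, then upstream
                lo, hi = max(c - half, 0), min(c + half + 1, L)
                dens[lo:hi] += (slow - 1.0) * gene_te
        rt = profile.readthrough.get(row.stop_codon, 0.0)
        if rt > 0:
            dens[L : L + profile.readthrough_window] += rt * gene_te
        if profile.noise == "poisson":
            dens = rng.poisson(dens).astype(float)
        vec = counts[(row.chrom, row.strand)]
        if row.strand == "+":
            lo, hi = row.start, min(row.start + len(dens), len(vec))
            vec[lo:hi] += dens[: hi - lo]
        else:
            hi, lo = row.end, max(row.end - len(dens), 0)
            vec[lo:hi] += dens[: hi - lo][::-1]
        truth_rows.append(
            {
                "gene_id": row.gene_id,
                "te": gene_te,
                "stop_codon": row.stop_codon,
                "slowdown": slow,
                "readthrough": rt,
                "n_queue_peaks": n_peaks,
            }
        )
    track = PileupTrack(counts, mapping_mode="center", meta={"simulated": True})
    return track, pd.DataFrame(truth_rows)


# ======================================================= gen_condition_series
def make_base_expression(
    n_genes: int = 400,
    sigb_frac: float = 0.02,
    translation_frac: float = 0.35,
    n_sigb: int = 40,
    n_translation: int = 80,
    total_reads: float = 1e6,
    seed: int = 0,
) -> pd.DataFrame:
    """Basal per-gene synthesis table with sigB / translation regulon labels.

    Basal sector sizes default to the wild-type picture: ~2% of synthesis to
    the general-stress (sigB) regulon and ~35% to translation proteins.
    """
    rng = np.random.default_rng(seed)
    weights = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    labels = np.array([""] * n_genes, dtype=object)
    labels[:n_sigb] = "sigB"
    labels[n_sigb : n_sigb + n_translation] = "translation"
    for label, frac in (("sigB", sigb_frac), ("translation", translation_frac)):
        m = labels == label
        weights[m] *= frac / weights[m].sum()
    rest = labels == ""
    weights[rest] *= (1.0 - sigb_frac - translation_frac) / weights[rest].sum()
    lengths = np.maximum((np.exp(rng.normal(np.log(900), 0.3, n_genes)) // 3) * 3, 60)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "length": lengths.astype(int),
            "reads": weights * total_reads,
            "regulons": labels,
        }
    )


def gen_condition_series(
    base: pd.DataFrame,
    phi_u_grid,
    compression: str = "proportional",
    noise_sd: float = 0.0,
    alpha_sigb: float = 1.41,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Condition series with graded regulon induction and sector compression.

    For each excess gratuitous fraction phi_U in ``phi_u_grid``:

    - ``compression='proportional'``: every non-regulon fraction scales by
      (1 - phi_U); the regulon takes up 1 - (1 - f0)(1 - phi_U).
    - ``compression='one_to_one'``: the regulon gains exactly phi_U and the
      translation sector alone absorbs it (phi_R -> phi_R - phi_U), other
      fractions unchanged.

    Relative growth rate truth is 1 - phi_U in both models. Multiplicative
    lognormal noise of log2-s.d. ``noise_sd`` is applied per gene when
    requested. Returns ``(tables, truths)``; truths also record the
    transcriptome fraction psi implied by the linear sigB calibration with
    slope ``alpha_sigb``.
    """
    phi_u_grid = np.asarray(list(phi_u_grid), dtype=float)
    if np.any(phi_u_grid < 0) or np.any(phi_u_grid > 0.5):
        raise ValueError("phi_U grid must lie within [0, 0.5]")
    rng = np.random.default_rng(seed)
    labels = base["regulons"].to_numpy()
    w0 = base["reads"].to_numpy(dtype=float)
    f0 = w0 / w0.sum()
    sig = labels == "sigB"
    trn = labels == "translation"
    f_sig0 = f0[sig].sum()
    f_trn0 = f0[trn].sum()

    tables, truths = [], []
    for ci, phi_u in enumerate(phi_u_grid):
        f = f0.copy()
        if compression == "proportional":
            f[~sig] = f0[~sig] * (1.0 - phi_u)
            f_sig = 1.0 - (1.0 - f_sig0) * (1.0 - phi_u)
            f[sig] = f0[sig] * f_sig / f_sig0
            phi_r = f_trn0 * (1.0 - phi_u)
        elif compression == "one_to_one":
            if phi_u >= f_trn0:
                raise ValueError("phi_U exceeds the translation sector under one_to_one")
            f_sig = f_sig0 + phi_u
            f[sig] = f0[sig] * f_sig / f_sig0
            f[trn] = f0[trn] * (f_trn0 - phi_u) / f_trn0
            phi_r = f_trn0 - phi_u
        else:
            raise ValueError(f"unknown compression model {compression!r}")
        reads = f * w0.sum()
        if noise_sd > 0:
            reads = reads * np.power(2.0, rng.normal(0.0, noise_sd, size=len(reads)))
        tab = base.copy()
        tab["reads"] = reads
        tab["condition"] = f"c{ci}"
        tables.append(tab)
        truths.append(
            {
                "condition": f"c{ci}",
                "phi_u": phi_u,
                "phi_sigb": f_sig,
                "phi_r": phi_r,
                "rel_growth": 1.0 - phi_u,
                "psi_sigb": f_sig0 + (f_sig - f_sig0) / alpha_sigb,
                "psi_sigb_basal": f_sig0,
                "phi_sigb_basal": f_sig0,
            }
        )
    return tables, pd.DataFrame(truths)
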