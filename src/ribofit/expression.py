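"""Per-gene expression quantification and proteome-sector calibration.

Turns pileup tracks into edge-trimmed gene densities and rpkm (normalized by
reads not mapping to rRNA/tRNA), proteome synthesis fractions, regulon
transcriptome/proteome fractions with the linear sector calibrations,
translation efficiencies, flux-weighted stop-codon usage, and delta-Ct
RT-qPCR quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation, STOP_CODONS
from .pileup import PileupTrack

DEFAULT_EXCLUDE_CLASSES = ("rRNA", "tRNA")


@dataclass
class CalibrationModel:
    """Linear transcriptome-to-proteome sector calibrations.

    phi_R = alpha_translation * psi_R for the translation sector, and
    phi = alpha_sigb * (psi - psi0) + phi0 for the general-stress (sigB)
    sector; TE fold-changes for the ectopic release-factor constructs are
    carried for the corrected proteome-fraction conversion.
    """

    alpha_translation: float = 1.1
    alpha_sigb: float = 1.41
    psi0_sigb: float = 0.02
    phi0_sigb: float = 0.02
    te_foldchange: dict = field(
        default_factory=lambda: {"RF2": 3.0, "RF1": 0.66, "PrmC": 1.0}
    )

    def __post_init__(self) -> None:
        if self.alpha_translation <= 0 or self.alpha_sigb <= 0:
            raise ValueError("calibration slopes must be positive")


# ------------------------------------------------------------ gene density
def gene_density(
    track: PileupTrack,
    ann: GeneAnnotation,
    edge_trim: int = 20,
    exclude_classes=DEFAULT_EXCLUDE_CLASSES,
) -> pd.DataFrame:
    """Edge-trimmed mean density and rpkm per gene.

    Density is the mean of the per-position track over
    [start + edge_trim, end - edge_trim) in transcription sense; rpkm is
    normalized by the total reads NOT mapping to genes of the excluded
    classes (rRNA/tRNA by default). Genes shorter than 2 x edge_trim are
    excluded with a flag.
    """
    excluded_reads = 0.0
    for row in ann.genes.itertuples():
        if row.gene_class in exclude_classes:
            excluded_reads += track.gene_profile(row).sum()
    total = track.total_reads() - excluded_reads

    rows = []
    for row in ann.genes.itertuples():
        L = row.end - row.start
        if L <= 2 * edge_trim:
            rows.append(
                {
                    "gene_id": row.gene_id,
                    "length": L,
                    "reads": np.nan,
                    "density": np.nan,
                    "rpkm": np.nan,
                    "flag": "too_short",
                }
            )
            continue
        prof = track.gene_profile(row)[edge_trim : L - edge_trim]
        reads = float(prof.sum())
        dens = reads / len(prof)
        rpkm = (reads / (len(prof) / 1e3)) / (total / 1e6) if total > 0 else np.nan
        rows.append(
            {
                "gene_id": row.gene_id,
                "length": L,
                "reads": reads,
                "density": dens,
                "rpkm": rpkm,
                "flag": "" if row.gene_class not in exclude_classes else "excluded_class",
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["total_reads"] = total
    return out


# ------------------------------------------------------ synthesis fraction
def synthesis_fraction(expr: pd.DataFrame) -> pd.Series:
    """Per-gene proteome synthesis fraction.

    fraction_i = density_i * length_i / sum_j density_j * length_j, i.e. the
    gene's share of trimmed-body reads; equals the proteome mass fraction
    for a stable proteome. Excluded-class and flagged genes contribute 0.
    """
    reads = expr["reads"].to_numpy(dtype=float).copy()
    if "flag" in expr.columns:
        reads[(expr["flag"] != "").to_numpy()] = 0.0
    reads = np.nan_to_num(reads)
    total = reads.sum()
    if total <= 0:
        raise ValueError("no usable reads for synthesis fractions")
    return pd.Series(reads / total, index=expr["gene_id"], name="synthesis_fraction")


def regulon_fraction(fractions: pd.Series, members) -> tuple[float, list]:
    """Summed fraction over regulon members; reports members absent from the table."""
    members = list(members)
    present = [g for g in members if g in fractions.index]
    missing = [g for g in members if g not in fractions.index]
    return float(fractions.loc[present].sum()), missing


# ----------------------------------------------------------- calibrations
def calibrate_sector(psi: float, model: CalibrationModel, sector: str) -> float:
    """Proteome fraction phi from transcriptome fraction psi.

    translation: phi_R = alpha_translation * psi_R (the regulon sum is
    expected to exclude RF1/RF2/PrmC); sigB: phi = alpha_sigb * (psi - psi0)
    + phi0.
    """
    if sector == "translation":
        return model.alpha_translation * psi
    if sector == "sigB":
        return model.alpha_sigb * (psi - model.psi0_sigb) + model.phi0_sigb
    raise ValueError(f"unknown sector {sector!r}")


def invert_sector(phi: float, model: CalibrationModel, sector: str) -> float:
    """Inverse of :func:`calibrate_sector` (exact round trip)."""
    if sector == "translation":
        return phi / model.alpha_translation
    if sector == "sigB":
        return (phi - model.phi0_sigb) / model.alpha_sigb + model.psi0_sigb
    raise ValueError(f"unknown sector {sector!r}")


def translation_efficiency(footprint_rpkm, mrna_rpkm):
    """TE = footprint rpkm / mRNA rpkm; NaN (flagged) where mRNA rpkm is 0."""
    fp = np.asarray(footprint_rpkm, dtype=float)
    mr = np.asarray(mrna_rpkm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(mr > 0, fp / mr, np.nan)
    return float(te) if np.isscalar(footprint_rpkm) else te


def corrected_proteome_fraction(
    wt_fraction: float, mrna_foldchange: float, te_foldchange: float
) -> float:
    """Calibrated proteome fraction of an ectopic construct.

    Wild-type proteome fraction x mRNA-level fold-change x TE fold-change.
    """
    return wt_fraction * mrna_foldchange * te_foldchange


# ------------------------------------------------------------- stop usage
def stop_usage(
    fractions: pd.Series, ann: GeneAnnotation, by: str = "stop_codon"
) -> pd.Series:
    """Flux-weighted stop-codon (or tetranucleotide) usage.

    usage_c = sum of synthesis fractions of genes ending with c; renormalized
    over the genes present so the usage sums to 1.
    """
    key = ann.genes.set_index("gene_id")[by]
    df = pd.DataFrame({"fraction": fractions}).join(key, how="inner")
    usage = df.groupby(by)["fraction"].sum()
    if by == "stop_codon":
        usage = usage.reindex(list(STOP_CODONS), fill_value=0.0)
    total = usage.sum()
    if total <= 0:
        raise ValueError("no synthesis flux to attribute to stop codons")
    return usage / total


# ------------------------------------------------------------------- qPCR
def qpcr_relative_level(
    ct: pd.DataFrame,
    reference_target: str = "gyrA",
    outlier_ct: float = 0.2,
    min_no_rt_gap: float = 7.0,
) -> pd.DataFrame:
    """Relative mRNA levels from Ct tables, 2**(Ct_ref - Ct_target).

    ``ct`` has columns sample/target/ct for technical replicates, plus
    optionally ``no_rt_ct`` (the -RT control Ct, may repeat across rows).
    Replicates lying more than ``outlier_ct`` from their nearest companion
    replicate are dropped; samples whose -RT minus +RT Ct gap is at most
    ``min_no_rt_gap`` are flagged.
    """
    rows = []
    for (sample, target), grp in ct.groupby(["sample", "target"]):
        vals = grp["ct"].to_numpy(dtype=float)
        keep = _drop_ct_outliers(vals, outlier_ct)
        mean_ct = float(vals[keep].mean())
        flag = ""
        if "no_rt_ct" in grp.columns and grp["no_rt_ct"].notna().any():
            gap = float(grp["no_rt_ct"].dropna().iloc[0]) - mean_ct
            if gap <= min_no_rt_gap:
                flag = "no_rt_gap"
        rows.append(
            {
                "sample": sample,
                "target": target,
                "mean_ct": mean_ct,
                "n_used": int(keep.sum()),
                "n_dropped": int((~keep).sum()),
                "flag": flag,
            }
        )
    res = pd.DataFrame(rows)
    out = []
    for sample, grp in res.groupby("sample"):
        ref = grp.loc[grp["target"] == reference_target, "mean_ct"]
        if ref.empty:
            raise ValueError(f"no {reference_target} reference Ct for sample {sample}")
        ref_ct = float(ref.iloc[0])
        for r in grp.itertuples():
            if r.target == reference_target:
                continue
            out.append(
                {
                    "sample": sample,
                    "target": r.target,
                    "relative_level": 2.0 ** (ref_ct - r.mean_ct),
                    "mean_ct": r.mean_ct,
                    "n_dropped": r.n_dropped,
                    "flag": r.flag,
                }
            )
    return pd.DataFrame(out)


def _drop_ct_outliers(vals: np.ndarray, threshold: float) -> np.ndarray:
    """Keep replicates whose nearest other replicate is within ``threshold`` Ct."""
    n = len(vals)
    if n <= 1:
        return np.ones(n, dtype=bool)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        others = np.abs(np.delete(vals, i) - vals[i])
        if others.min() > threshold:
            keep[i] = False
    if not keep.any():  # mutually inconsistent triplet: keep the closest pair
        keep = np.ones(n, dtype=bool)
    return keep
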