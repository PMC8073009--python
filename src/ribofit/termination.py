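"""Translation-termination stress metrics from footprint pileups.

Stop-aligned metagene traces (median of gene-normalized density), ribosome
queue counting on the ~25 nt period grid, per-gene readthrough scores
(downstream-window over gene-body density), and stop-codon /
tetranucleotide stratifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation, STOP_CODONS
from .pileup import PileupTrack


@dataclass
class MetageneTrace:
    """Median gene-normalized density aligned at the stop codon.

    Offset 0 is the last nt of the stop codon; negative offsets are
    upstream (inside the gene) in transcription sense.
    """

    stop_class: str
    offsets: np.ndarray
    median: np.ndarray
    n_genes: int

    def value_at(self, offset: int) -> float:
        idx = int(offset - self.offsets[0])
        return float(self.median[idx])


# ------------------------------------------------------------- metagene
def metagene_stop_profile(
    track: PileupTrack,
    ann: GeneAnnotation,
    min_density: float = 0.5,
    window: tuple[int, int] = (-150, 60),
    by: str = "stop_codon",
) -> dict[str, MetageneTrace]:
    """Stop-aligned metagene traces per stop class.

    Genes expressed to at least ``min_density`` reads/nt (mean over the
    gene) and at least twice the upstream window long are retained; each
    gene's trace is normalized by its mean density over the first half of
    the gene, aligned at the stop (offset 0 = last nt of the stop codon),
    and the per-offset median across genes is reported.
    """
    lo, hi = window
    per_class: dict[str, list[np.ndarray]] = {}
    for row in ann.genes.itertuples():
        L = row.end - row.start
        if L < 2 * abs(lo):
            continue
        prof = track.gene_profile(row, downstream=hi)
        body = prof[:L]
        if body.mean() < min_density:
            continue
        norm = body[: L // 2].mean()
        if norm <= 0:
            continue
        # transcription-sense index of the stop's last nt is L - 1
        seg = prof[L - 1 + lo : L - 1 + hi + 1] / norm
        if len(seg) != hi - lo + 1:
            continue
        per_class.setdefault(getattr(row, by), []).append(seg)

    offsets = np.arange(lo, hi + 1)
    traces = {}
    for cls, segs in per_class.items():
        arr = np.vstack(segs)
        traces[cls] = MetageneTrace(cls, offsets, np.median(arr, axis=0), len(segs))
    return traces


# ---------------------------------------------------------- queue metric
def queue_metric(
    trace: MetageneTrace,
    period: float = 25.0,
    threshold: float = 2.0,
    tolerance: int = 5,
) -> dict:
    """Count stalled-ribosome peaks on the period grid upstream of the stop.

    Successive peaks are sought at offsets ~ -k * period (k = 0, 1, ...)
    within +/- ``tolerance`` nt; a peak counts if its local maximum exceeds
    ``threshold`` times the baseline (median of the most-upstream third of
    the window, which is flat when no queue extends that far). Counting
    stops at the first missing peak. Returns the queue length (count) and
    the peak amplitudes.
    """
    offsets, med = trace.offsets, trace.median
    span = offsets[-1] - offsets[0]
    if span < 2 * period:
        raise ValueError("trace must span at least two queue periods")
    flank_end = offsets[0] + (offsets[-1] - offsets[0]) // 3
    baseline = float(np.median(med[offsets <= flank_end]))
    if baseline <= 0:
        baseline = float(np.median(med[med > 0])) if (med > 0).any() else 1.0

    count = 0
    amplitudes = []
    k = 0
    while True:
        center = -k * period
        lo, hi = center - tolerance, center + tolerance
        mask = (offsets >= lo) & (offsets <= hi) & (offsets <= 0)
        if not mask.any():
            break
        peak = float(med[mask].max())
        if peak > threshold * baseline:
            count += 1
            amplitudes.append(peak)
            k += 1
        else:
            break
    return {"queue_length": count, "amplitudes": amplitudes, "baseline": baseline}


# ------------------------------------------------------- readthrough score
def readthrough_score(
    track: PileupTrack,
    ann: GeneAnnotation,
    isolation: int = 55,
    window: tuple[int, int] = (5, 45),
    min_density: float = 0.1,
    edge_trim: int = 20,
) -> pd.DataFrame:
    """Per-gene readthrough scores with exclusion reason codes.

    Score = mean footprint density in the downstream window (offsets
    ``window`` nt past the stop's last nt) divided by the mean density in
    the gene body (edge-trimmed). Only isolated genes (nearest co-directional
    neighbours more than ``isolation`` bp away on both sides) above
    ``min_density`` are scored; scores above 1 are retained but flagged.
    """
    genes = ann.genes
    rows = []
    for idx, row in enumerate(genes.itertuples()):
        L = row.end - row.start
        reason = ""
        up_gap, down_gap = _codirectional_gaps(genes, idx)
        if min(up_gap, down_gap) <= isolation:
            reason = "not_isolated"
        prof = track.gene_profile(row, downstream=window[1])
        body = prof[edge_trim : max(L - edge_trim, edge_trim + 1)]
        body_density = float(body.mean()) if len(body) else 0.0
        if not reason and body_density <= min_density:
            reason = "low_density"
        if reason:
            rows.append(
                {
                    "gene_id": row.gene_id,
                    "stop_codon": row.stop_codon,
                    "stop_tetra": row.stop_tetra,
                    "body_density": body_density,
                    "downstream_density": np.nan,
                    "score": np.nan,
                    "flag": reason,
                }
            )
            continue
        down = prof[L - 1 + window[0] : L - 1 + window[1] + 1]
        down_density = float(down.mean())
        score = down_density / body_density
        rows.append(
            {
                "gene_id": row.gene_id,
                "stop_codon": row.stop_codon,
                "stop_tetra": row.stop_tetra,
                "body_density": body_density,
                "downstream_density": down_density,
                "score": score,
                "flag": "score_gt_1" if score > 1 else "",
            }
        )
    return pd.DataFrame(rows)


def _codirectional_gaps(genes: pd.DataFrame, idx: int) -> tuple[float, float]:
    """Signed distances to the nearest co-directional neighbours.

    Negative for overlapping neighbours; inf at chromosome ends. Computed
    genomically (left, right), which is strand-symmetric for the isolation
    filter since both sides are required to clear the cutoff.
    """
    row = genes.iloc[idx]
    same = genes[
        (genes["chrom"] == row["chrom"]) & (genes["strand"] == row["strand"])
    ].drop(genes.index[idx])
    left_genes = same[same["start"] <= row["start"]]
    right_genes = same[same["start"] > row["start"]]
    left = row["start"] - left_genes["end"].max() if len(left_genes) else np.inf
    right = right_genes["start"].min() - row["end"] if len(right_genes) else np.inf
    return float(left), float(right)


# ---------------------------------------------------------- stratification
def stratify_readthrough(
    records: pd.DataFrame, by: str = "stop_codon", min_group: int = 5
) -> pd.DataFrame:
    """Group medians and interquartile ranges of readthrough scores."""
    usable = records[records["score"].notna()]
    rows = []
    for key, grp in usable.groupby(by):
        scores = grp["score"].to_numpy()
        rows.append(
            {
                by: key,
                "median": float(np.median(scores)),
                "q25": float(np.percentile(scores, 25)),
                "q75": float(np.percentile(scores, 75)),
                "n_genes": len(scores),
                "flag": "small_group" if len(scores) < min_group else "",
            }
        )
    return pd.DataFrame(rows)
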