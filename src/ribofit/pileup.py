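"""Per-position read-density tracks (strand-aware pileups).

A :class:`PileupTrack` holds one float vector per (chromosome, strand) with
one entry per genomic position, plus metadata on how the reads were mapped
(3'-end counting for RNA-seq, center-mapped ribosome footprints). bedGraph
I/O uses 0-based half-open intervals, one file per strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PileupTrack:
    counts: dict  # (chrom, strand) -> np.ndarray of per-position counts
    mapping_mode: str = "center"  # "center" | "three_prime"
    footprint_range: tuple = (14, 44)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, vec in self.counts.items():
            arr = np.asarray(vec, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative counts in track {key}")
            self.counts[key] = arr

    @property
    def chroms(self) -> list[str]:
        return sorted({chrom for chrom, _ in self.counts})

    def chrom_length(self, chrom: str) -> int:
        for (c, _s), vec in self.counts.items():
            if c == chrom:
                return len(vec)
        raise KeyError(chrom)

    def strand_vector(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self.counts:
            self.counts[key] = np.zeros(self.chrom_length(chrom))
        return self.counts[key]

    def total_reads(self) -> float:
        return float(sum(vec.sum() for vec in self.counts.values()))

    def gene_profile(self, row, upstream: int = 0, downstream: int = 0) -> np.ndarray:
        """Density profile of one gene row in transcription (5'->3') sense.

        ``upstream``/``downstream`` extend the window beyond the gene ends;
        out-of-chromosome positions are returned as zero.
        """
        vec = self.strand_vector(row.chrom, row.strand)
        n = len(vec)
        if row.strand == "+":
            lo, hi = row.start - upstream, row.end + downstream
        else:
            lo, hi = row.start - downstream, row.end + upstream
        out = np.zeros(hi - lo)
        a, b = max(lo, 0), min(hi, n)
        if b > a:
            out[a - lo : b - lo] = vec[a:b]
        if row.strand == "-":
            out = out[::-1]
        return out

    def scaled(self, factor: float) -> "PileupTrack":
        return PileupTrack(
            {k: v * factor for k, v in self.counts.items()},
            mapping_mode=self.mapping_mode,
            footprint_range=self.footprint_range,
            meta=dict(self.meta),
        )

    def flipped(self, chrom_sizes: dict) -> "PileupTrack":
        """Track on the reverse-complemented genome (strand symmetry tests)."""
        new = {}
        for (chrom, strand), vec in self.counts.items():
            new[(chrom, "-" if strand == "+" else "+")] = vec[::-1].copy()
        return PileupTrack(
            new,
            mapping_mode=self.mapping_mode,
            footprint_range=self.footprint_range,
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------ I/O
    def to_bedgraph(self, plus_path, minus_path) -> None:
        for strand, path in (("+", plus_path), ("-", minus_path)):
            with open(path, "w") as fh:
                for (chrom, s), vec in sorted(self.counts.items()):
                    if s != strand:
                        continue
                    # run-length encode constant stretches
                    change = np.flatnonzero(np.diff(vec)) + 1
                    starts = np.concatenate([[0], change])
                    ends = np.concatenate([change, [len(vec)]])
                    for a, b in zip(starts, ends):
                        val = vec[a]
                        if val != 0:
                            fh.write(f"{chrom}\t{a}\t{b}\t{val:g}\n")

    @classmethod
    def from_bedgraph(
        cls,
        plus_path,
        minus_path,
        chrom_sizes: dict,
        mapping_mode: str = "center",
        footprint_range: tuple = (14, 44),
    ) -> "PileupTrack":
        counts = {
            (chrom, strand): np.zeros(size)
            for chrom, size in chrom_sizes.items()
            for strand in "+-"
        }
        for strand, path in (("+", plus_path), ("-", minus_path)):
            df = pd.read_csv(
                path,
                sep="\t",
                comment="#",
                header=None,
                names=["chrom", "start", "end", "value"],
            )
            for row in df.itertuples():
                counts[(row.chrom, strand)][row.start : row.end] += row.value
        return cls(counts, mapping_mode=mapping_mode, footprint_range=footprint_range)


def center_position(read_start: int, read_length: int) -> int:
    """Genomic position of the center of a footprint.

    The center of an even-length footprint is ``length // 2`` from the
    read's 5' end (rounded down).
    """
    return read_start + read_length // 2
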