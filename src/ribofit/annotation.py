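"""Gene annotations with stop-codon context.

Genes are stored in a :class:`pandas.DataFrame` with 0-based half-open
coordinates. GFF3 input/output uses the conventional 1-based closed
intervals; minus-strand genes are always interpreted in the transcription
sense (the stop codon of a minus-strand gene occupies the three lowest
genomic coordinates of its interval).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

STOP_CODONS = ("UAA", "UAG", "UGA")

#: DataFrame columns every annotation carries.
GENE_COLUMNS = [
    "gene_id",
    "chrom",
    "strand",
    "start",
    "end",
    "gene_class",
    "stop_codon",
    "stop_tetra",
    "regulons",
]


def _dna_to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def _rna_to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass
class GeneAnnotation:
    """A strand-aware, coordinate-sorted set of gene intervals.

    Parameters
    ----------
    genes : pandas.DataFrame
        One row per gene with columns :data:`GENE_COLUMNS`. ``start``/``end``
        are 0-based half-open genomic coordinates; ``strand`` is ``"+"`` or
        ``"-"``; ``stop_codon`` is one of UAA/UAG/UGA (RNA alphabet);
        ``regulons`` is a comma-separated label string (may be empty).
    chrom_sizes : dict
        Chromosome name -> length (nt).
    """

    genes: pd.DataFrame
    chrom_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.genes.copy()
        for col in GENE_COLUMNS:
            if col not in df.columns:
                if col == "gene_class":
                    df[col] = "mRNA"
                elif col in ("stop_codon", "stop_tetra", "regulons"):
                    df[col] = ""
                else:
                    raise ValueError(f"annotation missing required column {col!r}")
        if (df["end"] <= df["start"]).any():
            raise ValueError("gene intervals must satisfy end > start")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand values: {df.loc[bad, 'strand'].unique()}")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.genes = df[GENE_COLUMNS + [c for c in df.columns if c not in GENE_COLUMNS]]

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def lengths(self) -> pd.Series:
        return (self.genes["end"] - self.genes["start"]).rename("length")

    def stop_interval(self, row) -> tuple[int, int]:
        """Genomic half-open interval of the stop codon of one gene row."""
        if row.strand == "+":
            return row.end - 3, row.end
        return row.start, row.start + 3

    def regulon_members(self, label: str) -> list[str]:
        mask = self.genes["regulons"].fillna("").str.split(",").apply(lambda xs: label in xs)
        return self.genes.loc[mask, "gene_id"].tolist()

    # ------------------------------------------------------------------ I/O
    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, size in self.chrom_sizes.items():
                fh.write(f"##sequence-region {name} 1 {size}\n")
            for row in self.genes.itertuples():
                attrs = f"ID={row.gene_id}"
                if row.stop_codon:
                    attrs += f";stop_codon={row.stop_codon}"
                if row.stop_tetra:
                    attrs += f";stop_tetranucleotide={row.stop_tetra}"
                if row.regulons:
                    attrs += f";regulons={row.regulons}"
                fh.write(
                    "\t".join(
                        [
                            row.chrom,
                            "ribofit",
                            row.gene_class,
                            str(row.start + 1),
                            str(row.end),
                            ".",
                            row.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_gff3(cls, path, chrom_sizes: dict | None = None) -> "GeneAnnotation":
        import gffutils

        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        sizes = dict(chrom_sizes or {})
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, name, _one, size = line.split()[:4]
                    sizes.setdefault(name, int(size))
                elif not line.startswith("#"):
                    break
        rows = []
        for feat in db.all_features():
            rows.append(
                {
                    "gene_id": feat.attributes.get("ID", [feat.id])[0],
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "start": feat.start - 1,
                    "end": feat.end,
                    "gene_class": feat.featuretype,
                    "stop_codon": feat.attributes.get("stop_codon", [""])[0],
                    "stop_tetra": feat.attributes.get("stop_tetranucleotide", [""])[0],
                    "regulons": feat.attributes.get("regulons", [""])[0],
                }
            )
        return cls(pd.DataFrame(rows), chrom_sizes=sizes)

    # ------------------------------------------------------- genome checks
    def verify_stop_codons(self, genome: dict) -> pd.DataFrame:
        """Check annotated stop codons against the genome sequence.

        ``genome`` maps chromosome name to a DNA string. Returns a DataFrame
        with the annotated and observed stop codon per gene and a boolean
        ``consistent`` column; also fills in missing stop codons and
        tetranucleotides from the sequence.
        """
        recs = []
        for i, row in enumerate(self.genes.itertuples()):
            seq = genome[row.chrom]
            s, e = self.stop_interval(row)
            codon = seq[s:e]
            if row.strand == "+":
                nxt = seq[e : e + 1]
            else:
                codon = str(Seq(codon).reverse_complement())
                nxt = seq[s - 1 : s]
                nxt = str(Seq(nxt).reverse_complement()) if nxt else ""
            observed = _dna_to_rna(codon)
            tetra = observed + _dna_to_rna(nxt) if nxt else ""
            recs.append(
                {
                    "gene_id": row.gene_id,
                    "annotated": row.stop_codon,
                    "observed": observed,
                    "observed_tetra": tetra,
                    "consistent": (not row.stop_codon) or row.stop_codon == observed,
                }
            )
            if not row.stop_codon:
                self.genes.loc[i, "stop_codon"] = observed
            if not row.stop_tetra and tetra:
                self.genes.loc[i, "stop_tetra"] = tetra
        return pd.DataFrame(recs)


def read_fasta(path) -> dict:
    """Read a genome FASTA into a dict of chromosome -> DNA string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement_annotation(
    ann: GeneAnnotation, genome: dict | None = None
) -> tuple[GeneAnnotation, dict | None]:
    """Mirror an annotation (and genome) onto the reverse-complement axis.

    Used by strand-symmetry property tests: every transcription-sense
    quantity must be invariant under this transformation.
    """
    df = ann.genes.copy()
    new_rows = []
    for row in df.itertuples():
        L = ann.chrom_sizes[row.chrom]
        new_rows.append(
            {
                **{c: getattr(row, c) for c in GENE_COLUMNS},
                "start": L - row.end,
                "end": L - row.start,
                "strand": "-" if row.strand == "+" else "+",
            }
        )
    flipped = GeneAnnotation(pd.DataFrame(new_rows), chrom_sizes=dict(ann.chrom_sizes))
    if genome is None:
        return flipped, None
    rc = {name: str(Seq(seq).reverse_complement()) for name, seq in genome.items()}
    return flipped, rc
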