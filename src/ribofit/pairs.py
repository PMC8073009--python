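"""Operon gene-pair stoichiometry and the stop-codon reshuffling test.

Adjacent co-directional gene pairs are extracted with their signed
transcription-sense intergenic distance (negative = ORF overlap; the shared
AUGA start/stop punctuation gives d = -4). Downstream/upstream expression
ratios are compared between conditions, stratified by the upstream stop
codon, and tested against a label-reshuffling null; interval hits can also
be clustered into candidate operons with a permissive spatial cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation

PAIR_COLUMNS = [
    "upstream",
    "downstream",
    "strand",
    "distance",
    "upstream_stop",
    "downstream_stop",
    "overlap_class",
]


# ------------------------------------------------------------ pair extraction
def extract_pairs(ann: GeneAnnotation, genome: dict | None = None) -> pd.DataFrame:
    """Adjacent co-directional gene pairs with signed intergenic distance.

    For genomically adjacent genes on the same strand, the transcription-
    sense distance is d = (right start) - (left end) on either strand; the
    upstream gene is the left one on "+" and the right one on "-". Overlap
    class is A_UGA when d = -4 and the upstream stop is UGA (verified
    against the junction motif when a genome is given), other_overlap when
    d < 0, else none. Nested genes are skipped with a flag; opposite-strand
    neighbours are not pairs.
    """
    rows = []
    for chrom, sub in ann.genes.groupby("chrom"):
        sub = sub.sort_values(["start", "end"]).reset_index(drop=True)
        for i in range(len(sub) - 1):
            left, right = sub.iloc[i], sub.iloc[i + 1]
            if right["end"] <= left["end"]:  # nested
                continue
            if left["strand"] != right["strand"]:
                continue
            d = int(right["start"] - left["end"])
            if left["strand"] == "+":
                up, down = left, right
            else:
                up, down = right, left
            cls = "none"
            if d < 0:
                cls = "other_overlap"
                if d == -4 and up["stop_codon"] == "UGA":
                    if genome is None or _has_a_uga_motif(ann, up, genome):
                        cls = "A_UGA"
            rows.append(
                {
                    "upstream": up["gene_id"],
                    "downstream": down["gene_id"],
                    "strand": left["strand"],
                    "distance": d,
                    "upstream_stop": up["stop_codon"],
                    "downstream_stop": down["stop_codon"],
                    "overlap_class": cls,
                }
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def _has_a_uga_motif(ann: GeneAnnotation, up_row, genome: dict) -> bool:
    seq = genome[up_row["chrom"]]
    if up_row["strand"] == "+":
        e = up_row["end"]
        return seq[e - 4 : e] == "ATGA"
    s = up_row["start"]
    return seq[s : s + 4] == "TCAT"


# ----------------------------------------------------------- pair fold-change
def pair_fc(
    expr_ref: pd.DataFrame,
    expr_pert: pd.DataFrame,
    pairs: pd.DataFrame,
    min_reads: float = 10.0,
) -> pd.DataFrame:
    """Downstream/upstream stoichiometry fold-change per pair.

    r_cond = downstream density / upstream density in each condition;
    FC = r_perturbed / r_reference. Pairs require strictly more than
    ``min_reads`` reads in both genes in both conditions; excluded pairs
    carry a reason code.
    """
    ref = expr_ref.set_index("gene_id")
    pert = expr_pert.set_index("gene_id")
    rows = []
    for p in pairs.itertuples():
        reason = ""
        try:
            cells = [
                ref.loc[p.upstream],
                ref.loc[p.downstream],
                pert.loc[p.upstream],
                pert.loc[p.downstream],
            ]
        except KeyError:
            reason = "missing_gene"
            cells = None
        if cells is not None and any(
            not np.isfinite(c["reads"]) or c["reads"] <= min_reads for c in cells
        ):
            reason = "low_reads"
        if reason:
            rows.append({**_pair_dict(p), "fc": np.nan, "flag": reason})
            continue
        r_ref = ref.loc[p.downstream, "density"] / ref.loc[p.upstream, "density"]
        r_pert = pert.loc[p.downstream, "density"] / pert.loc[p.upstream, "density"]
        rows.append({**_pair_dict(p), "fc": float(r_pert / r_ref), "flag": ""})
    return pd.DataFrame(rows)


def _pair_dict(p) -> dict:
    return {c: getattr(p, c) for c in PAIR_COLUMNS}


# ------------------------------------------------------------ reshuffle test
@dataclass
class ReshuffleResult:
    effect_size: float  # median FC(focal stop) / median FC(UAA)
    p_value: float
    n_permutations: int
    n_focal: int
    n_reference: int
    seed: int | None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


def reshuffle_test(
    effects: pd.DataFrame,
    focal_stop: str,
    n_perm: int = 100_000,
    seed: int | None = 0,
    stop_column: str = "upstream_stop",
    reference_stop: str = "UAA",
) -> ReshuffleResult:
    """Stop-codon label-reshuffling test on fold-change effects.

    Effect size = median FC of the focal stop class divided by median FC of
    the reference (UAA) class. Stop labels are permuted across the analyzed
    pairs ``n_perm`` times; the p-value is the add-one-corrected fraction of
    permutations whose effect is more pronounced (strictly smaller) than
    observed: p = (1 + #{perm < observed}) / (1 + n_perm). Ties count in
    favour of the null, so exactly separated discrete inputs give
    p = 1 / (1 + n_perm).
    """
    df = effects[effects["fc"].notna()]
    labels = df[stop_column].to_numpy()
    fc = df["fc"].to_numpy(dtype=float)
    focal_mask = labels == focal_stop
    ref_mask = labels == reference_stop
    if not focal_mask.any():
        raise ValueError(f"no pairs in focal stop class {focal_stop}")
    if not ref_mask.any():
        raise ValueError(f"no pairs in reference stop class {reference_stop}")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two stop classes")
    observed = float(np.median(fc[focal_mask]) / np.median(fc[ref_mask]))

    rng = np.random.default_rng(seed)
    n_f, n_r = int(focal_mask.sum()), int(ref_mask.sum())
    # permuting labels over pairs == assigning each class a random disjoint
    # subset of the fold-changes; vectorized in chunks
    hits = 0
    remaining = n_perm
    chunk = max(1, min(n_perm, int(2e7 // max(len(fc), 1))))
    while remaining > 0:
        m = min(chunk, remaining)
        mat = rng.permuted(np.broadcast_to(fc, (m, len(fc))).copy(), axis=1)
        eff = np.median(mat[:, :n_f], axis=1) / np.median(mat[:, n_f : n_f + n_r], axis=1)
        hits += int((eff < observed).sum())
        remaining -= m
    p = (1 + hits) / (1 + n_perm)
    return ReshuffleResult(observed, p, n_perm, n_f, n_r, seed)


def gene_fc_by_stop(
    expr_ref: pd.DataFrame,
    expr_pert: pd.DataFrame,
    ann: GeneAnnotation,
    min_reads: float = 10.0,
) -> pd.DataFrame:
    """Per-gene expression fold-changes, median-normalized, by own stop codon.

    FC = perturbed density / reference density for genes with more than
    ``min_reads`` reads in both conditions, divided by the global median FC
    (removes uniform scaling); grouped by the gene's own stop codon so the
    same reshuffling test applies with ``stop_column='stop_codon'``.
    """
    ref = expr_ref.set_index("gene_id")
    pert = expr_pert.set_index("gene_id")
    common = ref.index.intersection(pert.index)
    ref, pert = ref.loc[common], pert.loc[common]
    ok = (ref["reads"] > min_reads) & (pert["reads"] > min_reads)
    fc = (pert.loc[ok, "density"] / ref.loc[ok, "density"]).astype(float)
    fc = fc / fc.median()
    stops = ann.genes.set_index("gene_id")["stop_codon"]
    out = pd.DataFrame({"gene_id": fc.index, "fc": fc.to_numpy()})
    out["stop_codon"] = out["gene_id"].map(stops)
    return out.dropna(subset=["stop_codon"]).reset_index(drop=True)


# ------------------------------------------------------------- operon calls
def cluster_hits(
    hits: pd.DataFrame,
    max_gap: float = 100.0,
    required_labels=(),
    require_codirectional: bool = False,
    required_order: list | None = None,
    score_column: str | None = None,
) -> pd.DataFrame:
    """Cluster homolog hits into candidate operons by spatial proximity.

    ``hits`` has columns species/label/chrom/start/end/strand. Intervals on
    the same (species, chrom) whose start-to-end gap is at most ``max_gap``
    are merged by single linkage; clusters are retained only if they contain
    all ``required_labels``, optionally share one strand and (for
    ``required_order``) occur in the given transcription-sense order. One
    call per species is returned (best by ``score_column`` when given,
    otherwise the first).
    """
    required = set(required_labels)
    calls = []
    for (species, chrom), sub in hits.groupby(["species", "chrom"]):
        sub = sub.sort_values("start").reset_index(drop=True)
        cluster_idx = np.zeros(len(sub), dtype=int)
        cid = 0
        max_end = sub.loc[0, "end"]
        for i in range(1, len(sub)):
            if sub.loc[i, "start"] - max_end > max_gap:
                cid += 1
            cluster_idx[i] = cid
            max_end = max(max_end, sub.loc[i, "end"])
        for cid, grp in sub.groupby(cluster_idx):
            labels = set(grp["label"])
            if required and not required.issubset(labels):
                continue
            if require_codirectional and grp["strand"].nunique() > 1:
                continue
            if required_order is not None:
                ordered = grp.sort_values("start")
                seq = list(ordered["label"])
                strand = ordered["strand"].iloc[0]
                want = list(required_order) if strand == "+" else list(required_order)[::-1]
                positions = [seq.index(lbl) for lbl in want if lbl in seq]
                if positions != sorted(positions) or len(positions) < len(want):
                    continue
            calls.append(
                {
                    "species": species,
                    "chrom": chrom,
                    "start": int(grp["start"].min()),
                    "end": int(grp["end"].max()),
                    "n_hits": len(grp),
                    "labels": ",".join(sorted(labels)),
                    "score": float(grp[score_column].max()) if score_column else np.nan,
                }
            )
    df = pd.DataFrame(calls)
    if df.empty:
        return df
    if score_column:
        df = df.sort_values("score", ascending=False)
    return df.groupby("species", as_index=False).first()
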