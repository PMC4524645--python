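"""Methylation over genes and annotation features, and genic-location
prediction from methylation.

Gene-body methylation is the unweighted mean of per-CpG methylation
fractions over the transcribed span, after masking the gene's promoter
(1000 bp upstream to 100 bp downstream of the TSS, strand-aware) and all
CpG islands; genes with fewer than 20 informative CpGs remaining are
dropped.  The spinogram quantifies P(window is genic | window methylation
bin) for 5-kb windows — how predictive methylation is of gene location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import as_intervals


def promoters_from_genes(
    genes: pd.DataFrame, upstream: int = 1000, downstream: int = 100
) -> pd.DataFrame:
    """Strand-aware promoter intervals around each TSS.

    Plus strand: [tss - upstream, tss + downstream); minus strand (TSS at
    ``end - 1``): [tx_end - downstream, tx_end + upstream).  Clipped at 0.
    """
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["start"] - upstream, genes["end"] - downstream)
    end = np.where(plus, genes["start"] + downstream, genes["end"] + upstream)
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.maximum(start, 0),
            "end": end,
            "label": "promoter",
            "gene_id": genes["gene_id"],
        }
    )
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def _merge_intervals(intervals: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-chromosome merged (start, end) arrays for fast point membership."""
    out = {}
    for chrom, grp in intervals.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        order = np.argsort(s, kind="mergesort")
        s, e = s[order], e[order]
        ms, me = [s[0]], [e[0]]
        for i in range(1, len(s)):
            if s[i] <= me[-1]:
                me[-1] = max(me[-1], e[i])
            else:
                ms.append(s[i])
                me.append(e[i])
        out[chrom] = np.column_stack([ms, me])
    return out


def _in_intervals(chrom: str, pos: np.ndarray, merged: dict[str, np.ndarray]) -> np.ndarray:
    if chrom not in merged:
        return np.zeros(len(pos), dtype=bool)
    blk = merged[chrom]
    idx = np.searchsorted(blk[:, 0], pos, side="right") - 1
    ok = idx >= 0
    return ok & (pos < blk[np.clip(idx, 0, None), 1])


@dataclass
class GeneBodyResult:
    """Per-gene masked gene-body methylation plus bookkeeping."""

    table: pd.DataFrame  # gene_id, methylation, n_cpgs, masked_cpgs
    n_genes_dropped: int


def gene_body_methylation(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    promoters: pd.DataFrame | None = None,
    cpg_islands: pd.DataFrame | None = None,
    min_cpgs: int = 20,
    exons: pd.DataFrame | None = None,
) -> GeneBodyResult:
    """Mean methylation over each gene body after promoter/island masking.

    CpGs inside the gene's own promoter or inside any CpG island never
    contribute.  With ``exons`` given (intervals carrying ``gene_id``),
    only exonic CpGs are used (intron-excluding mode); the default uses
    the whole transcribed span including introns.
    """
    if promoters is None:
        promoters = promoters_from_genes(genes)
    island_idx = (
        _merge_intervals(cpg_islands) if cpg_islands is not None and len(cpg_islands) else {}
    )
    prom_by_gene = promoters.set_index("gene_id") if "gene_id" in promoters else None

    rows = []
    dropped = 0
    calls_by_chrom = dict(tuple(calls[calls["fraction"].notna()].groupby("chrom", sort=False)))
    exon_by_gene = (
        dict(tuple(exons.groupby("gene_id", sort=False))) if exons is not None else None
    )
    for _, gene in genes.iterrows():
        grp = calls_by_chrom.get(gene["chrom"])
        if grp is None:
            dropped += 1
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, gene["start"], side="left")
        hi = np.searchsorted(pos, gene["end"], side="left")
        gpos = pos[lo:hi]
        gfrac = grp["fraction"].to_numpy()[lo:hi]
        keep = np.ones(len(gpos), dtype=bool)
        if exon_by_gene is not None:
            ex = exon_by_gene.get(gene["gene_id"])
            keep &= _in_intervals(
                gene["chrom"], gpos, _merge_intervals(ex) if ex is not None else {}
            )
        if prom_by_gene is not None and gene["gene_id"] in prom_by_gene.index:
            p = prom_by_gene.loc[gene["gene_id"]]
            keep &= ~((gpos >= p["start"]) & (gpos < p["end"]))
        keep &= ~_in_intervals(gene["chrom"], gpos, island_idx)
        n = int(keep.sum())
        if n < min_cpgs:
            dropped += 1
            continue
        rows.append(
            {
                "gene_id": gene["gene_id"],
                "methylation": float(gfrac[keep].mean()),
                "n_cpgs": n,
                "masked_cpgs": int(len(gpos) - n),
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "methylation", "n_cpgs", "masked_cpgs"])
    return GeneBodyResult(table=table, n_genes_dropped=dropped)


def feature_methylation(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    min_cpgs: int = 10,
    complement_label: str = "non_repetitive",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature and per-class pooled methylation summaries.

    Per-feature means are reported only for features with at least
    ``min_cpgs`` informative CpGs.  Per-class pooled means average all CpG
    sites falling in any feature of the class; sites outside every feature
    form the complement class.
    """
    informative = calls[calls["fraction"].notna()]
    calls_by_chrom = dict(tuple(informative.groupby("chrom", sort=False)))
    rows = []
    class_sums: dict[str, list[float]] = {}
    in_any = {
        chrom: np.zeros(len(grp), dtype=bool) for chrom, grp in calls_by_chrom.items()
    }
    for fi, feat in features.iterrows():
        grp = calls_by_chrom.get(feat["chrom"])
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, feat["start"], side="left")
        hi = np.searchsorted(pos, feat["end"], side="left")
        frac = grp["fraction"].to_numpy()[lo:hi]
        in_any[feat["chrom"]][lo:hi] = True
        label = feat["label"]
        class_sums.setdefault(label, [0.0, 0])
        class_sums[label][0] += float(frac.sum())
        class_sums[label][1] += len(frac)
        if len(frac) >= min_cpgs:
            rows.append(
                {
                    "chrom": feat["chrom"], "start": feat["start"], "end": feat["end"],
                    "label": label, "methylation": float(frac.mean()), "n_cpgs": len(frac),
                }
            )
    comp_sum, comp_n = 0.0, 0
    for chrom, grp in calls_by_chrom.items():
        outside = ~in_any[chrom]
        comp_sum += float(grp["fraction"].to_numpy()[outside].sum())
        comp_n += int(outside.sum())
    class_rows = [
        {"label": lab, "methylation": s / n if n else np.nan, "n_cpgs": n}
        for lab, (s, n) in class_sums.items()
    ]
    class_rows.append(
        {
            "label": complement_label,
            "methylation": comp_sum / comp_n if comp_n else np.nan,
            "n_cpgs": comp_n,
        }
    )
    per_feature = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label", "methylation", "n_cpgs"]
    )
    per_class = pd.DataFrame(class_rows, columns=["label", "methylation", "n_cpgs"])
    return per_feature, per_class


def genic_spinogram(
    windows5kb: pd.DataFrame, genes: pd.DataFrame, bin_width: float = 5.0
) -> pd.DataFrame:
    """P(genic | methylation bin) for non-missing windows.

    A window is genic iff its midpoint lies inside any gene body.  Bins
    tile [0, 100]% methylation; empty bins are reported with count 0 and
    undefined probability.  The informativeness score is |P - 0.5|.
    """
    wins = windows5kb[windows5kb["mean_meth"].notna()].reset_index(drop=True)
    gene_iv = as_intervals(
        genes.rename(columns={"gene_id": "label"})[["chrom", "start", "end", "label"]]
    )
    merged = _merge_intervals(gene_iv) if len(gene_iv) else {}
    genic = np.zeros(len(wins), dtype=bool)
    for chrom, grp in wins.groupby("chrom", sort=False):
        mid = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2).astype(np.int64)
        genic[grp.index.to_numpy()] = _in_intervals(chrom, mid, merged)

    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    pct = wins["mean_meth"].to_numpy() * 100.0
    idx = np.clip(np.digitize(pct, edges) - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    count = np.bincount(idx, minlength=n_bins)
    n_genic = np.bincount(idx, weights=genic.astype(float), minlength=n_bins).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(count > 0, n_genic / np.maximum(count, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "n_windows": count,
            "fraction": count / count.sum() if count.sum() else np.nan,
            "n_genic": n_genic,
            "p_genic": p,
            "informativeness": np.abs(p - 0.5),
        }
    )


def build_ortholog_matrix(
    gene_body: dict[str, pd.DataFrame],
    ortholog_pairs: dict[str, pd.DataFrame],
    pivot: str,
) -> pd.DataFrame:
    """Join per-species gene-body methylation over an ortholog map.

    ``gene_body`` maps species -> table (gene_id, methylation, n_cpgs);
    ``ortholog_pairs`` maps each non-pivot species to a table
    (gene_id_a = pivot id, gene_id_b = that species' id).  One row per
    pivot gene, one column per species; rows with fewer than two
    non-missing entries are dropped.  Duplicate orthologs for one pivot
    gene keep the entry with the most informative CpGs.
    """
    def best_per_gene(tab: pd.DataFrame, key: str) -> pd.Series:
        t = tab.sort_values("n_cpgs", ascending=False).drop_duplicates(key, keep="first")
        return t.set_index(key)["methylation"]

    pivot_tab = gene_body[pivot]
    mat = pd.DataFrame(index=pd.Index(sorted(pivot_tab["gene_id"].unique()), name="gene_id"))
    mat[pivot] = best_per_gene(pivot_tab, "gene_id").reindex(mat.index)
    for species, pairs in ortholog_pairs.items():
        tab = gene_body[species].merge(
            pairs, left_on="gene_id", right_on="gene_id_b", how="inner"
        )
        col = best_per_gene(tab, "gene_id_a")
        mat[species] = col.reindex(mat.index)
    # pivot genes absent from the pivot table but present via orthologs
    keep = mat.notna().sum(axis=1) >= 2
    return mat[keep]
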