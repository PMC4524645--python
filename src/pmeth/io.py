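"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open internally.  Per-CpG methylation
calls live in a pandas DataFrame (the "CpG track") with columns

    chrom        chromosome name (str)
    pos          0-based position of the CpG cytosine on the forward strand
    meth_reads   methylated read count (float; NaN when unknown)
    total_reads  total read count (float; NaN when unknown)
    fraction     methylation fraction in [0, 1]

Count-dialect inputs carry read counts; bedGraph/wig-style inputs carry
only a fraction, in which case ``meth_reads``/``total_reads`` are NaN and
the site acts as a weight-1 observation in all downstream averaging.

Interval tracks (genes, promoters, CpG islands, repeats, domains) are
DataFrames with columns ``chrom, start, end, label`` (BED-style half-open),
genes additionally carry ``gene_id`` and ``strand``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CPG_COLUMNS = ["chrom", "pos", "meth_reads", "total_reads", "fraction"]
INTERVAL_COLUMNS = ["chrom", "start", "end", "label"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# CpG tracks


def as_cpg_track(df: pd.DataFrame, sort: bool = True, validate: bool = True) -> pd.DataFrame:
    """Coerce a DataFrame into canonical CpG-track form (sorted, validated)."""
    out = df.copy()
    for col in ("meth_reads", "total_reads", "fraction"):
        if col not in out.columns:
            out[col] = np.nan
    out = out[CPG_COLUMNS]
    out["pos"] = out["pos"].astype(np.int64)
    for col in ("meth_reads", "total_reads", "fraction"):
        out[col] = out[col].astype(float)
    has_counts = out["total_reads"].notna()
    covered = has_counts & (out["total_reads"] > 0)
    out.loc[covered, "fraction"] = (
        out.loc[covered, "meth_reads"] / out.loc[covered, "total_reads"]
    )
    if validate:
        if (out["pos"] < 0).any():
            raise FormatError("negative CpG position")
        bad = has_counts & (
            (out["meth_reads"] < 0) | (out["meth_reads"] > out["total_reads"])
        )
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"meth_reads > total_reads (or negative) at row {i} "
                f"({out.iloc[i]['chrom']}:{out.iloc[i]['pos']})"
            )
        frac = out["fraction"]
        if ((frac < -1e-9) | (frac > 1 + 1e-9)).any():
            raise FormatError("methylation fraction outside [0, 1]")
    if sort:
        key = out[["chrom", "pos"]]
        if not (
            key["chrom"].is_monotonic_increasing
            and out.groupby("chrom", sort=False)["pos"].apply(
                lambda s: s.is_monotonic_increasing
            ).all()
        ):
            out = out.sort_values(["chrom", "pos"], kind="mergesort")
    return out.reset_index(drop=True)


def _detect_dialect(df: pd.DataFrame) -> str:
    c2, c3 = df.iloc[:, 2], df.iloc[:, 3]
    if (
        (c3 >= 0).all()
        and (c3 <= 1.0).all()
        and (c2 == df.iloc[:, 1] + 1).all()
    ):
        return "bedgraph"
    return "counts"


def read_cpg_track(path, dialect: str = "auto", combine_strands: bool = False) -> pd.DataFrame:
    """Read a per-CpG methylation call table.

    Two tab-delimited dialects are supported: ``counts``
    (chrom, pos, meth_reads, total_reads) and ``bedgraph``
    (chrom, start, end, fraction), auto-detected by default.  With
    ``combine_strands`` a call at position *p* and its reverse-strand
    partner at *p+1* are merged (read counts summed) onto position *p*.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            dtype={0: str}, na_values=["NA", "."],
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected 4 tab-delimited columns, got {df.shape[1]}")
    df = df.iloc[:, :4]
    if dialect == "auto":
        dialect = _detect_dialect(df)
    if dialect == "bedgraph":
        track = pd.DataFrame(
            {
                "chrom": df.iloc[:, 0],
                "pos": df.iloc[:, 1].astype(np.int64),
                "meth_reads": np.nan,
                "total_reads": np.nan,
                "fraction": df.iloc[:, 3].astype(float),
            }
        )
    elif dialect == "counts":
        for j, name in ((2, "meth_reads"), (3, "total_reads")):
            vals = df.iloc[:, j].astype(float)
            if not np.allclose(vals, np.round(vals), atol=0, rtol=0):
                i = int(np.flatnonzero(vals != np.round(vals))[0])
                raise FormatError(f"{path}: non-integer {name} at line {i + 1}")
        track = pd.DataFrame(
            {
                "chrom": df.iloc[:, 0],
                "pos": df.iloc[:, 1].astype(np.int64),
                "meth_reads": df.iloc[:, 2].astype(float),
                "total_reads": df.iloc[:, 3].astype(float),
                "fraction": np.nan,
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    key_sorted = track["chrom"].is_monotonic_increasing and (
        track.groupby("chrom", sort=False)["pos"]
        .apply(lambda s: s.is_monotonic_increasing)
        .all()
    )
    if not key_sorted:
        warnings.warn(f"{path}: input not sorted by (chrom, pos); sorting on load")
    track = as_cpg_track(track)
    if combine_strands:
        track = merge_strand_calls(track)
    return track


def merge_strand_calls(track: pd.DataFrame) -> pd.DataFrame:
    """Merge forward/reverse strand partners (positions p and p+1).

    Read counts are summed and the merged call keeps the lower position.
    For fraction-only sites the two fractions are averaged with equal
    weight.  Idempotent: a merged track has no partner pairs left (two
    genuine CpG sites cannot sit 1 bp apart on the forward strand).
    """
    if track.empty:
        return track.copy()
    out_parts = []
    for chrom, grp in track.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        is_partner = np.zeros(len(grp), dtype=bool)
        is_partner[1:] = pos[1:] == pos[:-1] + 1
        # a site already consumed as a partner cannot anchor another merge
        anchor = np.ones(len(grp), dtype=bool)
        for i in range(1, len(grp)):
            if is_partner[i] and anchor[i - 1]:
                anchor[i] = False
            else:
                is_partner[i] = False
        g = grp.reset_index(drop=True)
        merged = g[anchor].copy().reset_index(drop=True)
        partner_of = np.flatnonzero(is_partner)
        if partner_of.size:
            anchor_idx = partner_of - 1
            pos_to_row = {int(p): i for i, p in enumerate(merged["pos"].to_numpy())}
            for ai, pi in zip(anchor_idx, partner_of):
                row = pos_to_row[int(g.at[ai, "pos"])]
                if np.isnan(g.at[ai, "total_reads"]) or np.isnan(g.at[pi, "total_reads"]):
                    merged.at[row, "fraction"] = np.nanmean(
                        [g.at[ai, "fraction"], g.at[pi, "fraction"]]
                    )
                    merged.at[row, "meth_reads"] = np.nan
                    merged.at[row, "total_reads"] = np.nan
                else:
                    merged.at[row, "meth_reads"] = g.at[ai, "meth_reads"] + g.at[pi, "meth_reads"]
                    merged.at[row, "total_reads"] = g.at[ai, "total_reads"] + g.at[pi, "total_reads"]
        merged["chrom"] = chrom
        out_parts.append(merged)
    return as_cpg_track(pd.concat(out_parts, ignore_index=True))


def write_cpg_track(track: pd.DataFrame, path, dialect: str = "counts") -> None:
    if dialect == "counts":
        if track["total_reads"].isna().any():
            raise ValueError("count-dialect output requires read counts on every site")
        out = pd.DataFrame(
            {
                "chrom": track["chrom"],
                "pos": track["pos"],
                "meth": track["meth_reads"].astype(np.int64),
                "total": track["total_reads"].astype(np.int64),
            }
        )
    elif dialect == "bedgraph":
        out = pd.DataFrame(
            {
                "chrom": track["chrom"],
                "start": track["pos"],
                "end": track["pos"] + 1,
                "fraction": track["fraction"].round(6),
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Interval tracks and genes


def as_intervals(df: pd.DataFrame, label: str | None = None) -> pd.DataFrame:
    out = df.copy()
    if label is not None:
        out["label"] = label
    if "label" not in out.columns:
        out["label"] = ""
    extra = [c for c in out.columns if c not in INTERVAL_COLUMNS]
    out = out[INTERVAL_COLUMNS + extra]
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["start"] >= out["end"]).any():
        i = int(np.flatnonzero((out["start"] >= out["end"]).to_numpy())[0])
        raise FormatError(f"interval with start >= end at row {i}")
    if (out["start"] < 0).any():
        raise FormatError("negative interval start")
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def read_intervals(path, label: str | None = None) -> pd.DataFrame:
    """Read a BED3+ file into a sorted interval track carrying ``label``.

    Overlapping intervals are allowed and preserved.  If no label is given
    and a 4th BED column exists, it is used as the label.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    out = pd.DataFrame({"chrom": df.iloc[:, 0], "start": df.iloc[:, 1], "end": df.iloc[:, 2]})
    if label is None and df.shape[1] >= 4:
        out["label"] = df.iloc[:, 3]
        label = None
    return as_intervals(out, label=label)


def write_intervals(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end", "label"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_genes(path) -> pd.DataFrame:
    """Read a BED6 gene table -> DataFrame(gene_id, chrom, start, end, strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 6:
        raise FormatError(f"{path}: gene BED needs 6 columns (chrom start end name score strand)")
    genes = pd.DataFrame(
        {
            "gene_id": df.iloc[:, 3].astype(str),
            "chrom": df.iloc[:, 0],
            "start": df.iloc[:, 1].astype(np.int64),
            "end": df.iloc[:, 2].astype(np.int64),
            "strand": df.iloc[:, 5].astype(str),
        }
    )
    if not genes["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    if (genes["start"] >= genes["end"]).any():
        raise FormatError(f"{path}: gene with start >= end")
    return genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_genes(genes: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class GeneModel:
    """A single gene: transcribed span plus optional exon structure."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError("exon outside transcribed span")


# ---------------------------------------------------------------------------
# UCSC chain files


@dataclass
class Chain:
    """One UCSC chain: a gapless-block alignment from source (t) to target (q).

    ``blocks`` is an (n, 3) int array of (t_start, q_start, size) with q_start
    in strand coordinates (as in the file).  Source strand is always '+'.
    """

    chain_id: int
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))

    def forward_blocks(self) -> np.ndarray:
        """Blocks as (t_start, t_end, q_fwd_start, q_fwd_end, flipped) rows.

        Negative-strand target coordinates are reflected onto the forward
        strand (forward = q_size - strand_coordinate).
        """
        b = np.asarray(self.blocks, dtype=np.int64)
        out = np.empty((len(b), 5), dtype=np.int64)
        out[:, 0] = b[:, 0]
        out[:, 1] = b[:, 0] + b[:, 2]
        if self.q_strand == "+":
            out[:, 2] = b[:, 1]
            out[:, 3] = b[:, 1] + b[:, 2]
            out[:, 4] = 0
        else:
            out[:, 2] = self.q_size - (b[:, 1] + b[:, 2])
            out[:, 3] = self.q_size - b[:, 1]
            out[:, 4] = 1
        return out

    def map_positions(self, pos: np.ndarray) -> np.ndarray:
        """Map source positions through this chain; unmapped -> -1."""
        pos = np.asarray(pos, dtype=np.int64)
        fb = self.forward_blocks()
        order = np.argsort(fb[:, 0], kind="mergesort")
        fb = fb[order]
        idx = np.searchsorted(fb[:, 0], pos, side="right") - 1
        ok = idx >= 0
        idx_c = np.clip(idx, 0, None)
        inside = ok & (pos < fb[idx_c, 1])
        off = pos - fb[idx_c, 0]
        fwd = fb[idx_c, 2] + off
        rev = fb[idx_c, 3] - 1 - off
        mapped = np.where(fb[idx_c, 4] == 1, rev, fwd)
        return np.where(inside, mapped, -1)

    def invert(self) -> "Chain":
        """The inverse chain (maps target back to source)."""
        b = np.asarray(self.blocks, dtype=np.int64)
        if self.q_strand == "+":
            nb = np.column_stack([b[:, 1], b[:, 0], b[:, 2]])
            return Chain(
                chain_id=self.chain_id, score=self.score,
                t_name=self.q_name, t_size=self.q_size,
                t_start=self.q_start, t_end=self.q_end,
                q_name=self.t_name, q_size=self.t_size, q_strand="+",
                q_start=self.t_start, q_end=self.t_end, blocks=nb,
            )
        # negative strand: new source is the old target on the forward strand
        new_t = self.q_size - (b[:, 1] + b[:, 2])
        new_q = self.t_size - (b[:, 0] + b[:, 2])
        nb = np.column_stack([new_t, new_q, b[:, 2]])[::-1].copy()
        return Chain(
            chain_id=self.chain_id, score=self.score,
            t_name=self.q_name, t_size=self.q_size,
            t_start=self.q_size - self.q_end, t_end=self.q_size - self.q_start,
            q_name=self.t_name, q_size=self.t_size, q_strand="-",
            q_start=self.t_size - self.t_end, q_end=self.t_size - self.t_start,
            blocks=nb,
        )


def read_chain(path) -> list[Chain]:
    """Parse a UCSC chain file into a list of :class:`Chain` objects."""
    chains: list[Chain] = []
    header = None
    blocks: list[tuple[int, int, int]] = []
    t = q = 0

    def flush():
        nonlocal header, blocks
        if header is None:
            return
        if t != header["t_end"] or q != header["q_end"]:
            raise FormatError(
                f"chain {header['chain_id']}: block arithmetic does not sum to the "
                f"declared span (got t={t}, q={q})"
            )
        chains.append(Chain(blocks=np.array(blocks, dtype=np.int64).reshape(-1, 3), **header))
        header, blocks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                flush()
                parts = line.split()
                if len(parts) != 13:
                    raise FormatError(f"line {lineno}: malformed chain header")
                if parts[4] != "+":
                    raise FormatError(f"line {lineno}: source strand must be '+'")
                header = dict(
                    score=float(parts[1]),
                    t_name=parts[2], t_size=int(parts[3]),
                    t_start=int(parts[5]), t_end=int(parts[6]),
                    q_name=parts[7], q_size=int(parts[8]), q_strand=parts[9],
                    q_start=int(parts[10]), q_end=int(parts[11]),
                    chain_id=int(parts[12]),
                )
                t, q = header["t_start"], header["q_start"]
            else:
                parts = line.split()
                if header is None or len(parts) not in (1, 3):
                    raise FormatError(f"line {lineno}: malformed block line")
                size = int(parts[0])
                blocks.append((t, q, size))
                if len(parts) == 3:
                    t += size + int(parts[1])
                    q += size + int(parts[2])
                else:
                    t += size
                    q += size
    flush()
    return chains


def write_chain(chains: list[Chain], path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
                f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n"
            )
            b = np.asarray(c.blocks, dtype=np.int64)
            for i in range(len(b)):
                if i + 1 < len(b):
                    dt = b[i + 1, 0] - (b[i, 0] + b[i, 2])
                    dq = b[i + 1, 1] - (b[i, 1] + b[i, 2])
                    fh.write(f"{b[i, 2]} {dt} {dq}\n")
                else:
                    fh.write(f"{b[i, 2]}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Simple TSV tables


def read_expression(path) -> pd.DataFrame:
    """TSV with header: gene_id, fpkm (fpkm >= 0)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "fpkm"}.issubset(df.columns):
        raise FormatError(f"{path}: expression TSV needs columns gene_id, fpkm")
    if (df["fpkm"] < 0).any():
        raise FormatError(f"{path}: negative FPKM")
    return df[["gene_id", "fpkm"]].astype({"gene_id": str})


def read_orthologs(path) -> pd.DataFrame:
    """TSV with header: gene_id_a, gene_id_b (pivot-species id first)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: ortholog TSV needs two id columns")
    out = df.iloc[:, :2].copy()
    out.columns = ["gene_id_a", "gene_id_b"]
    return out.astype(str)


def read_synteny(path) -> pd.DataFrame:
    """Simplified synteny-net table: TSV with header chrom, start, end, level."""
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "level"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: synteny TSV needs columns {sorted(need)}")
    out = df[["chrom", "start", "end", "level"]].copy()
    out = out.astype({"start": np.int64, "end": np.int64, "level": int})
    if (out["level"] < 1).any() or (out["start"] >= out["end"]).any():
        raise FormatError(f"{path}: invalid synteny block")
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_synteny(blocks: pd.DataFrame, path) -> None:
    blocks[["chrom", "start", "end", "level"]].to_csv(path, sep="\t", index=False)


def normalize_chrom_names(names: pd.Series, style: str = "chr") -> pd.Series:
    """Normalize chromosome naming ('1' vs 'chr1') for cross-source joins."""
    s = names.astype(str)
    bare = s.str.replace("^chr", "", regex=True)
    if style == "chr":
        return "chr" + bare
    if style == "bare":
        return bare
    raise ValueError("style must be 'chr' or 'bare'")
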