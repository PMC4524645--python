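"""Cross-species methylome comparison in a common coordinate system.

CpG calls from one species are lifted onto a reference genome through
UCSC-style chain maps (positionally, with no sequence-conservation
requirement), cleaned by synteny-net fill level, scaled to a common
location/spread, and compared window-by-window to call regions of
differential methylation.  Syntenic-break enrichment in those regions is
assessed against a uniform permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Chain, as_cpg_track
from .windows import running_median


@dataclass
class LiftedTrack:
    """CpG calls in target coordinates with per-site provenance."""

    calls: pd.DataFrame  # CpG track + src_chrom, src_pos, chain_score columns
    n_input: int
    n_mapped: int
    n_unmapped: int
    n_removed: int = 0

    def counts_reconcile(self) -> bool:
        return self.n_mapped + self.n_unmapped + self.n_removed == self.n_input


def lift_cpgs(calls: pd.DataFrame, chains: list[Chain]) -> LiftedTrack:
    """Map CpG calls through chain alignments onto the target genome.

    Each site maps through the highest-scoring chain whose blocks contain
    it; sites falling in inter-block gaps (or outside every chain) stay
    unmapped.  When two source sites land on one target position the one
    from the higher-scoring chain wins, then the lower source coordinate.
    """
    n_input = len(calls)
    if not n_input:
        return LiftedTrack(calls.copy(), 0, 0, 0)
    parts = []
    for src_chrom, grp in calls.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        mapped = np.full(len(pos), False)
        tgt_pos = np.full(len(pos), -1, dtype=np.int64)
        tgt_chrom = np.empty(len(pos), dtype=object)
        score = np.full(len(pos), np.nan)
        relevant = [c for c in chains if c.t_name == src_chrom]
        for chain in sorted(relevant, key=lambda c: -c.score):
            todo = ~mapped
            if not todo.any():
                break
            res = chain.map_positions(pos[todo])
            hit = res >= 0
            idx = np.flatnonzero(todo)[hit]
            tgt_pos[idx] = res[hit]
            tgt_chrom[idx] = chain.q_name
            score[idx] = chain.score
            mapped[idx] = True
        sub = grp.loc[mapped].copy()
        sub["src_chrom"] = src_chrom
        sub["src_pos"] = sub["pos"]
        sub["chain_score"] = score[mapped]
        sub["chrom"] = tgt_chrom[mapped]
        sub["pos"] = tgt_pos[mapped]
        parts.append(sub)
    lifted = (
        pd.concat(parts, ignore_index=True)
        if parts else calls.iloc[0:0].copy()
    )
    if len(lifted):
        # resolve target collisions: higher chain score, then lower source coord
        lifted = lifted.sort_values(
            ["chrom", "pos", "chain_score", "src_pos"],
            ascending=[True, True, False, True],
            kind="mergesort",
        ).drop_duplicates(["chrom", "pos"], keep="first")
        extra = lifted[["src_chrom", "src_pos", "chain_score"]].reset_index(drop=True)
        lifted = as_cpg_track(lifted.drop(columns=["src_chrom", "src_pos", "chain_score"]))
        # as_cpg_track preserves row order only after its own stable sort;
        # re-attach provenance through an explicit sort of both
        lifted[["src_chrom", "src_pos", "chain_score"]] = extra
    n_mapped = len(lifted)
    return LiftedTrack(
        calls=lifted.reset_index(drop=True),
        n_input=n_input, n_mapped=n_mapped, n_unmapped=n_input - n_mapped,
    )


def clean_by_synteny(
    lifted: LiftedTrack, blocks: pd.DataFrame, min_level2_bp: int = 1_000_000
) -> LiftedTrack:
    """Drop sites inside short second-level synteny fills.

    Sites in a level-2 block spanning less than ``min_level2_bp`` are
    removed (small inter/intrachromosomal translocations and duplications);
    all other sites, including those in level-1 blocks of any size, are
    retained.
    """
    calls = lifted.calls
    if not len(calls) or not len(blocks):
        return LiftedTrack(calls.copy(), lifted.n_input, lifted.n_mapped,
                           lifted.n_unmapped, lifted.n_removed)
    bad = blocks[(blocks["level"] == 2) & (blocks["end"] - blocks["start"] < min_level2_bp)]
    drop = np.zeros(len(calls), dtype=bool)
    pos = calls["pos"].to_numpy()
    chrom = calls["chrom"].to_numpy()
    for _, blk in bad.iterrows():
        sel = chrom == blk["chrom"]
        drop |= sel & (pos >= blk["start"]) & (pos < blk["end"])
    kept = calls[~drop].reset_index(drop=True)
    return LiftedTrack(
        calls=kept,
        n_input=lifted.n_input,
        n_mapped=lifted.n_mapped - int(drop.sum()),
        n_unmapped=lifted.n_unmapped,
        n_removed=lifted.n_removed + int(drop.sum()),
    )


def scale_track(values, target_mean: float, target_sd: float) -> np.ndarray:
    """Affine-rescale a series to a target mean and SD (NaN-aware)."""
    x = np.asarray(values, dtype=float)
    mean = np.nanmean(x)
    sd = np.nanstd(x)
    if sd == 0 or np.isnan(sd):
        raise ValueError("cannot scale a series with zero standard deviation")
    return (x - mean) / sd * target_sd + target_mean


@dataclass
class DifferentialRegions:
    """Maximal runs of windows exceeding the differential threshold."""

    regions: pd.DataFrame   # chrom, start, end, direction, max_abs_diff, n_windows
    threshold: float        # in scaled methylation units
    sd_diff: float          # SD of the unsmoothed scaled difference series
    n_windows: int


def differential_regions(
    reference: pd.DataFrame,
    other: pd.DataFrame,
    width: int = 15,
    z_threshold: float = 1.5,
) -> DifferentialRegions:
    """Call regions of differential methylation between two window tracks.

    Both tracks are rescaled to the reference's mean/SD, the per-window
    difference (reference minus other, in which structure shared by the
    two species cancels) is smoothed with a running median — an
    edge-preserving smoother, so planted/real steps keep their extent —
    and the smoothed difference is thresholded at ``z_threshold`` times
    the SD of the *unsmoothed* difference series, i.e. the per-window
    noise scale.  Maximal same-sign runs of exceeding windows become
    regions; direction is 'higher-in-reference' where the difference is
    positive.
    """
    merged = reference.merge(other, on=["chrom", "start"], suffixes=("_ref", "_oth"))
    shared = (~merged["mean_meth_ref"].isna()) & (~merged["mean_meth_oth"].isna())
    if shared.sum() < 30:
        raise ValueError("fewer than 30 shared windows; difference SD unstable")

    ref_raw = merged["mean_meth_ref"].to_numpy(dtype=float)
    oth_raw = merged["mean_meth_oth"].to_numpy(dtype=float)
    mask = ~shared.to_numpy()
    ref_raw[mask] = np.nan
    oth_raw[mask] = np.nan

    t_mean, t_sd = np.nanmean(ref_raw), np.nanstd(ref_raw)
    ref_r = scale_track(ref_raw, t_mean, t_sd)   # identity, kept for symmetry
    oth_r = scale_track(oth_raw, t_mean, t_sd)

    diff_raw = ref_r - oth_r
    diff_parts = []
    for _, grp in merged.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        diff_parts.append(running_median(diff_raw[idx], width))
    diff_s = np.concatenate(diff_parts)
    sd_diff = float(np.nanstd(diff_raw))
    # numerically identical tracks: round-off must not trip the threshold
    thr = max(z_threshold * sd_diff, 1e-9)

    sign = np.zeros(len(diff_s), dtype=int)
    with np.errstate(invalid="ignore"):
        sign[diff_s > thr] = 1
        sign[diff_s < -thr] = -1

    rows = []
    end_col = merged["end_ref"] if "end_ref" in merged else merged["end"]
    for _, grp in merged.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        s = sign[idx]
        i = 0
        while i < len(s):
            if s[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(s) and s[j + 1] == s[i]:
                j += 1
            sel = idx[i:j + 1]
            rows.append(
                {
                    "chrom": grp["chrom"].iloc[0],
                    "start": int(grp["start"].iloc[i]),
                    "end": int(end_col.iloc[sel[-1]]),
                    "direction": "higher-in-reference" if s[i] > 0 else "lower-in-reference",
                    "max_abs_diff": float(np.nanmax(np.abs(diff_s[sel]))),
                    "n_windows": int(j - i + 1),
                }
            )
            i = j + 1
    regions = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "max_abs_diff", "n_windows"]
    )
    return DifferentialRegions(
        regions=regions, threshold=float(thr), sd_diff=sd_diff,
        n_windows=int(shared.sum()),
    )


@dataclass
class BreakEnrichmentResult:
    """Syntenic-break overlap with differential regions vs a uniform null."""

    observed_fraction: float
    null_fractions: np.ndarray
    p_value: float
    n_breaks: int
    applicable: bool = True


def synteny_breaks(blocks: pd.DataFrame, min_level2_bp: int = 1_000_000) -> pd.DataFrame:
    """Break positions: boundaries between level-1 blocks and between
    level-2 blocks larger than ``min_level2_bp`` (smaller fills having been
    removed from the methylation data)."""
    keep = blocks[
        (blocks["level"] == 1)
        | ((blocks["level"] == 2) & (blocks["end"] - blocks["start"] >= min_level2_bp))
    ]
    rows = []
    for chrom, grp in keep.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        edges = np.unique(np.concatenate([g["start"].to_numpy()[1:], g["end"].to_numpy()[:-1]]))
        for e in edges:
            rows.append({"chrom": chrom, "pos": int(e)})
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def _points_in_regions(chrom: np.ndarray, pos: np.ndarray, regions: pd.DataFrame) -> np.ndarray:
    hit = np.zeros(len(pos), dtype=bool)
    for _, reg in regions.iterrows():
        hit |= (chrom == reg["chrom"]) & (pos >= reg["start"]) & (pos < reg["end"])
    return hit


def break_enrichment(
    breaks: pd.DataFrame,
    regions: pd.DataFrame,
    spans: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> BreakEnrichmentResult:
    """Are syntenic breaks enriched (or depleted) in differential regions?

    Observed statistic: fraction of breaks inside a differential region.
    Null: per chromosome, breaks re-placed uniformly within the analyzable
    spans, preserving counts.  The statistic is discrete, so a two-sided
    mid-p empirical p-value is reported (half-weight on ties), which is
    close to uniform under the null rather than lumpily conservative.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not len(breaks):
        return BreakEnrichmentResult(np.nan, np.empty(0), np.nan, 0, applicable=False)
    rng = np.random.default_rng(seed)
    n_breaks = len(breaks)

    observed_hits = 0
    null_hits = np.zeros(n_perm, dtype=np.int64)
    for chrom, grp in breaks.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        regs = regions[regions["chrom"] == chrom]
        observed_hits += int(_points_in_regions(np.repeat(chrom, len(pos)), pos, regs).sum())
        sp = spans[spans["chrom"] == chrom]
        if not len(sp):
            raise ValueError(f"no analyzable span on {chrom}")
        starts = sp["start"].to_numpy()
        lens = (sp["end"] - sp["start"]).to_numpy()
        cum = np.concatenate([[0], np.cumsum(lens)])
        u = rng.integers(0, cum[-1], size=(n_perm, len(pos)))
        k = np.searchsorted(cum, u, side="right") - 1
        placed = starts[k] + (u - cum[k])
        hits = _points_in_regions(
            np.repeat(chrom, placed.size), placed.ravel(), regs
        ).reshape(n_perm, -1)
        null_hits += hits.sum(axis=1)

    observed = observed_hits / n_breaks
    null = null_hits / n_breaks
    greater = int(np.sum(null_hits > observed_hits))
    less = int(np.sum(null_hits < observed_hits))
    ties = n_perm - greater - less
    p_hi = (greater + 0.5 * ties + 0.5) / (n_perm + 1.0)
    p_lo = (less + 0.5 * ties + 0.5) / (n_perm + 1.0)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    return BreakEnrichmentResult(
        observed_fraction=float(observed), null_fractions=null,
        p_value=float(p), n_breaks=n_breaks,
    )


def track_spans(track: pd.DataFrame) -> pd.DataFrame:
    """Maximal runs of non-missing windows, as analyzable-span intervals."""
    rows = []
    for chrom, grp in track.groupby("chrom", sort=False):
        ok = grp["mean_meth"].notna().to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        i = 0
        while i < len(ok):
            if not ok[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(ok) and ok[j + 1]:
                j += 1
            rows.append({"chrom": chrom, "start": int(starts[i]), "end": int(ends[j])})
            i = j + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
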