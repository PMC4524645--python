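"""Synthetic genomes, methylomes, species pairs and expression tables.

The generator produces the statistical structure the analysis modules
assume, at desk scale and fully deterministically given a seed:

* an annotation bundle — CpG positions from an inhomogeneous Poisson
  process with CpG-island enrichment, non-overlapping genes, islands
  (half placed at TSSs), and repeat intervals by class;
* a methylome — alternating PMD/HMD blocks (truncated-exponential
  lengths) or a single state, gene-body elevation for expressed genes,
  CpG-island hypomethylation, truncated-Gaussian per-site noise, and
  binomial read sampling at low coverage;
* a log-normal expression table positively coupled to gene-body
  methylation through a logistic expressed/silent gate;
* a second "species" related to the first by a generated chain map
  (inversions, unmapped spans, planted second-level synteny fills) with
  optional planted differential-methylation regions.

Defaults describe a hypomethylated placenta-like methylome: PMD/HMD
means 0.40/0.80, domain lengths of a few hundred kb, ~5X coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Chain, as_cpg_track
from .genic import promoters_from_genes


@dataclass
class GenomeSpec:
    """Parameters of the synthetic genome annotation bundle."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    cpg_rate: float = 0.005              # background CpG sites per bp (~1 per 200 bp)
    island_enrichment: float = 10.0      # CpG density multiplier inside islands
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    n_islands: int = 400
    island_length_range: tuple[int, int] = (600, 2_000)
    island_tss_fraction: float = 0.5     # fraction of islands anchored at a TSS
    repeat_fractions: dict[str, float] = field(
        default_factory=lambda: {"LINE": 0.10, "SINE": 0.08, "LTR": 0.04}
    )
    repeat_length_range: tuple[int, int] = (300, 6_000)
    seed: int = 0

    def validate(self):
        if any(s <= 0 for s in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be positive")
        if self.cpg_rate <= 0 or self.island_enrichment < 1:
            raise ValueError("invalid CpG density parameters")
        genome = sum(self.chrom_sizes.values())
        if self.n_genes * self.gene_length_range[0] > 0.9 * genome:
            raise ValueError("requested genes cannot be packed into the genome")


@dataclass
class GenomeBundle:
    """Synthetic annotation bundle (no nucleotide sequence is emitted)."""

    spec: GenomeSpec
    chrom_sizes: dict[str, int]
    cpgs: pd.DataFrame        # chrom, pos
    genes: pd.DataFrame       # gene_id, chrom, start, end, strand
    promoters: pd.DataFrame
    islands: pd.DataFrame
    repeats: pd.DataFrame


def _place_nonoverlapping(rng, chrom_sizes, lengths, occupied, max_tries=200):
    """Place intervals of given lengths uniformly without mutual overlap.

    ``occupied`` maps chrom -> list of (start, end) this placement must
    avoid (and appends to).  Chromosomes are chosen size-weighted.
    """
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    out = []
    for L in lengths:
        for _ in range(max_tries):
            c = chroms[rng.choice(len(chroms), p=probs)]
            if chrom_sizes[c] <= L:
                continue
            s = int(rng.integers(0, chrom_sizes[c] - L))
            e = s + L
            if all(e <= a or s >= b for a, b in occupied[c]):
                occupied[c].append((s, e))
                out.append((c, s, e))
                break
        else:
            raise ValueError("could not place feature; genome too crowded")
    return out


def simulate_genome(spec: GenomeSpec) -> GenomeBundle:
    """Draw a deterministic annotation bundle from a genome spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chroms = list(spec.chrom_sizes)

    # genes: non-overlapping by construction
    occupied = {c: [] for c in chroms}
    lengths = rng.integers(*spec.gene_length_range, size=spec.n_genes)
    placed = _place_nonoverlapping(rng, spec.chrom_sizes, lengths, occupied)
    strands = rng.choice(["+", "-"], size=spec.n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(spec.n_genes)],
            "chrom": [p[0] for p in placed],
            "start": [p[1] for p in placed],
            "end": [p[2] for p in placed],
            "strand": strands,
        }
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    # islands: a fraction anchored at TSSs, the rest placed uniformly
    island_occ = {c: [] for c in chroms}
    n_tss = min(int(round(spec.island_tss_fraction * spec.n_islands)), len(genes))
    tss_genes = genes.iloc[rng.choice(len(genes), size=n_tss, replace=False)]
    island_rows = []
    for _, g in tss_genes.iterrows():
        L = int(rng.integers(*spec.island_length_range))
        tss = g["start"] if g["strand"] == "+" else g["end"] - 1
        s = max(0, int(tss - L // 2))
        e = min(spec.chrom_sizes[g["chrom"]], s + L)
        if all(e <= a or s >= b for a, b in island_occ[g["chrom"]]):
            island_occ[g["chrom"]].append((s, e))
            island_rows.append((g["chrom"], s, e))
    extra = spec.n_islands - len(island_rows)
    lengths = rng.integers(*spec.island_length_range, size=extra)
    island_rows += _place_nonoverlapping(rng, spec.chrom_sizes, lengths, island_occ)
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    islands["label"] = "cpg_island"
    islands = islands.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    # repeats by class: repeats may overlap genes but not each other
    rep_occ = {c: [] for c in chroms}
    genome = sum(spec.chrom_sizes.values())
    rep_rows = []
    for cls, frac in spec.repeat_fractions.items():
        target = frac * genome
        total = 0
        while total < target:
            L = int(rng.integers(*spec.repeat_length_range))
            (c, s, e), = _place_nonoverlapping(rng, spec.chrom_sizes, [L], rep_occ)
            rep_rows.append((c, s, e, f"repeat:{cls}"))
            total += L
    repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "label"])
    repeats = repeats.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    # CpG positions: background Poisson plus extra island draws
    cpg_parts = []
    for c in chroms:
        size = spec.chrom_sizes[c]
        n_bg = rng.poisson(spec.cpg_rate * size)
        pos = rng.integers(0, size, size=n_bg)
        isl = islands[islands["chrom"] == c]
        extra_parts = [pos]
        extra_rate = spec.cpg_rate * (spec.island_enrichment - 1.0)
        for _, iv in isl.iterrows():
            n_extra = rng.poisson(extra_rate * (iv["end"] - iv["start"]))
            extra_parts.append(rng.integers(iv["start"], iv["end"], size=n_extra))
        allpos = np.unique(np.concatenate(extra_parts))
        cpg_parts.append(pd.DataFrame({"chrom": c, "pos": allpos}))
    cpgs = pd.concat(cpg_parts, ignore_index=True)

    return GenomeBundle(
        spec=spec, chrom_sizes=dict(spec.chrom_sizes), cpgs=cpgs,
        genes=genes, promoters=promoters_from_genes(genes),
        islands=islands, repeats=repeats,
    )


@dataclass
class MethylomeSpec:
    """Parameters of the synthetic methylome and expression model."""

    pmd_mean: float = 0.40
    hmd_mean: float = 0.80
    pmd_sd: float = 0.03                 # SD of per-domain baselines
    hmd_sd: float = 0.03
    domain_length_mean: float = 250_000  # truncated exponential, bp
    domain_length_min: float = 120_000
    domain_length_max: float = 800_000
    single_state_mean: float | None = None  # set to disable PMD/HMD structure
    single_state_sd: float = 0.03
    gene_body_delta: float = 0.10        # elevation over expressed gene bodies
    island_mean: float | None = 0.10     # island override; None disables
    site_noise_sd: float = 0.03          # truncated-Gaussian per-CpG noise
    mean_depth: float = 5.0              # Poisson read depth per site
    kappa: float = 8.0                   # logistic coupling, methylation -> P(expressed)
    expressed_fpkm_log_mean: float = 1.6   # natural-log params, median ~5 FPKM
    expressed_fpkm_log_sd: float = 1.0
    silent_fpkm_log_mean: float = -3.9     # median ~0.02 FPKM
    silent_fpkm_log_sd: float = 1.0
    seed: int = 0

    def validate(self):
        for m in (self.pmd_mean, self.hmd_mean):
            if not 0 <= m <= 1:
                raise ValueError("state means must lie in [0, 1]")
        if self.single_state_mean is not None and not 0 <= self.single_state_mean <= 1:
            raise ValueError("single_state_mean must lie in [0, 1]")
        if self.hmd_mean + self.gene_body_delta > 1 + 1e-9:
            raise ValueError("gene-body elevation pushes methylation above 1")
        if not (0 < self.domain_length_min <= self.domain_length_mean <= self.domain_length_max):
            raise ValueError("invalid domain length distribution")


@dataclass
class MethylomeResult:
    """True per-CpG fractions, observed calls, and planted structure."""

    spec: MethylomeSpec
    truth: pd.DataFrame       # chrom, pos, true_frac, depth
    calls: pd.DataFrame       # CpG track (covered sites only)
    domains: pd.DataFrame     # chrom, start, end, state, baseline
    gene_truth: pd.DataFrame  # gene_id, baseline_meth, expressed
    expression: pd.DataFrame  # gene_id, fpkm


def _draw_domains(rng, chrom_sizes, spec: MethylomeSpec) -> pd.DataFrame:
    rows = []
    for chrom, size in chrom_sizes.items():
        pos = 0
        if spec.single_state_mean is not None:
            state_cycle = ["single"]
            means = {"single": (spec.single_state_mean, spec.single_state_sd)}
        else:
            first = rng.integers(0, 2)
            state_cycle = ["PMD", "HMD"] if first == 0 else ["HMD", "PMD"]
            means = {"PMD": (spec.pmd_mean, spec.pmd_sd), "HMD": (spec.hmd_mean, spec.hmd_sd)}
        k = 0
        while pos < size:
            L = spec.domain_length_min + rng.exponential(
                spec.domain_length_mean - spec.domain_length_min
            )
            L = int(min(L, spec.domain_length_max))
            end = min(pos + L, size)
            if size - end < spec.domain_length_min:
                end = size  # absorb a too-short terminal remainder
            state = state_cycle[k % len(state_cycle)]
            mu, sd = means[state]
            baseline = float(np.clip(rng.normal(mu, sd), 0.02, 0.98))
            rows.append({"chrom": chrom, "start": pos, "end": end,
                         "state": state, "baseline": baseline})
            pos = end
            k += 1
    return pd.DataFrame(rows)


def simulate_methylome(bundle: GenomeBundle, spec: MethylomeSpec) -> MethylomeResult:
    """Draw true per-CpG fractions and observed binomial calls.

    True fraction = domain baseline, +delta over the bodies of expressed
    genes, overridden inside CpG islands, plus truncated-Gaussian site
    noise; observed counts are binomial at Poisson per-site depth
    (zero-depth sites are uncovered and absent from the call track).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    domains = _draw_domains(rng, bundle.chrom_sizes, spec)

    cpgs = bundle.cpgs
    true = np.empty(len(cpgs))
    for chrom, grp in cpgs.groupby("chrom", sort=False):
        dom = domains[domains["chrom"] == chrom]
        idx = np.searchsorted(dom["start"].to_numpy(), grp["pos"].to_numpy(), side="right") - 1
        true[grp.index.to_numpy()] = dom["baseline"].to_numpy()[idx]

    # gene-body baselines (pre-elevation) drive the expression gate
    pos_by_chrom = {c: g["pos"].to_numpy() for c, g in cpgs.groupby("chrom", sort=False)}
    idx_by_chrom = {c: g.index.to_numpy() for c, g in cpgs.groupby("chrom", sort=False)}
    gene_baseline = np.full(len(bundle.genes), np.nan)
    gene_site_idx = []
    for gi, gene in bundle.genes.iterrows():
        pos = pos_by_chrom.get(gene["chrom"], np.empty(0, dtype=np.int64))
        lo = np.searchsorted(pos, gene["start"])
        hi = np.searchsorted(pos, gene["end"])
        rows = idx_by_chrom[gene["chrom"]][lo:hi] if hi > lo else np.empty(0, dtype=np.int64)
        gene_site_idx.append(rows)
        if len(rows):
            gene_baseline[gi] = true[rows].mean()

    center = np.nanmean(gene_baseline)
    logit = spec.kappa * (np.nan_to_num(gene_baseline, nan=center) - center)
    p_expressed = 1.0 / (1.0 + np.exp(-logit))
    expressed = rng.random(len(bundle.genes)) < p_expressed

    for gi, rows in enumerate(gene_site_idx):
        if expressed[gi] and len(rows):
            true[rows] = true[rows] + spec.gene_body_delta

    if spec.island_mean is not None and len(bundle.islands):
        for chrom, grp in bundle.islands.groupby("chrom", sort=False):
            pos = pos_by_chrom.get(chrom)
            if pos is None:
                continue
            rows = idx_by_chrom[chrom]
            for _, iv in grp.iterrows():
                lo = np.searchsorted(pos, iv["start"])
                hi = np.searchsorted(pos, iv["end"])
                true[rows[lo:hi]] = spec.island_mean

    true = np.clip(true + rng.normal(0, spec.site_noise_sd, size=len(true)), 0.0, 1.0)

    depth = rng.poisson(spec.mean_depth, size=len(true))
    meth = rng.binomial(depth, true)
    truth = pd.DataFrame(
        {"chrom": cpgs["chrom"], "pos": cpgs["pos"], "true_frac": true, "depth": depth}
    )
    covered = depth > 0
    calls = as_cpg_track(
        pd.DataFrame(
            {
                "chrom": cpgs["chrom"][covered],
                "pos": cpgs["pos"][covered],
                "meth_reads": meth[covered].astype(float),
                "total_reads": depth[covered].astype(float),
            }
        )
    )

    fpkm = np.where(
        expressed,
        rng.lognormal(spec.expressed_fpkm_log_mean, spec.expressed_fpkm_log_sd, len(expressed)),
        rng.lognormal(spec.silent_fpkm_log_mean, spec.silent_fpkm_log_sd, len(expressed)),
    )
    gene_truth = pd.DataFrame(
        {
            "gene_id": bundle.genes["gene_id"],
            "baseline_meth": gene_baseline,
            "expressed": expressed,
        }
    )
    expression = pd.DataFrame({"gene_id": bundle.genes["gene_id"], "fpkm": fpkm})
    return MethylomeResult(
        spec=spec, truth=truth, calls=calls, domains=domains,
        gene_truth=gene_truth, expression=expression,
    )


def simulate_gene_table(
    n_genes: int = 2000,
    kappa: float = 0.0,
    seed: int = 0,
    spec: MethylomeSpec | None = None,
) -> pd.DataFrame:
    """Gene-level methylation/expression table without a full genome.

    Gene-body methylation is drawn from an equal PMD/HMD-like mixture;
    expression follows the same logistic-gate + log-normal model as
    :func:`simulate_methylome` with coupling strength ``kappa`` (zero
    gives exact independence).
    """
    spec = spec or MethylomeSpec()
    rng = np.random.default_rng(seed)
    state = rng.integers(0, 2, size=n_genes)
    meth = np.where(
        state == 0,
        rng.normal(spec.pmd_mean, 0.08, n_genes),
        rng.normal(spec.hmd_mean, 0.05, n_genes),
    )
    meth = np.clip(meth, 0.0, 1.0)
    p = 1.0 / (1.0 + np.exp(-kappa * (meth - meth.mean())))
    if kappa == 0.0:
        p = np.full(n_genes, 0.5)
    expressed = rng.random(n_genes) < p
    fpkm = np.where(
        expressed,
        rng.lognormal(spec.expressed_fpkm_log_mean, spec.expressed_fpkm_log_sd, n_genes),
        rng.lognormal(spec.silent_fpkm_log_mean, spec.silent_fpkm_log_sd, n_genes),
    )
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "methylation": meth,
            "fpkm": fpkm,
            "expressed": expressed,
        }
    )


# ---------------------------------------------------------------------------
# Species pairs


@dataclass
class SpeciesPair:
    """A second genome/methylome tied to the reference by a chain map."""

    calls: pd.DataFrame        # CpG track in species-2 coordinates
    truth: pd.DataFrame        # chrom, pos, true_frac, ref_pos (species-2 coords)
    chains: list[Chain]        # species-2 -> reference
    synteny: pd.DataFrame      # reference coords: chrom, start, end, level
    diff_regions: pd.DataFrame # reference coords: chrom, start, end, offset
    rearrangements: list[dict]


def _validate_rearrangements(rearrangements, chrom_sizes):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in rearrangements:
        if r["type"] not in ("inversion", "unmapped", "level2"):
            raise ValueError(f"unknown rearrangement type {r['type']!r}")
        c, s, e = r["chrom"], int(r["start"]), int(r["end"])
        if c not in chrom_sizes or not (0 <= s < e <= chrom_sizes[c]):
            raise ValueError(f"rearrangement outside genome: {r}")
        for a, b in by_chrom.get(c, []):
            if s < b and a < e:
                raise ValueError("overlapping rearrangements")
        by_chrom.setdefault(c, []).append((s, e))


def simulate_species_pair(
    bundle: GenomeBundle,
    methylome: MethylomeResult,
    rearrangements: list[dict] | None = None,
    diff_regions: list[dict] | None = None,
    seed: int = 1,
) -> SpeciesPair:
    """Construct a second species from the reference methylome.

    ``rearrangements`` is a list of dicts with keys ``type`` ('inversion',
    'unmapped' or 'level2'), ``chrom``, ``start``, ``end`` in reference
    coordinates: inversions reverse the segment (negative-strand chain),
    unmapped spans get no chain coverage, and level2 segments map normally
    but are recorded as second-level synteny fills.  ``diff_regions`` is a
    list of dicts with ``chrom``, ``start``, ``end``, ``offset``: the
    methylation offset planted in the second species inside the region.

    The second methylome carries the reference's true per-site fractions
    through the map, applies the planted offsets, adds fresh site noise
    and re-samples binomial reads at fresh Poisson depth.
    """
    rearrangements = list(rearrangements or [])
    diff_list = list(diff_regions or [])
    _validate_rearrangements(rearrangements, bundle.chrom_sizes)
    rng = np.random.default_rng(seed)
    spec = methylome.spec

    # positions of reference CpGs in species-2 coordinates
    cpgs = methylome.truth
    sp2_pos = cpgs["pos"].to_numpy().copy()
    for r in rearrangements:
        if r["type"] != "inversion":
            continue
        sel = (cpgs["chrom"] == r["chrom"]).to_numpy() & (sp2_pos >= r["start"]) & (sp2_pos < r["end"])
        sp2_pos[sel] = r["start"] + r["end"] - 1 - sp2_pos[sel]

    # chains: species-2 (t) -> reference (q)
    chains: list[Chain] = []
    cid = 1
    synteny_rows = []
    for chrom, size in bundle.chrom_sizes.items():
        rs = sorted(
            [r for r in rearrangements if r["chrom"] == chrom], key=lambda r: r["start"]
        )
        # identity blocks = complement of inversion/unmapped segments
        blocks = []

        def add_block(s, e):
            if blocks and blocks[-1][1] == s:
                blocks[-1] = (blocks[-1][0], e)
            else:
                blocks.append((s, e))

        pos = 0
        for r in rs:
            if r["start"] > pos:
                add_block(pos, r["start"])
            if r["type"] == "level2":
                add_block(r["start"], r["end"])
                synteny_rows.append(
                    {"chrom": chrom, "start": r["start"], "end": r["end"], "level": 2}
                )
            pos = max(pos, r["end"])
        if pos < size:
            add_block(pos, size)
        if blocks:
            barr = np.array([(s, s, e - s) for s, e in blocks], dtype=np.int64)
            chains.append(
                Chain(
                    chain_id=cid, score=float(sum(e - s for s, e in blocks)),
                    t_name=chrom, t_size=size, t_start=int(blocks[0][0]),
                    t_end=int(blocks[-1][1]),
                    q_name=chrom, q_size=size, q_strand="+",
                    q_start=int(blocks[0][0]), q_end=int(blocks[-1][1]),
                    blocks=barr,
                )
            )
            cid += 1
        for r in rs:
            if r["type"] != "inversion":
                continue
            s, e = int(r["start"]), int(r["end"])
            chains.append(
                Chain(
                    chain_id=cid, score=float(e - s),
                    t_name=chrom, t_size=size, t_start=s, t_end=e,
                    q_name=chrom, q_size=size, q_strand="-",
                    q_start=size - e, q_end=size - s,
                    blocks=np.array([(s, size - e, e - s)], dtype=np.int64),
                )
            )
            cid += 1
        # level-1 fills: chromosome span minus planted level-2 segments
        pos = 0
        l2 = sorted(
            [r for r in rs if r["type"] == "level2"], key=lambda r: r["start"]
        )
        for r in l2:
            if r["start"] > pos:
                synteny_rows.append({"chrom": chrom, "start": pos, "end": r["start"], "level": 1})
            pos = r["end"]
        if pos < size:
            synteny_rows.append({"chrom": chrom, "start": pos, "end": size, "level": 1})

    synteny = (
        pd.DataFrame(synteny_rows)
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )

    # species-2 true fractions: reference truth plus planted offsets
    true2 = cpgs["true_frac"].to_numpy().copy()
    ref_pos = cpgs["pos"].to_numpy()
    diff_df = pd.DataFrame(diff_list, columns=["chrom", "start", "end", "offset"])
    for _, d in diff_df.iterrows():
        sel = (cpgs["chrom"] == d["chrom"]).to_numpy() & (ref_pos >= d["start"]) & (ref_pos < d["end"])
        true2[sel] = true2[sel] + d["offset"]
    true2 = np.clip(true2 + rng.normal(0, spec.site_noise_sd, len(true2)), 0.0, 1.0)

    depth = rng.poisson(spec.mean_depth, size=len(true2))
    meth = rng.binomial(depth, true2)
    truth2 = pd.DataFrame(
        {
            "chrom": cpgs["chrom"],
            "pos": sp2_pos,
            "true_frac": true2,
            "ref_pos": ref_pos,
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    covered = depth > 0
    calls2 = as_cpg_track(
        pd.DataFrame(
            {
                "chrom": cpgs["chrom"][covered],
                "pos": sp2_pos[covered],
                "meth_reads": meth[covered].astype(float),
                "total_reads": depth[covered].astype(float),
            }
        )
    )
    return SpeciesPair(
        calls=calls2, truth=truth2, chains=chains, synteny=synteny,
        diff_regions=diff_df, rearrangements=rearrangements,
    )


def demo_genome_spec(seed: int = 0) -> GenomeSpec:
    """The bundled demo genome: 2 chromosomes x 10 Mb, ~100k CpGs."""
    return GenomeSpec(seed=seed)


def demo_methylome_spec(seed: int = 0, domains_only: bool = False) -> MethylomeSpec:
    """Demo methylome conditions; ``domains_only`` disables gene-body
    elevation and island override, leaving pure PMD/HMD block structure."""
    spec = MethylomeSpec(seed=seed)
    if domains_only:
        spec = replace(spec, gene_body_delta=0.0, island_mean=None)
    return spec
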