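"""Ground-truth-known synthetic inputs for the whole pipeline.

``simulate_regulome`` draws TF expression from smooth latent-trajectory curves
(so pseudotime exists), accessibility probabilities per region with optional
branch-specific closures, and computes target expression exactly through the
interaction model Y = sum beta * e * a + Gaussian noise, floored at 0.  The
toy genome carries each wired TF's motif consensus inside its wired region, so
a motif scan rediscovers the wiring without threshold tuning, and gene bodies
are laid out so every wired region falls in its target's regulatory window.

``simulate_screen`` emulates a pooled CRISPR screen: bimodal guide UMI counts
(ambient low / real high log-normal components), branch composition shifted by
target-specific log odds, a configurable fraction of phenotypically
unperturbed escapers, and expression effects on a known gene set.

``simulate_fate_inputs`` produces the cluster-level absorption probabilities,
pseudotime and connectivities of a three-branch trajectory with a known branch
partition, for the fate-graph assignment benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    BASES,
    GeneAnnotation,
    MotifPFM,
    PairedMatrix,
    RegionSet,
    ValidationError,
)

# genome layout constants: one locus block per target, spaced beyond the
# 100-kb regulatory window so windows do not overlap neighbouring blocks
REGION_LEN = 400
REGION_SPACING = 200
GENE_LEN = 2000
BLOCK_STRIDE = 110_000
MOTIF_LEN = 8


@dataclass
class SyntheticTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    tf_ids: list[str]
    target_ids: list[str]
    region_ids: list[str]
    wiring: pd.DataFrame                      # tf, region_id, target, beta_true
    noise_sd: float
    genome: dict[str, str]
    placements: pd.DataFrame                  # region_id, motif_id, tf, offset, strand
    branch_closed_regions: dict[str, set]     # branch -> closed region ids
    screen_truth: dict = field(default_factory=dict)


@dataclass
class SimulatedScreen:
    """Synthetic pooled-screen tables plus their generating truth."""

    umi_counts: pd.DataFrame      # cells x guides
    guide_map: pd.Series          # guide -> target
    obs_meta: pd.DataFrame        # organoid, branch, cell_type, n_features
    expression: pd.DataFrame      # cells x genes, log-normalized scale
    true_assignment: pd.DataFrame # cells x guides binary
    perturbed: pd.Series          # cell -> bool (carries a phenotype)
    effect_genes: dict[str, list[str]]
    screen_truth: dict[str, tuple[str, float]]


def _smooth_curve(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A nonnegative Gaussian-bump trajectory over pseudotime."""
    amp = rng.uniform(1.0, 3.0)
    mu = rng.uniform(0.0, 1.0)
    width = rng.uniform(0.15, 0.4)
    base = rng.uniform(0.1, 0.5)
    return base + amp * np.exp(-((t - mu) ** 2) / (2 * width ** 2))


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _consensus_pfm(motif_id: str, tf: str, consensus: np.ndarray) -> MotifPFM:
    mat = np.full((4, len(consensus)), 5.0)
    mat[consensus, np.arange(len(consensus))] = 85.0
    return MotifPFM(motif_id, [tf], mat)


def simulate_regulome(
    n_tfs: int = 10,
    n_targets: int = 200,
    n_regions: int | None = None,
    n_obs: int = 500,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_branches: int = 3,
    n_organoids: int = 4,
    closed_fraction: float = 0.1,
    all_open: bool = False,
    region_len: int = REGION_LEN,
    motif_len: int = MOTIF_LEN,
) -> tuple[SyntheticTruth, PairedMatrix, RegionSet, GeneAnnotation, list[MotifPFM], dict[str, str]]:
    """Simulate a full regulome with known wiring.

    Each target owns a locus block: its wired candidate regions directly
    upstream of a 2-kb gene body, one region per wired edge.  Activating edges
    dominate (the first edge of every target is positive), keeping the linear
    predictor mostly positive so the expression floor at 0 bites rarely.
    Unless ``all_open``, a ``closed_fraction`` of regions is closed
    (accessibility 0) in one randomly chosen branch each.
    """
    if min(n_tfs, n_targets, n_obs) < 1 or noise_sd < 0:
        raise ValidationError("counts must be >= 1 and noise_sd >= 0")
    if n_regions is None:
        n_regions = 2 * n_targets
    if n_regions < n_targets:
        raise ValidationError("need at least one region per target")
    if region_len < motif_len:
        raise ValidationError("region shorter than motif: placement infeasible")
    rng = np.random.default_rng(seed)

    tf_ids = [f"TF{i}" for i in range(n_tfs)]
    target_ids = [f"G{i}" for i in range(n_targets)]
    branches = [f"branch{i}" for i in range(n_branches)]

    # observations: pseudotime, branch, organoid
    t = rng.uniform(0.0, 1.0, size=n_obs)
    branch = rng.choice(branches, size=n_obs)
    organoid = rng.integers(n_organoids, size=n_obs)
    obs_ids = [f"obs{i}" for i in range(n_obs)]

    # TF expression: smooth curve x mild branch modulation + jitter, >= 0
    e = np.empty((n_tfs, n_obs))
    for i in range(n_tfs):
        curve = _smooth_curve(t, rng)
        mod = rng.uniform(0.7, 1.3, size=n_branches)
        scale = mod[[branches.index(b) for b in branch]]
        e[i] = np.maximum(curve * scale + rng.normal(0, 0.15, n_obs), 0.0)

    # motifs: one per TF, distinct consensi
    consensi: list[np.ndarray] = []
    seen = set()
    while len(consensi) < n_tfs:
        c = _random_seq(motif_len, rng)
        key = c.tobytes()
        if key not in seen:
            seen.add(key)
            consensi.append(c)
    motifs = [
        _consensus_pfm(f"M{i}", tf_ids[i], consensi[i]) for i in range(n_tfs)
    ]

    # allocate regions to targets (>= 1 each, at most 3 wired edges per target)
    per_target = np.full(n_targets, n_regions // n_targets)
    per_target[: n_regions % n_targets] += 1
    per_target = np.minimum(per_target, 3)

    # genome layout and wiring
    chrom = "chr1"
    genome_len = n_targets * BLOCK_STRIDE + BLOCK_STRIDE
    genome_codes = _random_seq(genome_len, rng)
    region_rows, gene_rows, wiring_rows, placement_rows = [], [], [], []
    region_access_params = []
    for k, target in enumerate(target_ids):
        block = k * BLOCK_STRIDE + 1000
        n_edges = int(per_target[k])
        tfs = rng.choice(n_tfs, size=min(n_edges, n_tfs), replace=False)
        pos = block
        for j, tf_idx in enumerate(tfs):
            start, end = pos, pos + region_len
            rid = f"{chrom}:{start}-{end}"
            region_rows.append((chrom, start, end, rid))
            beta = (
                rng.uniform(1.0, 2.5)
                if j == 0
                else (rng.uniform(0.5, 2.0) if rng.random() < 0.6 else rng.uniform(-1.5, -0.3))
            )
            wiring_rows.append((tf_ids[tf_idx], rid, target, beta))
            offset = int(rng.integers(0, region_len - motif_len + 1))
            genome_codes[start + offset : start + offset + motif_len] = consensi[tf_idx]
            placement_rows.append((rid, f"M{tf_idx}", tf_ids[tf_idx], offset, "+"))
            pos = end + REGION_SPACING
        gene_start = pos + 1000
        gene_rows.append((target, chrom, gene_start, gene_start + GENE_LEN, "+"))
    # TF gene bodies live in the trailing block (no wired regions of their own)
    tail = n_targets * BLOCK_STRIDE + 1000
    for i, tf in enumerate(tf_ids):
        s = tail + i * (GENE_LEN + 500)
        gene_rows.append((tf, chrom, s, s + GENE_LEN, "+" if i % 2 == 0 else "-"))

    regions = RegionSet(
        pd.DataFrame(region_rows, columns=["chrom", "start", "end", "region_id"])
    )
    region_ids = list(regions.df["region_id"])
    genes = GeneAnnotation(
        pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )
    wiring = pd.DataFrame(wiring_rows, columns=["tf", "region_id", "target", "beta_true"])
    placements = pd.DataFrame(
        placement_rows, columns=["region_id", "motif_id", "tf", "offset", "strand"]
    )

    # accessibility: smooth per-region curve + jitter, clipped to [0, 1]
    a = np.empty((len(region_ids), n_obs))
    for r in range(len(region_ids)):
        base = rng.uniform(0.4, 0.8)
        amp = rng.uniform(-0.15, 0.15)
        mu = rng.uniform(0.0, 1.0)
        curve = base + amp * np.exp(-((t - mu) ** 2) / 0.08)
        a[r] = np.clip(curve + rng.normal(0, 0.05, n_obs), 0.0, 1.0)

    branch_closed: dict[str, set] = {b: set() for b in branches}
    if not all_open and closed_fraction > 0:
        n_closed = int(np.floor(closed_fraction * len(region_ids)))
        closed_idx = rng.choice(len(region_ids), size=n_closed, replace=False)
        for r in closed_idx:
            b = branches[int(rng.integers(n_branches))]
            branch_closed[b].add(region_ids[r])
            a[r, np.asarray(branch) == b] = 0.0

    # target expression through the generating model, floored at 0
    y = np.zeros((n_targets, n_obs))
    tf_index = {tf: i for i, tf in enumerate(tf_ids)}
    region_index = {rid: i for i, rid in enumerate(region_ids)}
    for tf, rid, target, beta in wiring.itertuples(index=False):
        y[target_ids.index(target)] += beta * e[tf_index[tf]] * a[region_index[rid]]
    if noise_sd > 0:
        y += rng.normal(0, noise_sd, y.shape)
    y = np.maximum(y, 0.0)

    base_seq = "".join(BASES[c] for c in genome_codes)
    genome = {chrom: base_seq}
    expression = pd.DataFrame(
        np.vstack([e, y]), index=tf_ids + target_ids, columns=obs_ids
    )
    accessibility = pd.DataFrame(a, index=region_ids, columns=obs_ids)
    obs_meta = pd.DataFrame(
        {
            "branch": branch,
            "pseudotime": t,
            "organoid": [f"org{o}" for o in organoid],
            "condition": "ctrl",
        },
        index=obs_ids,
    )
    truth = SyntheticTruth(
        tf_ids=tf_ids,
        target_ids=target_ids,
        region_ids=region_ids,
        wiring=wiring,
        noise_sd=noise_sd,
        genome=genome,
        placements=placements,
        branch_closed_regions=branch_closed,
    )
    data = PairedMatrix(expression, accessibility, obs_meta)
    return truth, data, regions, genes, motifs, genome


def truth_sites(truth: SyntheticTruth) -> pd.DataFrame:
    """The generator's motif placements as a BindingSiteTable frame."""
    df = truth.placements.copy()
    df["logodds_score"] = np.nan
    return df[["region_id", "motif_id", "tf", "strand", "offset", "logodds_score"]]


def null_regulome(
    n_tfs: int = 10,
    n_targets: int = 100,
    n_obs: int = 300,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[SyntheticTruth, PairedMatrix]:
    """A regulome whose wiring exists structurally but has beta_true = 0 everywhere.

    Target expression is pure floored noise, independent of every design term —
    the null for false-discovery-rate control checks.
    """
    truth, data, *_ = simulate_regulome(
        n_tfs=n_tfs, n_targets=n_targets, n_obs=n_obs, noise_sd=0.0,
        seed=seed, all_open=True,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 982451653]))
    truth.wiring["beta_true"] = 0.0
    y = np.maximum(rng.normal(0, noise_sd, (len(truth.target_ids), data.n_obs)), 0.0)
    expression = data.expression.copy()
    expression.loc[truth.target_ids] = y
    truth.noise_sd = noise_sd
    return truth, PairedMatrix(expression, data.accessibility, data.obs_meta)


def simulate_screen(
    n_cells: int = 2000,
    targets: Sequence[str] = tuple(f"T{i}" for i in range(20)),
    guides_per_target: int = 3,
    effect_sizes: Mapping[str, tuple[str, float]] | None = None,
    seed: int = 0,
    n_organoids: int = 4,
    n_genes: int = 500,
    n_effect_genes: int = 20,
    expr_effect: float = 1.0,
    escaper_fraction: float = 0.2,
    branches: Sequence[str] = ("dorsal", "ventral", "nontelen"),
    high_ln_mean: float = float(np.log(50.0)),
    low_ln_mean: float = float(np.log(2.0)),
    ln_sd: float = 0.5,
) -> SimulatedScreen:
    """Simulate a pooled CRISPR screen with known assignment and phenotype truth.

    Every cell carries exactly one true guide whose UMI count comes from the
    high log-normal component; a Poisson number of ambient guides get low
    counts, producing the bimodal ln-count mixture.  ``effect_sizes`` maps a
    target to (branch, log-odds shift) applied to that cell's branch sampling;
    unlisted targets have no composition effect.  A fraction
    ``escaper_fraction`` of guide-carrying cells receives no expression shift.
    """
    targets = list(targets)
    if n_cells < 10 * len(targets):
        raise ValidationError("need n_cells >= 10 x number of targets")
    if effect_sizes:
        unknown = set(effect_sizes) - set(targets)
        if unknown:
            raise ValidationError(f"effect size for unknown target(s): {sorted(unknown)}")
    effect_sizes = dict(effect_sizes or {})
    bad_branch = {t: b for t, (b, _) in effect_sizes.items() if b not in branches}
    if bad_branch:
        raise ValidationError(f"unknown branch in effect sizes: {bad_branch}")
    rng = np.random.default_rng(seed)

    guides = [f"{t}_g{j}" for t in targets for j in range(guides_per_target)]
    guide_map = pd.Series(
        {g: t for t in targets for g in [f"{t}_g{j}" for j in range(guides_per_target)]}
    )
    cells = [f"cell{i}" for i in range(n_cells)]
    n_guides = len(guides)

    true_guide = rng.integers(n_guides, size=n_cells)
    organoid = rng.integers(n_organoids, size=n_cells)
    perturbed = rng.random(n_cells) >= escaper_fraction

    # branch sampling with target-specific log-odds shifts
    base_probs = np.array([0.40, 0.35, 0.25])[: len(branches)]
    base_probs = base_probs / base_probs.sum()
    logits = np.log(base_probs)
    branch_labels = np.empty(n_cells, dtype=object)
    for i in range(n_cells):
        li = logits.copy()
        target = guide_map[guides[true_guide[i]]]
        if target in effect_sizes:
            b, shift = effect_sizes[target]
            li[list(branches).index(b)] += shift
        p = np.exp(li - li.max())
        p /= p.sum()
        branch_labels[i] = branches[rng.choice(len(branches), p=p)]

    # UMI counts: true guide high, ambient guides low
    counts = np.zeros((n_cells, n_guides), dtype=np.int64)
    true_counts = np.maximum(
        np.rint(np.exp(rng.normal(high_ln_mean, ln_sd, n_cells))), 1
    ).astype(np.int64)
    counts[np.arange(n_cells), true_guide] = true_counts
    n_ambient = rng.poisson(1.5, size=n_cells)
    for i in range(n_cells):
        if n_ambient[i] == 0:
            continue
        others = rng.choice(n_guides, size=min(n_ambient[i], n_guides), replace=False)
        others = others[others != true_guide[i]]
        if len(others):
            counts[i, others] = np.maximum(
                np.rint(np.exp(rng.normal(low_ln_mean, ln_sd, len(others)))), 1
            ).astype(np.int64)

    # expression: nonnegative baseline plus per-target effects in perturbed cells
    gene_ids = [f"gene{i}" for i in range(n_genes)]
    mu = rng.uniform(0.5, 2.0, size=n_genes)
    y = np.maximum(rng.normal(mu, 1.0, size=(n_cells, n_genes)), 0.0)
    effect_genes: dict[str, list[str]] = {}
    for t_idx, target in enumerate(targets):
        g_idx = rng.choice(n_genes, size=min(n_effect_genes, n_genes), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(g_idx))
        effect_genes[target] = [gene_ids[g] for g in g_idx]
        carriers = np.array(
            [guide_map[guides[true_guide[i]]] == target for i in range(n_cells)]
        )
        affected = carriers & perturbed
        if affected.any():
            y[np.ix_(affected, g_idx)] = np.maximum(
                y[np.ix_(affected, g_idx)] + signs * expr_effect, 0.0
            )

    true_assignment = np.zeros_like(counts, dtype=np.int8)
    true_assignment[np.arange(n_cells), true_guide] = 1
    n_features = (y > 0).sum(axis=1)
    obs_meta = pd.DataFrame(
        {
            "organoid": [f"org{o}" for o in organoid],
            "branch": branch_labels,
            "cell_type": branch_labels,
            "n_features": n_features,
        },
        index=cells,
    )
    return SimulatedScreen(
        umi_counts=pd.DataFrame(counts, index=cells, columns=guides),
        guide_map=guide_map,
        obs_meta=obs_meta,
        expression=pd.DataFrame(y, index=cells, columns=gene_ids),
        true_assignment=pd.DataFrame(true_assignment, index=cells, columns=guides),
        perturbed=pd.Series(perturbed, index=cells),
        effect_genes=effect_genes,
        screen_truth=effect_sizes,
    )


def simulate_fate_inputs(
    n_clusters: int = 60,
    branches: Sequence[str] = ("dorsal", "ventral", "nontelen"),
    split_at: float = 0.3,
    noise: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Cluster-level inputs of a known branching trajectory.

    Returns (absorption probabilities, pseudotime, connectivities, true
    labels).  Clusters before ``split_at`` form a shared trunk (true label:
    all branch names joined by "+"); afterwards each branch runs as a chain of
    clusters whose absorption probability into its own terminal state rises
    with pseudotime.  Connectivities are high along chains and across the
    split point, low elsewhere.
    """
    rng = np.random.default_rng(seed)
    branches = list(branches)
    n_b = len(branches)
    n_trunk = max(2, int(round(n_clusters * split_at)))
    n_rest = n_clusters - n_trunk
    per_branch = [n_rest // n_b + (1 if i < n_rest % n_b else 0) for i in range(n_b)]

    names, pt, probs, true = [], [], [], []
    chains: list[list[int]] = []
    trunk_chain = []
    for i in range(n_trunk):
        names.append(f"c{len(names)}")
        pt.append(split_at * (i + 1) / (n_trunk + 1))
        probs.append(np.full(n_b, 1.0 / n_b))
        true.append("+".join(sorted(branches)))
        trunk_chain.append(len(names) - 1)
    chains.append(trunk_chain)
    for b_idx, b in enumerate(branches):
        chain = [trunk_chain[-1]]
        for i in range(per_branch[b_idx]):
            names.append(f"c{len(names)}")
            frac = (i + 1) / per_branch[b_idx]
            pt.append(split_at + (1 - split_at) * frac)
            p = np.full(n_b, (1.0 - (1.0 / n_b + frac * (1 - 1.0 / n_b) * 0.95)) / (n_b - 1))
            p[b_idx] = 1.0 / n_b + frac * (1 - 1.0 / n_b) * 0.95
            probs.append(p)
            true.append(b)
            chain.append(len(names) - 1)
        chains.append(chain)

    probs = np.asarray(probs) + rng.normal(0, noise, size=(len(names), n_b))
    probs = np.clip(probs, 1e-4, 1.0)
    probs = probs / probs.sum(axis=1, keepdims=True)

    conn = np.full((len(names), len(names)), 0.02)
    # the trunk and each branch's first cluster form one well-connected hub so
    # that any kNN pair drawn among them survives the connectivity threshold
    hub = list(trunk_chain) + [chain[1] for chain in chains[1:] if len(chain) > 1]
    for u in hub:
        for v in hub:
            if u != v:
                conn[u, v] = 0.3
    for chain in chains:
        for u, v in zip(chain[:-1], chain[1:]):
            conn[u, v] = conn[v, u] = 0.9
    np.fill_diagonal(conn, 0.0)

    absorption = pd.DataFrame(probs, index=names, columns=branches)
    pseudotime = pd.Series(pt, index=names, dtype=float)
    connectivities = pd.DataFrame(conn, index=names, columns=names)
    return absorption, pseudotime, connectivities, pd.Series(true, index=names)
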