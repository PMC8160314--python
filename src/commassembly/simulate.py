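"""Synthetic communities assembled under known ecological regimes.

The study system (anaerobic granule microbiomes profiled by 16S ASVs)
does not come with ground truth about which assembly process produced
which samples, so this module builds datasets where the truth is known
by construction: a pure-birth phylogeny, a Brownian trait evolving
along it (the phylogenetically conserved niche axis that selection acts
on), a log-normal regional species-abundance pool, and per-regime
community sampling:

* ``homogeneous_selection`` — every sample filtered through one shared
  Gaussian niche optimum on the trait;
* ``variable_selection`` — two sample blocks with optima at least four
  trait standard deviations apart;
* ``dispersal_limitation`` — disjoint taxon subpools per sample block,
  followed by Wright-Fisher drift with weak migration from the
  metacommunity;
* ``homogenizing_dispersal`` — all samples resampled from a single
  realised "mother" community (mass effects);
* ``pure_drift`` — i.i.d. multinomial draws from the pool;
* ``nst_null`` — a drift table passed through the proportional-fixed
  stochasticity null (for self-calibration of NST).

A 24-sample preset mirrors the shape of a two-position x two
nucleic-acid x three-reactor granule study, with a clade-derived
synthetic taxonomy so clade-level (lottery) analyses run end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._seeds import derive_seed
from .errors import ValidationError
from .io import AbundanceTable, SampleMetadata, TaxonomyMap

REGIMES = (
    "homogeneous_selection",
    "variable_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "pure_drift",
    "nst_null",
)


#: pool evenness per regime: selection detection (abundance-weighted
#: betaNTI) needs turnover spread over many niche members, hence a
#: fairly even pool; dispersal detection (RC_bray occupancy null) needs
#: a rare-taxon tail, hence a heavy-tailed pool.
REGIME_POOL_SIGMA = {
    "homogeneous_selection": 0.5,
    "variable_selection": 0.5,
    "dispersal_limitation": 2.0,
    "homogenizing_dispersal": 2.5,
    "pure_drift": 2.0,
    "nst_null": 1.0,
}


@dataclass
class Scenario:
    """Parameters of one simulated assembly experiment.

    ``selection_width`` is the Gaussian niche width on the raw trait
    axis used by variable selection; ``conserved_width`` the relative
    niche width (in sd units of the conserved trait) for homogeneous
    selection; ``establishment_prob`` the per-sample probability that a
    niche member establishes at all (the membership lottery);
    ``demographic_sigma`` the log-normal sd of per-sample abundance
    jitter; ``migration`` the per-generation fraction of reads replaced
    by metacommunity migrants during drift. ``lognormal_sigma`` (pool
    evenness) defaults per regime, see ``REGIME_POOL_SIGMA``.
    """

    regime: str = "pure_drift"
    n_taxa_pool: int = 128
    n_samples: int = 10
    depth: int = 2000
    selection_width: float = 0.5
    conserved_width: float = 0.05
    niche_conservatism: float = 0.5
    niche_clade_fraction: float = 0.25
    establishment_prob: float = 0.5
    demographic_sigma: float = 0.75
    trait_sigma: float = 1.0
    migration: float = 0.001
    n_subpools: int = 2
    n_generations: int = 20
    lognormal_sigma: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.lognormal_sigma is None:
            self.lognormal_sigma = REGIME_POOL_SIGMA[self.regime]
        if self.depth < 100:
            raise ValidationError("depth must be at least 100")
        if self.n_samples < 4:
            raise ValidationError("need at least 4 samples")
        if not (0.0 <= self.migration <= 1.0):
            raise ValidationError("migration must lie in [0, 1]")
        if not (0.0 < self.establishment_prob <= 1.0):
            raise ValidationError("establishment_prob must lie in (0, 1]")
        if not (0.0 < self.niche_conservatism < 1.0):
            raise ValidationError("niche_conservatism must lie in (0, 1)")
        for name in ("n_taxa_pool", "selection_width", "conserved_width",
                     "trait_sigma", "n_subpools", "n_generations"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# tree / trait / pool
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int | None = None) -> TreeNode:
    """Pure-birth (Yule) tree with exponential waiting times, rate 1.

    Tips are labelled ``T0001`` .. in creation order; every branch gets
    strictly positive length (a final waiting interval extends the tips
    alive at the stopping time).
    """
    if n_tips < 3:
        raise ValidationError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    root = TreeNode(length=None)
    first, second = TreeNode(length=0.0), TreeNode(length=0.0)
    root.extend([first, second])
    active = [first, second]
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / len(active))
        for node in active:
            node.length += wait
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        kids = [TreeNode(length=0.0), TreeNode(length=0.0)]
        parent.extend(kids)
        active.extend(kids)
    final = rng.exponential(1.0 / len(active))
    for node in active:
        node.length += final
    for i, tip in enumerate(active):
        tip.name = f"T{i + 1:04d}"
    return root


def _brownian_values(tree: TreeNode, sigma: float, seed: int | None) -> dict[int, float]:
    """One Brownian realisation over every node (keyed by ``id(node)``)."""
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, sigma * np.sqrt(node.length)) if node.length else 0.0
        values[id(node)] = values[id(node.parent)] + step
    return values


def evolve_trait(tree: TreeNode, sigma: float, seed: int | None = None) -> pd.Series:
    """Brownian trait along the tree: child = parent + N(0, sigma^2 * t).

    The root trait is 0; returns tip values indexed by tip name.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    values = _brownian_values(tree, sigma, seed)
    traits = {tip.name: values[id(tip)] for tip in tree.tips()}
    return pd.Series(traits).sort_index()


def conserved_trait(
    tree: TreeNode,
    sigma: float,
    seed: int | None = None,
    depth_fraction: float = 0.5,
) -> tuple[pd.Series, list[tuple[float, int]]]:
    """Phylogenetically conserved component of a Brownian trait.

    For each tip, the trait value of its ancestor at ``depth_fraction``
    of the maximum root-to-tip depth — i.e. the clade-level niche value
    the lineage inherited, before tip-scale wobble accumulated. Within
    a deep clade the conserved value is exactly constant, so filtering
    on it yields clade-coherent communities (niche conservatism).

    Returns the per-tip conserved values (same Brownian realisation as
    :func:`evolve_trait` under the same seed) and the list of
    ``(conserved value, tip count)`` of the clades at the cut.
    """
    values = _brownian_values(tree, sigma, seed)
    depths: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depths[id(node)] = depths[id(node.parent)] + (node.length or 0.0)
    cut = depth_fraction * max(depths[id(t)] for t in tree.tips())

    cons: dict[str, float] = {}
    clades: list[tuple[float, int]] = []

    def walk(node: TreeNode, anchor: TreeNode | None) -> None:
        parent_d = depths[id(node.parent)]
        if anchor is None and depths[id(node)] >= cut > parent_d:
            anchor = node
            n_tips = 1 if node.is_tip() else node.count(tips=True)
            clades.append((values[id(node)], n_tips))
        if node.is_tip():
            cons[node.name] = values[id(anchor)] if anchor is not None else values[id(node)]
        else:
            for child in node.children:
                walk(child, anchor)

    for child in tree.children:
        walk(child, None)
    return pd.Series(cons).sort_index(), clades


def make_pool(tree: TreeNode, seed: int | None = None, lognormal_sigma: float = 1.5) -> pd.Series:
    """Log-normal regional relative abundances over the tree's tips."""
    tips = sorted(t.name for t in tree.tips())
    if len(tips) < 3:
        raise ValidationError("pool needs at least 3 taxa")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(tips))
    return pd.Series(raw / raw.sum(), index=tips)


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def _selection_weights(pool: np.ndarray, traits: np.ndarray, opt: float, width: float) -> np.ndarray:
    w = pool * np.exp(-((traits - opt) ** 2) / (2.0 * width**2))
    s = w.sum()
    if s <= 0:
        raise ValidationError("selection optimum leaves no taxon with positive weight")
    return w / s


def _establishment_lottery(
    weights: np.ndarray,
    rng: np.random.Generator,
    establishment_prob: float,
    demographic_sigma: float,
) -> np.ndarray:
    """Per-sample realisation of selection weights.

    Selection fixes which taxa pass the filter; establishment is a
    lottery (each candidate establishes with probability
    ``establishment_prob``) and realised abundances wobble log-normally
    (``demographic_sigma``). Without this turnover, replicate samples
    from the same selective environment would be near-identical and
    carry no signal for the pairwise null models to evaluate.
    """
    w = weights * rng.lognormal(0.0, demographic_sigma, size=len(weights))
    if establishment_prob < 1.0:
        w = w * (rng.random(len(weights)) < establishment_prob)
    s = w.sum()
    if s <= 0:  # pathological draw: fall back to the unthinned weights
        w = weights
        s = w.sum()
    return w / s


def _drift(counts: np.ndarray, meta_freq: np.ndarray, m: float, generations: int,
           rng: np.random.Generator) -> np.ndarray:
    """Wright-Fisher resampling with migration m from the metacommunity."""
    depth = int(counts.sum())
    for _ in range(generations):
        p = (1.0 - m) * counts / depth + m * meta_freq
        counts = rng.multinomial(depth, p / p.sum())
    return counts


def simulate_community(
    pool: pd.Series,
    traits: pd.Series,
    regime: str,
    scenario: Scenario,
    tree: TreeNode | None = None,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Sample an ASV table under one assembly regime.

    ``tree`` is required for homogeneous selection (the niche optimum
    is defined on the conserved component of the trait, which lives on
    the tree). Returns the table and per-sample truth annotations
    (regime plus the block / subpool each sample was drawn in, for
    between-block contrasts in the recovery tests).
    """
    if regime not in REGIMES:
        raise ValidationError(f"unknown regime {regime!r}")
    taxa = list(pool.index)
    p = pool.to_numpy()
    tr = traits.reindex(pool.index).to_numpy()
    sc = scenario
    rng = np.random.default_rng(derive_seed(sc.seed, "community", regime))
    n, depth = sc.n_samples, sc.depth
    samples = [f"S{i + 1:02d}" for i in range(n)]
    counts = np.zeros((len(taxa), n), dtype=np.int64)
    block = np.zeros(n, dtype=int)

    if regime == "homogeneous_selection":
        # Filtering acts on the conserved (clade-level) trait: the
        # environment favours an existing regional guild. The optimum is
        # the conserved value of a mid-sized deep clade; the narrow
        # width excludes convergent clades, not clade members (whose
        # conserved values are identical).
        if tree is None:
            raise ValidationError("homogeneous_selection needs the tree")
        cons, clades = conserved_trait(
            tree, sc.trait_sigma, derive_seed(sc.seed, "trait"), sc.niche_conservatism
        )
        c = cons.reindex(pool.index).to_numpy()
        target = int(round(sc.niche_clade_fraction * len(taxa)))
        opt = min(clades, key=lambda vc: abs(vc[1] - target))[0]
        width = sc.conserved_width * float(np.std(c))
        w = _selection_weights(p, c, opt, width)
        for j in range(n):
            wj = _establishment_lottery(w, rng, sc.establishment_prob, sc.demographic_sigma)
            counts[:, j] = rng.multinomial(depth, wj)
    elif regime == "variable_selection":
        sd = float(np.std(tr))
        centre = float(np.median(tr))
        opt1, opt2 = centre - 2.0 * sd, centre + 2.0 * sd
        w1 = _selection_weights(p, tr, opt1, sc.selection_width)
        w2 = _selection_weights(p, tr, opt2, sc.selection_width)
        half = n // 2
        for j in range(n):
            block[j] = 0 if j < half else 1
            w = w1 if j < half else w2
            wj = _establishment_lottery(w, rng, sc.establishment_prob, sc.demographic_sigma)
            counts[:, j] = rng.multinomial(depth, wj)
    elif regime == "dispersal_limitation":
        assignment = rng.permutation(len(taxa)) % sc.n_subpools
        for j in range(n):
            block[j] = j % sc.n_subpools
            mask = assignment == block[j]
            sub_p = np.where(mask, p, 0.0)
            sub_p = sub_p / sub_p.sum()
            init = rng.multinomial(depth, sub_p)
            counts[:, j] = _drift(init, p, sc.migration, sc.n_generations, rng)
    elif regime == "homogenizing_dispersal":
        mother = rng.multinomial(depth * 10, p).astype(float)
        mother_freq = mother / mother.sum()
        for j in range(n):
            counts[:, j] = rng.multinomial(depth, mother_freq)
    elif regime == "pure_drift":
        for j in range(n):
            counts[:, j] = rng.multinomial(depth, p)
    else:  # nst_null: drift table passed through the PF stochasticity null
        from .nst import nst_null_table

        for j in range(n):
            counts[:, j] = rng.multinomial(depth, p)
        base = AbundanceTable(pd.DataFrame(counts, index=taxa, columns=samples))
        null = nst_null_table(base, "PF", seed=derive_seed(sc.seed, "nst_null_pass"))
        counts = null.matrix

    table = AbundanceTable(pd.DataFrame(counts, index=taxa, columns=samples)).drop_empty_taxa()
    truth = pd.DataFrame({"sample": samples, "regime": regime, "block": block}).set_index("sample")
    return table, truth


@dataclass
class SimulatedDataset:
    """One complete synthetic experiment with its ground truth."""

    table: AbundanceTable
    tree: TreeNode
    traits: pd.Series
    pool: pd.Series
    truth: pd.DataFrame
    scenario: Scenario


def simulate_dataset(scenario: Scenario) -> SimulatedDataset:
    """Tree + trait + pool + community table for one scenario."""
    sc = scenario
    tree = simulate_tree(sc.n_taxa_pool, derive_seed(sc.seed, "tree"))
    traits = evolve_trait(tree, sc.trait_sigma, derive_seed(sc.seed, "trait"))
    pool = make_pool(tree, derive_seed(sc.seed, "pool"), sc.lognormal_sigma)
    table, truth = simulate_community(pool, traits, sc.regime, sc, tree=tree)
    return SimulatedDataset(table, tree, traits, pool, truth, sc)


# ---------------------------------------------------------------------------
# clade-structured synthetic taxonomy
# ---------------------------------------------------------------------------

def taxonomy_from_tree(tree: TreeNode, family_fraction: float = 0.3,
                       genus_fraction: float = 0.6) -> TaxonomyMap:
    """Synthetic taxonomy by cutting the tree at root-depth quantiles.

    Tips descending from the first ancestor past ``family_fraction`` of
    the maximum root-to-tip depth share a family; likewise for genera
    at ``genus_fraction``. Gives clade structure consistent with the
    phylogeny, so family-level (lottery) analyses are exercisable on
    simulated data.
    """
    depths: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depths[id(node)] = depths[id(node.parent)] + (node.length or 0.0)
    max_depth = max(depths[id(t)] for t in tree.tips())

    def clades_at(cut: float, prefix: str) -> dict[str, str]:
        labels: dict[str, str] = {}
        counter = 0
        for node in tree.preorder():
            parent_d = depths[id(node.parent)] if node.parent is not None else 0.0
            node_d = depths[id(node)]
            is_cut = node_d >= cut and (node.parent is None or parent_d < cut)
            if is_cut:
                counter += 1
                name = f"{prefix}{counter:03d}"
                tips = [node.name] if node.is_tip() else [t.name for t in node.tips()]
                for tip in tips:
                    labels[tip] = name
        return labels

    families = clades_at(family_fraction * max_depth, "Fam")
    genera = clades_at(genus_fraction * max_depth, "Gen")
    lineages = {
        tip.name: (
            "Bacteria", "SimPhylum", "SimClass", "SimOrder",
            families.get(tip.name, ""), genera.get(tip.name, ""), "",
        )
        for tip in tree.tips()
    }
    return TaxonomyMap(lineages)


# ---------------------------------------------------------------------------
# study-shaped preset
# ---------------------------------------------------------------------------

def paper_shaped_dataset(
    seed: int | None = None,
    n_taxa_pool: int = 1800,
    depth: int = 5000,
    regime_by_position: dict[str, str] | None = None,
    selection_width: float = 0.5,
) -> tuple[AbundanceTable, TreeNode, TaxonomyMap, SampleMetadata, dict]:
    """24-sample preset: 2 positions x 2 nucleic acids x 3 reactors.

    Each position gets its own assembly regime (default: homogeneous
    selection for both, with position-specific niche optima emerging
    from independent community draws), so position contrasts are
    non-trivial. Returns everything the pipeline consumes plus a truth
    dict.
    """
    regime_by_position = regime_by_position or {
        "floating": "homogeneous_selection",
        "settled": "homogeneous_selection",
    }
    tree = simulate_tree(n_taxa_pool, derive_seed(seed, "tree"))
    traits = evolve_trait(tree, 1.0, derive_seed(seed, "trait"))
    pool = make_pool(tree, derive_seed(seed, "pool"))
    tax = taxonomy_from_tree(tree)

    frames = []
    meta_rows = []
    truth: dict[str, dict] = {"positions": {}}
    for pos in ("floating", "settled"):
        regime = regime_by_position[pos]
        sc = Scenario(
            regime=regime,
            n_taxa_pool=n_taxa_pool,
            n_samples=12,
            depth=depth,
            selection_width=selection_width,
            seed=derive_seed(seed, "pos", pos),
        )
        table, _ = simulate_community(pool, traits, regime, sc, tree=tree)
        renamed = {}
        k = 0
        for na in ("DNA", "cDNA"):
            for reactor in ("R1", "R2", "R3"):
                for rep in (1, 2):
                    old = table.sample_ids[k]
                    new = f"{pos[:4]}-{na}-{reactor}-{rep}"
                    renamed[old] = new
                    meta_rows.append(
                        {"sample_id": new, "position": pos, "nucleic_acid": na, "reactor": reactor}
                    )
                    k += 1
        df = table.counts.rename(columns=renamed)
        frames.append(df)
        truth["positions"][pos] = {"regime": regime, "seed": sc.seed}
    merged = pd.concat(frames, axis=1).fillna(0).astype(np.int64)
    # re-align to the full taxon set so both positions share one index
    merged = merged.reindex(sorted(merged.index)).fillna(0).astype(np.int64)
    full = AbundanceTable(merged).drop_empty_taxa()
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth.update({"seed": seed, "n_taxa_pool": n_taxa_pool, "depth": depth})
    return full, tree, tax, meta, truth
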