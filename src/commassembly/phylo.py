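"""Phylogenetic null models: MNTD/NTI and betaMNTD/betaNTI.

NTI (nearest taxon index) is the negative z-score of a community's mean
nearest-taxon distance (MNTD) against a richness-preserving
randomisation: values above +2 indicate phylogenetic clustering
(environmental filtering), values below -2 overdispersion
(competition). betaNTI is the between-community analogue: the z-score
of betaMNTD against a tip-shuffling null, and drives the selection
branch of quantitative process estimates (betaNTI > +2 variable
selection, < -2 homogeneous selection).

The nulls are vectorised over randomisation replicates; a single tip
permutation per replicate is shared by every sample pair, the standard
practice for across-all-pairs turnover nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import UndefinedStatisticError, ValidationError
from .io import AbundanceTable

_CHUNK_ELEMS = 8_000_000  # cap on reps x n x n intermediate (floats)


@dataclass
class PhyloDistanceMatrix:
    """Tip-to-tip patristic distances d_kl (sums of branch lengths)."""

    taxon_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.taxon_ids)
        if d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match taxon ids")
        if not np.allclose(d, d.T):
            raise ValidationError("patristic distances must be symmetric")
        if np.any(d < 0):
            raise ValidationError("patristic distances must be non-negative")
        self.data = d
        self._index = {t: i for i, t in enumerate(self.taxon_ids)}

    def restrict(self, taxa: list[str]) -> "PhyloDistanceMatrix":
        """Reorder/subset to ``taxa``; unknown taxa raise with the full list."""
        missing = [t for t in taxa if t not in self._index]
        if missing:
            raise ValidationError(f"taxa missing from distance matrix: {missing}")
        idx = np.array([self._index[t] for t in taxa])
        return PhyloDistanceMatrix(list(taxa), self.data[np.ix_(idx, idx)])

    def between(self, a: str, b: str) -> float:
        return float(self.data[self._index[a], self._index[b]])


def cophenetic_distances(tree: TreeNode) -> PhyloDistanceMatrix:
    """Patristic distance matrix over all tips of a tree."""
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise ValidationError("tree must have at least 2 tips")
    dm = tree.tip_tip_distances()
    return PhyloDistanceMatrix(list(dm.ids), np.asarray(dm.data, dtype=float))


# ---------------------------------------------------------------------------
# MNTD
# ---------------------------------------------------------------------------

def mntd(vector, dist: PhyloDistanceMatrix, abundance_weighted: bool = False) -> float:
    """Mean nearest-taxon distance of one community.

    ``vector`` holds counts (or weights) aligned to ``dist.taxon_ids``;
    presence is ``> 0``. Unweighted: mean over present taxa of the
    distance to the closest other present taxon. Weighted: the same
    minima averaged with relative-abundance weights.
    """
    x = np.asarray(vector, dtype=float)
    if x.shape != (len(dist.taxon_ids),):
        raise ValidationError("vector length does not match distance matrix")
    present = np.flatnonzero(x > 0)
    if len(present) < 2:
        raise UndefinedStatisticError("MNTD needs at least 2 present taxa")
    sub = dist.data[np.ix_(present, present)].copy()
    np.fill_diagonal(sub, np.inf)
    mins = sub.min(axis=1)
    if not abundance_weighted:
        return float(mins.mean())
    w = x[present] / x[present].sum()
    return float((w * mins).sum())


def beta_mntd(x, y, dist: PhyloDistanceMatrix, abundance_weighted: bool = True) -> float:
    """Between-community MNTD.

    Average distance from each taxon in one community to its nearest
    relative in the other, symmetrised over the two directions. A taxon
    shared by both communities is its own nearest relative (distance 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(dist.taxon_ids)
    if x.shape != (n,) or y.shape != (n,):
        raise ValidationError("vector length does not match distance matrix")
    ix, iy = np.flatnonzero(x > 0), np.flatnonzero(y > 0)
    if len(ix) == 0 or len(iy) == 0:
        raise UndefinedStatisticError("betaMNTD needs two non-empty communities")
    sub = dist.data[np.ix_(ix, iy)]
    min_x = sub.min(axis=1)  # nearest in y for each taxon of x
    min_y = sub.min(axis=0)
    if abundance_weighted:
        fx = x[ix] / x[ix].sum()
        fy = y[iy] / y[iy].sum()
        return float(0.5 * ((fx * min_x).sum() + (fy * min_y).sum()))
    return float(0.5 * (min_x.mean() + min_y.mean()))


# ---------------------------------------------------------------------------
# NTI (ses-MNTD with richness null)
# ---------------------------------------------------------------------------

@dataclass
class NTIResult:
    """Per-sample observed MNTD, null moments and NTI = -z."""

    table: pd.DataFrame  # index sample; columns mntd_obs, null_mean, null_sd, nti
    reps: int
    null_model: str
    seed: int | None

    def write(self, path) -> None:
        df = self.table.copy()
        df.index.name = "sample"
        df.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


def _mntd_null_batch(D: np.ndarray, subsets: np.ndarray) -> np.ndarray:
    """Unweighted MNTD for each row of ``subsets`` (reps x richness)."""
    reps, r = subsets.shape
    out = np.empty(reps)
    step = max(1, _CHUNK_ELEMS // (r * r))
    for s in range(0, reps, step):
        block = subsets[s : s + step]
        sub = D[block[:, :, None], block[:, None, :]]
        idx = np.arange(r)
        sub[:, idx, idx] = np.inf
        out[s : s + step] = sub.min(axis=2).mean(axis=1)
    return out


def nti(
    table: AbundanceTable,
    tree: TreeNode,
    reps: int = 999,
    seed: int | None = None,
) -> NTIResult:
    """NTI per sample under the richness null.

    Presence/absence only: each replicate redraws the sample's observed
    richness from the pool of taxa observed anywhere in the table,
    uniformly without replacement, and recomputes unweighted MNTD.
    NTI = -(observed - null mean) / null sd; samples with a degenerate
    null (sd = 0) or fewer than 2 taxa get NaN rather than a silent 0.
    """
    work = table.drop_empty_taxa()
    dist = cophenetic_distances(tree).restrict(work.taxon_ids)
    D = dist.data
    n_pool = len(work.taxon_ids)
    rng = np.random.default_rng(seed)
    rows = {}
    mat = work.matrix
    for j, sample in enumerate(work.sample_ids):
        present = np.flatnonzero(mat[:, j] > 0)
        r = len(present)
        if r < 2:
            rows[sample] = (np.nan, np.nan, np.nan, np.nan)
            continue
        sub = D[np.ix_(present, present)].copy()
        np.fill_diagonal(sub, np.inf)
        obs = sub.min(axis=1).mean()
        # vectorised uniform subsets: top-r of random keys per replicate
        keys = rng.random((reps, n_pool))
        subsets = np.argpartition(keys, r - 1, axis=1)[:, :r]
        null = _mntd_null_batch(D, subsets)
        mu, sd = null.mean(), null.std(ddof=1)
        z = np.nan if sd == 0 else -(obs - mu) / sd
        rows[sample] = (obs, mu, sd, z)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mntd_obs", "null_mean", "null_sd", "nti"]
    )
    return NTIResult(df.loc[work.sample_ids], reps, "richness", seed)


# ---------------------------------------------------------------------------
# betaNTI (tip-shuffle null)
# ---------------------------------------------------------------------------

@dataclass
class BetaMNTDResult:
    """Per-pair observed betaMNTD, null moments and betaNTI."""

    pairs: pd.DataFrame  # columns sample_a, sample_b, bmntd_obs, null_mean, null_sd, bnti
    abundance_weighted: bool
    reps: int
    seed: int | None

    def bnti_lookup(self) -> dict[tuple[str, str], float]:
        out = {}
        for row in self.pairs.itertuples(index=False):
            out[(row.sample_a, row.sample_b)] = row.bnti
            out[(row.sample_b, row.sample_a)] = row.bnti
        return out

    def write(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def _beta_mntd_null_pair(
    D: np.ndarray,
    perms: np.ndarray,
    ix: np.ndarray,
    iy: np.ndarray,
    fx: np.ndarray | None,
    fy: np.ndarray | None,
) -> np.ndarray:
    """betaMNTD of one pair under each tip permutation (rows of perms)."""
    reps = perms.shape[0]
    out = np.empty(reps)
    step = max(1, _CHUNK_ELEMS // max(1, len(ix) * len(iy)))
    for s in range(0, reps, step):
        px = perms[s : s + step][:, ix]  # (b, nx) permuted tip indices
        py = perms[s : s + step][:, iy]
        sub = D[px[:, :, None], py[:, None, :]]  # (b, nx, ny)
        min_x = sub.min(axis=2)
        min_y = sub.min(axis=1)
        if fx is None:
            vals = 0.5 * (min_x.mean(axis=1) + min_y.mean(axis=1))
        else:
            vals = 0.5 * (min_x @ fx + min_y @ fy)
        out[s : s + step] = vals
    return out


def beta_nti(
    table: AbundanceTable,
    tree: TreeNode,
    reps: int = 999,
    seed: int | None = None,
    abundance_weighted: bool = True,
) -> BetaMNTDResult:
    """betaNTI for every sample pair of the table.

    The null permutes taxon labels across the patristic distance matrix
    of the whole tree (equivalently, shuffles all tree tips); one
    permutation per replicate is applied to all pairs. Shuffling over
    every tip — not just taxa observed in the table — is what lets a
    community confined to one clade register as clustered. Pairs whose
    null is degenerate (sd = 0, e.g. identical membership, where
    betaMNTD is invariant under any relabelling) are reported with
    betaNTI = NaN.
    """
    work = table.drop_empty_taxa()
    samples = work.sample_ids
    if len(samples) < 2:
        raise ValidationError("betaNTI needs at least 2 samples")
    full_dist = cophenetic_distances(tree)
    tip_index = {t: i for i, t in enumerate(full_dist.taxon_ids)}
    missing = [t for t in work.taxon_ids if t not in tip_index]
    if missing:
        raise ValidationError(f"taxa missing from tree: {missing}")
    taxon_pos = np.array([tip_index[t] for t in work.taxon_ids])
    dist = full_dist.restrict(work.taxon_ids)
    D = full_dist.data
    n = D.shape[0]
    mat = work.matrix.astype(float)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((reps, n)), axis=1)

    presents = []
    freqs = []
    for j in range(len(samples)):
        idx = np.flatnonzero(mat[:, j] > 0)
        presents.append(taxon_pos[idx])
        f = mat[idx, j] / mat[idx, j].sum()
        freqs.append(f)

    records = []
    for a in range(len(samples)):
        for b in range(a + 1, len(samples)):
            ix, iy = presents[a], presents[b]
            fx = freqs[a] if abundance_weighted else None
            fy = freqs[b] if abundance_weighted else None
            obs = beta_mntd(mat[:, a], mat[:, b], dist, abundance_weighted)
            null = _beta_mntd_null_pair(D, perms, ix, iy, fx, fy)
            mu, sd = null.mean(), null.std(ddof=1)
            z = np.nan if sd == 0 else (obs - mu) / sd
            records.append((samples[a], samples[b], obs, mu, sd, z))
    df = pd.DataFrame(
        records, columns=["sample_a", "sample_b", "bmntd_obs", "null_mean", "null_sd", "bnti"]
    )
    return BetaMNTDResult(df, abundance_weighted, reps, seed)
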