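"""Normalised stochasticity ratio (NST) and its permutation test.

NST asks how close observed community turnover sits to the turnover a
randomly assembled metacommunity would show. For each sample pair the
observed dissimilarity D_ij (Jaccard for incidence, Ruzicka for
abundance) is compared with the mean dissimilarity E_ij of null
communities assembled under a taxa-richness constraint:

* proportional-fixed (PF): each null sample keeps its observed
  richness; membership is drawn without replacement with probability
  proportional to occurrence frequency across samples;
* proportional-proportional (PP): richness itself is a binomial
  realisation with expectation equal to the observed richness, then
  membership is drawn as in PF.

For the abundance metric, reads are allocated to drawn taxa
proportionally to pool-wide relative abundance (at least one read
each), preserving sample totals.

The stochasticity ratio is ST = E/D when D >= E, else (1-E)/(1-D), and
the normalised form rescales ST to [0, 1] so that NST = 1 at D = E
(pure stochasticity) and NST = 0 at maximal deviation in either
direction. Group NST is the mean over within-group pairs and is
conventionally reported as a percentage.

Significance between groups uses a permutation test over sample-group
labels ("PANOVA") on the precomputed pairwise NST values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .io import AbundanceTable
from .metrics import jaccard, ruzicka

CONSTRAINTS = ("PP", "PF")
NST_METRICS = ("jaccard", "ruzicka")


# ---------------------------------------------------------------------------
# null table generation
# ---------------------------------------------------------------------------

def _draw_membership(rng, freq: np.ndarray, size: int) -> np.ndarray:
    """``size`` taxa without replacement, P(i) ~ freq (Gumbel top-k)."""
    with np.errstate(divide="ignore"):
        keys = np.log(freq) + rng.gumbel(size=len(freq))
    keys[freq <= 0] = -np.inf
    return np.argpartition(-keys, size - 1)[:size]


def nst_null_table(
    table: AbundanceTable,
    constraint: str = "PF",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AbundanceTable:
    """One randomised table under a taxa-richness constraint (PF or PP)."""
    if constraint not in CONSTRAINTS:
        raise ValidationError(f"unknown constraint {constraint!r}; choose from {CONSTRAINTS}")
    rng = np.random.default_rng(seed) if rng is None else rng
    mat = table.matrix
    n_taxa, n_samples = mat.shape
    occ = (mat > 0).sum(axis=1).astype(float)
    freq = occ / occ.sum()
    pool_abund = mat.sum(axis=1).astype(float)
    pool_abund = pool_abund / pool_abund.sum()
    n_avail = int(np.count_nonzero(freq > 0))

    out = np.zeros_like(mat)
    for j in range(n_samples):
        r_obs = int((mat[:, j] > 0).sum())
        total = int(mat[:, j].sum())
        if r_obs == 0:
            continue
        if constraint == "PF":
            r = r_obs
        else:  # PP: binomial with expectation r_obs over the pool size
            r = int(rng.binomial(n_avail, r_obs / n_avail))
            r = min(max(r, 1), n_avail, total)  # a null sample cannot be empty
        r = min(r, n_avail)
        members = _draw_membership(rng, freq, r)
        out[members, j] = 1
        remainder = total - r
        if remainder > 0:
            p = pool_abund[members]
            s = p.sum()
            p = np.full(r, 1.0 / r) if s <= 0 else p / s
            out[members, j] += rng.multinomial(remainder, p)
    df = pd.DataFrame(out, index=table.taxon_ids, columns=table.sample_ids)
    return AbundanceTable(df)


# ---------------------------------------------------------------------------
# stochasticity ratio
# ---------------------------------------------------------------------------

def _nst_from_d_e(d: float, e: float) -> tuple[float, float]:
    """(ST, NST) for one pair; edge cases resolved by their limits."""
    if d == e:
        return 1.0, 1.0
    if e <= 0.0 or e >= 1.0:
        # degenerate null with observed deviation: maximal determinism
        return (max(e, 1.0 - e), 0.0)
    if d >= e:
        st = e / d
        nst = (st - e) / (1.0 - e)
    else:
        st = (1.0 - e) / (1.0 - d)
        nst = (st - (1.0 - e)) / e
    return float(st), float(nst)


@dataclass
class NSTResult:
    """Pairwise and group-level normalised stochasticity ratios."""

    pairs: pd.DataFrame  # sample_a, sample_b, D, E, ST, NST
    metric: str
    constraint: str
    reps: int
    seed: int | None

    @property
    def group_nst(self) -> float:
        """Mean NST over the analysed pairs (fraction, not percent)."""
        return float(self.pairs["NST"].mean())

    @property
    def group_nst_percent(self) -> float:
        return 100.0 * self.group_nst

    def nst_lookup(self) -> dict[tuple[str, str], float]:
        out = {}
        for row in self.pairs.itertuples(index=False):
            out[(row.sample_a, row.sample_b)] = row.NST
            out[(row.sample_b, row.sample_a)] = row.NST
        return out

    def write(self, path) -> None:
        df = self.pairs.copy()
        df.insert(2, "metric", self.metric)
        df.insert(3, "constraint", self.constraint)
        df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def stochasticity(
    table: AbundanceTable,
    metric: str = "jaccard",
    constraint: str = "PF",
    reps: int = 1000,
    seed: int | None = None,
    group: list[str] | None = None,
) -> NSTResult:
    """NST over all pairs of one sample group.

    The null pool (occurrence frequencies and pool abundances) is the
    analysed group itself. E_ij is the mean null dissimilarity over
    ``reps`` randomised tables.
    """
    if metric not in NST_METRICS:
        raise ValidationError(f"metric must be one of {NST_METRICS}")
    samples = table.sample_ids if group is None else list(group)
    if len(samples) < 2:
        raise ValidationError("NST needs at least 2 samples")
    sub = table.select_samples(samples).drop_empty_taxa()
    fn = jaccard if metric == "jaccard" else ruzicka
    mat = sub.matrix
    pairs = list(combinations(range(len(samples)), 2))
    obs = np.array([fn(mat[:, i], mat[:, j]) for i, j in pairs])

    rng = np.random.default_rng(seed)
    null_sum = np.zeros(len(pairs))
    for _ in range(reps):
        null = nst_null_table(sub, constraint, rng=rng)
        nm = null.matrix
        null_sum += [fn(nm[:, i], nm[:, j]) for i, j in pairs]
    e = null_sum / reps

    records = []
    for (i, j), d_ij, e_ij in zip(pairs, obs, e):
        st, nst = _nst_from_d_e(float(d_ij), float(e_ij))
        records.append((samples[i], samples[j], float(d_ij), float(e_ij), st, nst))
    df = pd.DataFrame(records, columns=["sample_a", "sample_b", "D", "E", "ST", "NST"])
    return NSTResult(df, metric, constraint, reps, seed)


# ---------------------------------------------------------------------------
# PANOVA
# ---------------------------------------------------------------------------

@dataclass
class PanovaResult:
    groups: list[str]
    statistic: float
    permutations: int
    p_value: float

    def write(self, path) -> None:
        pd.DataFrame(
            [{"groups": ";".join(self.groups), "statistic": self.statistic,
              "permutations": self.permutations, "p_value": self.p_value}]
        ).to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def _group_mean_stat(nst_mat: np.ndarray, labels: np.ndarray, codes: np.ndarray) -> float:
    """Range of within-group mean NST across groups (|difference| for 2)."""
    means = []
    for g in codes:
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            return np.nan
        sub = nst_mat[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        means.append(sub[iu].mean())
    return float(max(means) - min(means))


def panova(
    nst_result: NSTResult,
    groups: dict[str, list[str]],
    permutations: int = 999,
    seed: int | None = None,
) -> PanovaResult:
    """Permutation test for a difference in group-mean NST.

    The statistic is the absolute difference between within-group mean
    pairwise NST values (the range of group means when more than two
    groups are given). The null permutes sample-to-group labels and
    recomputes the statistic from the precomputed pairwise NST matrix;
    p uses the +1 correction (the observed labelling counts as one
    permutation).
    """
    if len(groups) < 2:
        raise ValidationError("PANOVA needs at least 2 groups")
    for g, members in groups.items():
        if len(members) < 3:
            raise ValidationError(f"group {g!r} has fewer than 3 samples")
    samples = [s for members in groups.values() for s in members]
    if len(set(samples)) != len(samples):
        raise ValidationError("groups overlap")
    lookup = nst_result.nst_lookup()
    n = len(samples)
    nst_mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = (samples[i], samples[j])
            if key not in lookup:
                raise ValidationError(f"pair {key} missing from NST result")
            nst_mat[i, j] = nst_mat[j, i] = lookup[key]
    labels = np.concatenate(
        [np.full(len(members), k) for k, members in enumerate(groups.values())]
    )
    codes = np.unique(labels)
    obs = _group_mean_stat(nst_mat, labels, codes)
    if np.isnan(obs):
        raise ValidationError("each group needs at least 2 samples for within-group pairs")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(labels)
        stat = _group_mean_stat(nst_mat, perm, codes)
        if stat >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return PanovaResult(list(groups), obs, permutations, float(p))
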