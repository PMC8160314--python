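"""Quantitative process estimates (QPE).

Each sample pair is assigned to one of five community-assembly
processes. Phylogenetic turnover is screened first: betaNTI > +2 means
variable selection, betaNTI < -2 homogeneous selection. Pairs without a
selection signal are split by the abundance-based Raup-Crick metric
built on Bray-Curtis (RC_bray): > +0.95 dispersal limitation (with
drift), < -0.95 homogenising dispersal, otherwise undominated. All
threshold comparisons are strict, so boundary values fall through to
the weaker call.

The Raup-Crick null conditions on each sample's observed richness and
read total: membership is drawn without replacement with probability
proportional to occupancy in the regional pool, and reads are allocated
proportionally to pool-wide relative abundances (every drawn taxon
keeps at least one read, so realised richness equals drawn richness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import UndefinedStatisticError, ValidationError
from .io import AbundanceTable, SampleMetadata
from .phylo import BetaMNTDResult, beta_nti
from ._seeds import derive_seed


class Process(str, Enum):
    VARIABLE_SELECTION = "variable_selection"
    HOMOGENEOUS_SELECTION = "homogeneous_selection"
    DISPERSAL_LIMITATION = "dispersal_limitation"
    HOMOGENIZING_DISPERSAL = "homogenizing_dispersal"
    UNDOMINATED = "undominated"
    UNDEFINED = "undefined"


DEFINED_PROCESSES = [
    Process.VARIABLE_SELECTION,
    Process.HOMOGENEOUS_SELECTION,
    Process.DISPERSAL_LIMITATION,
    Process.HOMOGENIZING_DISPERSAL,
    Process.UNDOMINATED,
]


@dataclass
class QPEConfig:
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    reps: int = 999
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.bnti_threshold <= 0 or self.rc_threshold <= 0:
            raise ValidationError("QPE thresholds must be positive")


# ---------------------------------------------------------------------------
# Raup-Crick with Bray-Curtis
# ---------------------------------------------------------------------------

def _weighted_subsets(rng, weights: np.ndarray, size: int, reps: int) -> np.ndarray:
    """reps subsets of ``size`` indices, without replacement, P(i) ~ weights.

    Uses the Gumbel top-k trick so all replicates vectorise.
    """
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    keys = logw + rng.gumbel(size=(reps, len(weights)))
    keys[:, weights <= 0] = -np.inf
    return np.argpartition(-keys, size - 1, axis=1)[:, :size]


def _null_assemblage(
    rng,
    occupancy: np.ndarray,
    pool_abund: np.ndarray,
    richness: int,
    total: int,
    reps: int,
) -> np.ndarray:
    """reps null count vectors (reps x n_taxa) for one sample.

    Membership: ``richness`` taxa without replacement, P ~ occupancy.
    Abundance: 1 read per drawn taxon, remainder multinomial with
    probabilities proportional to pool abundance over the drawn taxa.
    """
    n = len(occupancy)
    if richness > np.count_nonzero(occupancy > 0):
        raise ValidationError(
            f"sample richness {richness} exceeds the {np.count_nonzero(occupancy > 0)} "
            "taxa available in the pool"
        )
    if total < richness:
        raise ValidationError("sample total smaller than its richness")
    members = _weighted_subsets(rng, occupancy, richness, reps)
    out = np.zeros((reps, n), dtype=np.int64)
    rows = np.repeat(np.arange(reps), richness)
    out[rows, members.ravel()] = 1
    remainder = total - richness
    if remainder > 0:
        for r in range(reps):
            p = pool_abund[members[r]]
            s = p.sum()
            p = np.full(richness, 1.0 / richness) if s <= 0 else p / s
            out[r, members[r]] += rng.multinomial(remainder, p)
    return out


def rc_bray(
    table: AbundanceTable,
    pair: tuple[str, str],
    reps: int = 999,
    seed: int | None = None,
    pool: list[str] | None = None,
) -> float:
    """Raup-Crick (Bray-Curtis) score for one sample pair, in [-1, +1].

    RC = 2 * [P(null < observed) + 0.5 * P(null = observed)] - 1, over
    ``reps`` null pair draws. Ties are resolved exactly: observed and
    null Bray-Curtis numerators are integers over a common denominator.
    """
    a, b = pair
    pool = table.sample_ids if pool is None else list(pool)
    for s in (a, b):
        if s not in pool:
            raise ValidationError(f"pair sample {s!r} not in the regional pool")
    sub = table.select_samples(pool).drop_empty_taxa()
    mat = sub.matrix
    occupancy = (mat > 0).mean(axis=1)
    pool_abund = mat.sum(axis=1).astype(float)
    pool_abund = pool_abund / pool_abund.sum()

    xa = sub.sample_counts(a)
    xb = sub.sample_counts(b)
    ta, tb = int(xa.sum()), int(xb.sum())
    if ta == 0 or tb == 0:
        raise UndefinedStatisticError("RC_bray needs two non-empty samples")
    obs_num = int(np.abs(xa - xb).sum())

    rng = np.random.default_rng(seed)
    null_a = _null_assemblage(rng, occupancy, pool_abund, int((xa > 0).sum()), ta, reps)
    null_b = _null_assemblage(rng, occupancy, pool_abund, int((xb > 0).sum()), tb, reps)
    null_num = np.abs(null_a - null_b).sum(axis=1)
    less = int((null_num < obs_num).sum())
    ties = int((null_num == obs_num).sum())
    return float(2.0 * (less + 0.5 * ties) / reps - 1.0)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pair(bnti: float, rc: float | None, config: QPEConfig | None = None) -> Process:
    """Five-way assembly-process call for one pair (strict thresholds)."""
    config = config or QPEConfig()
    if bnti is None or (isinstance(bnti, float) and np.isnan(bnti)):
        return Process.UNDEFINED
    if bnti > config.bnti_threshold:
        return Process.VARIABLE_SELECTION
    if bnti < -config.bnti_threshold:
        return Process.HOMOGENEOUS_SELECTION
    if rc is None or (isinstance(rc, float) and np.isnan(rc)):
        raise ValidationError(
            "RC_bray required when |betaNTI| does not exceed the selection threshold"
        )
    if rc > config.rc_threshold:
        return Process.DISPERSAL_LIMITATION
    if rc < -config.rc_threshold:
        return Process.HOMOGENIZING_DISPERSAL
    return Process.UNDOMINATED


# ---------------------------------------------------------------------------
# per-group summary
# ---------------------------------------------------------------------------

@dataclass
class QPESummary:
    """Per-group assembly-process fractions plus the per-pair calls."""

    pairs: pd.DataFrame  # sample_a, sample_b, group, bnti, rc_bray, process
    fractions: pd.DataFrame  # index group; columns = process names + n_pairs, n_undefined
    config: QPEConfig

    def modal_process(self, group: str) -> str:
        row = self.fractions.loc[group, [p.value for p in DEFINED_PROCESSES]]
        return str(row.astype(float).idxmax())

    def write(self, pairs_path, summary_path) -> None:
        self.pairs.to_csv(pairs_path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
        df = self.fractions.copy()
        df.index.name = "group"
        df.to_csv(summary_path, sep="\t", lineterminator="\n", float_format="%.10g")


def qpe_pairs(
    table: AbundanceTable,
    tree: TreeNode,
    config: QPEConfig | None = None,
    group_label: str = "all",
    bnti_result: BetaMNTDResult | None = None,
) -> pd.DataFrame:
    """Classify every pair within one sample set (the regional pool).

    RC_bray is only computed for pairs whose betaNTI does not clear the
    selection threshold, with the pool's occupancy/abundance weights.
    """
    config = config or QPEConfig()
    if bnti_result is None:
        bnti_result = beta_nti(
            table, tree, reps=config.reps, seed=derive_seed(config.seed, "bnti", group_label)
        )
    records = []
    for k, row in enumerate(bnti_result.pairs.itertuples(index=False)):
        bnti = row.bnti
        rc = np.nan
        if not np.isnan(bnti) and abs(bnti) <= config.bnti_threshold:
            rc = rc_bray(
                table,
                (row.sample_a, row.sample_b),
                reps=config.reps,
                seed=derive_seed(config.seed, "rc", group_label, str(k)),
            )
        proc = classify_pair(bnti, None if np.isnan(rc) else rc, config)
        records.append((row.sample_a, row.sample_b, group_label, bnti, rc, proc.value))
    return pd.DataFrame(
        records, columns=["sample_a", "sample_b", "group", "bnti", "rc_bray", "process"]
    )


def qpe_summary(
    table: AbundanceTable,
    tree: TreeNode,
    metadata: SampleMetadata | None = None,
    grouping: list[str] | None = None,
    config: QPEConfig | None = None,
) -> QPESummary:
    """Per-group QPE: fractions of pairs per process (a stacked-bar input).

    The regional pool for each group's null models is the group itself.
    Pairs with undefined betaNTI are excluded from fraction denominators
    and reported in ``n_undefined``. Groups with fewer than 2 samples
    are skipped with a warning.
    """
    import warnings

    config = config or QPEConfig()
    if metadata is None or grouping is None:
        groups = {"all": table.sample_ids}
    else:
        groups = metadata.groups(grouping, table.sample_ids)
    all_pairs = []
    frac_rows = {}
    for label, samples in groups.items():
        if len(samples) < 2:
            warnings.warn(f"group {label!r} has fewer than 2 samples; skipped", stacklevel=2)
            continue
        sub = table.select_samples(samples).drop_empty_taxa()
        pairs = qpe_pairs(sub, tree, config, group_label=label)
        all_pairs.append(pairs)
        defined = pairs[pairs["process"] != Process.UNDEFINED.value]
        n_def = len(defined)
        fracs = {
            p.value: (float((defined["process"] == p.value).sum()) / n_def if n_def else np.nan)
            for p in DEFINED_PROCESSES
        }
        fracs["n_pairs"] = len(pairs)
        fracs["n_undefined"] = len(pairs) - n_def
        frac_rows[label] = fracs
    if not frac_rows:
        raise ValidationError("no group with at least 2 samples")
    pairs_df = pd.concat(all_pairs, ignore_index=True)
    fractions = pd.DataFrame.from_dict(frac_rows, orient="index")
    return QPESummary(pairs_df, fractions, config)


def plot_process_fractions(summary: QPESummary, path) -> None:
    """Stacked-bar chart of assembly-process fractions per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [p.value for p in DEFINED_PROCESSES]
    df = summary.fractions[cols]
    ax = df.plot(kind="bar", stacked=True, figsize=(8, 5), colormap="viridis")
    ax.set_ylabel("fraction of sample pairs")
    ax.set_ylim(0, 1)
    ax.legend(bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=8)
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()
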