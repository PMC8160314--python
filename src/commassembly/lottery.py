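"""Competitive lottery model for clade-based community assembly.

Closely related taxa (here: members of the same family) are assumed to
share gene content, metabolism and niche space, and therefore to
compete for the same "slot" in a community. A clade member that
captures more than 90% of its clade's reads in a sample is that
sample's lottery *winner*. Two summaries describe each clade across
samples:

* winner prevalence — the fraction of eligible samples (clade observed
  above a read floor) that contain a winner;
* winner diversity — how evenly winner identity varies across the
  winner-containing samples, formalised as the Shannon entropy of
  winner identities normalised by its maximum (ln of the number of
  winner-containing samples). 0 means one ASV always wins; values near
  1 mean a different ASV wins nearly every time.

Comparing winner sets between sample categories (floating vs settled,
DNA vs cDNA) shows which clades gain or lose lottery behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import RANKS, AbundanceTable, TaxonomyMap


@dataclass
class CladeMap:
    """clade label -> taxon ids, at one taxonomic rank."""

    clades: dict[str, list[str]]
    rank: str
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, taxa in self.clades.items():
            overlap = seen & set(taxa)
            if overlap:
                raise ValidationError(f"taxa assigned to multiple clades: {sorted(overlap)}")
            seen |= set(taxa)


def build_clades(tax: TaxonomyMap, rank: str = "family") -> CladeMap:
    """Group taxa by their value at one lineage rank.

    Taxa with an empty value at that rank are excluded (their count is
    kept on the result); an entirely empty rank yields an empty map
    with a warning.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    idx = RANKS.index(rank)
    clades: dict[str, list[str]] = {}
    unassigned = 0
    for taxon, lineage in tax.lineages.items():
        value = lineage[idx]
        if value == "":
            unassigned += 1
            continue
        clades.setdefault(value, []).append(taxon)
    if not clades:
        warnings.warn(f"no taxon has a value at rank {rank!r}", stacklevel=2)
    return CladeMap(clades, rank, unassigned)


@dataclass
class LotteryResult:
    """Winner calls per (sample, clade) plus clade-level summaries."""

    calls: pd.DataFrame  # sample, clade, clade_reads, winner, share (winner rows only have winner != "")
    threshold: float
    min_clade_reads: int

    def eligible_samples(self, clade: str) -> list[str]:
        sub = self.calls[self.calls["clade"] == clade]
        return list(sub["sample"])

    def winners(self, clade: str) -> list[str]:
        sub = self.calls[(self.calls["clade"] == clade) & (self.calls["winner"] != "")]
        return list(sub["winner"])

    @property
    def clade_labels(self) -> list[str]:
        return sorted(self.calls["clade"].unique())

    def write(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def detect_winners(
    table: AbundanceTable,
    clades: CladeMap,
    threshold: float = 0.90,
    min_clade_reads: int = 10,
) -> LotteryResult:
    """Call lottery winners per sample and clade.

    A clade is eligible in a sample when its total reads reach
    ``min_clade_reads``; its most abundant member is the winner iff its
    share of the clade's reads strictly exceeds ``threshold``.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValidationError("winner threshold must lie in (0.5, 1]")
    counts = table.counts
    records = []
    for label, taxa in clades.clades.items():
        present = [t for t in taxa if t in counts.index]
        if not present:
            continue
        sub = counts.loc[present]
        totals = sub.sum(axis=0)
        for sample in table.sample_ids:
            total = int(totals[sample])
            if total < min_clade_reads:
                continue
            top_taxon = sub[sample].idxmax()
            share = float(sub.loc[top_taxon, sample]) / total
            winner = top_taxon if share > threshold else ""
            records.append((sample, label, total, winner, share))
    calls = pd.DataFrame(records, columns=["sample", "clade", "clade_reads", "winner", "share"])
    return LotteryResult(calls, threshold, min_clade_reads)


def winner_prevalence(result: LotteryResult, clade: str) -> float:
    """Fraction of eligible samples with a winner; NaN if never eligible."""
    eligible = result.eligible_samples(clade)
    if not eligible:
        return float("nan")
    return len(result.winners(clade)) / len(eligible)


def winner_diversity(result: LotteryResult, clade: str) -> float:
    """Normalised Shannon entropy of winner identities, H(p)/ln(S_w).

    S_w is the number of winner-containing samples; defined as 0 when
    S_w <= 1 or a single ASV wins everywhere, and NaN when the clade
    was never eligible.
    """
    eligible = result.eligible_samples(clade)
    if not eligible:
        return float("nan")
    winners = result.winners(clade)
    s_w = len(winners)
    if s_w <= 1:
        return 0.0
    freqs = pd.Series(winners).value_counts(normalize=True).to_numpy()
    if len(freqs) == 1:
        return 0.0
    h = float(-(freqs * np.log(freqs)).sum())
    return h / np.log(s_w)


def clade_summary(result: LotteryResult) -> pd.DataFrame:
    """Per-clade prevalence / diversity table."""
    rows = []
    for clade in result.clade_labels:
        rows.append(
            {
                "clade": clade,
                "n_eligible": len(result.eligible_samples(clade)),
                "n_winners": len(result.winners(clade)),
                "prevalence": winner_prevalence(result, clade),
                "diversity": winner_diversity(result, clade),
            }
        )
    return pd.DataFrame(rows)


def winner_status_changes(results: dict[str, LotteryResult]) -> pd.DataFrame:
    """Compare winner status of each clade across sample categories.

    Labels each clade ``winner_in_all``, ``winner_in_subset`` (with the
    categories listed) or ``no_lottery_behaviour``.
    """
    if len(results) < 2:
        raise ValidationError("need at least 2 categories to compare winner status")
    for cat, res in results.items():
        if res.calls.empty:
            raise ValidationError(f"category {cat!r} has no eligible clade calls")
    categories = list(results)
    clades = sorted({c for res in results.values() for c in res.clade_labels})
    rows = []
    for clade in clades:
        won_in = [cat for cat in categories if len(results[cat].winners(clade)) > 0]
        if not won_in:
            status = "no_lottery_behaviour"
        elif len(won_in) == len(categories):
            status = "winner_in_all"
        else:
            status = "winner_in_subset"
        rows.append(
            {"clade": clade, "status": status, "categories_won": ";".join(won_in)}
        )
    return pd.DataFrame(rows)


def plot_prevalence_diversity(summary: pd.DataFrame, path) -> None:
    """Scatter of winner prevalence vs winner diversity per clade."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(summary["prevalence"], summary["diversity"], s=20, alpha=0.7)
    ax.set_xlabel("winner prevalence")
    ax.set_ylabel("winner diversity")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()
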