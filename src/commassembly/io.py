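"""Readers, writers and preprocessing for ASV-table analyses.

The on-disk formats are the plain-text ones a 16S amplicon workflow
produces: a tab-separated taxa x samples count table (QIIME-style
``#OTU ID`` header accepted), a rooted Newick tree whose tips are ASV
ids, a taxonomy TSV mapping each ASV to a semicolon-delimited
SILVA-style lineage, and a sample-metadata TSV. Preprocessing covers
contaminant removal (chloroplast / mitochondrial reads) and rarefaction
to a common depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import FormatError, ValidationError

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

POSITIONS = frozenset({"floating", "settled"})
NUCLEIC_ACIDS = frozenset({"DNA", "cDNA"})

DEFAULT_CONTAMINANTS = frozenset({"Chloroplast", "Mitochondria"})


@dataclass
class AbundanceTable:
    """Integer read counts per (taxon, sample).

    Wraps a taxa-rows x sample-columns :class:`pandas.DataFrame`. Counts
    are non-negative integers; relative abundances are derived per
    sample (column) on demand.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[1] == 0:
            raise FormatError("abundance table must have at least one sample")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("abundance table contains non-numeric cells")
        if np.any(arr < 0):
            raise FormatError("abundance table contains negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise FormatError("abundance table contains non-integral counts")
        self.counts = df.astype(np.int64)

    # -- accessors -------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        """Counts as a taxa x samples int array (a copy-free view)."""
        return self.counts.to_numpy()

    def sample_counts(self, sample: str) -> np.ndarray:
        if sample not in self.counts.columns:
            raise ValidationError(f"unknown sample id: {sample!r}")
        return self.counts[sample].to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundances(self) -> pd.DataFrame:
        """Per-sample relative abundances f_ik; all-zero samples stay zero."""
        totals = self.counts.sum(axis=0)
        safe = totals.replace(0, 1)
        return self.counts / safe

    # -- manipulation ----------------------------------------------------
    def drop_empty_taxa(self) -> "AbundanceTable":
        """Remove taxa absent from every sample (unobserved rows break
        occupancy-weighted null models downstream)."""
        keep = self.counts.sum(axis=1) > 0
        if keep.all():
            return self
        return AbundanceTable(self.counts.loc[keep])

    def select_samples(self, samples: list[str]) -> "AbundanceTable":
        missing = [s for s in samples if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return AbundanceTable(self.counts[list(samples)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass
class TaxonomyMap:
    """taxon_id -> 7-rank lineage (domain..species); absent ranks are ''."""

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        fixed = {}
        for taxon, lineage in self.lineages.items():
            lineage = tuple(lineage)
            if len(lineage) > len(RANKS):
                raise FormatError(f"lineage for {taxon!r} has more than {len(RANKS)} ranks")
            lineage = lineage + ("",) * (len(RANKS) - len(lineage))
            fixed[taxon] = lineage
        self.lineages = fixed

    def rank(self, taxon: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.lineages[taxon][RANKS.index(rank)]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass
class SampleMetadata:
    """Per-sample grouping factors: position, nucleic acid, reactor."""

    rows: pd.DataFrame  # index = sample_id; columns position, nucleic_acid, reactor

    def __post_init__(self) -> None:
        required = {"position", "nucleic_acid", "reactor"}
        missing = required - set(self.rows.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        if self.rows.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        bad_pos = sorted(set(self.rows["position"]) - POSITIONS)
        if bad_pos:
            raise ValidationError(f"unknown position labels: {bad_pos} (expected {sorted(POSITIONS)})")
        bad_na = sorted(set(self.rows["nucleic_acid"]) - NUCLEIC_ACIDS)
        if bad_na:
            raise ValidationError(f"unknown nucleic_acid labels: {bad_na} (expected {sorted(NUCLEIC_ACIDS)})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rows.index)

    def group_label(self, sample: str, columns: list[str]) -> str:
        vals = [str(self.rows.loc[sample, c]) for c in columns]
        return "-".join(vals)

    def groups(self, columns: list[str], samples: list[str] | None = None) -> dict[str, list[str]]:
        """Partition samples into groups keyed by joined column values."""
        samples = self.sample_ids if samples is None else samples
        missing = [s for s in samples if s not in self.rows.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        out: dict[str, list[str]] = {}
        for s in samples:
            out.setdefault(self.group_label(s, columns), []).append(s)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(path) -> AbundanceTable:
    """Read a tab-separated taxa x samples count table.

    The first column holds taxon ids (any header, including the
    QIIME-style ``#OTU ID``); remaining columns are numeric counts.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"could not parse abundance table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError("abundance table has no sample columns")
    if df.shape[0] == 0:
        raise FormatError("abundance table has no taxon rows")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"non-numeric values in sample column {col!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceTable(df)


def write_abundance_table(table: AbundanceTable, path, id_header: str = "#OTU ID") -> None:
    df = table.counts.copy()
    df.index.name = id_header
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_newick(path) -> TreeNode:
    """Read a rooted Newick tree; tips must be uniquely labelled."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"could not parse Newick file {path}: {exc}") from exc
    _validate_tree(tree)
    return tree


def parse_newick(newick: str) -> TreeNode:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    try:
        tree = TreeNode.read([newick], format="newick")
    except Exception as exc:
        raise FormatError(f"could not parse Newick string: {exc}") from exc
    _validate_tree(tree)
    return tree


def _validate_tree(tree: TreeNode) -> None:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        dups = sorted({t for t in tips if tips.count(t) > 1})
        raise FormatError(f"duplicate tip labels: {dups}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError(f"negative branch length at node {node.name!r}")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_taxonomy(path, strip_prefixes: bool = True) -> TaxonomyMap:
    """Read a two-column TSV: taxon id, semicolon-delimited lineage.

    SILVA-style rank prefixes (``d__``, ``p__``, ... ) are stripped by
    default. Missing trailing ranks become empty strings.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str).fillna("")
    if df.shape[1] < 2:
        raise FormatError("taxonomy TSV needs at least two columns (id, lineage)")
    lineages: dict[str, tuple[str, ...]] = {}
    for _, row in df.iterrows():
        taxon = str(row.iloc[0])
        parts = [p.strip() for p in str(row.iloc[1]).split(";")]
        if parts and parts[-1] == "":
            parts = parts[:-1]
        if strip_prefixes:
            parts = [_strip_rank_prefix(p) for p in parts]
        if taxon in lineages:
            raise FormatError(f"duplicate taxon id in taxonomy: {taxon!r}")
        lineages[taxon] = tuple(parts)
    return TaxonomyMap(lineages)


def _strip_rank_prefix(token: str) -> str:
    if len(token) >= 3 and token[1:3] == "__":
        return token[3:]
    return token


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    prefixes = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Feature ID\tTaxon\n")
        for taxon, lineage in tax.lineages.items():
            labelled = [p + v for p, v in zip(prefixes, lineage) if v != ""]
            fh.write(f"{taxon}\t{';'.join(labelled)}\n")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.rows.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_contaminants(
    table: AbundanceTable,
    tax: TaxonomyMap,
    labels: frozenset[str] | set[str] = DEFAULT_CONTAMINANTS,
) -> AbundanceTable:
    """Drop taxa whose lineage matches a contaminant label at any rank.

    Matching is case-insensitive substring, because SILVA places
    Chloroplast at order level and Mitochondria at family level and the
    exact strings vary across releases. Samples are never removed.
    """
    needles = [lbl.lower() for lbl in labels]
    keep = []
    for taxon in table.taxon_ids:
        lineage = tax.lineages.get(taxon, ())
        hit = any(n in rank.lower() for rank in lineage for n in needles)
        keep.append(not hit)
    if not any(keep):
        warnings.warn("contaminant filter removed every taxon", stacklevel=2)
    return AbundanceTable(table.counts.loc[keep])


def rarefy(table: AbundanceTable, depth: int | str = "min", seed: int | None = None) -> AbundanceTable:
    """Subsample every sample to ``depth`` reads without replacement.

    ``depth="min"`` resolves to the minimum sample total (the common
    convention of rarefying to the shallowest library). Each sample is a
    uniform draw of ``depth`` reads from its observed reads, so rarefied
    counts follow a multivariate hypergeometric law, never exceed the
    originals, and sum exactly to ``depth``. Taxa left with all-zero
    rows are dropped.
    """
    totals = table.sample_totals()
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    shallow = totals[totals < depth]
    if len(shallow) > 0:
        raise ValidationError(
            f"rarefaction depth {depth} exceeds totals of samples: "
            f"{dict(shallow)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.matrix)
    for j, sample in enumerate(table.sample_ids):
        out[:, j] = _subsample_counts(table.matrix[:, j], depth, rng)
    df = pd.DataFrame(out, index=table.taxon_ids, columns=table.sample_ids)
    return AbundanceTable(df).drop_empty_taxa()


def _subsample_counts(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Multivariate hypergeometric subsample of a count vector."""
    return rng.multivariate_hypergeometric(counts, depth)


def validate_cross_references(
    table: AbundanceTable,
    tree: TreeNode | None = None,
    tax: TaxonomyMap | None = None,
    meta: SampleMetadata | None = None,
) -> None:
    """Fail fast if the table's taxa/samples are not covered by the
    companion artefacts; the error lists every offender."""
    problems = []
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        missing = sorted(set(table.taxon_ids) - tips)
        if missing:
            problems.append(f"taxa missing from tree: {missing}")
    if tax is not None:
        missing = sorted(t for t in table.taxon_ids if t not in tax)
        if missing:
            problems.append(f"taxa missing from taxonomy: {missing}")
    if meta is not None:
        missing = sorted(set(table.sample_ids) - set(meta.sample_ids))
        if missing:
            problems.append(f"samples missing from metadata: {missing}")
    if problems:
        raise ValidationError("; ".join(problems))
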