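"""End-to-end orchestration: preprocess -> NTI -> QPE -> NST -> lottery.

One global seed drives every stage; per-stage seeds are derived from it
and the stage name, so runs are reproducible bit-for-bit and adding a
stage never changes another stage's randomness. All tabular outputs are
deterministic TSV/JSON; wall-clock timings go to a separate log file so
the result bundle itself is byte-stable across reruns.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._seeds import derive_seed
from .errors import ValidationError
from .io import (
    AbundanceTable,
    SampleMetadata,
    TaxonomyMap,
    filter_contaminants,
    rarefy,
    read_abundance_table,
    read_metadata,
    read_newick,
    read_taxonomy,
    validate_cross_references,
    write_abundance_table,
    write_metadata,
    write_newick,
    write_taxonomy,
)
from .lottery import (
    build_clades,
    clade_summary,
    detect_winners,
    plot_prevalence_diversity,
    winner_status_changes,
)
from .metrics import richness, shannon_entropy
from .nst import NST_METRICS, CONSTRAINTS, panova, stochasticity
from .phylo import beta_nti, nti
from .qpe import QPEConfig, plot_process_fractions, qpe_summary
from .simulate import Scenario, paper_shaped_dataset, simulate_dataset, taxonomy_from_tree


@dataclass
class PipelineConfig:
    table: str
    tree: str
    taxonomy: str
    metadata: str
    output_dir: str
    seed: int
    grouping: list[str] = field(default_factory=lambda: ["position", "nucleic_acid"])
    rarefaction_depth: int | str = "min"
    reps: int = 999
    nst_reps: int = 1000
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    lottery_rank: str = "family"
    lottery_threshold: float = 0.90
    lottery_min_reads: int = 10
    panova_permutations: int = 999
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the JSON-able summary dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def stage(name):
        t0 = time.perf_counter()

        def done(note=""):
            log_lines.append(f"{name}\t{time.perf_counter() - t0:.2f}s\t{note}")

        return done

    # ---- load & validate ------------------------------------------------
    done = stage("load")
    table = read_abundance_table(config.table)
    tree = read_newick(config.tree)
    tax = read_taxonomy(config.taxonomy)
    meta = read_metadata(config.metadata)
    validate_cross_references(table, tree=tree, tax=tax, meta=meta)
    done(f"{len(table.taxon_ids)} taxa x {len(table.sample_ids)} samples")

    # ---- preprocess -----------------------------------------------------
    done = stage("preprocess")
    filtered = filter_contaminants(table, tax)
    rare = rarefy(filtered, config.rarefaction_depth, seed=derive_seed(config.seed, "rarefy"))
    write_abundance_table(rare, out / "rarefied_table.tsv")
    depth = int(rare.sample_totals().iloc[0])
    done(f"depth {depth}, {len(rare.taxon_ids)} taxa retained")

    # ---- alpha diversity ------------------------------------------------
    done = stage("alpha")
    alpha = pd.DataFrame(
        {
            "richness": [richness(rare, s) for s in rare.sample_ids],
            "shannon": [shannon_entropy(rare, s) for s in rare.sample_ids],
        },
        index=rare.sample_ids,
    )
    alpha.index.name = "sample"
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", lineterminator="\n", float_format="%.10g")
    done()

    # ---- NTI ------------------------------------------------------------
    done = stage("nti")
    nti_res = nti(rare, tree, reps=config.reps, seed=derive_seed(config.seed, "nti"))
    nti_res.write(out / "nti.tsv")
    done(f"{int(nti_res.table['nti'].isna().sum())} undefined samples")

    # ---- QPE ------------------------------------------------------------
    done = stage("qpe")
    qcfg = QPEConfig(
        bnti_threshold=config.bnti_threshold,
        rc_threshold=config.rc_threshold,
        reps=config.reps,
        seed=derive_seed(config.seed, "qpe"),
    )
    qpe_res = qpe_summary(rare, tree, meta, config.grouping, qcfg)
    qpe_res.write(out / "qpe_pairs.tsv", out / "qpe_summary.tsv")
    if config.make_plots:
        plot_process_fractions(qpe_res, out / "qpe_fractions.png")
    done(f"{len(qpe_res.fractions)} groups")

    # ---- NST + PANOVA ---------------------------------------------------
    done = stage("nst")
    groups = meta.groups(config.grouping, rare.sample_ids)
    nst_rows = []
    nst_pair_frames = []
    for metric in NST_METRICS:
        for constraint in CONSTRAINTS:
            for label, samples in groups.items():
                if len(samples) < 2:
                    continue
                res = stochasticity(
                    rare,
                    metric=metric,
                    constraint=constraint,
                    reps=config.nst_reps,
                    seed=derive_seed(config.seed, "nst", metric, constraint, label),
                    group=samples,
                )
                df = res.pairs.copy()
                df.insert(0, "group", label)
                df.insert(1, "metric", metric)
                df.insert(2, "constraint", constraint)
                nst_pair_frames.append(df)
                nst_rows.append(
                    {
                        "group": label,
                        "metric": metric,
                        "constraint": constraint,
                        "NST_mean_percent": res.group_nst_percent,
                        "n_pairs": len(res.pairs),
                    }
                )
    pd.concat(nst_pair_frames, ignore_index=True).to_csv(
        out / "nst_pairs.tsv", sep="\t", index=False, lineterminator="\n", float_format="%.10g"
    )
    nst_summary = pd.DataFrame(nst_rows)
    nst_summary.to_csv(
        out / "nst_summary.tsv", sep="\t", index=False, lineterminator="\n", float_format="%.10g"
    )
    done(f"{len(nst_rows)} metric/constraint/group combinations")

    done = stage("panova")
    primary = config.grouping[0]
    top_groups = meta.groups([primary], rare.sample_ids)
    panova_rows = []
    if len(top_groups) >= 2 and all(len(v) >= 3 for v in top_groups.values()):
        for metric in NST_METRICS:
            for constraint in CONSTRAINTS:
                union_res = stochasticity(
                    rare,
                    metric=metric,
                    constraint=constraint,
                    reps=config.nst_reps,
                    seed=derive_seed(config.seed, "nst_union", metric, constraint),
                )
                pres = panova(
                    union_res,
                    top_groups,
                    permutations=config.panova_permutations,
                    seed=derive_seed(config.seed, "panova", metric, constraint),
                )
                panova_rows.append(
                    {
                        "metric": metric,
                        "constraint": constraint,
                        "groups": ";".join(top_groups),
                        "statistic": pres.statistic,
                        "p_value": pres.p_value,
                    }
                )
    if panova_rows:
        pd.DataFrame(panova_rows).to_csv(
            out / "panova.tsv", sep="\t", index=False, lineterminator="\n", float_format="%.10g"
        )
    done()

    # ---- lottery --------------------------------------------------------
    done = stage("lottery")
    clades = build_clades(tax, config.lottery_rank)
    lottery_by_cat = {}
    for label, samples in groups.items():
        sub = rare.select_samples(samples).drop_empty_taxa()
        lottery_by_cat[label] = detect_winners(
            sub, clades, threshold=config.lottery_threshold, min_clade_reads=config.lottery_min_reads
        )
    overall = detect_winners(
        rare, clades, threshold=config.lottery_threshold, min_clade_reads=config.lottery_min_reads
    )
    overall.write(out / "lottery_calls.tsv")
    summary_df = clade_summary(overall)
    summary_df.to_csv(
        out / "lottery_summary.tsv", sep="\t", index=False, lineterminator="\n", float_format="%.10g"
    )
    changes = winner_status_changes(lottery_by_cat)
    changes.to_csv(
        out / "lottery_status_changes.tsv", sep="\t", index=False, lineterminator="\n"
    )
    if config.make_plots and not summary_df.empty:
        plot_prevalence_diversity(summary_df, out / "lottery_prevalence_diversity.png")
    done(f"{len(clades.clades)} clades")

    # ---- summary / manifest --------------------------------------------
    summary = {
        "n_taxa": len(rare.taxon_ids),
        "n_samples": len(rare.sample_ids),
        "rarefaction_depth": depth,
        "nti_mean": float(nti_res.table["nti"].mean()),
        "qpe_fractions": {
            g: {c: (None if pd.isna(v) else float(v)) for c, v in row.items()}
            for g, row in qpe_res.fractions.iterrows()
        },
        "nst_summary": nst_rows,
        "panova": panova_rows,
        "lottery": {
            "n_clades_eligible": int(summary_df.shape[0]),
            "n_clades_with_winners": int((summary_df["n_winners"] > 0).sum()) if not summary_df.empty else 0,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def simulate_to_disk(scenario: Scenario, output_dir, paper_shaped: bool = False) -> dict:
    """Write a synthetic dataset (table/tree/taxonomy/metadata + truth)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if paper_shaped:
        table, tree, tax, meta, truth = paper_shaped_dataset(seed=scenario.seed)
    else:
        ds = simulate_dataset(scenario)
        table, tree = ds.table, ds.tree
        tax = taxonomy_from_tree(tree)
        meta_rows = []
        for i, s in enumerate(table.sample_ids):
            meta_rows.append(
                {
                    "sample_id": s,
                    "position": "floating" if i % 2 == 0 else "settled",
                    "nucleic_acid": "DNA",
                    "reactor": f"R{(i % 3) + 1}",
                }
            )
        meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
        truth = {
            "regime": scenario.regime,
            "parameters": asdict(scenario),
            "blocks": {s: int(b) for s, b in ds.truth["block"].items()},
        }
    write_abundance_table(table, out / "table.tsv")
    write_newick(tree, out / "tree.nwk")
    write_taxonomy(tax, out / "taxonomy.tsv")
    write_metadata(meta, out / "metadata.tsv")
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True, default=str) + "\n")
    return truth
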