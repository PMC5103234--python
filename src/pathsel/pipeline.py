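"""End-to-end orchestration: expression screen, per-gene statistics,
selection classification, sweep scan, HKA validation, PRV and trees.

The pipeline runs the stages in the order the analysis is reported:
expressed genes are selected first, gene- and codon-level statistics are
computed per gene, empirical-percentile classification follows (with its
two-tier logic: percentile criteria propose candidates, the HKA
likelihood-ratio test validates them), the flanking-gene sweep scan and the
pathway-position correlation close the analysis.  All outputs are TSV /
Newick / JSON; a run manifest records the configuration and output hashes
so a rerun with the same seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity_stats as ds
from . import io_formats, kaks, pathway_prv, selection_scan
from .io_formats import HaplotypeAlignment, PopulationPartition
from .selection_scan import BackgroundTables, ClassifierThresholds

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "expression_screen", "load_dataset_alignments"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and options for one full analysis run."""

    alignments_dir: str
    partition_path: str
    pathway_path: str
    out_dir: str
    expression_path: str | None = None
    gene_models_path: str | None = None
    truth_path: str | None = None
    background_table_path: str | None = None   # external gene-stats TSV for percentiles
    outgroup_sample: str | None = None         # autodetected from the partition if None
    expression_threshold: float = 0.0
    allow_list: list[str] = field(default_factory=list)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    genome_mean_diversity: float | None = None  # codon-level cutoff; analysed-set mean if None
    sweep_radius: int = 10
    hka_neutral_genes: list[str] | None = None
    hka_max_neutral: int = 34
    kaks_mode: str = "consensus"
    tree_genes: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        self.thresholds.validate()
        if self.sweep_radius < 1:
            raise ValueError("sweep radius must be >= 1")
        if self.expression_threshold < 0:
            raise ValueError("expression threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        th = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if th:
            cfg.thresholds = ClassifierThresholds(**th)
        return cfg


def expression_screen(expression: pd.DataFrame, threshold: float = 0.0) -> set[str]:
    """Genes whose day-average FPKM exceeds the threshold (strictly).

    The day average is the mean of the available timepoint columns per
    gene; excluded genes are logged.
    """
    value_cols = [c for c in expression.columns if c != "gene"]
    day_avg = expression[value_cols].mean(axis=1)
    keep = expression.loc[day_avg > threshold, "gene"]
    dropped = expression.loc[day_avg <= threshold, "gene"].tolist()
    if dropped:
        logger.info("expression screen removed %d genes: %s", len(dropped), dropped[:10])
    return set(keep)


def load_dataset_alignments(alignments_dir: str | Path) -> dict[str, HaplotypeAlignment]:
    """All per-gene FASTA alignments in a directory, keyed by gene id."""
    out = {}
    for path in sorted(Path(alignments_dir).glob("*.fasta")):
        aln = io_formats.read_fasta_alignment(path)
        out[aln.gene_id] = aln
    if not out:
        raise io_formats.FormatError(f"no .fasta alignments in {alignments_dir}")
    return out


def _gene_stats_stage(
    alignments: dict[str, HaplotypeAlignment],
    partition: PopulationPartition,
    outgroup: str | None,
    kaks_mode: str,
) -> tuple[list[dict], dict[str, dict]]:
    """Per-gene records for every group plus cross-group FST and Ka/Ks."""
    rows: list[dict] = []
    per_gene: dict[str, dict] = {}
    for gene, aln in alignments.items():
        land = partition.members_in(aln, "landrace")
        wild = partition.members_in(aln, "wild")
        if len(land) < 2 or len(wild) < 2:
            logger.warning("%s skipped: fewer than 2 sequences in a group", gene)
            continue
        rec_l = ds.gene_stat_record(aln, land, "landrace")
        rec_w = ds.gene_stat_record(aln, wild, "wild")
        rec_all = ds.gene_stat_record(aln, land + wild, "all")
        fst = ds.hudson_fst(aln, partition)
        entry = {"landrace": rec_l, "wild": rec_w, "all": rec_all, "fst": fst}
        if outgroup and outgroup in aln.sample_ids:
            for group, members in (("landrace", land), ("wild", wild), ("all", land + wild)):
                try:
                    entry[f"kaks_{group}"] = kaks.group_kaks(
                        aln, members, outgroup, group=group, mode=kaks_mode)
                except ValueError as exc:
                    logger.warning("%s/%s Ka/Ks skipped: %s", gene, group, exc)
        per_gene[gene] = entry
        for group, rec in (("landrace", rec_l), ("wild", rec_w), ("all", rec_all)):
            kk = entry.get(f"kaks_{group}")
            rows.append({
                "gene": gene, "group": group, "n": rec.n, "L": rec.L,
                "L_effective": rec.L_effective, "S": rec.S,
                "theta_pi": rec.theta_pi, "theta_w": rec.theta_w,
                "tajimas_d": rec.tajimas_d,
                "fst": fst if group == "landrace" else None,
                "Ka": kk.Ka if kk else None, "Ks": kk.Ks if kk else None,
                "ka_ks": (kk.ratio if kk else None),
                "kaks_p_vs_1": (kk.p_vs_1 if kk else None),
            })
    return rows, per_gene


def _background_from_table(path: str | Path) -> BackgroundTables:
    df = io_formats.read_gene_stats(path)
    sub = df[df["group"] == "landrace"]
    d = pd.to_numeric(sub["tajimas_d"], errors="coerce").dropna()
    return BackgroundTables(
        theta_pi=sub["theta_pi"].to_numpy(float),
        theta_w=sub["theta_w"].to_numpy(float),
        fst=sub["fst"].to_numpy(float),
        tajimas_d=d.to_numpy(float),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a manifest of produced artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    partition, pathway_map, expression = io_formats.read_tables(
        config.partition_path, config.pathway_path, config.expression_path)
    outgroup = config.outgroup_sample
    if outgroup is None:
        outs = partition.samples("outgroup")
        outgroup = outs[0] if outs else None

    alignments = load_dataset_alignments(config.alignments_dir)

    # stage 1: expression-presence screen
    if expression is not None:
        included = expression_screen(expression, config.expression_threshold)
        included |= set(config.allow_list)
        selected = {g: a for g, a in alignments.items() if g in included}
        if not selected:
            raise ValueError("expression screen left no genes to analyse")
        alignments = selected

    # stage 2: per-gene statistics
    rows, per_gene = _gene_stats_stage(alignments, partition, outgroup, config.kaks_mode)
    if not per_gene:
        raise ValueError("no genes with enough data to analyse")

    # stage 3: gene-level classification
    records_l = [per_gene[g]["landrace"] for g in per_gene]
    fsts = [per_gene[g]["fst"] for g in per_gene]
    if config.background_table_path:
        background = _background_from_table(config.background_table_path)
    else:
        background = BackgroundTables.from_records(records_l, fsts)

    gene_calls: dict[str, str] = {}
    call_rows = []
    for gene in per_gene:
        call = selection_scan.classify_gene(
            per_gene[gene]["landrace"], per_gene[gene]["wild"],
            per_gene[gene]["fst"], background, config.thresholds)
        gene_calls[gene] = call.label
        call_rows.append({"gene": gene, "level": "gene", "label": call.label,
                          **{k: v for k, v in call.evidence.items()}})

    # stage 4: codon-level classification
    if config.genome_mean_diversity is not None:
        mean_div = config.genome_mean_diversity
    else:
        mean_div = float(np.mean([r.theta_pi for r in records_l]))
        logger.info("using analysed-set mean landrace diversity %.3g as the "
                    "codon-level cutoff", mean_div)
    codon_rows = []
    codon_calls_by_gene: dict[str, list] = {}
    for gene, aln in alignments.items():
        if gene not in per_gene:
            continue
        track = ds.codon_stats(aln, partition)
        calls = selection_scan.classify_codon(track, mean_div)
        codon_calls_by_gene[gene] = calls
        for c in calls:
            codon_rows.append({"gene": gene, "level": "codon",
                               "codon_index": c.codon_index, "label": c.label,
                               **c.evidence})

    # the merged label annotates mixed codon-level evidence ("both") without
    # replacing the percentile-level call used for truth comparisons
    merged_calls = {
        gene: selection_scan.combine_gene_and_codon_calls(
            selection_scan.SelectionCall(gene_id=gene, level="gene", label=gene_calls[gene]),
            codon_calls_by_gene.get(gene, []))
        for gene in gene_calls
    }
    for row in call_rows:
        row["label_with_codon"] = merged_calls[row["gene"]]

    # stage 5: flanking-gene sweep scan
    sweep_rows = []
    if config.gene_models_path:
        models = io_formats.read_gene_models(config.gene_models_path)
        model_ids = {m.gene_id for m in models}
        focal = [g for g in merged_calls
                 if merged_calls[g] not in ("none",) and g in model_ids]
        for gene in focal:
            summary = selection_scan.flanking_sweep_scan(
                gene, models, merged_calls, radius=config.sweep_radius)
            sweep_rows.append({
                "gene": gene, "label": merged_calls[gene],
                "n_flanking": summary.n_flanking, "sweep_flag": summary.sweep_flag,
                **{f"flanking_{k}": v for k, v in summary.counts.items()},
            })

    # stage 6: HKA validation of gene-level candidates
    hka_rows = []
    # fixation (invariant) is the extreme diversity-loss signal, so those
    # genes join the candidates the HKA test is asked to validate
    candidates = [g for g in merged_calls
                  if merged_calls[g] in ("purifying", "balancing", "both", "invariant")]
    neutral_pool = config.hka_neutral_genes or sorted(
        g for g in merged_calls if merged_calls[g] == "none")[:config.hka_max_neutral]
    neutral_pool = [g for g in neutral_pool if g in per_gene]
    if candidates and len(neutral_pool) >= 1 and outgroup:
        hka = _hka_stage(alignments, per_gene, partition, outgroup, candidates, neutral_pool)
        hka_rows.extend(hka)

    # stage 7: PRV per pathway and group
    kaks_rows = [
        {"gene": r["gene"], "group": r["group"], "ratio": r["ka_ks"]}
        for r in rows if r["ka_ks"] is not None
    ]
    prv_rows = []
    if kaks_rows:
        kaks_df = pd.DataFrame(kaks_rows)
        pathways = sorted({p for p, _ in pathway_map.positions.values()})
        for pw in pathways:
            for group in ("landrace", "wild", "all"):
                try:
                    res = pathway_prv.prv_test(kaks_df, pathway_map, pw, group)
                except ValueError as exc:
                    logger.info("PRV skipped for %s/%s: %s", pw, group, exc)
                    continue
                prv_rows.append(dataclasses.asdict(res))

    # stage 8: trees
    tree_paths = []
    (out / "trees").mkdir(exist_ok=True)
    for gene in config.tree_genes:
        if gene not in alignments:
            logger.warning("tree requested for unknown gene %s", gene)
            continue
        aln = alignments[gene]
        ingroup = [s for s in aln.sample_ids if s != outgroup]
        sub = aln.subset(ingroup)
        tree = pathway_prv.upgma(pathway_prv.pairwise_distance_matrix(sub), sub.sample_ids)
        tree_path = out / "trees" / f"{gene}.nwk"
        io_formats.write_newick(tree, tree_path)
        tree_paths.append(str(tree_path))

    # outputs
    stats_rows = []
    for r in rows:
        r = dict(r)
        r["call"] = gene_calls.get(r["gene"]) if r["group"] == "landrace" else None
        stats_rows.append(r)
    io_formats.write_gene_stats(stats_rows, out / "gene_stats.tsv")
    pd.DataFrame(call_rows).to_csv(out / "gene_calls.tsv", sep="\t", index=False)
    pd.DataFrame(codon_rows).to_csv(out / "codon_calls.tsv", sep="\t", index=False)
    pd.DataFrame(sweep_rows).to_csv(out / "sweep_scan.tsv", sep="\t", index=False)
    pd.DataFrame(hka_rows).to_csv(out / "hka_report.tsv", sep="\t", index=False)
    pd.DataFrame(prv_rows).to_csv(out / "prv_report.tsv", sep="\t", index=False)

    confusion = None
    if config.truth_path:
        truth_df = pd.read_csv(config.truth_path, sep="\t")
        truth = dict(zip(truth_df["gene"], truth_df["regime"]))
        truth = {g: r for g, r in truth.items() if g in gene_calls}
        metrics = selection_scan.recovery_metrics(truth, gene_calls)
        confusion = pd.crosstab(
            pd.Series({g: truth[g] for g in truth}, name="planted"),
            pd.Series({g: gene_calls[g] for g in truth}, name="called"))
        confusion.to_csv(out / "confusion_matrix.tsv", sep="\t")
        with open(out / "recovery_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)

    artifact_names = [
        "gene_stats.tsv", "gene_calls.tsv", "codon_calls.tsv",
        "sweep_scan.tsv", "hka_report.tsv", "prv_report.tsv",
    ]
    manifest = {
        "seed": config.seed,
        "n_genes": len(per_gene),
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "artifacts": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in artifact_names
        },
        "trees": tree_paths,
        "has_confusion_matrix": confusion is not None,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _hka_stage(alignments, per_gene, partition, outgroup, candidates, neutral_pool):
    """One HKA likelihood-ratio test per candidate against the neutral loci.

    D is counted as differences between the landrace consensus and the
    outgroup sequence; S is the landrace segregating-site count.
    """
    rows = []

    def locus_counts(gene):
        aln = alignments[gene]
        land = partition.members_in(aln, "landrace")
        cons = kaks.consensus_sequence(aln, land)
        out_seq = aln.subset([outgroup]).sequences[0]
        d = sum(1 for a, b in zip(cons, out_seq)
                if a != b and a in "ACGT" and b in "ACGT")
        rec = per_gene[gene]["landrace"]
        return rec.S, d, rec.L_effective, rec.n

    neutral_counts = [locus_counts(g) for g in neutral_pool]
    for gene in candidates:
        s, d, l, n = locus_counts(gene)
        S = np.array([s] + [c[0] for c in neutral_counts])
        D = np.array([d] + [c[1] for c in neutral_counts])
        L = np.array([l] + [c[2] for c in neutral_counts])
        N = np.array([n] + [c[3] for c in neutral_counts])
        dataset = selection_scan.HKADataset(
            S=S, D=D, L=L, n=N, selected=(0,),
            locus_ids=tuple([gene] + list(neutral_pool)))
        try:
            res = selection_scan.hka_lrt(dataset)
        except (ValueError, RuntimeError) as exc:
            logger.warning("HKA failed for %s: %s", gene, exc)
            continue
        rows.append({
            "gene": gene, "statistic": res.statistic, "df": res.df,
            "p_value": res.p_value, "k_hat": res.k.get(0),
            "T_hat": res.T_selection, "n_neutral_loci": len(neutral_pool),
        })
    return rows
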