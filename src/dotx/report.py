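"""Pipeline orchestration: chain the analysis stages and emit a report bundle.

``run_pipeline`` runs sex-linkage -> homology -> expression -> landscape in
order, skipping any stage whose inputs are absent from the
:class:`~dotx.config.RunConfig`, and writes per-stage tab-delimited tables, a
JSON manifest (seed, config hash, per-stage filter counts) and a human-readable
``report.md``.  ``write_synthetic_bundle`` materializes a complete simulated
input set so the full chain can run without any external data.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import expression as expr
from . import homology, io, landscape, sexlink
from .config import RunConfig, SimulationConfig
from .simulate import (
    generate_genome,
    simulate_coverage,
    simulate_expression,
    simulate_landscape_windows,
    simulate_partition_tables,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def write_synthetic_bundle(
    config: SimulationConfig, out_dir: str | Path, with_fasta: bool = True
) -> RunConfig:
    """Generate every synthetic input and return a ready-to-run RunConfig.

    Writes the genome FASTA (optional), the joint coverage window table,
    ortholog tables for two outgroups, kallisto-style abundance directories
    with a sample sheet, landscape window tables, the truth tables, a
    ``run.yaml`` and a manifest recording the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(config, with_sequences=with_fasta)
    if with_fasta and genome.sequences is not None:
        io.write_fasta(genome.sequences, out / "genome.fa")
    io.write_tsv(truth.scaffolds, out / "truth_scaffolds.tsv")
    io.write_tsv(truth.genes, out / "truth_genes.tsv")

    coverage = simulate_coverage(genome, truth, config)
    io.write_tsv(coverage, out / "coverage_windows.tsv")

    pairs1, pairs2 = simulate_partition_tables(config.seed)
    io.write_tsv(pairs1, out / "orthologs_out1.tsv")
    io.write_tsv(pairs2, out / "orthologs_out2.tsv")

    tpm, sheet = simulate_expression(config, truth)
    io.write_abundance_dir(tpm, out / "expression")
    io.write_tsv(sheet.reset_index(), out / "samples.tsv")

    tables = simulate_landscape_windows(config, truth)
    io.write_tsv(tables["gc_fraction"], out / "landscape_gc.tsv")
    io.write_tsv(tables["repeat_fraction"], out / "landscape_repeat.tsv")
    io.write_tsv(tables["pi"], out / "landscape_pi.tsv")

    run_config = RunConfig(
        out_dir=str(out / "results"),
        seed=config.seed,
        coverage_windows=str(out / "coverage_windows.tsv"),
        orthologs=str(out / "orthologs_out1.tsv"),
        orthologs2=str(out / "orthologs_out2.tsv"),
        abundance_dir=str(out / "expression"),
        sample_sheet=str(out / "samples.tsv"),
        gene_map=str(out / "truth_genes.tsv"),
        gc_table=str(out / "landscape_gc.tsv"),
        repeat_table=str(out / "landscape_repeat.tsv"),
        pi_table=str(out / "landscape_pi.tsv"),
        window_size=config.window_size,
    )
    with open(out / "run.yaml", "w") as fh:
        yaml.safe_dump(run_config.to_dict(), fh, sort_keys=True)
    io.write_manifest(
        out / "manifest.json",
        {
            "bundle": "synthetic",
            "seed": config.seed,
            "simulation_config": config.to_dict(),
            "dotx_version": __version__,
        },
    )
    return run_config


def _stage_sexlink(cfg: RunConfig, out: Path) -> Optional[dict]:
    if cfg.coverage_windows:
        joined = io.read_tsv(cfg.coverage_windows)
    elif cfg.male_depth and cfg.female_depth:
        lengths = None
        if cfg.scaffold_lengths:
            table = io.read_tsv(cfg.scaffold_lengths)
            lengths = dict(zip(table["scaffold"], table["length"]))
        male = sexlink.bin_depth(io.read_depth_text(cfg.male_depth), cfg.window_size, lengths)
        female = sexlink.bin_depth(io.read_depth_text(cfg.female_depth), cfg.window_size, lengths)
        joined = male.rename(columns={"depth": "male_depth"}).merge(
            female.rename(columns={"depth": "female_depth"}), on=["scaffold", "start", "end"]
        )
    else:
        return None
    male_w = joined[["scaffold", "start", "end", "male_depth"]].rename(columns={"male_depth": "depth"})
    female_w = joined[["scaffold", "start", "end", "female_depth"]].rename(
        columns={"female_depth": "depth"}
    )
    calls, candidates = sexlink.sexlink_pipeline(
        male_w,
        female_w,
        delta=cfg.delta,
        pseudocount=cfg.pseudocount,
        min_raw_depth=cfg.min_raw_depth,
        min_windows=cfg.min_windows,
        female_max=cfg.female_max,
        male_min=cfg.male_min,
    )
    io.write_tsv(calls, out / "scaffold_calls.tsv")
    x_scaffolds = calls.loc[calls["chrom_class"] == "X", "scaffold"]
    lengths = joined.groupby("scaffold")["end"].max()
    bed = pd.DataFrame(
        {"scaffold": x_scaffolds, "start": 0, "end": lengths.reindex(x_scaffolds).to_numpy()}
    )
    bed.to_csv(out / "x_scaffolds.bed", sep="\t", header=False, index=False)
    return {
        "calls": calls,
        "male_specific": candidates,
        "counts": {
            "windows_in": int(len(joined)),
            "scaffolds": int(calls.shape[0]),
            "x_scaffolds": int((calls["chrom_class"] == "X").sum()),
            "male_specific_candidates": len(candidates),
        },
    }


def _stage_homology(cfg: RunConfig, out: Path) -> Optional[dict]:
    if not cfg.orthologs:
        return None
    pairs = io.read_tsv(cfg.orthologs)
    enrichment = homology.element_enrichment(pairs)
    io.write_tsv(enrichment, out / "element_enrichment.tsv")
    result = {
        "threshold": homology.x_linkage_threshold(pairs),
        "enrichment": enrichment,
        "counts": {"orthologs": int(len(pairs))},
    }
    if cfg.orthologs2:
        pairs2 = io.read_tsv(cfg.orthologs2)
        partition = homology.partition_x_by_outgroup(
            pairs, pairs2, f_label=cfg.f_element, x_label=cfg.outgroup2_x_label
        )
        io.write_tsv(partition.groups, out / "partition_groups.tsv")
        io.write_tsv(partition.comparisons, out / "partition_comparisons.tsv")
        result["partition"] = partition
    return result


def _stage_expression(cfg: RunConfig, out: Path, calls: Optional[pd.DataFrame]) -> Optional[dict]:
    if not (cfg.abundance_dir and cfg.sample_sheet and cfg.gene_map):
        return None
    matrix = io.read_abundance_dir(cfg.abundance_dir)
    sheet = io.read_sample_sheet(cfg.sample_sheet)
    gene_map = io.read_tsv(cfg.gene_map)
    if calls is not None:
        scaffold_class = calls.set_index("scaffold")["chrom_class"]
        classes = gene_map.set_index("gene")["scaffold"].map(scaffold_class)
    elif "chrom_class" in gene_map.columns:
        classes = gene_map.set_index("gene")["chrom_class"]
    else:
        raise ValueError("expression stage needs scaffold calls or a gene_map with chrom_class")

    tissues = sorted(sheet["tissue"].unique())
    dosage_tables, bias_tables = {}, {}
    for tissue in tissues:
        averaged = expr.sex_average_per_tissue(matrix, sheet, tissue)
        expressed = expr.filter_expressed(averaged, floor=cfg.tpm_floor)
        dosage = expr.dosage_statistics(expressed, classes, tissue=tissue)
        dosage_tables[tissue] = dosage
        io.write_tsv(dosage.summary, out / f"dosage_summary_{tissue}.tsv")
        io.write_tsv(dosage.tests, out / f"dosage_tests_{tissue}.tsv")
        sub = sheet[sheet["tissue"] == tissue]
        if min((sub["sex"] == "M").sum(), (sub["sex"] == "F").sum()) >= 2:
            bias = expr.call_sex_bias(
                matrix, sheet, tissue, q_threshold=cfg.q_threshold, tpm_floor=cfg.tpm_floor, fold=cfg.fold
            )
            bias_tables[tissue] = bias
            io.write_tsv(bias.reset_index(), out / f"sex_bias_{tissue}.tsv")

    norm = expr.quantile_normalize(matrix)
    specific = expr.call_tissue_specific(norm, sheet, high=cfg.tissue_high, low=cfg.tpm_floor)
    io.write_tsv(specific.reset_index().rename(columns={"index": "gene"}), out / "tissue_specific.tsv")

    comparisons = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comparisons["tissue_specific"] = expr.compare_class_proportions(
            specific["specific_class"], classes
        )
        for tissue, bias in bias_tables.items():
            comparisons[f"sex_bias_{tissue}"] = expr.compare_class_proportions(
                bias["bias_class"], classes
            )
    for name, table in comparisons.items():
        io.write_tsv(table, out / f"proportions_{name}.tsv")
    return {
        "dosage": dosage_tables,
        "sex_bias": bias_tables,
        "tissue_specific": specific,
        "comparisons": comparisons,
        "counts": {"genes": int(matrix.shape[0]), "samples": int(matrix.shape[1])},
    }


def _stage_landscape(cfg: RunConfig, out: Path, calls: Optional[pd.DataFrame]) -> Optional[dict]:
    tables: dict[str, pd.DataFrame] = {}
    if cfg.gc_table:
        tables["gc_fraction"] = io.read_tsv(cfg.gc_table)
    elif cfg.fasta:
        tables["gc_fraction"] = landscape.gc_windows(cfg.fasta, cfg.window_size)
    if cfg.repeat_table:
        tables["repeat_fraction"] = io.read_tsv(cfg.repeat_table)
    elif cfg.rm_out and cfg.fasta:
        sequences = io.read_fasta(cfg.fasta)
        lengths = {name: len(seq) for name, seq in sequences.items()}
        annotations = landscape.parse_repeatmasker_out(cfg.rm_out)
        tables["repeat_fraction"] = landscape.repeat_windows(annotations, lengths, cfg.window_size)
    if cfg.pi_table:
        tables["pi"] = io.read_tsv(cfg.pi_table)
    if not tables:
        return None
    classes = calls.set_index("scaffold")["chrom_class"] if calls is not None else None
    if classes is not None:
        # analysis-path classes take precedence over any embedded truth labels
        tables = {
            name: t.drop(columns=["chrom_class"], errors="ignore") for name, t in tables.items()
        }
    summary = landscape.xa_summary(tables, classes)
    io.write_tsv(summary, out / "xa_summary.tsv")
    return {"summary": summary, "counts": {name: int(len(t)) for name, t in tables.items()}}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage with available inputs; returns the in-memory results.

    Stage outputs are written under ``cfg.out_dir`` as they are produced, so a
    later-stage failure retains the earlier tables; the failure is re-raised as
    :class:`PipelineError` naming the stage.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage_status: dict[str, dict] = {}

    calls: Optional[pd.DataFrame] = None
    stages = [
        ("sexlink", lambda: _stage_sexlink(cfg, out)),
        ("homology", lambda: _stage_homology(cfg, out)),
        ("expression", lambda: _stage_expression(cfg, out, calls)),
        ("landscape", lambda: _stage_landscape(cfg, out, calls)),
    ]
    for name, runner in stages:
        try:
            result = runner()
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        if result is None:
            stage_status[name] = {"status": "skipped (inputs absent)"}
            continue
        results[name] = result
        stage_status[name] = {"status": "ok", **{"counts": result.get("counts", {})}}
        if name == "sexlink":
            calls = result["calls"]

    io.write_manifest(
        out / "manifest.json",
        {
            "dotx_version": __version__,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "config_hash": cfg.content_hash(),
            "stages": stage_status,
        },
    )
    write_report(out, results, cfg)
    return results


def write_report(out_dir: str | Path, results: dict, cfg: Optional[RunConfig] = None) -> Path:
    """Render a markdown summary of every populated stage."""
    if not results:
        raise ValueError("no stage produced output; nothing to report")
    out = Path(out_dir)
    lines = ["# dotx analysis report", ""]
    if cfg is not None:
        lines += [f"config hash: `{cfg.content_hash()}`; seed: {cfg.seed}", ""]
    if "sexlink" in results:
        calls = results["sexlink"]["calls"]
        counts = calls["chrom_class"].value_counts().to_dict()
        lines += [
            "## Sex-linked scaffold classification",
            "",
            f"- scaffolds: {len(calls)}; class counts: {counts}",
            f"- male-specific candidates: {results['sexlink']['male_specific'] or 'none'}",
            "",
        ]
    if "homology" in results:
        enr = results["homology"]["enrichment"]
        over = enr.loc[enr["overrepresented"], "element"].tolist()
        lines += [
            "## X gene-content homology",
            "",
            f"- X-linkage threshold: {results['homology']['threshold']:.4f}",
            f"- overrepresented elements: {over or 'none'}",
            "",
        ]
        if "partition" in results["homology"]:
            groups = results["homology"]["partition"].groups
            lines += ["- partition groups (proportion X-linked in outgroup 2):"]
            for row in groups.itertuples():
                lines += [f"  - {row.group}: {row.n_x_outgroup2}/{row.n} = {row.prop_x_outgroup2:.3f}"]
            lines += [""]
    if "expression" in results:
        lines += ["## Expression, dosage compensation, gene classes", ""]
        for tissue, dosage in results["expression"]["dosage"].items():
            med = dosage.ratios.groupby("chrom_class")["log2_mf"].median().to_dict()
            lines += [f"- {tissue}: median log2(M/F) by class: " + ", ".join(f"{k}={v:.3f}" for k, v in med.items())]
        specific = results["expression"]["tissue_specific"]["specific_class"].value_counts().to_dict()
        lines += [f"- tissue-specific counts: {specific}", ""]
    if "landscape" in results:
        lines += ["## X vs autosome landscape", ""]
        for row in results["landscape"]["summary"].itertuples():
            lines += [
                f"- {row.metric}: median X={row.median_x:.4g}, A={row.median_autosome:.4g}, "
                f"X/A(means)={row.xa_ratio_of_means:.3f}, p={row.p_value:.3g}"
            ]
        lines += [""]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
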