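"""End-to-end driver: simulate -> profile -> annotate -> select -> model.

Runs the three conceptual stages — (1) profile and identify candidate
differential promoter tags, (2) evaluate markers across tissue panels,
(3) validate with cohort statistics and the cross-validated risk model
— on fully synthetic inputs, writing every artifact plus a manifest of
file hashes and the effective configuration. Byte-identical outputs for
a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import annotate, cohort_stats, dream, markers, risk_model, simulate
from .io import PipelineConfig, write_bed, write_fasta, write_tsv

log = logging.getLogger("radiomethyl")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and return the manifest (also written as JSON)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    log.info("effective config: %s", config)

    def emit(stage: str, name: str, path: Path):
        written[f"{stage}/{name}"] = path

    # -- stage 1: synthetic inputs ------------------------------------------
    stage = "simulate"
    genome = simulate.generate_genome(
        n_contigs=1,
        contig_length=config.contig_length,
        n_sites=config.n_sites,
        n_islands=config.n_islands,
        n_tss=config.n_tss,
        n_repeats=config.n_repeats,
        seed=config.seed,
    )
    catalog = genome.site_flanks()
    diff_sites = list(catalog["site_id"][: config.n_islands])  # island-embedded sites
    truth = simulate.plant_differential_truth(
        genome,
        n_per_group=config.samples_per_group,
        differential_sites=diff_sites,
        seed=config.seed,
    )
    tags = simulate.generate_dream_tags(
        genome, truth, depth=config.depth, error_rate=config.error_rate, seed=config.seed
    )
    cohort = simulate.finalize_cohort(
        simulate.generate_cohort(simulate.reference_cohort_spec(seed=config.seed))
    )
    pyro = simulate.generate_pyro_panel(seed=config.seed)

    p = outdir / "genome.fasta"; write_fasta(genome.sequences, p); emit(stage, "genome", p)
    p = outdir / "sites.bed"
    write_bed(
        [(c, pos, pos + 6, sid, 0, "+") for sid, c, pos in
         catalog[["site_id", "contig", "pos"]].itertuples(index=False)], p)
    emit(stage, "sites", p)
    p = outdir / "tss.bed"
    write_bed([(c, pos, pos + 1, g, 0, s) for g, c, pos, s in genome.tss], p)
    emit(stage, "tss", p)
    p = outdir / "islands_truth.bed"; write_bed(genome.islands, p); emit(stage, "islands_truth", p)
    p = outdir / "repeats.bed"; write_bed(genome.repeats, p); emit(stage, "repeats", p)
    p = outdir / "truth_methylation.tsv"; write_tsv(truth.fractions, p); emit(stage, "truth", p)
    p = outdir / "tags.tsv"; write_tsv(tags, p); emit(stage, "tags", p)
    p = outdir / "cohort.tsv"; write_tsv(cohort, p); emit(stage, "cohort", p)
    p = outdir / "pyro.tsv"; write_tsv(pyro, p); emit(stage, "pyro", p)

    # -- stage 2: profiling + differential filter ---------------------------
    stage = "profile"
    cfg = dream.DreamConfig(
        diff_threshold=config.diff_threshold,
        p_threshold=config.p_threshold,
        min_depth=config.min_depth,
        test_kind=config.test_kind,
    )
    profiles, qc = dream.profile_sites(tags, catalog, cfg)
    profiles = dream.exclude_repetitive(profiles, catalog, genome.repeats)
    p = outdir / "profiles.tsv"; write_tsv(profiles, p); emit(stage, "profiles", p)
    p = outdir / "qc.tsv"; write_tsv(qc, p); emit(stage, "qc", p)

    stage = "differential"
    diff = dream.differential_tags(profiles, truth.groups, cfg)
    p = outdir / "differential.tsv"; write_tsv(diff, p); emit(stage, "differential", p)

    # -- stage 3: islands + promoter narrowing ------------------------------
    stage = "annotate"
    detected = []
    for contig, seq in genome.sequences.items():
        detected += [
            (isl.contig, isl.start, isl.end)
            for isl in annotate.detect_islands(
                seq,
                min_gc=config.island_min_gc,
                min_oe=config.island_min_oe,
                min_length=config.island_min_length,
                contig=contig,
            )
        ]
    p = outdir / "islands_detected.bed"; write_bed(detected, p); emit(stage, "islands", p)
    promoter_tags = annotate.select_promoter_tags(
        diff, catalog, detected, genome.tss_table(), window=config.tss_window
    )
    p = outdir / "promoter_tags.tsv"; write_tsv(promoter_tags, p); emit(stage, "promoter_tags", p)

    # -- stage 4: marker evaluation -----------------------------------------
    stage = "markers"
    panel = simulate.panel_table(pyro)
    selection = markers.select_positive_genes(panel, threshold=config.positivity_threshold)
    p = outdir / "panel.tsv"; write_tsv(panel.reset_index(), p); emit(stage, "panel", p)
    p = outdir / "selected_markers.tsv"
    write_tsv(pd.DataFrame({"gene": selection.selected}), p)
    emit(stage, "selected", p)

    # -- stage 5: cohort statistics -----------------------------------------
    stage = "cohort"
    table = cohort_stats.compare_groups(
        cohort.drop(columns=["stenosis_extracranial", "stenosis_intracranial",
                             "stenosis_total"])
    )
    p = outdir / "group_comparison.tsv"; write_tsv(table, p); emit(stage, "comparison", p)

    # -- stage 6: risk model ------------------------------------------------
    stage = "predict"
    # candidates: risk factors, labs and methylation markers — never the
    # stenosis counts (label-defining) or stroke-severity scores
    candidates = [
        c for c in cohort.columns
        if c not in ("patient_id", "group", "stenosis_extracranial",
                     "stenosis_intracranial", "stenosis_total",
                     "nihss_admission", "nihss_discharge")
    ]
    labels = (cohort["group"] == "stenosis").astype(int)
    plan = risk_model.SplitPlan(
        train_fraction=config.train_fraction, folds=config.folds, seed=config.seed
    )
    report = risk_model.split_and_crossvalidate(
        cohort, labels, candidates, plan,
        retention_p=config.retention_p, threshold=config.class_threshold,
    )
    p = outdir / "model.tsv"
    write_tsv(report.final_model.params.rename_axis("variable").reset_index(), p)
    emit(stage, "model", p)
    p = outdir / "importance.tsv"; write_tsv(report.importance, p); emit(stage, "importance", p)
    perf = report.performance
    p = outdir / "performance.tsv"
    write_tsv(
        pd.DataFrame(
            {
                "metric": ["accuracy", "sensitivity_no_stenosis",
                           "specificity_stenosis", "auc"],
                "value": [perf.accuracy, perf.sensitivity_no_stenosis,
                          perf.specificity_stenosis, perf.auc],
            }
        ),
        p,
    )
    emit(stage, "performance", p)

    # -- manifest -----------------------------------------------------------
    cfg_path = outdir / "effective_config.yaml"
    config.to_yaml(cfg_path)
    manifest = {
        "config": str(cfg_path),
        "files": {key: {"path": str(path), "sha256": _sha256(path)}
                  for key, path in written.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
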