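"""End-to-end pipeline: simulate → enrich → cargo → motifs → triage → logos → clusters.

``run_pipeline`` composes every stage under one :class:`PipelineConfig`,
writes all intermediate tables into the output directory, and returns a
JSON-serialisable run report with the counts at each stage, the
parameters, the seed and package versions — enough to reproduce the run
byte-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__, io
from .annotation import term_enrichment
from .cargo import cargo_fraction, categorize, select_candidate_cargo
from .enrichment import DEFAULT_FC_CUT, DEFAULT_Q_CUT, EnrichmentModel
from .motifs import PHI, cterm_peptide, scan_proteome
from .simulate import SimConfig, simulate_experiment
from .structure import build_pwm, select_extremes, triage
from .timecourse import TimecourseModel

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Thresholds, seeds and paths for one pipeline run."""

    outdir: str = "endokit_out"
    seed: int = 0
    fc_cut: float = DEFAULT_FC_CUT
    q_cut: float = DEFAULT_Q_CUT
    iptm_threshold: float = 0.6
    shrink: float = 0.9
    phi: str = "".join(sorted(PHI))
    contrast: str = "genotype:tagged/untagged"
    n_top: int = 10
    n_bottom: int = 10
    n_clusters: int = 3
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic-study pipeline and write all outputs.

    Stages: simulate → normalize/differential → classify enriched →
    candidate-cargo selection → term enrichment → motif scan → ipTM
    triage → motif logos → time-course clustering. Any stage failure
    aborts with a :class:`StageError` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "fc_cut": config.fc_cut,
            "q_cut": config.q_cut,
            "iptm_threshold": config.iptm_threshold,
            "phi": config.phi,
            "contrast": config.contrast,
            "n_clusters": config.n_clusters,
            "sim": asdict(config.sim),
        },
        "counts": {},
    }
    phi = frozenset(config.phi)

    stage = "simulate"
    try:
        sim_cfg = config.sim
        if sim_cfg.seed != config.seed:
            sim_cfg = SimConfig(**{**asdict(sim_cfg), "seed": config.seed})
        expt = simulate_experiment(sim_cfg)
        io.write_quant(expt.quant, out / "quant.tsv", out / "design.tsv")
        io.write_annotations(expt.catalog, out / "annotations.tsv")
        io.write_fasta(expt.sequences, out / "sequences.fasta")
        io.write_terms(expt.catalog.terms, out / "terms.tsv")
        io.write_iptm(expt.iptm, out / "iptm.tsv")
        io.write_timecourse(expt.timecourse, out / "timecourse.tsv")
        io.write_ground_truth(expt.truth, out / "ground_truth.json")
        report["counts"]["proteins"] = len(expt.catalog.ids)
    except Exception as exc:  # noqa: BLE001 — rewrapped with stage context
        raise StageError(stage, exc) from exc

    stage = "enrichment"
    try:
        model = EnrichmentModel(expt.quant)
        results = model.fit(
            config.contrast,
            shrink=config.shrink,
            fc_cut=config.fc_cut,
            q_cut=config.q_cut,
        )
        io.write_enrichment(results.table, out / "enrichment.tsv")
        enriched = results.classify_enriched()
        report["counts"]["tested"] = results.n_tested
        report["counts"]["enriched"] = len(enriched)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "cargo"
    try:
        cargo = select_candidate_cargo(enriched, expt.catalog.table)
        io.write_tsv(cargo.table.reset_index(), out / "cargo.tsv")
        _, partition = categorize(cargo)
        pm_universe = set(
            expt.catalog.table.index[
                (expt.catalog.table["tm_count"] >= 1)
                & expt.catalog.table["cell_membrane"]
            ]
        )
        report["counts"]["candidate_cargo"] = len(cargo)
        report["counts"]["cargo_fraction_pct"] = (
            cargo_fraction(pm_universe, cargo) if pm_universe else 0
        )
        report["counts"]["cargo_categories"] = partition
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "terms"
    try:
        if not expt.catalog.terms.empty and enriched:
            universe = set(results.table.index[results.table["p_value"].notna()])
            rows = term_enrichment(enriched & universe, universe, expt.catalog.terms)
            io.write_tsv(rows, out / "term_enrichment.tsv")
            report["counts"]["terms_tested"] = len(rows)
            report["counts"]["terms_significant"] = int((rows["q_value"] <= 0.05).sum())
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "motifs"
    try:
        cargo_seqs = {pid: expt.sequences[pid] for pid in sorted(cargo.ids)}
        motif_table = scan_proteome(cargo_seqs, phi=phi)
        io.write_motifs(motif_table.hits, out / "motifs.tsv")
        report["counts"].update(motif_table.summary)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "triage"
    try:
        passed, failed = triage(expt.iptm, threshold=config.iptm_threshold)
        io.write_iptm(passed, out / "iptm_pass.tsv")
        report["counts"]["iptm_candidates"] = len(expt.iptm)
        report["counts"]["iptm_pass"] = len(passed)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "logos"
    try:
        snx27 = expt.iptm[expt.iptm["motif_class"] == "SNX27"]
        n_extreme = min(config.n_top, config.n_bottom, len(snx27) // 2)
        if n_extreme >= 2:
            top, bottom = select_extremes(snx27, n_extreme, n_extreme)
            for name, sel in (("top", top), ("bottom", bottom)):
                peptides = [cterm_peptide(p, 15) for p in sel["peptide"]]
                width = min(len(p) for p in peptides)
                pwm = build_pwm([p[-width:] for p in peptides])
                io.write_tsv(pwm.probs.reset_index(), out / f"pwm_snx27_{name}.tsv")
                io.write_tsv(
                    pwm.information.reset_index(), out / f"ic_snx27_{name}.tsv"
                )
            report["counts"]["logo_peptides"] = 2 * n_extreme
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "timecourse"
    try:
        tc_model = TimecourseModel(expt.timecourse)
        clusters = tc_model.fit(k=config.n_clusters, seed=config.seed)
        io.write_tsv(
            clusters.assignment.reset_index(), out / "cluster_assignment.tsv"
        )
        io.write_tsv(clusters.centroids.reset_index(), out / "cluster_centroids.tsv")
        report["counts"]["clusters"] = clusters.k
        report["counts"]["clustered_proteins"] = len(clusters.assignment)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    io.write_json(report, out / "report.json")
    return report
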