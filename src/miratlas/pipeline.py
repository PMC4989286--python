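"""End-to-end pipeline composition, configuration, and reporting.

Stage order mirrors the study design: simulate (or take real inputs) ->
annotate -> quantify -> enrich -> qpcr -> panel -> report.  Each stage logs
a record-count funnel, outputs are checksummed into a run manifest, and the
report is a pure function of stage outputs (byte-identical on rerun).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import enrichment as enr
from . import qpcr as qp
from . import quantify as qt
from . import simulate as sim
from .errors import ConfigError

log = logging.getLogger("miratlas")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class PipelineConfig:
    outdir: str = "atlas_run"
    seed: int = 17
    log_level: str = "INFO"
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    enrichment: enr.EnrichmentConfig = field(default_factory=enr.EnrichmentConfig)
    max_locations: int = 10
    gap_tolerance: int = 0
    overlap_frac: float = 0.7
    ct_cutoff: float = 38.0
    qpcr_references: tuple[str, ...] = ()
    panel_targets: tuple[str, ...] = ("cfa-miR-122", "cfa-miR-885")
    panel_value: str = "neg_delta_ct"

    def validate(self) -> None:
        self.simulation.seed = self.seed
        self.simulation.validate()
        self.enrichment.validate()
        if not (0 < self.overlap_frac <= 1):
            raise ConfigError(f"overlap_frac must be in (0,1], got {self.overlap_frac}")
        if self.ct_cutoff <= 0:
            raise ConfigError("ct_cutoff must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            sim_cfg = sim.SimulationConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.pop("simulation", {}).items()
            })
            enr_cfg = enr.EnrichmentConfig(**raw.pop("enrichment", {}))
            cfg = cls(simulation=sim_cfg, enrichment=enr_cfg, **{
                k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
            })
        except TypeError as exc:
            raise ConfigError(f"{path}: unknown configuration key ({exc})") from exc
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    checksums: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)

    def record(self, stage: str, *paths: Path) -> None:
        for p in paths:
            if p.is_file():
                self.checksums[str(p.name)] = _sha256(p)
        self.timestamps[stage] = time.time()

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True) + "\n")


def panel_study_from_tables(
    serum_ct: pd.DataFrame,
    chemistry: pd.DataFrame,
    references: list[str],
    panel: list[str],
    ct_cutoff: float = 38.0,
) -> qp.PanelStudy:
    """Build a PanelStudy from serum Ct plates + chemistry tables.

    The serum Ct table must carry animal/day/phase columns alongside the
    plate columns; delta-Ct is computed per serum sample against the given
    reference targets.
    """
    dct = qp.delta_ct_table(serum_ct, references, ct_cutoff)
    meta = serum_ct[["sample_id", "animal", "day", "phase"]].drop_duplicates()
    meas = dct.merge(meta, on="sample_id")
    meas = meas[["animal", "day", "phase", "target", "delta_ct", "rel_expr",
                 "censored"]]
    return qp.PanelStudy(meas, chemistry, panel=[qp.canonical_target(t)
                                                 for t in panel])


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Simulate inputs, run every stage, and write all artifacts.

    Stages run in dependency order; a stage whose inputs are unchanged
    (matching checksums in an existing manifest) is skipped on rerun.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = RunManifest(
        version="0.1.0",
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
    )

    # --- simulate -----------------------------------------------------
    sim_dir = outdir / "sim"
    log.info("stage simulate -> %s", sim_dir)
    paths = sim.simulate_all(config.simulation, sim_dir)
    manifest.record("simulate", *[p for p in paths.values() if p.is_file()])
    truth = sim.PlantedTruth.load(paths["truth"])

    # --- annotate -----------------------------------------------------
    hcfg = ann.HarmonizerConfig(
        species_fastas={sp: sim_dir / f"{sp}.fa"
                        for sp in config.simulation.species},
        genome_fasta=paths["genome"],
        target_species=config.simulation.species[0],
        max_locations=config.max_locations,
        gap_tolerance=config.gap_tolerance,
    )
    annotation, funnel = ann.build_annotation(hcfg)
    log.info("stage annotate: funnel %s", funnel)
    ann_dir = outdir / "annotation"
    ann_dir.mkdir(exist_ok=True)
    ann.write_gff3(annotation, ann_dir / "annotation.gff3")
    ann.write_bed(annotation, ann_dir / "annotation.bed")
    ann.write_funnel(funnel, ann_dir / "funnel.tsv")
    ann.write_manifest(hcfg, funnel, ann_dir / "run_manifest.json")
    manifest.record("annotate", ann_dir / "annotation.gff3",
                    ann_dir / "annotation.bed", ann_dir / "funnel.tsv")

    # --- quantify -----------------------------------------------------
    qdir = outdir / "quant"
    qdir.mkdir(exist_ok=True)
    samples = qt.SampleTable.read_tsv(paths["samples"])
    aln = {
        p.stem: qt.read_alignment_bed(p)
        for p in sorted((sim_dir / "alignments").glob("*.bed"))
    }
    read_counts = qt.assign_reads(
        aln, annotation, samples,
        overlap_frac=config.overlap_frac, max_locations=config.max_locations,
    )
    qt.write_matrix_tsv(read_counts.counts, qdir / "counts_from_reads.tsv")
    stats = pd.read_csv(paths["mapping_stats"], sep="\t").set_index("sample_id")
    pmap = qt.percent_mapped(stats["aligned"], stats["total"])
    pmap.rename("percent_mapped").to_csv(qdir / "percent_mapped.tsv", sep="\t")

    counts_df = qt.read_matrix_tsv(paths["counts"])
    cm = qt.CountMatrix(counts_df, counts_df.sum(axis=0))
    expr = qt.rpm_normalize(cm)
    qt.write_matrix_tsv(expr.values, qdir / "rpm.tsv")
    log.info("stage quantify: %d loci x %d samples", *expr.values.shape)
    manifest.record("quantify", qdir / "counts_from_reads.tsv",
                    qdir / "rpm.tsv", qdir / "percent_mapped.tsv")

    # --- enrich -------------------------------------------------------
    edir = outdir / "enrich"
    edir.mkdir(exist_ok=True)
    records, tally = enr.classify_all(expr, samples, config.enrichment)
    records.to_csv(edir / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
    tally.to_csv(edir / "tally.tsv", sep="\t")
    qc = enr.spearman_qc(expr, samples)
    qc.matrix.to_csv(edir / "spearman_r2.tsv", sep="\t", float_format="%.6g")
    qc.within_tissue_mean.rename("within_r2").to_csv(
        edir / "within_tissue_r2.tsv", sep="\t")
    refscore = enr.reference_score(expr, samples,
                                   config.enrichment.candidate_rpm)
    refscore.to_csv(edir / "reference_score.tsv", sep="\t",
                    float_format="%.6g")
    log.info("stage enrich: %d enriched records",
             int((records["class"] != "none").sum()))
    manifest.record("enrich", edir / "enrichment.tsv", edir / "tally.tsv",
                    edir / "spearman_r2.tsv", edir / "reference_score.tsv")

    # --- qpcr ---------------------------------------------------------
    qpdir = outdir / "qpcr"
    qpdir.mkdir(exist_ok=True)
    ct = qp.read_ct_csv(paths["ct"])
    references = list(config.qpcr_references) or truth.reference_loci
    dct = qp.delta_ct_table(ct, references, config.ct_cutoff)
    dct.to_csv(qpdir / "delta_ct.tsv", sep="\t", index=False,
               float_format="%.6g")
    plat_rows = []
    for target in sorted(dct["target"].unique()):
        sub = dct[(dct["target"] == target) & (~dct["censored"])]
        if target not in expr.values.index or len(sub) < 3:
            continue
        r2, slope, intercept, n = qp.platform_correlation(
            sub.set_index("sample_id")["rel_expr"], expr.values.loc[target]
        )
        plat_rows.append({"target": target, "r2": r2, "slope": slope,
                          "intercept": intercept, "n": n})
    platform = pd.DataFrame(plat_rows)
    platform.to_csv(qpdir / "platform_correlation.tsv", sep="\t", index=False,
                    float_format="%.6g")
    means = qp.mean_ct_table(ct, config.ct_cutoff)
    ref_cv = qp.reference_cv(means, samples.tissue_of(), references)
    ref_cv.to_csv(qpdir / "reference_cv.tsv", sep="\t",
                  float_format="%.6g")
    manifest.record("qpcr", qpdir / "delta_ct.tsv",
                    qpdir / "platform_correlation.tsv",
                    qpdir / "reference_cv.tsv")

    # --- panel --------------------------------------------------------
    pdir = outdir / "panel"
    pdir.mkdir(exist_ok=True)
    serum = pd.read_csv(paths["serum_ct"])
    chem = pd.read_csv(paths["chem"])
    study = panel_study_from_tables(
        serum, chem, list(config.simulation.reference_targets),
        list(config.panel_targets), config.ct_cutoff,
    )
    panel_rows = []
    for target in study.panel + list(config.simulation.nonliver_targets):
        for analyte in ("ALT", "AST"):
            res = qp.panel_correlate(study, target, analyte,
                                     value=config.panel_value)
            for _, row in res.iterrows():
                panel_rows.append({"target": target, "analyte": analyte,
                                   **row.to_dict()})
    panel = pd.DataFrame(panel_rows)
    panel.to_csv(pdir / "panel_correlation.tsv", sep="\t", index=False,
                 float_format="%.6g")
    manifest.record("panel", pdir / "panel_correlation.tsv")

    # --- report -------------------------------------------------------
    summary = report(outdir)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest.record("report", outdir / "summary.json")
    manifest.save(outdir / "manifest.json")
    return manifest


def report(outdir: str | Path) -> dict:
    """Summary JSON assembled purely from stage outputs on disk."""
    outdir = Path(outdir)
    summary: dict = {}
    funnel_path = outdir / "annotation" / "funnel.tsv"
    if funnel_path.exists():
        fdf = pd.read_csv(funnel_path, sep="\t")
        summary["annotation_funnel"] = dict(
            zip(fdf["step"], fdf["count"].astype(int).tolist())
        )
    tally_path = outdir / "enrich" / "tally.tsv"
    if tally_path.exists():
        tdf = pd.read_csv(tally_path, sep="\t", index_col=0)
        summary["enrichment_tally"] = {
            t: {c: int(tdf.loc[t, c]) for c in tdf.columns} for t in tdf.index
        }
        summary["enrichment_totals"] = {
            c: int(tdf[c].sum()) for c in tdf.columns
        }
    within_path = outdir / "enrich" / "within_tissue_r2.tsv"
    if within_path.exists():
        wdf = pd.read_csv(within_path, sep="\t", index_col=0)
        summary["qc_within_tissue_r2_mean"] = round(
            float(wdf["within_r2"].mean()), 6)
    plat_path = outdir / "qpcr" / "platform_correlation.tsv"
    if plat_path.exists():
        pdf = pd.read_csv(plat_path, sep="\t")
        if len(pdf):
            summary["platform_r2"] = {
                row["target"]: round(float(row["r2"]), 6)
                for _, row in pdf.iterrows()
            }
    panel_path = outdir / "panel" / "panel_correlation.tsv"
    if panel_path.exists():
        pl = pd.read_csv(panel_path, sep="\t")
        if len(pl):
            summary["panel_r2"] = {
                f"{t}_{a}": {
                    str(row["animal"]): round(float(row["r2"]), 6)
                    for _, row in grp.iterrows() if row["evaluable"]
                }
                for (t, a), grp in pl.groupby(["target", "analyte"])
            }
    return summary
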