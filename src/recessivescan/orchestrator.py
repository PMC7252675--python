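"""End-to-end pipeline driver: phenotypes -> REML -> scan -> fine-mapping.

Stages run in a fixed order; each stage either contributes to the run
report or is marked skipped (optional input missing) / aborted (error in a
prerequisite).  The report is written as JSON and Markdown and is a pure
function of the configuration and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import hapscan, haplosegment, recfilter, semenqc, splicekit, varcomp
from .panel import HaplotypePanel


@dataclass
class PipelineConfig:
    outdir: str
    ejaculates: str
    panel_vcf: str | None = None
    hap_matrix: str | None = None
    markers: str | None = None
    pedigree: str | None = None
    inseminations: str | None = None
    region_vcf: str | None = None
    junction_sam: str | None = None
    junction: dict | None = None  # wt_donor_end, truncation, acceptor_start
    region: str | None = None
    trait: str = "motility_pct"
    model: str = "recessive"
    window_size: int = 50
    step: int = 15
    n_pcs: int = 10
    run_varcomp: bool = False
    make_plot: bool = False
    min_inseminations: int = 200
    seed: int = 0
    filter_config: dict = field(default_factory=dict)
    compatibility_rule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if self.panel_vcf is None and self.hap_matrix is None:
            raise ValueError("either panel_vcf or hap_matrix (+ markers) is required")
        for name in ("ejaculates", "panel_vcf", "hap_matrix", "markers", "pedigree",
                     "inseminations", "region_vcf", "junction_sam"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{name}: {path}")
        if self.model not in hapscan.MODELS:
            raise ValueError(f"unknown model {self.model!r}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[E_{stage.upper()}] stage '{stage}' failed: {cause}")
        self.stage = stage
        self.code = f"E_{stage.upper()}"


def run(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run report."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def stage(name, fn, skip=False, reason=""):
        if skip:
            report["stages"][name] = {"status": "skipped", "reason": reason}
            return None
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            report["stages"][name] = {"status": "failed", "error": str(exc),
                                      "code": f"E_{name.upper()}"}
            _write_report(report, config.outdir)
            raise StageError(name, exc) from exc
        report["stages"][name] = {"status": "ok",
                                  "seconds": round(time.perf_counter() - t0, 3)}
        return out

    # 1. phenotypes -------------------------------------------------------
    def _phenotypes():
        records = pd.read_csv(config.ejaculates, dtype={"collector_id": str})
        fcfg = semenqc.FilterConfig(**config.filter_config)
        filtered, log = semenqc.filter_ejaculates(records, fcfg)
        traits = semenqc.aggregate_traits(filtered)
        log.to_csv(os.path.join(config.outdir, "attrition.tsv"), sep="\t", index=False)
        traits.to_csv(os.path.join(config.outdir, "bull_traits.csv"))
        report["attrition"] = log.to_dict(orient="records")
        report["n_bulls_phenotyped"] = int(len(traits))
        return filtered, traits

    filtered, traits = stage("phenotypes", _phenotypes)

    # 2. fertility (optional) --------------------------------------------
    def _fertility():
        insem = pd.read_csv(config.inseminations)
        res = semenqc.estimate_fertility(insem, min_inseminations=config.min_inseminations)
        res.index.to_csv(os.path.join(config.outdir, "fertility.csv"))
        report["fertility"] = {
            "n_bulls": int(len(res.index)),
            "outliers_removed": list(map(str, res.outliers_removed)),
        }
        return res

    stage("fertility", _fertility, skip=config.inseminations is None,
          reason="no insemination file")

    # 3. variance components (optional) ----------------------------------
    def _varcomp():
        pedigree = pd.read_csv(config.pedigree)
        y, X, bulls = varcomp.design_from_records(filtered, config.trait)
        fit = varcomp.reml_fit(y, X, bulls, pedigree, tol=1e-6)
        report["variance_components"] = {
            "sigma_g2": fit.sigma_g2, "sigma_pe2": fit.sigma_pe2,
            "sigma_e2": fit.sigma_e2, "h2": fit.h2,
            "repeatability": fit.repeatability, "converged": fit.converged,
        }
        return fit

    stage("varcomp", _varcomp,
          skip=not (config.run_varcomp and config.pedigree),
          reason="disabled or no pedigree")

    # 4. haplotype scan ---------------------------------------------------
    def _scan():
        if config.panel_vcf:
            panel = HaplotypePanel.from_vcf(config.panel_vcf)
        else:
            panel = HaplotypePanel.from_matrix(config.hap_matrix, config.markers)
        pcs, _ = hapscan.grm_pcs(panel.genotypes(), k=config.n_pcs)
        y = traits[config.trait]
        result = hapscan.scan(panel, y, pcs=pcs, model=config.model,
                              window_size=config.window_size, step=config.step)
        result.records.to_csv(os.path.join(config.outdir, "scan.tsv"),
                              sep="\t", index=False)
        report["scan"] = {config.trait: result.summary()}
        return panel, result

    panel, result = stage("scan", _scan)

    # 5. haplotype status + shared segment -------------------------------
    def _segment():
        top = result.top(1).iloc[0]
        window = hapscan.Window(
            chrom=str(top["chrom"]), start=int(top["start"]), end=int(top["end"]),
            start_bp=int(top["start_bp"]), end_bp=int(top["end_bp"]),
            index=int(top["window_index"]),
        )
        status = haplosegment.assign_status(panel, window, top["haplotype"])
        report["haplotype_status"] = {
            "n_noncarrier": int((status == 0).sum()),
            "n_heterozygous": int((status == 1).sum()),
            "n_homozygous": int((status == 2).sum()),
            "frequency": float(status.sum() / (2 * len(status))),
        }
        seg = None
        if (status == 2).sum() >= 2:
            seg = haplosegment.shared_segment(panel, status, window)
            report["shared_segment"] = {
                "chrom": seg.chrom, "start_bp": seg.start_bp, "end_bp": seg.end_bp,
                "length_bp": seg.length_bp, "n_markers": seg.n_markers,
                "n_carriers": seg.n_carriers,
            }
        return status, seg

    status_seg = stage("segment", _segment, skip=result is None or result.n_tests == 0,
                       reason="no scan results")
    status, seg = status_seg if status_seg else (None, None)

    # 6. recessive-compatibility filtration ------------------------------
    def _recfilter():
        groups = recfilter.StatusGroups.from_status(status)
        rule = recfilter.CompatibilityRule(**config.compatibility_rule)
        region = config.region
        if region is None:
            if seg is None:
                raise ValueError("no region configured and no shared segment found")
            region = f"{seg.chrom}:{max(1, seg.start_bp - 5_000_000)}-{seg.end_bp + 5_000_000}"
        inner = (seg.start_bp, seg.end_bp) if seg else None
        compat, summary = recfilter.filter_region(
            config.region_vcf, region, groups, rule, inner_interval=inner
        )
        report["compatible_variants"] = summary
        pd.DataFrame(
            [{"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
              "class": v.variant_class, **{f"freq_{k}": f for k, f in v.freqs.items()}}
             for v in compat]
        ).to_csv(os.path.join(config.outdir, "compatible_variants.tsv"),
                 sep="\t", index=False)
        return compat

    stage("recfilter", _recfilter,
          skip=config.region_vcf is None or status is None
          or (status == 2).sum() == 0,
          reason="no region VCF or no homozygous carriers")

    # 7. splice junction tally -------------------------------------------
    def _splice():
        pair = splicekit.SpliceJunctionPair(**config.junction)
        tally = splicekit.tally_junctions(config.junction_sam, pair)
        report["junction_tally"] = {
            "wt_reads": tally.wt_reads, "mt_reads": tally.mt_reads,
            "unassigned": tally.unassigned,
        }
        return tally

    stage("splice", _splice,
          skip=config.junction_sam is None or config.junction is None,
          reason="no junction SAM/geometry")

    # 8. Manhattan plot ---------------------------------------------------
    stage("plot",
          lambda: make_manhattan(result, os.path.join(config.outdir, "manhattan.png")),
          skip=not config.make_plot or result is None, reason="plot disabled")

    _write_report(report, config.outdir)
    return report


def _write_report(report: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    lines = ["# recessivescan run report", ""]
    for stage_name, info in report.get("stages", {}).items():
        lines.append(f"- **{stage_name}**: {info.get('status')}")
    for key in ("haplotype_status", "shared_segment", "variance_components",
                "junction_tally"):
        if key in report:
            lines.append(f"\n## {key}\n")
            for k, v in report[key].items():
                lines.append(f"- {k}: {v}")
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def make_manhattan(result, out_path: str):
    """-log10(P) by genomic position with the Bonferroni line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    rec = result.records
    if len(rec):
        offsets, xpos, colors = {}, [], []
        cum = 0
        for i, chrom in enumerate(dict.fromkeys(rec["chrom"])):
            sub = rec[rec["chrom"] == chrom]
            offsets[chrom] = cum
            cum += int(sub["end_bp"].max()) + 1
        sig = rec["p"] < result.bonferroni_alpha
        x = rec.apply(lambda r: offsets[r["chrom"]] + r["start_bp"], axis=1)
        ax.scatter(x[~sig], -np.log10(rec.loc[~sig, "p"]), s=6, c="grey")
        ax.scatter(x[sig], -np.log10(rec.loc[sig, "p"]), s=8, c="red")
    if result.n_tests:
        ax.axhline(-np.log10(result.bonferroni_alpha), color="red", lw=0.8, ls="--")
    ax.set_xlabel("genomic position")
    ax.set_ylabel(r"$-\log_{10}(P)$")
    ax.set_title(f"haplotype scan ({result.model} model)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
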