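"""End-to-end orchestration with manifests.

Two entry points mirror the study's two halves:

* :func:`run_prioritize` — VCF + peak tracks + index SNP → LD proxies →
  annotation-overlap prioritization → allele-specific motif calls, with a
  funnel summary (n_proxies, n_candidates, n_motif_calls);
* :func:`run_assays` — luciferase plates and Ct tables → consolidated
  statistics report (group sizes, estimates, test type, declared
  sidedness, p-values).

Every run writes a manifest recording the config snapshot, input-file
digests (taken before processing), package version, seed and per-stage
outputs; the manifest is written even when a stage fails, with the error
recorded. Timestamps live in their own field so reports stay
byte-comparable across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .annotation import build_annotation_matrix, prioritize, read_peak_track
from .ld import read_vcf_haplotypes, select_proxies, write_proxy_report
from .motif import (
    AlleleProbePair,
    allelic_motif_effect,
    load_foxa_core_pfm,
    pfm_to_pwm,
    read_jaspar_pfm,
    write_motif_report,
)
from .qpcr import CtTable, compare_conditions, compare_enrichment, fit_standard_curve, relative_expression
from .reporter import LuciferasePlate, compare_alleles, comparison_to_row

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def simulate_inputs(scenario, out_dir: str | Path) -> dict:
    """Write every synthetic study input for a scenario; returns the paths.

    Deterministic for a given scenario (seed included): reruns produce
    byte-identical files. Emits the phased VCF, peak tracks (+ metadata
    list for :func:`run_prioritize`), candidate probe pairs, one
    luciferase plate per virtual cell line, the ChIP and expression Ct
    tables, and the standard-curve dilution series.
    """
    import numpy as np

    from .motif import load_foxa_core_pfm, pfm_to_pwm
    from .simulate import (
        simulate_ct_table,
        simulate_dilution_series,
        simulate_expression_table,
        simulate_haplotype_panel,
        simulate_luciferase_plate,
        simulate_peak_tracks,
        simulate_probe_pair,
    )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Any] = {}

    vcf_path = out_dir / "panel.vcf"
    panel = simulate_haplotype_panel(scenario, vcf_path=vcf_path)
    paths["vcf"] = vcf_path

    tracks = simulate_peak_tracks(scenario, panel, out_dir=out_dir / "tracks")
    fmt_by_id = {e.track_id: e.fmt for e in scenario.peak_plan}
    paths["tracks_meta"] = [
        {
            "path": str(
                out_dir / "tracks" /
                f"{t.track_id}.{'narrowPeak' if fmt_by_id[t.track_id] == 'narrowPeak' else 'bed'}"
            ),
            "cell_type": t.cell_type,
            "assay_name": t.assay_name,
            "track_id": t.track_id,
        }
        for t in tracks
    ]

    probe = simulate_probe_pair(mode="printed", variant_id=scenario.motif_variant)
    probes = {scenario.motif_variant: probe}
    probes_path = out_dir / "probes.tsv"
    write_probe_table(probes, probes_path)
    paths["probes"] = probes_path

    rng = np.random.default_rng(scenario.seed + 1)
    paths["plates"] = {}
    for cell, plan in scenario.luciferase.items():
        plate = simulate_luciferase_plate(plan, rng)
        plate_path = out_dir / f"plate_{cell.replace('/', '_')}.tsv"
        plate.to_tsv(plate_path)
        paths["plates"][cell] = plate_path

    chip_table = simulate_ct_table(scenario.chip, rng)
    chip_path = out_dir / "chip_ct.tsv"
    chip_table.to_tsv(chip_path)
    paths["chip_ct"] = chip_path

    expr_table = simulate_expression_table(scenario.expression, rng)
    expr_path = out_dir / "expression_ct.tsv"
    expr_table.to_tsv(expr_path)
    paths["expression_ct"] = expr_path

    curves = {
        scenario.expression.gene: list(
            simulate_dilution_series(scenario.expression, scenario.expression.gene_intercept, rng)
        ),
        scenario.expression.housekeeping: list(
            simulate_dilution_series(
                scenario.expression, scenario.expression.housekeeping_intercept, rng
            )
        ),
    }
    curves_path = out_dir / "dilution_series.json"
    curves_path.write_text(json.dumps(curves, indent=2) + "\n")
    paths["curves"] = curves_path
    return paths


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    command: str
    config: dict
    seed: int | None = None
    tool_version: str = __version__
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    funnel: dict[str, int] = field(default_factory=dict)
    error: str | None = None
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "tool_version": self.tool_version,
            "input_digests": self.input_digests,
            "outputs": self.outputs,
            "funnel": self.funnel,
            "error": self.error,
            "timestamp": self.timestamp or datetime.now(timezone.utc).isoformat(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_probe_table(path: str | Path) -> dict[str, AlleleProbePair]:
    """Probe TSV (variant_id, snp_offset, ref_seq, alt_seq) → probe pairs."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[str(row["variant_id"])] = AlleleProbePair(
            variant_id=str(row["variant_id"]),
            ref_seq=str(row["ref_seq"]),
            alt_seq=str(row["alt_seq"]),
            snp_offset=int(row["snp_offset"]),
        )
    return out


def write_probe_table(probes: dict[str, AlleleProbePair], path: str | Path) -> None:
    rows = [
        {
            "variant_id": vid,
            "snp_offset": p.snp_offset,
            "ref_seq": p.ref_seq,
            "alt_seq": p.alt_seq,
        }
        for vid, p in probes.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _load_pwm(config: dict):
    pfm_path = config.get("pfm")
    if pfm_path in (None, "builtin", "foxa_core"):
        pfm = load_foxa_core_pfm()
    else:
        pfm = read_jaspar_pfm(pfm_path)[0]
    return pfm, pfm_to_pwm(
        pfm,
        background=config.get("background"),
        pseudocount=config.get("pseudocount", 1.0),
    )


def run_prioritize(config: dict, out_dir: str | Path) -> RunManifest:
    """Funnel: select_proxies → annotation matrix → prioritize → motif calls.

    Required config keys: ``vcf``, ``index_snp``, ``threshold``,
    ``tracks`` (list of {path, cell_type, assay_name[, track_id]}).
    Optional: ``probes`` (TSV path for candidate probe pairs), ``pfm``
    (JASPAR path; defaults to the bundled forkhead-core fixture),
    ``rel_score_threshold``, ``region``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="prioritize", config=config, seed=config.get("seed"))
    manifest_path = out_dir / "manifest.json"
    stage = "setup"
    try:
        for key in ("vcf", "index_snp", "threshold", "tracks"):
            if key not in config:
                raise ValueError(f"config missing required key {key!r}")
        input_paths = [config["vcf"]] + [t["path"] for t in config["tracks"]]
        if config.get("probes"):
            input_paths.append(config["probes"])
        for p in input_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
            manifest.input_digests[str(p)] = _sha256(p)

        stage = "ld"
        panel = read_vcf_haplotypes(config["vcf"], region=config.get("region"))
        proxies = select_proxies(panel, config["index_snp"], float(config["threshold"]))
        proxy_path = out_dir / "proxies.tsv"
        write_proxy_report(panel, config["index_snp"], proxies, proxy_path)
        manifest.outputs["proxies"] = str(proxy_path)

        stage = "overlap"
        proxy_variants = [panel.variant(vid) for vid, _ in proxies]
        tracks = [
            read_peak_track(
                t["path"], t["cell_type"], t["assay_name"], track_id=t.get("track_id")
            )
            for t in config["tracks"]
        ]
        if proxy_variants:
            matrix = build_annotation_matrix(proxy_variants, tracks)
            report = prioritize(matrix, min_open_chromatin=config.get("min_open_chromatin", 1))
            candidates = report.candidates
            report.to_tsv(out_dir / "prioritization.tsv")
            n_candidates = report.n_candidates
        else:
            (out_dir / "prioritization.tsv").write_text(
                "variant_id\tcandidate\tn_open_chromatin\tn_histone\tn_tf_chip\tsupporting_tracks\n"
            )
            candidates, n_candidates = [], 0
        manifest.outputs["prioritization"] = str(out_dir / "prioritization.tsv")

        stage = "motif"
        probes = read_probe_table(config["probes"]) if config.get("probes") else {}
        pfm, pwm = _load_pwm(config)
        rel_threshold = float(config.get("rel_score_threshold", 0.8))
        effects = []
        for vid in candidates:
            if vid not in probes:
                logger.info("no probe pair for candidate %s; skipping motif call", vid)
                continue
            effects.append(allelic_motif_effect(pwm, probes[vid], rel_threshold))
        write_motif_report(effects, pfm.motif_id, out_dir / "motif_report.tsv")
        manifest.outputs["motif_report"] = str(out_dir / "motif_report.tsv")

        manifest.funnel = {
            "n_proxies": len(proxies),
            "n_candidates": n_candidates,
            "n_motif_calls": sum(1 for e in effects if e.call != "neutral"),
        }
        funnel_path = out_dir / "funnel.json"
        funnel_path.write_text(json.dumps(manifest.funnel, indent=2) + "\n")
        manifest.outputs["funnel"] = str(funnel_path)
    except Exception as exc:
        manifest.error = f"{stage}: {exc}"
        manifest.write(manifest_path)
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    manifest.write(manifest_path)
    return manifest


def run_assays(config: dict, out_dir: str | Path) -> RunManifest:
    """All configured assay comparisons in one consolidated report.

    Config sections (each optional): ``luciferase`` (list of {plate,
    cell_line, risk_label, nonrisk_label, orientations}), ``chip``
    ({ct_table, antibodies, region, control_region, direction}),
    ``expression`` ({ct_table, gene, housekeeping, curves: {target: [mean
    Ct, ...]}, low_label, high_label, dilution_factor}). Every report row
    carries the test type and sidedness; the n_tests_run column states how
    many tests the whole run performed (no correction is applied).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="assays", config=config, seed=config.get("seed"))
    manifest_path = out_dir / "manifest.json"
    rows: list[dict] = []
    stage = "setup"
    try:
        for section, key in (("luciferase", "plate"), ("chip", "ct_table"), ("expression", "ct_table")):
            entries = config.get(section)
            if not entries:
                continue
            for entry in entries if isinstance(entries, list) else [entries]:
                p = entry[key]
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
                manifest.input_digests[str(p)] = _sha256(p)

        stage = "reporter"
        for entry in config.get("luciferase", []):
            plate = LuciferasePlate.from_tsv(entry["plate"])
            for orientation in entry.get("orientations", ["forward"]):
                cmp = compare_alleles(
                    plate,
                    entry["risk_label"],
                    entry["nonrisk_label"],
                    orientation,
                    equal_var=entry.get("equal_var", False),
                    log_scale=entry.get("log_scale", False),
                    unit=entry.get("unit", "clone"),
                )
                row = {"assay": "luciferase", "context": entry.get("cell_line", "")}
                row.update(comparison_to_row(cmp))
                row["sidedness"] = "two-sided"
                rows.append(row)

        stage = "chip"
        chip = config.get("chip")
        if chip:
            table = CtTable.from_tsv(chip["ct_table"])
            for antibody in chip["antibodies"]:
                for region in [chip["region"]] + ([chip["control_region"]] if chip.get("control_region") else []):
                    res = compare_enrichment(
                        table,
                        antibody,
                        region,
                        chip["direction"],
                        igg_label=chip.get("igg_label", "IgG"),
                        input_label=chip.get("input_label"),
                        input_fraction=chip.get("input_fraction", 0.05),
                    )
                    rows.append(
                        {
                            "assay": "chip_qpcr",
                            "context": f"{antibody}@{region}",
                            "group_means": json.dumps(res.group_means),
                            "n_by_group": json.dumps(
                                {g: len(v) for g, v in res.folds_by_group.items()}
                            ),
                            "t_statistic": res.t_statistic,
                            "p_value": res.p_value,
                            "test": "welch",
                            "sidedness": f"one-sided ({res.direction})",
                        }
                    )

        stage = "expression"
        expr = config.get("expression")
        if expr:
            table = CtTable.from_tsv(expr["ct_table"])
            curves = {
                target: fit_standard_curve(cts, dilution_factor=expr.get("dilution_factor", 3.0))
                for target, cts in expr["curves"].items()
            }
            curve_path = out_dir / "standard_curves.json"
            curve_path.write_text(
                json.dumps(
                    {
                        t: {
                            "slope": c.slope,
                            "intercept": c.intercept,
                            "efficiency": c.efficiency,
                            "r_squared": c.r_squared,
                        }
                        for t, c in curves.items()
                    },
                    indent=2,
                )
                + "\n"
            )
            manifest.outputs["standard_curves"] = str(curve_path)
            expression = relative_expression(table, expr["gene"], expr["housekeeping"], curves)
            fold, p = compare_conditions(expression, expr["low_label"], expr["high_label"])
            n_by_group = expression.groupby("group").size().to_dict()
            rows.append(
                {
                    "assay": "expression",
                    "context": f"{expr['gene']}/{expr['housekeeping']}",
                    "fold_ratio": fold,
                    "n_by_group": json.dumps({str(k): int(v) for k, v in n_by_group.items()}),
                    "p_value": p,
                    "test": "welch",
                    "sidedness": "two-sided",
                }
            )

        report = pd.DataFrame(rows)
        report["n_tests_run"] = len(rows)
        report_path = out_dir / "assay_report.tsv"
        report.to_csv(report_path, sep="\t", index=False)
        manifest.outputs["assay_report"] = str(report_path)
    except Exception as exc:
        manifest.error = f"{stage}: {exc}"
        manifest.write(manifest_path)
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    manifest.write(manifest_path)
    return manifest
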