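"""End-to-end orchestration: simulate -> scan -> average -> stats -> qPCR.

One YAML/JSON config drives the whole pipeline; a single global seed is
split into per-stage, per-image substreams by hashing the stage keys, so any
stage can be rerun independently yet reproducibly.  Each stage writes its
interchange file (TIFF/CSV/JSON) and the run ends with a machine-readable
:class:`RunReport` JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .image import invert_image, read_image, write_image
from .profiles import (
    AveragingConfig,
    ZeroProfileError,
    hierarchical_average,
    normalize_profile,
    save_curves,
)
from .qpcr import anova_by_gene, relative_expression
from .scan import (
    LaminaTrace,
    ScanMeta,
    extract_scan,
    frame_to_profiles,
    length_to_apical_edge,
    make_scan_line,
    profiles_to_frame,
)
from .synthetic import (
    CtDesign,
    EpitheliumModel,
    generate_ct_table,
    generate_epithelium_image,
    null_calibration_model,
    olfactory_cohort_model,
    to_brightfield,
    write_ground_truth,
)
from .windowstats import MarkerWindow, compare_windowed_integrals, derive_window, ks_compare

log = logging.getLogger("episcan")

ALL_STAGES = ("simulate", "scan", "average", "window_stats", "qpcr")


def derive_seed(root: int, *keys: Any) -> int:
    """Deterministic 31-bit substream seed from the global seed and keys."""
    data = json.dumps([int(root), *map(str, keys)]).encode()
    return int.from_bytes(hashlib.sha256(data).digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class CohortDesign:
    """How many animals, images and scans make up one probe's cohort."""

    n_animals: int = 3
    images_per_animal: int = 2
    scans_per_image: int = 2

    def __post_init__(self) -> None:
        if min(self.n_animals, self.images_per_animal, self.scans_per_image) < 1:
            raise ValueError("cohort counts must be positive")


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    outdir: str = "episcan_out"
    epithelium: EpitheliumModel = field(default_factory=olfactory_cohort_model)
    cohort: CohortDesign = field(default_factory=CohortDesign)
    probes: tuple[str, ...] | None = None  # default: all probes of the model
    scan_length_um: float | str = "auto"
    scan_step_px: float = 1.0
    averaging: AveragingConfig = field(default_factory=AveragingConfig)
    window: MarkerWindow = field(default_factory=MarkerWindow)
    window_from_marker: str | None = None
    comparisons: tuple[tuple[str, str], ...] = (("Gb1-like", "Gg13-like"),)
    ks_mode: str = "pointwise_values"
    qpcr_design: CtDesign | None = field(default_factory=CtDesign)
    qpcr_mode: str = "delta_ct"
    qpcr_anova: bool = True

    def resolved_probes(self) -> tuple[str, ...]:
        return self.probes or tuple(self.epithelium.probe_profiles)


# ---------------------------------------------------------------------------
# Config parsing / validation


def _build_epithelium(block: Mapping[str, Any]) -> EpitheliumModel:
    block = dict(block)
    preset = block.pop("preset", None)
    if preset == "olfactory_cohort":
        return olfactory_cohort_model(**block)
    if preset == "null_calibration":
        return null_calibration_model(**block)
    if preset is not None:
        raise ValueError(f"unknown epithelium preset {preset!r}")
    if "probe_profiles" in block:
        block["probe_profiles"] = {k: tuple(v) for k, v in block["probe_profiles"].items()}
    for key in ("layer_boundaries", "layer_names"):
        if key in block:
            block[key] = tuple(block[key])
    return EpitheliumModel(**block)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON) pipeline config; paths resolve against the file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    cfg = parse_config(raw)
    out = Path(cfg.outdir)
    if not out.is_absolute():
        cfg.outdir = str(path.parent / out)
    return cfg


def parse_config(raw: Mapping[str, Any]) -> PipelineConfig:
    kw: dict[str, Any] = {}
    kw["seed"] = int(raw.get("seed", 0))
    kw["stages"] = tuple(raw.get("stages", ALL_STAGES))
    if "outdir" in raw:
        kw["outdir"] = str(raw["outdir"])
    if "epithelium" in raw:
        kw["epithelium"] = _build_epithelium(raw["epithelium"])
    if "cohort" in raw:
        kw["cohort"] = CohortDesign(**raw["cohort"])
    if "probes" in raw:
        kw["probes"] = tuple(raw["probes"])
    scan_block = raw.get("scan", {})
    kw["scan_length_um"] = scan_block.get("length_um", "auto")
    kw["scan_step_px"] = float(scan_block.get("step_px", 1.0))
    if "averaging" in raw:
        kw["averaging"] = AveragingConfig(**raw["averaging"])
    if "window" in raw:
        block = dict(raw["window"])
        marker = block.pop("from_marker", None)
        if marker is not None:
            kw["window_from_marker"] = marker
        if block:
            kw["window"] = MarkerWindow(**block)
    if "comparisons" in raw:
        kw["comparisons"] = tuple(tuple(pair) for pair in raw["comparisons"])
    if "ks_mode" in raw:
        kw["ks_mode"] = raw["ks_mode"]
    if "qpcr" in raw:
        q = dict(raw["qpcr"])
        kw["qpcr_mode"] = q.pop("mode", "delta_ct")
        kw["qpcr_anova"] = bool(q.pop("anova", True))
        design = dict(q.pop("design", {}))
        for key in ("genes",):
            if key in design:
                design[key] = tuple(design[key])
        if "reference_gene" in q:
            design.setdefault("reference_gene", q.pop("reference_gene"))
        kw["qpcr_design"] = CtDesign(**design)
    return PipelineConfig(**kw)


@dataclass(frozen=True)
class Finding:
    key: str
    severity: str
    message: str


def validate_config(raw: Mapping[str, Any]) -> list[Finding]:
    """Structural validation of a raw config mapping; empty list means valid."""
    findings: list[Finding] = []
    stages = raw.get("stages", ALL_STAGES)
    for s in stages:
        if s not in ALL_STAGES:
            findings.append(Finding("stages", "error", f"unknown stage {s!r}"))
    stochastic = {"simulate", "qpcr"} & set(stages)
    if stochastic and "seed" not in raw:
        findings.append(Finding("seed", "warning",
                                f"stochastic stages {sorted(stochastic)} run without an explicit seed"))
    if "window" in raw:
        w = raw["window"]
        x1, x2 = w.get("x1"), w.get("x2")
        if x1 is not None and x2 is not None and not x1 < x2:
            findings.append(Finding("window", "error", f"x1 < x2 violated: ({x1}, {x2})"))
    if "qpcr" in raw and "reference_gene" in raw["qpcr"]:
        ref = raw["qpcr"]["reference_gene"]
        genes = raw["qpcr"].get("design", {}).get("genes", CtDesign().genes)
        if ref not in genes:
            findings.append(Finding("qpcr.reference_gene", "error",
                                    f"reference gene {ref!r} missing from gene list"))
    try:
        cfg = parse_config(raw)
    except (TypeError, ValueError, KeyError) as exc:
        findings.append(Finding("config", "error", str(exc)))
        return findings
    probes = cfg.resolved_probes()
    for pair in cfg.comparisons:
        for p in pair:
            if p not in probes:
                findings.append(Finding("comparisons", "error", f"unknown probe {p!r}"))
    if cfg.window_from_marker is not None and cfg.window_from_marker not in probes:
        findings.append(Finding("window.from_marker", "error",
                                f"unknown marker probe {cfg.window_from_marker!r}"))
    if "qpcr" in (raw.get("stages") or ALL_STAGES):
        if cfg.qpcr_design is None:
            findings.append(Finding("qpcr", "error", "qpcr stage requested without a design"))
        elif "qpcr" in raw and "reference_gene" in raw["qpcr"]:
            if raw["qpcr"]["reference_gene"] not in cfg.qpcr_design.genes:
                findings.append(Finding("qpcr.reference_gene", "error",
                                        "reference gene missing from gene list"))
    return findings


# ---------------------------------------------------------------------------
# In-memory cohort simulation (the workhorse for simulation studies)


def simulate_cohort_curves(
    model: EpitheliumModel,
    probes: Sequence[str],
    cohort: CohortDesign,
    seed: int,
    averaging: AveragingConfig = AveragingConfig(),
    scan_length_um: float | str = "auto",
    scan_step_px: float = 1.0,
    stream: str = "cohort",
):
    """Simulate images, scan and hierarchically average, without touching disk.

    Returns ``(curves, truths)``: group-level curve and ground truth per
    probe.  Scan anchors sit at evenly spaced interior fractions of the
    lamina trace so every scan stays clear of the image borders.
    """
    curves: dict[str, Any] = {}
    truths: dict[str, Any] = {}
    fractions = np.linspace(0.35, 0.65, cohort.scans_per_image)
    for probe in probes:
        by_animal: dict[str, list] = {}
        for a in range(cohort.n_animals):
            animal = f"m{a + 1}"
            scans = []
            for i in range(cohort.images_per_animal):
                img_seed = derive_seed(seed, stream, probe, a, i)
                img, truth = generate_epithelium_image(model, probe, seed=img_seed)
                truths[probe] = truth
                trace = truth.lamina_trace
                for s, frac in enumerate(fractions):
                    # stagger anchors between the two images of an animal
                    shift = 0.12 * ((i % 2) - 0.5)
                    idx = int(round((frac + shift) * (len(trace) - 1)))
                    length = (
                        length_to_apical_edge(trace, idx, model.pixel_size_um)
                        if scan_length_um == "auto"
                        else float(scan_length_um)
                    )
                    line = make_scan_line(
                        trace, idx, length, model.pixel_size_um,
                        step_um=scan_step_px * model.pixel_size_um,
                    )
                    meta = ScanMeta(animal, f"img{i + 1}", f"scan{s + 1}", probe)
                    scans.append(extract_scan(img, line, meta))
            by_animal[animal] = [normalize_profile(p) for p in scans]
        curves[probe] = hierarchical_average(by_animal, averaging)
    return curves, truths


# ---------------------------------------------------------------------------
# File-based pipeline


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages in dependency order; return the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "cohort": asdict(config.cohort),
            "averaging": asdict(config.averaging),
            "window": {"x1": config.window.x1, "x2": config.window.x2},
            "ks_mode": config.ks_mode,
            "scan_length_um": config.scan_length_um,
            "scan_step_px": config.scan_step_px,
        },
        "outputs": {},
        "summary": {},
    }
    probes = config.resolved_probes()
    if "simulate" in config.stages:
        _stage_simulate(config, out, probes, report)
    if "scan" in config.stages:
        _stage_scan(config, out, probes, report)
    if "average" in config.stages:
        _stage_average(config, out, report)
    if "window_stats" in config.stages:
        _stage_window_stats(config, out, report)
    if "qpcr" in config.stages:
        _stage_qpcr(config, out, report)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    report["outputs"]["report"] = str(report_path)
    log.info("pipeline complete: %s", report_path)
    return report


def _image_paths(out: Path, probe: str, animal: int, image: int) -> tuple[Path, Path]:
    stem = f"{probe}_a{animal + 1}_i{image + 1}"
    return out / "images" / f"{stem}.tif", out / "images" / f"{stem}_trace.csv"


def _stage_simulate(config: PipelineConfig, out: Path, probes, report) -> None:
    log.info("[stage:simulate] %d probes, %s", len(probes), config.cohort)
    (out / "images").mkdir(exist_ok=True)
    model = config.epithelium
    for probe in probes:
        for a in range(config.cohort.n_animals):
            for i in range(config.cohort.images_per_animal):
                img_seed = derive_seed(config.seed, "cohort", probe, a, i)
                img, truth = generate_epithelium_image(model, probe, seed=img_seed)
                tif, trace_csv = _image_paths(out, probe, a, i)
                write_image(to_brightfield(img), tif, dtype="uint16")
                truth.lamina_trace.to_csv(trace_csv)
        write_ground_truth(
            truth, out / "images" / f"{probe}_trace_truth.csv",
            out / "images" / f"{probe}_expected_profile.csv",
        )
    report["outputs"]["images"] = str(out / "images")
    report["parameters"]["epithelium"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(model).items()
        if k != "probe_profiles"
    }
    report["parameters"]["epithelium"]["probe_profiles"] = {
        k: list(v) for k, v in model.probe_profiles.items()
    }


def _stage_scan(config: PipelineConfig, out: Path, probes, report) -> None:
    log.info("[stage:scan]")
    model = config.epithelium
    fractions = np.linspace(0.35, 0.65, config.cohort.scans_per_image)
    profiles = []
    for probe in probes:
        for a in range(config.cohort.n_animals):
            for i in range(config.cohort.images_per_animal):
                tif, trace_csv = _image_paths(out, probe, a, i)
                if not tif.exists():
                    raise FileNotFoundError(f"missing upstream artifact {tif}")
                img = invert_image(read_image(tif, model.pixel_size_um))
                trace = LaminaTrace.from_csv(trace_csv)
                for s, frac in enumerate(fractions):
                    shift = 0.12 * ((i % 2) - 0.5)
                    idx = int(round((frac + shift) * (len(trace) - 1)))
                    length = (
                        length_to_apical_edge(trace, idx, model.pixel_size_um)
                        if config.scan_length_um == "auto"
                        else float(config.scan_length_um)
                    )
                    line = make_scan_line(trace, idx, length, model.pixel_size_um,
                                          step_um=config.scan_step_px * model.pixel_size_um)
                    meta = ScanMeta(f"m{a + 1}", f"img{i + 1}", f"scan{s + 1}", probe)
                    profiles.append(extract_scan(img, line, meta))
    path = out / "profiles.csv"
    profiles_to_frame(profiles).to_csv(path, index=False)
    report["outputs"]["profiles"] = str(path)


def _stage_average(config: PipelineConfig, out: Path, report) -> None:
    log.info("[stage:average]")
    src = out / "profiles.csv"
    if not src.exists():
        raise FileNotFoundError(f"missing upstream artifact {src}")
    df = pd.read_csv(src)
    curves = []
    for probe, g in df.groupby("probe", sort=False):
        by_animal: dict[str, list] = {}
        for p in frame_to_profiles(g):
            try:
                by_animal.setdefault(p.meta.animal_id, []).append(normalize_profile(p))
            except ZeroProfileError as exc:
                log.warning("%s", exc)
        curves.append(hierarchical_average(by_animal, config.averaging))
    path = out / "averaged.csv"
    save_curves(curves, path)
    report["outputs"]["averaged"] = str(path)


def _stage_window_stats(config: PipelineConfig, out: Path, report) -> None:
    log.info("[stage:window_stats]")
    src = out / "averaged.csv"
    if not src.exists():
        raise FileNotFoundError(f"missing upstream artifact {src}")
    from .profiles import load_curves

    curves = load_curves(src)
    window = config.window
    if config.window_from_marker is not None:
        window = derive_window(curves[config.window_from_marker])
    integrals, ratios = compare_windowed_integrals(curves, window)
    ks_results = []
    for a, b in config.comparisons:
        res = ks_compare(curves[a], curves[b], window, mode=config.ks_mode)
        ks_results.append(
            {
                "probe_a": a, "probe_b": b, "D": res.D, "p_value": res.p_value,
                "n1": res.n1, "n2": res.n2, "mode": res.mode,
                "sample_unit": res.sample_unit, "p_is_placeholder": res.p_is_placeholder,
            }
        )
    stats_obj = {
        "window": {"x1": window.x1, "x2": window.x2, "source": window.source,
                   "marker_probe": window.marker_probe},
        "integrals": dict(zip(integrals["probe"], integrals["integral"])),
        "ratios": ratios.to_dict(orient="records"),
        "ks": ks_results,
    }
    path = out / "stats.json"
    path.write_text(json.dumps(stats_obj, indent=2, sort_keys=True))
    report["outputs"]["stats"] = str(path)
    report["summary"]["window_stats"] = stats_obj


def _stage_qpcr(config: PipelineConfig, out: Path, report) -> None:
    log.info("[stage:qpcr]")
    design = config.qpcr_design
    if design is None:
        raise ValueError("qpcr stage requested without a qpcr design")
    table = generate_ct_table(design, seed=derive_seed(config.seed, "qpcr"))
    ct_path = out / "ct.csv"
    table.to_csv(ct_path)
    rel = relative_expression(table, mode=config.qpcr_mode)
    rel_path = out / "rel_expr.csv"
    rel.to_csv(rel_path, index=False)
    summary: dict[str, Any] = {
        "mode": config.qpcr_mode,
        "reference_gene": design.reference_gene,
        "folds": {
            f"{r.gene}/{r.group}": {"fold": r.fold, "sem": r.sem_fold, "n": int(r.n)}
            for r in rel.itertuples()
        },
    }
    if config.qpcr_anova:
        res = anova_by_gene(table)
        anova_obj = {
            "F": res.F, "df_between": res.df_between, "df_within": res.df_within,
            "p_value": res.p_value, "degenerate": res.degenerate,
            "tukey": res.tukey.to_dict(orient="records"),
        }
        (out / "anova.json").write_text(json.dumps(anova_obj, indent=2, sort_keys=True))
        summary["anova"] = anova_obj
        report["outputs"]["anova"] = str(out / "anova.json")
    report["outputs"]["ct"] = str(ct_path)
    report["outputs"]["rel_expr"] = str(rel_path)
    report["summary"]["qpcr"] = summary


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
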