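"""End-to-end orchestration: screen -> tree check -> island scan -> pI.

A run is configured by a YAML file (or an in-memory :class:`RunConfig`)
naming the inputs and parameters; stages run in a fixed order, each
writing its outputs before the next begins, and a JSON report cross-links
screening candidates to tree verdicts and planted genes to island
containment.  Stages whose inputs are not configured are skipped, not
failed; a stage that raises is recorded as failed and the remaining stages
still run, so partial outputs are always retained.

All stage outputs are pure functions of (inputs, parameters, seed); the
report echoes the effective parameters and the SHA-256 of every input file
so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import hit_screen, island_scan, tree_hgt
from .domain_pi import PKA_SETS, domain_pi_table
from .taxonomy import Domain, load_lineages

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; the message lists every problem found."""


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration with defaults filled in."""

    # inputs (hit table + lineages are required; the rest enable stages)
    hit_table: Optional[Path] = None
    lineages: Optional[Path] = None
    trees_dir: Optional[Path] = None
    leaf_domains: Optional[Path] = None
    genome: Optional[Path] = None
    genes: Optional[Path] = None
    proteins: Optional[Path] = None
    domains: Optional[Path] = None
    out_dir: Path = Path("hgtscreen_out")
    # screening
    focal: str = "Bacteria"
    tau: float = 0.80
    min_hits: int = 5
    max_hits: Optional[int] = 250
    unknown_policy: str = "exclude"
    self_taxa: tuple = ()
    taxid_col: int = 12
    # tree test
    s_min: float = 0.8
    p_min: float = 1.0
    m_min: int = 2
    # island scan
    k: int = 4
    w: int = 5000
    step: int = 2500
    z_min: float = 4.0
    merge_gap: int = 1
    # pI
    pka_set: str = "bjellqvist"
    include_termini: bool = True
    seed: int = 0

    def parameters(self) -> dict:
        d = dataclasses.asdict(self)
        return {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in d.items()
        }


_PATH_KEYS = (
    "hit_table",
    "lineages",
    "trees_dir",
    "leaf_domains",
    "genome",
    "genes",
    "proteins",
    "domains",
)


def validate_config(source: Union[str, Path, dict]) -> RunConfig:
    """Load and validate a YAML config (or dict), filling defaults.

    Every problem — unknown keys, out-of-range parameters, missing input
    paths — is collected and reported in a single error.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of keys to values")

    known = {f.name for f in dataclasses.fields(RunConfig)}
    problems = [f"unknown config key {k!r}" for k in raw if k not in known]
    kwargs = {k: v for k, v in raw.items() if k in known}
    for key in _PATH_KEYS + ("out_dir",):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = Path(kwargs[key])
    if "self_taxa" in kwargs and kwargs["self_taxa"] is not None:
        kwargs["self_taxa"] = tuple(str(t) for t in kwargs["self_taxa"])

    cfg = RunConfig(**kwargs)

    if not (0.0 < cfg.tau <= 1.0):
        problems.append(f"tau must be in (0, 1], got {cfg.tau}")
    for name in ("s_min", "p_min"):
        v = getattr(cfg, name)
        if not (0.0 <= v <= 1.0):
            problems.append(f"{name} must be in [0, 1], got {v}")
    if cfg.min_hits < 1:
        problems.append(f"min_hits must be >= 1, got {cfg.min_hits}")
    if cfg.k < 1 or cfg.w < cfg.k or cfg.step < 1:
        problems.append(
            f"island-scan geometry invalid: k={cfg.k}, w={cfg.w}, step={cfg.step}"
        )
    if cfg.pka_set not in PKA_SETS:
        problems.append(
            f"unknown pka_set {cfg.pka_set!r}; available: {sorted(PKA_SETS)}"
        )
    if cfg.unknown_policy not in ("exclude", "count_as_alien", "count_as_focal"):
        problems.append(f"unknown unknown_policy {cfg.unknown_policy!r}")
    if cfg.hit_table is None or cfg.lineages is None:
        problems.append("hit_table and lineages are required inputs")

    missing = [
        f"{key}: {getattr(cfg, key)}"
        for key in _PATH_KEYS
        if getattr(cfg, key) is not None and not Path(getattr(cfg, key)).exists()
    ]
    if missing:
        problems.append("missing input path(s): " + "; ".join(missing))
    if problems:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))
    logger.info("effective configuration: %s", cfg.parameters())
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Union[RunConfig, str, Path, dict]) -> dict:
    """Run every configured stage; returns the report (also written to disk).

    The report maps stage name -> {status, outputs, summary}; ``status`` is
    ``ok``, ``skipped`` or ``failed`` and the top-level ``success`` flag is
    False when any stage failed (callers should exit non-zero on it).
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "parameters": cfg.parameters(),
        "input_checksums": {
            key: _sha256(Path(getattr(cfg, key)))
            for key in _PATH_KEYS
            if getattr(cfg, key) is not None and Path(getattr(cfg, key)).is_file()
        },
        "stages": {},
        "success": True,
    }
    candidates: list[str] = []

    # --- stage 1: alien-fraction screen -----------------------------------
    stage: dict = {"status": "skipped", "outputs": [], "summary": {}}
    report["stages"]["screen"] = stage
    if cfg.hit_table and cfg.lineages:
        try:
            lineages = load_lineages(cfg.lineages, format="flat_tsv")
            table = hit_screen.read_hit_table(cfg.hit_table, taxid_col=cfg.taxid_col)
            results = hit_screen.screen_proteome(
                table,
                lineages,
                Domain(cfg.focal),
                cfg.tau,
                cfg.min_hits,
                cfg.self_taxa,
                cfg.max_hits,
                cfg.unknown_policy,
            )
            tsv = hit_screen.write_screen_tsv(results, out / "screen.tsv")
            js = hit_screen.write_screen_json(results, out / "screen.json")
            candidates = [r.query_id for r in results if r.candidate]
            stage.update(
                status="ok",
                outputs=[str(tsv), str(js)],
                summary={
                    "n_queries": len(results),
                    "n_candidates": len(candidates),
                    "candidates": candidates[:50],
                },
            )
        except Exception as exc:
            logger.exception("screen stage failed")
            stage.update(status="failed", summary={"error": str(exc)})
            report["success"] = False

    # --- stage 2: tree topology check --------------------------------------
    stage = {"status": "skipped", "outputs": [], "summary": {}}
    report["stages"]["tree_check"] = stage
    if cfg.trees_dir:
        try:
            label_map = (
                tree_hgt.read_label_map(cfg.leaf_domains) if cfg.leaf_domains else {}
            )
            calls = tree_hgt.batch_tree_screen(
                cfg.trees_dir,
                label_map,
                focal=Domain(cfg.focal),
                s_min=cfg.s_min,
                p_min=cfg.p_min,
                m_min=cfg.m_min,
            )
            tsv = out / "tree_calls.tsv"
            calls.to_csv(tsv, sep="\t", index=False)
            stage.update(
                status="ok",
                outputs=[str(tsv)],
                summary={
                    "n_trees": int(len(calls)),
                    "verdicts": calls["verdict"].value_counts().to_dict(),
                },
            )
        except Exception as exc:
            logger.exception("tree stage failed")
            stage.update(status="failed", summary={"error": str(exc)})
            report["success"] = False

    # --- stage 3: island scan ----------------------------------------------
    stage = {"status": "skipped", "outputs": [], "summary": {}}
    report["stages"]["island_scan"] = stage
    if cfg.genome:
        try:
            tracks = island_scan.scan_composition(cfg.genome, cfg.k, cfg.w, cfg.step)
            regions = []
            for track in tracks:
                regions.extend(
                    island_scan.call_alien_regions(track, cfg.z_min, cfg.merge_gap)
                )
            gff = island_scan.write_regions_gff3(regions, out / "islands.gff3")
            outputs = [str(gff)]
            overlap_summary = []
            if cfg.genes:
                genes = island_scan.read_gene_intervals(cfg.genes)
                reports = []
                for gene in genes:
                    same = [r for r in regions if r.contig_id == gene.contig_id]
                    rep = island_scan.gene_island_overlap(gene, same)
                    reports.append(rep)
                    overlap_summary.append(
                        {
                            "gene": gene.label or f"{gene.start}-{gene.end}",
                            "relation": rep.relation,
                            "nearest_distance_bp": rep.nearest_distance_bp,
                        }
                    )
                tsv = island_scan.write_regions_tsv(reports, out / "gene_islands.tsv")
                outputs.append(str(tsv))
            stage.update(
                status="ok",
                outputs=outputs,
                summary={
                    "n_regions": len(regions),
                    "gene_overlaps": overlap_summary,
                },
            )
        except Exception as exc:
            logger.exception("island stage failed")
            stage.update(status="failed", summary={"error": str(exc)})
            report["success"] = False

    # --- stage 4: domain pI -------------------------------------------------
    stage = {"status": "skipped", "outputs": [], "summary": {}}
    report["stages"]["domain_pi"] = stage
    if cfg.proteins and cfg.domains:
        try:
            tab = domain_pi_table(
                cfg.proteins, cfg.domains, cfg.pka_set, cfg.include_termini
            )
            tsv = out / "domain_pi.tsv"
            tab.to_csv(tsv, sep="\t", index=False)
            stage.update(
                status="ok",
                outputs=[str(tsv)],
                summary={
                    "n_segments": int(len(tab)),
                    "pI_min": float(tab["pI"].min()),
                    "pI_max": float(tab["pI"].max()),
                },
            )
        except Exception as exc:
            logger.exception("pI stage failed")
            stage.update(status="failed", summary={"error": str(exc)})
            report["success"] = False

    # --- cross-links --------------------------------------------------------
    tree_verdicts = {}
    tcalls = report["stages"]["tree_check"]
    if tcalls["status"] == "ok":
        import pandas as pd

        calls = pd.read_csv(tcalls["outputs"][0], sep="\t")
        for _, row in calls.iterrows():
            q = str(row["query"])
            base = q.split("_t")[0]  # tree leaves may suffix the query id
            tree_verdicts.setdefault(base, str(row["verdict"]))
    report["candidate_crosslinks"] = [
        {"query_id": q, "tree_verdict": tree_verdicts.get(q, "no_tree")}
        for q in candidates
    ]

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1) + "\n", encoding="utf-8")
    _write_summary(report, out / "summary.txt")
    report["report_path"] = str(report_path)
    return report


def _write_summary(report: dict, path: Path) -> None:
    lines = ["hgtscreen pipeline summary", "=" * 26]
    for name, stage in report["stages"].items():
        lines.append(f"{name}: {stage['status']}")
        for k, v in stage.get("summary", {}).items():
            lines.append(f"  {k}: {v}")
    lines.append(f"success: {report['success']}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
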