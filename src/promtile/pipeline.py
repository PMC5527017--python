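"""End-to-end orchestration: design -> simulate -> normalize -> call -> compare -> scan.

A single configuration mapping (usually loaded from YAML) drives all
stages; every run writes its outputs plus a JSON provenance report with the
fully resolved parameters, seeds, output checksums and package version.
When real scan files are supplied the simulation stage is skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as pio
from .compare import GeneSet, compare_conditions
from .design import design_probes
from .enrich import ThresholdSpec, call_bound_genes
from .normalize import normalize_condition
from .simulate import SimulationConfig, make_genome, simulate_arrays
from .trescan import ArrangementSpec, HalfSiteMotif, scan_gene_set

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "outdir": "promtile_run",
    # optional real inputs; when absent the simulation stage supplies them
    "genome_fasta": None,
    "genes_bed": None,
    "probes_tsv": None,
    "scans": None,  # {"control": [tsv, ...], "t3": [tsv, ...]}
    "seed": 0,
    "simulation": {},  # overrides for SimulationConfig fields
    "design": {"upstream": 5500, "downstream": 2500, "probe_len": 60, "spacing": 205},
    "normalization": {"floor_value": 1.0, "loess_span": 0.3},
    "calling": {
        "window_bp": 1400,
        "sd_multiplier": 2.5,
        "min_run": 3,
        "merge_gap": 0,
        "center_statistic": "median",
    },
    "scanner": {
        "arrangement": "DR",
        "spacer_min": 4,
        "spacer_max": 4,
        "max_mm_per_half": 3,
        "max_mm_total": 4,
        "both_strands": True,
    },
}

_RANGES = {
    "design.upstream": (0, 100_000),
    "design.downstream": (0, 100_000),
    "design.probe_len": (1, 1000),
    "design.spacing": (1, 10_000),
    "normalization.floor_value": (0.0, None),
    "normalization.loess_span": (0.0, 1.0),
    "calling.window_bp": (1, None),
    "calling.sd_multiplier": (0.0, None),
    "calling.min_run": (1, None),
    "calling.merge_gap": (0, None),
    "scanner.spacer_min": (0, 10),
    "scanner.spacer_max": (0, 10),
    "scanner.max_mm_per_half": (0, 6),
    "scanner.max_mm_total": (0, 12),
}


def merge_config(overrides: dict | None = None) -> dict:
    """Overlay user overrides on the defaults (one level of nesting)."""
    config = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def validate_config(config: dict) -> list[str]:
    """Check every parameter against its documented range.

    Returns a list of human-readable violations (empty = valid); each names
    the offending field and the allowed range.
    """
    violations = []
    for dotted, (lo, hi) in _RANGES.items():
        section, name = dotted.split(".")
        value = config.get(section, {}).get(name)
        if value is None:
            continue
        if lo is not None and value < lo:
            violations.append(f"{dotted} = {value} violates {dotted} >= {lo}")
        if hi is not None and value > hi:
            violations.append(f"{dotted} = {value} violates {dotted} <= {hi}")
    cal = config.get("calling", {})
    if cal.get("sd_multiplier") is not None and cal["sd_multiplier"] <= 0:
        violations.append(f"calling.sd_multiplier = {cal['sd_multiplier']} violates sd_multiplier > 0")
    sc = config.get("scanner", {})
    if sc.get("spacer_min") is not None and sc.get("spacer_max") is not None:
        if sc["spacer_min"] > sc["spacer_max"]:
            violations.append("scanner.spacer_min must be <= scanner.spacer_max")
    if sc.get("arrangement") not in (None, "DR", "IR", "ER"):
        violations.append(f"scanner.arrangement = {sc['arrangement']!r} not in {{DR, IR, ER}}")
    for path_key in ("genome_fasta", "genes_bed", "probes_tsv"):
        path = config.get(path_key)
        if path is not None and not Path(path).exists():
            violations.append(f"{path_key} = {path} does not exist")
    if config.get("scans"):
        for cond, paths in config["scans"].items():
            for p in paths:
                if not Path(p).exists():
                    violations.append(f"scans.{cond}: {p} does not exist")
    return violations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def window_sequences(genome: dict[str, str], genes, upstream: int, downstream: int) -> dict[str, str]:
    """Plus-strand design-window sequence per gene (scanner covers both strands)."""
    from .design import design_window

    out = {}
    for g in genes:
        win = design_window(g, upstream, downstream, chrom_length=len(genome[g.chrom]))
        out[g.gene_id] = genome[g.chrom][win.start : win.end]
    return out


def run_all(config: dict | None = None) -> dict:
    """Run every stage in order and write outputs plus a provenance report.

    Raises ``ValueError`` before any stage runs if the configuration is
    invalid; a stage failure propagates with the stage named, leaving the
    outputs of completed stages in place. Reruns with the same configuration
    are bitwise-reproducible.
    """
    config = merge_config(config)
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration:\n" + "\n".join(violations))

    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": _jsonable(config), "stages": {}}
    stage = "inputs"
    try:
        sim_cfg = SimulationConfig(
            genome_seed=config["seed"],
            upstream=config["design"]["upstream"],
            downstream=config["design"]["downstream"],
            **config["simulation"],
        )
        if config["genome_fasta"] and config["genes_bed"]:
            genome = pio.read_fasta(config["genome_fasta"])
            genes = pio.read_gene_bed(config["genes_bed"])
            truth = None
        else:
            genome, genes, truth = make_genome(sim_cfg)
            pio.write_fasta(genome, outdir / "genome.fa")
            pio.write_gene_bed(genes, outdir / "genes.bed")
            pio.write_tsv(truth, outdir / "truth.tsv")
        report["stages"][stage] = {"n_genes": len(genes), "simulated": truth is not None}

        stage = "design"
        if config["probes_tsv"]:
            probes = pio.read_tsv(config["probes_tsv"])
        else:
            d = config["design"]
            probes = design_probes(
                genes, genome, d["upstream"], d["downstream"], d["probe_len"], d["spacing"]
            )
            pio.write_tsv(probes, outdir / "probes.tsv")
        logger.info("designed/loaded %d probes for %d genes", len(probes), len(genes))
        report["stages"][stage] = {"n_probes": len(probes)}

        stage = "simulate"
        if config["scans"]:
            scans = {
                cond: [pio.read_tsv(p) for p in paths]
                for cond, paths in config["scans"].items()
            }
            report["stages"][stage] = {"skipped": True}
        else:
            scans = {}
            for ci, cond in enumerate(("control", "t3")):
                scans[cond] = []
                for r in range(sim_cfg.n_replicates):
                    seed = (config["seed"] * 1000 + ci * 100 + r + 1) % (2**31)
                    scan = simulate_arrays(probes, truth, sim_cfg, cond, seed)
                    pio.write_tsv(scan, outdir / f"scan_{cond}_rep{r + 1}.tsv")
                    scans[cond].append(scan)
            report["stages"][stage] = {
                cond: len(reps) for cond, reps in scans.items()
            }

        stage = "normalize"
        norm = config["normalization"]
        normalized = {}
        for cond, reps in scans.items():
            averaged = normalize_condition(
                reps, floor_value=norm["floor_value"], span=norm["loess_span"]
            )
            pio.write_tsv(averaged, outdir / f"normalized_{cond}.tsv")
            normalized[cond] = averaged
        report["stages"][stage] = {cond: len(df) for cond, df in normalized.items()}

        stage = "callpeaks"
        cal = config["calling"]
        spec = ThresholdSpec(
            sd_multiplier=cal["sd_multiplier"],
            min_run=cal["min_run"],
            center_statistic=cal["center_statistic"],
        )
        calls = {}
        for cond, table in normalized.items():
            result = call_bound_genes(
                table, window_bp=cal["window_bp"], spec=spec, merge_gap=cal["merge_gap"]
            )
            pio.write_regions_bed(result["regions"], outdir / f"regions_{cond}.bed")
            pio.write_gene_set(result["bound_genes"], outdir / f"bound_genes_{cond}.tsv")
            calls[cond] = result
            logger.info(
                "%s: threshold %.4f, %d regions, %d bound genes",
                cond, result["threshold"], len(result["regions"]), len(result["bound_genes"]),
            )
        report["stages"][stage] = {
            cond: {
                "threshold": calls[cond]["threshold"],
                "n_regions": int(len(calls[cond]["regions"])),
                "n_bound_genes": len(calls[cond]["bound_genes"]),
            }
            for cond in calls
        }

        stage = "compare"
        conditions = list(calls)
        overlap = compare_conditions(
            GeneSet(conditions[0], frozenset(calls[conditions[0]]["bound_genes"])),
            GeneSet(conditions[1], frozenset(calls[conditions[1]]["bound_genes"])),
        )
        candidates = set(overlap.union_members)
        pio.write_gene_set(candidates, outdir / "candidate_targets.tsv")
        report["stages"][stage] = overlap.to_dict()

        stage = "scan-tre"
        sc = config["scanner"]
        windows = window_sequences(
            genome,
            [g for g in genes if g.gene_id in candidates],
            config["design"]["upstream"],
            config["design"]["downstream"],
        )
        if windows:
            per_gene, hits, summary = scan_gene_set(
                windows,
                HalfSiteMotif(),
                ArrangementSpec(sc["arrangement"], sc["spacer_min"], sc["spacer_max"]),
                sc["max_mm_per_half"],
                sc["max_mm_total"],
                sc["both_strands"],
            )
            pio.write_tsv(per_gene, outdir / "tre_per_gene.tsv")
            pio.write_tsv(hits, outdir / "tre_hits.tsv")
        else:
            summary = {"n_genes": 0, "n_with_hit": 0, "frac_with_hit": 0.0, "pct_with_hit": 0}
        report["stages"][stage] = summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["checksums"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.name != "report.json"
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
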