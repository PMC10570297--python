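"""End-to-end orchestration: simulate/ingest -> filter -> merge -> genotype
-> Vst scan -> annotate, with a run manifest and report tables.

A run is driven by one :class:`PipelineConfig` (usually loaded from YAML)
holding either a simulation block or paths to real inputs, plus the stage
options. Identical config + seed gives byte-identical analysis outputs;
the manifest records config, version, input checksums and per-stage counts
so the conservation invariants (filtered <= parsed, every filtered call in
exactly one CNVR, matrix dims = CNVRs x samples) are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from ._util import fmt_pct
from .annotate import DEFAULT_FLANK_BP, annotation_table, read_gff3, region_distribution
from .callset import (
    CNVCall,
    FilterSpec,
    filter_calls,
    read_calls,
    read_group_map,
    summarize_groups,
    write_calls,
)
from .cnvr import (
    CNVR,
    SIZE_BIN_LABELS,
    coverage_percent,
    merge_calls,
    merge_per_group,
    presence_and_specific,
    size_distribution,
    write_bed,
)
from .genotype_vst import build_cn_matrix, classify_cn, select_top, vst_scan, vst_table
from .simulate import (
    SimulationConfig,
    config_from_dict,
    emit_callset,
    emit_depth,
    emit_genes,
    generate_truth,
)

logger = logging.getLogger("cnvrpop")

MANIFEST_NAME = "manifest.json"


@dataclass
class Contrast:
    """A named two-sided group contrast for the Vst scan."""

    name: str
    side_a: tuple[str, ...]
    side_b: tuple[str, ...]


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of simulation/real inputs."""

    outdir: Path
    simulation: SimulationConfig | None = None
    call_files: dict[str, Path] | None = None  # sample -> path
    group_map_path: Path | None = None
    gff3_path: Path | None = None
    chrom_lengths: dict[str, int] | None = None
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    min_overlap_frac: float = 0.0
    per_group_merge: bool = False
    contrasts: tuple[Contrast, ...] = ()
    top_fraction: float = 0.01
    flank_bp: int = DEFAULT_FLANK_BP
    emit_depth_tracks: bool = False
    seed: int = 0
    overwrite: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        has_sim = self.simulation is not None
        has_real = self.call_files is not None
        if has_sim == has_real:
            raise ValueError(
                "exactly one of a simulation block or real input paths required"
            )
        if has_real:
            missing = [
                str(p)
                for p in [*self.call_files.values(), self.group_map_path]
                if p is None or not Path(p).exists()
            ]
            if missing:
                raise FileNotFoundError(f"missing inputs: {missing}")


def config_from_yaml(path: str | Path, outdir: str | Path | None = None) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text())
    sim = None
    call_files = None
    if "simulation" in doc:
        sim_doc = dict(doc["simulation"])
        sim_doc.setdefault("seed", doc.get("seed", 0))
        sim = config_from_dict(sim_doc)
    if "call_files" in doc:
        call_files = {s: Path(p) for s, p in doc["call_files"].items()}
    fdoc = doc.get("filter", {})
    contrasts = tuple(
        Contrast(name=c["name"], side_a=tuple(c["side_a"]), side_b=tuple(c["side_b"]))
        for c in doc.get("contrasts", [])
    )
    return PipelineConfig(
        outdir=Path(outdir or doc.get("outdir", "cnvrpop_run")),
        simulation=sim,
        call_files=call_files,
        group_map_path=Path(doc["group_map"]) if "group_map" in doc else None,
        gff3_path=Path(doc["gff3"]) if "gff3" in doc else None,
        chrom_lengths={c: int(n) for c, n in doc["chrom_lengths"].items()}
        if "chrom_lengths" in doc
        else None,
        filter_spec=FilterSpec(
            max_p=float(fdoc.get("max_p", 0.01)),
            min_size=int(fdoc.get("min_size", 1000)),
            max_q0=float(fdoc.get("max_q0", 0.5)),
        ),
        min_overlap_frac=float(doc.get("min_overlap_frac", 0.0)),
        per_group_merge=bool(doc.get("per_group_merge", False)),
        contrasts=contrasts,
        top_fraction=float(doc.get("top_fraction", 0.01)),
        flank_bp=int(doc.get("flank_bp", DEFAULT_FLANK_BP)),
        emit_depth_tracks=bool(doc.get("emit_depth_tracks", False)),
        seed=int(doc.get("seed", 0)),
        overwrite=bool(doc.get("overwrite", False)),
    )


def _md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; returns the artifact paths.

    Refuses to run into a directory already holding a manifest unless
    ``overwrite`` is set.
    """
    outdir = config.outdir
    manifest_path = outdir / MANIFEST_NAME
    if manifest_path.exists() and not config.overwrite:
        raise FileExistsError(
            f"{outdir} already holds a pipeline run ({MANIFEST_NAME}); "
            "pass overwrite to replace it"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "inputs": {},
    }
    artifacts: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            try:
                t0 = time.time()
                counts = fn()
                manifest["stages"][name] = {
                    "seconds": round(time.time() - t0, 3),
                    **(counts or {}),
                }
                logger.info("stage %s: %s", name, counts)
            except Exception as exc:  # noqa: BLE001 - annotate stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return deco

    # --- inputs (simulate or ingest) ----------------------------------
    state: dict = {}

    @stage("inputs")
    def _inputs():
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            truth = generate_truth(sim)
            paths = emit_callset(truth, outdir)
            gpaths = emit_genes(sim, outdir)
            if config.emit_depth_tracks:
                emit_depth(truth, outdir)
            truth.cn.to_csv(outdir / "truth_cn.tsv", sep="\t")
            state["call_files"] = {
                s: paths["calls_dir"] / f"{s}.cnv.tsv" for s in sim.samples
            }
            state["group_map"] = sim.group_map
            state["gff3"] = gpaths["gff3"]
            state["chrom_lengths"] = sim.chrom_lengths
            artifacts["gff3"] = gpaths["gff3"]
            artifacts["loci_design"] = gpaths["loci_design"]
            artifacts["sidecar"] = paths["sidecar"]
        else:
            state["call_files"] = dict(config.call_files)
            state["group_map"] = read_group_map(config.group_map_path)
            state["gff3"] = config.gff3_path
            state["chrom_lengths"] = config.chrom_lengths
        for s, p in state["call_files"].items():
            manifest["inputs"][str(p)] = _md5(Path(p))
        return {"samples": len(state["call_files"])}

    @stage("parse")
    def _parse():
        calls: list[CNVCall] = []
        for sample, path in sorted(state["call_files"].items()):
            calls.extend(read_calls(path, sample))
        state["calls"] = calls
        return {"calls": len(calls)}

    @stage("filter")
    def _filter():
        kept = filter_calls(state["calls"], config.filter_spec)
        state["filtered"] = kept
        path = outdir / "filtered_calls.tsv"
        write_calls(kept, path)
        artifacts["filtered_calls"] = path
        summary = summarize_groups(kept, state["group_map"])
        spath = outdir / "cnv_group_summary.tsv"
        summary.to_csv(spath, sep="\t")
        artifacts["cnv_group_summary"] = spath
        return {"parsed": len(state["calls"]), "retained": len(kept)}

    @stage("merge")
    def _merge():
        cnvrs = merge_calls(state["filtered"], config.min_overlap_frac)
        state["cnvrs"] = cnvrs
        assigned = sum(len(r.supporting_calls) for r in cnvrs)
        if assigned != len(state["filtered"]):
            raise ValueError(
                f"call conservation violated: {assigned} assigned vs "
                f"{len(state['filtered'])} filtered"
            )
        bed = outdir / "cnvrs.bed"
        write_bed(cnvrs, bed)
        artifacts["cnvr_bed"] = bed
        dist = size_distribution(cnvrs)
        dpath = outdir / "cnvr_size_distribution.tsv"
        dist.to_csv(dpath, sep="\t", index=False)
        artifacts["cnvr_size_distribution"] = dpath
        presence, specific, shared = presence_and_specific(cnvrs, state["group_map"])
        presence.to_csv(outdir / "presence_matrix.tsv", sep="\t")
        artifacts["presence_matrix"] = outdir / "presence_matrix.tsv"
        with (outdir / "group_sharing.tsv").open("w") as fh:
            fh.write("group\tspecific_cnvrs\n")
            for g, n in specific.items():
                fh.write(f"{g}\t{n}\n")
            fh.write(f"__all_groups_shared__\t{shared}\n")
        artifacts["group_sharing"] = outdir / "group_sharing.tsv"
        if config.per_group_merge:
            per_group = merge_per_group(state["filtered"], state["group_map"])
            with (outdir / "per_group_cnvr_counts.tsv").open("w") as fh:
                fh.write("group\tcnvrs\n")
                for g, rs in per_group.items():
                    fh.write(f"{g}\t{len(rs)}\n")
            artifacts["per_group_cnvr_counts"] = outdir / "per_group_cnvr_counts.tsv"
        if state["chrom_lengths"]:
            per_chrom, genome = coverage_percent(cnvrs, state["chrom_lengths"])
            with (outdir / "coverage_percent.tsv").open("w") as fh:
                fh.write("chrom\tpercent\n")
                for c, p in per_chrom.items():
                    fh.write(f"{c}\t{p:.6f}\n")
                fh.write(f"__genome__\t{genome:.6f}\n")
            artifacts["coverage_percent"] = outdir / "coverage_percent.tsv"
        return {"cnvrs": len(cnvrs), "calls_assigned": assigned}

    @stage("genotype")
    def _genotype():
        samples = sorted(state["group_map"])
        matrix = build_cn_matrix(state["cnvrs"], state["filtered"], samples)
        if matrix.shape != (len(state["cnvrs"]), len(samples)):
            raise ValueError("copy-number matrix dimensions do not match")
        state["matrix"] = matrix
        mpath = outdir / "cn_matrix.tsv"
        matrix.to_csv(mpath, sep="\t")
        artifacts["cn_matrix"] = mpath
        classes = matrix.map(classify_cn)
        classes.to_csv(outdir / "cn_class.tsv", sep="\t")
        artifacts["cn_class"] = outdir / "cn_class.tsv"
        return {"cnvrs": matrix.shape[0], "samples": matrix.shape[1]}

    @stage("vst")
    def _vst():
        if state["matrix"].shape[0] == 0:
            (outdir / "vst.tsv").write_text(
                "cnvr_id\tcontrast\tv_total\tv_within\tvst\tcandidate\tthreshold\n"
            )
            (outdir / "candidates.bed").write_text("")
            artifacts["vst"] = outdir / "vst.tsv"
            artifacts["candidates_bed"] = outdir / "candidates.bed"
            state["candidates"] = []
            return {"records": 0, "candidates": 0}
        frames = []
        n_cand = 0
        scans = [("all", None)] + [
            (c.name, (set(c.side_a), set(c.side_b))) for c in config.contrasts
        ]
        for name, contrast in scans:
            records = vst_scan(
                state["matrix"], state["group_map"], contrast, contrast_name=name
            )
            candidates, threshold = select_top(records, config.top_fraction)
            n_cand += len(candidates)
            table = vst_table(records, candidates)
            table["threshold"] = threshold
            frames.append(table)
            if name == "all":
                state["candidates"] = candidates
        vst_df = pd.concat(frames, ignore_index=True)
        vpath = outdir / "vst.tsv"
        vst_df.to_csv(vpath, sep="\t", index=False)
        artifacts["vst"] = vpath
        by_id = {r.id: r for r in state["cnvrs"]}
        write_bed([by_id[c.cnvr_id] for c in state["candidates"]], outdir / "candidates.bed")
        artifacts["candidates_bed"] = outdir / "candidates.bed"
        return {"records": len(vst_df), "candidates": n_cand}

    @stage("annotate")
    def _annotate():
        if state["gff3"] is None:
            return {"skipped": 1}
        models = read_gff3(state["gff3"])
        table = annotation_table(state["cnvrs"], models, config.flank_bp)
        apath = outdir / "annotation.tsv"
        table.to_csv(apath, sep="\t", index=False)
        artifacts["annotation"] = apath
        if state["cnvrs"]:
            dist = region_distribution(state["cnvrs"], models, config.flank_bp)
            with (outdir / "region_distribution.tsv").open("w") as fh:
                fh.write("region_class\tfraction\n")
                for cls, frac in dist.items():
                    fh.write(f"{cls}\t{frac:.6f}\n")
            artifacts["region_distribution"] = outdir / "region_distribution.tsv"
        return {"genes": len(models)}

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["artifacts"] = {k: str(v) for k, v in artifacts.items()}
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    artifacts["manifest"] = manifest_path
    report_tables(outdir, state)
    artifacts["table1"] = outdir / "table1_group_summary.tsv"
    artifacts["table2"] = outdir / "table2_cnvr_summary.tsv"
    return artifacts


def table2_rows(cnvrs: Sequence[CNVR]) -> pd.DataFrame:
    """CNVR summary in the classic layout: type counts with percentages,
    total/mean lengths, and size-bin counts per type."""
    types = ["total", "duplication", "deletion", "both"]
    sets = {
        "total": list(cnvrs),
        "duplication": [r for r in cnvrs if r.cnvr_type == "duplication"],
        "deletion": [r for r in cnvrs if r.cnvr_type == "deletion"],
        "both": [r for r in cnvrs if r.cnvr_type == "both"],
    }
    n_all = len(cnvrs)
    rows: dict[str, list] = {"row": [], **{t: [] for t in types}}

    def add(label, values):
        rows["row"].append(label)
        for t, v in zip(types, values):
            rows[t].append(v)

    counts = [len(sets[t]) for t in types]
    add(
        "Number of CNVRs",
        [
            f"{c} ({fmt_pct(100.0 * c / n_all)}%)" if n_all else f"{c} ()"
            for c in counts
        ],
    )
    add(
        "Total length (Mb)",
        [f"{sum(r.length for r in sets[t]) / 1e6:.2f}" for t in types],
    )
    add(
        "Average length per CNVR (Kb)",
        [
            f"{sum(r.length for r in sets[t]) / len(sets[t]) / 1e3:.2f}"
            if sets[t]
            else ""
            for t in types
        ],
    )
    for label, (lo, hi) in zip(SIZE_BIN_LABELS, _size_bins()):
        add(
            label,
            [
                str(sum(1 for r in sets[t] if lo <= r.length < hi))
                for t in types
            ],
        )
    return pd.DataFrame(rows)


def _size_bins():
    from .cnvr import SIZE_BINS

    return SIZE_BINS


def report_tables(outdir: str | Path, state: Mapping | None = None) -> None:
    """Write the per-group CNV/CNVR block table and the CNVR summary table.

    When called standalone (state=None) the artifacts are re-read from the
    run directory; a missing artifact is an error.
    """
    outdir = Path(outdir)
    if state is None:
        from .callset import read_multi_sample_calls

        needed = [outdir / "filtered_calls.tsv", outdir / "groups.tsv"]
        for p in needed:
            if not p.exists():
                raise FileNotFoundError(f"missing pipeline artifact: {p}")
        filtered = read_multi_sample_calls(outdir / "filtered_calls.tsv")
        group_map = read_group_map(outdir / "groups.tsv")
        cnvrs = merge_calls(filtered)
    else:
        filtered = state["filtered"]
        group_map = state["group_map"]
        cnvrs = state["cnvrs"]

    t1_cnv = summarize_groups(filtered, group_map)
    per_group = merge_per_group(filtered, group_map)
    rows = []
    for g, rs in per_group.items():
        total_bp = sum(r.length for r in rs)
        rows.append(
            {
                "group": g,
                "cnvr_count": len(rs),
                "duplication": sum(1 for r in rs if r.cnvr_type == "duplication"),
                "deletion": sum(1 for r in rs if r.cnvr_type == "deletion"),
                "both": sum(1 for r in rs if r.cnvr_type == "both"),
                "total_length_mb": total_bp / 1e6,
                "mean_length_kb": total_bp / len(rs) / 1e3 if rs else float("nan"),
            }
        )
    t1 = pd.concat(
        [
            t1_cnv.assign(block="CNVs"),
            pd.DataFrame(rows).set_index("group").assign(block="CNVRs"),
        ],
        sort=False,
    )
    t1.to_csv(outdir / "table1_group_summary.tsv", sep="\t")
    table2_rows(cnvrs).to_csv(outdir / "table2_cnvr_summary.tsv", sep="\t", index=False)
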