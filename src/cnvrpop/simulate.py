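"""Synthetic multi-group CNV cohorts with known ground truth.

The generator emulates the data a read-depth CNV caller produces for a
resequenced cohort of several populations: per-sample call files in the
caller dialect, optional binned depth tracks, a toy GFF3 gene annotation,
a sample->group map, and truth sidecars, so every downstream stage
(filtering, merging, genotyping, Vst, annotation) can be checked against
a planted answer.

Copy number is on the normalized-read-depth scale (diploid = 1.0)
everywhere; a locus's per-group state distribution is categorical over
such values (e.g. {0.5: 0.3, 1.0: 0.7} for a segregating deletion).
Depth is Poisson per bin with mean ``mean_coverage * CN``. One global
seed governs everything; per-sample, per-stage substreams are derived
deterministically from it, so identical configs give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotate import (
    DOWNSTREAM,
    EXONIC,
    INTERGENIC,
    INTRONIC,
    REGION_CLASSES,
    UPSTREAM,
)
from .callset import CNVCall, format_call_line, write_group_map

# substream tags, combined with the global seed and sample index
_STAGE_TRUTH, _STAGE_CALLS, _STAGE_DEPTH = 0, 1, 2

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class LocusSpec:
    """A variant locus with per-group copy-number state distributions.

    ``dist`` maps group name -> {normalized CN state: probability}; states
    are on the diploid-=-1.0 scale and each group's probabilities sum to 1.
    Coordinates are 1-based inclusive.
    """

    chrom: str
    start: int
    end: int
    dist: Mapping[str, Mapping[float, float]]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus {self.id}: start > end")
        for group, d in self.dist.items():
            if not d:
                raise ValueError(f"locus {self.id}: empty distribution for {group}")
            if any(state < 0 for state in d):
                raise ValueError(f"locus {self.id}: negative CN state")
            if any(p < 0 for p in d.values()):
                raise ValueError(f"locus {self.id}: negative probability")
            if abs(sum(d.values()) - 1.0) > _PROB_TOL:
                raise ValueError(
                    f"locus {self.id}: probabilities for group {group} "
                    f"sum to {sum(d.values())}, not 1"
                )

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort layout and noise model for the generator.

    Defaults mirror a small multi-population resequencing study: seven
    groups of four samples at ~20x coverage (use :func:`default_config`
    for a fully populated example with loci).
    """

    chromosomes: tuple[tuple[str, int], ...]
    groups: tuple[tuple[str, int], ...]
    loci: tuple[LocusSpec, ...]
    mean_coverage: float = 20.0
    bin_size: int = 100
    rd_noise_sd: float = 0.05
    junk_call_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if self.mean_coverage < 0 or self.rd_noise_sd < 0:
            raise ValueError("mean_coverage and rd_noise_sd must be >= 0")
        if not 0 <= self.junk_call_rate:
            raise ValueError("junk_call_rate must be >= 0")
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, n in self.groups:
            if n < 1:
                raise ValueError(f"group {name}: sample count must be >= 1")
        group_names = [g for g, _ in self.groups]
        if len(set(group_names)) != len(group_names):
            raise ValueError("duplicate group names")
        seen = set()
        for locus in self.loci:
            if locus.chrom not in lengths:
                raise ValueError(f"locus {locus.id}: unknown chromosome")
            if locus.end > lengths[locus.chrom]:
                raise ValueError(f"locus {locus.id}: beyond chromosome end")
            if locus.id in seen:
                raise ValueError(f"duplicate locus {locus.id}")
            seen.add(locus.id)
            missing = set(group_names) - set(locus.dist)
            if missing:
                raise ValueError(
                    f"locus {locus.id}: no distribution for groups {sorted(missing)}"
                )

    @property
    def samples(self) -> list[str]:
        return [f"{g}_{k}" for g, n in self.groups for k in range(1, n + 1)]

    @property
    def group_map(self) -> dict[str, str]:
        return {f"{g}_{k}": g for g, n in self.groups for k in range(1, n + 1)}

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class TruthTable:
    """True normalized copy number for every (sample, locus) pair."""

    config: SimulationConfig
    cn: pd.DataFrame  # rows = locus ids, columns = sample ids

    def value(self, sample: str, locus: LocusSpec) -> float:
        return float(self.cn.at[locus.id, sample])


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([seed, *tags])


def generate_truth(config: SimulationConfig) -> TruthTable:
    """Draw each sample's copy number at each locus from its group's
    categorical distribution; identical seed -> identical table."""
    group_map = config.group_map
    data = {}
    for i, sample in enumerate(config.samples):
        rng = _rng(config.seed, _STAGE_TRUTH, i)
        group = group_map[sample]
        col = []
        for locus in config.loci:
            d = locus.dist[group]
            states = sorted(d)
            probs = np.array([d[s] for s in states], dtype=float)
            probs /= probs.sum()  # guard 1e-9 slack
            col.append(float(rng.choice(states, p=probs)))
        data[sample] = col
    cn = pd.DataFrame(data, index=[l.id for l in config.loci], dtype=float)
    return TruthTable(config=config, cn=cn)


def expected_vst(
    locus: LocusSpec, group_sizes: Mapping[str, int] | Sequence[int]
) -> float:
    """Population-level Vst implied by a locus's group distributions.

    V_T is the variance of the size-weighted pooled mixture, V_S the
    size-weighted mean within-group variance; returns 0 when V_T = 0.
    ``group_sizes`` is a {group: n} mapping (or a sequence aligned with the
    locus's distribution keys in their iteration order).
    """
    if not isinstance(group_sizes, Mapping):
        group_sizes = dict(zip(locus.dist.keys(), group_sizes))
    if len(group_sizes) < 2:
        raise ValueError("Vst needs >= 2 groups")
    total_n = sum(group_sizes.values())
    means, variances, weights = [], [], []
    for group, n in group_sizes.items():
        d = locus.dist[group]
        mean = sum(s * p for s, p in d.items())
        ex2 = sum(s * s * p for s, p in d.items())
        means.append(mean)
        variances.append(ex2 - mean * mean)
        weights.append(n / total_n)
    pooled_mean = sum(w * m for w, m in zip(weights, means))
    pooled_ex2 = sum(w * (v + m * m) for w, v, m in zip(weights, variances, means))
    v_total = pooled_ex2 - pooled_mean * pooled_mean
    v_within = sum(w * v for w, v in zip(weights, variances))
    if v_total <= 0:
        return 0.0
    return (v_total - v_within) / v_total


# ---------------------------------------------------------------------------
# callset emission


def emit_callset(
    truth: TruthTable, outdir: str | Path
) -> dict[str, Path]:
    """Write per-sample call files plus group map and truth sidecar.

    For every (sample, locus) with CN != 1.0 one record is emitted at the
    locus coordinates: deletion below 1.0, duplication above; normalized RD
    is the true CN plus Gaussian jitter (sd = rd_noise_sd, truncated at 0);
    p-value and q0 are drawn to pass the default quality filter. On top,
    ``junk_call_rate`` x (signal count) extra calls are planted per sample,
    each engineered to fail exactly one filter criterion (p-value, size, or
    q0, cycling); the sidecar flags every record as signal or junk.

    Returns paths keyed by 'calls_dir', 'group_map', 'sidecar'.
    """
    config = truth.config
    outdir = Path(outdir)
    calls_dir = outdir / "calls"
    calls_dir.mkdir(parents=True, exist_ok=True)
    chrom_lengths = config.chrom_lengths
    chrom_names = [c for c, _ in config.chromosomes]

    sidecar_rows = []
    paths: dict[str, Path] = {"calls_dir": calls_dir}
    for i, sample in enumerate(config.samples):
        rng = _rng(config.seed, _STAGE_CALLS, i)
        lines = []
        n_signal = 0
        for locus in config.loci:
            cn = truth.value(sample, locus)
            if cn == 1.0:
                continue
            n_signal += 1
            rd = max(0.0, cn + rng.normal(0.0, config.rd_noise_sd))
            call = CNVCall(
                sample_id=sample,
                chrom=locus.chrom,
                start=locus.start,
                end=locus.end,
                cnv_type="deletion" if cn < 1.0 else "duplication",
                normalized_rd=rd,
                p_value=float(rng.uniform(1e-12, 0.009)),
                extra_evals=tuple(rng.uniform(1e-12, 0.009, size=3)),
                q0=float(rng.uniform(0.0, 0.49)),
            )
            lines.append(format_call_line(call))
            sidecar_rows.append(
                dict(
                    sample_id=sample,
                    chrom=locus.chrom,
                    start=locus.start,
                    end=locus.end,
                    cnv_type=call.cnv_type,
                    true_cn=cn,
                    kind="signal",
                    failed_criterion="none",
                )
            )
        n_junk = round(config.junk_call_rate * n_signal)
        for j in range(n_junk):
            criterion = ("p_value", "size", "q0")[j % 3]
            call = _junk_call(rng, sample, chrom_names, chrom_lengths, criterion)
            lines.append(format_call_line(call))
            sidecar_rows.append(
                dict(
                    sample_id=sample,
                    chrom=call.chrom,
                    start=call.start,
                    end=call.end,
                    cnv_type=call.cnv_type,
                    true_cn=float("nan"),
                    kind="junk",
                    failed_criterion=criterion,
                )
            )
        path = calls_dir / f"{sample}.cnv.tsv"
        path.write_text("".join(line + "\n" for line in lines))

    group_map_path = outdir / "groups.tsv"
    write_group_map(config.group_map, group_map_path)
    sidecar_path = outdir / "calls_truth.tsv"
    pd.DataFrame(
        sidecar_rows,
        columns=[
            "sample_id",
            "chrom",
            "start",
            "end",
            "cnv_type",
            "true_cn",
            "kind",
            "failed_criterion",
        ],
    ).to_csv(sidecar_path, sep="\t", index=False)
    paths["group_map"] = group_map_path
    paths["sidecar"] = sidecar_path
    return paths


def _junk_call(
    rng: np.random.Generator,
    sample: str,
    chrom_names: list[str],
    chrom_lengths: dict[str, int],
    criterion: str,
) -> CNVCall:
    """One extra call failing exactly the given filter criterion."""
    chrom = chrom_names[int(rng.integers(len(chrom_names)))]
    if criterion == "size":
        size = int(rng.integers(200, 1001))  # <= 1 kb fails the strict > 1 kb
    else:
        size = int(rng.integers(1500, 5001))
    start = int(rng.integers(1, max(2, chrom_lengths[chrom] - size)))
    p = float(rng.uniform(0.01, 1.0)) if criterion == "p_value" else float(
        rng.uniform(1e-12, 0.009)
    )
    q0 = float(rng.uniform(0.5, 1.0)) if criterion == "q0" else float(
        rng.uniform(0.0, 0.49)
    )
    if rng.random() < 0.5:
        cnv_type, rd = "deletion", float(rng.uniform(0.2, 0.8))
    else:
        cnv_type, rd = "duplication", float(rng.uniform(1.2, 2.2))
    return CNVCall(
        sample_id=sample,
        chrom=chrom,
        start=start,
        end=start + size - 1,
        cnv_type=cnv_type,
        normalized_rd=rd,
        p_value=p,
        extra_evals=tuple(rng.uniform(1e-12, 0.009, size=3)),
        q0=q0,
    )


# ---------------------------------------------------------------------------
# depth emission


def depth_track(truth: TruthTable, sample: str) -> pd.DataFrame:
    """Binned depth for one sample: Poisson(mean_coverage * CN) per bin.

    A bin takes a locus's CN when its midpoint falls inside the locus;
    elsewhere CN = 1. Columns: chrom, bin_start (0-based), depth.
    """
    config = truth.config
    i = config.samples.index(sample)
    rng = _rng(config.seed, _STAGE_DEPTH, i)
    frames = []
    for chrom, length in config.chromosomes:
        n_bins = length // config.bin_size
        starts = np.arange(n_bins, dtype=np.int64) * config.bin_size
        cn = np.ones(n_bins, dtype=float)
        mid = starts + config.bin_size / 2.0  # 0-based midpoint
        for locus in config.loci:
            if locus.chrom != chrom:
                continue
            inside = (mid >= locus.start - 1) & (mid < locus.end)
            cn[inside] = truth.value(sample, locus)
        depth = rng.poisson(config.mean_coverage * cn)
        frames.append(
            pd.DataFrame({"chrom": chrom, "bin_start": starts, "depth": depth})
        )
    return pd.concat(frames, ignore_index=True)


def emit_depth(truth: TruthTable, outdir: str | Path) -> dict[str, Path]:
    """Write per-sample binned depth TSVs (chrom, bin_start 0-based, depth)."""
    outdir = Path(outdir)
    depth_dir = outdir / "depth"
    depth_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample in truth.config.samples:
        df = depth_track(truth, sample)
        path = depth_dir / f"{sample}.depth.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[sample] = path
    return {"depth_dir": depth_dir, **paths}


# ---------------------------------------------------------------------------
# gene emission

#: planted region classes cycle over loci in config order
_CLASS_CYCLE = (EXONIC, INTRONIC, UPSTREAM, DOWNSTREAM, INTERGENIC)

#: gap between a flank-class locus and its gene; within the default 1900 bp
#: flank but outside a 500 bp one
_FLANK_GAP = 1000


def planted_classes(config: SimulationConfig) -> dict[str, str]:
    """Region class planted for each locus id (cycling through the five)."""
    return {
        locus.id: _CLASS_CYCLE[i % len(_CLASS_CYCLE)]
        for i, locus in enumerate(config.loci)
    }


def emit_genes(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a toy GFF3 placing genes so each locus gets its planted class.

    Loci cycle through exonic, intronic, upstream, downstream, intergenic
    (see :func:`planted_classes`); gene strands alternate +/- so both
    flank orientations are exercised. Intergenic loci get no nearby gene.
    Genes are emitted as gene -> mRNA -> exon chains. Raises when a placed
    gene would overflow its chromosome. Loci should be spaced far enough
    apart (> ~2x the largest flank in play) that one locus's gene cannot
    contaminate a neighbour's class.

    Also writes a locus-design sidecar TSV (locus_id, chrom, start, end,
    planted_class). Returns paths keyed 'gff3', 'loci_design'.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = config.chrom_lengths
    classes = planted_classes(config)
    genes = []  # (chrom, start, end, strand, exons, gene_id)
    for i, locus in enumerate(config.loci):
        cls = classes[locus.id]
        strand = "+" if i % 2 == 0 else "-"
        gene_id = f"gene{i + 1:03d}"
        placed = _place_gene(locus, cls, strand)
        if placed is None:
            continue
        start, end, exons = placed
        if start < 1 or end > lengths[locus.chrom]:
            raise ValueError(
                f"gene for locus {locus.id} ({cls}) overflows chromosome "
                f"{locus.chrom} (1..{lengths[locus.chrom]})"
            )
        genes.append((locus.chrom, start, end, strand, exons, gene_id))

    gff_path = outdir / "genes.gff3"
    with gff_path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in config.chromosomes:
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for chrom, start, end, strand, exons, gid in genes:
            fh.write(
                f"{chrom}\tcnvrpop_sim\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid};Name={gid}\n"
            )
            fh.write(
                f"{chrom}\tcnvrpop_sim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            for k, (es, ee) in enumerate(exons, start=1):
                fh.write(
                    f"{chrom}\tcnvrpop_sim\texon\t{es}\t{ee}\t.\t{strand}\t.\t"
                    f"ID={gid}.t1.e{k};Parent={gid}.t1\n"
                )

    design_path = outdir / "loci_design.tsv"
    with design_path.open("w") as fh:
        fh.write("locus_id\tchrom\tstart\tend\tplanted_class\n")
        for locus in config.loci:
            fh.write(
                f"{locus.id}\t{locus.chrom}\t{locus.start}\t{locus.end}\t"
                f"{classes[locus.id]}\n"
            )
    return {"gff3": gff_path, "loci_design": design_path}


def _place_gene(
    locus: LocusSpec, cls: str, strand: str
) -> tuple[int, int, list[tuple[int, int]]] | None:
    """Gene span and exons realizing the class for the locus, or None."""
    if cls == INTERGENIC:
        return None
    if cls == EXONIC:
        start, end = locus.start - 100, locus.end + 100
        return start, end, [(start, end)]
    if cls == INTRONIC:
        start, end = locus.start - 500, locus.end + 500
        return start, end, [(start, start + 99), (end - 99, end)]
    # flank classes: the gene sits _FLANK_GAP away on the side the
    # class + strand combination requires
    before = (cls == UPSTREAM) == (strand == "+")  # gene after locus if class
    if (cls == UPSTREAM and strand == "+") or (cls == DOWNSTREAM and strand == "-"):
        # locus must lie below the gene's 5'-on-plus anchor: gene after locus
        start = locus.end + _FLANK_GAP
        end = start + 600
    else:
        end = locus.start - _FLANK_GAP
        start = end - 600
    return start, end, [(start, end)]


# ---------------------------------------------------------------------------
# config I/O and defaults


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    doc = {
        "chromosomes": [[c, int(n)] for c, n in config.chromosomes],
        "groups": [[g, int(n)] for g, n in config.groups],
        "mean_coverage": config.mean_coverage,
        "bin_size": config.bin_size,
        "rd_noise_sd": config.rd_noise_sd,
        "junk_call_rate": config.junk_call_rate,
        "seed": config.seed,
        "loci": [
            {
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "dist": {g: {float(s): float(p) for s, p in d.items()}
                         for g, d in l.dist.items()},
            }
            for l in config.loci
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_from_yaml(path: str | Path) -> SimulationConfig:
    doc = yaml.safe_load(Path(path).read_text())
    return config_from_dict(doc)


def config_from_dict(doc: Mapping) -> SimulationConfig:
    loci = tuple(
        LocusSpec(
            chrom=l["chrom"],
            start=int(l["start"]),
            end=int(l["end"]),
            dist={
                g: {float(s): float(p) for s, p in d.items()}
                for g, d in l["dist"].items()
            },
        )
        for l in doc.get("loci", [])
    )
    return SimulationConfig(
        chromosomes=tuple((c, int(n)) for c, n in doc["chromosomes"]),
        groups=tuple((g, int(n)) for g, n in doc["groups"]),
        loci=loci,
        mean_coverage=float(doc.get("mean_coverage", 20.0)),
        bin_size=int(doc.get("bin_size", 100)),
        rd_noise_sd=float(doc.get("rd_noise_sd", 0.05)),
        junk_call_rate=float(doc.get("junk_call_rate", 0.1)),
        seed=int(doc.get("seed", 0)),
    )


#: the seven cohort groups: six breeds, one of them split into a polled and
#: a horned flock, four ewes each (28 samples)
DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("BD", 4),
    ("GY", 4),
    ("HZ", 4),
    ("OL", 4),
    ("SG1", 4),
    ("SG2", 4),
    ("ZK", 4),
)


def default_config(seed: int = 0) -> SimulationConfig:
    """A small but structured cohort: 7 groups x 4 samples, two toy
    chromosomes, 15 loci mixing shared polymorphisms, group-specific
    variants, and two strongly differentiated loci; loci spaced 60 kb so
    gene placement cannot cross-contaminate region classes."""
    groups = DEFAULT_GROUPS
    names = [g for g, _ in groups]

    def shared(p_del: float = 0.5) -> dict:
        return {g: {0.5: p_del, 1.0: 1 - p_del} for g in names}

    def shared_dup(p_dup: float = 0.5) -> dict:
        return {g: {1.0: 1 - p_dup, 2.0: p_dup} for g in names}

    def specific(target: str, state: float = 0.5) -> dict:
        return {
            g: ({state: 0.9, 1.0: 0.1} if g == target else {1.0: 1.0})
            for g in names
        }

    def differentiated(high: set[str], hi_state: float = 2.0) -> dict:
        return {
            g: ({hi_state: 1.0} if g in high else {0.5: 1.0}) for g in names
        }

    spacing = 60_000
    loci = []
    dists = [
        shared(0.5),
        shared_dup(0.4),
        specific("BD", 0.5),
        specific("GY", 2.0),
        shared(0.3),
        differentiated({"BD", "GY", "HZ"}),  # planted high-Vst locus
        shared_dup(0.5),
        specific("ZK", 0.0),
        shared(0.6),
        specific("OL", 1.5),
        differentiated({"SG1", "SG2"}, hi_state=0.0),  # second planted locus
        shared(0.5),
        specific("HZ", 2.0),
        shared_dup(0.3),
        shared(0.4),
    ]
    chroms = (("chr1", 1_000_000), ("chr2", 600_000))
    per_chrom = {"chr1": 12, "chr2": 3}
    i = 0
    for chrom, _length in chroms:
        for k in range(per_chrom[chrom]):
            start = 50_001 + k * spacing
            end = start + 4_999  # 5 kb loci
            loci.append(LocusSpec(chrom=chrom, start=start, end=end, dist=dists[i]))
            i += 1
    return SimulationConfig(
        chromosomes=chroms,
        groups=groups,
        loci=tuple(loci),
        mean_coverage=20.0,
        bin_size=100,
        rd_noise_sd=0.05,
        junk_call_rate=0.1,
        seed=seed,
    )
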