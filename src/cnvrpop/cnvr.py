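"""Merging filtered CNV calls across samples into copy number variable regions.

A CNVR is a connected component of the >=1-bp-overlap relation among calls on
one chromosome (transitive closure), spanning the union envelope
[min start, max end]. Book-ended calls (end + 1 == next start) share no base
and are NOT merged. A CNVR is typed ``duplication`` or ``deletion`` when all
supporting calls agree, and ``both`` when the two types meet in one region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up
from .callset import CNVCall, DELETION, DUPLICATION

#: Size bins (bp), left-closed right-open, as conventional for CNVR size
#: distributions: <10 kb, 10-50 kb, 50-100 kb, 100-500 kb, 500 kb-1 Mb, >=1 Mb.
SIZE_BINS: tuple[tuple[float, float], ...] = (
    (0, 10_000),
    (10_000, 50_000),
    (50_000, 100_000),
    (100_000, 500_000),
    (500_000, 1_000_000),
    (1_000_000, math.inf),
)

SIZE_BIN_LABELS = (
    "<10 Kb",
    ">=10 Kb to <50 Kb",
    ">=50 Kb to <100 Kb",
    ">=100 Kb to <500 Kb",
    ">=500 Kb to <1 Mb",
    ">=1 Mb",
)


@dataclass(frozen=True)
class CNVR:
    """A merged multi-sample region, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    cnvr_type: str
    supporting_calls: tuple[CNVCall, ...]

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def samples(self) -> frozenset[str]:
        return frozenset(c.sample_id for c in self.supporting_calls)

    def groups_present(self, group_map: Mapping[str, str]) -> frozenset[str]:
        return frozenset(group_map[s] for s in self.samples)


def _type_of(calls: Sequence[CNVCall]) -> str:
    types = {c.cnv_type for c in calls}
    if types == {DELETION}:
        return DELETION
    if types == {DUPLICATION}:
        return DUPLICATION
    return "both"


def merge_calls(
    calls: Iterable[CNVCall], min_overlap_frac: float = 0.0
) -> list[CNVR]:
    """Merge overlapping calls (any samples) into CNVRs, per chromosome.

    Overlap means >= 1 shared base; adjacency does not merge. With
    ``min_overlap_frac`` > 0, a call joins the growing region only when its
    overlap with the region envelope is at least that fraction of the
    shorter of the two (order independence is then no longer guaranteed;
    the default 0 applies plain overlap and is order independent).
    Output is sorted by (chrom, start, end) and deterministic.
    """
    if not 0.0 <= min_overlap_frac <= 1.0:
        raise ValueError("min_overlap_frac must be in [0, 1]")
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)

    cnvrs: list[CNVR] = []
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(
            by_chrom[chrom],
            key=lambda c: (c.start, c.end, c.sample_id, c.cnv_type),
        )
        cluster: list[CNVCall] = []
        env_start = env_end = 0
        for call in chrom_calls:
            if cluster and _joins(call, env_start, env_end, min_overlap_frac):
                cluster.append(call)
                env_end = max(env_end, call.end)
            else:
                if cluster:
                    cnvrs.append(_close(chrom, env_start, env_end, cluster))
                cluster = [call]
                env_start, env_end = call.start, call.end
        if cluster:
            cnvrs.append(_close(chrom, env_start, env_end, cluster))
    return cnvrs


def _joins(call: CNVCall, env_start: int, env_end: int, frac: float) -> bool:
    overlap = min(env_end, call.end) - call.start + 1
    if overlap < 1:
        return False
    if frac == 0.0:
        return True
    shorter = min(call.size, env_end - env_start + 1)
    return overlap >= frac * shorter


def _close(chrom: str, start: int, end: int, cluster: list[CNVCall]) -> CNVR:
    return CNVR(
        chrom=chrom,
        start=start,
        end=end,
        cnvr_type=_type_of(cluster),
        supporting_calls=tuple(cluster),
    )


def merge_per_group(
    calls: Sequence[CNVCall],
    group_map: Mapping[str, str],
    min_overlap_frac: float = 0.0,
) -> dict[str, list[CNVR]]:
    """Re-run the merge within each group's samples (per-group CNVR tables)."""
    missing = sorted({c.sample_id for c in calls} - set(group_map))
    if missing:
        raise ValueError(f"samples missing from group map: {missing}")
    out: dict[str, list[CNVR]] = {g: [] for g in sorted(set(group_map.values()))}
    for group in out:
        gcalls = [c for c in calls if group_map[c.sample_id] == group]
        out[group] = merge_calls(gcalls, min_overlap_frac)
    return out


def bin_percentages(counts: Sequence[int]) -> list[float]:
    """Percentages (2 decimals, half-up) of bin counts over their total."""
    total = sum(counts)
    if total == 0:
        return [float("nan")] * len(counts)
    return [round_half_up(100.0 * c / total, 2) for c in counts]


def size_distribution(cnvrs: Sequence[CNVR]) -> pd.DataFrame:
    """Counts and percentages of CNVRs per size bin, plus summary lengths."""
    counts = [0] * len(SIZE_BINS)
    for r in cnvrs:
        for i, (lo, hi) in enumerate(SIZE_BINS):
            if lo <= r.length < hi:
                counts[i] += 1
                break
    df = pd.DataFrame(
        {
            "size_bin": SIZE_BIN_LABELS,
            "count": counts,
            "percent": bin_percentages(counts),
        }
    )
    total_bp = sum(r.length for r in cnvrs)
    df.attrs["total_length_mb"] = total_bp / 1e6
    df.attrs["mean_length_kb"] = (
        total_bp / len(cnvrs) / 1e3 if cnvrs else float("nan")
    )
    return df


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by 1-based inclusive intervals, counted once."""
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    return total + (cur_e - cur_s + 1)


def coverage_percent(
    cnvrs: Sequence[CNVR], chrom_lengths: Mapping[str, int]
) -> tuple[dict[str, float], float]:
    """Percent of each chromosome (and of the genome) covered by CNVRs."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in cnvrs:
        if r.chrom not in chrom_lengths:
            raise ValueError(f"no length for chromosome {r.chrom!r}")
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    per_chrom = {
        chrom: 100.0 * _union_length(by_chrom.get(chrom, [])) / length
        for chrom, length in chrom_lengths.items()
    }
    total_union = sum(_union_length(iv) for iv in by_chrom.values())
    genome = 100.0 * total_union / sum(chrom_lengths.values())
    return per_chrom, genome


def presence_and_specific(
    cnvrs: Sequence[CNVR], group_map: Mapping[str, str]
) -> tuple[pd.DataFrame, dict[str, int], int]:
    """Presence matrix (CNVR x group, 0/1), per-group specific counts, and
    the count of CNVRs present in every group.

    A CNVR is present in a group iff at least one of the group's samples
    contributes a supporting call; specific = present in exactly one group.
    """
    groups = sorted(set(group_map.values()))
    rows = {}
    for r in cnvrs:
        present = r.groups_present(group_map)
        rows[r.id] = [1 if g in present else 0 for g in groups]
    presence = pd.DataFrame.from_dict(rows, orient="index", columns=groups)
    specific = {g: 0 for g in groups}
    shared = 0
    for r_id, row in presence.iterrows():
        hit = [g for g in groups if row[g]]
        if len(hit) == 1:
            specific[hit[0]] += 1
        if len(hit) == len(groups):
            shared += 1
    return presence, specific, shared


def write_bed(cnvrs: Sequence[CNVR], path: str | Path) -> None:
    """Write CNVRs as BED (0-based half-open); column 5 carries the type."""
    with Path(path).open("w") as fh:
        fh.write("# BED: 0-based half-open; name=CNVR id; col5=type\n")
        for r in cnvrs:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.id}\t{r.cnvr_type}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Read a CNVR BED back to 1-based inclusive tuples
    (chrom, start, end, id, type)."""
    out = []
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            chrom, s0, e, name, cnvr_type = line.split("\t")[:5]
            out.append((chrom, int(s0) + 1, int(e), name, cnvr_type))
    return out
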