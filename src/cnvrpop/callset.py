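"""Reading, validation, filtering and per-group summaries of CNV call files.

The on-disk dialect follows the read-depth caller convention: one call per
line, tab-separated columns

    CNV_type  coordinates  CNV_size  normalized_RD  e-val1  e-val2  e-val3  e-val4  q0

with ``coordinates`` written as ``chrom:start-end`` in 1-based inclusive
base pairs, ``normalized_RD`` on the diploid-=-1.0 scale, and ``q0`` the
fraction of zero-mapping-quality reads in the call (sentinel -1 when not
computable). Coordinates stay 1-based inclusive in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

DELETION = "deletion"
DUPLICATION = "duplication"
CNV_TYPES = (DELETION, DUPLICATION)

#: Column order of the call-file dialect.
CALL_COLUMNS = (
    "CNV_type",
    "coordinates",
    "CNV_size",
    "normalized_RD",
    "e-val1",
    "e-val2",
    "e-val3",
    "e-val4",
    "q0",
)


class CallParseError(ValueError):
    """A call file line could not be parsed; the message names the line."""


@dataclass(frozen=True)
class CNVCall:
    """One per-sample CNV call (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    normalized_rd: float
    p_value: float
    q0: float
    extra_evals: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"call {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"unknown CNV type {self.cnv_type!r}")
        if self.normalized_rd < 0:
            raise ValueError("normalized_rd must be >= 0")

    @property
    def size(self) -> int:
        """Length in bp (end - start + 1)."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class FilterSpec:
    """Quality-filter thresholds; all inequalities are strict.

    A call is retained iff p_value < max_p AND size > min_size AND
    q0 < max_q0. A q0 of -1 (caller sentinel for "no reads to assess")
    is treated as missing and retained by default.
    """

    max_p: float = 0.01
    min_size: int = 1000
    max_q0: float = 0.5
    keep_missing_q0: bool = True

    def __post_init__(self) -> None:
        if self.max_p <= 0 or self.min_size <= 0 or self.max_q0 <= 0:
            raise ValueError("filter thresholds must be > 0")

    def passes(self, call: CNVCall) -> bool:
        if not call.p_value < self.max_p:
            return False
        if not call.size > self.min_size:
            return False
        if call.q0 == -1:
            return self.keep_missing_q0
        return call.q0 < self.max_q0


def _parse_coordinates(text: str) -> tuple[str, int, int]:
    try:
        chrom, span = text.rsplit(":", 1)
        start_s, end_s = span.split("-", 1)
        return chrom, int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"malformed coordinate string {text!r}") from exc


def read_calls(path: str | Path, sample_id: str) -> list[CNVCall]:
    """Parse one per-sample call file into CNVCall records.

    Lines whose CNV_size column disagrees with end - start + 1 raise a
    warning and are corrected to the coordinate-derived size. Blank lines
    and ``#`` comments are skipped. Malformed lines raise
    :class:`CallParseError` naming the line number.
    """
    path = Path(path)
    calls: list[CNVCall] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(CALL_COLUMNS):
                raise CallParseError(
                    f"{path.name}:{lineno}: expected {len(CALL_COLUMNS)} "
                    f"tab-separated columns, got {len(fields)}"
                )
            cnv_type = fields[0].strip().lower()
            if cnv_type not in CNV_TYPES:
                raise CallParseError(
                    f"{path.name}:{lineno}: unknown CNV_type {fields[0]!r}"
                )
            try:
                chrom, start, end = _parse_coordinates(fields[1])
                size = int(float(fields[2]))
                rd = float(fields[3])
                evals = tuple(float(x) for x in fields[4:8])
                q0 = float(fields[8])
            except ValueError as exc:
                raise CallParseError(f"{path.name}:{lineno}: {exc}") from exc
            true_size = end - start + 1
            if size != true_size:
                warnings.warn(
                    f"{path.name}:{lineno}: CNV_size {size} != end-start+1 "
                    f"({true_size}); using coordinate-derived size",
                    stacklevel=2,
                )
            calls.append(
                CNVCall(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    cnv_type=cnv_type,
                    normalized_rd=rd,
                    p_value=evals[0],
                    extra_evals=evals[1:],
                    q0=q0,
                )
            )
    return calls


def format_call_line(call: CNVCall) -> str:
    evals = list(call.extra_evals) + [0.0] * (3 - len(call.extra_evals))
    cols = [
        call.cnv_type,
        f"{call.chrom}:{call.start}-{call.end}",
        str(call.size),
        repr(float(call.normalized_rd)),
        repr(float(call.p_value)),
        *(repr(float(e)) for e in evals),
        repr(float(call.q0)),
    ]
    return "\t".join(cols)


def write_calls(calls: Iterable[CNVCall], path: str | Path) -> None:
    """Write calls in the input dialect plus a leading sample_id column."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# coordinates are 1-based inclusive (chrom:start-end)\n")
        fh.write("#sample_id\t" + "\t".join(CALL_COLUMNS) + "\n")
        for call in calls:
            fh.write(f"{call.sample_id}\t{format_call_line(call)}\n")


def read_multi_sample_calls(path: str | Path) -> list[CNVCall]:
    """Read back a file written by :func:`write_calls`."""
    path = Path(path)
    calls: list[CNVCall] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            sample_id, rest = line.split("\t", 1)
            fields = rest.split("\t")
            chrom, start, end = _parse_coordinates(fields[1])
            evals = tuple(float(x) for x in fields[4:8])
            calls.append(
                CNVCall(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    cnv_type=fields[0],
                    normalized_rd=float(fields[3]),
                    p_value=evals[0],
                    extra_evals=evals[1:],
                    q0=float(fields[8]),
                )
            )
    return calls


def filter_calls(
    calls: Sequence[CNVCall], spec: FilterSpec | None = None
) -> list[CNVCall]:
    """Retain calls passing all three quality thresholds; order preserved."""
    spec = spec or FilterSpec()
    return [c for c in calls if spec.passes(c)]


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a sample -> group TSV (two columns; optional header)."""
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"group map line needs 2 columns: {line!r}")
            if parts[0].lower() in ("sample", "sample_id"):
                continue
            mapping[parts[0]] = parts[1]
    return mapping


def write_group_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in mapping.items():
            fh.write(f"{sample}\t{group}\n")


def summarize_groups(
    calls: Sequence[CNVCall], group_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group CNV summary: counts, type split, lengths, mean per sample.

    Returns a DataFrame indexed by group (plus a ``Total`` row) with columns
    count, duplication, deletion, total_length_mb, mean_length_kb,
    mean_cnvs_per_sample. Total length is the sum of call sizes in Mb;
    mean length is total length / count in kb; mean CNVs per sample divides
    by the number of samples the group map assigns to the group (samples
    with zero calls count in the denominator).
    """
    missing = sorted({c.sample_id for c in calls} - set(group_map))
    if missing:
        raise ValueError(f"samples missing from group map: {missing}")

    group_samples: dict[str, set[str]] = {}
    for sample, group in group_map.items():
        group_samples.setdefault(group, set()).add(sample)

    rows = []
    for group in sorted(group_samples):
        gcalls = [c for c in calls if group_map[c.sample_id] == group]
        rows.append(_summary_row(group, gcalls, len(group_samples[group])))
    rows.append(_summary_row("Total", list(calls), len(group_map)))
    df = pd.DataFrame(rows).set_index("group")
    return df


def _summary_row(group: str, calls: list[CNVCall], n_samples: int) -> dict:
    n = len(calls)
    dup = sum(1 for c in calls if c.cnv_type == DUPLICATION)
    total_bp = sum(c.size for c in calls)
    return {
        "group": group,
        "n_samples": n_samples,
        "count": n,
        "duplication": dup,
        "deletion": n - dup,
        "total_length_mb": total_bp / 1e6,
        "mean_length_kb": (total_bp / n / 1e3) if n else float("nan"),
        "mean_cnvs_per_sample": (n / n_samples) if n_samples else float("nan"),
    }
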