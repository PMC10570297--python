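"""Copy-number genotyping per CNVR, state classification, and the Vst scan.

Copy number (CN) lives on the normalized read-depth scale throughout:
diploid = 1.0. States follow the Redon convention — deleted (CN < 0.4),
conserved (0.4 <= CN <= 1.6), duplicated (CN > 1.6).

Vst partitions the variance of CN across individuals: with V_T the variance
of all values and V_S = sum(n_i * Var_i) / sum(n_i) the size-weighted mean
within-group variance,

    Vst = (V_T - V_S) / V_T        (0 by convention when V_T = 0).

Population (denominator N) variances are the default; the sample
(denominator N-1, weights n_i - 1) convention is switchable for
sensitivity checks. Negative Vst is reported as computed, never clamped,
so the top-quantile scan sees the full empirical distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .callset import CNVCall
from .cnvr import CNVR

DELETED = "deleted"
CONSERVED = "conserved"
DUPLICATED = "duplicated"

#: Redon thresholds on the normalized-RD scale.
CN_DELETED_BELOW = 0.4
CN_DUPLICATED_ABOVE = 1.6


def classify_cn(cn: float) -> str:
    """Classify a copy number: deleted < 0.4 <= conserved <= 1.6 < duplicated."""
    if cn < 0:
        raise ValueError(f"copy number must be >= 0, got {cn}")
    if cn < CN_DELETED_BELOW:
        return DELETED
    if cn <= CN_DUPLICATED_ABOVE:
        return CONSERVED
    return DUPLICATED


def genotype_from_calls(cnvr: CNVR, sample_calls: Sequence[CNVCall]) -> float:
    """Overlap-length-weighted mean normalized RD of one sample over a CNVR.

    Bases of the CNVR not covered by any of the sample's calls contribute
    1.0 (diploid). Where the sample's own calls overlap each other (rare in
    practice: read-depth callers emit disjoint calls per sample), shared
    bases are weighted once, by whichever call sorts first in (start, end)
    order. No intersecting call at all -> 1.0.
    """
    length = cnvr.length
    total = 0.0
    covered = 0
    # segments already assigned, as sorted disjoint (start, end) 1-based
    taken: list[tuple[int, int]] = []
    for call in sorted(sample_calls, key=lambda c: (c.start, c.end)):
        if call.chrom != cnvr.chrom:
            continue
        s = max(call.start, cnvr.start)
        e = min(call.end, cnvr.end)
        if s > e:
            continue
        for fs, fe in _subtract(s, e, taken):
            total += call.normalized_rd * (fe - fs + 1)
            covered += fe - fs + 1
            taken.append((fs, fe))
        taken.sort()
    total += 1.0 * (length - covered)
    return total / length


def _subtract(s: int, e: int, taken: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Portions of [s, e] not covered by the sorted disjoint intervals."""
    free = []
    cur = s
    for ts, te in taken:
        if te < cur:
            continue
        if ts > e:
            break
        if ts > cur:
            free.append((cur, ts - 1))
        cur = max(cur, te + 1)
        if cur > e:
            break
    if cur <= e:
        free.append((cur, e))
    return free


def genotype_from_depth(
    cnvr: CNVR,
    depth: pd.DataFrame,
    genome_mean: float | None = None,
    bin_size: int = 100,
) -> float:
    """CN from a binned depth track: mean depth over bins overlapping the
    CNVR divided by the sample's genome-wide mean bin depth.

    ``depth`` has columns chrom, bin_start (0-based), depth. Raises if the
    CNVR lies outside the track extent (no overlapping bin).
    """
    if genome_mean is None:
        genome_mean = float(depth["depth"].mean())
    sel = depth[
        (depth["chrom"] == cnvr.chrom)
        & (depth["bin_start"] + bin_size >= cnvr.start)  # bin end (1-based) >= start
        & (depth["bin_start"] < cnvr.end)  # bin start (0-based) < end
    ]
    if sel.empty:
        raise ValueError(f"CNVR {cnvr.id} outside depth track extent")
    return float(sel["depth"].mean()) / genome_mean


def build_cn_matrix(
    cnvrs: Sequence[CNVR],
    calls: Sequence[CNVCall] | None = None,
    samples: Sequence[str] = (),
) -> pd.DataFrame:
    """CNVR x sample copy-number matrix in call mode.

    Complete: every cell gets a value, defaulting to 1.0 (diploid) where a
    sample contributes no evidence. The CNVRs carry their supporting calls,
    which are exactly the calls intersecting them, so ``calls`` (the same
    filtered set the CNVRs were merged from) is accepted only for interface
    symmetry with depth mode.
    """
    known = set(samples)
    mat = pd.DataFrame(1.0, index=[r.id for r in cnvrs], columns=list(samples))
    col_pos = {s: i for i, s in enumerate(samples)}
    values = mat.to_numpy()
    for row, r in enumerate(cnvrs):
        # every call intersecting the CNVR is one of its supporting calls,
        # so genotyping only needs those
        per_sample: dict[str, list[CNVCall]] = {}
        for c in r.supporting_calls:
            if c.sample_id in known:
                per_sample.setdefault(c.sample_id, []).append(c)
        for s, s_calls in per_sample.items():
            values[row, col_pos[s]] = genotype_from_calls(r, s_calls)
    return pd.DataFrame(values, index=mat.index, columns=mat.columns)


@dataclass(frozen=True)
class VstRecord:
    """Per-CNVR differentiation statistic with its variance components."""

    cnvr_id: str
    contrast: str
    v_total: float
    v_within: float
    n_i: tuple[int, ...]
    vst: float


def compute_vst(
    values: Sequence[float],
    labels: Sequence[str],
    cnvr_id: str = "",
    contrast: str = "all",
    convention: str = "population",
) -> VstRecord:
    """Vst = (V_T - V_S)/V_T over per-sample copy numbers and group labels.

    ``convention="population"`` (default): denominator-N variances, V_S
    weighted by n_i. ``"sample"``: denominator-(N-1) variances, V_S weighted
    by n_i - 1 (every group then needs >= 2 samples).
    """
    x = np.asarray(values, dtype=float)
    if len(x) != len(labels):
        raise ValueError("values and labels must align")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(labels):
        groups.setdefault(g, []).append(i)
    if len(groups) < 2:
        raise ValueError("Vst needs >= 2 groups")
    if convention == "population":
        ddof = 0
    elif convention == "sample":
        ddof = 1
    else:
        raise ValueError(f"unknown variance convention {convention!r}")
    names = sorted(groups)
    n_i = tuple(len(groups[g]) for g in names)
    if min(n_i) < 1 + ddof:
        raise ValueError("every group needs at least %d samples" % (1 + ddof))
    v_total = float(np.var(x, ddof=ddof))
    weights = np.array([n - ddof for n in n_i], dtype=float)
    within = np.array([np.var(x[groups[g]], ddof=ddof) for g in names])
    v_within = float(np.sum(weights * within) / np.sum(weights))
    vst = 0.0 if v_total == 0.0 else (v_total - v_within) / v_total
    return VstRecord(
        cnvr_id=cnvr_id,
        contrast=contrast,
        v_total=v_total,
        v_within=v_within,
        n_i=n_i,
        vst=vst,
    )


def vst_scan(
    cn_matrix: pd.DataFrame,
    group_map: Mapping[str, str],
    contrast: tuple[frozenset[str] | set[str], frozenset[str] | set[str]] | None = None,
    contrast_name: str = "all",
    convention: str = "population",
) -> list[VstRecord]:
    """Vst per CNVR row of the copy-number matrix.

    ``contrast=(groups_A, groups_B)`` pools the named groups into two sides
    and restricts to their samples; None contrasts all groups against each
    other (one label per group).
    """
    samples = list(cn_matrix.columns)
    missing = sorted(set(samples) - set(group_map))
    if missing:
        raise ValueError(f"samples missing from group map: {missing}")
    if contrast is None:
        use = samples
        labels = [group_map[s] for s in samples]
    else:
        side_a, side_b = (set(contrast[0]), set(contrast[1]))
        if side_a & side_b:
            raise ValueError("contrast sides must be disjoint")
        use, labels = [], []
        for s in samples:
            g = group_map[s]
            if g in side_a:
                use.append(s)
                labels.append("A")
            elif g in side_b:
                use.append(s)
                labels.append("B")
    sub = cn_matrix[use]
    return [
        compute_vst(
            sub.loc[r_id].to_numpy(),
            labels,
            cnvr_id=str(r_id),
            contrast=contrast_name,
            convention=convention,
        )
        for r_id in cn_matrix.index
    ]


def select_top(
    records: Sequence[VstRecord], fraction: float = 0.01
) -> tuple[list[VstRecord], float]:
    """Top-fraction scan candidates and the Vst threshold they clear.

    The threshold is the k-th largest Vst with k = ceil(fraction * n)
    (the empirical top-``fraction`` cut); all records with vst >= threshold
    are candidates, so ties at the threshold are included. Candidates are
    sorted by vst descending (id as tie-break).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if not records:
        raise ValueError("need at least one record")
    k = max(1, math.ceil(fraction * len(records)))
    ordered = sorted(records, key=lambda r: (-r.vst, r.cnvr_id))
    threshold = ordered[k - 1].vst
    candidates = [r for r in ordered if r.vst >= threshold]
    return candidates, threshold


def ddct_quantity(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative quantity by the 2^-ddCt method (qPCR validation arithmetic).

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,cal - Ct_ref,cal).
    """
    ddct = (ct_target_test - ct_ref_test) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return 2.0 ** (-ddct)


def vst_table(records: Sequence[VstRecord], candidates: Sequence[VstRecord] | None = None) -> pd.DataFrame:
    cand_ids = {r.cnvr_id for r in candidates} if candidates is not None else set()
    return pd.DataFrame(
        {
            "cnvr_id": [r.cnvr_id for r in records],
            "contrast": [r.contrast for r in records],
            "v_total": [r.v_total for r in records],
            "v_within": [r.v_within for r in records],
            "vst": [r.vst for r in records],
            "candidate": [int(r.cnvr_id in cand_ids) for r in records],
        }
    )
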