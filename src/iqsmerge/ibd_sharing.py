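"""Aggregation of pairwise IBD segments into group-level sharing summaries.

Pairwise identity-by-descent segments (RefinedIBD-style output) between a
*target* cohort (e.g. individuals recruited around cities) and a *reference*
cohort partitioned into fine-structure clusters are aggregated into a
target-group x reference-cluster matrix of mean total shared centimorgans.
Segments are split at a genetic-length threshold (default 3 cM): long
segments reflect recent shared ancestry and drive the imputation benefit of
a local panel; short segments reflect older, more diffuse sharing.

Two distinct aggregation semantics coexist and are both provided:

* totals — overlapping segments to different cluster members are *summed*
  (total sharing, per individual first, then averaged over the group,
  counting individuals with no segments as zeros);
* interval masks — segments of one individual are *merged* by physical
  overlap (coverage), producing per-chromosome intervals suitable as the
  genotype-level mask for dosage stratification
  (:func:`iqsmerge.metrics.het_dosage_distribution`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .vcf_io import ConfigurationError, VariantKey

__all__ = [
    "IBDSegment",
    "read_ibd_segments",
    "read_group_table",
    "SharingMatrix",
    "SharingMatrixSet",
    "group_sharing_matrix",
    "ibd_intervals_for_individual",
    "interval_mask",
    "write_intervals_bed",
]

#: Genetic-length threshold separating long from short segments (cM).
DEFAULT_THRESHOLD_CM = 3.0

IBD_COLUMNS = [
    "sample1",
    "hap1",
    "sample2",
    "hap2",
    "chrom",
    "start",
    "end",
    "lod",
    "length_cm",
]


@dataclass(frozen=True)
class IBDSegment:
    """One pairwise shared segment; coordinates are 1-based inclusive bp."""

    sample1: str
    sample2: str
    chrom: str
    start: int
    end: int
    length_cm: float
    hap1: int | None = None
    hap2: int | None = None
    lod: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment end {self.end} before start {self.start} on {self.chrom}"
            )
        if self.length_cm <= 0:
            raise ValueError(f"non-positive genetic length {self.length_cm}")
        if self.sample1 == self.sample2:
            raise ValueError(f"self-segment for sample {self.sample1}")


def read_ibd_segments(path) -> list[IBDSegment]:
    """Parse a RefinedIBD-style tab-delimited segment file.

    Expected columns (no header): sample1, hap1, sample2, hap2, chrom,
    start, end, LOD, length_cM.  The genetic length must be present — no
    genetic map is consulted.  Malformed rows raise with their line number.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=IBD_COLUMNS, dtype={4: str}
        )
    except pd.errors.EmptyDataError:
        return []
    except Exception as exc:
        raise ValueError(f"cannot parse IBD file {path}: {exc}") from exc
    if df.shape[1] < len(IBD_COLUMNS) or df["length_cm"].isna().any():
        raise ConfigurationError(
            f"{path}: genetic length column (9th) is required; a genetic map is not consulted"
        )
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            segments.append(
                IBDSegment(
                    sample1=str(row.sample1),
                    sample2=str(row.sample2),
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    length_cm=float(row.length_cm),
                    hap1=int(row.hap1),
                    hap2=int(row.hap2),
                    lod=float(row.lod),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed IBD row at line {i}: {exc}") from exc
    return segments


def read_group_table(path) -> dict[str, str]:
    """Read a two-column (sample, label) tab-delimited assignment table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"{path}: sample {dup!r} assigned more than once")
    return dict(zip(df["sample"], df["label"]))


@dataclass
class SharingMatrix:
    """Target-group x reference-cluster mean total sharing for one length class."""

    values: pd.DataFrame  # rows: target groups, cols: reference clusters (cM)
    length_class: str  # 'all' | 'gt_threshold' | 'le_threshold'
    threshold_cm: float


@dataclass
class SharingMatrixSet:
    """The three length-class matrices plus bookkeeping counts.

    Invariant: ``all = gt_threshold + le_threshold`` cell-wise.
    """

    all: SharingMatrix
    gt_threshold: SharingMatrix
    le_threshold: SharingMatrix
    n_segments_used: int
    n_segments_ignored: int  # endpoints not covered by target+reference labels

    def __getitem__(self, key: str) -> SharingMatrix:
        return {"all": self.all, "gt_threshold": self.gt_threshold,
                "le_threshold": self.le_threshold}[key]


def _orient(seg: IBDSegment, targets: Mapping[str, str], refs: Mapping[str, str]):
    """Return (target sample, reference sample) for a segment, or None.

    A segment connects a target-labelled and a reference-labelled sample in
    either column order; anything else is ignored (and counted upstream).
    """
    if seg.sample1 in targets and seg.sample2 in refs:
        return seg.sample1, seg.sample2
    if seg.sample2 in targets and seg.sample1 in refs:
        return seg.sample2, seg.sample1
    return None


def group_sharing_matrix(
    segments: Iterable[IBDSegment],
    targets: Mapping[str, str],
    refs: Mapping[str, str],
    threshold_cm: float = DEFAULT_THRESHOLD_CM,
) -> SharingMatrixSet:
    """Mean total shared cM between target groups and reference clusters.

    For each target individual and cluster, the total genetic length of its
    segments to any cluster member is summed (each segment once, in the
    length class given by ``length_cm > threshold_cm`` or ``<=``); the matrix
    cell is the mean of these totals over the target group's individuals,
    with individuals having no segments contributing zeros — otherwise group
    means would be inflated toward active sharers.
    """
    groups = sorted(set(targets.values()))
    clusters = sorted(set(refs.values()))
    t_samples = sorted(targets)
    t_index = {s: i for i, s in enumerate(t_samples)}
    c_index = {c: j for j, c in enumerate(clusters)}
    totals = {
        cls: np.zeros((len(t_samples), len(clusters)))
        for cls in ("gt_threshold", "le_threshold")
    }
    used = ignored = 0
    for seg in segments:
        pair = _orient(seg, targets, refs)
        if pair is None:
            ignored += 1
            continue
        t, r = pair
        cls = "gt_threshold" if seg.length_cm > threshold_cm else "le_threshold"
        totals[cls][t_index[t], c_index[refs[r]]] += seg.length_cm
        used += 1

    def to_matrix(per_ind: np.ndarray, cls: str) -> SharingMatrix:
        df = pd.DataFrame(
            np.full((len(groups), len(clusters)), np.nan),
            index=pd.Index(groups, name="target_group"),
            columns=pd.Index(clusters, name="reference_cluster"),
        )
        for g in groups:
            members = [t_index[s] for s in t_samples if targets[s] == g]
            df.loc[g] = per_ind[members].mean(axis=0)
        return SharingMatrix(df, cls, threshold_cm)

    long_m = to_matrix(totals["gt_threshold"], "gt_threshold")
    short_m = to_matrix(totals["le_threshold"], "le_threshold")
    all_m = to_matrix(totals["gt_threshold"] + totals["le_threshold"], "all")
    return SharingMatrixSet(
        all=all_m,
        gt_threshold=long_m,
        le_threshold=short_m,
        n_segments_used=used,
        n_segments_ignored=ignored,
    )


def ibd_intervals_for_individual(
    segments: Iterable[IBDSegment],
    individual: str,
    ref_group: set[str] | Sequence[str],
    min_cm: float = DEFAULT_THRESHOLD_CM,
) -> dict[str, list[tuple[int, int]]]:
    """Merged physical spans of one individual's long segments to a reference set.

    Segments between ``individual`` and any member of ``ref_group`` with
    ``length_cm > min_cm`` are collected per chromosome and merged when
    overlapping (coverage semantics), yielding intervals usable as a
    genotype-level mask.  An empty result is valid.
    """
    ref_group = set(ref_group)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        if seg.length_cm <= min_cm:
            continue
        if seg.sample1 == individual and seg.sample2 in ref_group:
            pass
        elif seg.sample2 == individual and seg.sample1 in ref_group:
            pass
        else:
            continue
        by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [spans[0]]
        for start, end in spans[1:]:
            if start <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], end))
            else:
                out.append((start, end))
        merged[chrom] = out
    return merged


def interval_mask(
    intervals: Mapping[str, Sequence[tuple[int, int]]],
    variants: Sequence[VariantKey],
) -> np.ndarray:
    """Boolean per-variant mask: True where the position falls in an interval."""
    mask = np.zeros(len(variants), dtype=bool)
    for v, key in enumerate(variants):
        for start, end in intervals.get(key.chrom, ()):
            if start <= key.pos <= end:
                mask[v] = True
                break
    return mask


def write_intervals_bed(
    intervals: Mapping[str, Sequence[tuple[int, int]]], path
) -> None:
    """Write merged intervals as BED (converted to 0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for start, end in intervals[chrom]:
                fh.write(f"{chrom}\t{start - 1}\t{end}\n")
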