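"""Chance-corrected imputation quality scoring (IQS).

The IQS of a set of imputed genotypes against truth calls is Cohen's kappa
computed on a 3x3 truth-by-imputed genotype table:

    IQS = (P_o - P_c) / (1 - P_c)

where ``P_o`` is the observed agreement proportion and ``P_c`` the agreement
expected by chance from the table margins.  By default the table cells are
posterior-weighted fractional counts — cell (j, k) accumulates, over genotypes
whose truth call is j, the posterior probability of imputed genotype k — so
the score uses the full posterior trio rather than only the best-guess call.
A hard-call mode (argmax trios collapsed to point masses) is available for
cross-checks.

An IQS of 1 means perfect imputation; 0 means no better than chance (any
constant prediction scores exactly 0); the score is undefined when the chance
agreement is itself 1 (e.g. a monomorphic stratum perfectly predicted), in
which case a flagged undefined result is propagated rather than an arbitrary
0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .vcf_io import (
    MISSING,
    EvalAlignment,
    ImputedDataset,
    TruthGenotypes,
    align_imputed_truth,
)

__all__ = [
    "ContingencyTable3x3",
    "IQSResult",
    "StratumSpec",
    "Region",
    "read_bed",
    "build_contingency",
    "iqs_from_table",
    "iqs",
    "hard_call_gp",
    "iqs_stratified",
    "het_dosage_distribution",
]

#: 1 - P_c below this is treated as an undefined (degenerate) score.
DEGENERACY_EPS = 1e-12

#: Default MAF threshold separating rare from non-rare variants.
RARE_MAF_THRESHOLD = 0.01


@dataclass
class ContingencyTable3x3:
    """Truth (rows) by imputed-genotype-mass (columns) fractional counts."""

    n: np.ndarray  # (3, 3) fractional counts
    N: float  # number of genotypes included

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.shape != (3, 3):
            raise ValueError("contingency table must be 3x3")
        if (self.n < -1e-12).any():
            raise ValueError("negative cell in contingency table")

    @property
    def empty(self) -> bool:
        return self.N == 0

    def __add__(self, other: "ContingencyTable3x3") -> "ContingencyTable3x3":
        """Cell-wise pooling: the table of a pooled stratum is the sum."""
        return ContingencyTable3x3(self.n + other.n, self.N + other.N)


@dataclass
class IQSResult:
    p_o: float
    p_c: float
    iqs: float
    n_genotypes: float
    defined: bool

    @classmethod
    def undefined(cls, n_genotypes: float = 0.0) -> "IQSResult":
        return cls(np.nan, np.nan, np.nan, n_genotypes, False)


def build_contingency(gp: np.ndarray, truth: np.ndarray) -> ContingencyTable3x3:
    """Accumulate posterior mass into a truth x imputed table.

    ``gp`` is (..., 3) trios and ``truth`` the matching hard calls; genotypes
    with missing truth or a missing (NaN) trio are excluded.  Cell (j, k) is
    the summed probability of genotype k over entries with truth j, so row
    sums equal the truth genotype counts exactly.
    """
    gp = np.asarray(gp, dtype=float).reshape(-1, 3)
    truth = np.asarray(truth).reshape(-1)
    if gp.shape[0] != truth.shape[0]:
        raise ValueError("gp and truth lengths differ")
    keep = (truth != MISSING) & ~np.isnan(gp).any(axis=1)
    gp = gp[keep]
    truth = truth[keep]
    n = np.zeros((3, 3))
    for j in range(3):
        sel = truth == j
        if sel.any():
            n[j] = gp[sel].sum(axis=0)
    return ContingencyTable3x3(n, float(truth.shape[0]))


def iqs_from_table(t: ContingencyTable3x3) -> IQSResult:
    """Cohen's kappa of a (possibly fractional) 3x3 table.

    ``P_o`` is the diagonal mass over N; ``P_c`` the margin product sum over
    N^2.  An empty table or degenerate margins (1 - P_c ~ 0) yield a flagged
    undefined result instead of raising.
    """
    if t.empty:
        return IQSResult.undefined()
    p_o = float(np.trace(t.n)) / t.N
    rows = t.n.sum(axis=1)
    cols = t.n.sum(axis=0)
    p_c = float(rows @ cols) / (t.N * t.N)
    if 1.0 - p_c < DEGENERACY_EPS:
        return IQSResult(p_o, p_c, np.nan, t.N, False)
    return IQSResult(p_o, p_c, (p_o - p_c) / (1.0 - p_c), t.N, True)


def iqs(gp: np.ndarray, truth: np.ndarray) -> IQSResult:
    """IQS of a flat set of genotypes (convenience composition)."""
    return iqs_from_table(build_contingency(gp, truth))


def hard_call_gp(gp: np.ndarray) -> np.ndarray:
    """Collapse trios to point masses on the argmax genotype (ties -> smaller).

    Missing trios stay missing.  Used for the hard-call IQS cross-check mode.
    """
    gp = np.asarray(gp, dtype=float)
    missing = np.isnan(gp).any(axis=-1)
    idx = np.argmax(np.nan_to_num(gp, nan=-1.0), axis=-1)
    out = np.zeros_like(gp)
    np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
    out[missing] = np.nan
    return out


class Region(NamedTuple):
    """A named genomic interval, 1-based inclusive."""

    name: str
    chrom: str
    start: int
    end: int


def read_bed(path) -> list[Region]:
    """Read a BED file into 1-based inclusive regions.

    BED is 0-based half-open; conversion happens here, at the boundary.
    The optional 4th column provides the region name.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}
    )
    regions = []
    for i, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 else f"region{i}"
        regions.append(Region(name, str(row[0]), int(row[1]) + 1, int(row[2])))
    return regions


@dataclass
class StratumSpec:
    """How to partition genotypes before scoring.

    axis
        ``individual`` pools each sample's genotypes; ``variant`` pools each
        variant across samples; ``region`` pools genotypes of variants inside
        each region (regions may overlap — a variant contributes to every
        region containing it); ``maf_bin`` splits variants at
        ``maf_threshold`` into rare/common using truth-derived MAF; ``mask``
        splits genotype-wise by a boolean matrix (inside/outside).
    """

    axis: str
    regions: list[Region] | None = None
    maf_threshold: float = RARE_MAF_THRESHOLD
    mask: np.ndarray | None = None

    AXES = ("individual", "variant", "region", "maf_bin", "mask")

    def __post_init__(self) -> None:
        if self.axis not in self.AXES:
            raise ValueError(f"unknown stratum axis {self.axis!r}")
        if self.axis == "region" and not self.regions:
            raise ValueError("region axis requires a region list")
        if self.axis == "mask" and self.mask is None:
            raise ValueError("mask axis requires a boolean mask")


def _result_row(stratum: str, r: IQSResult) -> dict:
    return {
        "stratum": stratum,
        "n_genotypes": r.n_genotypes,
        "p_o": r.p_o,
        "p_c": r.p_c,
        "iqs": r.iqs,
        "defined": r.defined,
    }


def iqs_stratified(
    imputed: ImputedDataset | EvalAlignment,
    truth: TruthGenotypes | None,
    spec: StratumSpec,
    hard_calls: bool = False,
    allow_swap: bool = False,
) -> pd.DataFrame:
    """IQS per stratum, as a table (stratum, n_genotypes, p_o, p_c, iqs, defined).

    Accepts either a raw (imputed, truth) pair — aligned here — or a
    pre-built :class:`EvalAlignment` with ``truth=None``.  Strata with zero
    evaluable genotypes get a flagged undefined row.
    """
    if isinstance(imputed, EvalAlignment):
        ev = imputed
    else:
        if truth is None:
            raise ValueError("truth required when passing an ImputedDataset")
        ev = align_imputed_truth(imputed, truth, allow_swap=allow_swap)
    gp = hard_call_gp(ev.gp) if hard_calls else ev.gp
    rows = []
    if spec.axis == "individual":
        for s, sample in enumerate(ev.samples):
            rows.append(_result_row(sample, iqs(gp[:, s], ev.calls[:, s])))
    elif spec.axis == "variant":
        for v, key in enumerate(ev.keys):
            rows.append(_result_row(str(key), iqs(gp[v], ev.calls[v])))
    elif spec.axis == "region":
        pos = np.array([k.pos for k in ev.keys])
        chrom = np.array([k.chrom for k in ev.keys])
        for reg in spec.regions:
            sel = (chrom == reg.chrom) & (pos >= reg.start) & (pos <= reg.end)
            rows.append(_result_row(reg.name, iqs(gp[sel], ev.calls[sel])))
    elif spec.axis == "maf_bin":
        rare = ev.maf < spec.maf_threshold
        for name, sel in (("rare", rare), ("common", ~rare)):
            rows.append(_result_row(name, iqs(gp[sel], ev.calls[sel])))
    else:  # mask
        mask = np.asarray(spec.mask, dtype=bool)
        if mask.shape != ev.calls.shape:
            raise ValueError("mask shape does not match aligned genotypes")
        for name, sel in (("inside", mask), ("outside", ~mask)):
            rows.append(_result_row(name, iqs(gp[sel], ev.calls[sel])))
    return pd.DataFrame(
        rows, columns=["stratum", "n_genotypes", "p_o", "p_c", "iqs", "defined"]
    )


def het_dosage_distribution(
    imputed: ImputedDataset | EvalAlignment,
    truth: TruthGenotypes | None,
    mask: np.ndarray,
    bin_width: float = 0.05,
    allow_swap: bool = False,
) -> pd.DataFrame:
    """Histogram imputed dosages at truth-heterozygous genotypes, split by a mask.

    The dosage ``p1 + 2*p2`` of a perfectly imputed heterozygote is 1.  The
    genotype-level boolean ``mask`` partitions the het genotypes (typically:
    inside vs outside long IBD intervals shared with relevant reference
    clusters).  Returns a table (bin_left, bin_right, count_inside,
    count_outside) with bins covering [0, 2].
    """
    if isinstance(imputed, EvalAlignment):
        ev = imputed
    else:
        if truth is None:
            raise ValueError("truth required when passing an ImputedDataset")
        ev = align_imputed_truth(imputed, truth, allow_swap=allow_swap)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ev.calls.shape:
        raise ValueError("mask shape does not match aligned genotypes")
    dosage = ev.gp[:, :, 1] + 2.0 * ev.gp[:, :, 2]
    het = (ev.calls == 1) & ~np.isnan(dosage)
    edges = np.arange(0.0, 2.0 + bin_width / 2, bin_width)
    if edges[-1] < 2.0:
        edges = np.append(edges, 2.0)
    inside, _ = np.histogram(np.clip(dosage[het & mask], 0, 2), bins=edges)
    outside, _ = np.histogram(np.clip(dosage[het & ~mask], 0, 2), bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count_inside": inside,
            "count_outside": outside,
        }
    )
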