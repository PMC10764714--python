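"""Reading, writing and aligning genotype data in VCF dialects.

Imputation runs are represented as variants x samples matrices of posterior
genotype probability trios (the VCF ``GP`` FORMAT field, or any compatible
three-float field).  Truth sets are hard diploid calls coded as alt-allele
counts {0, 1, 2} with -1 for missing.  Variant identity is the exact tuple
(chrom, pos, ref, alt); reconciliation of ref/alt-swapped records between two
runs is opt-in and never attempts strand flips, which are ambiguous for A/T
and C/G variants.

Coordinates are 1-based inclusive throughout (VCF convention); BED regions are
converted from 0-based half-open at the parsing boundary (see
:func:`iqsmerge.metrics.read_bed`).
"""

from __future__ import annotations

import gzip
import math
import re
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from cyvcf2 import VCF

__all__ = [
    "MISSING",
    "VCFParseError",
    "ConfigurationError",
    "VariantKey",
    "GenotypePosterior",
    "ImputedDataset",
    "TruthGenotypes",
    "read_imputed_vcf",
    "read_truth_vcf",
    "write_imputed_vcf",
    "match_keys",
    "align_datasets",
    "Alignment",
    "AlignedPair",
    "align_imputed_truth",
    "EvalAlignment",
]

#: Sentinel for a missing hard genotype call.
MISSING = -1

#: Trio sums further than this from 1 are flagged and treated as missing.
GP_SUM_TOLERANCE = 1e-2

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class VCFParseError(ValueError):
    """A VCF record (or file) could not be interpreted."""


class ConfigurationError(ValueError):
    """The requested field/option does not match the input data."""


class VariantKey(NamedTuple):
    """Exact variant identity used for cross-run matching."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def validate(self) -> "VariantKey":
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not _ALLELE_RE.match(allele):
                raise ValueError(
                    f"non-ACGT or symbolic allele {allele!r} at {self.chrom}:{self.pos}"
                )
        return self

    def swapped(self) -> "VariantKey":
        """The same site with ref and alt exchanged."""
        return VariantKey(self.chrom, self.pos, self.alt, self.ref)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class GenotypePosterior:
    """Posterior probabilities of the three diploid genotypes at one site.

    ``p0``, ``p1``, ``p2`` are the probabilities of carrying 0, 1 or 2 copies
    of the alternate allele.  After normalisation the trio sums to 1, which
    guarantees ``p_max >= 1/3``.
    """

    p0: float
    p1: float
    p2: float

    @property
    def p_max(self) -> float:
        return max(self.p0, self.p1, self.p2)

    @property
    def genotype(self) -> int:
        """Most likely genotype; ties break toward the smaller code."""
        return int(np.argmax([self.p0, self.p1, self.p2]))

    @property
    def dosage(self) -> float:
        """Expected alternate-allele count, ``p1 + 2 * p2``."""
        return self.p1 + 2.0 * self.p2

    def as_array(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2], dtype=float)

    def normalized(self, tol: float = GP_SUM_TOLERANCE) -> "GenotypePosterior":
        s = self.p0 + self.p1 + self.p2
        if not math.isfinite(s) or abs(s - 1.0) > tol:
            raise ValueError(f"trio sums to {s}, further than {tol} from 1")
        return GenotypePosterior(self.p0 / s, self.p1 / s, self.p2 / s)


def _check_unique(items: Sequence, what: str) -> None:
    if len(set(items)) != len(items):
        raise ValueError(f"duplicate {what} in dataset")


@dataclass
class ImputedDataset:
    """One imputation run: posterior trios over variants x samples.

    ``gp`` has shape ``(n_variants, n_samples, 3)``; a missing genotype is an
    all-NaN trio and is excluded from every downstream metric rather than
    replaced by a fabricated trio.
    """

    variants: list[VariantKey]
    samples: list[str]
    gp: np.ndarray
    variant_quality: np.ndarray | None = None
    source: str = ""
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gp = np.asarray(self.gp, dtype=float)
        if self.gp.shape != (len(self.variants), len(self.samples), 3):
            raise ValueError(
                f"gp shape {self.gp.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        _check_unique(self.variants, "variant keys")
        _check_unique(self.samples, "sample IDs")
        if self.variant_quality is not None:
            self.variant_quality = np.asarray(self.variant_quality, dtype=float)
            if self.variant_quality.shape != (len(self.variants),):
                raise ValueError("variant_quality length mismatch")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def missing_mask(self) -> np.ndarray:
        """Boolean (variants x samples), True where the trio is missing."""
        return np.isnan(self.gp).any(axis=2)

    @property
    def p_max(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmax(self.gp, axis=2)

    @property
    def hard_calls(self) -> np.ndarray:
        """Argmax genotypes (ties to the smaller code); MISSING where absent."""
        calls = np.argmax(np.nan_to_num(self.gp, nan=-1.0), axis=2).astype(np.int8)
        calls[self.missing_mask()] = MISSING
        return calls

    @property
    def dosage(self) -> np.ndarray:
        """Expected alt-allele dosage ``p1 + 2*p2``; NaN where missing."""
        return self.gp[:, :, 1] + 2.0 * self.gp[:, :, 2]

    def trio(self, v: int, s: int) -> GenotypePosterior | None:
        row = self.gp[v, s]
        if np.isnan(row).any():
            return None
        return GenotypePosterior(*row)

    def subset_variants(self, idx: Sequence[int]) -> "ImputedDataset":
        idx = list(idx)
        return ImputedDataset(
            variants=[self.variants[i] for i in idx],
            samples=list(self.samples),
            gp=self.gp[idx],
            variant_quality=None
            if self.variant_quality is None
            else self.variant_quality[idx],
            source=self.source,
        )


@dataclass
class TruthGenotypes:
    """Hard truth calls (alt-allele counts) used as the evaluation gold set."""

    variants: list[VariantKey]
    samples: list[str]
    calls: np.ndarray  # (variants, samples) int8 in {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValueError("calls shape mismatch")
        ok = np.isin(self.calls, [0, 1, 2, MISSING])
        if not ok.all():
            raise ValueError("truth calls outside {0,1,2,missing}")
        _check_unique(self.variants, "variant keys")
        _check_unique(self.samples, "sample IDs")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def alt_frequency(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing calls."""
        valid = self.calls != MISSING
        n_alleles = 2.0 * valid.sum(axis=1)
        alt = np.where(valid, self.calls, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency in [0, 0.5]."""
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def mac(self) -> np.ndarray:
        """Per-variant minor allele count over non-missing calls."""
        valid = self.calls != MISSING
        n_alleles = 2 * valid.sum(axis=1)
        alt = np.where(valid, self.calls, 0).sum(axis=1)
        return np.minimum(alt, n_alleles - alt)

    def subset_variants(self, idx: Sequence[int]) -> "TruthGenotypes":
        idx = list(idx)
        return TruthGenotypes(
            variants=[self.variants[i] for i in idx],
            samples=list(self.samples),
            calls=self.calls[idx],
        )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _iter_biallelic(vcf: VCF, region: str | None, qc: dict):
    """Yield biallelic SNV/indel records, counting exclusions in ``qc``."""
    records = vcf(region) if region else vcf
    for rec in records:
        if len(rec.ALT) != 1:
            qc["multiallelic_excluded"] = qc.get("multiallelic_excluded", 0) + 1
            continue
        try:
            key = VariantKey(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]).validate()
        except ValueError:
            qc["symbolic_excluded"] = qc.get("symbolic_excluded", 0) + 1
            continue
        yield key, rec


def read_imputed_vcf(
    path,
    gp_field_name: str = "GP",
    region: str | None = None,
    quality_tag: str | None = "R2",
    source: str = "",
) -> ImputedDataset:
    """Load an imputed VCF into an :class:`ImputedDataset`.

    Parameters
    ----------
    path
        VCF file (plain or bgzip).
    gp_field_name
        FORMAT field carrying the three genotype posterior probabilities
        per biallelic genotype.  Server and local pipelines emit different
        dialects, hence configurable.
    region
        Optional ``chrom:start-end`` restriction (requires an index for
        compressed files).
    quality_tag
        INFO tag to read as per-variant quality (e.g. the RSQ emitted by the
        imputation run); missing tags yield NaN.

    Trios whose sum is within ``1e-2`` of 1 are renormalised to sum exactly 1;
    larger deviations are counted in ``qc['bad_sum']`` and the genotype set
    missing.  Missing trios stay missing — nothing is fabricated.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    qc: dict = {}
    keys: list[VariantKey] = []
    rows: list[np.ndarray] = []
    quality: list[float] = []
    n_records = 0
    n_field_absent = 0
    for key, rec in _iter_biallelic(vcf, region, qc):
        n_records += 1
        try:
            arr = rec.format(gp_field_name)
        except KeyError:
            # field not declared in the header at all
            raise ConfigurationError(
                f"FORMAT field {gp_field_name!r} not declared in the header of {path}"
            ) from None
        if arr is None:
            n_field_absent += 1
            rows.append(np.full((len(samples), 3), np.nan))
            keys.append(key)
            quality.append(np.nan)
            continue
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(samples), 3):
            raise VCFParseError(
                f"{gp_field_name} at {key} has shape {arr.shape}, expected (n_samples, 3)"
            )
        trio_sum = arr.sum(axis=1)
        bad = ~np.isfinite(trio_sum) | (np.abs(trio_sum - 1.0) > GP_SUM_TOLERANCE)
        n_bad = int((bad & np.isfinite(trio_sum)).sum())
        if n_bad:
            qc["bad_sum"] = qc.get("bad_sum", 0) + n_bad
        arr[bad] = np.nan
        with np.errstate(invalid="ignore"):
            arr = arr / trio_sum[:, None]
        arr[bad] = np.nan
        rows.append(arr)
        keys.append(key)
        q = rec.INFO.get(quality_tag) if quality_tag else None
        quality.append(float(q) if q is not None else np.nan)
    if n_records and n_field_absent == n_records:
        raise ConfigurationError(
            f"FORMAT field {gp_field_name!r} absent on every record of {path}"
        )
    qc["n_records"] = n_records
    gp = np.array(rows) if rows else np.empty((0, len(samples), 3))
    vq = np.array(quality) if quality else None
    return ImputedDataset(keys, samples, gp, variant_quality=vq, source=source, qc=qc)


def read_truth_vcf(path, region: str | None = None) -> TruthGenotypes:
    """Load hard diploid calls from a sequence VCF as the truth set.

    Half-missing genotypes (e.g. ``./1``) map to missing.  Haploid or
    polyploid calls are a record-level error: ploidy must be uniform for
    alt-allele-count coding to be meaningful.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    qc: dict = {}
    keys: list[VariantKey] = []
    rows: list[np.ndarray] = []
    for key, rec in _iter_biallelic(vcf, region, qc):
        calls = np.full(len(samples), MISSING, dtype=np.int8)
        for s, g in enumerate(rec.genotypes):
            if len(g) != 3:  # [a0, a1, phased] for diploid
                raise VCFParseError(
                    f"non-diploid genotype for sample {samples[s]} at {key}"
                )
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                continue  # fully or half missing
            calls[s] = a0 + a1
        keys.append(key)
        rows.append(calls)
    arr = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), np.int8)
    return TruthGenotypes(keys, samples, arr)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def write_imputed_vcf(
    dataset: ImputedDataset,
    path,
    provenance: np.ndarray | None = None,
    provenance_labels: dict[int, str] | None = None,
) -> None:
    """Write an :class:`ImputedDataset` as a VCF with GT, GP and DS fields.

    The hard call is the argmax genotype and the dosage is ``p1 + 2*p2``.
    ``provenance`` is an optional (variants x samples) integer code matrix
    emitted as the per-genotype string field ``SRC`` using
    ``provenance_labels`` for decoding (see :mod:`iqsmerge.hybrid`).
    Round-trips through :func:`read_imputed_vcf` within 1e-4 per probability.
    """
    calls = dataset.hard_calls
    dosage = dataset.dosage
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    has_src = provenance is not None
    fmt = "GT:GP:DS" + (":SRC" if has_src else "")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if dataset.source:
            fh.write(f"##source={dataset.source}\n")
        for chrom in dict.fromkeys(k.chrom for k in dataset.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality from the run">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Most likely genotype">\n')
        fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior probabilities">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alt allele dosage">\n')
        if has_src:
            fh.write('##FORMAT=<ID=SRC,Number=1,Type=String,Description="Merge provenance label">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(dataset.samples) + "\n")
        for v, key in enumerate(dataset.variants):
            info = "."
            if dataset.variant_quality is not None and np.isfinite(
                dataset.variant_quality[v]
            ):
                info = f"R2={_fmt_float(dataset.variant_quality[v])}"
            cols = [key.chrom, str(key.pos), ".", key.ref, key.alt, ".", ".", info, fmt]
            for s in range(dataset.n_samples):
                trio = dataset.gp[v, s]
                if np.isnan(trio).any():
                    entry = "./.:.:."
                else:
                    entry = (
                        gt_strings[int(calls[v, s])]
                        + ":" + ",".join(_fmt_float(p) for p in trio)
                        + ":" + _fmt_float(dosage[v, s])
                    )
                if has_src:
                    code = int(provenance[v, s])
                    label = (provenance_labels or {}).get(code, str(code))
                    entry += ":" + label
                cols.append(entry)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


class AlignedPair(NamedTuple):
    key: VariantKey
    a_idx: int
    b_idx: int
    swapped: bool  # b's record had (ref, alt) exchanged relative to a's


def match_keys(
    a_keys: Sequence[VariantKey],
    b_keys: Sequence[VariantKey],
    allow_swap: bool = False,
) -> tuple[list[AlignedPair], list[int], list[int]]:
    """Match variant keys exactly, optionally reconciling ref/alt swaps.

    Returns (pairs, a-only indices, b-only indices).  When ``allow_swap`` is
    set and b carries the same site with ref and alt exchanged, the pair is
    matched with ``swapped=True`` — the caller must reverse b's trios
    (p2, p1, p0) before comparing, since genotype codes count alt alleles.
    """
    _check_unique(a_keys, "variant keys (a)")
    _check_unique(b_keys, "variant keys (b)")
    b_index = {k: i for i, k in enumerate(b_keys)}
    pairs: list[AlignedPair] = []
    matched_b: set[int] = set()
    only_a: list[int] = []
    for i, key in enumerate(a_keys):
        j = b_index.get(key)
        swapped = False
        if j is None and allow_swap:
            j = b_index.get(key.swapped())
            swapped = j is not None
        if j is None:
            only_a.append(i)
        else:
            pairs.append(AlignedPair(key, i, j, swapped))
            matched_b.add(j)
    only_b = [j for j in range(len(b_keys)) if j not in matched_b]
    return pairs, only_a, only_b


def reverse_trios(gp: np.ndarray) -> np.ndarray:
    """Relabel trios for a ref/alt-swapped record: (p0,p1,p2) -> (p2,p1,p0)."""
    return gp[..., ::-1]


@dataclass
class Alignment:
    """Variant/sample correspondence between two imputation runs.

    ``samples`` is the sample intersection in canonical (run-a) order;
    ``a_sample_idx``/``b_sample_idx`` map it into each run.  ``intersection``
    holds matched variant pairs (evaluation set); the union additionally
    includes single-source variants (merge set).
    """

    samples: list[str]
    a_sample_idx: np.ndarray
    b_sample_idx: np.ndarray
    intersection: list[AlignedPair]
    only_a: list[int]
    only_b: list[int]

    @property
    def n_union(self) -> int:
        return len(self.intersection) + len(self.only_a) + len(self.only_b)

    def union_keys(
        self, a: "ImputedDataset", b: "ImputedDataset"
    ) -> list[VariantKey]:
        keys = [p.key for p in self.intersection]
        keys += [a.variants[i] for i in self.only_a]
        keys += [b.variants[j] for j in self.only_b]
        return keys


def align_datasets(
    a: ImputedDataset,
    b: ImputedDataset,
    allow_swap: bool = False,
) -> Alignment:
    """Align two imputation runs on shared samples and variant keys."""
    common = [s for s in a.samples if s in set(b.samples)]
    if not common:
        raise ValueError("no samples in common between the two runs")
    a_pos = {s: i for i, s in enumerate(a.samples)}
    b_pos = {s: i for i, s in enumerate(b.samples)}
    pairs, only_a, only_b = match_keys(a.variants, b.variants, allow_swap)
    return Alignment(
        samples=common,
        a_sample_idx=np.array([a_pos[s] for s in common]),
        b_sample_idx=np.array([b_pos[s] for s in common]),
        intersection=pairs,
        only_a=only_a,
        only_b=only_b,
    )


@dataclass
class EvalAlignment:
    """Imputed posteriors aligned against truth calls, ready for metrics.

    Arrays are restricted to the shared variants and samples; ``maf`` is the
    per-variant minor allele frequency computed from the truth calls (never
    from imputed dosages).
    """

    keys: list[VariantKey]
    samples: list[str]
    gp: np.ndarray  # (V, S, 3)
    calls: np.ndarray  # (V, S)
    maf: np.ndarray  # (V,)

    @property
    def n_variants(self) -> int:
        return len(self.keys)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def align_imputed_truth(
    imputed: ImputedDataset,
    truth: TruthGenotypes,
    allow_swap: bool = False,
) -> EvalAlignment:
    """Restrict an imputation run and a truth set to their shared index."""
    common = [s for s in imputed.samples if s in set(truth.samples)]
    if not common:
        raise ValueError("no samples in common between imputed run and truth")
    i_pos = {s: i for i, s in enumerate(imputed.samples)}
    t_pos = {s: i for i, s in enumerate(truth.samples)}
    i_idx = np.array([i_pos[s] for s in common])
    t_idx = np.array([t_pos[s] for s in common])
    pairs, _, _ = match_keys(imputed.variants, truth.variants, allow_swap)
    if not pairs:
        raise ValueError("no variants in common between imputed run and truth")
    vi = np.array([p.a_idx for p in pairs])
    vt = np.array([p.b_idx for p in pairs])
    gp = imputed.gp[np.ix_(vi, i_idx)]
    swapped = np.array([p.swapped for p in pairs])
    if swapped.any():
        gp = gp.copy()
        gp[swapped] = reverse_trios(gp[swapped])
    maf = truth.maf()[vt]
    return EvalAlignment(
        keys=[p.key for p in pairs],
        samples=common,
        gp=gp,
        calls=truth.calls[np.ix_(vt, t_idx)],
        maf=maf,
    )
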