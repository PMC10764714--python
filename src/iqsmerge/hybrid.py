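"""Most-confident-vote combination (HYB) of two imputation runs.

Two imputation runs of the same target samples — typically one against a
study-specific panel and one against a large public panel reached through a
server — are merged genotype by genotype.  At each genotype present in both
runs, the posterior trio with the larger maximum probability wins, but the
priority run (by default run B, the server run) is kept unless the other
run's maximum exceeds it by more than a margin ``delta`` (default 0.05):

    keep A  iff  p_max(A) > p_max(B) + delta        (strict)

The retained trio is copied unchanged — never blended — and selection is
per genotype, so two individuals can draw from different runs at the same
variant.  Variants imputed by only one run pass through as-is, giving a
merged set covering the union of the two runs' variants.

Genotypes where both runs' most likely genotype agrees are labelled Accord,
disagreements Discord; agreement is empirically a strong indicator of
correct imputation, which is what makes the confidence vote effective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .vcf_io import (
    MISSING,
    Alignment,
    GenotypePosterior,
    ImputedDataset,
    TruthGenotypes,
    align_datasets,
    reverse_trios,
)

__all__ = [
    "HybridConfig",
    "MergeProvenance",
    "select_trio",
    "merge_runs",
    "classify_concordance",
    "accord_split_iqs",
    "SOURCE_LABELS",
    "CONCORDANCE_LABELS",
]

# provenance codes
A_ONLY, B_ONLY, A_SELECTED, B_SELECTED, NO_DATA = 0, 1, 2, 3, -1
SOURCE_LABELS = {
    A_ONLY: "A_only",
    B_ONLY: "B_only",
    A_SELECTED: "A_selected",
    B_SELECTED: "B_selected",
    NO_DATA: "missing",
}
# concordance codes
NA, ACCORD, DISCORD = 0, 1, 2
CONCORDANCE_LABELS = {NA: "n/a", ACCORD: "Accord", DISCORD: "Discord"}


@dataclass(frozen=True)
class HybridConfig:
    """Selection rule parameters.

    delta
        Priority margin: the non-priority run must beat the priority run's
        maximum probability by more than this to be retained.  The default
        0.05 absorbs the systematic ~1e-2 inflation of maxima that different
        imputation software produce, where nothing is gained by switching.
    priority_source
        'b' (default) or 'a': which run wins when the maxima are within
        delta of each other, including exact ties.
    """

    delta: float = 0.05
    priority_source: str = "b"

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta < 1.0):
            raise ValueError(f"delta must be in [0, 1), got {self.delta}")
        if self.priority_source not in ("a", "b"):
            raise ValueError("priority_source must be 'a' or 'b'")


def select_trio(
    a: GenotypePosterior | None,
    b: GenotypePosterior | None,
    cfg: HybridConfig = HybridConfig(),
) -> tuple[GenotypePosterior | None, str]:
    """Apply the most-confident-vote rule to one genotype.

    Returns the retained trio (unchanged) and its provenance label.  A
    missing trio on one side passes the other through as ``A_only``/``B_only``;
    both missing yields ``(None, 'missing')``.
    """
    if a is None and b is None:
        return None, SOURCE_LABELS[NO_DATA]
    if b is None:
        return a, SOURCE_LABELS[A_ONLY]
    if a is None:
        return b, SOURCE_LABELS[B_ONLY]
    if cfg.priority_source == "b":
        take_a = a.p_max > b.p_max + cfg.delta
    else:
        take_a = not (b.p_max > a.p_max + cfg.delta)
    if take_a:
        return a, SOURCE_LABELS[A_SELECTED]
    return b, SOURCE_LABELS[B_SELECTED]


def classify_concordance(
    a: GenotypePosterior | None, b: GenotypePosterior | None
) -> str:
    """'Accord' if both runs' most likely genotype agrees, else 'Discord'.

    Argmax ties within a trio break toward the smaller genotype code.  A
    missing trio on either side yields 'n/a'.
    """
    if a is None or b is None:
        return CONCORDANCE_LABELS[NA]
    return (
        CONCORDANCE_LABELS[ACCORD]
        if a.genotype == b.genotype
        else CONCORDANCE_LABELS[DISCORD]
    )


@dataclass
class MergeProvenance:
    """Per-genotype selection and concordance labels for a merged dataset.

    ``source`` and ``concordance`` are (union variants x samples) code
    matrices; decode with :data:`SOURCE_LABELS` / :data:`CONCORDANCE_LABELS`.
    Accord/Discord is defined only on the variant intersection.
    """

    source: np.ndarray  # int8 codes
    concordance: np.ndarray  # int8 codes
    n_intersection: int
    n_only_a: int
    n_only_b: int

    def to_frame(self, merged: ImputedDataset) -> pd.DataFrame:
        """Long-format provenance (chrom, pos, ref, alt, sample, source, concordance)."""
        rows = []
        for v, key in enumerate(merged.variants):
            for s, sample in enumerate(merged.samples):
                rows.append(
                    (
                        key.chrom,
                        key.pos,
                        key.ref,
                        key.alt,
                        sample,
                        SOURCE_LABELS[int(self.source[v, s])],
                        CONCORDANCE_LABELS[int(self.concordance[v, s])],
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "ref", "alt", "sample", "source", "concordance"],
        )


def _vector_select(
    gp_a: np.ndarray, gp_b: np.ndarray, cfg: HybridConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised selection over (V, S, 3) trio stacks -> (gp, source, concordance)."""
    miss_a = np.isnan(gp_a).any(axis=2)
    miss_b = np.isnan(gp_b).any(axis=2)
    with np.errstate(invalid="ignore"):
        pmax_a = np.nanmax(np.where(miss_a[..., None], -np.inf, gp_a), axis=2)
        pmax_b = np.nanmax(np.where(miss_b[..., None], -np.inf, gp_b), axis=2)
    if cfg.priority_source == "b":
        take_a = pmax_a > pmax_b + cfg.delta
    else:
        take_a = ~(pmax_b > pmax_a + cfg.delta)
    source = np.where(take_a, A_SELECTED, B_SELECTED).astype(np.int8)
    source[miss_b & ~miss_a] = A_ONLY
    source[miss_a & ~miss_b] = B_ONLY
    source[miss_a & miss_b] = NO_DATA
    use_a = (source == A_SELECTED) | (source == A_ONLY)
    gp = np.where(use_a[..., None], gp_a, gp_b)
    gp[source == NO_DATA] = np.nan
    arg_a = np.argmax(np.nan_to_num(gp_a, nan=-1.0), axis=2)
    arg_b = np.argmax(np.nan_to_num(gp_b, nan=-1.0), axis=2)
    conc = np.where(arg_a == arg_b, ACCORD, DISCORD).astype(np.int8)
    conc[miss_a | miss_b] = NA
    return gp, source, conc


def merge_runs(
    a: ImputedDataset,
    b: ImputedDataset,
    cfg: HybridConfig = HybridConfig(),
    allow_swap: bool = False,
    alignment: Alignment | None = None,
) -> tuple[ImputedDataset, MergeProvenance]:
    """Merge two runs into the HYB dataset over the union of their variants.

    Intersection genotypes are resolved by :func:`select_trio` (vectorised);
    single-source variants are copied through with ``A_only``/``B_only``
    provenance.  Ref/alt-swap pairs (when ``allow_swap``) have run B's trios
    reversed before selection so both runs count the same allele.
    """
    if alignment is None:
        alignment = align_datasets(a, b, allow_swap=allow_swap)
    al = alignment
    n_union = al.n_union
    n_samples = len(al.samples)
    gp = np.full((n_union, n_samples, 3), np.nan)
    source = np.full((n_union, n_samples), NO_DATA, dtype=np.int8)
    conc = np.full((n_union, n_samples), NA, dtype=np.int8)

    if al.intersection:
        ai = np.array([p.a_idx for p in al.intersection])
        bi = np.array([p.b_idx for p in al.intersection])
        gp_a = a.gp[np.ix_(ai, al.a_sample_idx)]
        gp_b = b.gp[np.ix_(bi, al.b_sample_idx)]
        swapped = np.array([p.swapped for p in al.intersection])
        if swapped.any():
            gp_b = gp_b.copy()
            gp_b[swapped] = reverse_trios(gp_b[swapped])
        sel_gp, sel_src, sel_conc = _vector_select(gp_a, gp_b, cfg)
        k = len(al.intersection)
        gp[:k], source[:k], conc[:k] = sel_gp, sel_src, sel_conc
    off = len(al.intersection)
    if al.only_a:
        gp_a = a.gp[np.ix_(al.only_a, al.a_sample_idx)]
        gp[off : off + len(al.only_a)] = gp_a
        src = np.where(np.isnan(gp_a).any(axis=2), NO_DATA, A_ONLY)
        source[off : off + len(al.only_a)] = src.astype(np.int8)
        off += len(al.only_a)
    if al.only_b:
        gp_b = b.gp[np.ix_(al.only_b, al.b_sample_idx)]
        gp[off : off + len(al.only_b)] = gp_b
        src = np.where(np.isnan(gp_b).any(axis=2), NO_DATA, B_ONLY)
        source[off : off + len(al.only_b)] = src.astype(np.int8)

    merged = ImputedDataset(
        variants=al.union_keys(a, b),
        samples=list(al.samples),
        gp=gp,
        source=f"HYB({a.source or 'A'},{b.source or 'B'})",
    )
    prov = MergeProvenance(
        source=source,
        concordance=conc,
        n_intersection=len(al.intersection),
        n_only_a=len(al.only_a),
        n_only_b=len(al.only_b),
    )
    return merged, prov


def accord_split_iqs(
    a: ImputedDataset,
    b: ImputedDataset,
    merged: ImputedDataset,
    truth: TruthGenotypes,
    allow_swap: bool = False,
) -> pd.DataFrame:
    """Per-individual report of imputation accuracy inside Accord and Discord.

    For each individual on the variant intersection of the two runs:
    the fraction of genotypes in Accord; within Accord, the fraction whose
    shared argmax matches truth; within Discord, the fraction where each
    source's argmax (and the merged HYB argmax) matches truth; plus IQS of
    each source restricted to each set.  Individuals with an empty Discord
    set get flagged NaN entries.
    """
    ev_a = metrics.align_imputed_truth(a, truth, allow_swap=allow_swap)
    ev_b = metrics.align_imputed_truth(b, truth, allow_swap=allow_swap)
    ev_m = metrics.align_imputed_truth(merged, truth, allow_swap=allow_swap)
    # restrict all three to the common (key, sample) index
    common_keys = [k for k in ev_m.keys if k in set(ev_a.keys) & set(ev_b.keys)]
    samples = [s for s in ev_m.samples if s in set(ev_a.samples) & set(ev_b.samples)]

    def take(ev, keys, smps):
        kpos = {k: i for i, k in enumerate(ev.keys)}
        spos = {s: i for i, s in enumerate(ev.samples)}
        vi = np.array([kpos[k] for k in keys])
        si = np.array([spos[s] for s in smps])
        return ev.gp[np.ix_(vi, si)], ev.calls[np.ix_(vi, si)]

    gp_a, calls = take(ev_a, common_keys, samples)
    gp_b, _ = take(ev_b, common_keys, samples)
    gp_m, _ = take(ev_m, common_keys, samples)

    miss = (
        np.isnan(gp_a).any(axis=2)
        | np.isnan(gp_b).any(axis=2)
        | np.isnan(gp_m).any(axis=2)
        | (calls == MISSING)
    )
    arg_a = np.argmax(np.nan_to_num(gp_a, nan=-1.0), axis=2)
    arg_b = np.argmax(np.nan_to_num(gp_b, nan=-1.0), axis=2)
    arg_m = np.argmax(np.nan_to_num(gp_m, nan=-1.0), axis=2)
    accord = (arg_a == arg_b) & ~miss
    discord = (arg_a != arg_b) & ~miss

    rows = []
    for s, sample in enumerate(samples):
        n_eval = int((~miss[:, s]).sum())
        acc = accord[:, s]
        dis = discord[:, s]
        n_acc, n_dis = int(acc.sum()), int(dis.sum())
        row = {
            "sample": sample,
            "n_genotypes": n_eval,
            "accord_fraction": n_acc / n_eval if n_eval else np.nan,
            "discord_fraction": n_dis / n_eval if n_eval else np.nan,
        }
        row["accord_correct"] = (
            float((arg_a[acc, s] == calls[acc, s]).mean()) if n_acc else np.nan
        )
        for name, arg in (("a", arg_a), ("b", arg_b), ("hyb", arg_m)):
            row[f"discord_correct_{name}"] = (
                float((arg[dis, s] == calls[dis, s]).mean()) if n_dis else np.nan
            )
        for name, gp in (("a", gp_a), ("b", gp_b), ("hyb", gp_m)):
            row[f"iqs_accord_{name}"] = metrics.iqs(gp[acc, s], calls[acc, s]).iqs
            row[f"iqs_discord_{name}"] = metrics.iqs(gp[dis, s], calls[dis, s]).iqs
        row["discord_defined"] = n_dis > 0
        rows.append(row)
    return pd.DataFrame(rows)
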