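"""Switch-error-rate estimation from repeated phasing runs.

Population phasing is stochastic: running the same phaser K times with K
random seeds yields K haplotype configurations of identical genotypes.
Treating, for every pair of adjacent heterozygous sites of an individual,
the relative phase orientation reported by the majority of seeds as the
correct phase gives a truth-free approximation of the switch error rate
(SER): each replicate's SER is the fraction of adjacent het pairs whose
orientation disagrees with the consensus, and the per-individual estimate
is the mean across replicates.  K defaults to 21 and must be odd so the
majority is unique.

Orientation is defined between *adjacent* heterozygous sites only — the
standard switch-error convention, under which a long-range switch is
counted once at its boundary.  For validation, :func:`true_ser` computes
the standard SER of one phasing against fully known truth haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .vcf_io import VCFParseError, VariantKey

__all__ = [
    "SeedPhasingSet",
    "SERResult",
    "read_seed_phasings",
    "relative_phase",
    "consensus_phase",
    "estimate_ser",
    "true_ser",
]

# orientation codes
SAME, OPPOSITE, UNAVAILABLE = 1, 0, -1


@dataclass
class SeedPhasingSet:
    """K phased configurations of the same genotypes.

    ``haplotypes`` has shape (K, variants, samples, 2) with 0/1 alleles;
    ``phased`` marks genotypes whose phase is known in that replicate.
    Unordered genotype content must be identical across replicates — phasing
    must not change genotypes — and K must be odd and at least 3 so that a
    strict majority always exists among full votes.
    """

    haplotypes: np.ndarray
    phased: np.ndarray
    samples: list[str]
    variants: list[VariantKey]
    seeds: list | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        k, v, s, two = self.haplotypes.shape
        if two != 2:
            raise ValueError("haplotypes last axis must be 2")
        if self.phased.shape != (k, v, s):
            raise ValueError("phased mask shape mismatch")
        if k < 3 or k % 2 == 0:
            raise ValueError(f"K must be odd and >= 3, got {k}")
        if v != len(self.variants) or s != len(self.samples):
            raise ValueError("variant/sample dimension mismatch")
        geno = np.sort(self.haplotypes, axis=3)
        if not (geno == geno[0]).all():
            raise ValueError(
                "replicates disagree on genotype content; phasing must preserve genotypes"
            )

    @property
    def K(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[2]

    def het_sites(self, individual: int) -> np.ndarray:
        """Indices of the individual's heterozygous sites, in variant order."""
        g = self.haplotypes[0, :, individual, :]
        return np.where(g.sum(axis=1) == 1)[0]


def read_seed_phasings(paths) -> SeedPhasingSet:
    """Load K phased VCFs (identical variants and samples) into a set.

    Phase is taken from the GT separator: '|' phased, '/' unphased.
    Missing genotypes are allowed and marked unphased everywhere.
    """
    paths = list(paths)
    haps, phased = [], []
    samples = variants = None
    for path in paths:
        try:
            vcf = VCF(str(path))
        except Exception as exc:
            raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
        these_samples = list(vcf.samples)
        keys, h_rows, p_rows = [], [], []
        for rec in vcf:
            if len(rec.ALT) != 1:
                continue
            keys.append(VariantKey(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
            h = np.zeros((len(these_samples), 2), dtype=np.int8)
            p = np.zeros(len(these_samples), dtype=bool)
            for s, g in enumerate(rec.genotypes):
                if len(g) != 3:
                    raise VCFParseError(f"non-diploid genotype in {path} at {keys[-1]}")
                a0, a1, is_phased = g
                if a0 < 0 or a1 < 0:
                    continue
                h[s] = (a0, a1)
                p[s] = bool(is_phased)
            h_rows.append(h)
            p_rows.append(p)
        if samples is None:
            samples, variants = these_samples, keys
        elif these_samples != samples or keys != variants:
            raise VCFParseError(f"{path} differs in samples or variants from the first replicate")
        haps.append(np.array(h_rows, dtype=np.int8))
        phased.append(np.array(p_rows))
    return SeedPhasingSet(
        haplotypes=np.stack(haps),
        phased=np.stack(phased),
        samples=samples,
        variants=variants,
        seeds=list(range(len(paths))),
    )


def relative_phase(alleles_i, alleles_j) -> str:
    """Orientation of two adjacent het genotypes: 'same' or 'opposite'.

    'same' iff the alternate allele sits on the same haplotype at both
    sites; the result is invariant to globally relabelling the two
    haplotypes of the individual.
    """
    ai = np.asarray(alleles_i)
    aj = np.asarray(alleles_j)
    if sorted(ai) != [0, 1] or sorted(aj) != [0, 1]:
        raise ValueError("both sites must be heterozygous")
    return "same" if int(ai[0]) == int(aj[0]) else "opposite"


def _orientation_matrix(pset: SeedPhasingSet, individual: int):
    """(K, n_pairs) orientation codes for one individual's adjacent het pairs.

    An entry is UNAVAILABLE in a replicate where either site of the pair is
    unphased in that replicate.
    """
    het = pset.het_sites(individual)
    if het.size < 2:
        return np.empty((pset.K, 0), dtype=np.int8), het
    alt_on_first = pset.haplotypes[:, het, individual, 0]  # (K, H)
    ok = pset.phased[:, het, individual]
    orient = np.where(
        alt_on_first[:, 1:] == alt_on_first[:, :-1], SAME, OPPOSITE
    ).astype(np.int8)
    orient[~(ok[:, 1:] & ok[:, :-1])] = UNAVAILABLE
    return orient, het


@dataclass
class ConsensusResult:
    orientations: np.ndarray  # (n_pairs,) SAME/OPPOSITE/UNAVAILABLE
    n_pairs: int
    n_tied_dropped: int


def consensus_phase(pset: SeedPhasingSet, individual: int) -> ConsensusResult:
    """Majority-vote orientation per adjacent het pair for one individual.

    With odd K and full votes the majority is strict; pairs where
    replicate-level exclusions leave an exact tie are dropped and counted.
    """
    orient, _ = _orientation_matrix(pset, individual)
    if orient.shape[1] == 0:
        return ConsensusResult(np.empty(0, dtype=np.int8), 0, 0)
    valid = orient != UNAVAILABLE
    same_votes = ((orient == SAME) & valid).sum(axis=0)
    total_votes = valid.sum(axis=0)
    consensus = np.full(orient.shape[1], UNAVAILABLE, dtype=np.int8)
    consensus[2 * same_votes > total_votes] = SAME
    consensus[2 * same_votes < total_votes] = OPPOSITE
    tied = (total_votes > 0) & (2 * same_votes == total_votes)
    consensus[tied] = UNAVAILABLE
    consensus[total_votes == 0] = UNAVAILABLE
    return ConsensusResult(consensus, int(orient.shape[1]), int(tied.sum()))


@dataclass
class SERResult:
    """Consensus-based SER estimates.

    ``per_individual`` is a table (sample, n_pairs, n_tied_dropped, mean_ser);
    ``per_replicate`` has one column per replicate.  The per-individual mean
    is the arithmetic mean of that individual's per-replicate rates.
    """

    per_individual: pd.DataFrame
    per_replicate: pd.DataFrame


def estimate_ser(pset: SeedPhasingSet) -> SERResult:
    """Estimate SER of every replicate against the majority consensus.

    Per replicate and individual, SER is the fraction of evaluable adjacent
    het pairs whose orientation differs from the consensus.  Individuals
    with no evaluable pair get a flagged NaN.
    """
    rows = []
    rep_rows = {}
    for s, sample in enumerate(pset.samples):
        orient, _ = _orientation_matrix(pset, s)
        cons = consensus_phase(pset, s)
        usable = (orient != UNAVAILABLE) & (cons.orientations != UNAVAILABLE)[None, :]
        mismatch = (orient != cons.orientations[None, :]) & usable
        n_eval = usable.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_rep = np.where(n_eval > 0, mismatch.sum(axis=1) / n_eval, np.nan)
        rep_rows[sample] = per_rep
        mean_ser = float(np.nanmean(per_rep)) if np.isfinite(per_rep).any() else np.nan
        rows.append(
            {
                "sample": sample,
                "n_pairs": cons.n_pairs,
                "n_tied_dropped": cons.n_tied_dropped,
                "mean_ser": mean_ser,
                "defined": bool(np.isfinite(per_rep).any()),
            }
        )
    per_replicate = pd.DataFrame(
        rep_rows, index=[f"replicate_{k}" for k in range(pset.K)]
    ).T
    return SERResult(per_individual=pd.DataFrame(rows), per_replicate=per_replicate)


def true_ser(
    haplotypes: np.ndarray,
    truth_haplotypes: np.ndarray,
    samples: list[str] | None = None,
    phased: np.ndarray | None = None,
) -> pd.DataFrame:
    """Standard SER of one phasing against fully phased truth haplotypes.

    Both inputs are (variants, samples, 2) allele arrays over identical
    variants.  Per individual, SER is the fraction of adjacent het pairs
    whose relative orientation differs between estimate and truth; pairs
    with an unphased site in the estimate are excluded.
    """
    est = np.asarray(haplotypes, dtype=np.int8)
    tru = np.asarray(truth_haplotypes, dtype=np.int8)
    if est.shape != tru.shape:
        raise ValueError("estimate and truth shapes differ")
    if not (np.sort(est, axis=2) == np.sort(tru, axis=2)).all():
        raise ValueError("estimate and truth disagree on genotype content")
    n_v, n_s, _ = est.shape
    if samples is None:
        samples = [f"sample{i}" for i in range(n_s)]
    rows = []
    for s in range(n_s):
        het = np.where(est[:, s].sum(axis=1) == 1)[0]
        if het.size < 2:
            rows.append({"sample": samples[s], "n_pairs": 0, "ser": np.nan, "defined": False})
            continue
        e_first = est[het, s, 0]
        t_first = tru[het, s, 0]
        e_or = e_first[1:] == e_first[:-1]
        t_or = t_first[1:] == t_first[:-1]
        ok = np.ones(het.size - 1, dtype=bool)
        if phased is not None:
            p = np.asarray(phased, dtype=bool)[het, s]
            ok = p[1:] & p[:-1]
        n_eval = int(ok.sum())
        ser = float((e_or[ok] != t_or[ok]).mean()) if n_eval else np.nan
        rows.append(
            {"sample": samples[s], "n_pairs": n_eval, "ser": ser, "defined": n_eval > 0}
        )
    return pd.DataFrame(rows)
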