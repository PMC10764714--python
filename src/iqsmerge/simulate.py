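"""Synthetic data generation for every component of the toolkit.

The generator emulates the structure of a two-strategy imputation study of a
geographically structured cohort, without any real genotype data:

* truth genotypes drawn i.i.d. under Hardy-Weinberg equilibrium from a MAF
  spectrum mixing rare (MAF < 0.01) and common variants;
* two imputation runs with controlled accuracy per (strategy, MAF bin,
  sample group) — the "ssp" strategy is most accurate for rare variants of
  the group its panel covers, the "server" strategy is uniformly strong on
  common variants — and optionally *calibrated* posteriors, meaning the
  retained maximum probability equals the realized probability that the
  best-guess genotype is correct;
* K seed-perturbed phasings whose adjacent-het-pair orientations are
  independently flipped from a known truth with a known switch rate;
* group-structured pairwise IBD segments with an excess rate between chosen
  (target group, reference cluster) pairs.

Variants are simulated independently (no linkage disequilibrium): every
contract exercised by the toolkit is marginal per genotype or per adjacent
het pair, so LD structure would add cost without adding coverage.  All
operations are fully deterministic given their seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .ibd_sharing import IBDSegment
from .phase_eval import SeedPhasingSet
from .vcf_io import ConfigurationError, ImputedDataset, TruthGenotypes, VariantKey

__all__ = [
    "SimulationConfig",
    "DEFAULT_ACCURACY",
    "simulate_truth",
    "simulate_posteriors",
    "simulate_chance_posteriors",
    "simulate_seed_phasings",
    "simulate_ibd_segments",
    "Scenario",
    "france_scenario",
]


#: Correctness probability per strategy, MAF bin and sample group.
#: "ssp" mimics a local sequenced panel covering the 'west' group: excellent
#: on rare variants of covered individuals, weaker elsewhere.  "server"
#: mimics a large cosmopolitan panel: uniformly strong on common variants,
#: middling on rare ones regardless of group.
DEFAULT_ACCURACY: dict[str, dict[str, dict[str, float]]] = {
    "ssp": {
        "rare": {"west": 0.97, "east": 0.80},
        "common": {"west": 0.96, "east": 0.90},
    },
    "server": {
        "rare": {"west": 0.85, "east": 0.85},
        "common": {"west": 0.97, "east": 0.97},
    },
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-strategy benchmark.

    Defaults encode the benchmark scenario: 120 individuals in two groups of
    60 ('west' = region covered by the local panel, 'east' = not covered),
    3000 independent variants of which 40% are rare (MAF uniform on
    [0.002, 0.01)) and 60% common (MAF uniform on [0.01, 0.5]), calibrated
    posteriors, 21 phasing replicates with a 0.02 switch rate, and an IBD
    model with excess sharing between 'west' targets and reference cluster
    'c1'.
    """

    n_variants: int = 3000
    n_samples: int = 120
    groups: list[str] | None = None  # per-sample labels; default 60 west + 60 east
    maf_rare_fraction: float = 0.4
    rare_maf_range: tuple[float, float] = (0.002, 0.01)
    common_maf_range: tuple[float, float] = (0.01, 0.5)
    maf_point_masses: list[float] | None = None  # overrides the range sampler
    accuracy: dict = field(default_factory=lambda: DEFAULT_ACCURACY)
    calibrated: bool = True
    concentration: float = 0.9  # p_max when not calibrated
    maf_threshold: float = 0.01
    mac_filter: dict = field(default_factory=lambda: {"ssp": 5})
    panel_size: int = 850  # notional sequenced-panel size behind the MAC filter
    switch_rate: float = 0.02
    K: int = 21
    n_het_pairs: int = 2000
    ibd_rates: dict = field(
        default_factory=lambda: {("west", "c1"): 0.08, ("west", "c2"): 0.02,
                                 ("east", "c1"): 0.02, ("east", "c2"): 0.02}
    )
    ibd_mean_cm: float = 4.0
    ibd_min_cm: float = 1.0  # detector-limit shift of the length distribution
    n_ref_per_cluster: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.groups is None:
            half = self.n_samples // 2
            self.groups = ["west"] * half + ["east"] * (self.n_samples - half)
        if len(self.groups) != self.n_samples:
            raise ConfigurationError("groups length must equal n_samples")
        if not (0.0 <= self.switch_rate < 0.5):
            raise ConfigurationError("switch_rate must be in [0, 0.5)")
        if self.K < 3 or self.K % 2 == 0:
            raise ConfigurationError("K must be odd and >= 3")
        for strat, bins in self.accuracy.items():
            for b, per_group in bins.items():
                for g, a in per_group.items():
                    if not (0.0 < a <= 1.0):
                        raise ConfigurationError(
                            f"accuracy[{strat}][{b}][{g}] = {a} outside (0, 1]"
                        )
                    if self.calibrated and a <= 0.5:
                        raise ConfigurationError(
                            f"calibrated posteriors require accuracy > 0.5, "
                            f"got {a} for [{strat}][{b}][{g}]"
                        )

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.rng_seed, stream))


def _variant_keys(n: int, chrom: str = "1") -> list[VariantKey]:
    return [VariantKey(chrom, 1000 * (i + 1), "A", "G") for i in range(n)]


def _hwe_priors(f: np.ndarray) -> np.ndarray:
    """Genotype probabilities ((1-f)^2, 2f(1-f), f^2) per variant, shape (V, 3)."""
    f = np.asarray(f, dtype=float)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def simulate_truth(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[TruthGenotypes, np.ndarray]:
    """Draw truth genotypes i.i.d. under HWE from the configured MAF spectrum.

    Returns the truth set and the per-variant true alternate-allele
    frequencies used to draw it.
    """
    rng = cfg.rng(1) if rng is None else rng
    v = cfg.n_variants
    if cfg.maf_point_masses is not None:
        freqs = rng.choice(np.asarray(cfg.maf_point_masses, dtype=float), size=v)
    else:
        rare = rng.random(v) < cfg.maf_rare_fraction
        freqs = np.where(
            rare,
            rng.uniform(*cfg.rare_maf_range, size=v),
            rng.uniform(*cfg.common_maf_range, size=v),
        )
    priors = _hwe_priors(freqs)
    u = rng.random((v, cfg.n_samples))
    cum = priors.cumsum(axis=1)
    calls = (u[:, :, None] > cum[:, None, :]).sum(axis=2).astype(np.int8)
    truth = TruthGenotypes(_variant_keys(v), [f"ind{i:03d}" for i in range(cfg.n_samples)], calls)
    return truth, freqs


def _trios_around(
    argmax: np.ndarray, p_top: np.ndarray, priors: np.ndarray
) -> np.ndarray:
    """Build trios with mass ``p_top`` on ``argmax`` and the remainder split
    over the other two genotypes proportional to their HWE priors.

    ``argmax`` and ``p_top`` are (V, S); ``priors`` is (V, 3).  When both
    other priors are zero (degenerate frequency) the remainder splits
    equally.
    """
    v, s = argmax.shape
    idx = argmax[:, :, None].astype(int)
    others = np.repeat(priors[:, None, :], s, axis=1).astype(float)  # (V, S, 3)
    np.put_along_axis(others, idx, 0.0, axis=2)
    tot = others.sum(axis=2, keepdims=True)
    equal = np.ones_like(others)
    np.put_along_axis(equal, idx, 0.0, axis=2)
    others = np.where(tot > 0, others / np.where(tot == 0, 1.0, tot), equal / 2.0)
    gp = others * (1.0 - p_top)[:, :, None]
    np.put_along_axis(gp, idx, p_top[:, :, None], axis=2)
    return gp


def _accuracy_matrix(
    cfg: SimulationConfig, strategy: str, maf: np.ndarray
) -> np.ndarray:
    """(V, S) correctness probabilities from the strategy's accuracy table."""
    if strategy not in cfg.accuracy:
        raise ConfigurationError(f"no accuracy model for strategy {strategy!r}")
    table = cfg.accuracy[strategy]
    bins = np.where(maf < cfg.maf_threshold, "rare", "common")
    a = np.empty((cfg.n_variants, cfg.n_samples))
    for s, group in enumerate(cfg.groups):
        a[:, s] = [table[b][group] for b in bins]
    return a


def _draw_wrong_genotype(
    truth_calls: np.ndarray, priors: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample a genotype != truth, proportional to HWE priors of the others."""
    v, s = truth_calls.shape
    p = np.repeat(priors[:, None, :], s, axis=1).astype(float)
    np.put_along_axis(p, truth_calls[:, :, None].astype(int), 0.0, axis=2)
    tot = p.sum(axis=2, keepdims=True)
    equal = np.full_like(p, 1 / 3)
    np.put_along_axis(equal, truth_calls[:, :, None].astype(int), 0.0, axis=2)
    equal = equal / equal.sum(axis=2, keepdims=True)
    p = np.where(tot > 0, p / np.where(tot == 0, 1, tot), equal)
    u = rng.random((v, s))
    cum = p.cumsum(axis=2)
    return (u[:, :, None] > cum).sum(axis=2).astype(np.int8)


def simulate_posteriors(
    truth: TruthGenotypes,
    freqs: np.ndarray,
    cfg: SimulationConfig,
    strategy: str,
    rng: np.random.Generator | None = None,
) -> ImputedDataset:
    """Generate an imputation run with controlled accuracy and calibration.

    Per genotype, with probability ``a`` (from the strategy's accuracy table
    by MAF bin and sample group) the trio's argmax is the true genotype;
    otherwise the argmax is drawn among the two other genotypes proportional
    to their HWE priors — which pins chance-level IQS at zero by
    construction.  With ``calibrated=True`` the retained maximum equals
    ``a``, so the confidence of the call matches its realized correctness;
    otherwise the maximum is the fixed ``concentration``.  Variants whose
    truth minor allele count falls below the strategy's ``mac_filter``
    entry are dropped, emulating a sequenced panel's allele-count cutoff.
    """
    if rng is None:
        rng = cfg.rng(zlib.crc32(strategy.encode()) % 2**31)
    maf = np.minimum(freqs, 1 - freqs)
    a = _accuracy_matrix(cfg, strategy, maf)
    priors = _hwe_priors(freqs)
    correct = rng.random(a.shape) < a
    wrong = _draw_wrong_genotype(truth.calls, priors, rng)
    argmax = np.where(correct, truth.calls, wrong).astype(np.int8)
    p_top = a if cfg.calibrated else np.full_like(a, cfg.concentration)
    gp = _trios_around(argmax.astype(int), p_top, priors)
    dataset = ImputedDataset(
        variants=list(truth.variants),
        samples=list(truth.samples),
        gp=gp,
        source=strategy,
    )
    mac_min = cfg.mac_filter.get(strategy)
    if mac_min:
        # the allele-count cutoff operates on the strategy's sequenced panel,
        # not on the target cohort: draw each variant's panel minor-allele
        # count from the panel size and drop variants falling below it
        panel_alt = rng.binomial(2 * cfg.panel_size, freqs)
        panel_mac = np.minimum(panel_alt, 2 * cfg.panel_size - panel_alt)
        keep = np.where(panel_mac >= mac_min)[0]
        dataset = dataset.subset_variants(keep)
        dataset.source = strategy
    return dataset


def simulate_chance_posteriors(
    truth: TruthGenotypes,
    freqs: np.ndarray,
    concentration: float = 0.9,
    rng: np.random.Generator | None = None,
) -> ImputedDataset:
    """A run whose best guess is drawn from the HWE priors, ignoring truth.

    The observed agreement of such a run equals its chance agreement in
    expectation, so its IQS converges to 0 — the chance-level control.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    priors = _hwe_priors(freqs)
    v = len(truth.variants)
    s = len(truth.samples)
    u = rng.random((v, s))
    cum = priors.cumsum(axis=1)
    argmax = (u[:, :, None] > cum[:, None, :]).sum(axis=2)
    p_top = np.full((v, s), concentration)
    gp = _trios_around(argmax, p_top, priors)
    return ImputedDataset(list(truth.variants), list(truth.samples), gp, source="chance")


def simulate_seed_phasings(
    n_individuals: int,
    n_het_pairs: int,
    s: float,
    K: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[SeedPhasingSet, np.ndarray]:
    """K phasings of all-heterozygous individuals with known switch rate.

    The truth orientation of each adjacent het pair is uniform; each
    replicate flips each orientation independently with probability ``s``.
    Returns the phasing set plus the truth orientation matrix
    (n_het_pairs x n_individuals, True = 'same').  ``s`` must be below 0.5:
    at and beyond it the majority consensus no longer tracks the truth.
    """
    if not (0.0 <= s < 0.5):
        raise ConfigurationError(f"switch rate must be in [0, 0.5), got {s}")
    if K < 3 or K % 2 == 0:
        raise ConfigurationError(f"K must be odd and >= 3, got {K}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_variants = n_het_pairs + 1
    truth_same = rng.random((n_het_pairs, n_individuals)) < 0.5
    flips = rng.random((K, n_het_pairs, n_individuals)) < s
    rep_same = truth_same[None, :, :] ^ flips
    # orientation 'opposite' toggles which haplotype carries the alt allele
    toggles = ~rep_same  # (K, P, S)
    alt_on_first = np.zeros((K, n_variants, n_individuals), dtype=np.int8)
    alt_on_first[:, 1:, :] = np.cumsum(toggles, axis=1) % 2
    haps = np.zeros((K, n_variants, n_individuals, 2), dtype=np.int8)
    haps[:, :, :, 0] = 1 - alt_on_first
    haps[:, :, :, 1] = alt_on_first
    # every genotype is 0/1 het; hap0 carries alt iff alt_on_first == 0
    phased = np.ones((K, n_variants, n_individuals), dtype=bool)
    pset = SeedPhasingSet(
        haplotypes=haps,
        phased=phased,
        samples=[f"ind{i:03d}" for i in range(n_individuals)],
        variants=_variant_keys(n_variants),
        seeds=list(range(K)),
    )
    return pset, truth_same


def truth_haplotypes_from_orientations(truth_same: np.ndarray) -> np.ndarray:
    """(variants, individuals, 2) truth haplotypes matching a phasing set."""
    n_pairs, n_ind = truth_same.shape
    alt_on_first = np.zeros((n_pairs + 1, n_ind), dtype=np.int8)
    alt_on_first[1:] = np.cumsum(~truth_same, axis=0) % 2
    haps = np.zeros((n_pairs + 1, n_ind, 2), dtype=np.int8)
    haps[:, :, 0] = 1 - alt_on_first
    haps[:, :, 1] = alt_on_first
    return haps


def simulate_ibd_segments(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[IBDSegment], dict[str, str], dict[str, str]]:
    """Group-structured pairwise IBD segments between targets and references.

    Per (target, reference) pair the segment count is Poisson with the
    group-pair rate from ``cfg.ibd_rates`` (0 when absent); lengths are
    ``ibd_min_cm`` plus an exponential with mean ``ibd_mean_cm - ibd_min_cm``
    — the shift mimics the detection limit of IBD callers.  Physical spans
    are placed uniformly on a 250 Mb chromosome at ~1 Mb/cM.  Returns the
    segments plus the target and reference group assignment tables.
    """
    rng = cfg.rng(4) if rng is None else rng
    targets = {f"ind{i:03d}": g for i, g in enumerate(cfg.groups)}
    clusters = sorted({c for (_, c) in cfg.ibd_rates})
    refs = {
        f"ref_{c}_{j:03d}": c for c in clusters for j in range(cfg.n_ref_per_cluster)
    }
    segments: list[IBDSegment] = []
    mean_excess = max(cfg.ibd_mean_cm - cfg.ibd_min_cm, 1e-9)
    for t, tg in targets.items():
        for r, rc in refs.items():
            rate = cfg.ibd_rates.get((tg, rc), 0.0)
            if rate <= 0:
                continue
            count = rng.poisson(rate)
            for _ in range(count):
                length = cfg.ibd_min_cm + rng.exponential(mean_excess)
                chrom = str(rng.integers(1, 23))
                start = int(rng.integers(1, 250_000_000))
                end = start + int(length * 1_000_000)
                segments.append(
                    IBDSegment(
                        sample1=t,
                        sample2=r,
                        chrom=chrom,
                        start=start,
                        end=end,
                        length_cm=float(length),
                        hap1=int(rng.integers(1, 3)),
                        hap2=int(rng.integers(1, 3)),
                        lod=float(3.0 + 10 * length),
                    )
                )
    return segments, targets, refs


@dataclass
class Scenario:
    """A fully simulated two-strategy study, ready for evaluation."""

    config: SimulationConfig
    truth: TruthGenotypes
    freqs: np.ndarray
    run_a: ImputedDataset  # ssp-like strategy
    run_b: ImputedDataset  # server-like strategy
    groups: dict[str, str]


def france_scenario(
    seed: int = 0, cfg: SimulationConfig | None = None
) -> Scenario:
    """Simulate the benchmark scenario with two complementary strategies.

    Strategy A ("ssp") is most accurate on rare variants of 'west'
    individuals but only covers variants above its panel's allele-count
    cutoff; strategy B ("server") is uniformly strong on common variants
    and covers everything.  Per-individual IQS should favour A for 'west'
    and B for 'east', and the most-confident-vote merge should match or
    beat both in every group.
    """
    if cfg is None:
        cfg = SimulationConfig(rng_seed=seed)
    else:
        cfg.rng_seed = seed
    truth, freqs = simulate_truth(cfg)
    run_a = simulate_posteriors(truth, freqs, cfg, "ssp", rng=cfg.rng(2))
    run_b = simulate_posteriors(truth, freqs, cfg, "server", rng=cfg.rng(3))
    groups = {s: g for s, g in zip(truth.samples, cfg.groups)}
    return Scenario(cfg, truth, freqs, run_a, run_b, groups)
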