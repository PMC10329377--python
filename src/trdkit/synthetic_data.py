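"""Gene-drop simulator for trio datasets with known TRD mechanisms.

The simulator emulates the family structure of large dairy-cattle genotyping
programs: paternal half-sib families (tens to thousands of offspring per
sire), each dam contributing a single offspring, biallelic SNPs on one or
more chromosomes, phased founder haplotypes and recombination at a constant
rate per base pair (1 cM/Mbp by default).  Distortion mechanisms are planted
at chosen loci:

* ``allelic`` — a heterozygous sire (dam) transmits allele A with
  probability 0.5 + alpha_s (0.5 + alpha_d) instead of 0.5; implemented by
  conditioning the meiosis strand process at the focal locus, so linked
  markers inherit the bias through recombination exactly as in real data;
* ``genotypic`` — offspring genotypes at the locus are drawn from the
  mating-specific genotypic-TRD kernel, implemented as zygote viability
  rejection (weight 1 + alpha_g - delta_g, 1 + delta_g, 1 - alpha_g -
  delta_g for AA/AB/BB), which reproduces the fitted likelihood exactly in
  every mating type;
* ``recessive_lethal`` — shorthand for the complete-lethality point
  genotypic(-2/3, +1/3): no surviving AA offspring.

``carrier_frequency`` of a planted locus is the founder frequency of the
focal allele A.  Every run is reproducible from its seed, and a
SyntheticTruth record stores mechanism, parameters, realized carrier
frequency and the number of non-viable offspring removed at each locus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeTable, validate_pedigree
from .mating_model import genotypic_in_space

logger = logging.getLogger("trdkit")

__all__ = ["LocusSpec", "SimConfig", "SyntheticTruth", "SimResult",
           "simulate", "inject_errors", "make_fixture"]

_LETHAL_AG, _LETHAL_DG = -2.0 / 3.0, 1.0 / 3.0


@dataclass(frozen=True)
class LocusSpec:
    """One planted locus: mechanism and parameters at a SNP of a chromosome."""

    chrom: str
    snp: int                      # marker index within the chromosome
    mechanism: str                # null | allelic | genotypic | recessive_lethal
    alpha_s: float = 0.0
    alpha_d: float = 0.0
    alpha_g: float = 0.0
    delta_g: float = 0.0
    carrier_frequency: float = 0.1  # founder frequency of focal allele A

    def __post_init__(self) -> None:
        if self.mechanism not in ("null", "allelic", "genotypic",
                                  "recessive_lethal"):
            raise ValueError(f"unknown mechanism: {self.mechanism}")
        if self.mechanism == "allelic":
            if not (-0.5 <= self.alpha_s <= 0.5 and -0.5 <= self.alpha_d <= 0.5):
                raise ValueError("allelic parameters outside [-0.5, 0.5]")
        if self.mechanism == "genotypic":
            if not bool(genotypic_in_space(self.alpha_g, self.delta_g)):
                raise ValueError("genotypic parameters outside the space")
        if not 0.0 < self.carrier_frequency < 1.0:
            raise ValueError("carrier frequency must be in (0, 1)")

    @property
    def genotypic_params(self) -> tuple[float, float]:
        if self.mechanism == "recessive_lethal":
            return (_LETHAL_AG, _LETHAL_DG)
        return (self.alpha_g, self.delta_g)


@dataclass
class SimConfig:
    """Study design of one synthetic dataset."""

    n_sires: int = 100
    offspring_per_sire: Union[int, tuple[int, int]] = 50  # int or (lo, hi)
    n_chromosomes: int = 1
    snps_per_chrom: int = 50
    spacing_bp: int = 50_000
    founder_freq_b: Optional[float] = None   # None: Uniform(0.1, 0.9) per SNP
    founder_pools: Optional[dict] = None     # chrom -> (haplotypes (K,M), freqs)
    loci: Sequence[LocusSpec] = ()
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    recomb_rate_per_bp: float = 1e-8         # 1 cM/Mbp
    seed: int = 0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def validate(self) -> None:
        names = set(self.chrom_names())
        allelic_per_chrom: dict[str, int] = {}
        for spec in self.loci:
            if spec.chrom not in names:
                raise ValueError(f"locus on unknown chromosome {spec.chrom}")
            if not 0 <= spec.snp < self.snps_per_chrom:
                raise ValueError("locus SNP index out of range")
            if spec.mechanism == "allelic":
                allelic_per_chrom[spec.chrom] = \
                    allelic_per_chrom.get(spec.chrom, 0) + 1
        if any(v > 1 for v in allelic_per_chrom.values()):
            raise ValueError("at most one allelic-TRD locus per chromosome")


@dataclass
class SyntheticTruth:
    """Generating mechanism per planted locus, for recovery testing."""

    loci: list[dict] = field(default_factory=list)
    n_offspring: int = 0
    seed: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "n_offspring": self.n_offspring,
                       "loci": self.loci}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(loci=raw["loci"], n_offspring=raw["n_offspring"],
                   seed=raw["seed"])

    @property
    def non_null(self) -> list[dict]:
        return [l for l in self.loci if l["mechanism"] != "null"]


@dataclass
class SimResult:
    gt: GenotypeTable
    pedigree: pd.DataFrame
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _meioses(hap_a: np.ndarray, hap_b: np.ndarray, rfrac: np.ndarray,
             rng: np.random.Generator,
             bias_locus: Optional[int] = None,
             p_focal: float = 0.5) -> np.ndarray:
    """One gamete per row from phased parent haplotypes (rows x markers).

    ``rfrac`` holds the recombination fraction of each adjacent-marker
    interval.  With ``bias_locus`` set, heterozygous parents transmit
    allele A (0) at that locus with probability ``p_focal``: the crossover
    strand process is flip-symmetric, so conditioning on the strand at the
    focal locus is achieved by flipping whole strand paths, leaving the
    recombination law intact.
    """
    n, m = hap_a.shape
    steps = np.empty((n, m), dtype=np.int8)
    steps[:, 0] = rng.integers(0, 2, size=n)
    if m > 1:
        steps[:, 1:] = rng.random((n, m - 1)) < rfrac
    strand = np.cumsum(steps, axis=1, dtype=np.int64) % 2
    if bias_locus is not None:
        l = bias_locus
        het = hap_a[:, l] != hap_b[:, l]
        want_a = rng.random(n) < p_focal
        target = np.where(want_a, 0, 1)
        s_star = np.where(hap_a[:, l] == target, 0, 1)
        flip = het & (strand[:, l] != s_star)
        strand[flip] = 1 - strand[flip]
    return np.where(strand == 0, hap_a, hap_b).astype(np.int8)


# ---------------------------------------------------------------------------
# main simulator
# ---------------------------------------------------------------------------

def _viability(spec: LocusSpec) -> np.ndarray:
    """Relative viability of AA/AB/BB offspring; exact zeros at lethality."""
    ag, dg = spec.genotypic_params
    v = np.array([1.0 + ag - dg, 1.0 + dg, 1.0 - ag - dg])
    v[np.abs(v) < 1e-12] = 0.0
    return v


def simulate(config: SimConfig) -> SimResult:
    """Gene-drop one dataset: founders, biased meioses, viability selection.

    Returns phased genotypes for sires, dams and offspring, the pedigree
    (one offspring per dam, paternal half-sib families) and the truth
    record.  Byte-identical outputs for identical configs and seeds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if isinstance(config.offspring_per_sire, tuple):
        lo, hi = config.offspring_per_sire
        n_per_sire = rng.integers(lo, hi + 1, size=config.n_sires)
    else:
        n_per_sire = np.full(config.n_sires, config.offspring_per_sire)
    n_off = int(n_per_sire.sum())
    n_sires, n_dams = config.n_sires, n_off

    sire_ids = [f"S{i + 1:05d}" for i in range(n_sires)]
    dam_ids = [f"D{i + 1:06d}" for i in range(n_dams)]
    off_ids = [f"O{i + 1:06d}" for i in range(n_off)]
    samples = sire_ids + dam_ids + off_ids
    off_sire_idx = np.repeat(np.arange(n_sires), n_per_sire)
    off_dam_idx = np.arange(n_off)

    chroms = config.chrom_names()
    m = config.snps_per_chrom
    rfrac_interval = 0.5 * (1.0 - np.exp(
        -2.0 * config.recomb_rate_per_bp * config.spacing_bp))

    marker_rows = []
    hap_a_blocks, hap_b_blocks = [], []
    truth_loci = []
    dead_offspring = np.zeros(n_off, dtype=bool)

    for chrom in chroms:
        loci = [s for s in config.loci if s.chrom == chrom]
        # founder allele frequencies (of allele B) per SNP
        if config.founder_pools and chrom in config.founder_pools:
            pool, pool_freqs = config.founder_pools[chrom]
            pool = np.asarray(pool, dtype=np.int8)
            pool_freqs = np.asarray(pool_freqs, dtype=float)
            pool_freqs = pool_freqs / pool_freqs.sum()
            for spec in loci:
                f_a = float(pool_freqs[pool[:, spec.snp] == 0].sum())
                if abs(f_a - spec.carrier_frequency) > 0.05:
                    raise ValueError(
                        f"pool gives carrier frequency {f_a:.3f} at "
                        f"{spec.chrom}:snp{spec.snp}, target "
                        f"{spec.carrier_frequency}")
            draw = rng.choice(len(pool), size=(n_sires + n_dams, 2),
                              p=pool_freqs)
            founder = pool[draw]                       # (F, 2, M)
        else:
            if config.founder_freq_b is None:
                freq_b = rng.uniform(0.1, 0.9, size=m)
            else:
                freq_b = np.full(m, float(config.founder_freq_b))
            for spec in loci:
                freq_b[spec.snp] = 1.0 - spec.carrier_frequency
            founder = (rng.random((n_sires + n_dams, 2, m))
                       < freq_b).astype(np.int8)
        sire_h = founder[:n_sires]
        dam_h = founder[n_sires:]

        allelic = next((s for s in loci if s.mechanism == "allelic"), None)
        genotypic = [s for s in loci if s.mechanism in
                     ("genotypic", "recessive_lethal")]
        rfrac = np.full(m - 1, rfrac_interval) if m > 1 else np.empty(0)

        sire_a = sire_h[off_sire_idx, 0]
        sire_b = sire_h[off_sire_idx, 1]
        dam_a = dam_h[off_dam_idx, 0]
        dam_b = dam_h[off_dam_idx, 1]

        bias_l = allelic.snp if allelic else None
        p_s = 0.5 + (allelic.alpha_s if allelic else 0.0)
        p_d = 0.5 + (allelic.alpha_d if allelic else 0.0)

        gam_s = _meioses(sire_a, sire_b, rfrac, rng, bias_l, p_s)
        gam_d = _meioses(dam_a, dam_b, rfrac, rng, bias_l, p_d)

        removed = {id(s): 0 for s in genotypic}
        if genotypic:
            # matings that cannot yield any viable genotype produce no
            # offspring at all: mark those conceptions dead up front
            impossible = np.zeros(n_off, dtype=bool)
            for spec in genotypic:
                v = _viability(spec)
                viable = v > 0.0
                best = np.zeros(n_off, dtype=bool)
                for sa in (sire_a[:, spec.snp], sire_b[:, spec.snp]):
                    for da in (dam_a[:, spec.snp], dam_b[:, spec.snp]):
                        best |= viable[sa + da]
                removed[id(spec)] += int((~best & ~impossible).sum())
                impossible |= ~best
            dead_offspring |= impossible
            pending = np.nonzero(~impossible)[0]
            for _ in range(10_000):
                if pending.size == 0:
                    break
                keep = np.ones(pending.size, dtype=bool)
                for spec in genotypic:
                    v = _viability(spec)
                    w = v / v.max()
                    g = gam_s[pending, spec.snp] + gam_d[pending, spec.snp]
                    ok = rng.random(pending.size) < w[g]
                    removed[id(spec)] += int((keep & ~ok).sum())
                    keep &= ok
                redo = pending[~keep]
                if redo.size:
                    gam_s[redo] = _meioses(sire_a[redo], sire_b[redo],
                                           rfrac, rng, bias_l, p_s)
                    gam_d[redo] = _meioses(dam_a[redo], dam_b[redo],
                                           rfrac, rng, bias_l, p_d)
                pending = redo
            else:
                raise RuntimeError("viability rejection did not converge")

        # truth bookkeeping: realized carrier frequency among parental haps
        parental = np.concatenate([sire_h.reshape(-1, m),
                                   dam_h.reshape(-1, m)])
        for spec in loci:
            entry = {"chrom": chrom, "snp": int(spec.snp),
                     "marker_id": f"{chrom}_snp{spec.snp + 1:04d}",
                     "mechanism": spec.mechanism,
                     "carrier_frequency_target": spec.carrier_frequency,
                     "carrier_frequency_realized":
                         float((parental[:, spec.snp] == 0).mean()),
                     "n_removed": 0}
            if spec.mechanism == "allelic":
                entry.update(alpha_s=spec.alpha_s, alpha_d=spec.alpha_d)
            elif spec.mechanism in ("genotypic", "recessive_lethal"):
                ag, dg = spec.genotypic_params
                entry.update(alpha_g=ag, delta_g=dg,
                             n_removed=removed[id(spec)])
            truth_loci.append(entry)

        hap_a_blocks.append(np.concatenate(
            [sire_h[:, 0], dam_h[:, 0], gam_s]).T)   # (M, n_samples)
        hap_b_blocks.append(np.concatenate(
            [sire_h[:, 1], dam_h[:, 1], gam_d]).T)
        marker_rows.extend(
            (chrom, f"{chrom}_snp{i + 1:04d}", (i + 1) * config.spacing_bp)
            for i in range(m))

    hap_a = np.concatenate(hap_a_blocks)
    hap_b = np.concatenate(hap_b_blocks)
    if dead_offspring.any():
        # non-viable conceptions leave no genotyped offspring behind
        keep = np.ones(len(samples), dtype=bool)
        keep[n_sires + n_dams + np.nonzero(dead_offspring)[0]] = False
        samples = [s for s, k in zip(samples, keep) if k]
        hap_a, hap_b = hap_a[:, keep], hap_b[:, keep]
        alive = ~dead_offspring
        off_ids = [o for o, k in zip(off_ids, alive) if k]
        off_sire_idx = off_sire_idx[alive]
        off_dam_idx = off_dam_idx[alive]
        n_off = int(alive.sum())
    codes = (hap_a + hap_b).astype(np.int16)
    markers = pd.DataFrame(marker_rows, columns=["chrom", "marker_id", "pos_bp"])
    gt = GenotypeTable(samples, markers, codes,
                       hap_a.astype(np.int8), hap_b.astype(np.int8),
                       np.ones(codes.shape, dtype=bool))

    ped = pd.DataFrame({
        "offspring": off_ids,
        "sire": [sire_ids[i] for i in off_sire_idx],
        "dam": [dam_ids[i] for i in off_dam_idx],
    })
    validate_pedigree(ped)

    if config.genotyping_error_rate or config.missing_rate:
        gt = inject_errors(gt, config.genotyping_error_rate,
                           config.missing_rate,
                           seed=int(rng.integers(0, 2**31 - 1)))

    truth = SyntheticTruth(loci=truth_loci, n_offspring=n_off,
                           seed=config.seed)
    return SimResult(gt=gt, pedigree=ped, truth=truth)


# ---------------------------------------------------------------------------
# genotyping error / missingness
# ---------------------------------------------------------------------------

def inject_errors(gt: GenotypeTable, error_rate: float, missing_rate: float,
                  seed: int = 0) -> GenotypeTable:
    """Flip genotypes to a random different code and mask entries missing.

    Each non-missing entry is independently replaced by one of the two
    other genotype codes with probability ``error_rate``, then set missing
    with probability ``missing_rate``.  Phase of flipped entries is redrawn
    consistently with the new code.  Counts are logged.
    """
    if not (0.0 <= error_rate <= 1.0 and 0.0 <= missing_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    codes = gt.codes.copy()
    hap_a = gt.hap_a.copy() if gt.hap_a is not None else None
    hap_b = gt.hap_b.copy() if gt.hap_b is not None else None
    phased = gt.phased.copy()

    present = codes != MISSING
    flip = present & (rng.random(codes.shape) < error_rate)
    if flip.any():
        old = codes[flip]
        shift = rng.integers(1, 3, size=old.size)        # +1 or +2 mod 3
        new = (old + shift) % 3
        codes[flip] = new
        if hap_a is not None:
            a = np.where(new == 0, 0, np.where(new == 2, 1,
                         rng.integers(0, 2, size=new.size)))
            hap_a[flip] = a.astype(np.int8)
            hap_b[flip] = (new - a).astype(np.int8)
    miss = present & (rng.random(codes.shape) < missing_rate)
    codes[miss] = MISSING
    phased[miss] = False
    if hap_a is not None:
        hap_a[miss] = MISSING
        hap_b[miss] = MISSING
    logger.info("injected %d genotype errors, %d missing entries",
                int(flip.sum()), int(miss.sum()))
    return GenotypeTable(gt.samples, gt.markers, codes, hap_a, hap_b, phased)


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str, seed: int = 0) -> SimResult:
    """Deterministic datasets used across the test suite.

    * ``null_genome`` — 2 chromosomes x 50 SNPs, 60 half-sib families of 25,
      no distortion anywhere.
    * ``planted_three_signals`` — 5 chromosomes x 200 SNPs, 300 sires x 50
      offspring, three planted loci: overall allelic TRD (alpha = -0.3),
      sire-only TRD (alpha_s = -0.4, alpha_d = 0) and a recessive lethal.
    * ``single_skewed_sire`` — one heterozygous sire transmits the focal
      allele to all of its 60 offspring while 24 other het sires segregate
      exactly Mendelian (constructed, not simulated).
    * ``table1_patterns`` — five genotypic-TRD loci spanning the recessive,
      homozygote advantage/disadvantage and heterosis excess/deficiency
      patterns.
    """
    if name == "null_genome":
        return simulate(SimConfig(
            n_sires=60, offspring_per_sire=25, n_chromosomes=2,
            snps_per_chrom=50, seed=seed))
    if name == "planted_three_signals":
        loci = (
            LocusSpec("chr1", 100, "allelic", alpha_s=-0.3, alpha_d=-0.3,
                      carrier_frequency=0.3),
            LocusSpec("chr2", 100, "allelic", alpha_s=-0.4, alpha_d=0.0,
                      carrier_frequency=0.3),
            LocusSpec("chr3", 100, "recessive_lethal",
                      carrier_frequency=0.15),
        )
        return simulate(SimConfig(
            n_sires=300, offspring_per_sire=50, n_chromosomes=5,
            snps_per_chrom=200, loci=loci, seed=seed))
    if name == "single_skewed_sire":
        return _single_skewed_sire_fixture()
    if name == "table1_patterns":
        pairs = [(-0.66, 0.33), (0.09, -0.04), (-0.05, 0.04),
                 (0.05, 0.25), (-0.40, -0.25)]
        loci = tuple(
            LocusSpec(f"chr{i + 1}", 0, "genotypic", alpha_g=ag, delta_g=dg,
                      carrier_frequency=0.5)
            for i, (ag, dg) in enumerate(pairs))
        return simulate(SimConfig(
            n_sires=700, offspring_per_sire=8, n_chromosomes=5,
            snps_per_chrom=1, loci=loci, seed=seed))
    raise ValueError(f"unknown fixture: {name}")


def _single_skewed_sire_fixture() -> SimResult:
    """One fully-skewed het sire among 25; everyone else exactly Mendelian."""
    n_other, per_other, n_skew = 24, 6, 60
    n_off = n_other * per_other + n_skew
    sires = [f"S{i + 1:03d}" for i in range(25)]
    dams = [f"D{i + 1:04d}" for i in range(n_off)]
    offs = [f"O{i + 1:04d}" for i in range(n_off)]
    samples = sires + dams + offs
    # genotype codes at the single SNP: sires AB, dams AA
    codes = np.zeros((1, len(samples)), dtype=np.int16)
    codes[0, :25] = 1
    off_codes, ped_sire = [], []
    for i in range(n_other):                      # 3 AA + 3 AB per sire
        off_codes.extend([0] * 3 + [1] * 3)
        ped_sire.extend([sires[i + 1]] * per_other)
    off_codes.extend([0] * n_skew)                # skewed sire: all allele A
    ped_sire.extend([sires[0]] * n_skew)
    codes[0, 25 + n_off:] = off_codes
    markers = pd.DataFrame({"chrom": ["chr1"], "marker_id": ["chr1_snp0001"],
                            "pos_bp": [50_000]})
    gt = GenotypeTable(samples, markers, codes)
    ped = pd.DataFrame({"offspring": offs, "sire": ped_sire, "dam": dams})
    truth = SyntheticTruth(
        loci=[{"chrom": "chr1", "snp": 0, "marker_id": "chr1_snp0001",
               "mechanism": "null", "carrier_frequency_target": 0.5,
               "carrier_frequency_realized": 0.5, "n_removed": 0,
               "note": "single fully-skewed sire"}],
        n_offspring=n_off, seed=0)
    return SimResult(gt=gt, pedigree=ped, truth=truth)
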