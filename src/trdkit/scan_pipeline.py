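"""Genome-wide TRD scan: per-locus fits, filters, integration, reporting.

The scan walks every SNP (or every haplotype allele of every sliding
window), assembles trios, fits the null and the three TRD models, flags
decisive Bayes factors (BF >= 100) and selects the best-fitting model by
DIC.  Candidate regions then pass a filtering ledger targeting genotyping
errors and chance distortion:

1. informative parents — at least 20 heterozygous sires and/or 100
   heterozygous dams;
2. sire robustness — the signal must survive leave-one-out removal of
   fully-skewed heterozygous-sire families (a classic genotyping-error
   signature);
3. empirical null — the parameter estimate must exceed the two-sided
   Mendelian-sampling quantile for the locus's informative-offspring count
   at tail probability 1e-5;
4. stability — posterior coefficient of variation of the lead parameter
   at most 20 %.

Surviving records are deduplicated to the highest-BF record per overlapping
region, the BF is smoothed along each chromosome with a Gaussian kernel
(bandwidth sigma in bp), and core regions are read off the smoothed track as
separated local maxima with a significance span of +/- z * sigma around the
peak.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bayes_engine import (
    FitResult,
    classify_pattern,
    fit_all_models,
    grid_fit,
    select_model,
)
from .config import DEFAULT_CONFIG, ScanConfig
from .genotype_io import (
    MISSING,
    GenotypeTable,
    TrioSet,
    mendelian_consistent_mask,
)
from .mating_model import (
    CELLS,
    CELL_INDEX,
    N_CELLS,
    TRD_MODELS,
    MatingCountTable,
    tabulate,
)
from .window_recode import enumerate_alleles, make_windows

logger = logging.getLogger("trdkit")

__all__ = [
    "RegionRecord", "CoreRegion", "SmoothTrack", "NullTable",
    "scan", "apply_filters", "build_null_table", "dedup_best_bf",
    "kernel_smooth", "significance_halfwidth", "extract_core_regions",
    "under_represented", "integrate", "write_regions_tsv", "write_core_bed",
    "write_bedgraph",
]

# informative (sire, dam, offspring) -> flat cell index; -1 elsewhere
_CELL_LUT = np.full((3, 3, 3), -1, dtype=np.int64)
for (_s, _d), _mating in ((1, 0), "ABxAA"), ((1, 2), "ABxBB"), \
                         ((0, 1), "AAxAB"), ((2, 1), "BBxAB"), ((1, 1), "ABxAB"):
    for _o in CELLS[_mating]:
        _CELL_LUT[_s, _d, _o] = CELL_INDEX[(_mating, _o)]


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class RegionRecord:
    """One scanned SNP or haplotype allele with its fits and audit trail."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snp: int
    allele_id: str
    carrier_frequency: float
    n_het_sires: int
    n_het_dams: int
    n_informative: int
    n_inconsistent: int
    counts: MatingCountTable
    fits: dict[str, FitResult]
    selected_model: str
    delta_dic: dict[str, float]
    pattern: str
    bf: float                      # max BF across the three TRD models
    bf_model: str                  # model attaining it
    under_represented_count: int
    non_observed_hom: Optional[int] = None
    filter_flags: list[tuple[str, bool]] = field(default_factory=list)
    trios: Optional[TrioSet] = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)

    @property
    def passed_filters(self) -> bool:
        return all(ok for _, ok in self.filter_flags)

    @property
    def decisive(self) -> bool:
        return bool(self.bf >= 100.0)

    def flag(self, name: str) -> Optional[bool]:
        for n, ok in self.filter_flags:
            if n == name:
                return ok
        return None

    def to_row(self) -> dict:
        sel = self.fits[self.selected_model]
        row = {
            "chrom": self.chrom, "start_bp": self.start_bp,
            "end_bp": self.end_bp, "n_snp": self.n_snp,
            "allele_id": self.allele_id,
            "carrier_frequency": round(self.carrier_frequency, 6),
            "n_het_sires": self.n_het_sires, "n_het_dams": self.n_het_dams,
            "n_informative": self.n_informative,
            "n_inconsistent": self.n_inconsistent,
            "selected_model": self.selected_model, "pattern": self.pattern,
            "log10_bf": round(np.log10(self.bf) if np.isfinite(self.bf)
                              and self.bf > 0 else np.inf, 4),
            "bf_model": self.bf_model,
            "under_represented": self.under_represented_count,
            "non_observed_hom": self.non_observed_hom,
        }
        for name, val in zip(sel.param_names, sel.mean):
            row[name] = round(float(val), 4)
        row.update({f"filter_{n}": ok for n, ok in self.filter_flags})
        row.update(self.counts.to_row())
        return row


@dataclass(frozen=True)
class CoreRegion:
    chrom: str
    peak_bp: float
    peak_value: float
    start_bp: float
    end_bp: float


@dataclass
class SmoothTrack:
    """Kernel-smoothed BF along the genome, one array pair per chromosome."""

    sigma_bp: float
    chroms: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (pos, value)
    rescaled: bool = True

    def to_bedgraph(self, path: str, step: Optional[float] = None) -> None:
        with open(path, "w") as fh:
            for chrom, (pos, val) in self.chroms.items():
                half = (step if step is not None
                        else (pos[1] - pos[0] if pos.size > 1 else 1.0)) / 2
                for p, v in zip(pos, val):
                    fh.write(f"{chrom}\t{max(0, int(p - half))}"
                             f"\t{int(p + half)}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# per-locus machinery shared by both scan modes
# ---------------------------------------------------------------------------

def _ped_indices(gt: GenotypeTable, ped: pd.DataFrame):
    index = {s: i for i, s in enumerate(gt.samples)}
    off, sire, dam, sid, did = [], [], [], [], []
    n_unknown = 0
    for o, s, d in ped[["offspring", "sire", "dam"]].itertuples(index=False):
        try:
            off.append(index[o]); sire.append(index[s]); dam.append(index[d])
            sid.append(s); did.append(d)
        except KeyError:
            n_unknown += 1
    if n_unknown:
        logger.info("scan: skipped %d pedigree rows with unknown ids", n_unknown)
    return (np.asarray(off, dtype=np.int64), np.asarray(sire, dtype=np.int64),
            np.asarray(dam, dtype=np.int64),
            np.asarray(sid, dtype=object), np.asarray(did, dtype=object))


def _locus_record(codes: np.ndarray, idx, *, chrom: str, start: int, end: int,
                  n_snp: int, allele_id: str, carrier_freq: float,
                  config: ScanConfig, engine: str, resolution: int,
                  seed: int) -> Optional[RegionRecord]:
    """Fit one genotype-code column; None when below the trio minimum."""
    off_idx, sire_idx, dam_idx, sire_ids, dam_ids = idx
    s = codes[sire_idx]
    d = codes[dam_idx]
    o = codes[off_idx]
    complete = (s != MISSING) & (d != MISSING) & (o != MISSING)
    consistent = np.zeros_like(complete)
    consistent[complete] = mendelian_consistent_mask(
        s[complete], d[complete], o[complete])
    n_inconsistent = int(complete.sum() - consistent.sum())
    valid = complete & consistent
    if int(valid.sum()) < config.min_trios:
        return None
    sv, dv, ov = s[valid], d[valid], o[valid]
    cell = _CELL_LUT[sv, dv, ov]
    informative = cell >= 0
    counts_vec = np.bincount(cell[informative], minlength=N_CELLS)
    n_het_sires = int(np.unique(sire_idx[valid][sv == 1]).size)
    n_het_dams = int(np.unique(dam_idx[valid][dv == 1]).size)
    counts = MatingCountTable(counts_vec, n_het_sires=n_het_sires,
                              n_het_dams=n_het_dams,
                              n_inconsistent=n_inconsistent)

    fits = fit_all_models(counts, engine=engine, resolution=resolution,
                          seed=seed)
    trd_fits = {m: fits[m] for m in TRD_MODELS}
    selected, delta = select_model(trd_fits, margin=config.dic_margin)
    pattern = classify_pattern(selected, fits[selected], config)
    bf_model = max(TRD_MODELS, key=lambda m: fits[m].log_bf)
    bf = fits[bf_model].bayes_factor

    alpha_mag = min(abs(float(fits["allelic_overall"].mean[0])), 0.5)
    under = under_represented(counts.n_informative, alpha_mag)
    non_obs = None
    if selected == "genotypic":
        ag = float(fits["genotypic"].mean[0])
        hom_cell = 0 if ag < 0 else 2          # disadvantaged homozygote
        n_hh = counts.mating_total("ABxAB")
        non_obs = int(round(n_hh / 4)) - counts.cell("ABxAB", hom_cell)

    trios = None
    if bf >= config.bf_decisive:
        trios = TrioSet(
            marker=allele_id, sire=sv[informative], dam=dv[informative],
            offspring=ov[informative],
            sire_ids=sire_ids[valid][informative],
            dam_ids=dam_ids[valid][informative],
            n_het_sires=n_het_sires, n_het_dams=n_het_dams,
            n_inconsistent=n_inconsistent, usable=True)

    return RegionRecord(
        chrom=chrom, start_bp=start, end_bp=end, n_snp=n_snp,
        allele_id=allele_id, carrier_frequency=carrier_freq,
        n_het_sires=n_het_sires, n_het_dams=n_het_dams,
        n_informative=counts.n_informative, n_inconsistent=n_inconsistent,
        counts=counts, fits=fits, selected_model=selected,
        delta_dic=delta, pattern=pattern, bf=bf, bf_model=bf_model,
        under_represented_count=under, non_observed_hom=non_obs,
        trios=trios)


def scan(gt: GenotypeTable, ped: pd.DataFrame, mode: str = "snp",
         config: ScanConfig = DEFAULT_CONFIG, engine: str = "grid",
         seed: int = 0, window_sizes: Optional[Sequence[int]] = None,
         ) -> list[RegionRecord]:
    """Scan all SNPs (``mode='snp'``) or window haplotype alleles
    (``mode='windows'``) and fit all three TRD models per locus.

    Returns one record per locus passing the trio minimum; deterministic
    given the seed.  Window mode requires phased genotypes.
    """
    idx = _ped_indices(gt, ped)
    parents = np.unique(np.concatenate([idx[1], idx[2]])) if idx[0].size else \
        np.empty(0, dtype=np.int64)
    records: list[RegionRecord] = []
    resolution = config.grid_resolution

    if mode == "snp":
        for r in range(gt.n_markers):
            row = gt.markers.iloc[r]
            codes = gt.codes[r]
            pcodes = codes[parents] if parents.size else codes
            obs = pcodes[pcodes != MISSING]
            freq_a = float(1.0 - obs.sum() / (2 * obs.size)) if obs.size else np.nan
            rec = _locus_record(
                codes, idx, chrom=str(row["chrom"]),
                start=int(row["pos_bp"]), end=int(row["pos_bp"]), n_snp=1,
                allele_id=str(row["marker_id"]), carrier_freq=freq_a,
                config=config, engine=engine, resolution=resolution,
                seed=seed + r)
            if rec is not None:
                records.append(rec)
        return records

    if mode == "windows":
        if gt.hap_a is None or not bool(gt.phased.any()):
            raise ValueError("window mode requires phased genotypes")
        from .window_recode import recode_biallelic

        parent_ids = {gt.samples[i] for i in parents}
        sizes = window_sizes if window_sizes is not None else config.window_sizes
        for size in sizes:
            for w in make_windows(gt.markers, size, config.window_step):
                for allele in enumerate_alleles(gt, w, parent_ids):
                    codes = recode_biallelic(gt, w, allele)
                    rec = _locus_record(
                        codes, idx, chrom=w.chrom, start=w.start_bp,
                        end=w.end_bp, n_snp=size, allele_id=allele.label,
                        carrier_freq=allele.carrier_frequency,
                        config=config, engine=engine, resolution=resolution,
                        seed=seed + hash(allele.label) % 100_000)
                    if rec is not None:
                        records.append(rec)
        return records

    raise ValueError(f"unknown scan mode: {mode}")


# ---------------------------------------------------------------------------
# empirical null table
# ---------------------------------------------------------------------------

DEFAULT_MATING_MIX = {"ABxAA": 0.2, "ABxBB": 0.2, "AAxAB": 0.2,
                      "BBxAB": 0.2, "ABxAB": 0.2}
DEFAULT_NULL_BINS = (20, 50, 100, 250, 500, 1000, 2500, 5000, 10000, 25000)


@dataclass
class NullTable:
    """Two-sided Mendelian-sampling exceedance thresholds per offspring bin.

    ``thresholds[param][i]`` is the smallest magnitude t with
    P(|estimate| >= t) <= p_null under Mendelian segregation for loci in
    offspring bin ``bins[i]``; +inf when no magnitude is that rare.
    Thresholds are non-increasing in offspring count.
    """

    bins: np.ndarray
    thresholds: dict[str, np.ndarray]
    p_null: float
    replicates: int
    seed: int

    def threshold(self, param: str, n_informative: int) -> float:
        i = int(np.searchsorted(self.bins, n_informative, side="right") - 1)
        i = max(i, 0)
        return float(self.thresholds[param][i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_informative": self.bins,
                             **{k: v for k, v in self.thresholds.items()}})


def _null_estimates(n: int, mix: dict[str, float], replicates: int,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Moment estimates of each TRD parameter under Mendelian sampling.

    Offspring are allocated to matings by ``mix`` and their genotypes drawn
    at the Mendelian ratios; the estimators are the transmission-fraction
    statistics (alpha, alpha_s, alpha_d) and the het x het genotype moments
    (alpha_g = 2(pAA - pBB), delta_g = 2 pAB - 1).
    """
    matings = list(mix)
    probs = np.array([mix[m] for m in matings], dtype=float)
    probs = probs / probs.sum()
    n_mating = rng.multinomial(n, probs, size=replicates)
    cols = dict(zip(matings, n_mating.T))
    z = np.zeros(replicates, dtype=np.int64)
    # two-cell het x hom matings: first-cell count ~ Binomial(n_m, 1/2)
    k = {m: rng.binomial(cols.get(m, z), 0.5) for m in
         ("ABxAA", "ABxBB", "AAxAB", "BBxAB")}
    n_hh = cols.get("ABxAB", z)
    aa = rng.binomial(n_hh, 0.25)
    ab = rng.binomial(n_hh - aa, 2.0 / 3.0)
    bb = n_hh - aa - ab

    with np.errstate(divide="ignore", invalid="ignore"):
        # overall: A-transmissions from het parents over total transmissions
        a_trans = (k["ABxAA"] + k["ABxBB"] + k["AAxAB"] + k["BBxAB"]
                   + 2 * aa + ab)
        t_trans = (cols.get("ABxAA", z) + cols.get("ABxBB", z)
                   + cols.get("AAxAB", z) + cols.get("BBxAB", z) + 2 * n_hh)
        alpha = a_trans / t_trans - 0.5
        # sire-specific: het-sire matings; het x het restricted to the
        # unambiguous AA/BB offspring (AB carries no sire information)
        a_s = k["ABxAA"] + k["ABxBB"] + aa
        t_s = cols.get("ABxAA", z) + cols.get("ABxBB", z) + aa + bb
        alpha_s = a_s / t_s - 0.5
        a_d = k["AAxAB"] + k["BBxAB"] + aa
        t_d = cols.get("AAxAB", z) + cols.get("BBxAB", z) + aa + bb
        alpha_d = a_d / t_d - 0.5
        # genotypic moments from het x het matings
        alpha_g = 2.0 * (aa - bb) / n_hh
        delta_g = 2.0 * ab / n_hh - 1.0
    return {"alpha": alpha, "alpha_s": alpha_s, "alpha_d": alpha_d,
            "alpha_g": alpha_g, "delta_g": delta_g}


def _exceedance_threshold(est: np.ndarray, p_null: float) -> float:
    """Smallest observed magnitude with empirical exceedance <= p_null."""
    mag = np.abs(est[np.isfinite(est)])
    if mag.size == 0:
        return np.inf
    k_max = p_null * mag.size
    uniq = np.unique(mag)
    n_ge = mag.size - np.searchsorted(np.sort(mag), uniq, side="left")
    ok = n_ge <= k_max
    if not ok.any():
        return np.inf
    return float(uniq[np.argmax(ok)])


def build_null_table(bins: Sequence[int] = DEFAULT_NULL_BINS,
                     mating_mix: dict[str, float] = None,
                     replicates: int = DEFAULT_CONFIG.null_replicates,
                     p_null: float = DEFAULT_CONFIG.p_null,
                     seed: int = 0) -> NullTable:
    """Empirical null thresholds of the TRD estimators by offspring count.

    Draws ``replicates`` Mendelian datasets per bin and records the
    (1 - p_null) two-sided exceedance magnitude of each parameter's
    estimator.  Reproducible by seed; thresholds forced non-increasing in
    offspring count.
    """
    if mating_mix is None:
        mating_mix = DEFAULT_MATING_MIX
    if not bins:
        raise ValueError("at least one offspring bin required")
    if replicates < 10 / p_null:
        logger.warning("null table: %d replicates is below the recommended "
                       "10/p_null = %.0f", replicates, 10 / p_null)
    rng = np.random.default_rng(seed)
    bins_arr = np.asarray(sorted(bins), dtype=np.int64)
    params = ("alpha", "alpha_s", "alpha_d", "alpha_g", "delta_g")
    raw = {p: np.empty(bins_arr.size) for p in params}
    for i, n in enumerate(bins_arr):
        est = _null_estimates(int(n), mating_mix, replicates, rng)
        for p in params:
            raw[p][i] = _exceedance_threshold(est[p], p_null)
    # enforce monotonicity: a smaller sample can never have a lower threshold
    thresholds = {p: np.maximum.accumulate(v[::-1])[::-1]
                  for p, v in raw.items()}
    return NullTable(bins_arr, thresholds, p_null, replicates, seed)


# ---------------------------------------------------------------------------
# filtering ledger
# ---------------------------------------------------------------------------

def _sire_transmissions(trios: TrioSet):
    """(sire_id, transmitted allele 0/1) for unambiguous het-sire trios."""
    het = trios.sire == 1
    dam, off = trios.dam[het], trios.offspring[het]
    ids = trios.sire_ids[het]
    allele = np.full(off.size, -1, dtype=np.int8)
    hom = dam != 1
    allele[hom] = off[hom] - dam[hom] // 2
    allele[~hom & (off == 0)] = 0
    allele[~hom & (off == 2)] = 1
    keep = allele >= 0
    return ids[keep], allele[keep]


def _fully_skewed_sires(trios: TrioSet) -> list[tuple[str, int]]:
    """Sire families whose unambiguous transmissions are all one allele,
    sorted by family size descending."""
    ids, allele = _sire_transmissions(trios)
    out = []
    for sire in pd.unique(ids):
        a = allele[ids == sire]
        if a.size and (a == a[0]).all():
            out.append((sire, int(a.size)))
    out.sort(key=lambda t: -t[1])
    return out


def apply_filters(records: list[RegionRecord],
                  null_table: Optional[NullTable] = None,
                  config: ScanConfig = DEFAULT_CONFIG) -> list[RegionRecord]:
    """Append the four-filter audit trail to every record (in place).

    Flags are independent; the final verdict is their conjunction.  Records
    below the decisive BF carry flags too, but only decisive records store
    the trio-level data the sire-robustness refits need; non-decisive
    records pass that filter vacuously.
    """
    for rec in records:
        flags: list[tuple[str, bool]] = []
        flags.append(("informative_parents",
                      rec.n_het_sires >= config.min_het_sires
                      or rec.n_het_dams >= config.min_het_dams))
        flags.append(("sire_robustness", _sire_robust(rec, config)))
        if null_table is not None:
            sel = rec.fits[rec.selected_model]
            exceeds = [
                abs(float(mu)) >= null_table.threshold(name, rec.n_informative)
                for name, mu in zip(sel.param_names, sel.mean)
            ]
            flags.append(("null_exceedance", any(exceeds)))
        flags.append(("stability", _lead_cv(rec) <= config.max_cv))
        rec.filter_flags = flags
    return records


def _lead_cv(rec: RegionRecord) -> float:
    """CV of the selected model's lead (largest-magnitude) parameter."""
    sel = rec.fits[rec.selected_model]
    i = int(np.argmax(np.abs(sel.mean)))
    return float(sel.cv[i])


def _sire_robust(rec: RegionRecord, config: ScanConfig) -> bool:
    if not rec.decisive or rec.trios is None:
        return True
    skewed = _fully_skewed_sires(rec.trios)[: config.skewed_sire_k]
    if not skewed:
        return True
    for sire, _size in skewed:
        sub = rec.trios.subset(rec.trios.sire_ids != sire)
        counts = tabulate(sub)
        gp = grid_fit(counts, rec.bf_model, resolution=config.grid_resolution)
        from .bayes_engine import bayes_factor
        if bayes_factor(counts, rec.bf_model, fit=gp) < config.bf_decisive:
            return False
    return True


# ---------------------------------------------------------------------------
# integration: dedup, smoothing, core regions
# ---------------------------------------------------------------------------

def dedup_best_bf(records: list[RegionRecord]) -> list[RegionRecord]:
    """Keep only the highest-BF record within each overlap cluster.

    Records on one chromosome whose intervals transitively overlap form a
    cluster; ties break toward the smaller interval, then leftmost start.
    """
    kept: list[RegionRecord] = []
    by_chrom: dict[str, list[RegionRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: (r.start_bp, r.end_bp))
        cluster: list[RegionRecord] = []
        cluster_end = -np.inf
        for r in recs:
            if cluster and r.start_bp > cluster_end:
                kept.append(_best_of(cluster))
                cluster = []
                cluster_end = -np.inf
            cluster.append(r)
            cluster_end = max(cluster_end, r.end_bp)
        if cluster:
            kept.append(_best_of(cluster))
    return kept


def _best_of(cluster: list[RegionRecord]) -> RegionRecord:
    return max(cluster, key=lambda r: (r.bf, -(r.end_bp - r.start_bp),
                                       -r.start_bp))


def kernel_smooth(records: list[RegionRecord], sigma_bp: float,
                  query: Optional[dict[str, np.ndarray]] = None,
                  step: Optional[float] = None) -> SmoothTrack:
    """Gaussian-kernel smoothing of record BF along each chromosome.

    y_hat(i) = sum_j N(k_i - k_j; sigma) * BF_j, rescaled by
    sqrt(2 pi sigma^2) so that an isolated record's peak equals its BF.
    Records anchor at their interval midpoint; infinite BF values are
    clipped to the largest finite BF present (the smoothed track is a
    mapping aid, not an inference).
    """
    if sigma_bp <= 0:
        raise ValueError("sigma must be positive")
    if step is None:
        step = sigma_bp / 10.0
    by_chrom: dict[str, list[RegionRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    all_bf = np.array([r.bf for r in records], dtype=float)
    finite = all_bf[np.isfinite(all_bf)]
    finite_max = float(finite.max()) if finite.size else 1e300
    for chrom, recs in by_chrom.items():
        anchors = np.array([r.midpoint for r in recs], dtype=float)
        bf = np.array([min(r.bf, finite_max) for r in recs], dtype=float)
        if query is not None and chrom in query:
            q = np.asarray(query[chrom], dtype=float)
        else:
            q = np.arange(anchors.min() - 3 * sigma_bp,
                          anchors.max() + 3 * sigma_bp + step, step)
        z = (q[:, None] - anchors[None, :]) / sigma_bp
        y = (np.exp(-0.5 * z * z) * bf[None, :]).sum(axis=1)
        out[chrom] = (q, y)
    return SmoothTrack(sigma_bp=sigma_bp, chroms=out, rescaled=True)


def significance_halfwidth(sigma_bp: float, coverage: float) -> float:
    """Half-width (bp) of the significance span around a smoothed-BF peak.

    z * sigma with z the two-sided standard-normal quantile of ``coverage``
    rounded to two decimals (1.96, 2.58, 3.29 for 95/99/99.9 %).
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    z = round(float(norm.ppf(0.5 + coverage / 2.0)), 2)
    return z * sigma_bp


def extract_core_regions(track: SmoothTrack, min_peak: float,
                         coverage: float = 0.95) -> list[CoreRegion]:
    """Separated local maxima of the smoothed track above ``min_peak``.

    Adjacent peaks merge (keeping the taller) unless the track dips below
    half the smaller peak between them.  Each core region spans
    peak +/- significance_halfwidth(sigma, coverage).
    """
    half = significance_halfwidth(track.sigma_bp, coverage)
    cores: list[CoreRegion] = []
    for chrom, (pos, y) in track.chroms.items():
        if y.size < 3:
            continue
        idx = [i for i in range(1, y.size - 1)
               if y[i] >= y[i - 1] and y[i] >= y[i + 1] and y[i] >= min_peak]
        # collapse plateau runs to their centre
        peaks: list[int] = []
        for i in idx:
            if peaks and i - peaks[-1] == 1 and y[i] == y[peaks[-1]]:
                continue
            peaks.append(i)
        changed = True
        while changed and len(peaks) > 1:
            changed = False
            for a, b in zip(peaks, peaks[1:]):
                valley = y[a:b + 1].min()
                if valley >= 0.5 * min(y[a], y[b]):
                    peaks.remove(a if y[a] <= y[b] else b)
                    changed = True
                    break
        for i in peaks:
            cores.append(CoreRegion(chrom, float(pos[i]), float(y[i]),
                                    float(pos[i] - half), float(pos[i] + half)))
    cores.sort(key=lambda c: (c.chrom, c.peak_bp))
    return cores


def under_represented(n_informative: int, trd_magnitude: float) -> int:
    """Estimated missing (non-viable) offspring: n x 2 x |TRD|, rounded."""
    if n_informative < 0:
        raise ValueError("n_informative must be >= 0")
    if abs(trd_magnitude) > 0.5:
        raise ValueError("|TRD| cannot exceed 0.5")
    return int(round(n_informative * 2.0 * abs(trd_magnitude)))


def integrate(records: list[RegionRecord], config: ScanConfig = DEFAULT_CONFIG,
              sigma_bp: Optional[float] = None,
              ) -> tuple[list[RegionRecord], SmoothTrack, list[CoreRegion]]:
    """Significant records -> dedup -> smoothing -> core regions."""
    sigma = sigma_bp if sigma_bp is not None else config.smooth_sigma_bp
    significant = [r for r in records
                   if r.bf >= config.bf_decisive and r.passed_filters]
    deduped = dedup_best_bf(significant)
    if not deduped:
        return [], SmoothTrack(sigma, {}), []
    track = kernel_smooth(deduped, sigma)
    cores = extract_core_regions(track, min_peak=config.bf_decisive)
    return deduped, track, cores


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def write_regions_tsv(records: list[RegionRecord], path: str) -> None:
    pd.DataFrame([r.to_row() for r in records]).to_csv(
        path, sep="\t", index=False)


def write_core_bed(cores: list[CoreRegion], path: str) -> None:
    """Core regions as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for c in cores:
            start = max(0, int(c.start_bp) - 1)
            fh.write(f"{c.chrom}\t{start}\t{int(c.end_bp)}\t"
                     f"peak@{int(c.peak_bp)}\t{c.peak_value:.4g}\n")


def write_bedgraph(track: SmoothTrack, path: str) -> None:
    track.to_bedgraph(path)


def write_run_metadata(path: str, config: ScanConfig, seed: int,
                       extra: Optional[dict] = None) -> None:
    import trdkit

    meta = {"version": trdkit.__version__, "seed": seed,
            "config": dataclasses.asdict(config)}
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
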