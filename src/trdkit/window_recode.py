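"""Sliding SNP windows and biallelic recoding of haplotype alleles.

A window of k consecutive SNPs on one chromosome defines multi-SNP
haplotype alleles (the distinct phased allele strings observed among
parental haplotypes).  Each haplotype allele H_j is then recoded against
the pool of all remaining alleles H_-j as a biallelic pseudo-marker — an
individual's pseudo-genotype is its count of haplotypes equal to H_j — so
the whole allelic/genotypic TRD machinery applies to windows unchanged.
Window mode requires phased input; no on-the-fly phasing is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeTable

logger = logging.getLogger("trdkit")

__all__ = ["Window", "HaplotypeAllele", "make_windows",
           "enumerate_alleles", "recode_biallelic"]


@dataclass(frozen=True)
class Window:
    """k consecutive markers of one chromosome (map order)."""

    chrom: str
    marker_ids: tuple[str, ...]
    rows: tuple[int, ...]          # row indices into the genotype table
    start_bp: int
    end_bp: int

    @property
    def size(self) -> int:
        return len(self.marker_ids)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"


@dataclass(frozen=True)
class HaplotypeAllele:
    """One observed haplotype string H_j of a window."""

    window: Window
    allele: tuple[int, ...]        # ordered 0/1 alleles, length = window size
    carrier_frequency: float       # fraction of included parental haplotypes

    @property
    def allele_string(self) -> str:
        return "".join(map(str, self.allele))

    @property
    def label(self) -> str:
        return f"{self.window.label}:{self.allele_string}"


def make_windows(markers: pd.DataFrame, size: int, step: int = 1) -> list[Window]:
    """All sliding windows of ``size`` markers, never spanning chromosomes.

    For step 1 each chromosome contributes max(0, n_markers - size + 1)
    windows; a chromosome with fewer markers than ``size`` contributes none.
    """
    if size < 2:
        raise ValueError("window size must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    windows: list[Window] = []
    for chrom, grp in markers.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        ids = grp["marker_id"].to_numpy()
        pos = grp["pos_bp"].to_numpy()
        for start in range(0, len(rows) - size + 1, step):
            sl = slice(start, start + size)
            windows.append(Window(
                chrom=str(chrom),
                marker_ids=tuple(ids[sl]),
                rows=tuple(int(r) for r in rows[sl]),
                start_bp=int(pos[start]),
                end_bp=int(pos[start + size - 1]),
            ))
    return windows


def _phased_haplotypes(gt: GenotypeTable, window: Window):
    """(hap_a, hap_b, included-mask) at the window's markers.

    Individuals with any missing or unphased entry inside the window are
    excluded (and counted in the log).
    """
    if gt.hap_a is None:
        raise ValueError("window recoding requires phased genotypes")
    rows = list(window.rows)
    ok = gt.phased[rows].all(axis=0)
    ok &= (gt.hap_a[rows] != MISSING).all(axis=0)
    ok &= (gt.hap_b[rows] != MISSING).all(axis=0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.debug("%s: %d individuals excluded (missing/unphased)",
                     window.label, n_dropped)
    return gt.hap_a[rows], gt.hap_b[rows], ok


def enumerate_alleles(gt: GenotypeTable, window: Window,
                      parent_ids=None) -> list[HaplotypeAllele]:
    """Distinct haplotype alleles of ``window`` among parental haplotypes.

    ``parent_ids``: the individuals whose haplotypes define the allele pool
    (the TRD models condition on parental genotypes); defaults to all
    samples.  Frequencies are over included parental haplotypes and sum to 1.
    """
    hap_a, hap_b, ok = _phased_haplotypes(gt, window)
    sel = np.asarray(ok)
    if parent_ids is not None:
        wanted = set(parent_ids)
        in_parents = np.array([s in wanted for s in gt.samples])
        sel = sel & in_parents
    if not sel.any():
        return []
    haps = np.concatenate([hap_a[:, sel].T, hap_b[:, sel].T])  # (2n, k)
    uniq, counts = np.unique(haps, axis=0, return_counts=True)
    total = counts.sum()
    alleles = [
        HaplotypeAllele(window, tuple(int(a) for a in uniq[i]),
                        carrier_frequency=float(counts[i] / total))
        for i in range(uniq.shape[0])
    ]
    alleles.sort(key=lambda h: -h.carrier_frequency)
    return alleles


def recode_biallelic(gt: GenotypeTable, window: Window,
                     allele: HaplotypeAllele) -> np.ndarray:
    """Pseudo-genotype column: per-sample count of haplotypes equal to H_j.

    All non-H_j strings pool into H_-j; the pseudo-genotype is 2 for
    H_j/H_j, 1 for H_j/H_-j and 0 for H_-j/H_-j, so the focal haplotype
    plays the role of allele B in the downstream kernels (orientation only
    flips parameter signs).  Individuals excluded from the window get a
    missing pseudo-genotype.
    """
    hap_a, hap_b, ok = _phased_haplotypes(gt, window)
    target = np.asarray(allele.allele, dtype=hap_a.dtype)[:, None]
    match = (hap_a == target).all(axis=0).astype(np.int16) + \
            (hap_b == target).all(axis=0).astype(np.int16)
    codes = np.where(ok, match, MISSING).astype(np.int16)
    return codes
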