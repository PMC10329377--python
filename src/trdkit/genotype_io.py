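"""Genotype, pedigree and marker-map I/O, and trio assembly.

Input genotypes are diploid biallelic SNP calls coded as the count of the
alternate allele B (0 = AA, 1 = AB, 2 = BB, -1 = missing), optionally phased.
Two on-disk dialects are supported:

* variant-call format (plain-text VCF with a GT field; ``|`` marks a phased
  call, ``/`` an unphased one), read through :mod:`cyvcf2`;
* a simple matrix TSV with one row per marker (``marker_id  chrom  pos_bp``
  followed by one column per sample).  Cells hold ``0/1/2/NA`` for unphased
  entries; phased entries serialize as ordered allele pairs ``a|b``
  (paternal slot first) so that a write/read round trip preserves phase.

A pedigree is a three-column table (offspring, sire, dam).  Trio assembly
pairs each offspring's genotype with both parents' genotypes at one marker,
drops incomplete trios, screens Mendelian-inconsistent trios (a genotyping
error signature) and counts distinct heterozygous parents — the raw material
of every transmission-ratio-distortion fit downstream.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("trdkit")

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeTable",
    "TrioSet",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "validate_pedigree",
    "validate_marker_map",
    "assemble_trios",
    "trios_from_codes",
    "mendelian_check",
    "mendelian_consistent_mask",
    "minor_allele_frequency",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Genotype codes (and optional phase) for samples × markers.

    ``codes`` has shape (n_markers, n_samples) with entries in {0,1,2,-1}.
    When phase is known, ``hap_a``/``hap_b`` hold the ordered allele pair
    (paternal slot, maternal slot; alleles 0/1, -1 missing) and ``phased``
    flags the entries whose ordering is meaningful.  Phased entries always
    satisfy ``hap_a + hap_b == codes``.
    """

    samples: list[str]
    markers: pd.DataFrame  # columns: chrom, marker_id, pos_bp
    codes: np.ndarray
    hap_a: Optional[np.ndarray] = None
    hap_b: Optional[np.ndarray] = None
    phased: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        validate_marker_map(self.markers)
        n_markers, n_samples = self.codes.shape
        if n_markers != len(self.markers) or n_samples != len(self.samples):
            raise ValueError("codes shape does not match markers/samples")
        if self.phased is None:
            self.phased = np.zeros_like(self.codes, dtype=bool)
        if self.hap_a is not None:
            ok = ~self.phased | (self.hap_a + self.hap_b == self.codes)
            if not ok.all():
                raise ValueError("phased haplotypes inconsistent with codes")
        self._marker_index = {
            m: i for i, m in enumerate(self.markers["marker_id"])
        }

    @property
    def n_markers(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def marker_row(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id: {marker_id}") from None

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.samples)}

    @property
    def fully_phased(self) -> bool:
        """True when every non-missing entry carries phase."""
        if self.hap_a is None:
            return False
        return bool((self.phased | (self.codes == MISSING)).all())


@dataclass
class TrioSet:
    """Mendelian-consistent genotype trios at one (pseudo-)marker.

    Arrays are aligned per trio; parents may repeat across trios (half-sib
    families), so heterozygous-parent counts are over distinct individuals.
    """

    marker: str
    sire: np.ndarray
    dam: np.ndarray
    offspring: np.ndarray
    sire_ids: np.ndarray
    dam_ids: np.ndarray
    n_het_sires: int
    n_het_dams: int
    n_inconsistent: int
    usable: bool

    @property
    def n_trios(self) -> int:
        return self.sire.size

    @property
    def n_informative(self) -> int:
        """Offspring whose mating has at least one heterozygous parent."""
        return int(((self.sire == 1) | (self.dam == 1)).sum())

    def subset(self, mask: np.ndarray) -> "TrioSet":
        """A new TrioSet restricted to ``mask`` (het-parent counts refreshed)."""
        sire, dam = self.sire[mask], self.dam[mask]
        sire_ids, dam_ids = self.sire_ids[mask], self.dam_ids[mask]
        return TrioSet(
            marker=self.marker,
            sire=sire,
            dam=dam,
            offspring=self.offspring[mask],
            sire_ids=sire_ids,
            dam_ids=dam_ids,
            n_het_sires=len(set(sire_ids[sire == 1])),
            n_het_dams=len(set(dam_ids[dam == 1])),
            n_inconsistent=self.n_inconsistent,
            usable=self.usable,
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_marker_map(markers: pd.DataFrame) -> None:
    """Check marker-map invariants: unique ids, sorted increasing positions."""
    required = {"chrom", "marker_id", "pos_bp"}
    if not required.issubset(markers.columns):
        raise ValueError(f"marker map needs columns {sorted(required)}")
    if markers["marker_id"].duplicated().any():
        dup = markers["marker_id"][markers["marker_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicated marker id: {dup}")
    for chrom, grp in markers.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"positions not strictly increasing on {chrom}")


def validate_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Check pedigree invariants; returns the (unmodified) frame."""
    required = ["offspring", "sire", "dam"]
    if list(ped.columns[:3]) != required:
        if set(required).issubset(ped.columns):
            ped = ped[required]
        else:
            raise ValueError("pedigree needs columns offspring/sire/dam")
    if ped["offspring"].duplicated().any():
        dup = ped["offspring"][ped["offspring"].duplicated()].iloc[0]
        raise ValueError(f"duplicated offspring id: {dup}")
    off = ped["offspring"].to_numpy()
    edges = list(zip(ped["sire"].to_numpy(), off))
    edges += list(zip(ped["dam"].to_numpy(), off))
    g = nx.DiGraph(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("pedigree contains an ancestry cycle")
    return ped


def read_pedigree(path: str) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype=str)
    return validate_pedigree(ped)


def write_pedigree(ped: pd.DataFrame, path: str) -> None:
    ped[["offspring", "sire", "dam"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path: str, dialect: str = "matrix_tsv") -> GenotypeTable:
    """Read genotypes + marker map from ``path`` under the given dialect.

    dialect ``vcf``: biallelic SNP records only; multi-allelic records are
    skipped with a logged count.  dialect ``matrix_tsv``: the package's
    matrix layout (see module docstring).
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "matrix_tsv":
        return _read_matrix(path)
    raise ValueError(f"unknown dialect: {dialect}")


def _read_vcf(path: str) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, codes, hap_a, hap_b, phased = [], [], [], [], []
    n_multi = 0
    seen_ids: set[str] = set()
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        if mid in seen_ids:
            raise ValueError(f"duplicated marker id: {mid}")
        seen_ids.add(mid)
        g = np.array(v.genotypes, dtype=np.int16)  # (n_samples, 3)
        a, b, ph = g[:, 0], g[:, 1], g[:, 2].astype(bool)
        miss = (a < 0) | (b < 0)
        code = np.where(miss, MISSING, a + b)
        rows.append((v.CHROM, mid, v.POS))
        codes.append(code)
        hap_a.append(np.where(miss, MISSING, a).astype(np.int8))
        hap_b.append(np.where(miss, MISSING, b).astype(np.int8))
        phased.append(ph & ~miss)
    if n_multi:
        logger.info("skipped %d multi-allelic records in %s", n_multi, path)
    markers = pd.DataFrame(rows, columns=["chrom", "marker_id", "pos_bp"])
    return GenotypeTable(
        samples=samples,
        markers=markers,
        codes=np.asarray(codes, dtype=np.int16),
        hap_a=np.asarray(hap_a, dtype=np.int8),
        hap_b=np.asarray(hap_b, dtype=np.int8),
        phased=np.asarray(phased, dtype=bool),
    )


def _read_matrix(path: str) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["marker_id", "chrom", "pos_bp"]
    if list(df.columns[:3]) != fixed:
        raise ValueError(f"matrix TSV must start with columns {fixed}")
    samples = list(df.columns[3:])
    markers = df[fixed].copy()
    markers["pos_bp"] = markers["pos_bp"].astype(np.int64)
    markers = markers[["chrom", "marker_id", "pos_bp"]]
    n_m, n_s = len(df), len(samples)
    codes = np.full((n_m, n_s), MISSING, dtype=np.int16)
    hap_a = np.full((n_m, n_s), MISSING, dtype=np.int8)
    hap_b = np.full((n_m, n_s), MISSING, dtype=np.int8)
    phased = np.zeros((n_m, n_s), dtype=bool)
    if n_s:
        cells = df[samples].astype(str).to_numpy(dtype="U3")
        missing = (cells == "NA") | (cells == "nan") | (cells == "")
        piped = np.char.find(cells, "|") >= 0
        plain = ~missing & ~piped
        tok = pd.Series(cells[piped]) if piped.any() else pd.Series(dtype=str)
        try:
            if piped.any():
                a = tok.str[0].astype(np.int8).to_numpy()
                b = tok.str[2].astype(np.int8).to_numpy()
                if not ((cells[piped] == pd.Series(a.astype(str)).str
                         .cat(pd.Series(b.astype(str)), sep="|")).all()
                        and np.isin(a, (0, 1)).all()
                        and np.isin(b, (0, 1)).all()):
                    raise ValueError
                hap_a[piped], hap_b[piped] = a, b
                codes[piped] = (a + b).astype(np.int16)
                phased[piped] = True
            if plain.any():
                c = pd.to_numeric(pd.Series(cells[plain]),
                                  errors="raise").to_numpy()
                if not np.isin(c, (0, 1, 2)).all():
                    raise ValueError
                codes[plain] = c.astype(np.int16)
        except (ValueError, TypeError):
            bad = ~missing & ~np.isin(cells, ("0", "1", "2", "0|0", "0|1",
                                              "1|0", "1|1"))
            line = int(np.nonzero(bad.any(axis=1))[0][0]) + 2
            raise ValueError(f"malformed genotype at line {line}") from None
    return GenotypeTable(samples, markers, codes, hap_a, hap_b, phased)


def write_genotypes(gt: GenotypeTable, path: str, dialect: str = "matrix_tsv") -> None:
    """Write a GenotypeTable in either dialect (round-trip safe)."""
    if dialect == "matrix_tsv":
        _write_matrix(gt, path)
    elif dialect == "vcf":
        _write_vcf(gt, path)
    else:
        raise ValueError(f"unknown dialect: {dialect}")


def _write_matrix(gt: GenotypeTable, path: str) -> None:
    cells = np.empty(gt.codes.shape, dtype=object)
    cells[:] = "NA"
    unphased = (gt.codes != MISSING) & ~gt.phased
    cells[unphased] = gt.codes[unphased].astype(str)
    if gt.hap_a is not None and gt.phased.any():
        # vectorized "a|b" tokens for phased entries
        ph = gt.phased
        tok = np.char.add(
            np.char.add(gt.hap_a[ph].astype(str), "|"),
            gt.hap_b[ph].astype(str))
        cells[ph] = tok
    body = pd.DataFrame(cells, columns=gt.samples)
    head = gt.markers[["marker_id", "chrom", "pos_bp"]].reset_index(drop=True)
    pd.concat([head, body], axis=1).to_csv(path, sep="\t", index=False)


def _write_vcf(gt: GenotypeTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gt.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gt.samples) + "\n")
        for i in range(gt.n_markers):
            row = gt.markers.iloc[i]
            gts = []
            for j in range(gt.n_samples):
                c = gt.codes[i, j]
                if c == MISSING:
                    gts.append("./.")
                elif gt.phased[i, j]:
                    gts.append(f"{gt.hap_a[i, j]}|{gt.hap_b[i, j]}")
                else:
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(c)])
            fh.write(f"{row['chrom']}\t{row['pos_bp']}\t{row['marker_id']}"
                     f"\tA\tB\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Mendelian screening
# ---------------------------------------------------------------------------

def _consistency_table() -> np.ndarray:
    """27-entry lookup: gamete enumeration over all genotype triples."""
    gametes = {0: (0,), 1: (0, 1), 2: (1,)}
    table = np.zeros((3, 3, 3), dtype=bool)
    for s, d, o in itertools.product(range(3), repeat=3):
        table[s, d, o] = any(
            p + m == o for p in gametes[s] for m in gametes[d]
        )
    return table


_CONSISTENT = _consistency_table()


def mendelian_check(sire: int, dam: int, offspring: int) -> bool:
    """True when some pair of parental gametes can produce the offspring."""
    if MISSING in (sire, dam, offspring):
        raise ValueError("mendelian_check requires non-missing genotypes")
    return bool(_CONSISTENT[sire, dam, offspring])


def mendelian_consistent_mask(
    sire: np.ndarray, dam: np.ndarray, offspring: np.ndarray
) -> np.ndarray:
    return _CONSISTENT[sire, dam, offspring]


# ---------------------------------------------------------------------------
# trio assembly
# ---------------------------------------------------------------------------

def assemble_trios(
    gt: GenotypeTable,
    ped: pd.DataFrame,
    marker_id: str,
    min_trios: int = 10,
) -> TrioSet:
    """Assemble all complete, Mendelian-consistent trios at one marker."""
    row = gt.marker_row(marker_id)
    return trios_from_codes(
        gt.codes[row], gt.samples, ped, marker=marker_id, min_trios=min_trios
    )


def trios_from_codes(
    codes: np.ndarray,
    samples: list[str],
    ped: pd.DataFrame,
    marker: str = "",
    min_trios: int = 10,
) -> TrioSet:
    """Trio assembly from a single genotype-code vector (one per sample).

    Shared by SNP-level assembly and by the haplotype pseudo-marker recode.
    Offspring with an unknown sire or dam id are skipped and logged; trios
    with any missing genotype are dropped; Mendelian-inconsistent trios are
    excluded and tallied.
    """
    index = {s: i for i, s in enumerate(samples)}
    off_idx, sire_idx, dam_idx, sire_ids, dam_ids = [], [], [], [], []
    n_unknown = 0
    for o, s, d in ped[["offspring", "sire", "dam"]].itertuples(index=False):
        try:
            oi, si, di = index[o], index[s], index[d]
        except KeyError:
            n_unknown += 1
            continue
        off_idx.append(oi)
        sire_idx.append(si)
        dam_idx.append(di)
        sire_ids.append(s)
        dam_ids.append(d)
    if n_unknown:
        logger.debug("%s: skipped %d trios with unknown parent/offspring id",
                     marker, n_unknown)
    if not off_idx:
        return TrioSet(marker, *(np.empty(0, dtype=np.int16),) * 3,
                       np.empty(0, dtype=object), np.empty(0, dtype=object),
                       0, 0, 0, usable=False)
    sire = codes[np.asarray(sire_idx)]
    dam = codes[np.asarray(dam_idx)]
    off = codes[np.asarray(off_idx)]
    sire_ids = np.asarray(sire_ids, dtype=object)
    dam_ids = np.asarray(dam_ids, dtype=object)

    complete = (sire != MISSING) & (dam != MISSING) & (off != MISSING)
    sire, dam, off = sire[complete], dam[complete], off[complete]
    sire_ids, dam_ids = sire_ids[complete], dam_ids[complete]

    ok = mendelian_consistent_mask(sire, dam, off)
    n_inconsistent = int((~ok).sum())
    sire, dam, off = sire[ok], dam[ok], off[ok]
    sire_ids, dam_ids = sire_ids[ok], dam_ids[ok]

    n_het_sires = len(set(sire_ids[sire == 1]))
    n_het_dams = len(set(dam_ids[dam == 1]))
    return TrioSet(
        marker=marker,
        sire=sire,
        dam=dam,
        offspring=off,
        sire_ids=sire_ids,
        dam_ids=dam_ids,
        n_het_sires=n_het_sires,
        n_het_dams=n_het_dams,
        n_inconsistent=n_inconsistent,
        usable=sire.size >= min_trios,
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def minor_allele_frequency(gt: GenotypeTable, marker_id: str) -> float:
    """MAF over all non-missing individuals at ``marker_id``."""
    row = gt.marker_row(marker_id)
    codes = gt.codes[row]
    obs = codes[codes != MISSING]
    if obs.size == 0:
        raise ValueError(f"all genotypes missing at {marker_id}")
    f = obs.sum() / (2 * obs.size)
    return float(min(f, 1.0 - f))
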