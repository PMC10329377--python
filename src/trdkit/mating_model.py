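"""Mating types, offspring-count tables and TRD likelihood kernels.

Transmission ratio distortion (TRD) is modeled through the conditional
distribution of offspring genotypes given the parental mating type.  Only
matings with at least one heterozygous parent are informative; ordered
sire × dam they are::

    AB x AA   AB x BB   AA x AB   BB x AB   AB x AB

Three nested parameterizations are fit to the offspring counts:

* allelic, overall: a heterozygous parent transmits allele A with
  probability 0.5 + alpha (flat prior on [-0.5, 0.5]);
* allelic, parent-specific: separate sire (alpha_s) and dam (alpha_d)
  transmission biases;
* genotypic: additive (alpha_g) and dominance (delta_g) distortion of the
  offspring genotype itself, with renormalization in het x hom matings so
  probabilities sum to one.  Admissible (alpha_g, delta_g) are those for
  which every offspring probability lies in [0, 1]:
  ``1 + alpha_g - delta_g >= 0``, ``1 - alpha_g - delta_g >= 0`` and
  ``1 + delta_g >= 0`` (alpha_g in [-1, 1], delta_g in [-1, 1 - |alpha_g|]).

Likelihoods are multinomial over mating-specific offspring cells; the
multinomial coefficient is omitted throughout — it is constant across
models, so Bayes factors and DIC differences are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genotype_io import TrioSet

__all__ = [
    "MATINGS",
    "CELLS",
    "CELL_INDEX",
    "N_CELLS",
    "AllelicParams",
    "GenotypicParams",
    "MatingCountTable",
    "tabulate",
    "allelic_probs",
    "genotypic_probs",
    "allelic_cell_probs",
    "genotypic_cell_probs",
    "null_cell_probs",
    "log_likelihood",
    "genotypic_in_space",
]

# ordered sire x dam matings and their possible offspring genotype codes
MATINGS: tuple[str, ...] = ("ABxAA", "ABxBB", "AAxAB", "BBxAB", "ABxAB")
CELLS: dict[str, tuple[int, ...]] = {
    "ABxAA": (0, 1),
    "ABxBB": (1, 2),
    "AAxAB": (0, 1),
    "BBxAB": (1, 2),
    "ABxAB": (0, 1, 2),
}
# flat layout of the 11 data cells, in MATINGS order
CELL_INDEX: dict[tuple[str, int], int] = {}
for _m in MATINGS:
    for _o in CELLS[_m]:
        CELL_INDEX[(_m, _o)] = len(CELL_INDEX)
N_CELLS = len(CELL_INDEX)  # 11

_MATING_CODE = {(1, 0): "ABxAA", (1, 2): "ABxBB",
                (0, 1): "AAxAB", (2, 1): "BBxAB", (1, 1): "ABxAB"}


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AllelicParams:
    """Allelic transmission bias; ``mode`` overall merges sire and dam."""

    mode: str = "overall"  # "overall" | "parent_specific"
    alpha: float = 0.0
    alpha_s: float = 0.0
    alpha_d: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("overall", "parent_specific"):
            raise ValueError(f"unknown allelic mode: {self.mode}")
        for v in self.values():
            if not -0.5 <= v <= 0.5:
                raise ValueError("allelic parameter outside [-0.5, 0.5]")

    def values(self) -> tuple[float, ...]:
        if self.mode == "overall":
            return (self.alpha,)
        return (self.alpha_s, self.alpha_d)

    @property
    def effective(self) -> tuple[float, float]:
        """(alpha_s, alpha_d) with overall mode tied to a single alpha."""
        if self.mode == "overall":
            return (self.alpha, self.alpha)
        return (self.alpha_s, self.alpha_d)


def genotypic_in_space(alpha_g, delta_g) -> np.ndarray:
    """Vectorized admissibility test for the genotypic parameter space."""
    a = np.asarray(alpha_g, dtype=float)
    d = np.asarray(delta_g, dtype=float)
    return (
        (np.abs(a) <= 1.0)
        & (1.0 + d >= 0.0)
        & (1.0 + a - d >= 0.0)
        & (1.0 - a - d >= 0.0)
    )


@dataclass(frozen=True)
class GenotypicParams:
    """Additive (alpha_g) and dominance (delta_g) genotypic TRD."""

    alpha_g: float = 0.0
    delta_g: float = 0.0

    def __post_init__(self) -> None:
        if not bool(genotypic_in_space(self.alpha_g, self.delta_g)):
            raise ValueError(
                f"(alpha_g={self.alpha_g}, delta_g={self.delta_g}) outside "
                "the admissible genotypic space"
            )

    def values(self) -> tuple[float, float]:
        return (self.alpha_g, self.delta_g)


# complete lethality of the AA homozygote: P_off(AA) = 0 in every mating
RECESSIVE_LETHAL = GenotypicParams(alpha_g=-2.0 / 3.0, delta_g=1.0 / 3.0)


# ---------------------------------------------------------------------------
# count table
# ---------------------------------------------------------------------------

@dataclass
class MatingCountTable:
    """Offspring-genotype counts cross-classified by informative mating.

    ``counts`` is the flat 11-vector in CELL_INDEX order — the data vector y
    of every TRD likelihood.  Structurally impossible cells (e.g. BB
    offspring from AB x AA) are absent by construction.
    """

    counts: np.ndarray
    n_het_sires: int = 0
    n_het_dams: int = 0
    n_inconsistent: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CELLS,):
            raise ValueError(f"counts must have shape ({N_CELLS},)")
        if (self.counts < 0).any():
            raise ValueError("negative count")

    @classmethod
    def from_cells(cls, cells: dict[tuple[str, int], int], **kw) -> "MatingCountTable":
        counts = np.zeros(N_CELLS, dtype=np.int64)
        for key, n in cells.items():
            counts[CELL_INDEX[key]] = n
        return cls(counts, **kw)

    def cell(self, mating: str, offspring: int) -> int:
        return int(self.counts[CELL_INDEX[(mating, offspring)]])

    def mating_total(self, mating: str) -> int:
        return int(sum(self.cell(mating, o) for o in CELLS[mating]))

    @property
    def n_informative(self) -> int:
        return int(self.counts.sum())

    def to_row(self) -> dict:
        """One flat record in the published table layout (per mating cell)."""
        row = {f"{m}:{'AA AB BB'.split()[o]}": self.cell(m, o)
               for m in MATINGS for o in CELLS[m]}
        row.update(n_het_sires=self.n_het_sires, n_het_dams=self.n_het_dams,
                   n_informative=self.n_informative,
                   n_inconsistent=self.n_inconsistent)
        return row


def tabulate(trios: TrioSet) -> MatingCountTable:
    """Tally a TrioSet into a MatingCountTable (sire x dam order preserved)."""
    counts = np.zeros(N_CELLS, dtype=np.int64)
    for (s, d), mating in _MATING_CODE.items():
        sel = (trios.sire == s) & (trios.dam == d)
        if not sel.any():
            continue
        off = trios.offspring[sel]
        for o in CELLS[mating]:
            counts[CELL_INDEX[(mating, o)]] = int((off == o).sum())
    return MatingCountTable(
        counts,
        n_het_sires=trios.n_het_sires,
        n_het_dams=trios.n_het_dams,
        n_inconsistent=trios.n_inconsistent,
    )


# ---------------------------------------------------------------------------
# offspring-probability kernels
# ---------------------------------------------------------------------------

def allelic_cell_probs(alpha_s, alpha_d) -> np.ndarray:
    """Offspring probabilities for all 11 cells, vectorized over parameters.

    ``alpha_s``/``alpha_d`` broadcast; the result has shape
    ``broadcast_shape + (11,)``.  Overall-TRD callers pass alpha twice.
    """
    s = np.asarray(alpha_s, dtype=float)
    d = np.asarray(alpha_d, dtype=float)
    s, d = np.broadcast_arrays(s, d)
    out = np.empty(s.shape + (N_CELLS,), dtype=float)
    ps, qs = 0.5 + s, 0.5 - s
    pd_, qd = 0.5 + d, 0.5 - d
    out[..., CELL_INDEX[("ABxAA", 0)]] = ps
    out[..., CELL_INDEX[("ABxAA", 1)]] = qs
    out[..., CELL_INDEX[("ABxBB", 1)]] = ps
    out[..., CELL_INDEX[("ABxBB", 2)]] = qs
    out[..., CELL_INDEX[("AAxAB", 0)]] = pd_
    out[..., CELL_INDEX[("AAxAB", 1)]] = qd
    out[..., CELL_INDEX[("BBxAB", 1)]] = pd_
    out[..., CELL_INDEX[("BBxAB", 2)]] = qd
    out[..., CELL_INDEX[("ABxAB", 0)]] = ps * pd_
    out[..., CELL_INDEX[("ABxAB", 1)]] = ps * qd + qs * pd_
    out[..., CELL_INDEX[("ABxAB", 2)]] = qs * qd
    return out


def genotypic_cell_probs(alpha_g, delta_g) -> np.ndarray:
    """Genotypic-model probabilities for all 11 cells (vectorized).

    het x hom matings renormalize by 1 +/- alpha_g/2 — the overall loss of
    individuals — so each mating's probabilities sum to one.
    """
    a = np.asarray(alpha_g, dtype=float)
    d = np.asarray(delta_g, dtype=float)
    a, d = np.broadcast_arrays(a, d)
    out = np.empty(a.shape + (N_CELLS,), dtype=float)
    # snap to exact zero at lethality boundaries (e.g. 1 - 2/3 - 1/3)
    v_aa = np.where(np.abs(1.0 + a - d) < 1e-12, 0.0, 1.0 + a - d)
    v_ab = np.where(np.abs(1.0 + d) < 1e-12, 0.0, 1.0 + d)
    v_bb = np.where(np.abs(1.0 - a - d) < 1e-12, 0.0, 1.0 - a - d)
    norm_a = 2.0 * (1.0 + a / 2.0)   # matings with an AA parent
    norm_b = 2.0 * (1.0 - a / 2.0)   # matings with a BB parent
    with np.errstate(divide="ignore", invalid="ignore"):
        out[..., CELL_INDEX[("ABxAA", 0)]] = v_aa / norm_a
        out[..., CELL_INDEX[("ABxAA", 1)]] = v_ab / norm_a
        out[..., CELL_INDEX[("AAxAB", 0)]] = v_aa / norm_a
        out[..., CELL_INDEX[("AAxAB", 1)]] = v_ab / norm_a
        out[..., CELL_INDEX[("ABxBB", 1)]] = v_ab / norm_b
        out[..., CELL_INDEX[("ABxBB", 2)]] = v_bb / norm_b
        out[..., CELL_INDEX[("BBxAB", 1)]] = v_ab / norm_b
        out[..., CELL_INDEX[("BBxAB", 2)]] = v_bb / norm_b
    out[..., CELL_INDEX[("ABxAB", 0)]] = v_aa / 4.0
    out[..., CELL_INDEX[("ABxAB", 1)]] = v_ab / 2.0
    out[..., CELL_INDEX[("ABxAB", 2)]] = v_bb / 4.0
    return out


def null_cell_probs() -> np.ndarray:
    """Mendelian offspring probabilities for all 11 cells."""
    return allelic_cell_probs(0.0, 0.0)


def _mating_slice(mating: str, flat: np.ndarray) -> np.ndarray:
    return np.array([flat[CELL_INDEX[(mating, o)]] for o in CELLS[mating]])


def allelic_probs(mating: str, params: AllelicParams) -> np.ndarray:
    """Offspring probability vector for one mating under the allelic model."""
    if mating not in MATINGS:
        raise ValueError(f"unknown mating: {mating}")
    a_s, a_d = params.effective
    return _mating_slice(mating, allelic_cell_probs(a_s, a_d))


def genotypic_probs(mating: str, params: GenotypicParams) -> np.ndarray:
    """Offspring probability vector for one mating under the genotypic model."""
    if mating not in MATINGS:
        raise ValueError(f"unknown mating: {mating}")
    return _mating_slice(mating, genotypic_cell_probs(*params.values()))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def log_prob_cells(model: str, theta: np.ndarray) -> np.ndarray:
    """log cell probabilities for parameter array ``theta`` (last axis = dim).

    models: ``null`` (theta ignored), ``allelic_overall`` (1),
    ``allelic_parent_specific`` (2: alpha_s, alpha_d), ``genotypic`` (2).
    Cells with probability 0 map to -inf.
    """
    if model == "null":
        p = null_cell_probs()
    elif model == "allelic_overall":
        t = np.asarray(theta, dtype=float)[..., 0]
        p = allelic_cell_probs(t, t)
    elif model == "allelic_parent_specific":
        t = np.asarray(theta, dtype=float)
        p = allelic_cell_probs(t[..., 0], t[..., 1])
    elif model == "genotypic":
        t = np.asarray(theta, dtype=float)
        p = genotypic_cell_probs(t[..., 0], t[..., 1])
    else:
        raise ValueError(f"unknown model: {model}")
    with np.errstate(divide="ignore"):
        return np.log(p)


def log_likelihood(counts: MatingCountTable, model: str, params=None) -> float:
    """Multinomial log-likelihood (coefficient omitted) of one count table.

    ``params`` is an AllelicParams / GenotypicParams / raw parameter tuple
    as the model requires; the null model takes none.  Returns -inf when a
    cell with observations has probability zero.
    """
    theta = _params_to_theta(model, params)
    lp = log_prob_cells(model, theta)
    n = counts.counts.astype(float)
    terms = np.where(n > 0, n * lp, 0.0)
    return float(terms.sum())


def _params_to_theta(model: str, params) -> np.ndarray:
    if model == "null":
        return np.zeros(0)
    if isinstance(params, AllelicParams):
        if model == "allelic_overall":
            return np.array([params.alpha if params.mode == "overall"
                             else params.alpha_s])
        return np.array(params.effective)
    if isinstance(params, GenotypicParams):
        return np.array(params.values())
    if params is None:
        raise ValueError(f"model {model} requires parameters")
    return np.atleast_1d(np.asarray(params, dtype=float))


MODEL_DIM = {"null": 0, "allelic_overall": 1,
             "allelic_parent_specific": 2, "genotypic": 2}
TRD_MODELS = ("allelic_overall", "allelic_parent_specific", "genotypic")
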