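"""Run-time configuration for the TRD scan.

All thresholds that the scan applies (trio minima, informative-parent minima,
Bayes-factor decisiveness, DIC parsimony margin, empirical-null tail
probability, coefficient-of-variation cut, pattern-classification splits,
MCMC chain lengths and grid resolutions) live here so that every stage of the
pipeline reads a single, serializable source of truth.  Values default to the
study design this package implements; a YAML key-value file can override any
of them.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import yaml

logger = logging.getLogger("trdkit")


@dataclass
class ScanConfig:
    """Thresholds and numerical settings for the genome scan."""

    # --- data filters -----------------------------------------------------
    min_trios: int = 10                 # minimum complete trios per locus
    min_het_sires: int = 20             # informative-parent filter ...
    min_het_dams: int = 100             # ... passes on sires OR dams
    # --- significance -----------------------------------------------------
    bf_decisive: float = 100.0          # Jeffreys' decisive-evidence cut
    dic_margin: float = 3.0             # DIC units deemed relevant
    # --- empirical null ---------------------------------------------------
    p_null: float = 1e-5                # "< 0.001 %" two-sided tail
    null_replicates: int = 2_000_000    # Monte-Carlo replicates per bin
    # --- stability --------------------------------------------------------
    max_cv: float = 0.20                # posterior CV cut on the lead parameter
    # --- sire-robustness --------------------------------------------------
    skewed_sire_k: int = 2              # leave-out count of fully-skewed sires
    # --- pattern classification -------------------------------------------
    lethality_margin: float = 0.5       # recessive when hom viability < this
    dominance_split: float = 0.10       # |delta_g| split: heterosis vs hom. adv/dis
    # --- inference engines ------------------------------------------------
    grid_resolution: int = 201          # points per dimension (scan default)
    mcmc_iterations: int = 110_000
    mcmc_burn_in: int = 10_000
    # --- windows ----------------------------------------------------------
    window_sizes: Sequence[int] = (2, 4, 7, 10, 20)
    window_step: int = 1
    # --- smoothing --------------------------------------------------------
    smooth_sigma_bp: float = 500_000.0
    smooth_sigmas_bp: Sequence[float] = (500_000.0, 2_000_000.0, 5_000_000.0)

    @classmethod
    def from_yaml(cls, path: str) -> "ScanConfig":
        """Load a config from a YAML key-value file; unknown keys error."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


DEFAULT_CONFIG = ScanConfig()
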