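"""Synthetic plate-readout generator for dual-luciferase screens.

The generator emulates the statistical structure the analysis assumes:
positive luminescence counts with multiplicative (lognormal) noise around
per-reporter calibration means, a two-level replicate structure (biological
x technical), and planted fold effects on either reporter.

Noise model
-----------
A measurement for group *g*, reporter *r*, biological replicate *b*,
technical replicate *t* is drawn as::

    counts = calib_r * m_{g,r} * B_{g,b} * T_{g,r,b,t}

where ``m`` is the planted fold multiplier and ``B`` and ``T`` are
independent mean-one lognormal factors.  The total log-variance
``sigma^2 = ln(1 + cv_total^2)`` is split between the biological and
technical level by ``bio_fraction``; each factor uses the mean-one
parameterization (log-mean ``-sigma_i^2/2``), so the expectation of every
count is exactly ``calib_r * m``.  The biological factor is shared between
the FF and REN reporters of the same replicate — both are read from the
same culture, which is the covariation the dual-reporter design exists to
cancel.

With ``cv_total = 0.24`` the standard deviation of wild-type-normalized
single measurements converges to 0.24, i.e. a two-fold SD of 48%, matching
the calibration of the screen this package models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ReadoutTable
from .manifest import StrainManifest

__all__ = [
    "EffectSpec",
    "SimConfig",
    "DEFAULT_DOSES",
    "dose_multiplier",
    "simulate_screen",
    "simulate_dose_panel",
]

#: default dose grid, molar: six decades from 1 nM to 100 uM.
DEFAULT_DOSES: tuple[float, ...] = (1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)


@dataclass(frozen=True)
class EffectSpec:
    """A planted fold effect on one strain or compound.

    ``ff_multiplier``/``ren_multiplier`` scale the mean of the respective
    reporter.  For compounds they are the *top-dose* multipliers; the
    effect at lower doses follows :func:`dose_multiplier` with shape
    exponent ``exponent``.
    """

    target_id: str
    ff_multiplier: float = 1.0
    ren_multiplier: float = 1.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.ff_multiplier <= 0 or self.ren_multiplier <= 0:
            raise ValueError(f"{self.target_id}: multipliers must be positive")
        if self.exponent <= 0:
            raise ValueError(f"{self.target_id}: dose exponent must be positive")


@dataclass
class SimConfig:
    """Generator calibration: replicate structure, means, noise and seed."""

    n_bio: int = 2
    n_tech: int = 3
    calib_ff: float = 1.0e4
    calib_ren: float = 8.0e7
    cv_total: float = 0.24
    bio_fraction: float = 0.5
    seed: int = 0
    doses: tuple[float, ...] = DEFAULT_DOSES
    assay_variant: str = "dual_luciferase_screen"

    def __post_init__(self) -> None:
        self.doses = tuple(self.doses)
        self.validate()

    def validate(self) -> None:
        if self.n_bio < 1 or self.n_tech < 1 or self.n_bio * self.n_tech < 2:
            raise ValueError("need n_bio*n_tech >= 2 replicates")
        if self.calib_ff <= 0 or self.calib_ren <= 0:
            raise ValueError("calibration means must be positive")
        if self.cv_total < 0:
            raise ValueError("cv_total must be non-negative")
        if not 0.0 <= self.bio_fraction <= 1.0:
            raise ValueError("bio_fraction must lie in [0, 1]")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")

    # -- presets ---------------------------------------------------------
    @classmethod
    def screen(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Screen-format dual-luciferase assay: 2 biological x 3 technical
        replicates, wild-type means 1.0e4 (FF) and 8.0e7 (REN)."""
        return cls(seed=seed, **overrides)

    @classmethod
    def dual_glo(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Homogeneous Dual-Glo compound assay: triplicate wells (modelled
        as three independent cultures), means 2.5e3 (FF) and 1.7e5 (REN)."""
        defaults = dict(
            n_bio=3,
            n_tech=1,
            calib_ff=2.5e3,
            calib_ren=1.7e5,
            assay_variant="dual_glo_compound",
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {
            "n_bio": self.n_bio,
            "n_tech": self.n_tech,
            "calib_ff": self.calib_ff,
            "calib_ren": self.calib_ren,
            "cv_total": self.cv_total,
            "bio_fraction": self.bio_fraction,
            "seed": self.seed,
            "doses": list(self.doses),
            "assay_variant": self.assay_variant,
        }
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        data["doses"] = tuple(data.get("doses", DEFAULT_DOSES))
        return cls(**data)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _sigmas(config: SimConfig) -> tuple[float, float]:
    """Biological / technical log-SDs splitting the total log-variance."""
    if config.cv_total == 0:
        return 0.0, 0.0
    var_log = math.log1p(config.cv_total**2)
    return (
        math.sqrt(config.bio_fraction * var_log),
        math.sqrt((1.0 - config.bio_fraction) * var_log),
    )


def _mean_one_lognormal(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    if sigma == 0.0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _draw_counts(
    rng: np.random.Generator,
    config: SimConfig,
    group_ids: Sequence[str],
    mult_ff: np.ndarray,
    mult_ren: np.ndarray,
) -> pd.DataFrame:
    """Draw the full replicate grid for a list of groups.

    ``mult_ff``/``mult_ren`` are per-group mean multipliers.  The biological
    factor is drawn once per (group, bio) and shared across reporters.
    """
    n_g, n_b, n_t = len(group_ids), config.n_bio, config.n_tech
    sigma_b, sigma_t = _sigmas(config)
    bio = _mean_one_lognormal(rng, sigma_b, (n_g, n_b))  # shared FF/REN
    tech = _mean_one_lognormal(rng, sigma_t, (n_g, 2, n_b, n_t))

    calib = np.array([config.calib_ff, config.calib_ren])
    mult = np.stack([np.asarray(mult_ff), np.asarray(mult_ren)], axis=1)  # (G, 2)
    counts = (
        calib[None, :, None, None]
        * mult[:, :, None, None]
        * bio[:, None, :, None]
        * tech
    )  # (G, 2, B, T)

    n_rows = n_g * 2 * n_b * n_t
    frame = pd.DataFrame(
        {
            "group_id": np.repeat(np.asarray(group_ids, dtype=object), 2 * n_b * n_t),
            "reporter": np.tile(np.repeat(["FF", "REN"], n_b * n_t), n_g),
            "bio_rep": np.tile(np.repeat(np.arange(1, n_b + 1), n_t), n_g * 2),
            "tech_rep": np.tile(np.arange(1, n_t + 1), n_g * 2 * n_b),
            "counts": counts.reshape(n_rows),
        }
    )
    return frame


def simulate_screen(
    manifest: StrainManifest,
    effects: Iterable[EffectSpec] = (),
    config: SimConfig | None = None,
) -> ReadoutTable:
    """Simulate a full RVS screen readout table.

    One record per (usable vehicle x reporter x biological x technical
    replicate); usable vehicles are the wild type plus every viable strain.
    Effects may only target viable strains.
    """
    config = config or SimConfig.screen()
    effects = list(effects)
    viable = {s.gene_id for s in manifest.viable_strains}
    for e in effects:
        if e.target_id not in viable:
            if e.target_id in manifest.gene_ids:
                raise ValueError(f"effect targets non-viable strain {e.target_id!r}")
            raise ValueError(f"effect targets unknown strain {e.target_id!r}")
    by_target = {e.target_id: e for e in effects}

    groups = [manifest.wildtype_id] + [s.gene_id for s in manifest.viable_strains]
    mult_ff = np.array(
        [by_target[g].ff_multiplier if g in by_target else 1.0 for g in groups]
    )
    mult_ren = np.array(
        [by_target[g].ren_multiplier if g in by_target else 1.0 for g in groups]
    )

    rng = np.random.default_rng(config.seed)
    frame = _draw_counts(rng, config, groups, mult_ff, mult_ren)
    return ReadoutTable(df=frame, assay_variant="dual_luciferase_screen")


def dose_multiplier(m_top: float, d: float, d_max: float, exponent: float = 1.0) -> float:
    """Planted fold effect at dose ``d``.

    ``m(d) = 1 + (m_top - 1) * (d / d_max) ** exponent`` — anchored so the
    top-dose multiplier equals ``m_top`` exactly and ``m -> 1`` as
    ``d -> 0``.
    """
    if d <= 0:
        raise ValueError("dose must be positive")
    if m_top <= 0:
        raise ValueError("m_top must be positive")
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    return 1.0 + (m_top - 1.0) * (d / d_max) ** exponent


#: group id used for the untreated-control condition in dose panels.
CONTROL_ID = "control"


def condition_id(compound_id: str, dose: float) -> str:
    return f"{compound_id}:{dose:g}"


def parse_condition_id(group_id: str) -> tuple[str, float]:
    """Split a ``compound:dose`` group id; raises ValueError otherwise."""
    compound, _, dose = group_id.rpartition(":")
    if not compound:
        raise ValueError(f"not a compound:dose group id: {group_id!r}")
    return compound, float(dose)


def simulate_dose_panel(
    compounds: Iterable[EffectSpec],
    config: SimConfig | None = None,
) -> ReadoutTable:
    """Simulate a compound dose panel plus a shared untreated control.

    One group per compound x dose (ids ``"<compound>:<dose>"``) and one
    ``"control"`` group, each with the configured replicate grid.  The
    planted multiplier at dose ``d`` follows :func:`dose_multiplier` with
    the compound's top-dose multipliers and exponent.
    """
    config = config or SimConfig.dual_glo()
    compounds = list(compounds)
    if not config.doses:
        raise ValueError("config.doses must be non-empty")
    ids = [c.target_id for c in compounds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids")
    for cid in ids:
        if ":" in cid or cid == CONTROL_ID:
            raise ValueError(f"invalid compound id {cid!r}")

    d_max = config.doses[-1]
    groups: list[str] = [CONTROL_ID]
    mult_ff: list[float] = [1.0]
    mult_ren: list[float] = [1.0]
    for c in compounds:
        for d in config.doses:
            groups.append(condition_id(c.target_id, d))
            mult_ff.append(dose_multiplier(c.ff_multiplier, d, d_max, c.exponent))
            mult_ren.append(dose_multiplier(c.ren_multiplier, d, d_max, c.exponent))

    rng = np.random.default_rng(config.seed)
    frame = _draw_counts(rng, config, groups, np.array(mult_ff), np.array(mult_ren))
    return ReadoutTable(df=frame, assay_variant="dual_glo_compound")
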