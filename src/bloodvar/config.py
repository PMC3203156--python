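"""Simulation configuration for the synthetic blood-transcriptome generator.

The generator emulates the statistical structure of a whole-blood microarray
study: a log2 expression matrix over ``n_donors x n_series`` arrays, where
each donor contributes one intact RNA aliquot and further aliquots degraded
to lower RNA integrity (RIN), and where expression variation is driven by
cell-type composition, demographic covariates, RNA degradation, donor
identity and measurement noise.  Every variance component has a configurable
magnitude so that downstream estimators can be checked against an exact
ground-truth variance ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class EffectBlock:
    """A block of genes responding to one sample covariate.

    ``scale`` is the standard deviation (log2 units) of the per-gene effect
    sizes drawn for the block.  Covariates are standardized before the
    effect is applied, except RIN, which enters as a centered (not
    standardized) slope so that the effect has units of log2 per RIN unit.
    """

    variable: str
    n_genes: int
    scale: float


@dataclass(frozen=True)
class CellTypeSignature:
    """A marker-gene signature tied to one cell-proportion covariate."""

    variable: str
    n_genes: int
    scale: float


# Substream identifiers: each variance component draws from its own
# counter-based stream so adding a block never perturbs earlier components.
_COMPONENT_STREAMS = {
    "covariates": 0,
    "baseline": 1,
    "cell_mixture": 2,
    "donor": 3,
    "noise": 4,
    "blocks": 5,  # offset; block i uses 5 + i
}


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 9859
    n_donors: int = 8
    n_series: int = 3
    cell_types: tuple[CellTypeSignature, ...] = ()
    effect_blocks: tuple[EffectBlock, ...] = ()
    rin_series_means: tuple[float, ...] = (8.9, 7.7, 6.5)
    rin_sd: float = 0.4
    donor_sd: float = 0.1
    noise_sd: float = 0.35
    baseline_mean: float = 7.5
    baseline_sd: float = 1.5
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_donors * self.n_series

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_donors < 1 or self.n_series < 1:
            raise ConfigurationError("n_donors and n_series must be >= 1")
        if len(self.rin_series_means) != self.n_series:
            raise ConfigurationError(
                f"rin_series_means has length {len(self.rin_series_means)}, "
                f"expected n_series={self.n_series}"
            )
        for sd_name in ("rin_sd", "donor_sd", "noise_sd", "baseline_sd"):
            if getattr(self, sd_name) < 0:
                raise ConfigurationError(f"{sd_name} must be >= 0")
        for block in list(self.effect_blocks) + list(self.cell_types):
            if block.n_genes < 0 or block.n_genes > self.n_genes:
                raise ConfigurationError(
                    f"block for {block.variable!r} requests {block.n_genes} genes "
                    f"but the matrix has {self.n_genes}"
                )
            if block.scale < 0:
                raise ConfigurationError(f"negative scale for {block.variable!r}")

    def rng(self, component: str, index: int = 0) -> np.random.Generator:
        """Deterministic substream for one variance component."""
        if component == "blocks":
            stream = _COMPONENT_STREAMS["blocks"] + index
        else:
            stream = _COMPONENT_STREAMS[component]
        return np.random.default_rng([self.seed, stream])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["cell_types"] = tuple(
            CellTypeSignature(**ct) if isinstance(ct, dict) else ct
            for ct in d.get("cell_types", ())
        )
        d["effect_blocks"] = tuple(
            EffectBlock(**b) if isinstance(b, dict) else b
            for b in d.get("effect_blocks", ())
        )
        d["rin_series_means"] = tuple(d.get("rin_series_means", (8.9, 7.7, 6.5)))
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _expected_rin_variance(config_kwargs: dict) -> float:
    means = np.asarray(config_kwargs["rin_series_means"], dtype=float)
    n_d = config_kwargs["n_donors"]
    per_sample = np.repeat(means, n_d)
    return float(np.var(per_sample, ddof=1) + config_kwargs["rin_sd"] ** 2)


def config_from_fractions(
    n_genes: int = 9859,
    n_donors: int = 8,
    n_series: int = 3,
    fractions: dict[str, float] | None = None,
    block_sizes: dict[str, int] | None = None,
    cell_block_sizes: dict[str, int] | None = None,
    donor_fraction: float = 0.08,
    noise_sd: float = 0.35,
    rin_series_means: Sequence[float] = (8.9, 7.7, 6.5),
    rin_sd: float = 0.4,
    seed: int = 0,
) -> SimulationConfig:
    """Build a configuration whose expected variance budget matches ``fractions``.

    ``fractions`` maps component names (``cell_mixture``, covariate names,
    ``rin``) to target shares of total across-sample expression variance; the
    noise share is the remainder after these and ``donor_fraction``.  Effect
    scales are solved analytically from the budget: a standardized covariate
    block of ``B`` genes with per-gene effect sd ``tau`` contributes
    ``B * tau**2`` expected variance, gene-wise noise contributes
    ``n_genes * noise_sd**2``, and donor intercepts contribute
    ``n_genes * donor_sd**2 * (n - n_series)/(n - 1)``.  Realized fractions
    fluctuate around the targets with the random effect draws; the emitted
    ground-truth ledger records the exact realized values.
    """
    if fractions is None:
        fractions = {"cell_mixture": 0.30, "gender": 0.09, "age": 0.08, "rin": 0.02}
    if block_sizes is None:
        block_sizes = {"gender": 120, "age": 200, "rin": 60, "bmi": 120}
    if cell_block_sizes is None:
        cell_block_sizes = {
            "lymphocyte_pct": 500,
            "neutrophil_pct": 500,
            "monocyte_pct": 150,
        }

    f_named = sum(fractions.values())
    f_noise = 1.0 - f_named - donor_fraction
    if f_noise <= 0:
        raise ConfigurationError("variance fractions plus donor share must sum to < 1")
    total = n_genes * noise_sd**2 / f_noise

    n = n_donors * n_series
    kwargs = dict(
        n_genes=n_genes,
        n_donors=n_donors,
        n_series=n_series,
        rin_series_means=tuple(rin_series_means),
        rin_sd=rin_sd,
        noise_sd=noise_sd,
        seed=seed,
    )

    cell_types: list[CellTypeSignature] = []
    blocks: list[EffectBlock] = []
    for name, frac in fractions.items():
        if name == "cell_mixture":
            b_total = sum(cell_block_sizes.values())
            tau = np.sqrt(frac * total / b_total)
            for var, b in cell_block_sizes.items():
                cell_types.append(CellTypeSignature(var, b, float(tau)))
        elif name == "rin":
            b = block_sizes["rin"]
            var_rin = _expected_rin_variance(kwargs)
            blocks.append(
                EffectBlock("rin", b, float(np.sqrt(frac * total / (b * var_rin))))
            )
        else:
            b = block_sizes[name]
            blocks.append(EffectBlock(name, b, float(np.sqrt(frac * total / b))))

    donor_var = donor_fraction * total / (n_genes * (n - n_series) / (n - 1))
    cfg = SimulationConfig(
        cell_types=tuple(cell_types),
        effect_blocks=tuple(blocks),
        donor_sd=float(np.sqrt(donor_var)),
        **kwargs,
    )
    cfg.validate()
    return cfg


def study_scale_config(seed: int = 0) -> SimulationConfig:
    """Default study-scale conditions: 9,859 genes, 8 donors x 3 series."""
    return config_from_fractions(seed=seed)


def recovery_config(seed: int = 0, n_genes: int = 2000, n_donors: int = 16) -> SimulationConfig:
    """Conditions for variance-recovery checks: 2,000 genes, 16 donors x 3."""
    return config_from_fractions(n_genes=n_genes, n_donors=n_donors, seed=seed)
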