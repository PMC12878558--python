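"""Synthetic geography and environment: coordinates, gradients, clines.

Samples get coordinates spread over a configured lat/lon box; each
environmental variable is a linear function of latitude plus Gaussian noise.
Optionally, a subset of variant loci can be turned into "adaptive" loci whose
allele frequencies follow the first environment variable, for power tests of
the genotype-environment association stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from popg.variants import GenotypeMatrix, MISSING

__all__ = ["EnvironmentConfig", "simulate_environment", "inject_adaptive_loci"]


class EnvironmentConfigError(ValueError):
    pass


@dataclass
class EnvironmentConfig:
    """Coordinate box, gradient slopes and adaptive-locus settings."""

    lat_range: tuple[float, float] = (40.0, 65.0)
    lon_range: tuple[float, float] = (-5.0, 30.0)
    n_env_vars: int = 4
    slopes: list[float] | None = None  # per-variable slope vs latitude
    noise_sd: float = 1.0
    n_adaptive_loci: int = 0
    effect_size: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_env_vars < 1:
            raise EnvironmentConfigError("n_env_vars must be >= 1")
        if self.noise_sd < 0:
            raise EnvironmentConfigError("noise_sd must be >= 0")
        if self.n_adaptive_loci < 0:
            raise EnvironmentConfigError("n_adaptive_loci must be >= 0")
        if self.slopes is not None and len(self.slopes) != self.n_env_vars:
            raise EnvironmentConfigError("slopes length must equal n_env_vars")


def simulate_environment(
    samples: list[str], config: EnvironmentConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-sample coordinates and environment variables.

    Returns ``(coords, env)``: coords has columns ``sample, lat, lon``;
    env is indexed by sample with columns ``env_1 .. env_K`` where
    ``env_k = slope_k * lat + N(0, noise_sd)``.
    """
    config.validate()
    if not samples:
        raise ValueError("sample list is empty")
    rng = np.random.default_rng(config.seed)
    n = len(samples)
    lat = rng.uniform(*config.lat_range, size=n)
    lon = rng.uniform(*config.lon_range, size=n)
    coords = pd.DataFrame({"sample": samples, "lat": lat, "lon": lon})

    slopes = config.slopes
    if slopes is None:
        slopes = [1.0] * config.n_env_vars
    env = {}
    for k in range(config.n_env_vars):
        env[f"env_{k + 1}"] = slopes[k] * lat + rng.normal(
            0.0, config.noise_sd, size=n
        )
    env_df = pd.DataFrame(env, index=pd.Index(samples, name="sample"))
    return coords, env_df


def inject_adaptive_loci(
    matrix: GenotypeMatrix,
    env_values: np.ndarray,
    config: EnvironmentConfig,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Overwrite ``n_adaptive_loci`` columns with environment-driven clines.

    Each chosen locus gets dosages drawn Binomial(2, p) with
    ``p = logistic(effect_size * z)`` where z is the standardized environment
    value, producing an allele-frequency cline along the gradient.  Returns
    the modified matrix (copy) and the indices of the planted loci.
    """
    config.validate()
    if config.n_adaptive_loci > matrix.n_sites:
        raise EnvironmentConfigError(
            "n_adaptive_loci exceeds the number of variant loci"
        )
    rng = np.random.default_rng(config.seed + 1)
    out = GenotypeMatrix(
        samples=list(matrix.samples),
        dosage=matrix.dosage.copy(),
        contig=matrix.contig,
        pos=matrix.pos,
    )
    if config.n_adaptive_loci == 0:
        return out, np.empty(0, dtype=np.intp)
    loci = rng.choice(matrix.n_sites, size=config.n_adaptive_loci, replace=False)
    loci.sort()
    z = np.asarray(env_values, dtype=float)
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    p = 1.0 / (1.0 + np.exp(-config.effect_size * z))
    for j in loci:
        out.dosage[:, j] = rng.binomial(2, p).astype(np.int8)
    return out, loci.astype(np.intp)
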