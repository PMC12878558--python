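"""Sequencing-artifact layer: depth, allele depths, QUAL and missingness.

Turns a clean simulated table into something that looks like the output of
short-read calling: per-genotype DP drawn negative-binomially around a
per-sample mean, AD for heterozygotes binomial around 0.5 (optionally forced
aberrant), per-site QUAL, and random genotype dropout.  The clean genotypes
are retained in ``truth_gt`` so filter behaviour can be scored against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from popg.variants import MISSING, VariantTable

__all__ = ["ArtifactConfig", "apply_sequencing_artifacts"]


class ArtifactConfigError(ValueError):
    pass


@dataclass
class ArtifactConfig:
    """Knobs for the artifact layer.

    ``depth_dispersion`` is the negative-binomial size parameter (larger =
    closer to Poisson).  ``aberrant_ab_fraction`` is the fraction of
    heterozygous genotypes whose allele balance is pushed outside
    ``[0.25, 0.75]``.  ``qual_mean``/``qual_sd`` parameterize site QUAL
    (normal, clipped at 0).
    """

    mean_depth: float = 20.0
    depth_dispersion: float = 10.0
    qual_mean: float = 60.0
    qual_sd: float = 10.0
    genotype_missing_rate: float = 0.0
    aberrant_ab_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.mean_depth < 0:
            raise ArtifactConfigError("mean_depth must be >= 0")
        if self.depth_dispersion <= 0:
            raise ArtifactConfigError("depth_dispersion must be > 0")
        for name in ("genotype_missing_rate", "aberrant_ab_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ArtifactConfigError(f"{name} must be in [0, 1]")
        if self.qual_sd < 0:
            raise ArtifactConfigError("qual_sd must be >= 0")


def apply_sequencing_artifacts(
    truth: VariantTable, config: ArtifactConfig
) -> VariantTable:
    """Return a copy of ``truth`` decorated with DP/AD/QUAL and missingness.

    Deterministic for a fixed ``config.seed``.  Raises if ``truth`` already
    contains missing genotypes (the artifact layer owns missingness).
    """
    config.validate()
    if np.any(truth.gt == MISSING):
        raise ValueError("truth table already contains missing genotypes")

    rng = np.random.default_rng(config.seed)
    out = truth.copy()
    out.truth_gt = truth.gt.copy()
    ns, nsamp = out.n_sites, out.n_samples

    # per-sample mean depths jitter around the configured mean
    sample_means = config.mean_depth * rng.uniform(0.8, 1.2, size=nsamp)
    r = config.depth_dispersion
    p = r / (r + sample_means)  # NB(r, p) has mean r(1-p)/p = sample mean
    dp = rng.negative_binomial(r, p[None, :], size=(ns, nsamp)).astype(np.int32)
    out.dp = dp

    qual = rng.normal(config.qual_mean, config.qual_sd, size=ns)
    out.qual = np.clip(qual, 0.0, None)

    gt = out.gt
    ad_ref = np.zeros((ns, nsamp), dtype=np.int32)
    ad_alt = np.zeros((ns, nsamp), dtype=np.int32)
    ad_ref[gt == 0] = dp[gt == 0]
    ad_alt[gt == 2] = dp[gt == 2]

    het = gt == 1
    if het.any():
        d_het = dp[het]
        alt_d = rng.binomial(d_het, 0.5).astype(np.int32)
        if config.aberrant_ab_fraction > 0:
            force = rng.random(alt_d.shape) < config.aberrant_ab_fraction
            # alt depth < floor(0.25*DP) gives AB strictly below 0.25
            cap = np.maximum(np.floor(0.25 * d_het).astype(np.int32), 1)
            tail = rng.integers(0, cap).astype(np.int32)
            low_side = rng.random(alt_d.shape) < 0.5
            aber = np.where(low_side, tail, d_het - tail)
            alt_d = np.where(force, aber, alt_d)
        ad_alt[het] = alt_d
        ad_ref[het] = d_het - alt_d
    out.ad_ref = ad_ref
    out.ad_alt = ad_alt

    if config.genotype_missing_rate > 0:
        drop = rng.random((ns, nsamp)) < config.genotype_missing_rate
        out.gt = np.where(drop, np.int8(MISSING), gt)
    return out
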