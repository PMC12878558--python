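"""The variant/genotype filter cascade for all-sites tables.

Application order (fixed):

1. site QUAL below threshold -> variant site removed
2. heterozygous calls with allele balance outside [ab_low, ab_high]
   -> genotype masked (or whole site removed with ``ab_site_removal``)
3. variant sites whose every non-missing call is heterozygous -> removed
4. genotype depth: DP below ``min_dp`` or above the per-sample bound
   (mean + ``dp_sd_mult`` * SD, computed over all sites) -> genotype masked,
   at variant AND invariant sites
5. sites with more than ``max_site_missing`` missing genotypes -> removed

The per-sample depth bounds use the population SD (divisor n) and are
computed once on the input table; pass ``thresholds=`` to reuse bounds, e.g.
when re-applying the cascade to an already-filtered table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from popg.variants import MISSING, VariantTable

__all__ = [
    "FilterConfig",
    "FilterReport",
    "compute_depth_thresholds",
    "filter_variants",
]


@dataclass
class FilterConfig:
    min_qual: float = 20.0
    ab_low: float = 0.25
    ab_high: float = 0.75
    min_dp: int = 3
    dp_sd_mult: float = 3.0
    max_site_missing: float = 0.10
    drop_all_het: bool = True
    ab_site_removal: bool = False  # remove whole site instead of masking
    qual_applies_to_invariant: bool = False

    def validate(self) -> None:
        if not (0.0 <= self.ab_low < self.ab_high <= 1.0):
            raise ValueError("need 0 <= ab_low < ab_high <= 1")
        if not (0.0 <= self.max_site_missing <= 1.0):
            raise ValueError("max_site_missing must be in [0, 1]")
        if self.min_dp < 0 or self.dp_sd_mult < 0:
            raise ValueError("depth thresholds must be non-negative")


@dataclass
class FilterReport:
    """Counts of removed sites / masked genotypes per rule, in order."""

    n_input_sites: int = 0
    n_removed_qual: int = 0
    n_masked_ab: int = 0
    n_removed_ab_site: int = 0
    n_removed_all_het: int = 0
    n_masked_depth: int = 0
    n_removed_missing: int = 0
    n_retained_sites: int = 0
    n_het_missing_ad: int = 0
    depth_thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def n_removed_sites(self) -> int:
        return (
            self.n_removed_qual
            + self.n_removed_ab_site
            + self.n_removed_all_het
            + self.n_removed_missing
        )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_input_sites", "n_removed_qual", "n_masked_ab",
            "n_removed_ab_site", "n_removed_all_het", "n_masked_depth",
            "n_removed_missing", "n_retained_sites", "n_het_missing_ad",
        )}
        d["depth_thresholds"] = self.depth_thresholds
        return d


def compute_depth_thresholds(
    table: VariantTable, dp_sd_mult: float = 3.0
) -> np.ndarray:
    """Per-sample upper depth bound: mean DP + dp_sd_mult * SD (divisor n).

    Uses every genotype with an observed DP (variant and invariant sites),
    regardless of whether the genotype call itself is missing.  Raises if a
    sample has no DP observations at all.
    """
    if table.dp is None:
        raise ValueError("table has no DP field; cannot compute depth bounds")
    dp = table.dp.astype(np.float64)
    seen = table.dp >= 0
    n_obs = seen.sum(axis=0)
    for j, n in enumerate(n_obs):
        if n == 0:
            raise ValueError(
                f"sample {table.samples[j]!r} has no DP observations"
            )
    dp_masked = np.where(seen, dp, 0.0)
    mean = dp_masked.sum(axis=0) / n_obs
    var = (np.where(seen, (dp - mean[None, :]) ** 2, 0.0)).sum(axis=0) / n_obs
    return mean + dp_sd_mult * np.sqrt(var)


def filter_variants(
    table: VariantTable,
    cfg: FilterConfig | None = None,
    thresholds: np.ndarray | None = None,
) -> tuple[VariantTable, FilterReport]:
    """Apply the filter cascade; return the filtered table and a report."""
    cfg = cfg or FilterConfig()
    cfg.validate()
    report = FilterReport(n_input_sites=table.n_sites)

    if thresholds is None and table.dp is not None:
        thresholds = compute_depth_thresholds(table, cfg.dp_sd_mult)
    if thresholds is not None:
        report.depth_thresholds = {
            s: float(t) for s, t in zip(table.samples, thresholds)
        }

    out = table.copy()
    is_var = out.is_variant()

    # 1. site QUAL
    qual_ok = ~(out.qual < cfg.min_qual)  # NaN passes
    if not cfg.qual_applies_to_invariant:
        qual_ok |= ~is_var
    report.n_removed_qual = int((~qual_ok).sum())
    out = out.take_sites(qual_ok)
    is_var = out.is_variant()

    # 2. allele balance on heterozygous calls at variant sites; skipped
    # entirely when the table carries no AD data at all
    het = (out.gt == 1) & is_var[:, None]
    if het.any() and out.ad_ref is not None:
        tot = out.ad_ref.astype(np.float64) + out.ad_alt.astype(np.float64)
        have_ad = (out.ad_ref >= 0) & (tot > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ab = np.where(have_ad, out.ad_alt / np.where(tot > 0, tot, 1), np.nan)
        bad_ab = het & have_ad & ((ab < cfg.ab_low) | (ab > cfg.ab_high))
        # het without usable AD fails conservatively
        no_ad = het & ~have_ad
        report.n_het_missing_ad = int(no_ad.sum())
        bad = bad_ab | no_ad
        if cfg.ab_site_removal:
            bad_site = bad.any(axis=1)
            report.n_removed_ab_site = int(bad_site.sum())
            out = out.take_sites(~bad_site)
            is_var = out.is_variant()
        else:
            report.n_masked_ab = int(bad.sum())
            out.gt = np.where(bad, np.int8(MISSING), out.gt)

    # 3. variant sites where every non-missing call is heterozygous
    if cfg.drop_all_het:
        called = out.gt != MISSING
        n_called = called.sum(axis=1)
        n_het = (out.gt == 1).sum(axis=1)
        all_het = is_var & (n_called > 0) & (n_het == n_called)
        report.n_removed_all_het = int(all_het.sum())
        out = out.take_sites(~all_het)

    # 4. genotype depth masking at all sites
    if out.dp is not None and thresholds is not None:
        dp_seen = out.dp >= 0
        bad_dp = dp_seen & (
            (out.dp < cfg.min_dp) | (out.dp > thresholds[None, :])
        )
        newly = bad_dp & (out.gt != MISSING)
        report.n_masked_depth = int(newly.sum())
        out.gt = np.where(bad_dp, np.int8(MISSING), out.gt)

    # 5. site missingness
    miss_frac = (out.gt == MISSING).mean(axis=1)
    keep = miss_frac <= cfg.max_site_missing
    report.n_removed_missing = int((~keep).sum())
    out = out.take_sites(keep)

    report.n_retained_sites = out.n_sites
    return out, report
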