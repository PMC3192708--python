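"""Unit conversions between mutation rates, population sizes and times.

Conventions used throughout:

* mu is a per-lineage substitution rate in substitutions/site/year;
* a published between-lineage divergence rate of X% per Myr corresponds to
  mu = X/100/2/1e6 per site per year (divergence accrues on both lineages);
* theta = ploidy_factor * Ne * mu links the population mutation parameter
  per site to effective size (factor 4 for diploid autosomal loci, 2 for a
  haploid uniparental locus such as mtDNA).

Model-scaled divergence times are converted to years by multiplying by the
per-locus rate scalars and dividing by the geometric mean of the calibrated
locus rates (the multilocus scaling recipe used with isolation-with-
migration output).
"""

from __future__ import annotations

import math
from typing import Sequence

__all__ = [
    "theta_to_ne",
    "ne_to_theta",
    "divergence_rate_to_mu",
    "mu_to_divergence_rate",
    "scaled_t_to_years",
    "RATE_PRESETS",
]

#: named per-site per-year rate presets used in the toad analysis:
#: bufonid cyt b (1.38%/Myr between-lineage divergence) and the
#: Neotropical c-myc calibration.
RATE_PRESETS: dict[str, float] = {
    "bufonid_cytb_1.38": 0.69e-8,
    "neotropical_cmyc_2.01e-9": 2.01e-9,
}


def theta_to_ne(theta_per_site: float, mu: float, ploidy_factor: int = 4) -> float:
    """Effective size from theta = ploidy_factor * Ne * mu."""
    if theta_per_site <= 0 or mu <= 0 or ploidy_factor <= 0:
        raise ValueError("all inputs must be positive")
    return theta_per_site / (ploidy_factor * mu)


def ne_to_theta(ne: float, mu: float, ploidy_factor: int = 4) -> float:
    if ne <= 0 or mu <= 0 or ploidy_factor <= 0:
        raise ValueError("all inputs must be positive")
    return ploidy_factor * ne * mu


def divergence_rate_to_mu(pct_per_myr: float) -> float:
    """Per-lineage mu (site/year) from between-lineage % divergence per Myr."""
    if pct_per_myr <= 0:
        raise ValueError("rate must be positive")
    return pct_per_myr / 100.0 / 2.0 / 1e6


def mu_to_divergence_rate(mu: float) -> float:
    if mu <= 0:
        raise ValueError("rate must be positive")
    return mu * 2.0 * 100.0 * 1e6


def scaled_t_to_years(
    t_model: float, locus_scalars: Sequence[float], mu_locus: Sequence[float]
) -> float:
    """Years = t_model * geomean(scalars) / geomean(locus rates)."""
    if len(locus_scalars) == 0 or len(locus_scalars) != len(mu_locus):
        raise ValueError("need equal-length, non-empty rate lists")
    if any(s <= 0 for s in locus_scalars) or any(m <= 0 for m in mu_locus):
        raise ValueError("scalars and rates must be positive")
    m = len(locus_scalars)
    log_scal = sum(math.log(s) for s in locus_scalars) / m
    log_mu = sum(math.log(x) for x in mu_locus) / m
    return t_model * math.exp(log_scal - log_mu)
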