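"""Newborn-screening discovery simulation for pathogenic ARSA alleles.

Molecularly screened MLD patients are modeled as draws of two pathogenic
alleles with replacement, weighted by each allele's population frequency
(normalized over the pathogenic set). Simulated patients accumulate until
every allele in the set has been seen; the patient index at which the k-th
distinct allele first appears, averaged over simulations, is the discovery
curve. A weighted coupon-collector process, in other words: the first allele
is always discovered with the first patient, and ever more patients separate
consecutive discoveries as only rare alleles remain.

Extrapolating the curve past the last known rank (monotone piecewise-cubic
fit) predicts how many screened patients separate discoveries of alleles not
yet catalogued, and multiplying patients-per-novel-allele by births-per-patient
(the reciprocal disease incidence) converts that to births per novel allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "DiscoveryCurve",
    "simulate_discovery",
    "extrapolate_discovery",
    "births_per_novel_allele",
]


@dataclass
class DiscoveryCurve:
    """Mean screening index at which each successive distinct allele appears.

    ``mean_patients_to_rank[k-1]`` is the mean patient index at which the k-th
    distinct allele is first observed; it is strictly increasing in k and
    exactly 1 at rank 1.
    """

    population: Optional[str]
    variant_ids: list[str]
    mean_patients_to_rank: np.ndarray
    n_sims: int
    seed: Optional[int]

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def rank_gaps(self) -> np.ndarray:
        """Mean additional patients screened between consecutive discoveries."""
        return np.diff(self.mean_patients_to_rank, prepend=0.0)


def simulate_discovery(
    freqs: Mapping[str, float],
    n_sims: int = 100_000,
    seed: Optional[int] = None,
    population: Optional[str] = None,
    patient_cap: int = 10_000_000,
    rng: Optional[np.random.Generator] = None,
) -> DiscoveryCurve:
    """Monte-Carlo discovery curve over a pool of pathogenic alleles.

    ``freqs`` maps allele id to population frequency; weights are frequencies
    normalized over the pool (so the curve is invariant under uniform
    rescaling). Alleles with zero frequency cannot ever be drawn and are
    dropped with a warning. Runs that exceed ``patient_cap`` patients before
    seeing every allele are aborted with a warning and excluded from the
    averages (a guard against vanishing-frequency tails).
    """
    ids = [vid for vid, f in freqs.items() if f > 0]
    dropped = [vid for vid, f in freqs.items() if f <= 0]
    if any(f < 0 for f in freqs.values()):
        raise ValueError("negative allele frequency")
    if not ids:
        raise ValueError("no variant with positive frequency")
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-frequency allele(s): {dropped[:5]}...",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    w = np.asarray([freqs[v] for v in ids], dtype=float)
    w /= w.sum()
    cum = np.cumsum(w)
    cum[-1] = 1.0  # guard against rounding
    k = len(ids)

    totals = np.zeros(k)
    n_done = 0
    allele_cap = 2 * patient_cap
    for _ in range(n_sims):
        first = np.full(k, -1, dtype=np.int64)
        seen = 0
        drawn = 0
        block = max(4 * k, 64)
        aborted = False
        while seen < k:
            if drawn >= allele_cap:
                warnings.warn(
                    "simulation run exceeded the patient cap; run aborted",
                    stacklevel=2,
                )
                aborted = True
                break
            draws = np.searchsorted(cum, rng.random(block), side="right")
            uniq, idx = np.unique(draws, return_index=True)
            for u, i in zip(uniq, idx):
                if first[u] < 0:
                    first[u] = drawn + i
                    seen += 1
            drawn += block
            block = min(block * 2, 1 << 20)
        if aborted:
            continue
        patients = np.sort(first // 2 + 1)
        totals += patients
        n_done += 1
    if n_done == 0:
        raise RuntimeError("every simulation run exceeded the patient cap")
    return DiscoveryCurve(
        population=population,
        variant_ids=ids,
        mean_patients_to_rank=totals / n_done,
        n_sims=n_done,
        seed=seed,
    )


def extrapolate_discovery(curve: DiscoveryCurve, extra_ranks: int = 1) -> np.ndarray:
    """Predict mean patients screened for ranks n+1 .. n+extra_ranks.

    Fits a monotone piecewise-cubic (PCHIP) interpolant to (rank, mean
    patients) -- monotone-preserving, so the fit cannot oscillate the way an
    unconstrained cubic can -- and evaluates it past the last rank. Requires
    at least 4 ranks; the extrapolated values must come out strictly
    increasing, which holds for the convex curves this process produces.
    """
    n = curve.n_variants
    if n < 4:
        raise ValueError(f"need at least 4 ranks to extrapolate, got {n}")
    if extra_ranks < 1:
        raise ValueError("extra_ranks must be positive")
    ranks = np.arange(1, n + 1, dtype=float)
    fit = PchipInterpolator(ranks, curve.mean_patients_to_rank, extrapolate=True)
    new_ranks = np.arange(n + 1, n + extra_ranks + 1, dtype=float)
    values = fit(new_ranks)
    if np.any(np.diff(np.concatenate(([curve.mean_patients_to_rank[-1]], values))) <= 0):
        warnings.warn("extrapolated discovery curve is not strictly increasing", stacklevel=2)
    return values


def births_per_novel_allele(patients_per_novel: float, births_per_patient: float) -> float:
    """Births per novel-allele encounter ("1 in N" with N the return value).

    ``patients_per_novel`` is the expected number of screened patients between
    consecutive novel-allele discoveries; ``births_per_patient`` is the
    reciprocal of the disease incidence. Their product is the expected number
    of births per novel allele encountered.
    """
    if patients_per_novel <= 0 or births_per_patient <= 0:
        raise ValueError("both inputs must be positive")
    return patients_per_novel * births_per_patient
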