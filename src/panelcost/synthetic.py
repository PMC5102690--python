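"""Seeded synthetic patient cohorts with the case-study's utilisation structure.

The institutional patient-level data behind the before/after comparison are
not published; this module generates cohorts whose summary statistics match
the published aggregates (cohort size, mean and range of tests per patient,
mean mutations, category proportions) so the whole comparison pipeline is
testable end to end.

Per patient:

* the number of tests is a shifted Poisson truncated to ``[min, max]``, with
  the rate calibrated numerically so the *truncated* mean equals the profile
  mean;
* test types are drawn without replacement, weighted by the profile's test
  mix;
* the mutation count is a Poisson truncated to the profile range, again
  mean-calibrated under truncation;
* category flags are independent Bernoulli draws.

Identical (profile, seed) pairs yield identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .case_study import PatientRecord
from .errors import ValidationError

_LAMBDA_MAX = 1e3


@dataclass(frozen=True)
class CohortProfile:
    """Target statistical structure of one indication × period cohort."""

    indication: str
    period: str
    n_patients: int
    tests_mean: float
    tests_min: int
    tests_max: int
    test_mix: Mapping[str, float]
    mutation_mean: float
    mutation_min: int = 0
    mutation_max: int = 10
    category_probs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be positive")
        if self.tests_min < 1:
            raise ValidationError("tests_min must be at least 1")
        if not self.tests_min <= self.tests_mean <= self.tests_max:
            raise ValidationError(
                f"infeasible profile: tests mean {self.tests_mean} outside "
                f"[{self.tests_min}, {self.tests_max}]"
            )
        if not self.mutation_min <= self.mutation_mean <= self.mutation_max:
            raise ValidationError(
                f"infeasible profile: mutation mean {self.mutation_mean} "
                f"outside [{self.mutation_min}, {self.mutation_max}]"
            )
        weights = list(self.test_mix.values())
        if not weights or any(w < 0 for w in weights) or sum(weights) == 0:
            raise ValidationError(
                "test_mix weights must be non-negative and not all zero"
            )
        if len(self.test_mix) < self.tests_max:
            raise ValidationError(
                f"test_mix offers {len(self.test_mix)} distinct tests but "
                f"tests_max is {self.tests_max} (sampling is without replacement)"
            )
        for cat, p in self.category_probs.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"category probability for {cat!r} not in [0, 1]")


def truncated_poisson_mean(lam: float, lo: int, hi: int, shift: int = 0) -> float:
    """E[clip(shift + Poisson(lam), lo, hi)], computed from the pmf."""
    ks = np.arange(0, hi - shift + 1)
    pmf = stats.poisson.pmf(ks, lam)
    values = np.clip(shift + ks, lo, hi)
    tail = 1.0 - pmf.sum()
    return float((values * pmf).sum() + hi * tail)


@lru_cache(maxsize=256)
def calibrate_rate(mean: float, lo: int, hi: int, shift: int = 0) -> float:
    """Poisson rate whose truncated/clipped mean equals ``mean``.

    With ``shift=1`` this is the shifted-Poisson used for test counts; with
    ``shift=0`` the plain truncated Poisson used for mutation counts.
    """
    if hi == lo:
        return 0.0
    floor = max(lo, shift)
    if mean <= floor:
        return 0.0
    if truncated_poisson_mean(_LAMBDA_MAX, lo, hi, shift) < mean:
        raise ValidationError(
            f"mean {mean} unreachable under truncation to [{lo}, {hi}]"
        )
    return float(
        optimize.brentq(
            lambda lam: truncated_poisson_mean(lam, lo, hi, shift) - mean,
            1e-12,
            _LAMBDA_MAX,
        )
    )


def _draw_counts(
    rng: np.random.Generator, n: int, mean: float, lo: int, hi: int, shift: int
) -> np.ndarray:
    lam = calibrate_rate(mean, lo, hi, shift)
    return np.clip(shift + rng.poisson(lam, size=n), lo, hi)


def generate_cohort(profile: CohortProfile, seed) -> list[PatientRecord]:
    """Generate ``profile.n_patients`` records; deterministic in the seed.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = profile.n_patients
    test_names = np.array(list(profile.test_mix))
    weights = np.array(list(profile.test_mix.values()), dtype=float)
    weights = weights / weights.sum()
    n_tests = _draw_counts(
        rng, n, profile.tests_mean, profile.tests_min, profile.tests_max, shift=1
    )
    mutations = _draw_counts(
        rng, n, profile.mutation_mean, profile.mutation_min, profile.mutation_max,
        shift=0,
    )
    categories = list(profile.category_probs)
    flag_draws = rng.random((n, len(categories)))
    records = []
    for i in range(n):
        tests = rng.choice(test_names, size=int(n_tests[i]), replace=False, p=weights)
        flags = {
            cat: bool(flag_draws[i, j] < profile.category_probs[cat])
            for j, cat in enumerate(categories)
        }
        records.append(
            PatientRecord(
                patient_id=f"{profile.indication}-{profile.period}-{i + 1:04d}",
                indication=profile.indication,
                period=profile.period,
                tests=tuple(str(t) for t in tests),
                mutation_count=int(mutations[i]),
                category_flags=flags,
            )
        )
    return records


def paired_cohorts(
    before_profile: CohortProfile, after_profile: CohortProfile, seed: int
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Two independent cohorts from one seed, for before/after comparisons."""
    if before_profile.indication != after_profile.indication:
        raise ValidationError("paired cohorts must share an indication")
    child_a, child_b = np.random.SeedSequence(seed).spawn(2)
    return (
        generate_cohort(before_profile, np.random.default_rng(child_a)),
        generate_cohort(after_profile, np.random.default_rng(child_b)),
    )
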