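"""Prevalence-derived allele-frequency threshold under a recessive HWE model.

For a fully penetrant autosomal-recessive disease at Hardy-Weinberg
equilibrium, prevalence P equals the homozygote frequency q^2, so the
pathogenic allele frequency is q = sqrt(P). Variants more common than q in
reference populations are too frequent to explain the disease and are
excluded upstream. No carrier correction or compound-het inflation term is
applied; the model is deliberately the simplest one consistent with a
point-prevalence input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .model import round_half_even


@dataclass(frozen=True, slots=True)
class PrevalenceSpec:
    """Disease prevalence as an affected count over a screened cohort size."""

    affected_count: int
    cohort_size: int

    def __post_init__(self):
        if self.affected_count < 0:
            raise ValidationError("affected_count must be non-negative")
        if self.cohort_size <= 0:
            raise ValidationError("cohort_size must be positive")
        if self.affected_count > self.cohort_size:
            raise ValidationError("affected_count cannot exceed cohort_size")

    @property
    def prevalence(self) -> float:
        return self.affected_count / self.cohort_size


@dataclass(frozen=True, slots=True)
class MafThreshold:
    """The raw recessive allele frequency q and its rounded filter threshold."""

    raw_q: float
    threshold: float
    policy: str


def hwe_maf_threshold(prev: PrevalenceSpec, decimals: int = 2) -> MafThreshold:
    """Derive the MAF exclusion threshold from prevalence.

    Parameters
    ----------
    prev
        Disease prevalence (affected / screened).
    decimals
        Rounding precision for the reported threshold; the raw q is always
        returned alongside so the rounding is auditable.

    Returns
    -------
    MafThreshold
        ``raw_q = sqrt(prevalence)`` and ``threshold`` = raw_q rounded
        half-even to `decimals` places.
    """
    if decimals < 0:
        raise ValidationError("decimals must be non-negative")
    q = math.sqrt(prev.prevalence)
    return MafThreshold(
        raw_q=q,
        threshold=round_half_even(q, decimals),
        policy=f"half_even_{decimals}dp",
    )
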