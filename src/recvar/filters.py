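"""The three-stage variant filtering funnel.

Stages, applied in order: (1) population-frequency exclusion — a variant is
dropped when any consulted database reports an allele frequency strictly
above the threshold; (2) control exclusion — dropped when any control
carries it homozygous-alt, or hemizygous-alt for male X; (3) consequence
selection — only non-synonymous / indel / splice-site classes are retained.
Each stage is a pure per-variant predicate, so the final surviving set is
independent of stage order; the funnel records per-stage counts.

Male X handling: a male heterozygous call on X is treated as hemizygous-alt
(single-copy chromosome; a het there is a coding artifact) both here and in
candidate calling, except inside configured pseudoautosomal intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ConfigurationError, ValidationError
from .model import DAMAGING_CONSEQUENCES, FilterFunnel

log = logging.getLogger(__name__)

DEFAULT_DB_NAMES = ("dbSNP", "1000G", "gnomAD")


@dataclass(frozen=True)
class FilterConfig:
    """Knobs for the filtering funnel.

    missing_af_passes defaults to True: a variant absent from every
    consulted database is treated as rare (novel variants must survive).
    x_par_intervals are (start, end) 1-based inclusive intervals on X that
    are exempt from male hemizygous recoding (empty by default).
    """

    maf_threshold: float
    db_names: tuple = DEFAULT_DB_NAMES
    allowed_consequences: frozenset = field(
        default_factory=lambda: DAMAGING_CONSEQUENCES
    )
    missing_af_passes: bool = True
    x_par_intervals: tuple = ()

    def __post_init__(self):
        if not 0.0 <= self.maf_threshold <= 1.0:
            raise ValidationError("maf_threshold must be in [0, 1]")
        if not self.db_names:
            raise ValidationError("db_names must be non-empty")
        if not self.allowed_consequences:
            raise ValidationError("allowed_consequences must be non-empty")
        object.__setattr__(
            self, "allowed_consequences", frozenset(self.allowed_consequences)
        )


def in_par(pos: int, par_intervals) -> bool:
    return any(lo <= pos <= hi for lo, hi in par_intervals)


def is_male_x(variant, sample, par_intervals=()) -> bool:
    """True when `sample`'s call at `variant` is on a single-copy male X."""
    return (
        variant.is_x
        and sample.sex == "male"
        and not in_par(variant.pos, par_intervals)
    )


def filter_by_maf(variants, cfg: FilterConfig):
    """Drop variants whose max AF over the consulted databases exceeds the threshold.

    The comparison is strict (> threshold removes); a variant with no AF
    entry in any consulted database survives when ``missing_af_passes``.
    """
    out = []
    for v in variants:
        afs = [v.pop_af[db] for db in cfg.db_names if db in v.pop_af]
        if not afs:
            keep = cfg.missing_af_passes
        else:
            keep = max(afs) <= cfg.maf_threshold
        if keep:
            out.append(v)
        elif log.isEnabledFor(logging.DEBUG):
            log.debug("maf: drop %s (max AF %.3g)", v.key_str, max(afs))
    return out


def filter_by_controls(variants, samples, par_intervals=()):
    """Drop variants homozygous-alt (or male-X hemizygous-alt) in any control.

    Heterozygous controls never cause removal: under a recessive model a
    het control is just a healthy carrier.
    """
    controls = [s for s in samples if s.role == "control"]
    if not controls:
        raise ConfigurationError("control exclusion requires >= 1 control sample")
    out = []
    for v in variants:
        hit = None
        for s in controls:
            call = v.genotypes.get(s.sample_id)
            if call is None or call.is_missing:
                continue
            if call.is_hom_alt or (is_male_x(v, s, par_intervals) and call.has_alt):
                hit = s.sample_id
                break
        if hit is None:
            out.append(v)
        elif log.isEnabledFor(logging.DEBUG):
            log.debug("controls: drop %s (control %s)", v.key_str, hit)
    return out


def filter_by_consequence(variants, cfg: FilterConfig):
    """Retain exactly the variants whose consequence class is allowed."""
    out = [v for v in variants if v.consequence in cfg.allowed_consequences]
    if log.isEnabledFor(logging.DEBUG):
        for v in variants:
            if v.consequence not in cfg.allowed_consequences:
                log.debug("consequence: drop %s (%s)", v.key_str, v.consequence)
    return out


def run_funnel(variants, samples, cfg: FilterConfig):
    """Apply maf -> controls -> consequence, recording the funnel.

    Returns ``(survivors, FilterFunnel)``. The funnel is monotone by
    construction; a post-hoc soundness check re-asserts that no survivor is
    homozygous/hemizygous-alt in a control.
    """
    funnel = FilterFunnel()
    stages = (
        ("maf", lambda vs: filter_by_maf(vs, cfg)),
        ("controls", lambda vs: filter_by_controls(vs, samples, cfg.x_par_intervals)),
        ("consequence", lambda vs: filter_by_consequence(vs, cfg)),
    )
    current = list(variants)
    for name, fn in stages:
        n_in = len(current)
        current = fn(current)
        funnel.add(name, n_in, len(current))
    assert_controls_clean(current, samples, cfg.x_par_intervals)
    return current, funnel


def assert_controls_clean(survivors, samples, par_intervals=()) -> None:
    """Raise if any surviving variant is hom/hemizygous-alt in a control."""
    controls = [s for s in samples if s.role == "control"]
    for v in survivors:
        for s in controls:
            call = v.genotypes.get(s.sample_id)
            if call is None or call.is_missing:
                continue
            if call.is_hom_alt or (is_male_x(v, s, par_intervals) and call.has_alt):
                raise ValidationError(
                    f"control-exclusion violated: {v.key_str} in {s.sample_id}"
                )
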