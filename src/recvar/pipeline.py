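"""End-to-end run orchestration: threshold -> funnel -> candidates -> kinship -> report.

All randomness is confined to cohort simulation; every analysis stage is a
deterministic function of its inputs, so a run directory can be regenerated
byte-identically from the echoed configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError, StageError
from .filters import DEFAULT_DB_NAMES, FilterConfig, run_funnel
from .inheritance import call_candidates, summarize_candidate_genes
from .kinship import pairwise_case_kinship
from .model import DAMAGING_CONSEQUENCES
from .report import build_report, read_demographics
from .synthetic_data import SimConfig, simulate_cohort
from .thresholds import PrevalenceSpec, hwe_maf_threshold
from .variant_io import AnnotationConfig, read_cohort, write_variants_tsv

log = logging.getLogger(__name__)

#: Stage name -> process exit code for the CLI.
STAGE_EXIT_CODES = {
    "config": 2,
    "simulate": 3,
    "io": 4,
    "threshold": 5,
    "filter": 6,
    "candidates": 7,
    "kinship": 8,
    "report": 9,
}


@dataclass
class RunConfig:
    """Configuration for a full prioritization run.

    Exactly one threshold source must be supplied: either an explicit
    ``maf_threshold`` or a prevalence (``affected`` / ``cohort``). Input is
    either an existing VCF + sample sheet or a simulation config.
    """

    out_dir: str
    vcf: str | None = None
    samples: str | None = None
    simulate: SimConfig | None = None
    affected: int | None = None
    cohort: int | None = None
    maf_threshold: float | None = None
    decimals: int = 2
    db_names: tuple = DEFAULT_DB_NAMES
    allowed_consequences: tuple = tuple(sorted(DAMAGING_CONSEQUENCES))
    missing_af_passes: bool = True
    x_par_intervals: tuple = ()
    demographics: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        prevalence_given = self.affected is not None or self.cohort is not None
        explicit_given = self.maf_threshold is not None
        if prevalence_given == explicit_given:
            raise ConfigurationError(
                "supply exactly one of (affected+cohort, maf_threshold)"
            )
        if prevalence_given and (self.affected is None or self.cohort is None):
            raise ConfigurationError("prevalence needs both affected and cohort")
        if (self.vcf is None) == (self.simulate is None):
            raise ConfigurationError(
                "supply exactly one input: vcf+samples or a simulation config"
            )
        if self.vcf is not None and self.samples is None:
            raise ConfigurationError("a VCF input needs a sample sheet")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "simulate" in d and d["simulate"] is not None:
            sim = dict(d["simulate"])
            if "planted" in sim and sim["planted"] is not None:
                sim["planted"] = tuple(sim["planted"])
            d["simulate"] = SimConfig(**sim)
        for key in ("db_names", "allowed_consequences", "x_par_intervals"):
            if key in d and d[key] is not None:
                d[key] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in d[key]
                )
        return cls(**d)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - mapped to exit codes
                raise StageError(name, exc) from exc
        return wrapper
    return decorate


def run_all(cfg: RunConfig) -> Path:
    """Execute the full pipeline into ``cfg.out_dir`` and return that path.

    Stage order: (optional) simulate -> read -> threshold -> funnel ->
    candidates -> kinship -> report. Any stage failure raises
    :class:`StageError` carrying the stage name.
    """
    try:
        cfg.validate()
    except Exception as exc:
        raise StageError("config", exc) from exc
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth = None
    seed = None
    if cfg.simulate is not None:
        sim = _stage("simulate")(simulate_cohort)(cfg.simulate, out_dir / "sim")
        vcf_path, sheet_path, truth = sim.vcf_path, sim.sample_sheet_path, sim.truth
        seed = cfg.simulate.seed
    else:
        vcf_path, sheet_path = cfg.vcf, cfg.samples

    variants, samples = _stage("io")(read_cohort)(
        vcf_path, sheet_path, AnnotationConfig()
    )

    @_stage("threshold")
    def _threshold():
        if cfg.maf_threshold is not None:
            return None, cfg.maf_threshold
        thr = hwe_maf_threshold(
            PrevalenceSpec(cfg.affected, cfg.cohort), decimals=cfg.decimals
        )
        return thr, thr.threshold

    thr_obj, threshold = _threshold()

    fcfg = FilterConfig(
        maf_threshold=threshold,
        db_names=tuple(cfg.db_names),
        allowed_consequences=frozenset(cfg.allowed_consequences),
        missing_af_passes=cfg.missing_af_passes,
        x_par_intervals=tuple(cfg.x_par_intervals),
    )
    survivors, funnel = _stage("filter")(run_funnel)(variants, samples, fcfg)
    _stage("filter")(write_variants_tsv)(survivors, out_dir / "survivors.tsv")

    candidates = _stage("candidates")(call_candidates)(
        survivors, samples, fcfg.x_par_intervals
    )
    gene_summary = _stage("candidates")(summarize_candidate_genes)(candidates)

    kinship_results = _stage("kinship")(pairwise_case_kinship)(variants, samples)

    demographics = (
        _stage("report")(read_demographics)(cfg.demographics)
        if cfg.demographics
        else None
    )
    config_echo = cfg.echo()
    if thr_obj is not None:
        config_echo["derived_threshold"] = {
            "raw_q": thr_obj.raw_q,
            "threshold": thr_obj.threshold,
            "policy": thr_obj.policy,
        }
    _stage("report")(build_report)(
        out_dir,
        funnel,
        candidates,
        gene_summary,
        kinship_results=kinship_results,
        demographics=demographics,
        truth=truth,
        config_echo=config_echo,
        seed=seed,
        variants=survivors,
    )
    log.info(
        "run complete: funnel %s, %d candidates", funnel.counts, len(candidates)
    )
    return out_dir
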