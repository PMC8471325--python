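"""Run reporting: funnel, candidate table, kinship matrix, pooled demographics.

Group demographics are pooled as n-weighted means only. Pooled standard
deviations are deliberately not computed: reconstructing a pooled SD from
printed group means and SDs requires the exact within-group sums (or the raw
data), and fabricating one from rounded summaries would be wrong more often
than useful.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .model import round_half_even
from .variant_io import write_candidates_tsv


@dataclass(frozen=True)
class GroupStat:
    """A printed group summary: label, size, mean, optional SD (absent when n=1)."""

    label: str
    n: int
    mean: float
    sd: float | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("group size must be >= 1")
        if self.n == 1 and self.sd is not None:
            raise ValidationError("a single-observation group has no SD")


def pooled_mean(groups, decimals: int | None = 1) -> float:
    """n-weighted mean over group summaries, rounded half-even.

    Pass ``decimals=None`` for the unrounded value (pooling is then exactly
    associative).
    """
    groups = list(groups)
    if not groups:
        raise ValidationError("pooled_mean requires at least one group")
    total_n = sum(g.n for g in groups)
    value = sum(g.n * g.mean for g in groups) / total_n
    return value if decimals is None else round_half_even(value, decimals)


def read_demographics(path) -> list:
    """Read a demographics TSV (columns: label, n, mean, sd) into GroupStats."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "n", "mean"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"demographics TSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out = []
    for row in df.to_dict("records"):
        sd = row.get("sd")
        sd = None if sd is None or pd.isna(sd) else float(sd)
        out.append(GroupStat(str(row["label"]), int(row["n"]), float(row["mean"]), sd))
    return out


def planted_recovery(candidates, truth) -> dict:
    """Compare called candidates against a simulation truth ledger.

    A planted entry is recovered when a called candidate matches its
    (sample, gene, model) and includes all its planted variant keys
    (a compound-het candidate may legitimately list extra incidental hets
    in the same gene).
    """
    called = {
        (c.sample_id, c.gene, c.model): set(c.variant_keys) for c in candidates
    }
    recovered, missing = [], []
    for entry in truth.planted:
        key = (entry["sample_id"], entry["gene"], entry["model"])
        want = set(entry["variant_keys"])
        (recovered if key in called and want <= called[key] else missing).append(entry)
    total = len(truth.planted)
    return {
        "n_planted": total,
        "n_recovered": len(recovered),
        "recovery_fraction": (len(recovered) / total) if total else 1.0,
        "missing": missing,
    }


def funnel_frame(funnel) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"stage": s.name, "variants_in": s.variants_in, "variants_out": s.variants_out}
            for s in funnel.stages
        ],
        columns=["stage", "variants_in", "variants_out"],
    )


def kinship_frame(kinship_results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_i": r.pair[0],
                "sample_j": r.pair[1],
                "phi": r.phi,
                "n_sites": r.n_sites,
                "n_het_het": r.n_het_het,
                "n_ibs0": r.n_ibs0,
                "n_het_i": r.n_het_i,
                "n_het_j": r.n_het_j,
            }
            for r in kinship_results
        ],
        columns=[
            "sample_i", "sample_j", "phi", "n_sites",
            "n_het_het", "n_ibs0", "n_het_i", "n_het_j",
        ],
    )


def build_report(
    out_dir,
    funnel,
    candidates,
    gene_summary: pd.DataFrame,
    kinship_results=None,
    demographics=None,
    truth=None,
    config_echo: dict | None = None,
    seed: int | None = None,
    variants=None,
) -> dict:
    """Write the deterministic report bundle and return its summary dict.

    Files: funnel.tsv, candidates.tsv, gene_summary.tsv, kinship.tsv (when
    kinship results exist) and summary.json. Regenerating from the same
    inputs is byte-identical (no timestamps, sorted keys).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    funnel_frame(funnel).to_csv(out_dir / "funnel.tsv", sep="\t", index=False)
    write_candidates_tsv(candidates, out_dir / "candidates.tsv", variants=variants)
    gene_summary.to_csv(out_dir / "gene_summary.tsv", sep="\t", index=False)
    if kinship_results is not None:
        kinship_frame(kinship_results).to_csv(
            out_dir / "kinship.tsv", sep="\t", index=False
        )

    summary = {
        "seed": seed,
        "config": config_echo or {},
        "funnel": funnel.counts,
        "n_candidates": len(candidates),
        "n_candidate_genes": int(gene_summary["gene"].nunique())
        if len(gene_summary)
        else 0,
        "candidates_by_model": {
            m: int(n)
            for m, n in gene_summary.groupby("model")["gene"].nunique().items()
        }
        if len(gene_summary)
        else {},
    }
    if demographics:
        summary["demographics"] = {
            "groups": [asdict(g) for g in demographics],
            "pooled_mean": pooled_mean(demographics),
        }
    if truth is not None:
        rec = planted_recovery(candidates, truth)
        summary["planted_recovery"] = rec
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
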