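"""Read and write cohort variant data.

VCF input goes through cyvcf2; multiallelic records are decomposed into one
:class:`~recvar.model.VariantRecord` per alternate allele, with genotype
alleles equal to a *different* alt recoded as ref for the retained record
(decompose-then-filter convention — the recessive logic downstream is
per-alt). Annotations (gene symbol, consequence class, per-database allele
frequencies, predictor scores) come from configurable INFO keys or a sidecar
TSV keyed by (chrom, pos, ref, alt); the sidecar wins on conflict.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .errors import ConsistencyError, FormatError, ValidationError
from .model import GenotypeCall, InheritanceCandidate, SampleInfo, VariantRecord

log = logging.getLogger(__name__)

#: Sequence-ontology-style terms mapped onto the pipeline's closed vocabulary.
#: Unknown terms map to "other" (strict-unknown rule).
SO_CONSEQUENCE_MAP = {
    "missense": "missense",
    "missense_variant": "missense",
    "stop_gained": "stop_gained",
    "nonsense": "stop_gained",
    "stop_lost": "stop_lost",
    "start_lost": "start_lost",
    "frameshift": "frameshift",
    "frameshift_variant": "frameshift",
    "inframe_indel": "inframe_indel",
    "inframe_insertion": "inframe_indel",
    "inframe_deletion": "inframe_indel",
    "splice_site": "splice_site",
    "splice_acceptor_variant": "splice_site",
    "splice_donor_variant": "splice_site",
    "splice_region_variant": "splice_site",
    "synonymous": "synonymous",
    "synonymous_variant": "synonymous",
}


def normalize_consequence(term: str) -> str:
    """Map an annotator consequence term to the closed vocabulary."""
    return SO_CONSEQUENCE_MAP.get(str(term).strip().lower(), "other")


@dataclass(frozen=True)
class AnnotationConfig:
    """Which INFO keys carry gene / consequence / AF / score annotations."""

    gene_key: str = "GENE"
    consequence_key: str = "CSQ"
    af_keys: dict = field(
        default_factory=lambda: {
            "dbSNP": "AF_DBSNP",
            "1000G": "AF_1000G",
            "gnomAD": "AF_GNOMAD",
        }
    )
    score_keys: dict = field(default_factory=dict)  # predictor -> INFO key


def read_sample_sheet(path) -> list:
    """Read a TSV with columns sample_id, sex, role into SampleInfo records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sex", "role"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"sample sheet must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id in sheet: {dup!r}")
    return [
        SampleInfo(r.sample_id, r.sex, r.role)
        for r in df.itertuples(index=False)
    ]


def _per_alt(value, alt_index: int, n_alts: int):
    """Pick the per-alt entry from an INFO value (scalar or Number=A list)."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if len(value) == n_alts:
            return value[alt_index]
        return value[0] if value else None
    if isinstance(value, str) and n_alts > 1 and "," in value:
        parts = value.split(",")
        return parts[alt_index] if len(parts) == n_alts else parts[0]
    return value


def read_sidecar(path) -> dict:
    """Read a sidecar annotation TSV keyed by (chrom, pos, ref, alt).

    Recognized columns beyond the key: ``gene``, ``consequence`` and one
    column per database name (allele frequency, may be empty).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise FormatError(f"sidecar TSV missing required column {col!r}")
    out = {}
    for row in df.to_dict("records"):
        key = (str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
        out[key] = row
    return out


def read_cohort(
    vcf_path,
    sample_sheet_path,
    annotation: AnnotationConfig | None = None,
    sidecar_path=None,
):
    """Read a multi-sample VCF plus sample sheet into the internal model.

    Returns ``(variants, samples)`` with variants decomposed to biallelic
    records and sorted by (chrom, pos, ref, alt). Raises
    :class:`FormatError` if the VCF has no GT field,
    :class:`ConsistencyError` if a VCF sample is absent from the sheet, and
    :class:`ValidationError` for malformed allele frequencies.
    """
    ann = annotation or AnnotationConfig()
    samples = read_sample_sheet(sample_sheet_path)
    sheet_ids = {s.sample_id for s in samples}
    sidecar = read_sidecar(sidecar_path) if sidecar_path else {}

    vcf = VCF(str(vcf_path))
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise FormatError(f"{vcf_path}: VCF has no GT FORMAT field")
    vcf_samples = list(vcf.samples)
    unknown = set(vcf_samples) - sheet_ids
    if unknown:
        raise ConsistencyError(
            f"VCF samples absent from sample sheet: {sorted(unknown)}"
        )

    variants = []
    for v in vcf:
        alts = list(v.ALT)
        n_alts = len(alts)
        gts = v.genotypes  # per sample: [a0, a1, phased] (or [a0, phased])
        gene_raw = v.INFO.get(ann.gene_key)
        csq_raw = v.INFO.get(ann.consequence_key)
        for k, alt in enumerate(alts):
            alt_code = k + 1
            genotypes = {}
            for si, sid in enumerate(vcf_samples):
                g = gts[si]
                alleles = list(g[:-1])
                phased = bool(g[-1])
                if len(alleles) == 1:  # haploid call carried hom-coded
                    alleles = alleles * 2
                code = [
                    -1 if a < 0 else (1 if a == alt_code else 0)
                    for a in alleles[:2]
                ]
                genotypes[sid] = GenotypeCall(code[0], code[1], phased)

            gene = _per_alt(gene_raw, k, n_alts) or ""
            csq = normalize_consequence(_per_alt(csq_raw, k, n_alts) or "")
            pop_af = {}
            for db, info_key in ann.af_keys.items():
                val = _per_alt(v.INFO.get(info_key), k, n_alts)
                if val is None or (isinstance(val, str) and not val):
                    continue
                pop_af[db] = float(val)
            scores = {}
            for name, info_key in ann.score_keys.items():
                val = _per_alt(v.INFO.get(info_key), k, n_alts)
                if val is not None:
                    scores[name] = float(val)

            key = (str(v.CHROM).removeprefix("chr"), int(v.POS), v.REF, alt)
            side = sidecar.get(key)
            if side is not None:
                if side.get("gene") not in (None, "") and not pd.isna(side["gene"]):
                    gene = str(side["gene"])
                if side.get("consequence") not in (None, "") and not pd.isna(
                    side["consequence"]
                ):
                    csq = normalize_consequence(side["consequence"])
                for db in ann.af_keys:
                    if db in side and not pd.isna(side[db]):
                        pop_af[db] = float(side[db])

            variants.append(
                VariantRecord(
                    chrom=str(v.CHROM),
                    pos=int(v.POS),
                    ref=v.REF,
                    alt=alt,
                    gene=str(gene),
                    consequence=csq,
                    pop_af=pop_af,
                    scores=scores,
                    genotypes=genotypes,
                )
            )
    variants.sort(key=lambda r: r.sort_key)
    log.debug("read %d decomposed variants, %d samples", len(variants), len(samples))
    return variants, samples


# ---------------------------------------------------------------------------
# TSV serialization (survivors and candidates)

_VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence",
    "pop_af", "scores", "genotypes",
]


def write_variants_tsv(variants, path) -> None:
    """Serialize variant records (with genotypes) to a round-trippable TSV."""
    rows = [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "consequence": v.consequence,
            "pop_af": json.dumps(v.pop_af, sort_keys=True),
            "scores": json.dumps(v.scores, sort_keys=True),
            "genotypes": json.dumps(
                {s: str(g) for s, g in v.genotypes.items()}, sort_keys=True
            ),
        }
        for v in sorted(variants, key=lambda r: r.sort_key)
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
        keep_default_na=False,
    )
    out = []
    for row in df.to_dict("records"):
        out.append(
            VariantRecord(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=str(row["gene"]),
                consequence=row["consequence"],
                pop_af=json.loads(row["pop_af"] or "{}"),
                scores=json.loads(row["scores"] or "{}"),
                genotypes={
                    s: GenotypeCall.from_string(g)
                    for s, g in json.loads(row["genotypes"] or "{}").items()
                },
            )
        )
    return out


_CANDIDATE_COLUMNS = ["sample_id", "gene", "model", "variants"]


def write_candidates_tsv(candidates, path, variants=None) -> None:
    """Write inheritance candidates, stably sorted by gene then sample.

    When `variants` (a list of VariantRecord) is supplied, per-variant
    consequence and pass-through predictor scores are appended as extra
    annotation columns.
    """
    vmap = {v.key_str: v for v in variants} if variants else {}
    rows = []
    for c in sorted(candidates, key=lambda c: (c.gene, c.sample_id, c.model)):
        row = {
            "sample_id": c.sample_id,
            "gene": c.gene,
            "model": c.model,
            "variants": ",".join(c.variant_keys),
        }
        if vmap:
            hits = [vmap.get(k) for k in c.variant_keys]
            row["consequences"] = ",".join(
                h.consequence if h else "?" for h in hits
            )
            row["scores"] = json.dumps(
                {k: (vmap[k].scores if k in vmap else {}) for k in c.variant_keys},
                sort_keys=True,
            )
        rows.append(row)
    cols = _CANDIDATE_COLUMNS + (["consequences", "scores"] if vmap else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        InheritanceCandidate(
            sample_id=row["sample_id"],
            gene=row["gene"],
            model=row["model"],
            variant_keys=tuple(row["variants"].split(",")),
        )
        for row in df.to_dict("records")
    ]
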