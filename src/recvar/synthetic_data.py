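"""Synthetic multi-sample cohort generation with a recoverable truth ledger.

Emulates the statistical structure the filtering pipeline assumes: a small
case series (default 7) plus a control panel (default 46), background
variants drawn under Hardy-Weinberg equilibrium from a rare-heavy
allele-frequency spectrum, sex-aware X-chromosome dosage (males carry a
single X allele, emitted hom-coded), database AF annotations equal to the
true simulation AF (with optional missingness for very rare sites, so the
missing-AF-passes rule is exercised), and planted causal genotypes
(compound-het, homozygous, X-hemizygous) recorded in a SimTruth ledger.

Determinism: one root seed; every draw comes from a named substream
(variants / genotypes / plants), so adding or removing a plant does not
perturb the background genotypes.

Not modelled: sequencing error, read depth, linkage disequilibrium.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import ValidationError
from .model import CONSEQUENCES, SampleInfo, chrom_rank

log = logging.getLogger(__name__)

AUTOSOMES = tuple(str(i) for i in range(1, 23))
CHROMS = AUTOSOMES + ("X",)
_BASES = "ACGT"

#: AF ranges for the three spectrum components.
AF_RANGES = {
    "common": (0.05, 0.5),
    "low": (0.001, 0.05),
    "rare": (1e-6, 0.001),
}

DEFAULT_AF_SPECTRUM = {"common": 0.2, "low": 0.3, "rare": 0.5}

DEFAULT_CONSEQUENCE_MIX = {
    "missense": 0.42,
    "synonymous": 0.40,
    "splice_site": 0.03,
    "frameshift": 0.02,
    "stop_gained": 0.02,
    "inframe_indel": 0.01,
    "start_lost": 0.003,
    "stop_lost": 0.002,
    "other": 0.095,
}

_SUBSTREAMS = {"variants": 0, "genotypes": 1, "plants": 2}


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[name],))
    )


@dataclass(frozen=True)
class PlantVariant:
    """Template for one planted variant: where it sits and how it is annotated."""

    chrom: str
    pos: int
    consequence: str = "missense"
    af: float = 5e-4  # the AF reported to every consulted database

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")
        if not 0.0 < self.af < 1.0:
            raise ValidationError("plant AF must be in (0, 1)")


@dataclass(frozen=True)
class PlantSpec:
    """A causal genotype to inject: (sample, gene, model, variant templates)."""

    sample_id: str
    gene: str
    model: str  # homozygous | compound_het | hemizygous
    variants: tuple  # of PlantVariant

    def __post_init__(self):
        if self.model not in ("homozygous", "compound_het", "hemizygous"):
            raise ValidationError(f"unknown plant model {self.model!r}")
        if self.model == "compound_het" and len(self.variants) < 2:
            raise ValidationError("compound_het plant needs >= 2 variant templates")
        if self.model != "compound_het" and len(self.variants) != 1:
            raise ValidationError(f"{self.model} plant needs exactly 1 variant template")
        if self.model == "hemizygous" and any(v.chrom != "X" for v in self.variants):
            raise ValidationError("hemizygous plants must sit on X")


@dataclass
class SimConfig:
    """Cohort simulation parameters. ``seed`` is required and explicit."""

    seed: int
    n_cases: int = 7
    n_controls: int = 46
    n_background_variants: int = 20_000
    af_spectrum: dict = field(default_factory=lambda: dict(DEFAULT_AF_SPECTRUM))
    consequence_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX)
    )
    x_fraction: float = 0.05
    variants_per_gene: int = 10
    db_names: tuple = ("dbSNP", "1000G", "gnomAD")
    db_missing_rate: float = 0.5  # P(db entry absent) for true AF below...
    db_missing_below: float = 1e-4
    planted: tuple | None = None  # None -> default_plants(); () -> no plants

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValidationError("n_cases must be >= 1")
        if self.n_controls < 0 or self.n_background_variants < 0:
            raise ValidationError("counts must be non-negative")
        for mix, label in ((self.af_spectrum, "af_spectrum"),
                           (self.consequence_mix, "consequence_mix")):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"{label} weights must sum to 1, got {total}")
        if not 0.0 <= self.x_fraction <= 1.0:
            raise ValidationError("x_fraction must be in [0, 1]")
        if set(self.af_spectrum) - set(AF_RANGES):
            raise ValidationError(
                f"af_spectrum components must be among {sorted(AF_RANGES)}"
            )


@dataclass
class SimTruth:
    """Ledger of what was planted, for recovery checks downstream."""

    planted: list = field(default_factory=list)  # dicts: sample, gene, model, keys
    relationships: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"planted": self.planted, "relationships": self.relationships},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(planted=d.get("planted", []), relationships=d.get("relationships", []))


@dataclass(frozen=True)
class SimResult:
    vcf_path: Path
    sample_sheet_path: Path
    truth_path: Path
    truth: SimTruth


def make_samples(n_cases: int, n_controls: int) -> list:
    """Build the sample sheet: cases CASE01.., controls CTRL01.., sexes
    alternating male/female deterministically (odd indices male)."""
    samples = []
    for i in range(1, n_cases + 1):
        sex = "male" if i % 2 == 1 else "female"
        samples.append(SampleInfo(f"CASE{i:02d}", sex, "case"))
    for i in range(1, n_controls + 1):
        sex = "male" if i % 2 == 1 else "female"
        samples.append(SampleInfo(f"CTRL{i:02d}", sex, "control"))
    return samples


def default_plants() -> tuple:
    """The default plant set for the 7-case cohort.

    One compound het (CASE01), eight homozygous genes spread over the other
    six cases, and four X-hemizygous genes on the male cases with one gene
    shared by two of them. Plant positions sit above 2.1e8, past the
    background position range, so keys never collide. The compound-het AFs
    (2.2e-5) are low enough to trigger database missingness.
    """
    base = 210_000_000
    ch = PlantSpec(
        "CASE01", "PLANT_CH01", "compound_het",
        (
            PlantVariant("4", base + 1_000, "missense", 2.2e-5),
            PlantVariant("4", base + 2_000, "missense", 2.2e-5),
        ),
    )
    hom_targets = ["CASE02", "CASE03", "CASE04", "CASE05", "CASE06", "CASE07",
                   "CASE02", "CASE04"]
    homs = tuple(
        PlantSpec(
            target, f"PLANT_HOM{i:02d}", "homozygous",
            (PlantVariant(str(2 * i + 1), base + 10_000 + i * 1_000),),
        )
        for i, target in enumerate(hom_targets, start=1)
    )
    hemi_assignments = [
        ("CASE03", "PLANT_HEMI01"),
        ("CASE05", "PLANT_HEMI01"),  # shared X gene, two male carriers
        ("CASE03", "PLANT_HEMI02"),
        ("CASE05", "PLANT_HEMI03"),
        ("CASE07", "PLANT_HEMI04"),
    ]
    hemis = tuple(
        PlantSpec(
            target, gene, "hemizygous",
            (PlantVariant("X", base + 20_000 + i * 1_000),),
        )
        for i, (target, gene) in enumerate(hemi_assignments, start=1)
    )
    return (ch,) + homs + hemis


# ---------------------------------------------------------------------------
# Internal row generation


def _draw_alt(rng: np.random.Generator, ref: str, consequence: str) -> str:
    if consequence == "frameshift":
        return ref + _BASES[rng.integers(4)]
    if consequence == "inframe_indel":
        return ref + "".join(_BASES[rng.integers(4)] for _ in range(3))
    others = [b for b in _BASES if b != ref]
    return others[rng.integers(3)]


def _hwe_dosages(
    rng: np.random.Generator, af: float, samples, is_x: bool
) -> np.ndarray:
    """Draw per-sample dosages under HWE; male X as a single allele."""
    n = len(samples)
    if not is_x:
        return rng.binomial(2, af, size=n)
    d = np.empty(n, dtype=np.int64)
    for i, s in enumerate(samples):
        if s.sex == "male":
            d[i] = 2 * rng.binomial(1, af)  # hom-coded hemizygous
        else:
            d[i] = rng.binomial(2, af)
    return d


def _db_afs(rng: np.random.Generator, af: float, cfg: SimConfig) -> dict:
    out = {}
    for db in cfg.db_names:
        if af < cfg.db_missing_below and rng.random() < cfg.db_missing_rate:
            continue
        out[db] = af
    return out


def _background_rows(cfg: SimConfig, samples) -> list:
    rngv = _rng(cfg.seed, "variants")
    rngg = _rng(cfg.seed, "genotypes")
    n = cfg.n_background_variants
    if n == 0:
        return []

    n_x = int(round(n * cfg.x_fraction))
    chroms = np.concatenate(
        [
            rngv.choice(np.array(AUTOSOMES), size=n - n_x),
            np.repeat("X", n_x),
        ]
    )
    components = list(cfg.af_spectrum)
    comp_draw = rngv.choice(components, size=n, p=[cfg.af_spectrum[c] for c in components])
    afs = np.empty(n)
    for c in components:
        lo, hi = AF_RANGES[c]
        m = comp_draw == c
        afs[m] = rngv.uniform(lo, hi, size=int(m.sum()))
    csq_names = list(cfg.consequence_mix)
    csqs = rngv.choice(csq_names, size=n, p=[cfg.consequence_mix[c] for c in csq_names])

    # unique positions per chromosome, below 2e8 (plants live above 2.1e8)
    rows = []
    idx_by_chrom = {}
    for i in range(n):
        idx_by_chrom.setdefault(chroms[i], []).append(i)
    for chrom in sorted(idx_by_chrom, key=chrom_rank):
        idxs = idx_by_chrom[chrom]
        m = len(idxs)
        pos = np.unique(rngv.integers(1, 200_000_000, size=int(m * 1.2) + 8))
        while pos.size < m:
            pos = np.unique(
                np.concatenate([pos, rngv.integers(1, 200_000_000, size=m)])
            )
        pos = np.sort(rngv.choice(pos, size=m, replace=False))
        for j, i in enumerate(idxs):
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos[j]),
                    "consequence": str(csqs[i]),
                    "af": float(afs[i]),
                }
            )

    # gene labels: contiguous blocks of ~variants_per_gene along each chromosome
    gene_counter = 0
    prev_chrom = None
    in_block = 0
    for row in rows:
        if row["chrom"] != prev_chrom or in_block >= cfg.variants_per_gene:
            gene_counter += 1
            in_block = 0
            prev_chrom = row["chrom"]
        row["gene"] = f"GENE{gene_counter:04d}"
        in_block += 1

    for row in rows:
        ref = _BASES[rngv.integers(4)]
        row["ref"] = ref
        row["alt"] = _draw_alt(rngv, ref, row["consequence"])
        row["pop_af"] = _db_afs(rngv, row["af"], cfg)
        row["dosages"] = _hwe_dosages(rngg, row["af"], samples, row["chrom"] == "X")
    return rows


def _plant_rows(cfg: SimConfig, samples, plants) -> tuple:
    rngp = _rng(cfg.seed, "plants")
    sample_ids = [s.sample_id for s in samples]
    by_id = {s.sample_id: s for s in samples}
    rows, truth_entries = [], []
    seen_positions = set()
    for plant in plants:
        target = by_id.get(plant.sample_id)
        if target is None:
            raise ValidationError(f"plant targets unknown sample {plant.sample_id!r}")
        if plant.model == "hemizygous" and target.sex != "male":
            raise ValidationError(
                f"hemizygous plant targets female sample {plant.sample_id!r}"
            )
        keys = []
        for pv in plant.variants:
            if (pv.chrom, pv.pos) in seen_positions:
                raise ValidationError(
                    f"plant position collision at {pv.chrom}:{pv.pos}"
                )
            seen_positions.add((pv.chrom, pv.pos))
            ref = _BASES[rngp.integers(4)]
            alt = _draw_alt(rngp, ref, pv.consequence)
            dosages = _hwe_dosages(rngp, pv.af, samples, pv.chrom == "X")
            ti = sample_ids.index(plant.sample_id)
            if plant.model == "compound_het":
                dosages[ti] = 1
            else:  # homozygous or hemizygous -> hom-coded alt
                dosages[ti] = 2
            rows.append(
                {
                    "chrom": pv.chrom,
                    "pos": pv.pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": plant.gene,
                    "consequence": pv.consequence,
                    "af": pv.af,
                    "pop_af": _db_afs(rngp, pv.af, cfg),
                    "dosages": dosages,
                }
            )
            keys.append(f"{pv.chrom}:{pv.pos}:{ref}:{alt}")
        truth_entries.append(
            {
                "sample_id": plant.sample_id,
                "gene": plant.gene,
                "model": plant.model,
                "variant_keys": sorted(keys),
            }
        )
    return rows, truth_entries


# ---------------------------------------------------------------------------
# VCF emission


def _vcf_header(cfg: SimConfig, sample_ids) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in CHROMS:
        h.contigs.add(c, length=260_000_000)
    h.add_meta(
        "INFO",
        items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
               ("Description", "Gene symbol")],
    )
    h.add_meta(
        "INFO",
        items=[("ID", "CSQ"), ("Number", "1"), ("Type", "String"),
               ("Description", "Consequence class")],
    )
    db_info_keys = {"dbSNP": "AF_DBSNP", "1000G": "AF_1000G", "gnomAD": "AF_GNOMAD"}
    for db in cfg.db_names:
        key = db_info_keys.get(db, f"AF_{db.upper()}")
        h.add_meta(
            "INFO",
            items=[("ID", key), ("Number", "1"), ("Type", "Float"),
                   ("Description", f"{db} allele frequency")],
        )
    h.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    for sid in sample_ids:
        h.add_sample(sid)
    return h


_DOSAGE_TO_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
_DB_INFO_KEYS = {"dbSNP": "AF_DBSNP", "1000G": "AF_1000G", "gnomAD": "AF_GNOMAD"}


def _write_vcf(path: Path, cfg: SimConfig, samples, rows) -> None:
    sample_ids = [s.sample_id for s in samples]
    header = _vcf_header(cfg, sample_ids)
    rows = sorted(rows, key=lambda r: (chrom_rank(r["chrom"]), r["pos"], r["alt"]))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in rows:
            rec = out.new_record(
                contig=row["chrom"],
                start=row["pos"] - 1,
                alleles=(row["ref"], row["alt"]),
            )
            rec.info["GENE"] = row["gene"]
            rec.info["CSQ"] = row["consequence"]
            for db, af in row["pop_af"].items():
                rec.info[_DB_INFO_KEYS.get(db, f"AF_{db.upper()}")] = af
            for sid, d in zip(sample_ids, row["dosages"]):
                rec.samples[sid]["GT"] = _DOSAGE_TO_GT[int(d)]
                rec.samples[sid].phased = False
            out.write(rec)


def simulate_cohort(cfg: SimConfig, out_dir) -> SimResult:
    """Generate a cohort and write ``cohort.vcf``, ``samples.tsv``, ``truth.json``.

    Deterministic: the same (config, seed) produces byte-identical output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = make_samples(cfg.n_cases, cfg.n_controls)
    plants = default_plants() if cfg.planted is None else tuple(cfg.planted)

    rows = _background_rows(cfg, samples)
    plant_rows, truth_entries = _plant_rows(cfg, samples, plants)
    rows.extend(plant_rows)

    vcf_path = out_dir / "cohort.vcf"
    _write_vcf(vcf_path, cfg, samples, rows)

    sheet_path = out_dir / "samples.tsv"
    pd.DataFrame(
        [{"sample_id": s.sample_id, "sex": s.sex, "role": s.role} for s in samples]
    ).to_csv(sheet_path, sep="\t", index=False)

    truth = SimTruth(planted=sorted(
        truth_entries, key=lambda e: (e["gene"], e["sample_id"], e["model"])
    ))
    truth_path = out_dir / "truth.json"
    truth_path.write_text(truth.to_json() + "\n")
    log.info(
        "simulated cohort: %d samples, %d variants (%d planted)",
        len(samples), len(rows), len(plant_rows),
    )
    return SimResult(vcf_path, sheet_path, truth_path, truth)


# ---------------------------------------------------------------------------
# Related-pair simulation (gamete dropping)

RELATIONSHIPS = ("MZ", "parent_offspring", "full_sib", "unrelated")
EXPECTED_PHI = {"MZ": 0.5, "parent_offspring": 0.25, "full_sib": 0.25, "unrelated": 0.0}


def simulate_related_pair(af_vector, relationship: str, seed: int):
    """Simulate a genotype (dosage) pair with a known relatedness.

    parent_offspring transmits one gamete from a simulated parent; full sibs
    each receive one gamete from each of two simulated parents; MZ duplicates
    share one genotype; unrelated pairs are independent HWE draws.
    """
    p = np.asarray(af_vector, dtype=float)
    if p.size == 0:
        raise ValidationError("AF vector must be non-empty")
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("AFs must lie strictly in (0, 1)")
    if relationship not in RELATIONSHIPS:
        raise ValidationError(f"unknown relationship {relationship!r}")
    rng = np.random.default_rng(seed)
    n = p.size

    def hap():
        return (rng.random(n) < p).astype(np.int8)

    def gamete(parent_haps):
        pick = rng.integers(0, 2, size=n)
        return parent_haps[pick, np.arange(n)]

    if relationship == "MZ":
        g = hap() + hap()
        return g, g.copy()
    if relationship == "unrelated":
        return hap() + hap(), hap() + hap()
    if relationship == "parent_offspring":
        parent_haps = np.stack([hap(), hap()])
        parent = parent_haps.sum(axis=0, dtype=np.int8)
        child = gamete(parent_haps) + hap()
        return parent, child
    # full_sib
    father = np.stack([hap(), hap()])
    mother = np.stack([hap(), hap()])
    sib1 = gamete(father) + gamete(mother)
    sib2 = gamete(father) + gamete(mother)
    return sib1, sib2
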