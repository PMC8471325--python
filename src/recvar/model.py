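"""Core domain types for recessive-model variant prioritization.

A cohort is a list of :class:`VariantRecord` (one decomposed biallelic site
each, with per-sample :class:`GenotypeCall` and annotations) plus a list of
:class:`SampleInfo`. Downstream stages produce :class:`FilterFunnel`,
:class:`InheritanceCandidate` and :class:`KinshipResult` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

from .errors import ValidationError

#: Closed consequence vocabulary used throughout the pipeline.
CONSEQUENCES = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift",
        "inframe_indel",
        "splice_site",
        "synonymous",
        "other",
    }
)

#: Default set retained by the consequence filter: non-synonymous SNVs,
#: indels and splice-site changes.
DAMAGING_CONSEQUENCES = frozenset(CONSEQUENCES - {"synonymous", "other"})

#: Inheritance models called by the pipeline.
MODELS = ("homozygous", "compound_het", "hemizygous")

_CHROM_RANK = {str(i): i for i in range(1, 23)}
_CHROM_RANK["X"] = 23


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix; chromosome labels are "1".."22", "X"."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def chrom_rank(chrom: str) -> int:
    """Numeric sort rank for a chromosome label (autosomes, then X)."""
    c = normalize_chrom(chrom)
    try:
        return _CHROM_RANK[c]
    except KeyError:
        raise ValidationError(f"unsupported chromosome label: {chrom!r}") from None


def round_half_even(x: float, decimals: int) -> float:
    """Round to `decimals` places with banker's rounding on the decimal value.

    Goes through :class:`decimal.Decimal` so that e.g. 0.015 rounds to 0.02
    rather than being bitten by its binary representation.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """An unordered diploid genotype for one sample at one biallelic site.

    Alleles are coded 0 (ref), 1 (alt) and -1 (missing). Half-calls such as
    ``./1`` are normalized to fully missing on construction; hemizygous calls
    are carried hom-coded (e.g. a male X alt as ``1/1``). Phase is recorded
    but every downstream stage treats calls as unphased.
    """

    a: int
    b: int
    phased: bool = False

    def __post_init__(self):
        for x in (self.a, self.b):
            if x not in (-1, 0, 1):
                raise ValidationError(f"allele code must be -1, 0 or 1, got {x}")
        if (self.a == -1) != (self.b == -1):  # half-call -> fully missing
            object.__setattr__(self, "a", -1)
            object.__setattr__(self, "b", -1)

    @property
    def is_missing(self) -> bool:
        return self.a == -1

    @property
    def is_het(self) -> bool:
        return self.a + self.b == 1 and not self.is_missing

    @property
    def is_hom_alt(self) -> bool:
        return self.a == 1 and self.b == 1

    @property
    def is_hom_ref(self) -> bool:
        return self.a == 0 and self.b == 0

    @property
    def has_alt(self) -> bool:
        return not self.is_missing and (self.a == 1 or self.b == 1)

    @property
    def dosage(self) -> int:
        """Alt-allele count, or -1 when missing."""
        return -1 if self.is_missing else self.a + self.b

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        fmt = lambda x: "." if x == -1 else str(x)
        return f"{fmt(self.a)}{sep}{fmt(self.b)}"

    @classmethod
    def from_string(cls, s: str) -> "GenotypeCall":
        phased = "|" in s
        parts = s.replace("|", "/").split("/")
        if len(parts) == 1:  # haploid notation, carry hom-coded
            parts = parts * 2
        if len(parts) != 2:
            raise ValidationError(f"cannot parse genotype {s!r}")
        conv = lambda p: -1 if p == "." else int(p)
        return cls(conv(parts[0]), conv(parts[1]), phased)


@dataclass(frozen=True, slots=True)
class SampleInfo:
    """One cohort member: identifier, sex and case/control role."""

    sample_id: str
    sex: str  # "male" | "female"
    role: str  # "case" | "control"

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")
        if self.role not in ("case", "control"):
            raise ValidationError(f"role must be case/control, got {self.role!r}")


@dataclass(slots=True)
class VariantRecord:
    """One decomposed biallelic site with annotations and genotype calls.

    ``pop_af`` maps database name (e.g. "gnomAD") to an allele frequency in
    [0, 1]; absent entries mean the variant is not reported by that database.
    ``scores`` carries precomputed pathogenicity predictor values through the
    pipeline untouched.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "other"
    pop_af: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)
    genotypes: dict = field(default_factory=dict)  # sample_id -> GenotypeCall

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        chrom_rank(self.chrom)
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")
        for db, af in self.pop_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValidationError(
                    f"{self.key_str}: {db} AF {af} outside [0, 1]"
                )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def sort_key(self) -> tuple:
        return (chrom_rank(self.chrom), self.pos, self.ref, self.alt)

    @property
    def is_x(self) -> bool:
        return self.chrom == "X"


@dataclass(frozen=True, slots=True)
class InheritanceCandidate:
    """A (sample, gene, model) call with its supporting variant keys.

    One candidate is emitted per (sample, gene, model); ``variant_keys`` are
    "chrom:pos:ref:alt" strings in position order (>= 2 for compound_het,
    usually 1 for homozygous/hemizygous).
    """

    sample_id: str
    gene: str
    model: str
    variant_keys: tuple

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValidationError(f"unknown model {self.model!r}")
        if not self.variant_keys:
            raise ValidationError("candidate must reference at least one variant")
        if self.model == "compound_het" and len(set(self.variant_keys)) < 2:
            raise ValidationError("compound_het requires >= 2 distinct variants")


@dataclass(frozen=True, slots=True)
class FunnelStage:
    name: str
    variants_in: int
    variants_out: int

    def __post_init__(self):
        if self.variants_out > self.variants_in:
            raise ValidationError(
                f"stage {self.name}: out ({self.variants_out}) > in ({self.variants_in})"
            )


@dataclass(slots=True)
class FilterFunnel:
    """Ordered per-stage surviving-variant counts; monotone by construction."""

    stages: list = field(default_factory=list)

    def add(self, name: str, variants_in: int, variants_out: int) -> None:
        if self.stages and variants_in != self.stages[-1].variants_out:
            raise ValidationError(
                f"stage {name}: in ({variants_in}) != previous out "
                f"({self.stages[-1].variants_out})"
            )
        self.stages.append(FunnelStage(name, variants_in, variants_out))

    @property
    def counts(self) -> list:
        """[n_in_first, out_1, out_2, ...] — the funnel as plain numbers."""
        if not self.stages:
            return []
        return [self.stages[0].variants_in] + [s.variants_out for s in self.stages]


@dataclass(frozen=True, slots=True)
class KinshipResult:
    """Pairwise kinship estimate with its audit counts."""

    pair: tuple
    phi: float
    n_sites: int
    n_het_het: int
    n_ibs0: int
    n_het_i: int
    n_het_j: int
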