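"""VCF/sample-sheet ingestion, multiallelic decomposition, TSV round-trips."""

import numpy as np
import pytest

from recvar import (
    ConsistencyError,
    FormatError,
    InheritanceCandidate,
    ValidationError,
)
from recvar.variant_io import (
    normalize_consequence,
    read_candidates_tsv,
    read_cohort,
    read_variants_tsv,
    write_candidates_tsv,
    write_variants_tsv,
)

from helpers import random_cohort

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=260000000>
##contig=<ID=X,length=260000000>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=AF_GNOMAD,Number=A,Type=Float,Description="gnomAD AF">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(tmp_path, body, samples=("S1", "S2", "S3"), header=VCF_HEADER):
    cols = "\t".join(
        ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        + list(samples)
    )
    path = tmp_path / "test.vcf"
    path.write_text(header + cols + "\n" + body)
    return path


def write_sheet(tmp_path, rows):
    path = tmp_path / "samples.tsv"
    lines = ["sample_id\tsex\trole"] + [f"{i}\t{s}\t{r}" for i, s, r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


SHEET3 = [("S1", "male", "case"), ("S2", "female", "case"), ("S3", "female", "control")]


def test_biallelic_site_parses_genotype_classes(tmp_path):
    vcf = write_vcf(
        tmp_path,
        "1\t100\t.\tG\tA\t.\t.\tGENE=SLC2A9;CSQ=missense_variant;AF_GNOMAD=0.000022\tGT\t0/1\t1/1\t0/0\n",
    )
    variants, samples = read_cohort(vcf, write_sheet(tmp_path, SHEET3))
    assert len(variants) == 1 and len(samples) == 3
    v = variants[0]
    assert v.genotypes["S1"].is_het
    assert v.genotypes["S2"].is_hom_alt
    assert v.genotypes["S3"].is_hom_ref
    assert v.gene == "SLC2A9" and v.consequence == "missense"
    # annotated frequency carried into pop_af (float32 transport tolerance)
    assert v.pop_af["gnomAD"] == pytest.approx(0.000022, rel=1e-4)


def test_multiallelic_decomposition_recodes_other_alts_as_ref(tmp_path):
    vcf = write_vcf(
        tmp_path,
        "1\t100\t.\tG\tA,T\t.\t.\tGENE=GX;CSQ=missense;AF_GNOMAD=0.0001,0.2\tGT\t0/1\t1/1\t0/2\n",
    )
    variants, _ = read_cohort(vcf, write_sheet(tmp_path, SHEET3))
    assert [v.alt for v in variants] == ["A", "T"]
    rec_a, rec_t = variants
    assert rec_a.genotypes["S1"].is_het and rec_a.genotypes["S2"].is_hom_alt
    assert rec_a.genotypes["S3"].is_hom_ref  # the "2" allele recoded to ref here
    assert rec_t.genotypes["S3"].is_het and rec_t.genotypes["S1"].is_hom_ref
    assert rec_a.pop_af["gnomAD"] == pytest.approx(0.0001, rel=1e-4)
    assert rec_t.pop_af["gnomAD"] == pytest.approx(0.2, rel=1e-6)
    # allele mass conserved: alt-carrying slots across decomposed records
    # equal the original non-ref slots (1 het + 2 hom + 1 other-alt = 4)
    alt_slots = sum(
        (g.a == 1) + (g.b == 1)
        for v in variants
        for g in v.genotypes.values()
    )
    assert alt_slots == 4


def test_half_calls_normalize_to_missing(tmp_path):
    vcf = write_vcf(
        tmp_path,
        "1\t100\t.\tG\tA\t.\t.\tGENE=GX;CSQ=missense\tGT\t./1\t./.\t0/1\n",
    )
    variants, _ = read_cohort(vcf, write_sheet(tmp_path, SHEET3))
    v = variants[0]
    assert v.genotypes["S1"].is_missing
    assert v.genotypes["S2"].is_missing
    assert v.genotypes["S3"].is_het


def test_variants_sorted_chrom_pos_alt(tmp_path):
    vcf = write_vcf(
        tmp_path,
        "1\t200\t.\tG\tT,A\t.\t.\tGENE=GX;CSQ=missense\tGT\t0/1\t0/0\t0/0\n"
        "X\t50\t.\tG\tA\t.\t.\tGENE=GX;CSQ=missense\tGT\t0/1\t0/0\t0/0\n",
    )
    variants, _ = read_cohort(vcf, write_sheet(tmp_path, SHEET3))
    keys = [(v.chrom, v.pos, v.alt) for v in variants]
    assert keys == [("1", 200, "A"), ("1", 200, "T"), ("X", 50, "A")]


def test_vcf_sample_missing_from_sheet_is_an_error(tmp_path):
    vcf = write_vcf(
        tmp_path,
        "1\t100\t.\tG\tA\t.\t.\tGENE=GX;CSQ=missense\tGT\t0/1\t0/0\t0/0\n",
    )
    sheet = write_sheet(tmp_path, SHEET3[:2])
    with pytest.raises(ConsistencyError):
        read_cohort(vcf, sheet)


def test_vcf_without_gt_is_a_format_error(tmp_path):
    header = VCF_HEADER.replace(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n', ""
    )
    path = tmp_path / "nogt.vcf"
    path.write_text(
        header
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        + "1\t100\t.\tG\tA\t.\t.\tGENE=GX\n"
    )
    with pytest.raises(FormatError):
        read_cohort(path, write_sheet(tmp_path, SHEET3))


def test_allele_frequency_outside_unit_interval_rejected(tmp_path):
    vcf = write_vcf(
        tmp_path,
        "1\t100\t.\tG\tA\t.\t.\tGENE=GX;CSQ=missense;AF_GNOMAD=1.5\tGT\t0/1\t0/0\t0/0\n",
    )
    with pytest.raises(ValidationError):
        read_cohort(vcf, write_sheet(tmp_path, SHEET3))


@pytest.mark.parametrize(
    "term,expected",
    [
        ("missense_variant", "missense"),
        ("stop_gained", "stop_gained"),
        ("inframe_deletion", "inframe_indel"),
        ("splice_donor_variant", "splice_site"),
        ("synonymous_variant", "synonymous"),
        ("intergenic_variant", "other"),  # strict-unknown rule
    ],
)
def test_consequence_vocabulary_mapping(term, expected):
    assert normalize_consequence(term) == expected


def test_variants_tsv_roundtrip_and_idempotence(tmp_path):
    rng = np.random.default_rng(11)
    variants, _ = random_cohort(rng, max_samples=6, max_variants=30)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_variants_tsv(variants, p1)
    back = read_variants_tsv(p1)
    assert sorted(back, key=lambda v: v.sort_key) == sorted(
        variants, key=lambda v: v.sort_key
    )
    write_variants_tsv(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_candidates_tsv_roundtrip_on_random_set(tmp_path):
    rng = np.random.default_rng(5)
    models = ["homozygous", "compound_het", "hemizygous"]
    cands = []
    for i in range(50):
        model = models[int(rng.integers(3))]
        n_keys = 2 + int(rng.integers(2)) if model == "compound_het" else 1
        keys = tuple(f"1:{100 + i * 10 + j}:A:G" for j in range(n_keys))
        cands.append(
            InheritanceCandidate(f"S{int(rng.integers(8)):02d}", f"G{i % 7}", model, keys)
        )
    path = tmp_path / "cands.tsv"
    write_candidates_tsv(cands, path)
    back = read_candidates_tsv(path)
    assert sorted(back, key=lambda c: (c.gene, c.sample_id, c.model)) == sorted(
        cands, key=lambda c: (c.gene, c.sample_id, c.model)
    )


def test_empty_candidate_list_writes_header_only(tmp_path):
    path = tmp_path / "empty.tsv"
    write_candidates_tsv([], path)
    assert path.read_text() == "sample_id\tgene\tmodel\tvariants\n"
    assert read_candidates_tsv(path) == []
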