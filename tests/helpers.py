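"""Shared test utilities: random in-memory cohorts and a brute-force
inheritance oracle kept independent of the library implementation."""

from itertools import combinations

import numpy as np

from recvar import GenotypeCall, SampleInfo, VariantRecord
from recvar.model import CONSEQUENCES

_CONSEQ = sorted(CONSEQUENCES)
_DBS = ("dbSNP", "1000G", "gnomAD")
_DOSAGE_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (-1, -1)}


def make_variant(chrom="1", pos=100, ref="A", alt="G", gene="G1",
                 consequence="missense", pop_af=None, genotypes=None):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence, pop_af=pop_af or {},
        genotypes=genotypes or {},
    )


def gt(dosage, phased=False):
    a, b = _DOSAGE_GT[dosage]
    return GenotypeCall(a, b, phased)


def random_cohort(rng: np.random.Generator, max_samples=10, max_variants=50,
                  n_genes=5, empty_gene_prob=0.05):
    """A random small cohort: >=1 case, >=1 control, arbitrary genotypes
    (including het-coded male X calls and missing calls)."""
    n_s = int(rng.integers(2, max_samples + 1))
    samples = []
    for i in range(n_s):
        sex = str(rng.choice(["male", "female"]))
        role = "case" if i == 0 else ("control" if i == 1 else str(rng.choice(["case", "control"])))
        samples.append(SampleInfo(f"S{i:02d}", sex, role))

    n_v = int(rng.integers(1, max_variants + 1))
    variants = []
    for i in range(n_v):
        chrom = str(rng.choice(["1", "2", "X"]))
        gene = "" if rng.random() < empty_gene_prob else f"G{int(rng.integers(n_genes))}"
        pop_af = {}
        for db in _DBS:
            if rng.random() < 0.7:
                pop_af[db] = float(
                    rng.uniform(0, 0.03) if rng.random() < 0.7 else rng.uniform(0, 0.5)
                )
        genotypes = {
            s.sample_id: gt(int(rng.choice([0, 1, 2, -1], p=[0.55, 0.2, 0.15, 0.1])))
            for s in samples
        }
        variants.append(
            make_variant(
                chrom=chrom, pos=100 + i, ref="A", alt="G", gene=gene,
                consequence=str(rng.choice(_CONSEQ)), pop_af=pop_af,
                genotypes=genotypes,
            )
        )
    return variants, samples


def oracle_candidates(variants, samples):
    """Brute-force inheritance calls: enumerate every (case, gene) cell and
    test variant subsets against the rule table directly.

    Rules: on a male's X any alt-carrying call is hemizygous; elsewhere a
    hom-alt call is homozygous; a pair of het calls in one gene is a
    (putative) compound het unless the gene already has a homozygous call.
    Returns a set of (sample_id, gene, model, sorted-variant-key tuple).
    """
    out = set()
    genes = sorted({v.gene for v in variants if v.gene})
    for s in samples:
        if s.role != "case":
            continue
        for g in genes:
            gv = [v for v in variants if v.gene == g]
            hemi, hom, het = [], [], []
            for v in gv:
                call = v.genotypes.get(s.sample_id)
                if call is None or call.is_missing:
                    continue
                if v.chrom == "X" and s.sex == "male":
                    if call.a == 1 or call.b == 1:
                        hemi.append(v.key_str)
                elif call.a == 1 and call.b == 1:
                    hom.append(v.key_str)
                elif {call.a, call.b} == {0, 1}:
                    het.append(v.key_str)
            if hemi:
                out.add((s.sample_id, g, "hemizygous", tuple(sorted(hemi))))
            if hom:
                out.add((s.sample_id, g, "homozygous", tuple(sorted(hom))))
            elif any(True for _ in combinations(het, 2)):
                out.add((s.sample_id, g, "compound_het", tuple(sorted(het))))
    return out


def candidate_set(candidates):
    """Normalize library candidates for comparison with the oracle."""
    return {
        (c.sample_id, c.gene, c.model, tuple(sorted(c.variant_keys)))
        for c in candidates
    }
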