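"""Pairwise kinship estimation from genotypes.

Uses the heterozygote-concordance (KING-robust-style) estimator

    phi_hat = (N_het,het - 2 * N_IBS0) / (N_het(i) + N_het(j))

where N_het,het counts sites at which both samples are heterozygous and
N_IBS0 counts opposite homozygotes. The estimator needs no allele-frequency
weights, which makes it usable on cohorts far too small to estimate
frequencies from. Expected values: 0.5 for monozygotic duplicates, 0.25 for
parent-offspring and full siblings, ~0 for unrelated pairs.

Sites: autosomal biallelic only, pairwise-complete (any site missing in
either sample is dropped), no MAF floor by default.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .errors import UndefinedResultError, ValidationError
from .model import KinshipResult


def king_kinship(genotypes_i, genotypes_j, pair=("i", "j")) -> KinshipResult:
    """Estimate kinship between two samples from dosage vectors.

    Parameters
    ----------
    genotypes_i, genotypes_j
        Alt-allele dosages (0/1/2; negative = missing) over the same
        autosomal biallelic site list.
    pair
        Sample-identifier pair carried into the result.

    Raises
    ------
    UndefinedResultError
        If no usable sites remain or neither sample has a heterozygous
        call (the denominator would be zero) — never a silent 0.
    """
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    if gi.shape != gj.shape:
        raise ValidationError(
            f"genotype vectors differ in length: {gi.shape} vs {gj.shape}"
        )
    mask = (gi >= 0) & (gj >= 0)
    gi, gj = gi[mask], gj[mask]
    n_sites = int(gi.size)
    if n_sites == 0:
        raise UndefinedResultError(f"pair {pair}: no pairwise-complete sites")

    het_i = gi == 1
    het_j = gj == 1
    n_het_het = int(np.count_nonzero(het_i & het_j))
    n_ibs0 = int(np.count_nonzero(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    n_het_i = int(np.count_nonzero(het_i))
    n_het_j = int(np.count_nonzero(het_j))
    denom = n_het_i + n_het_j
    if denom == 0:
        raise UndefinedResultError(
            f"pair {pair}: no heterozygous calls in either sample"
        )
    return KinshipResult(
        pair=tuple(pair),
        phi=(n_het_het - 2 * n_ibs0) / denom,
        n_sites=n_sites,
        n_het_het=n_het_het,
        n_ibs0=n_ibs0,
        n_het_i=n_het_i,
        n_het_j=n_het_j,
    )


def dosage_matrix(variants, sample_ids, autosomes_only: bool = True) -> np.ndarray:
    """Stack variant genotypes into a (sites x samples) int8 dosage matrix."""
    rows = [v for v in variants if not (autosomes_only and v.is_x)]
    m = np.full((len(rows), len(sample_ids)), -1, dtype=np.int8)
    for vi, v in enumerate(rows):
        for si, sid in enumerate(sample_ids):
            call = v.genotypes.get(sid)
            if call is not None:
                m[vi, si] = call.dosage
    return m


def pairwise_case_kinship(variants, samples):
    """KING-style kinship for every case pair over autosomal sites.

    Pairs whose estimate is undefined (no usable hets) yield phi = NaN with
    zeroed counts rather than aborting the run.
    """
    case_ids = [s.sample_id for s in samples if s.role == "case"]
    dosages = dosage_matrix(variants, case_ids, autosomes_only=True)
    results = []
    for i, j in combinations(range(len(case_ids)), 2):
        pair = (case_ids[i], case_ids[j])
        try:
            results.append(king_kinship(dosages[:, i], dosages[:, j], pair))
        except UndefinedResultError:
            results.append(
                KinshipResult(pair, float("nan"), 0, 0, 0, 0, 0)
            )
    return results
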