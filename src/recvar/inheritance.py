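"""Candidate genotype-configuration calling under recessive models.

Per case sample and gene, three mutually aware rules:

* male X (outside any pseudoautosomal interval): any alt-carrying call is a
  hemizygous candidate — a single X copy suffices under an X-linked
  recessive model;
* otherwise, a homozygous-alt call is a homozygous candidate;
* otherwise, two or more heterozygous calls in one gene form a putative
  compound heterozygote. Calling is phase-unaware (no parental genotypes):
  cis pairs cannot be excluded, hence "putative". A gene with a homozygous
  candidate does not additionally contribute its het calls to a compound
  het — the homozygous site alone already satisfies the model.

A single heterozygous variant with no partner yields nothing; controls are
never evaluated; female X is treated autosomally.
"""

from __future__ import annotations

import logging

import pandas as pd

from .filters import is_male_x
from .model import InheritanceCandidate

log = logging.getLogger(__name__)


def call_candidates(variants, samples, par_intervals=()):
    """Call per-case inheritance candidates from filtered variants.

    Returns a list of :class:`InheritanceCandidate`, one per
    (sample, gene, model), sorted by (sample, gene, model). Variants with an
    empty gene label cannot be grouped and are logged and skipped.
    """
    by_gene = {}
    for v in variants:
        if not v.gene:
            log.warning("skipping variant %s: empty gene label", v.key_str)
            continue
        by_gene.setdefault(v.gene, []).append(v)

    cases = [s for s in samples if s.role == "case"]
    candidates = []
    for sample in cases:
        for gene, gene_variants in by_gene.items():
            hemi, hom, het = [], [], []
            for v in sorted(gene_variants, key=lambda r: r.sort_key):
                call = v.genotypes.get(sample.sample_id)
                if call is None or call.is_missing:
                    continue
                if is_male_x(v, sample, par_intervals):
                    if call.has_alt:
                        hemi.append(v.key_str)
                elif call.is_hom_alt:
                    hom.append(v.key_str)
                elif call.is_het:
                    het.append(v.key_str)
            if hemi:
                candidates.append(
                    InheritanceCandidate(
                        sample.sample_id, gene, "hemizygous", tuple(hemi)
                    )
                )
            if hom:
                candidates.append(
                    InheritanceCandidate(
                        sample.sample_id, gene, "homozygous", tuple(hom)
                    )
                )
            elif len(het) >= 2:
                candidates.append(
                    InheritanceCandidate(
                        sample.sample_id, gene, "compound_het", tuple(het)
                    )
                )
    candidates.sort(key=lambda c: (c.sample_id, c.gene, c.model))
    return candidates


def summarize_candidate_genes(candidates) -> pd.DataFrame:
    """Tabulate candidate genes: one row per (gene, model) with case counts.

    Columns: gene, model, n_cases (distinct case carriers), samples
    (comma-joined, sorted). Rows are gene-alphabetical, then model.
    """
    cells = {}
    for c in candidates:
        cells.setdefault((c.gene, c.model), set()).add(c.sample_id)
    rows = [
        {
            "gene": gene,
            "model": model,
            "n_cases": len(sample_ids),
            "samples": ",".join(sorted(sample_ids)),
        }
        for (gene, model), sample_ids in sorted(cells.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "model", "n_cases", "samples"])
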