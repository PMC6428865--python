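"""Differential translation-efficiency testing and behavioral classification.

Per gene we fit one negative-binomial GLM to the eight (or more) counts of
the 2x2 design assay x condition with log link::

    log mu_j = log s_j + b0 + bA * A_j + bC * C_j + bI * A_j * C_j

where A = 1 for ribosome-footprint (RPF) libraries, C = 1 for the
knock-down condition (t30), and s_j are median-of-ratios size factors
computed once on the combined mRNA+RPF matrix. Then

* log2fc_mrna = bC / ln 2       (mRNA abundance change),
* log2fc_rpf  = (bC + bI) / ln 2 (ribosome occupancy change),
* delta_te    = bI / ln 2       (the translational-efficiency change),

and the Wald test on bI asks whether the RPF change exceeds what the mRNA
change explains. Genes are classified by the sign of delta_te (negative =
translationally activated by the depleted factor, since its efficiency
falls upon knock-down) crossed with the mRNA status relative to the
buffering band |log2fc_mrna| < 0.433 (~ +/-35% abundance change).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np

from . import stats
from .datatypes import CountTable, GeneAnnotation, TEResult

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

DEFAULT_FDR_CUT = 0.05
#: log2(1.35): mRNA fold changes within ~ +/-35% count as buffered.
DEFAULT_BUFFER_THRESHOLD = 0.433


def buffering_threshold(fold_change: float = 1.35, digits: int = 3) -> float:
    """The buffering band half-width in log2 units, rounded for reporting."""
    return round(math.log2(fold_change), digits)


def run_te_test(
    table: CountTable,
    min_mean_count: float = 0.0,
    fdr_cut: float = DEFAULT_FDR_CUT,
    buffer_threshold: float = DEFAULT_BUFFER_THRESHOLD,
) -> list[TEResult]:
    """Interaction Wald test for translational-efficiency change, per gene.

    Size factors and per-gene dispersions are estimated from the table
    itself; genes whose counts are all <= ``min_mean_count`` are not tested
    (missing p). Per-gene fitting failures are recorded as missing values,
    never abort the run. FDR is Benjamini-Hochberg across all tested genes,
    and class labels are assigned with the supplied thresholds.
    """
    samples = table.samples
    assays = {s.assay for s in samples}
    conditions = {s.condition for s in samples}
    if assays != {"mRNA", "RPF"} or conditions != {"t0", "t30"}:
        raise ValueError(
            "count table must contain both assays (mRNA, RPF) and both "
            f"conditions (t0, t30); found assays={sorted(assays)}, "
            f"conditions={sorted(conditions)}"
        )

    a_col = np.array([1.0 if s.assay == "RPF" else 0.0 for s in samples])
    c_col = np.array([1.0 if s.condition == "t30" else 0.0 for s in samples])
    design = np.column_stack([np.ones(len(samples)), a_col, c_col, a_col * c_col])
    cells = [f"{s.assay}:{s.condition}" for s in samples]

    sf = stats.size_factors(table)
    offsets = np.log(sf)

    n_genes = len(table.gene_ids)
    lfc_mrna = np.full(n_genes, np.nan)
    lfc_rpf = np.full(n_genes, np.nan)
    delta = np.full(n_genes, np.nan)
    wald_z = np.full(n_genes, np.nan)
    pvals = np.full(n_genes, np.nan)
    n_failed = 0

    for g in range(n_genes):
        y = table.counts[g]
        if np.all(y <= min_mean_count):
            continue
        try:
            alpha = stats.estimate_dispersion(y, cells, sf)
            fit = stats.nb_glm_fit(y, design, offsets, alpha)
        except ValueError:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        b = fit.coefficients
        lfc_mrna[g] = b[2] / LN2
        lfc_rpf[g] = (b[2] + b[3]) / LN2
        delta[g] = b[3] / LN2
        try:
            wald_z[g], pvals[g] = stats.wald_test(fit, 3)
        except ValueError:
            n_failed += 1
            wald_z[g] = np.nan
            pvals[g] = np.nan

    if n_failed:
        logger.info("TE test: %d/%d genes yielded no usable fit", n_failed, n_genes)

    fdr = stats.bh_fdr(pvals)
    results = [
        TEResult(
            table.gene_ids[g],
            float(lfc_mrna[g]),
            float(lfc_rpf[g]),
            float(delta[g]),
            float(wald_z[g]),
            float(pvals[g]),
            float(fdr[g]),
        )
        for g in range(n_genes)
    ]
    return classify_genes(results, fdr_cut=fdr_cut, buffer_threshold=buffer_threshold)


def classify_genes(
    results: Sequence[TEResult],
    fdr_cut: float = DEFAULT_FDR_CUT,
    buffer_threshold: float = DEFAULT_BUFFER_THRESHOLD,
) -> list[TEResult]:
    """Assign the behavioral class label to every result (new list).

    A gene is significant iff fdr < fdr_cut (strict). Direction: delta_te <
    0 means translationally activated by the factor (efficiency falls upon
    its knock-down), delta_te > 0 repressed. mRNA status: buffered iff
    |log2fc_mrna| < buffer_threshold (strict, so a change of exactly the
    threshold is not buffered); otherwise decreased or increased by sign.
    """
    if not (0.0 < fdr_cut < 1.0):
        raise ValueError("fdr_cut must lie in (0, 1)")
    if buffer_threshold <= 0:
        raise ValueError("buffer_threshold must be > 0")
    out = []
    for r in results:
        label = "not_regulated"
        if (
            np.isfinite(r.fdr)
            and np.isfinite(r.delta_te)
            and np.isfinite(r.log2fc_mrna)
            and r.fdr < fdr_cut
            and r.delta_te != 0.0
        ):
            direction = "activated" if r.delta_te < 0 else "repressed"
            if abs(r.log2fc_mrna) < buffer_threshold:
                status = "buffered"
            elif r.log2fc_mrna < 0:
                status = "decreased"
            else:
                status = "increased"
            label = f"{direction}_{status}"
        out.append(
            TEResult(
                r.gene_id,
                r.log2fc_mrna,
                r.log2fc_rpf,
                r.delta_te,
                r.wald_z,
                r.p,
                r.fdr,
                label,
            )
        )
    return out


def overlap_significance(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[int, float, float]:
    """Observed overlap, its expectation under independence, and the
    upper-tail hypergeometric p-value."""
    a, b, u = set(set_a), set(set_b), set(universe)
    stray = (a | b) - u
    if stray:
        raise ValueError(f"{len(stray)} set elements outside the universe, e.g. {sorted(stray)[:3]}")
    k = len(a & b)
    expected = len(a) * len(b) / len(u) if u else 0.0
    p = stats.hypergeom_overlap_p(k, len(a), len(b), len(u))
    return k, expected, p


def membrane_enrichment(
    results: Sequence[TEResult], annotations: Sequence[GeneAnnotation]
) -> tuple[float, dict[str, int]]:
    """How much likelier activated transcripts are to encode membrane
    proteins, relative to transcripts that do not depend on the factor.

    Returns the ratio of membrane fractions and the underlying 2x2 table:
    a/b = membrane/non-membrane among activated genes, c/d the same among
    not_regulated genes.
    """
    membrane = {ann.gene_id: ann.is_membrane for ann in annotations}
    a = b = c = d = 0
    for r in results:
        if r.gene_id not in membrane:
            continue
        is_mem = membrane[r.gene_id]
        if r.class_label.startswith("activated"):
            a += is_mem
            b += not is_mem
        elif r.class_label == "not_regulated":
            c += is_mem
            d += not is_mem
    if a + b == 0:
        raise ValueError("no activated genes with annotation")
    if c + d == 0:
        raise ValueError("no not_regulated genes with annotation")
    ratio = stats.relative_enrichment(a, b, c, d)
    return ratio, {"a": a, "b": b, "c": c, "d": d}
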