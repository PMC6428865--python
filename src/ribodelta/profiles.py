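"""Positional analyses: codon-level footprint metagenes, TIS-centered
structure-score metagenes, region averages, and group feature comparisons.

Footprint metagenes answer an initiation-vs-elongation question: a defect
in initiation shifts ribosome density uniformly along the CDS, whereas an
elongation stall changes the slope. Structure metagenes around the
translation initiation site (TIS) reveal whether a gene group carries an
unusually structured initiation context.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .datatypes import (
    CodonCoverage,
    GeneAnnotation,
    MetageneProfile,
    PARSProfile,
    SampleMeta,
)

logger = logging.getLogger(__name__)

DEFAULT_MASK_CODONS = 15
DEFAULT_N_BINS = 100
DEFAULT_MIN_CODONS = 40
DEFAULT_TIS_UP = 100
DEFAULT_TIS_DOWN = 300


def mask_start_region(cov: CodonCoverage, n_codons: int = DEFAULT_MASK_CODONS) -> CodonCoverage:
    """Drop the first ``n_codons`` codons (cycloheximide artefact region).

    A gene with no codons left is returned with empty coverage (excluded),
    not raised as an error.
    """
    if n_codons < 0:
        raise ValueError("n_codons must be >= 0")
    return CodonCoverage(cov.gene_id, cov.sample_id, cov.counts_per_codon[n_codons:])


def rpf_metagene(
    coverages: Sequence[CodonCoverage],
    samples: Sequence[SampleMeta],
    mrna_fc: Mapping[str, float],
    group: Iterable[str],
    n_bins: int = DEFAULT_N_BINS,
    mask_codons: int = DEFAULT_MASK_CODONS,
    min_codons: int = DEFAULT_MIN_CODONS,
    group_label: str = "group",
) -> dict[str, MetageneProfile]:
    """Mean mRNA-normalized footprint density along the CDS, per condition.

    Per codon the signal is observed/expected where the expectation assumes
    uniform codon usage: expected = library_total / total retained codons,
    with both totals taken over *all* genes supplied (the analysis set), so
    values are comparable across libraries and between-condition level
    shifts survive. Knock-down (t30) values are divided per gene by that
    gene's linear mRNA fold change before averaging. Codon positions are
    mapped to ``n_bins`` equal-width relative bins; the profile averages
    replicates, then genes. Group genes retaining fewer than ``min_codons``
    codons after masking are excluded (counted in the log).
    """
    group = set(group)
    rpf_samples = [s for s in samples if s.assay == "RPF"]
    if not rpf_samples:
        raise ValueError("no RPF samples supplied")
    sample_cond = {s.sample_id: s.condition for s in rpf_samples}

    masked: dict[tuple[str, str], np.ndarray] = {}
    retained_len: dict[str, int] = {}
    for cov in coverages:
        if cov.sample_id not in sample_cond:
            continue
        m = mask_start_region(cov, mask_codons)
        masked[(cov.gene_id, cov.sample_id)] = m.counts_per_codon
        retained_len[cov.gene_id] = len(m.counts_per_codon)

    # uniform-usage expectation over the whole analysis set
    lib_totals = {sid: 0.0 for sid in sample_cond}
    total_codons = sum(retained_len.values())
    if total_codons == 0:
        raise ValueError("no retained codons in the analysis set")
    for (gid, sid), vec in masked.items():
        lib_totals[sid] += float(vec.sum())
    for sid, tot in lib_totals.items():
        if tot <= 0:
            raise ValueError(f"zero library total for sample {sid!r}")
    expected = {sid: lib_totals[sid] / total_codons for sid in lib_totals}

    usable = []
    n_short = 0
    for gid in sorted(group):
        if retained_len.get(gid, 0) < min_codons:
            n_short += 1
            continue
        if any((gid, s.sample_id) not in masked for s in rpf_samples):
            raise ValueError(f"group gene {gid!r} lacks coverage in some RPF sample")
        if gid not in mrna_fc or not mrna_fc[gid] > 0:
            raise ValueError(f"group gene {gid!r} needs a positive mRNA fold change")
        usable.append(gid)
    if n_short:
        logger.info("metagene: excluded %d group genes shorter than %d retained codons",
                    n_short, min_codons)
    if not usable:
        raise ValueError("no usable group genes for the metagene")

    profiles = {}
    for condition in ("t0", "t30"):
        cond_samples = [s.sample_id for s in rpf_samples if s.condition == condition]
        if not cond_samples:
            continue
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        for gid in usable:
            length = retained_len[gid]
            # mean over replicates of the normalized per-codon signal
            per_codon = np.mean(
                [masked[(gid, sid)] / expected[sid] for sid in cond_samples], axis=0
            )
            if condition == "t30":
                per_codon = per_codon / mrna_fc[gid]
            bins = (np.arange(length) * n_bins) // length
            gene_vals = np.full(n_bins, np.nan)
            for b in range(n_bins):
                sel = bins == b
                if np.any(sel):
                    gene_vals[b] = per_codon[sel].mean()
            has = np.isfinite(gene_vals)
            sums[has] += gene_vals[has]
            counts[has] += 1
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        profiles[condition] = MetageneProfile(
            axis="codon_bins",
            positions=np.arange(1, n_bins + 1),
            values=values,
            n_genes=counts,
            group_label=group_label,
            condition=condition,
        )
    return profiles


def pars_tis_profile(
    profiles: Sequence[PARSProfile],
    annotations: Sequence[GeneAnnotation],
    group: Iterable[str],
    up: int = DEFAULT_TIS_UP,
    down: int = DEFAULT_TIS_DOWN,
    group_label: str = "group",
) -> MetageneProfile:
    """Mean structure score per nucleotide around the TIS (position 0 = first
    CDS nucleotide).

    Each gene contributes upstream positions only as far as its 5'UTR
    extends and downstream positions only as far as its CDS extends;
    missing scores are skipped. Genes in the group without a profile are
    skipped with a logged count.
    """
    ann_by_id = {a.gene_id: a for a in annotations}
    prof_by_id = {p.gene_id: p for p in profiles}
    positions = np.arange(-up, down)
    sums = np.zeros(len(positions))
    counts = np.zeros(len(positions), dtype=int)
    n_missing = 0
    for gid in sorted(set(group)):
        ann = ann_by_id.get(gid)
        prof = prof_by_id.get(gid)
        if ann is None or prof is None:
            n_missing += 1
            continue
        if len(prof.scores) != ann.total_length:
            raise ValueError(
                f"{gid}: profile length {len(prof.scores)} != annotation "
                f"length {ann.total_length}"
            )
        lo = -min(ann.utr5_length, up)
        hi = min(ann.cds_length, down)
        for pos in range(lo, hi):
            score = prof.scores[ann.utr5_length + pos]
            if np.isfinite(score):
                idx = pos + up
                sums[idx] += score
                counts[idx] += 1
    if n_missing:
        logger.info("TIS profile: %d group genes without profile/annotation skipped", n_missing)
    values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MetageneProfile(
        axis="nt_relative_to_TIS",
        positions=positions,
        values=values,
        n_genes=counts,
        group_label=group_label,
    )


def pars_region_means(
    profile: PARSProfile, annotation: GeneAnnotation
) -> tuple[float, float, float]:
    """Mean structure score over the 5'UTR, CDS and 3'UTR (missing skipped).

    A region of length 0 yields NaN.
    """
    if len(profile.scores) != annotation.total_length:
        raise ValueError(
            f"{profile.gene_id}: profile length {len(profile.scores)} != "
            f"annotation length {annotation.total_length}"
        )

    def region_mean(lo: int, hi: int) -> float:
        if hi <= lo:
            return float("nan")
        seg = profile.scores[lo:hi]
        if np.all(~np.isfinite(seg)):
            return float("nan")
        return float(np.nanmean(seg))

    u5 = annotation.utr5_length
    cds_end = u5 + annotation.cds_length
    return (
        region_mean(0, u5),
        region_mean(u5, cds_end),
        region_mean(cds_end, annotation.total_length),
    )


def compare_group_feature(
    values_by_group: Mapping[str, Sequence[float]],
    background: Sequence[float],
) -> pd.DataFrame:
    """Per-group mean/median plus a two-sided rank test against background.

    The background itself is included as a row (p = NaN).
    """
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background must be non-empty")
    rows = []
    for name, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
        u, p = stats.mann_whitney(vals, background, alternative="two-sided", mode="auto")
        rows.append(
            {
                "group": name,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "U": u,
                "p": p,
            }
        )
    rows.append(
        {
            "group": "background",
            "n": int(background.size),
            "mean": float(background.mean()),
            "median": float(np.median(background)),
            "U": float("nan"),
            "p": float("nan"),
        }
    )
    return pd.DataFrame(rows, columns=["group", "n", "mean", "median", "U", "p"])
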