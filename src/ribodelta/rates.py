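"""Synthesis-rate / half-life calculus and small reporter-assay arithmetic.

Run-on assays give a nascent transcription rate (nTR) per gene; dividing by
the average cell volume yields the mRNA synthesis rate SR, and combining SR
with the steady-state abundance RA gives the half-life HL = RA / SR, all in
arbitrary units. Group comparisons ask whether a behavioral class changed
its SR or HL upon knock-down relative to the unaffected background.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .datatypes import RateRecord

logger = logging.getLogger(__name__)

POLYSOME_GROUPS = {
    "free": (0, 5),  # fractions 1-5
    "subunits": (5, 11),  # 6-11
    "monosomes": (11, 15),  # 12-15
    "light_polysomes": (15, 21),  # 16-21
    "heavy_polysomes": (21, 26),  # 22-26
}


def synthesis_rate(ntr: float, cell_volume: float) -> float:
    """SR = nTR / cell_volume."""
    if cell_volume <= 0:
        raise ValueError("cell_volume must be > 0")
    return ntr / cell_volume


def half_life(ra: float, sr: float) -> float:
    """HL = RA / SR; missing (NaN) when SR <= 0."""
    if sr <= 0:
        logger.info("half_life: SR <= 0, returning missing")
        return float("nan")
    if ra < 0:
        raise ValueError("RA must be >= 0")
    return ra / sr


def group_rate_comparison(
    records: Sequence[RateRecord],
    classes: Mapping[str, str],
    background_class: str = "not_regulated",
) -> pd.DataFrame:
    """Per-class log2(t30/t0) changes of SR and HL vs the background.

    Returns one row per class with the median log2 ratios and two-sided
    rank-test p-values against the background class. Genes missing one
    condition (or with non-positive rates) are excluded with a logged count.
    """
    by_gene: dict[str, dict[str, RateRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, {})[rec.condition] = rec

    sr_ratio: dict[str, float] = {}
    hl_ratio: dict[str, float] = {}
    n_excluded = 0
    for gid, conds in by_gene.items():
        if "t0" not in conds or "t30" not in conds:
            n_excluded += 1
            continue
        r0, r30 = conds["t0"], conds["t30"]
        if min(r0.SR, r30.SR, r0.HL, r30.HL) <= 0:
            n_excluded += 1
            continue
        sr_ratio[gid] = math.log2(r30.SR / r0.SR)
        hl_ratio[gid] = math.log2(r30.HL / r0.HL)
    if n_excluded:
        logger.info("rate comparison: %d genes excluded (missing condition or "
                    "non-positive rate)", n_excluded)

    groups: dict[str, list[str]] = {}
    for gid in sr_ratio:
        label = classes.get(gid)
        if label is not None:
            groups.setdefault(label, []).append(gid)
    bg = groups.get(background_class, [])
    if not bg:
        raise ValueError(f"background class {background_class!r} is empty")
    bg_sr = np.array([sr_ratio[g] for g in bg])
    bg_hl = np.array([hl_ratio[g] for g in bg])

    rows = []
    for label in sorted(groups):
        gids = groups[label]
        if not gids:
            raise ValueError(f"group {label!r} is empty")
        g_sr = np.array([sr_ratio[g] for g in gids])
        g_hl = np.array([hl_ratio[g] for g in gids])
        if label == background_class:
            p_sr = p_hl = float("nan")
        else:
            _, p_sr = stats.mann_whitney(g_sr, bg_sr, "two-sided", "auto")
            _, p_hl = stats.mann_whitney(g_hl, bg_hl, "two-sided", "auto")
        rows.append(
            {
                "class_label": label,
                "n": len(gids),
                "median_log2_sr_change": float(np.median(g_sr)),
                "median_log2_hl_change": float(np.median(g_hl)),
                "p_sr": p_sr,
                "p_hl": p_hl,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "class_label",
            "n",
            "median_log2_sr_change",
            "median_log2_hl_change",
            "p_sr",
            "p_hl",
        ],
    )


def translatability(protein_rel: float, rna_rel: float) -> float:
    """Change in protein level divided by change in mRNA level."""
    if rna_rel <= 0:
        raise ValueError("rna_rel must be > 0")
    return protein_rel / rna_rel


def capped_adjusted_translatability(
    t: float, capped_fraction_mut: float, capped_fraction_wt: float = 1.0
) -> float:
    """Translatability restricted to the capped pool of molecules.

    Only capped molecules are translation substrates; if only a fraction of
    the mutant's transcripts is capped, the per-capped-molecule
    translatability is t * capped_fraction_wt / capped_fraction_mut.
    """
    for name, frac in (("capped_fraction_mut", capped_fraction_mut),
                       ("capped_fraction_wt", capped_fraction_wt)):
        if not (0.0 < frac <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1], got {frac}")
    return t * capped_fraction_wt / capped_fraction_mut


def decay_half_life_fit(times: Sequence[float], levels: Sequence[float]) -> float:
    """Half-life from a transcription shut-off time course.

    Ordinary least squares of ln(level) on time; t_half = ln 2 / |slope|.
    A non-negative slope (no decay) is flagged as an infinite half-life.
    """
    times = np.asarray(times, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 time points")
    if times.size != levels.size:
        raise ValueError("times and levels must have equal length")
    if np.any(levels <= 0):
        raise ValueError("levels must be > 0")
    slope = np.polyfit(times, np.log(levels), 1)[0]
    if slope >= 0:
        logger.info("decay fit: non-negative slope, half-life flagged infinite")
        return float("inf")
    return math.log(2.0) / abs(slope)


def polysome_distribution(fraction_signal: Sequence[float]) -> tuple[np.ndarray, dict[str, float]]:
    """Normalize a 26-fraction sucrose-gradient profile and sum five groups.

    Fractions 1-5 are free mRNPs, 6-11 single ribosomal subunits, 12-15
    monosomes, 16-21 light polysomes and 22-26 heavy polysomes. The group
    sums total 1 after normalization.
    """
    signal = np.asarray(fraction_signal, dtype=float)
    if signal.shape != (26,):
        raise ValueError(f"expected 26 fractions, got {signal.shape}")
    if np.any(signal < 0):
        raise ValueError("fraction signal must be non-negative")
    total = signal.sum()
    if total <= 0:
        raise ValueError("total signal must be > 0")
    dist = signal / total
    groups = {name: float(dist[lo:hi].sum()) for name, (lo, hi) in POLYSOME_GROUPS.items()}
    return dist, groups
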