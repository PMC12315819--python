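"""Well-level aggregation, dilution linearity and batch QC.

Field counts are summed (not averaged) within a well and reported as
densities per mm^2, which makes acquisitions at different magnifications
(60x vs 63x platforms) directly comparable.  A standard dilution series —
an aggregate standard serially diluted 5-fold from 1 ug/mL — validates each
batch: the particle count should fall in proportion to concentration
(log-log slope near 1 in the dilute regime), and an alpha-synuclein-only
standard must not light up the amylin channel.  Batches with a poor
standard curve or massive amylin bleed-through are failed and excluded.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import ColocSummary, ParameterError, QCVerdict, StandardSeries, WellSummary

__all__ = ["summarize_well", "dilution_linearity", "qc_batch"]

#: default QC thresholds; "poor" and "massive" are not fixed by the assay
#: protocol, so these are declared, overridable defaults.
DEFAULT_MIN_RANK_CORR = 0.9
DEFAULT_MAX_BLEEDTHROUGH_FRAC = 0.10


def summarize_well(field_summaries: list[ColocSummary],
                   well_id: str = "well0", sample_id: str = "sample0",
                   dilution_factor: float = 1.0) -> WellSummary:
    """Aggregate per-field counts to one well.

    Counts and imaged areas are summed over fields; densities per mm^2
    follow from the totals.  Permutation-invariant over fields.
    """
    if not field_summaries:
        raise ValueError("at least one field summary is required")
    return WellSummary(
        well_id=well_id, sample_id=sample_id,
        n_fields=len(field_summaries),
        total_red=int(sum(s.n_red for s in field_summaries)),
        total_blue=int(sum(s.n_blue for s in field_summaries)),
        total_coloc=int(sum(s.n_coloc for s in field_summaries)),
        total_corrected=float(sum(s.corrected_count for s in field_summaries)),
        total_area_mm2=float(sum(s.field_area_mm2 for s in field_summaries)),
        dilution_factor=dilution_factor)


def dilution_linearity(series: StandardSeries, channel: str = "red",
                       min_quant_count: float = 5.0) -> tuple[float, bool]:
    """Log-log linearity of a standard dilution curve.

    Returns the least-squares slope of log(count) vs log(relative
    concentration) over the quantifiable steps (at least 3 required) and
    whether counts are monotone non-increasing with dilution.  A slope of 1
    means counts proportional to concentration.

    Steps with fewer than ``min_quant_count`` counts are excluded from the
    fit: below ~5 counts the Poisson coefficient of variation exceeds 45%
    and conditioning on a nonzero observation biases log-counts upward,
    which would systematically flatten the fitted slope in the
    deep-dilution tail.
    """
    counts = np.asarray(series.red_counts if channel == "red"
                        else series.blue_counts, dtype=float)
    conc = np.asarray(series.concentrations, dtype=float)
    if np.all(counts == 0):
        raise ValueError("all counts are zero; no linearity to assess")
    nz = counts >= max(min_quant_count, np.finfo(float).tiny)
    if nz.sum() < 3:
        raise ValueError("need at least 3 quantifiable steps "
                         f"(count >= {min_quant_count})")
    rel = conc / conc[0]
    slope = float(np.polyfit(np.log(rel[nz]), np.log(counts[nz]), 1)[0])
    monotone = bool(np.all(np.diff(counts) <= 0))
    return slope, monotone


def qc_batch(series: StandardSeries,
             min_rank_corr: float = DEFAULT_MIN_RANK_CORR,
             max_bleedthrough_frac: float = DEFAULT_MAX_BLEEDTHROUGH_FRAC,
             ) -> QCVerdict:
    """Batch pass/fail from its appended standard series.

    Fails with ``poor_standard_curve`` when the red counts are not monotone
    with dilution, or the Spearman rank correlation between concentration
    and red count falls below ``min_rank_corr``, or the top standard does
    not exceed the blank.  Fails with ``amylin_bleedthrough`` when an
    alpha-synuclein-only standard shows total blue signal above
    ``max_bleedthrough_frac`` of total red.  The verdict depends only on
    the standard series, never on cohort data.
    """
    if series.blank_red is None or series.blank_blue is None:
        raise ValueError("blank-well counts are required for batch QC")
    reasons: list[str] = []
    red = np.asarray(series.red_counts, dtype=float)
    conc = np.asarray(series.concentrations, dtype=float)
    monotone = bool(np.all(np.diff(red) <= 0))
    rho = stats.spearmanr(conc, red).statistic if len(red) >= 3 else 1.0
    if (not monotone) or (rho < min_rank_corr) or (red[0] <= series.blank_red):
        reasons.append("poor_standard_curve")
    if series.standard_type == "alpha_syn_only":
        tot_red = float(np.sum(red))
        tot_blue = float(np.sum(series.blue_counts))
        if tot_red <= 0 or tot_blue > max_bleedthrough_frac * tot_red:
            reasons.append("amylin_bleedthrough")
    return QCVerdict(passed=not reasons, reasons=reasons)
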