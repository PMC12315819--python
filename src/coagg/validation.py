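"""Simulation studies that validate the pipeline end-to-end.

Each study generates synthetic data with known ground truth, runs the
production code path, and reports summary metrics.  They are used by the
test suite and by ``scripts/acceptance.py``; problem sizes are chosen so a
full run completes in minutes on one core (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .assay_qc import dilution_linearity
from .cohort_stats import auc_mann_whitney, compare_two_groups, roc
from .colocalization import (
    coloc_summary,
    evaluate_detections,
    expected_chance_coloc,
    match_points,
    match_spots,
)
from .detection import detect_spots
from .kinetics import fit_1to1
from .synth import derive_seed, generate_field, simulate_sensorgram
from .types import KineticParams, StandardSeries, SynthFieldParams

__all__ = [
    "detection_quality_study",
    "coloc_fraction_recovery_study",
    "chance_null_study",
    "dilution_slope_study",
    "type_i_error_study",
    "designed_auc_study",
    "kinetics_recovery_study",
]


def detection_quality_study(n_fields: int = 50, seed: int = 0,
                            ) -> tuple[float, float]:
    """Mean detection recall and precision (2-px tolerance) over synthetic
    fields at peak-SNR ~10 with ~50 spots per channel, both channels."""
    recs, precs = [], []
    for i in range(n_fields):
        p = SynthFieldParams(seed=derive_seed(seed, 1, i))
        fld, truth = generate_field(p)
        for img, centers, ch in ((fld.red_image, truth.red_centers, "red"),
                                 (fld.blue_image, truth.blue_centers, "blue")):
            r, pr, _ = evaluate_detections(
                detect_spots(img, channel=ch), centers, tol_px=2.0)
            recs.append(r)
            precs.append(pr)
    return float(np.mean(recs)), float(np.mean(precs))


def coloc_fraction_recovery_study(
        levels=(0.0, 0.25, 0.5, 0.75, 1.0), n_fields: int = 50,
        n_red_total: float = 50.0, n_extra_blue: float = 20.0,
        d_max_px: float = 3.0, seed: int = 0) -> dict[float, float]:
    """Mean chance-corrected co-localization estimate per true fraction.

    Each level f uses fields with f * n_red_total true pairs plus
    (1 - f) * n_red_total red-only spots and ``n_extra_blue`` blue-only
    spots; the estimate is corrected_count / n_red from detected spots.
    """
    out = {}
    for li, f in enumerate(levels):
        ests = []
        for i in range(n_fields):
            p = SynthFieldParams(
                lambda_pair=f * n_red_total,
                lambda_red_only=(1.0 - f) * n_red_total,
                lambda_blue_only=n_extra_blue,
                seed=derive_seed(seed, 2, li, i))
            fld, _ = generate_field(p)
            red = detect_spots(fld.red_image, channel="red")
            blue = detect_spots(fld.blue_image, channel="blue")
            m = match_spots(red, blue, d_max_px)
            h, w = fld.red_image.shape
            s = coloc_summary(m, len(red), len(blue), h * w, p.pixel_size_um)
            ests.append(s.corrected_count / s.n_red if s.n_red else 0.0)
        out[f] = float(np.mean(ests))
    return out


def chance_null_study(n_fields: int = 10_000, n_per_channel: int = 20,
                      d_max_px: float = 3.0, side_px: int = 512,
                      seed: int = 0) -> dict[str, float]:
    """Monte-Carlo check of the chance-overlap formula under complete
    spatial randomness: matched-pair mean vs analytic expectation."""
    rng = np.random.default_rng(derive_seed(seed, 3))
    matched = np.empty(n_fields)
    for i in range(n_fields):
        a = rng.uniform(0, side_px, (n_per_channel, 2))
        b = rng.uniform(0, side_px, (n_per_channel, 2))
        matched[i] = len(match_points(a, b, d_max_px))
    analytic = expected_chance_coloc(n_per_channel, n_per_channel,
                                     side_px ** 2, d_max_px)
    se = float(matched.std(ddof=1) / np.sqrt(n_fields))
    return {"mc_mean": float(matched.mean()), "analytic": analytic,
            "se": se, "z": float((matched.mean() - analytic) / se)}


def dilution_slope_study(n_series: int = 100, n_fields_per_step: int = 6,
                         fold: float = 5.0, steps: int = 7,
                         seed: int = 0) -> dict[str, object]:
    """Detected-count linearity across a 5-fold/7-step dilution.

    Per series and step, red-channel detections are summed over
    ``n_fields_per_step`` fields of 256 px whose spot rates scale as
    fold**(-k) from 50 red spots/field; the log-log slope of count vs
    relative concentration is fitted per series over nonzero steps.
    """
    conc = [fold ** (-k) for k in range(steps)]
    slopes = []
    step_totals = np.zeros(steps)
    n_used = 0
    for s in range(n_series):
        counts = np.zeros(steps)
        for k in range(steps):
            scale = fold ** (-k)
            for r in range(n_fields_per_step):
                p = SynthFieldParams(
                    width_px=256, height_px=256,
                    lambda_pair=30.0 * scale, lambda_red_only=20.0 * scale,
                    lambda_blue_only=0.0,
                    seed=derive_seed(seed, 4, s, k, r))
                fld, _ = generate_field(p)
                counts[k] += len(detect_spots(fld.red_image, channel="red"))
        step_totals += counts
        series = StandardSeries(conc, list(counts), [0.0] * steps,
                                "alpha_syn_only", blank_red=0.0, blank_blue=0.0)
        try:
            slope, _ = dilution_linearity(series)
        except ValueError:  # fewer than 3 nonzero steps (deep-dilution tail)
            continue
        slopes.append(slope)
        n_used += 1
    mean_counts = step_totals / n_series
    return {"mean_slope": float(np.mean(slopes)),
            "sd_slope": float(np.std(slopes, ddof=1)),
            "n_series_used": n_used,
            "mean_counts_per_step": mean_counts.tolist(),
            "monotone_in_expectation": bool(np.all(np.diff(mean_counts) < 0))}


def type_i_error_study(n_sims: int = 2000, n_per_group: int = 20,
                       mean: float = 50.0, dispersion: float = 10.0,
                       alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I rate of the two-group t-test on null cohorts.

    Both groups draw per-sample counts from the same negative-binomial
    (gamma-mixed Poisson readout means), mirroring the cohort generator.
    """
    rng = np.random.default_rng(derive_seed(seed, 5))
    n_reject = 0
    for _ in range(n_sims):
        lam_a = rng.gamma(dispersion, mean / dispersion, n_per_group)
        lam_b = rng.gamma(dispersion, mean / dispersion, n_per_group)
        a = rng.poisson(lam_a[:, None], (n_per_group, 12)).mean(axis=1)
        b = rng.poisson(lam_b[:, None], (n_per_group, 12)).mean(axis=1)
        _, p = compare_two_groups(a, b)
        n_reject += p < alpha
    return n_reject / n_sims


def designed_auc_study(n_per_group: int = 200, mean_hc: float = 5.0,
                       mean_pd: float = 15.0, dispersion: float = 2.0,
                       n_boot: int = 2000, seed: int = 0) -> dict[str, float]:
    """AUC on a cohort with designed separation vs its design value.

    The design AUC is estimated independently by direct Monte-Carlo of
    P(X_PD > X_HC) + 0.5 * P(tie) from the generative model (1e5 draws);
    the observed AUC and bootstrap CI come from ``roc`` on one generated
    cohort of ``n_per_group`` samples per group.
    """
    from .synth import cohort_sample_summary, generate_cohort
    from .types import SyntheticCohortParams

    rng = np.random.default_rng(derive_seed(seed, 6))
    n_mc = 100_000
    xh = rng.poisson(rng.gamma(dispersion, mean_hc / dispersion, (n_mc, 1)),
                     (n_mc, 12)).mean(axis=1)
    xp = rng.poisson(rng.gamma(dispersion, mean_pd / dispersion, (n_mc, 1)),
                     (n_mc, 12)).mean(axis=1)
    design = auc_mann_whitney(np.concatenate([xh, xp]),
                              np.array([0] * n_mc + [1] * n_mc))

    params = SyntheticCohortParams(
        n_per_group=n_per_group,
        group_means={"HC": mean_hc, "PD": mean_pd},
        dispersion=dispersion, seed=derive_seed(seed, 7))
    summ = cohort_sample_summary(generate_cohort(params))
    labels = (summ.group == "PD").astype(int).to_numpy()
    res = roc(summ.coagg_count.to_numpy(), labels, n_boot=n_boot,
              seed=derive_seed(seed, 8))
    return {"design_auc": float(design), "observed_auc": res.auc,
            "ci_low": res.ci_low, "ci_high": res.ci_high}


def kinetics_recovery_study(n_seeds: int = 20, noise_frac: float = 0.01,
                            concs=(0.1, 0.3, 1.0, 3.0, 10.0),
                            seed: int = 0) -> dict[str, float]:
    """Simulate-then-fit recovery of (ka, kd) at 1% amplitude noise over
    concentrations spanning 0.1-10x KD; reports worst-case relative errors."""
    true = KineticParams(ka=5809.0, kd=2.136e-3, Rmax=100.0)
    ka_errs, kd_errs = [], []
    for i in range(n_seeds):
        sgs = [simulate_sensorgram(true, c * true.KD, t_assoc=300,
                                   t_dissoc=300,
                                   noise_sd=noise_frac * true.Rmax,
                                   seed=derive_seed(seed, 9, i, j))
               for j, c in enumerate(concs)]
        est, _ = fit_1to1(sgs)
        ka_errs.append(abs(est.ka - true.ka) / true.ka)
        kd_errs.append(abs(est.kd - true.kd) / true.kd)
    return {"max_rel_err_ka": float(max(ka_errs)),
            "max_rel_err_kd": float(max(kd_errs)),
            "mean_rel_err_ka": float(np.mean(ka_errs)),
            "mean_rel_err_kd": float(np.mean(kd_errs))}
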