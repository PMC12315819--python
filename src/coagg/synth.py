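"""Synthetic assay data with known ground truth.

Emulates the surface-based fluorescence distribution assay: sparse
diffraction-limited particles on a noisy camera background, imaged in a red
(alpha-synuclein) and a far-red (amylin) channel, where a controllable
fraction of red spots has a co-localized blue partner.  Also generates
standard dilution series, participant cohorts and 1:1-binding sensorgrams so
every downstream stage can be exercised without real data.

Image model
-----------
Spot counts per field are Poisson with separate rates for true pairs,
red-only and blue-only spots.  Centers follow a homogeneous spatial Poisson
process restricted to lie at least ``3 * psf_sigma_px`` from the border (so
no truncated spots bias detection checks); a paired blue center is its red
center displaced by isotropic Gaussian registration jitter.  Each spot is a
2-D Gaussian with log-normal peak amplitude.  The camera applies Poisson
shot noise to signal+background, adds Gaussian read noise, and quantizes to
16 bits with clipping.
"""

from __future__ import annotations

import numpy as np

from .kinetics import langmuir_response
from .types import (
    DualChannelField,
    GroundTruthField,
    KineticParams,
    ParameterError,
    Sensorgram,
    SynthFieldParams,
    SyntheticCohortParams,
)

__all__ = [
    "generate_field",
    "generate_dilution_series",
    "generate_cohort",
    "cohort_sample_summary",
    "simulate_sensorgram",
    "derive_seed",
]


def derive_seed(base_seed: int, *keys: int) -> int:
    """Deterministic child seed from a base seed and integer keys (< 2**31)."""
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Field generation
# ---------------------------------------------------------------------------

def _draw_centers(rng: np.random.Generator, n: int, w: int, h: int,
                  margin: float) -> np.ndarray:
    """Uniform centers inside the margin box (equivalent to redrawing any
    center that falls within ``margin`` of the border)."""
    lo_x, hi_x = margin, w - 1 - margin
    lo_y, hi_y = margin, h - 1 - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ParameterError("psf_sigma_px: border margin leaves no interior")
    xy = np.empty((n, 2))
    xy[:, 0] = rng.uniform(lo_x, hi_x, n)
    xy[:, 1] = rng.uniform(lo_y, hi_y, n)
    return xy


def _render(shape: tuple[int, int], centers: np.ndarray, amps: np.ndarray,
            sigma: float) -> np.ndarray:
    """Sum of 2-D Gaussian spots evaluated on local windows (+-5 sigma)."""
    h, w = shape
    img = np.zeros(shape, dtype=float)
    half = int(np.ceil(5 * sigma))
    for (cx, cy), a in zip(centers, amps):
        x0 = max(int(np.floor(cx)) - half, 0)
        x1 = min(int(np.ceil(cx)) + half + 1, w)
        y0 = max(int(np.floor(cy)) - half, 0)
        y1 = min(int(np.ceil(cy)) + half + 1, h)
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        img[y0:y1, x0:x1] += a * np.exp(
            -(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma ** 2))
    return img


def _camera(rng: np.random.Generator, signal: np.ndarray,
            p: SynthFieldParams) -> np.ndarray:
    img = signal + p.background_level
    if p.shot_noise:
        img = rng.poisson(img).astype(float)
    if p.read_noise_sd > 0:
        img = img + rng.normal(0.0, p.read_noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def generate_field(params: SynthFieldParams,
                   field_id: str = "field0",
                   well_id: str = "well0",
                   sample_id: str = "sample0",
                   ) -> tuple[DualChannelField, GroundTruthField]:
    """Simulate one dual-channel field and its ground truth.

    Identical ``params`` (including seed) yield bit-identical images.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    w, h = p.width_px, p.height_px
    margin = 3.0 * p.psf_sigma_px

    n_pair = rng.poisson(p.lambda_pair)
    n_red_only = rng.poisson(p.lambda_red_only)
    n_blue_only = rng.poisson(p.lambda_blue_only)

    pair_red = _draw_centers(rng, n_pair, w, h, margin)
    # blue partner = red center + isotropic jitter, redrawn until inside box
    pair_blue = np.empty_like(pair_red)
    lo = margin
    hi_x, hi_y = w - 1 - margin, h - 1 - margin
    for i in range(n_pair):
        while True:
            cand = pair_red[i] + rng.normal(0.0, p.registration_jitter_sd_px, 2)
            if lo <= cand[0] <= hi_x and lo <= cand[1] <= hi_y:
                pair_blue[i] = cand
                break
    red_only = _draw_centers(rng, n_red_only, w, h, margin)
    blue_only = _draw_centers(rng, n_blue_only, w, h, margin)

    red_centers = np.vstack([pair_red, red_only]) if (n_pair + n_red_only) else np.empty((0, 2))
    blue_centers = np.vstack([pair_blue, blue_only]) if (n_pair + n_blue_only) else np.empty((0, 2))

    (mu_r, mu_b) = p.amplitude_log_mean_rb
    (sd_r, sd_b) = p.amplitude_log_sd_rb
    amps_red = rng.lognormal(mu_r, sd_r, len(red_centers))
    amps_blue = rng.lognormal(mu_b, sd_b, len(blue_centers))

    red_img = _camera(rng, _render((h, w), red_centers, amps_red, p.psf_sigma_px), p)
    blue_img = _camera(rng, _render((h, w), blue_centers, amps_blue, p.psf_sigma_px), p)

    field = DualChannelField(
        red_image=red_img, blue_image=blue_img, pixel_size_um=p.pixel_size_um,
        field_id=field_id, well_id=well_id, sample_id=sample_id)
    truth = GroundTruthField(
        red_centers=[tuple(c) for c in red_centers],
        blue_centers=[tuple(c) for c in blue_centers],
        pair_index=[(i, i) for i in range(n_pair)])
    return field, truth


def generate_dilution_series(base: SynthFieldParams, fold: float = 5.0,
                             steps: int = 7,
                             ) -> list[tuple[DualChannelField, GroundTruthField]]:
    """Serial dilution: step k scales all three spot rates by fold**(-k).

    Mirrors the assay's validation design of a 5-fold serial dilution of the
    aggregate standard.  Per-step seeds derive deterministically from the
    base seed so series are reproducible yet internally independent.
    """
    if fold <= 1:
        raise ParameterError("fold: must be > 1")
    if steps < 2:
        raise ParameterError("steps: must be >= 2")
    out = []
    for k in range(steps):
        scale = fold ** (-k)
        pk = SynthFieldParams(
            **{**base.__dict__,
               "lambda_pair": base.lambda_pair * scale,
               "lambda_red_only": base.lambda_red_only * scale,
               "lambda_blue_only": base.lambda_blue_only * scale,
               "seed": derive_seed(base.seed, k)})
        out.append(generate_field(pk, field_id=f"dilution_step{k}"))
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _rank_coupled_covariate(rng: np.random.Generator, values: np.ndarray,
                            rho_s: float, loc: float, scale: float) -> np.ndarray:
    """Covariate with target Spearman correlation to ``values``.

    Gaussian copula: convert value ranks to normal scores z1, mix with
    independent noise at Pearson rho = 2*sin(pi*rho_s/6) (the bivariate-normal
    rank-correlation inverse), and map to a clinical-looking scale.
    """
    from scipy import stats

    n = len(values)
    # jitter breaks count ties so the copula ranks are well defined
    ranks = stats.rankdata(values + rng.uniform(-1e-9, 1e-9, n), method="ordinal")
    z1 = stats.norm.ppf((ranks - 0.5) / n)
    rho = 2.0 * np.sin(np.pi * rho_s / 6.0)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho ** 2)) * rng.standard_normal(n)
    return loc + scale * z2


def generate_cohort(params: SyntheticCohortParams):
    """Simulate a participant cohort as a tidy readout-level table.

    Per sample, a latent per-readout rate is Gamma(dispersion,
    mean/dispersion) so readout counts are negative-binomial marginally;
    each sample carries ``n_replicates`` x ``n_readouts`` field-level
    readouts.  One covariate is rank-coupled to the per-sample mean count.

    Returns a pandas DataFrame with columns sample_id, group, analyte,
    replicate, readout, coagg_count and the covariate (repeated per row).
    """
    import pandas as pd

    p = params
    rng = np.random.default_rng(p.seed)
    rows = []
    sample_means = []
    sample_ids = []
    for group, mean in p.group_means.items():
        asyn_mean = p.alpha_syn_mean_factor * mean
        for i in range(p.n_per_group):
            sid = f"{group}_{i:03d}"
            lam = rng.gamma(shape=p.dispersion, scale=mean / p.dispersion) if mean > 0 else 0.0
            lam_a = rng.gamma(shape=p.dispersion,
                              scale=asyn_mean / p.dispersion) if asyn_mean > 0 else 0.0
            counts = rng.poisson(lam, p.n_replicates * p.n_readouts)
            counts_a = rng.poisson(lam_a, p.n_replicates * p.n_readouts)
            k = 0
            for rep in range(p.n_replicates):
                for ro in range(p.n_readouts):
                    rows.append((sid, group, p.analyte, rep, ro,
                                 int(counts_a[k]), int(counts[k])))
                    k += 1
            sample_ids.append(sid)
            sample_means.append(counts.mean())
    df = pd.DataFrame(rows, columns=["sample_id", "group", "analyte",
                                     "replicate", "readout",
                                     "alpha_syn_count", "coagg_count"])
    cov = _rank_coupled_covariate(rng, np.asarray(sample_means),
                                  p.covariate_rank_corr, loc=5.8, scale=1.1)
    cov_map = dict(zip(sample_ids, cov))
    df[p.covariate_name] = df["sample_id"].map(cov_map)
    return df


def cohort_sample_summary(table, covariate: str | None = None):
    """Collapse a readout-level cohort table to one row per sample
    (mean count over all readouts), keeping group/analyte/covariate."""
    keep = ["sample_id", "group", "analyte"]
    if covariate is not None:
        keep.append(covariate)
    cols = [c for c in ("alpha_syn_count", "coagg_count") if c in table.columns]
    agg = table.groupby(keep, as_index=False)[cols].mean()
    return agg


# ---------------------------------------------------------------------------
# Sensorgrams
# ---------------------------------------------------------------------------

def simulate_sensorgram(kp: KineticParams, conc: float, t_assoc: float,
                        t_dissoc: float, noise_sd: float = 0.0,
                        seed: int = 0, dt: float = 1.0) -> Sensorgram:
    """Simulate a 1:1 Langmuir sensorgram at one analyte concentration.

    Association: R(t) = Req * (1 - exp(-(ka*C + kd) t)) with
    Req = Rmax * C / (C + KD); dissociation decays as exp(-kd (t - t_assoc))
    from the association end-point.  Gaussian noise of sd ``noise_sd`` (RU)
    is added when nonzero.
    """
    if conc <= 0:
        raise ParameterError("conc: must be positive")
    if t_assoc <= 0 or t_dissoc <= 0:
        raise ParameterError("t_assoc/t_dissoc: must be positive")
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    r = langmuir_response(t, conc, kp.ka, kp.kd, kp.Rmax, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, r.shape)
    return Sensorgram(t=t, response=r, conc=conc, t_assoc=t_assoc)
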