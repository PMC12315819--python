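"""Domain types shared across the pipeline.

Conventions
-----------
* Coordinates are 0-based with ``x`` = column index and ``y`` = row index,
  center-of-pixel; sub-pixel positions are floats.
* Images are single-channel 2-D arrays in 16-bit range (detection converts
  to 8-bit internally during enhancement).
* Counts-per-area normalization uses mm^2 computed from ``pixel_size_um``
  so acquisitions at different magnifications are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SynthFieldParams",
    "GroundTruthField",
    "SyntheticCohortParams",
    "DualChannelField",
    "Spot",
    "DetectConfig",
    "ColocMatch",
    "ColocSummary",
    "WellSummary",
    "StandardSeries",
    "QCVerdict",
    "RocResult",
    "CorrelationResult",
    "KineticParams",
    "Sensorgram",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a user-supplied parameter violates its documented domain."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{name}: {msg}")


def _as_pair(v) -> tuple[float, float]:
    """Accept a scalar (applied to both channels) or an explicit (red, blue) pair."""
    if np.isscalar(v):
        return float(v), float(v)
    a, b = v
    return float(a), float(b)


# ---------------------------------------------------------------------------
# Synthetic-data parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SynthFieldParams:
    """Parameters of one simulated dual-channel fluorescence field.

    Spots are diffraction-limited 2-D Gaussians of width ``psf_sigma_px``
    placed by a homogeneous spatial Poisson process; a fraction of spots are
    true red/blue pairs whose blue partner is displaced by isotropic Gaussian
    jitter of sd ``registration_jitter_sd_px``.  Peak amplitudes are
    log-normal per channel; the camera model is Poisson shot noise on
    signal+background followed by Gaussian read noise and 16-bit quantization.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.108
    lambda_pair: float = 30.0
    lambda_red_only: float = 20.0
    lambda_blue_only: float = 20.0
    psf_sigma_px: float = 1.5
    # log-normal peak amplitude; scalar applies to both channels, or (red, blue)
    amplitude_log_mean: float | tuple[float, float] = float(np.log(180.0))
    amplitude_log_sd: float | tuple[float, float] = 0.2
    background_level: float = 200.0
    read_noise_sd: float = 10.0
    shot_noise: bool = True
    registration_jitter_sd_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.width_px >= 32 and self.height_px >= 32,
               "width_px/height_px", "image must be at least 32x32")
        _check(self.pixel_size_um > 0, "pixel_size_um", "must be positive")
        for nm in ("lambda_pair", "lambda_red_only", "lambda_blue_only"):
            _check(getattr(self, nm) >= 0, nm, "rate must be >= 0")
        _check(self.psf_sigma_px > 0, "psf_sigma_px", "must be positive")
        _check(self.background_level >= 0, "background_level", "must be >= 0")
        _check(self.read_noise_sd >= 0, "read_noise_sd", "must be >= 0")
        _check(self.registration_jitter_sd_px >= 0,
               "registration_jitter_sd_px", "must be >= 0")

    @property
    def amplitude_log_mean_rb(self) -> tuple[float, float]:
        return _as_pair(self.amplitude_log_mean)

    @property
    def amplitude_log_sd_rb(self) -> tuple[float, float]:
        return _as_pair(self.amplitude_log_sd)


@dataclass
class GroundTruthField:
    """True spot positions and pairing of one simulated field."""

    red_centers: list[tuple[float, float]]
    blue_centers: list[tuple[float, float]]
    pair_index: list[tuple[int, int]]

    def __post_init__(self) -> None:
        r = [i for i, _ in self.pair_index]
        b = [j for _, j in self.pair_index]
        if len(set(r)) != len(r) or len(set(b)) != len(b):
            raise ValueError("pair_index must be one-to-one")
        if r and (max(r) >= len(self.red_centers) or max(b) >= len(self.blue_centers)):
            raise ValueError("pair_index out of range")

    @property
    def coloc_fraction(self) -> float:
        """True co-aggregate fraction of red spots: |pairs| / |red|, 0 if no red."""
        if not self.red_centers:
            return 0.0
        return len(self.pair_index) / len(self.red_centers)


@dataclass
class SyntheticCohortParams:
    """Design of a synthetic participant cohort.

    ``group_means`` maps a group label (e.g. HC, PD) to the expected
    per-readout co-aggregate count; per-sample counts are negative-binomial
    (gamma-mixed Poisson) with overdispersion ``dispersion``.  A clinical-style
    covariate (HbA1c-like) is generated with Spearman rank correlation
    ``covariate_rank_corr`` to the per-sample count via a Gaussian copula.
    """

    n_per_group: int = 20
    group_means: dict[str, float] = field(default_factory=lambda: {"HC": 5.0, "PD": 15.0})
    dispersion: float = 2.0
    covariate_rank_corr: float = 0.0
    analyte: str = "L1EV"
    # alpha-syn aggregates outnumber co-aggregates; their mean scales with it
    alpha_syn_mean_factor: float = 2.0
    n_replicates: int = 2
    n_readouts: int = 6
    covariate_name: str = "HbA1c_pct"
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_per_group >= 2, "n_per_group", "must be >= 2")
        _check(self.dispersion > 0, "dispersion", "must be > 0")
        _check(abs(self.covariate_rank_corr) <= 1,
               "covariate_rank_corr", "must lie in [-1, 1]")
        _check(self.n_replicates >= 1 and self.n_readouts >= 1,
               "n_replicates/n_readouts", "must be >= 1")


# ---------------------------------------------------------------------------
# Imaging
# ---------------------------------------------------------------------------

@dataclass
class DualChannelField:
    """One imaged field: red (alpha-synuclein) and blue/far-red (amylin) frames.

    The two frames share a stage position; exposure differs per channel
    (0.5 s TRITC vs 2 s Cy7 in the reference acquisition), which is why no
    cross-channel intensity comparison is ever made downstream.
    """

    red_image: np.ndarray
    blue_image: np.ndarray
    pixel_size_um: float
    exposure_red_s: float = 0.5
    exposure_blue_s: float = 2.0
    field_id: str = "field0"
    well_id: str = "well0"
    sample_id: str = "sample0"

    def __post_init__(self) -> None:
        self.red_image = np.asarray(self.red_image)
        self.blue_image = np.asarray(self.blue_image)
        if self.red_image.shape != self.blue_image.shape:
            raise ValueError(
                f"channel shape mismatch: red {self.red_image.shape} vs "
                f"blue {self.blue_image.shape}")
        if self.red_image.ndim != 2:
            raise ValueError("images must be 2-D single-channel arrays")
        _check(self.pixel_size_um > 0, "pixel_size_um", "must be positive")

    @property
    def area_mm2(self) -> float:
        h, w = self.red_image.shape
        return h * w * (self.pixel_size_um * 1e-3) ** 2


@dataclass
class Spot:
    """One detected fluorescent particle."""

    x_px: float
    y_px: float
    radius_px: float
    mean_intensity: float
    method: str  # contour | hough | merged
    channel: str = ""  # red | blue | ""

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")


@dataclass
class DetectConfig:
    """Free parameters of the detection stage (none are fixed by the assay)."""

    equalization: str = "global"          # global | clahe
    threshold_method: str = "otsu"        # otsu | fixed
    fixed_threshold: float | None = None
    min_area_px: int = 4
    max_area_px: int = 400
    min_circularity: float = 0.5
    hough_r_min_px: int = 2
    hough_r_max_px: int = 10
    hough_vote_threshold: float = 0.55
    merge_dist_px: float = 3.0
    smooth_sigma_px: float = 1.5          # matched filter width for bandpass
    noise_floor_k: float = 5.0            # robust noise floor, in MADs

    def __post_init__(self) -> None:
        _check(self.min_area_px < self.max_area_px,
               "min_area_px", "must be < max_area_px")
        _check(self.hough_r_min_px < self.hough_r_max_px,
               "hough_r_min_px", "must be < hough_r_max_px")
        _check(0 < self.min_circularity <= 1,
               "min_circularity", "must lie in (0, 1]")
        _check(self.merge_dist_px > 0, "merge_dist_px", "must be positive")
        if self.equalization not in ("global", "clahe"):
            raise ParameterError(f"equalization: unknown method {self.equalization!r}")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ParameterError(f"threshold_method: unknown method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ParameterError("fixed_threshold: required when threshold_method='fixed'")


# ---------------------------------------------------------------------------
# Co-localization
# ---------------------------------------------------------------------------

@dataclass
class ColocMatch:
    """One-to-one red/blue pairing at matching radius ``d_max_px``."""

    pairs: list[tuple[int, int, float]]   # (red_index, blue_index, distance_px)
    d_max_px: float

    def __post_init__(self) -> None:
        r = [p[0] for p in self.pairs]
        b = [p[1] for p in self.pairs]
        if len(set(r)) != len(r) or len(set(b)) != len(b):
            raise ValueError("matching must be one-to-one")
        if any(d > self.d_max_px + 1e-9 for *_, d in self.pairs):
            raise ValueError("pair distance exceeds d_max_px")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class ColocSummary:
    """Per-field co-aggregate counts with the chance-overlap correction."""

    n_red: int
    n_blue: int
    n_coloc: int
    expected_chance: float
    field_area_mm2: float
    corrected_count: float = field(init=False)
    coloc_rate: float = field(init=False)
    field_id: str = "field0"

    def __post_init__(self) -> None:
        if self.n_coloc > min(self.n_red, self.n_blue):
            raise ValueError("n_coloc cannot exceed min(n_red, n_blue)")
        _check(self.field_area_mm2 > 0, "field_area_mm2", "must be positive")
        _check(self.expected_chance >= 0, "expected_chance", "must be >= 0")
        self.corrected_count = max(0.0, self.n_coloc - self.expected_chance)
        self.coloc_rate = self.n_coloc / self.n_red if self.n_red > 0 else 0.0


# ---------------------------------------------------------------------------
# Assay QC
# ---------------------------------------------------------------------------

@dataclass
class WellSummary:
    """Field counts aggregated to one well, normalized to densities per mm^2."""

    well_id: str
    sample_id: str
    n_fields: int
    total_red: int
    total_blue: int
    total_coloc: int
    total_corrected: float
    total_area_mm2: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        _check(self.n_fields >= 1, "n_fields", "must be >= 1")
        _check(self.total_area_mm2 > 0, "total_area_mm2", "must be positive")
        _check(self.dilution_factor > 0, "dilution_factor", "must be positive")

    @property
    def density_red(self) -> float:
        return self.total_red / self.total_area_mm2

    @property
    def density_blue(self) -> float:
        return self.total_blue / self.total_area_mm2

    @property
    def density_coloc(self) -> float:
        return self.total_coloc / self.total_area_mm2

    @property
    def density_corrected(self) -> float:
        return self.total_corrected / self.total_area_mm2


@dataclass
class StandardSeries:
    """A standard dilution curve (descending concentrations) with blanks."""

    concentrations: Sequence[float]       # ug/mL, strictly decreasing
    red_counts: Sequence[float]
    blue_counts: Sequence[float]
    standard_type: str                    # alpha_syn_only | coaggregate
    blank_red: float | None = None
    blank_blue: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if len(c) != len(self.red_counts) or len(c) != len(self.blue_counts):
            raise ValueError("concentrations and counts must have equal length")
        if not np.all(np.diff(c) < 0):
            raise ValueError("concentrations must be strictly decreasing")
        if self.standard_type not in ("alpha_syn_only", "coaggregate"):
            raise ParameterError(f"standard_type: unknown {self.standard_type!r}")


@dataclass
class QCVerdict:
    """Batch pass/fail decision with labeled failure reasons."""

    passed: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to an empty reason list")


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

GROUPS = ("HC", "PD", "MSA")
ANALYTES = ("serum_free", "L1EV")


@dataclass
class CohortRecord:
    """One participant-sample row: per-sample aggregate counts with group,
    analyte type and optional clinical covariates (UPDRS_III, HbA1c_pct,
    FPG, MoCA, MMSE, ADL, HAMA, HAMD)."""

    sample_id: str
    group: str                       # HC | PD | MSA
    analyte: str                     # serum_free | L1EV
    alpha_syn_count: float
    coagg_count: float
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ParameterError(f"group: must be one of {GROUPS}")
        if self.analyte not in ANALYTES:
            raise ParameterError(f"analyte: must be one of {ANALYTES}")
        _check(self.alpha_syn_count >= 0, "alpha_syn_count", "must be >= 0")
        _check(self.coagg_count >= 0, "coagg_count", "must be >= 0")


@dataclass
class RocResult:
    """AUC with a stratified percentile-bootstrap confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")
        if not (self.ci_low <= self.auc + 1e-12 and self.auc <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("r must lie in [-1, 1]")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

@dataclass
class KineticParams:
    """1:1 Langmuir binding parameters; KD = kd/ka is an enforced identity."""

    ka: float          # association rate, 1/(M*s)
    kd: float          # dissociation rate, 1/s
    Rmax: float = 100.0  # maximal response, RU
    KD: float = field(init=False)

    def __post_init__(self) -> None:
        _check(self.ka > 0, "ka", "must be positive")
        _check(self.kd >= 0, "kd", "must be >= 0")
        _check(self.Rmax > 0, "Rmax", "must be positive")
        self.KD = self.kd / self.ka


@dataclass
class Sensorgram:
    """One SPR trace: association up to ``t_assoc`` then dissociation."""

    t: np.ndarray          # seconds, strictly increasing
    response: np.ndarray   # RU
    conc: float            # molar analyte concentration
    t_assoc: float         # seconds, association/dissociation boundary

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.t.shape != self.response.shape:
            raise ValueError("t and response must have the same length")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        _check(self.conc > 0, "conc", "must be positive")
        _check(self.t_assoc > 0, "t_assoc", "must be positive")
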