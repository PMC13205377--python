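"""Synthetic genotype-phenotype-depth-video cohorts for the TME analysis.

This module generates everything the downstream pipeline consumes, with the
statistical structure the analysis assumes:

* independent biallelic SNPs coded 0/1/2 with uniform allele frequencies;
* an additive body-weight (BW) trait with a configurable number of QTL,
  heritability, fixed effects (sex, birth farm, pen density, age, parity of
  dam), and a Gaussian residual;
* a ventral-clearance trait (ground-to-ventral-abdomen gap) with its own,
  disjoint QTL set and its own heritability — the hypothesized channel
  through which trait measurement error could become genetic;
* top-view depth videos of an allometric half-ellipsoid "pig" standing
  ``clearance`` above the floor, seen by a camera 1.40 m overhead, emitted
  as per-frame distance maps (meters) plus pseudo-color images whose hue is
  a fixed invertible linear function of distance;
* a fast "feature space" mode that emits the biometric features the image
  pipeline would measure, computed from the same closed-form geometry the
  renderer uses, so large cohorts do not require per-pixel rendering.

All randomness flows from a single integer seed through
``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import color as _skcolor

__all__ = [
    "SimConfig",
    "FixedEffectSpec",
    "GenotypeMatrix",
    "TraitArchitecture",
    "PigShape",
    "DepthFrame",
    "DepthVideo",
    "TIME_POINT_MEAN_BW",
    "simulate_genotypes",
    "simulate_covariates",
    "design_matrix",
    "simulate_trait",
    "simulate_clearance",
    "shape_from_weight",
    "render_depth_frame",
    "render_depth_video",
    "analytic_features",
    "simulate_features",
    "distance_to_hue",
    "hue_to_distance",
    "encode_color",
    "decode_distance",
]

#: cohort mean scale BW (kg) at each of the four farm visits
TIME_POINT_MEAN_BW = {"T1": 65.0, "T2": 78.0, "T3": 92.0, "T4": 114.0}

#: camera horizontal / vertical field of view, degrees (stereo depth head)
HFOV_DEG = 87.0
VFOV_DEG = 58.0

#: hue (degrees) assigned to the floor plane; hue is linear in distance,
#: 0 deg at the camera and HUE_FLOOR_DEG at ``camera_height``
HUE_FLOOR_DEG = 240.0

#: per-frame head / tail protrusion extents as fractions of body length,
#: drawn uniformly from these ranges by the renderer; the analytic feature
#: mode uses the range midpoints as the expected extents
HEAD_EXT_RANGE = (0.05, 0.12)
TAIL_EXT_RANGE = (0.03, 0.08)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class RenderError(ValueError):
    """Shape cannot be rendered inside the requested frame."""


@dataclass
class FixedEffectSpec:
    """Magnitudes (kg) of the simulated fixed effects on scale BW.

    Effects are applied as deviations from the cohort mean (each covariate
    contribution is centered), so ``mean_bw`` stays the cohort mean.  The
    defaults are small relative to the phenotypic SD.
    """

    sex: float = 2.0  # barrow vs gilt contrast
    birth_farm: float = 1.5  # SD of per-farm shifts, 3 farms
    pen_density: float = -0.8  # kg per animal-per-pen deviation
    age: float = 0.8  # kg per day of within-visit age spread
    parity: float = 0.5  # kg per unit parity of dam


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    Genetic architecture, camera geometry and image size all live here so a
    single object reproduces the whole experiment.  ``seed`` is mandatory.
    """

    seed: int
    n_individuals: int = 800
    n_markers: int = 10_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_qtl: int = 10
    h2_bw: float = 0.4
    h2_clearance: float = 0.0
    # commercial cohorts are sired batches: half-sib families of n/n_sires
    # offspring give the genomic relationship matrix the contrast it needs
    # for usefully tight REML estimates; None simulates unrelated animals
    n_sires: int | None = 25
    mean_bw: float = TIME_POINT_MEAN_BW["T2"]
    sd_bw: float = 12.0
    fixed_effects: FixedEffectSpec = field(default_factory=FixedEffectSpec)
    camera_height: float = 1.40
    image_shape: tuple[int, int] = (180, 320)  # rows, cols
    n_frames: int = 20
    # ventral clearance (meters): baseline gap plus genetic + environmental
    # variation; clearance QTL are drawn from the low-frequency end of the
    # panel so the genetic part is carrier-like and right-skewed
    clearance_baseline: float = 0.17
    sd_clearance: float = 0.02
    n_qtl_clearance: int = 1
    clearance_qtl_maf_max: float = 0.06
    # allometry: linear body dimensions = coef * BW^(1/3), meters per kg^(1/3)
    allometry_length: float = 0.28
    allometry_width: float = 0.082
    allometry_height: float = 0.075
    # between-animal conformation scatter: lognormal SD of the length and
    # width coefficients, compensated in height so body volume stays
    # proportional to mass (longer-leaner vs shorter-rounder animals)
    shape_sd: float = 0.025
    # segmentation-facing defaults shared with the feature-space mode
    trim_ratio: float = 1.0
    # per-feature multiplicative measurement noise SD in feature-space mode
    feature_noise: float = 0.01
    # renderer nuisance parameters
    jitter_px: float = 2.0
    jitter_deg: float = 2.0
    head_tail: bool = True
    dropout_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigError(
                f"need 0 < maf_low <= maf_high <= 0.5, got ({self.maf_low}, {self.maf_high})"
            )
        if self.n_qtl > self.n_markers:
            raise ConfigError("n_qtl exceeds n_markers")
        for name in ("h2_bw", "h2_clearance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.camera_height <= 0:
            raise ConfigError("camera_height must be positive")
        if self.h2_bw == 1.0 and self.sd_bw == 0.0:
            raise ConfigError("h2_bw = 1 with sd_bw = 0 is degenerate")

    @property
    def px_per_m(self) -> float:
        """Orthographic pixels-per-meter at the floor plane.

        Derived from the horizontal field of view projected onto the floor;
        the same scale is used on both image axes (no intrinsics model).
        """
        width_m = 2.0 * self.camera_height * np.tan(np.deg2rad(HFOV_DEG / 2.0))
        return self.image_shape[1] / width_m


@dataclass
class GenotypeMatrix:
    """n x m additive SNP codes in {0, 1, 2}."""

    codes: np.ndarray
    animal_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ConfigError("duplicate animal ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ConfigError("duplicate marker ids")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Observed allele frequency per marker (column mean / 2)."""
        return self.codes.mean(axis=0) / 2.0


@dataclass
class TraitArchitecture:
    """True genetic architecture of a simulated trait (simulation-only truth)."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    breeding_values: np.ndarray


@dataclass
class PigShape:
    """Body envelope of one animal: half-ellipsoid torso above a ground gap."""

    body_length: float
    body_width: float
    body_height: float
    clearance: float

    def __post_init__(self) -> None:
        if min(self.body_length, self.body_width, self.body_height) <= 0:
            raise ConfigError("body dimensions must be positive")
        if self.clearance < 0:
            raise ConfigError("clearance must be non-negative")


@dataclass
class DepthFrame:
    """One frame: distance map in meters plus its pseudo-color rendering."""

    distance_map: np.ndarray
    color_image: np.ndarray
    frame_index: int = 0


@dataclass
class DepthVideo:
    frames: list[DepthFrame]

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# hue <-> distance pseudo-color codec


def distance_to_hue(distance, camera_height: float = 1.40):
    """Hue in degrees, linear in distance: 0 at the camera, 240 at the floor."""
    return HUE_FLOOR_DEG * np.asarray(distance, dtype=np.float64) / camera_height


def hue_to_distance(hue_deg, camera_height: float = 1.40):
    """Inverse of :func:`distance_to_hue`."""
    return np.asarray(hue_deg, dtype=np.float64) * camera_height / HUE_FLOOR_DEG


def encode_color(distance_map: np.ndarray, camera_height: float = 1.40) -> np.ndarray:
    """Render a distance map as a saturated uint8 RGB pseudo-color image."""
    hue = distance_to_hue(distance_map, camera_height) / 360.0
    hsv = np.stack([hue, np.ones_like(hue), np.ones_like(hue)], axis=-1)
    rgb = _skcolor.hsv2rgb(hsv)
    return np.round(rgb * 255.0).astype(np.uint8)


def decode_distance(color_image: np.ndarray, camera_height: float = 1.40) -> np.ndarray:
    """Recover distances from a pseudo-color image via the hue channel."""
    hsv = _skcolor.rgb2hsv(color_image.astype(np.float64) / 255.0)
    return hue_to_distance(hsv[..., 0] * 360.0, camera_height)


# ---------------------------------------------------------------------------
# genotypes, covariates, traits


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw unlinked SNPs with p_j ~ U(maf_low, maf_high).

    With ``n_sires = None`` every animal is an independent Binomial(2, p_j)
    draw (an unrelated population).  With ``n_sires`` set — the default, and
    the structure of a commercial finishing batch — sires are drawn from
    Hardy-Weinberg proportions and each offspring receives one gamete from
    its (round-robin assigned) sire and one from the dam population, giving
    paternal half-sib families with relatedness 1/4 and unchanged marginal
    allele frequencies.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_individuals, config.n_markers
    p = rng.uniform(config.maf_low, config.maf_high, size=m)
    if config.n_sires is None:
        codes = rng.binomial(2, p[None, :], size=(n, m)).astype(np.int8)
    else:
        s = int(config.n_sires)
        if s < 1:
            raise ConfigError("n_sires must be positive or None")
        sires = rng.binomial(2, p[None, :], size=(s, m))
        assign = np.arange(n) % s
        sire_gamete = rng.binomial(1, sires[assign] / 2.0)
        dam_gamete = rng.binomial(1, p[None, :], size=(n, m))
        codes = (sire_gamete + dam_gamete).astype(np.int8)
    animal_ids = [f"pig{i:05d}" for i in range(n)]
    marker_ids = [f"snp{j:06d}" for j in range(m)]
    return GenotypeMatrix(codes=codes, animal_ids=animal_ids, marker_ids=marker_ids)


def simulate_covariates(
    config: SimConfig,
    rng: np.random.Generator,
    time_point: str = "T2",
    mean_age: float | None = None,
) -> pd.DataFrame:
    """Per-animal covariates: sex, birth farm, pen density, age, parity of dam."""
    n = config.n_individuals
    ages = {"T1": 103.0, "T2": 117.0, "T3": 131.0, "T4": 159.0}
    mu_age = ages.get(time_point, 117.0) if mean_age is None else mean_age
    return pd.DataFrame(
        {
            "animal_id": [f"pig{i:05d}" for i in range(n)],
            "time_point": time_point,
            "sex": rng.choice(["barrow", "gilt"], size=n),
            "birth_farm": rng.choice(["F1", "F2", "F3"], size=n),
            "pen_density": rng.integers(18, 25, size=n).astype(float),
            "age": np.round(rng.normal(mu_age, 3.0, size=n)),
            "parity": rng.integers(1, 6, size=n).astype(float),
        }
    )


def design_matrix(covars: pd.DataFrame, add_intercept: bool = True) -> np.ndarray:
    """Fixed-effect design: intercept, sex and farm dummies, numeric covariates."""
    cols = [
        (covars["sex"] == "gilt").to_numpy(float),
        (covars["birth_farm"] == "F2").to_numpy(float),
        (covars["birth_farm"] == "F3").to_numpy(float),
        covars["pen_density"].to_numpy(float),
        covars["age"].to_numpy(float),
        covars["parity"].to_numpy(float),
    ]
    X = np.column_stack(cols)
    if add_intercept:
        X = np.column_stack([np.ones(len(covars)), X])
    return X


def _fixed_effect_values(covars: pd.DataFrame, spec: FixedEffectSpec, rng: np.random.Generator) -> np.ndarray:
    """Centered fixed-effect contribution Xb (kg)."""
    farm_shift = {"F1": 0.0, "F2": spec.birth_farm, "F3": -spec.birth_farm}
    xb = (
        np.where(covars["sex"] == "gilt", -spec.sex / 2.0, spec.sex / 2.0)
        + covars["birth_farm"].map(farm_shift).to_numpy(float)
        + spec.pen_density * (covars["pen_density"] - covars["pen_density"].mean()).to_numpy(float)
        + spec.age * (covars["age"] - covars["age"].mean()).to_numpy(float)
        + spec.parity * (covars["parity"] - covars["parity"].mean()).to_numpy(float)
    )
    return xb - xb.mean()


def _scaled_genetic_values(
    geno: GenotypeMatrix,
    qtl_indices: np.ndarray,
    raw_effects: np.ndarray,
    target_var: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale QTL effects so the realized genetic variance equals target_var."""
    Wq = geno.codes[:, qtl_indices].astype(np.float64)
    Wq -= Wq.mean(axis=0)
    g = Wq @ raw_effects
    v = g.var()
    if v == 0.0:
        return np.zeros(geno.n), raw_effects * 0.0
    c = np.sqrt(target_var / v)
    return g * c, raw_effects * c


def simulate_trait(
    geno: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    time_point: str = "T2",
    mean_bw: float | None = None,
) -> tuple[TraitArchitecture, pd.DataFrame]:
    """Simulate scale BW: mean + fixed effects + additive QTL values + residual.

    QTL are sampled without replacement; per-QTL effects have equal expected
    variance contribution and random sign, then are rescaled so the realized
    breeding-value variance is exactly ``h2_bw * sd_bw**2``.  The residual is
    N(0, (1 - h2_bw) sd_bw**2).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.n_qtl > geno.m:
        raise ConfigError("n_qtl exceeds number of markers")
    mu = config.mean_bw if mean_bw is None else mean_bw
    covars = simulate_covariates(config, rng, time_point=time_point)
    xb = _fixed_effect_values(covars, config.fixed_effects, rng)

    qtl = rng.choice(geno.m, size=config.n_qtl, replace=False)
    p = geno.allele_freq[qtl]
    # equal variance per QTL: |effect| ~ 1/sqrt(2 p (1-p)), random sign
    raw = rng.choice([-1.0, 1.0], size=config.n_qtl) / np.sqrt(
        np.maximum(2.0 * p * (1.0 - p), 1e-12)
    )
    target = config.h2_bw * config.sd_bw**2
    if target == 0.0:
        bv = np.zeros(geno.n)
        eff = raw * 0.0
    else:
        bv, eff = _scaled_genetic_values(geno, qtl, raw, target)
    resid = rng.normal(0.0, np.sqrt((1.0 - config.h2_bw)) * config.sd_bw, size=geno.n)
    scale_bw = mu + xb + bv + resid
    arch = TraitArchitecture(qtl_indices=qtl, qtl_effects=eff, breeding_values=bv)
    pheno = covars.copy()
    pheno["scale_bw"] = scale_bw
    pheno["true_bv"] = bv
    if (pheno["scale_bw"] <= 0).any():
        raise ConfigError("simulated scale BW not positive; check mean/sd settings")
    return arch, pheno


def simulate_clearance(
    geno: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    exclude_qtl: np.ndarray | None = None,
) -> tuple[TraitArchitecture, np.ndarray]:
    """Simulate ventral clearance (m) with heritability ``h2_clearance``.

    Clearance QTL are chosen disjoint from the BW QTL (``exclude_qtl``) and,
    by default, from markers in the low-frequency tail of the panel with
    uniformly positive effects: a small number of "clearance-raising"
    variants segregating at low frequency, so carriers sit in the upper
    tail.  The trait is baseline + genetic + environment, truncated at 0.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = geno.n
    base = np.full(n, config.clearance_baseline)
    var_g = config.h2_clearance * config.sd_clearance**2
    var_e = (1.0 - config.h2_clearance) * config.sd_clearance**2

    excluded = set() if exclude_qtl is None else set(np.asarray(exclude_qtl).tolist())
    p = geno.allele_freq
    # The counted allele itself must be rare so that "carrier" animals sit in
    # the upper clearance tail; folded MAF would let the common allele carry
    # the positive effect and flip the skew.  The lower bound keeps the
    # causal variant above the downstream MAF filter (both use the observed
    # frequency of the same matrix), since with independent markers a
    # filtered causal variant is invisible to the GRM.
    pool = np.array(
        [
            j
            for j in range(geno.m)
            if j not in excluded
            and config.maf_low <= p[j] <= config.clearance_qtl_maf_max
        ]
    )
    if pool.size < config.n_qtl_clearance:
        pool = np.array([j for j in range(geno.m) if j not in excluded])
    k = config.n_qtl_clearance
    if var_g > 0.0 and k > 0:
        qtl = rng.choice(pool, size=k, replace=False)
        raw = np.ones(k)  # all effects increase clearance
        g, eff = _scaled_genetic_values(geno, qtl, raw, var_g)
    else:
        qtl = np.array([], dtype=int)
        eff = np.array([])
        g = np.zeros(n)
    e = rng.normal(0.0, np.sqrt(var_e), size=n) if var_e > 0 else np.zeros(n)
    clearance = np.maximum(base + g + e, 0.0)
    arch = TraitArchitecture(qtl_indices=qtl, qtl_effects=eff, breeding_values=g)
    return arch, clearance


# ---------------------------------------------------------------------------
# geometry: weight -> shape -> depth frames / analytic features


def shape_from_weight(
    bw: float,
    config: SimConfig | None = None,
    clearance: float = 0.0,
    allometry: tuple[float, float, float] | None = None,
    shape_dev: tuple[float, float] = (0.0, 0.0),
) -> PigShape:
    """Allometric body envelope: each linear dimension scales as BW^(1/3).

    ``shape_dev = (d_length, d_width)`` applies an animal's conformation
    deviation: length and width are scaled by exp(d), and height by
    exp(-d_length - d_width) so length*width*height — and hence body volume
    — remains a fixed function of BW.
    """
    if bw <= 0:
        raise ConfigError(f"body weight must be positive, got {bw}")
    if allometry is None:
        cfg = config if config is not None else SimConfig(seed=0)
        allometry = (cfg.allometry_length, cfg.allometry_width, cfg.allometry_height)
    cl, cw, ch = allometry
    dl, dw = shape_dev
    s = bw ** (1.0 / 3.0)
    return PigShape(
        body_length=cl * s * np.exp(dl),
        body_width=cw * s * np.exp(dw),
        body_height=ch * s * np.exp(-dl - dw),
        clearance=clearance,
    )


def _pig_height_field(
    shape: PigShape,
    config: SimConfig,
    center_rc: tuple[float, float],
    angle_rad: float,
    head_tail: tuple[float, float] | None,
) -> np.ndarray:
    """Per-pixel body height z(r, c) in meters (0 outside the animal).

    The torso is the upper half of an ellipsoid with semi-axes
    (length/2, width/2, body_height); optional head/tail protrusions are
    smaller half-ellipsoids attached beyond the long-axis ends.
    """
    rows, cols = config.image_shape
    ppm = config.px_per_m
    r = np.arange(rows, dtype=np.float64)[:, None] - center_rc[0]
    c = np.arange(cols, dtype=np.float64)[None, :] - center_rc[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    # long axis along +x (columns when angle = 0), in meters
    x = (c * ca + r * sa) / ppm
    ymat = (-c * sa + r * ca) / ppm
    a, b, h = shape.body_length / 2.0, shape.body_width / 2.0, shape.body_height
    q = 1.0 - (x / a) ** 2 - (ymat / b) ** 2
    z = h * np.sqrt(np.clip(q, 0.0, None))
    if head_tail is not None:
        for sign, ext in ((1.0, head_tail[0]), (-1.0, head_tail[1])):
            if ext <= 0:
                continue
            xa = x - sign * a  # protrusion centered at the body end
            qa = 1.0 - (xa / ext) ** 2 - (ymat / (0.45 * b)) ** 2
            za = 0.5 * h * np.sqrt(np.clip(qa, 0.0, None))
            z = np.maximum(z, np.where(x * sign > 0, za, 0.0))
    return z


def render_depth_frame(
    shape: PigShape | None,
    config: SimConfig,
    rng: np.random.Generator,
    frame_index: int = 0,
) -> DepthFrame:
    """Render one top-view frame with pose jitter and optional depth dropout.

    ``shape=None`` renders the empty scene: every pixel at the floor plane.
    """
    rows, cols = config.image_shape
    if shape is None:
        dist = np.full((rows, cols), config.camera_height, dtype=np.float64)
        return DepthFrame(
            distance_map=dist,
            color_image=encode_color(dist, config.camera_height),
            frame_index=frame_index,
        )
    ppm = config.px_per_m
    half_len_px = (shape.body_length / 2.0) * ppm
    half_wid_px = (shape.body_width / 2.0) * ppm
    margin = 8.0 + config.jitter_px  # keep the box clear of the border rule
    if half_len_px + margin > cols / 2.0 or half_wid_px + margin > rows / 2.0:
        raise RenderError(
            f"shape {shape.body_length:.2f}x{shape.body_width:.2f} m does not fit "
            f"a {rows}x{cols} frame at {ppm:.1f} px/m"
        )
    center = (
        rows / 2.0 + rng.normal(0.0, config.jitter_px),
        cols / 2.0 + rng.normal(0.0, config.jitter_px),
    )
    angle = np.deg2rad(rng.normal(0.0, config.jitter_deg))
    ht = None
    if config.head_tail:
        ht = (
            float(rng.uniform(*HEAD_EXT_RANGE) * shape.body_length),
            float(rng.uniform(*TAIL_EXT_RANGE) * shape.body_length),
        )
    z = _pig_height_field(shape, config, center, angle, ht)
    dist = np.full((rows, cols), config.camera_height, dtype=np.float64)
    on = z > 0
    dist[on] = config.camera_height - (shape.clearance + z[on])
    if config.dropout_rate > 0:
        drop = rng.random((rows, cols)) < config.dropout_rate
        dist[drop] = 0.0
    return DepthFrame(
        distance_map=dist,
        color_image=encode_color(dist, config.camera_height),
        frame_index=frame_index,
    )


def render_depth_video(
    shape: PigShape, config: SimConfig, seed: int | np.random.Generator
) -> DepthVideo:
    """Render ``config.n_frames`` jittered frames of one animal."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = [
        render_depth_frame(shape, config, rng, frame_index=i)
        for i in range(config.n_frames)
    ]
    return DepthVideo(frames=frames)


# ---------------------------------------------------------------------------
# feature-space mode: closed-form biometric features of the rendered body


def _ellipse_band_integrals(t0: float, t1: float, npts: int = 513) -> tuple[float, float]:
    """Integrals over the kept torso band t in [t0, t1] (units of semi-length).

    Returns (footprint area / (a*b), mean relative torso height), where the
    half-chord profile is rho(t) = sqrt(1 - t^2) and the half-ellipsoid
    cross-section at fixed t has mean height (pi/4) * rho(t) * body_height.
    """
    t = np.linspace(max(t0, -1.0), min(t1, 1.0), npts)
    rho = np.sqrt(np.clip(1.0 - t**2, 0.0, None))
    area = 2.0 * float(np.trapezoid(rho, t))
    mean_h = (np.pi / 4.0) * float(np.trapezoid(rho**2, t)) / max(
        float(np.trapezoid(rho, t)), 1e-12
    )
    return area, mean_h


def analytic_features(shape: PigShape, config: SimConfig) -> dict[str, float]:
    """Expected biometric features implied by the rendered geometry.

    Mirrors what the segmentation stage measures on a clean frame: the box
    of the head/tail-trimmed footprint (pixels), the mean of
    ``camera_height - distance`` over the kept pixels (meters; this includes
    the ventral clearance), and the per-pixel sum of the same quantity.
    Head/tail protrusions enter at their expected extents, since trimming
    operates on the protrusion-extended long-axis extent.
    """
    ppm = config.px_per_m
    L, W, a = shape.body_length, shape.body_width, shape.body_length / 2.0
    eh = float(np.mean(HEAD_EXT_RANGE)) * L if config.head_tail else 0.0
    et = float(np.mean(TAIL_EXT_RANGE)) * L if config.head_tail else 0.0
    ext = L + eh + et
    f = min(config.trim_ratio * W / ext, 0.25)
    cut = f * ext
    x_hi = min(a + eh - cut, a)  # kept band in torso coordinates
    x_lo = max(-a - et + cut, -a)
    if x_hi <= x_lo:
        raise ConfigError("trim removes the whole torso in analytic mode")
    area_rel, mean_h_rel = _ellipse_band_integrals(x_lo / a, x_hi / a)
    area_px = area_rel * a * (W / 2.0) * ppm**2
    height = shape.clearance + mean_h_rel * shape.body_height
    return {
        "dorsal_length": (x_hi - x_lo) * ppm,
        "abdominal_width": W * ppm,
        "height": height,
        "volume": area_px * height,
    }


def volumetric_calibration(
    config: SimConfig,
    bw_range: tuple[float, float] = (15.0, 200.0),
    n_grid: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Calibration curve volume(BW) at the reference ventral clearance.

    This is the geometric model the depth system itself implies: the volume
    feature a clean frame would yield for each BW, computed at
    ``clearance_baseline`` and zero conformation deviation.  Inverting it
    (see :class:`pigtme.bwreg.RegressionModel` kind ``volumetric``) gives a
    model-based BW estimate that assumes every animal stands at the
    reference clearance — the assumption whose failure makes trait
    measurement error heritable when clearance is genetic.
    """
    grid_bw = np.linspace(bw_range[0], bw_range[1], n_grid)
    grid_vol = np.array(
        [
            analytic_features(
                shape_from_weight(b, config, clearance=config.clearance_baseline), config
            )["volume"]
            for b in grid_bw
        ]
    )
    return grid_bw, grid_vol


def simulate_shape_deviations(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-animal (d_length, d_width) conformation deviations, N(0, shape_sd)."""
    return rng.normal(0.0, config.shape_sd, size=(config.n_individuals, 2))


def simulate_features(
    bw: np.ndarray,
    clearance: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    shape_dev: np.ndarray | None = None,
) -> pd.DataFrame:
    """Feature-space mode: analytic features plus multiplicative measurement noise.

    Emulates the per-video median features the image pipeline would produce
    for a whole cohort without rendering pixels.  ``shape_dev`` carries the
    per-animal conformation deviations (rows of (d_length, d_width)); noise
    is i.i.d. (1 + N(0, feature_noise)) per feature per animal, representing
    the residual frame-sampling and segmentation variability left after
    taking the within-video median.
    """
    bw = np.asarray(bw, dtype=np.float64)
    clearance = np.asarray(clearance, dtype=np.float64)
    if shape_dev is None:
        shape_dev = np.zeros((bw.size, 2))
    rows = []
    for w, c, dev in zip(bw, clearance, shape_dev):
        shape = shape_from_weight(w, config, clearance=float(c), shape_dev=tuple(dev))
        rows.append(analytic_features(shape, config))
    feats = pd.DataFrame(rows)
    noise = rng.normal(1.0, config.feature_noise, size=feats.shape)
    return feats * np.maximum(noise, 0.05)
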