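"""Synthetic lamb cohort generator.

Every downstream stage of the pipeline is exercised against data from this
module: ground-truth hysteretic sigmoid pressure-volume curves per lamb,
regional volume partitions (right whole lung split into ventral / central /
dorsal), EIT-like relative-impedance records calibrated against super-syringe
volumes by construction, and rendered B-mode-like still frames whose
sub-pleural band brightness is affine in the regional aeration of the imaged
region.

The emulated experiment: preterm lambs undergo a static pressure-volume
manoeuvre between 0 and 35 cm H2O (stepwise inflation then deflation), imaged
with a linear ultrasound probe on either the dependent (right lower lateral)
or non-dependent (right anterior upper) chest wall. Those two windows see the
central and ventral EIT regions respectively. Deflation-limb curves are
left-shifted copies of the inflation sigmoid (lower inflection pressure c),
which guarantees deflation volume >= inflation volume at every pressure —
pulmonary hysteresis by construction.

Frames are stylised, not physical: a bright pleural line, a speckled
sub-pleural band whose mean grey value encodes regional volume, dark rib
shadows at both flanks. No wave propagation is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .pv import PVSeries, venegas_curve

__all__ = [
    "VenegasParams",
    "AcquisitionSchedule",
    "DEFAULT_SCHEDULE",
    "GeneratorConfig",
    "LambTruth",
    "SimulatedFrame",
    "EITRecord",
    "venegas_volume",
    "make_lamb_truth",
    "simulate_pv_series",
    "render_frame",
    "simulate_eit_record",
    "simulate_cohort",
]

REGIONS = ("ventral", "central", "dorsal")
#: ultrasound window -> EIT region it images
WINDOW_REGION = {"dependent": "central", "non_dependent": "ventral"}


class VenegasParams(NamedTuple):
    """Sigmoid PV parameters: V(P) = a + b/(1+exp((c-P)/d))."""

    a: float  # lower asymptote, ml/kg
    b: float  # span, ml/kg
    c: float  # inflection pressure, cm H2O
    d: float  # width, cm H2O


def venegas_volume(params: VenegasParams, pressure) -> np.ndarray | float:
    """Evaluate the sigmoid PV curve; strictly increasing in P, bounded in
    (a, a+b). Requires b > 0 and d > 0."""
    if params.d <= 0 or params.b <= 0:
        raise ValidationError("Venegas parameters require b > 0 and d > 0")
    out = venegas_curve(pressure, *params)
    return float(out) if np.isscalar(pressure) else out


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Pressure steps of the manoeuvre, in acquisition order (cm H2O)."""

    inflation_pressures: tuple[float, ...] = (0, 5, 10, 15, 20, 25, 30, 35)
    deflation_pressures: tuple[float, ...] = (30, 25, 20, 15, 10)

    def __post_init__(self) -> None:
        inf = np.asarray(self.inflation_pressures, dtype=float)
        dfl = np.asarray(self.deflation_pressures, dtype=float)
        if inf.size < 2 or inf[0] != 0 or np.any(np.diff(inf) <= 0):
            raise ValidationError("inflation pressures must increase strictly from 0")
        if dfl.size < 2 or np.any(np.diff(dfl) >= 0):
            raise ValidationError("deflation pressures must decrease strictly")
        lo, hi = 0.0, 35.0
        allp = np.concatenate([inf, dfl])
        if allp.min() < lo or allp.max() > hi:
            raise ValidationError("pressures must lie within [0, 35] cm H2O")

    @property
    def n_frames(self) -> int:
        return len(self.inflation_pressures) + len(self.deflation_pressures)

    def iter_steps(self):
        """Yield (limb, pressure) in acquisition order."""
        for p in self.inflation_pressures:
            yield "inflation", float(p)
        for p in self.deflation_pressures:
            yield "deflation", float(p)


DEFAULT_SCHEDULE = AcquisitionSchedule()


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling ranges and rendering constants for the synthetic cohort.

    Curve-shape defaults put the cohort on the scale of a preterm-lamb
    manoeuvre: maximal volume near 24 ml/kg in the dependent imaging group
    and 22 ml/kg in the non-dependent group, inflection of the inflation limb
    in the high-teens to low-twenties of cm H2O, and a deflation limb
    left-shifted by 4-10 cm H2O.
    """

    # --- PV curve sampling -------------------------------------------------
    vmax_mean_dependent: float = 24.0      # ml/kg at 35 cm H2O
    vmax_mean_non_dependent: float = 22.0  # ml/kg
    vmax_sd: float = 3.0
    a_range: tuple[float, float] = (0.0, 2.0)        # ml/kg
    c_inflation_range: tuple[float, float] = (18.0, 24.0)  # cm H2O
    d_range: tuple[float, float] = (2.0, 4.0)        # cm H2O
    delta_c_range: tuple[float, float] = (4.0, 10.0)  # deflation left shift
    # --- regional partition -------------------------------------------------
    right_whole_fraction_range: tuple[float, float] = (0.40, 0.50)
    weight_jitter: tuple[float, float] = (0.8, 1.2)  # pre-normalisation draw
    # --- echogenicity coupling ---------------------------------------------
    echo_baseline_range: tuple[float, float] = (35.0, 45.0)  # AU
    echo_gain_range: tuple[float, float] = (8.0, 15.0)       # AU per ml/kg
    noise_sigma_range: tuple[float, float] = (1.0, 2.0)      # AU
    # --- frame geometry and rendering levels --------------------------------
    frame_shape: tuple[int, int] = (160, 200)  # rows, cols
    pixel_spacing_mm: float = 0.02             # 50 px = 1 mm
    pleural_row_range: tuple[int, int] = (40, 70)
    shadow_width_range: tuple[int, int] = (15, 30)  # columns per flank
    tissue_level: float = 30.0   # chest wall above the pleura, AU
    deep_level: float = 20.0     # below the measured band, AU
    shadow_level: float = 3.0    # rib shadow, AU
    shadow_ceiling: float = 12.0  # rendered shadows must stay below this mean
    pleural_boost: float = 40.0  # pleural-line brightness above band mean
    # --- acquisition metadata (recorded, not modelled) -----------------------
    gain_db: float = 50.0
    depth_cm: float = 2.5
    frequency_mhz: float = 12.0

    def validate(self) -> None:
        problems = []
        if self.delta_c_range[0] <= 0:
            problems.append("delta_c_range must be positive to guarantee hysteresis")
        for name in ("a_range", "c_inflation_range", "d_range", "delta_c_range",
                     "right_whole_fraction_range", "echo_baseline_range",
                     "echo_gain_range", "noise_sigma_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                problems.append(f"{name} is inverted")
        if self.d_range[0] <= 0:
            problems.append("d_range must be positive")
        if self.noise_sigma_range[0] < 0:
            problems.append("noise_sigma_range must be non-negative")
        if not (0 <= self.echo_baseline_range[0]
                and self.echo_baseline_range[1] <= 255):
            problems.append("echo_baseline_range must lie in [0, 255]")
        rows, cols = self.frame_shape
        depth_px = round(1.0 / self.pixel_spacing_mm)
        if self.pleural_row_range[1] + depth_px >= rows:
            problems.append("pleural band does not fit below pleural_row_range")
        if 2 * self.shadow_width_range[1] >= cols:
            problems.append("rib shadows would cover the whole frame width")
        if problems:
            raise ConfigError(problems)


DEFAULT_CONFIG = GeneratorConfig()


@dataclass(frozen=True)
class LambTruth:
    """Ground truth for one synthetic lamb."""

    lamb_id: str
    region_imaged: str  # "dependent" | "non_dependent"
    inflation_params: VenegasParams
    deflation_params: VenegasParams
    regional_weights: dict[str, float]  # ventral/central/dorsal, sum to 1
    right_whole_fraction: float
    echo_baseline: float  # AU
    echo_gain: float      # AU per ml/kg regional volume
    noise_sigma: float    # AU
    seed: int

    def __post_init__(self) -> None:
        if self.region_imaged not in WINDOW_REGION:
            raise ValidationError(f"unknown imaging window {self.region_imaged!r}")
        for p in (self.inflation_params, self.deflation_params):
            if p.b <= 0 or p.d <= 0:
                raise ValidationError("sigmoid parameters require b > 0, d > 0")
        w = np.array([self.regional_weights[r] for r in REGIONS])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("regional weights must be non-negative and sum to 1")
        if not 0 <= self.echo_baseline <= 255:
            raise ValidationError("echo_baseline outside [0, 255]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        # hysteresis by construction: deflation curve at or above inflation
        grid = np.linspace(0, 35, 36)
        lo = venegas_curve(grid, *self.inflation_params)
        hi = venegas_curve(grid, *self.deflation_params)
        if np.any(hi < lo - 1e-9):
            raise ValidationError("deflation curve must dominate inflation curve")

    def params(self, limb: str) -> VenegasParams:
        if limb == "inflation":
            return self.inflation_params
        if limb == "deflation":
            return self.deflation_params
        raise ValueError(f"unknown limb {limb!r}")

    def regional_volume(self, limb: str, pressure, region: str | None = None):
        """Volume (ml/kg) of one EIT region; defaults to the imaged region."""
        region = region or WINDOW_REGION[self.region_imaged]
        total = venegas_volume(self.params(limb), pressure)
        return total * self.right_whole_fraction * self.regional_weights[region]


@dataclass
class SimulatedFrame:
    """Rendered 8-bit still plus its ground-truth geometry and metadata."""

    pixels: np.ndarray  # uint8, (rows, cols)
    pixel_spacing_mm: float
    pleural_row_truth: int
    shadow_cols_truth: tuple[tuple[int, int], tuple[int, int]]  # inclusive spans
    meta: dict = field(default_factory=dict)


@dataclass
class EITRecord:
    """Relative-impedance time course over the manoeuvre, one sample per
    pressure step, plus the super-syringe total volumes (ml/kg)."""

    lamb_id: str
    limbs: np.ndarray       # "inflation"/"deflation" per sample
    pressures: np.ndarray   # cm H2O
    syringe_volumes: np.ndarray  # ml/kg, noiseless totals
    z_right_whole: np.ndarray    # AU
    z_ventral: np.ndarray
    z_central: np.ndarray
    z_dorsal: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.pressures)
        for name in ("limbs", "syringe_volumes", "z_right_whole",
                     "z_ventral", "z_central", "z_dorsal"):
            if len(getattr(self, name)) != n:
                raise ValidationError("EIT record fields must have equal length")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def make_lamb_truth(seed: int, config: GeneratorConfig = DEFAULT_CONFIG,
                    lamb_id: str | None = None,
                    region_imaged: str = "dependent") -> LambTruth:
    """Draw one lamb's ground truth; deterministic for a fixed seed.

    The deflation limb reuses the inflation parameters with the inflection c
    reduced by a draw from ``delta_c_range``, so deflation volume dominates
    inflation volume at every pressure.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    vmax_mean = (config.vmax_mean_dependent if region_imaged == "dependent"
                 else config.vmax_mean_non_dependent)
    a = rng.uniform(*config.a_range)
    vmax = max(rng.normal(vmax_mean, config.vmax_sd), a + 5.0)
    c = rng.uniform(*config.c_inflation_range)
    d = rng.uniform(*config.d_range)
    # b chosen so the upper asymptote a+b sits at the drawn maximal volume
    b = vmax - a
    delta_c = rng.uniform(*config.delta_c_range)

    raw_w = rng.uniform(*config.weight_jitter, size=3)
    w = raw_w / raw_w.sum()

    return LambTruth(
        lamb_id=lamb_id or f"lamb{seed:04d}",
        region_imaged=region_imaged,
        inflation_params=VenegasParams(a, b, c, d),
        deflation_params=VenegasParams(a, b, c - delta_c, d),
        regional_weights=dict(zip(REGIONS, map(float, w))),
        right_whole_fraction=float(rng.uniform(*config.right_whole_fraction_range)),
        echo_baseline=float(rng.uniform(*config.echo_baseline_range)),
        echo_gain=float(rng.uniform(*config.echo_gain_range)),
        noise_sigma=float(rng.uniform(*config.noise_sigma_range)),
        seed=int(seed),
    )


def simulate_pv_series(truth: LambTruth,
                       schedule: AcquisitionSchedule = DEFAULT_SCHEDULE,
                       ) -> tuple[PVSeries, dict[str, PVSeries]]:
    """Noiseless ground-truth series: total volume per limb and the regional
    partition (right whole = ventral + central + dorsal exactly)."""
    inf_p = np.asarray(schedule.inflation_pressures, dtype=float)
    def_p = np.asarray(schedule.deflation_pressures, dtype=float)
    v_inf = venegas_curve(inf_p, *truth.inflation_params)
    v_def = venegas_curve(def_p, *truth.deflation_params)

    total = PVSeries(truth.lamb_id, "volume_total", inf_p, v_inf, def_p, v_def)

    regional: dict[str, PVSeries] = {}
    f = truth.right_whole_fraction
    regional["right_whole"] = PVSeries(
        truth.lamb_id, "volume_regional:right_whole",
        inf_p, v_inf * f, def_p, v_def * f)
    for region in REGIONS:
        wf = f * truth.regional_weights[region]
        regional[region] = PVSeries(
            truth.lamb_id, f"volume_regional:{region}",
            inf_p, v_inf * wf, def_p, v_def * wf)
    return total, regional


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

def _frame_geometry(truth: LambTruth, config: GeneratorConfig):
    """Per-lamb probe placement, fixed across the manoeuvre."""
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0xF1A]))
    pleural_row = int(rng.integers(config.pleural_row_range[0],
                                   config.pleural_row_range[1] + 1))
    lw = int(rng.integers(config.shadow_width_range[0],
                          config.shadow_width_range[1] + 1))
    rw = int(rng.integers(config.shadow_width_range[0],
                          config.shadow_width_range[1] + 1))
    return pleural_row, lw, rw


def render_frame(truth: LambTruth, pressure: float, limb: str,
                 rng: np.random.Generator | int,
                 config: GeneratorConfig = DEFAULT_CONFIG) -> SimulatedFrame:
    """Render one stylised B-mode still.

    The 1-mm (50 px at the default 0.02 mm/px spacing) band below and
    including the pleural line has expected mean intensity
    ``clip(echo_baseline + echo_gain * regional_volume, 0, 255)`` within the
    inter-shadow columns; the pleural-line row itself is brighter and the 49
    rows beneath it dimmer so the band mean hits the target exactly before
    quantisation. Additive Gaussian speckle proxy with sd ``noise_sigma``.
    """
    if np.isscalar(rng):
        rng = np.random.default_rng(rng)
    rows, cols = config.frame_shape
    depth_px = round(1.0 / config.pixel_spacing_mm)
    pleural_row, lw, rw = _frame_geometry(truth, config)

    vol = truth.regional_volume(limb, pressure)
    target = float(np.clip(truth.echo_baseline + truth.echo_gain * vol, 0, 255))

    img = np.full((rows, cols), config.deep_level, dtype=float)
    img[:pleural_row, :] = config.tissue_level
    if target >= 1.0:
        line = min(255.0, target + config.pleural_boost)
        # interior level so the 50-row band mean equals the target exactly
        interior = (depth_px * target - line) / (depth_px - 1)
    else:
        line = interior = target
    img[pleural_row, :] = line
    img[pleural_row + 1: pleural_row + depth_px, :] = interior

    img += rng.normal(0.0, truth.noise_sigma, size=img.shape)
    # rib shadows overwrite everything below the pleural line at both flanks
    shadow = np.clip(
        config.shadow_level
        + rng.normal(0.0, truth.noise_sigma, size=(rows - pleural_row, lw + rw)),
        0, config.shadow_ceiling - 1.0)
    img[pleural_row:, :lw] = shadow[:, :lw]
    img[pleural_row:, cols - rw:] = shadow[:, lw:]

    pixels = np.rint(np.clip(img, 0, 255)).astype(np.uint8)
    region = WINDOW_REGION[truth.region_imaged]
    return SimulatedFrame(
        pixels=pixels,
        pixel_spacing_mm=config.pixel_spacing_mm,
        pleural_row_truth=pleural_row,
        shadow_cols_truth=((0, lw - 1), (cols - rw, cols - 1)),
        meta={
            "lamb_id": truth.lamb_id,
            "region": truth.region_imaged,
            "eit_region": region,
            "limb": limb,
            "pressure_cmH2O": float(pressure),
            "gain_db": config.gain_db,
            "depth_cm": config.depth_cm,
            "frequency_mhz": config.frequency_mhz,
        },
    )


# ---------------------------------------------------------------------------
# EIT record
# ---------------------------------------------------------------------------

def simulate_eit_record(truth: LambTruth,
                        schedule: AcquisitionSchedule = DEFAULT_SCHEDULE,
                        gain: float = 0.5, offset: float = 0.0) -> EITRecord:
    """Relative-impedance record affine in regional volume:
    z = gain * volume + offset per channel; syringe volumes are the noiseless
    totals. Exactly invertible by :func:`greylung.pv.calibrate_eit`."""
    if gain == 0:
        raise ValidationError("EIT gain must be non-zero")
    limbs, pressures = zip(*schedule.iter_steps())
    pressures = np.asarray(pressures, dtype=float)
    limbs = np.asarray(limbs)

    totals = np.array([venegas_volume(truth.params(l), p)
                       for l, p in zip(limbs, pressures)])
    v_rw = totals * truth.right_whole_fraction
    z = {"right_whole": gain * v_rw + offset}
    for region in REGIONS:
        z[region] = gain * v_rw * truth.regional_weights[region] + offset
    return EITRecord(
        lamb_id=truth.lamb_id, limbs=limbs, pressures=pressures,
        syringe_volumes=totals, z_right_whole=z["right_whole"],
        z_ventral=z["ventral"], z_central=z["central"], z_dorsal=z["dorsal"],
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _lamb_seeds(master_seed: int, n: int) -> np.ndarray:
    """Independent per-lamb seeds, each below 2**31."""
    return np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32) >> 1


def simulate_cohort(n_lambs: int, out_dir: str | Path,
                    schedule: AcquisitionSchedule = DEFAULT_SCHEDULE,
                    config: GeneratorConfig = DEFAULT_CONFIG,
                    master_seed: int = 0) -> dict[str, Path]:
    """Write a fully labelled cohort: one PNG frame per pressure step per
    lamb, plus metadata, ground-truth and EIT CSV tables.

    Lambs alternate imaging windows deterministically (even index dependent,
    odd non-dependent) so the two groups are balanced; each lamb is imaged
    from a single window, as in a one-probe protocol. Bit-for-bit
    reproducible from ``master_seed``.
    """
    if n_lambs < 1:
        raise ValidationError("n_lambs must be >= 1")
    config.validate()
    out_dir = Path(out_dir)
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)

    seeds = _lamb_seeds(master_seed, n_lambs)
    meta_rows, truth_rows, eit_rows = [], [], []

    for i, seed in enumerate(seeds):
        region = "dependent" if i % 2 == 0 else "non_dependent"
        lamb_id = f"lamb{i + 1:03d}"
        truth = make_lamb_truth(int(seed), config, lamb_id=lamb_id,
                                region_imaged=region)

        for limb in ("inflation", "deflation"):
            p = truth.params(limb)
            truth_rows.append({
                "lamb_id": lamb_id, "region": region, "limb": limb,
                "a": p.a, "b": p.b, "c": p.c, "d": p.d,
                "right_whole_fraction": truth.right_whole_fraction,
                "w_ventral": truth.regional_weights["ventral"],
                "w_central": truth.regional_weights["central"],
                "w_dorsal": truth.regional_weights["dorsal"],
                "echo_baseline": truth.echo_baseline,
                "echo_gain": truth.echo_gain,
                "noise_sigma": truth.noise_sigma,
                "seed": int(seed),
            })

        for k, (limb, pressure) in enumerate(schedule.iter_steps()):
            frame_rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), k]))
            frame = render_frame(truth, pressure, limb, frame_rng, config)
            name = f"{lamb_id}_{region}_{limb}_{pressure:g}.png"
            iio.imwrite(frames_dir / name, frame.pixels)
            meta_rows.append({
                "lamb_id": lamb_id, "region": region, "limb": limb,
                "pressure_cmH2O": pressure,
                "frame_path": f"frames/{name}",
                "pixel_spacing_mm": config.pixel_spacing_mm,
            })

        record = simulate_eit_record(truth, schedule)
        for j in range(len(record.pressures)):
            eit_rows.append({
                "lamb_id": lamb_id, "limb": record.limbs[j],
                "pressure_cmH2O": record.pressures[j],
                "syringe_volume_mlkg": record.syringe_volumes[j],
                "z_right_whole": record.z_right_whole[j],
                "z_ventral": record.z_ventral[j],
                "z_central": record.z_central[j],
                "z_dorsal": record.z_dorsal[j],
            })

    paths = {
        "metadata": out_dir / "metadata.csv",
        "truth": out_dir / "truth.csv",
        "eit": out_dir / "eit.csv",
        "frames_dir": frames_dir,
    }
    pd.DataFrame(meta_rows).to_csv(paths["metadata"], index=False)
    pd.DataFrame(truth_rows).to_csv(paths["truth"], index=False, float_format="%.10g")
    pd.DataFrame(eit_rows).to_csv(paths["eit"], index=False, float_format="%.10g")
    return paths
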