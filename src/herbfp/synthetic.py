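"""Synthetic LC-MS trituration study generator.

Emulates the data structure of a one-target screening study: a pure reference
plant chromatogram, a panel of blank supplement matrices (botanical blends
plus one lactose filler), and *triturations* — powdered mixtures of reference
into blank at fixed mass fractions — measured with run-to-run retention-time
shifts, a flat baseline, and heteroscedastic detector noise. Each simulated
export carries two channels per time point: summed intensity and base-peak
m/z, the latter taken from whichever component dominates the signal there.

Peaks are Gaussian in time; no attempt is made to simulate mass-spectral
physics (isotopes, adducts, fragmentation) or chromatographic band broadening
beyond a fixed per-peak width. The point is statistical structure, not
chemistry: class separation is controlled by the reference signature height
relative to noise (``GeneratorConfig.signal_scale`` is the dial), and the
shift band guarantees the aligner has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset_io import Dataset, Fingerprint
from .errors import ConfigurationError, GridError, ParameterError

#: Mixing fractions of reference into blank, smallest first (1/20 ... 1/2).
DEFAULT_RATIOS = (1 / 20, 1 / 15, 1 / 10, 1 / 5, 1 / 2)

#: m/z scan range all generated peaks must respect.
MZ_RANGE = (50.0, 2000.0)


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian chromatographic peak with a single associated base-peak m/z."""

    retention_time: float  # minutes
    width: float  # Gaussian sigma, minutes
    height: float  # arbitrary intensity units
    mz: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError(f"peak width must be positive, got {self.width}")
        if self.height < 0:
            raise ConfigurationError(f"peak height must be non-negative, got {self.height}")
        if not MZ_RANGE[0] <= self.mz <= MZ_RANGE[1]:
            raise ConfigurationError(f"peak m/z {self.mz} outside scan range {MZ_RANGE}")


@dataclass(frozen=True)
class MatrixProfile:
    """A blank matrix: its peak list and baseline level."""

    matrix_id: str
    peaks: tuple[PeakSpec, ...]
    baseline_level: float

    def __post_init__(self) -> None:
        if len(self.peaks) < 1:
            raise ConfigurationError(f"matrix {self.matrix_id!r} needs at least one peak")
        if self.baseline_level < 0:
            raise ConfigurationError("baseline level must be non-negative")


@dataclass(frozen=True)
class TriturationDesign:
    """Study layout: which ratios, how many blank matrices, which target."""

    ratios: tuple[float, ...] = DEFAULT_RATIOS
    n_matrices: int = 11
    target_plant: str = "target"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_matrices < 1:
            raise ConfigurationError("need at least one blank matrix")
        if not all(0 < r < 1 for r in self.ratios):
            raise ConfigurationError("all mixing ratios must lie strictly in (0, 1)")

    @property
    def n_triturations(self) -> int:
        return self.n_matrices * len(self.ratios)

    @property
    def n_samples(self) -> int:
        # triturations + blanks + 1 reference
        return self.n_triturations + self.n_matrices + 1


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable knobs of the simulated instrument and study.

    The run spans ``run_start``..``run_end`` minutes sampled at
    ``points_per_min``; defaults give ~1500 points over the 3-10 min
    fingerprint region. Noise on the intensity channel has standard deviation
    ``noise_scale * sqrt(intensity) + noise_floor`` (heteroscedastic shot-like
    noise plus a detector floor). Per-sample retention-time shifts are drawn
    uniformly from +/- ``shift_band`` x run length. ``signal_scale``
    multiplies the reference signature heights only — the separability dial.
    """

    run_start: float = 0.0
    run_end: float = 13.0
    points_per_min: int = 214
    noise_scale: float = 0.02
    noise_floor: float = 0.5
    shift_band: float = 0.02
    n_signature_peaks: int = 24
    signature_rt_range: tuple[float, float] = (3.6, 9.4)
    signature_height: tuple[float, float] = (250.0, 400.0)
    signature_width: tuple[float, float] = (0.025, 0.06)
    signature_min_separation: float = 0.15
    blank_peak_count: tuple[int, int] = (15, 40)
    blank_height: tuple[float, float] = (20.0, 150.0)
    blank_width: tuple[float, float] = (0.015, 0.05)
    blank_rt_margin: float = 0.3
    n_excipient_peaks: int = 36
    excipient_height_jitter: tuple[float, float] = (0.92, 1.08)
    blank_specific_height_factor: float = 0.6
    mass_detect_threshold: float = 5.0  # peak-picker S/N limit (~10x the noise floor)
    loading_rsd: float = 0.03  # per-sample injection/weighing variability (relative sd)
    baseline_range: tuple[float, float] = (2.0, 8.0)
    reference_baseline: float = 1.0
    analyte_mz_range: tuple[float, float] = (100.0, 900.0)  # typical plant metabolite base peaks
    background_amplitude: float = 40.0
    background_n_humps: int = 4
    background_width_range: tuple[float, float] = (0.8, 2.5)
    n_system_peaks: int = 4
    system_height: tuple[float, float] = (300.0, 800.0)
    system_width: tuple[float, float] = (0.04, 0.12)
    signal_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.points_per_min <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if self.run_end <= self.run_start:
            raise ConfigurationError("run length must be positive")
        if self.signal_scale < 0:
            raise ConfigurationError("signal_scale must be non-negative")

    @property
    def run_length(self) -> float:
        return self.run_end - self.run_start

    def time_grid(self) -> np.ndarray:
        n = int(round(self.run_length * self.points_per_min)) + 1
        return self.run_start + np.arange(n) / self.points_per_min


# ---------------------------------------------------------------------------
# Rendering


def render_peaks(
    peaks: Sequence[PeakSpec], baseline: float, grid: np.ndarray,
    mass_detect_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless render: intensity = baseline + sum of Gaussians; mass = m/z of
    the dominant peak per time point.

    Where no peak contribution reaches ``mass_detect_threshold`` intensity
    units no base peak is recorded and the mass channel reads 0 — emulating
    the peak-picking detection limit of the export software.
    """
    intensity = np.full(grid.size, float(baseline))
    mass = np.zeros(grid.size)
    if peaks:
        contrib = np.empty((len(peaks), grid.size))
        for i, p in enumerate(peaks):
            contrib[i] = p.height * np.exp(-0.5 * ((grid - p.retention_time) / p.width) ** 2)
        intensity += contrib.sum(axis=0)
        winner = np.argmax(contrib, axis=0)
        mzs = np.array([p.mz for p in peaks])
        mass = mzs[winner]
        mass[contrib.max(axis=0) < mass_detect_threshold] = 0.0
    return intensity, mass


def _add_noise(intensity: np.ndarray, rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    if cfg.noise_scale == 0 and cfg.noise_floor == 0:
        return intensity
    sd = cfg.noise_scale * np.sqrt(np.maximum(intensity, 0.0)) + cfg.noise_floor
    return np.maximum(intensity + rng.normal(0.0, 1.0, intensity.size) * sd, 0.0)


def _shift(grid: np.ndarray, signal: np.ndarray, shift_min: float) -> np.ndarray:
    """Delay a channel by ``shift_min`` minutes via linear resampling (edge-clamped)."""
    if shift_min == 0.0:
        return signal
    return np.interp(grid - shift_min, grid, signal)


def _draw_separated(rng, n, lo, hi, min_sep, max_tries=10000) -> np.ndarray:
    """Rejection-sample n retention times keeping a minimum mutual separation."""
    out: list[float] = []
    for _ in range(max_tries):
        c = rng.uniform(lo, hi)
        if all(abs(c - o) >= min_sep for o in out):
            out.append(c)
            if len(out) == n:
                return np.array(out)
    raise ConfigurationError(f"could not place {n} peaks with separation {min_sep} in [{lo},{hi}]")


# ---------------------------------------------------------------------------
# Single-sample generators


def reference_peaks(
    seed: int, n_signature_peaks: int | None = None, config: GeneratorConfig | None = None
) -> tuple[PeakSpec, ...]:
    """Draw the target plant's signature peak list (reproducible under the seed)."""
    cfg = config or GeneratorConfig()
    n = cfg.n_signature_peaks if n_signature_peaks is None else n_signature_peaks
    if n < 3:
        raise ConfigurationError(f"a signature needs at least 3 peaks, got {n}")
    rng = np.random.default_rng(seed)
    lo = max(cfg.signature_rt_range[0], cfg.run_start)
    hi = min(cfg.signature_rt_range[1], cfg.run_end)
    rts = _draw_separated(rng, n, lo, hi, cfg.signature_min_separation)
    return tuple(
        PeakSpec(
            retention_time=float(rt),
            width=float(rng.uniform(*cfg.signature_width)),
            height=float(rng.uniform(*cfg.signature_height)) * cfg.signal_scale,
            mz=float(rng.uniform(*cfg.analyte_mz_range)),
        )
        for rt in rts
    )


def generate_reference(
    seed: int,
    n_signature_peaks: int | None = None,
    config: GeneratorConfig | None = None,
    noise_seed: int | None = None,
    sample_id: str = "reference",
) -> Fingerprint:
    """Generate the pure reference-plant fingerprint.

    The peak layout depends only on ``seed``; measurement noise is driven by
    ``noise_seed`` (defaults to ``seed`` so equal seeds give bit-identical
    fingerprints).
    """
    cfg = config or GeneratorConfig()
    peaks = reference_peaks(seed, n_signature_peaks, cfg)
    grid = cfg.time_grid()
    intensity, mass = render_peaks(peaks, cfg.reference_baseline, grid)
    rng = np.random.default_rng(seed if noise_seed is None else noise_seed)
    intensity = _add_noise(intensity, rng, cfg)
    return Fingerprint(
        sample_id=sample_id,
        times=grid,
        intensities=intensity,
        masses=mass,
        metadata={"role": "reference", "class": 1, "ratio": 1.0, "matrix_id": "", "peaks": peaks},
    )


def generate_blank(
    profile: MatrixProfile,
    seed: int,
    config: GeneratorConfig | None = None,
    shift_min: float = 0.0,
    sample_id: str | None = None,
) -> Fingerprint:
    """Generate one blank-matrix fingerprint (class 2, no target signature)."""
    cfg = config or GeneratorConfig()
    grid = cfg.time_grid()
    intensity, mass = render_peaks(profile.peaks, profile.baseline_level, grid)
    intensity = _shift(grid, intensity, shift_min)
    mass = _shift(grid, mass, shift_min)
    intensity = _add_noise(intensity, np.random.default_rng(seed), cfg)
    return Fingerprint(
        sample_id=sample_id or f"blank_{profile.matrix_id}",
        times=grid,
        intensities=intensity,
        masses=mass,
        metadata={"role": "blank", "class": 2, "ratio": np.nan, "matrix_id": profile.matrix_id},
    )


def make_trituration(
    blank: Fingerprint,
    reference: Fingerprint,
    ratio: float,
    shift: float = 0.0,
    seed: int | None = None,
    config: GeneratorConfig | None = None,
    sample_id: str | None = None,
) -> Fingerprint:
    """Mix reference into blank at ``ratio``: intensity is the convex combination
    ``ratio * reference + (1 - ratio) * blank``; the mass channel takes the m/z
    of whichever component dominates intensity at each time point. The mixture
    is then delayed by ``shift`` minutes (linear resampling) and, when a seed
    is given, measurement noise is added. Class label 1 (target present)."""
    if not 0 < ratio < 1:
        raise ParameterError(f"ratio must lie strictly in (0, 1), got {ratio}")
    if blank.times.size != reference.times.size or not np.array_equal(blank.times, reference.times):
        raise GridError("blank and reference must share one time grid")
    cfg = config or GeneratorConfig()
    ref_part = ratio * reference.intensities
    blank_part = (1 - ratio) * blank.intensities
    intensity = ref_part + blank_part
    mass = np.where(ref_part >= blank_part, reference.masses, blank.masses)
    grid = blank.times
    intensity = _shift(grid, intensity, shift)
    mass = _shift(grid, mass, shift)
    if seed is not None:
        intensity = _add_noise(intensity, np.random.default_rng(seed), cfg)
    matrix_id = blank.metadata.get("matrix_id", blank.sample_id)
    return Fingerprint(
        sample_id=sample_id or f"trit_{matrix_id}_{ratio:.4f}",
        times=grid,
        intensities=intensity,
        masses=mass,
        metadata={"role": "trituration", "class": 1, "ratio": float(ratio), "matrix_id": matrix_id},
    )


# ---------------------------------------------------------------------------
# Whole-study generation


def random_profiles(
    n_matrices: int, seed: int, config: GeneratorConfig | None = None
) -> list[MatrixProfile]:
    """Draw the blank-matrix panel.

    Botanical supplement blends share formulation excipients, so every
    botanical profile carries a common excipient peak set (with per-matrix
    height jitter) on top of its own specific peaks. The last matrix is a
    sparse lactose-like filler with no botanical content.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    lo = cfg.run_start + cfg.blank_rt_margin
    hi = cfg.run_end - cfg.blank_rt_margin

    def _draw_peak(height_factor: float = 1.0) -> PeakSpec:
        return PeakSpec(
            retention_time=float(rng.uniform(lo, hi)),
            width=float(rng.uniform(*cfg.blank_width)),
            height=float(rng.uniform(*cfg.blank_height)) * height_factor,
            mz=float(rng.uniform(*cfg.analyte_mz_range)),
        )

    excipients = tuple(_draw_peak() for _ in range(cfg.n_excipient_peaks))
    profiles = []
    for m in range(n_matrices):
        lactose = m == n_matrices - 1 and n_matrices > 1
        if lactose:
            mid = "lactose"
            peaks = tuple(_draw_peak(0.2) for _ in range(int(rng.integers(2, 5))))
        else:
            mid = f"matrix_{m + 1:02d}"
            n_total = int(rng.integers(cfg.blank_peak_count[0], cfg.blank_peak_count[1] + 1))
            n_shared = min(len(excipients), max(0, n_total - 4))
            shared = tuple(
                replace(p, height=p.height * float(rng.uniform(*cfg.excipient_height_jitter)))
                for p in excipients[:n_shared]
            )
            peaks = shared + tuple(
                _draw_peak(cfg.blank_specific_height_factor) for _ in range(n_total - n_shared)
            )
        profiles.append(
            MatrixProfile(
                matrix_id=mid,
                peaks=peaks,
                baseline_level=float(rng.uniform(*cfg.baseline_range)),
            )
        )
    return profiles


@dataclass
class StudyPlan:
    """Deterministic composition of a study, independent of grid and noise level.

    Rendering the same plan under two instrument configs yields two detector
    blocks over identical samples (the fusion scenario).
    """

    design: TriturationDesign
    ref_peaks: tuple[PeakSpec, ...]
    profiles: list[MatrixProfile]
    shifts: dict[str, float]  # sample_id -> retention-time shift, minutes
    order: list[dict] = field(default_factory=list)  # manifest rows in sample order
    background: tuple[tuple[float, float, float], ...] = ()  # (rt, width, rel_height) humps
    system_peaks: tuple[PeakSpec, ...] = ()  # solvent front / column artifacts, in every run


def plan_study(
    design: TriturationDesign | None = None,
    seed: int | None = None,
    config: GeneratorConfig | None = None,
) -> StudyPlan:
    design = design or TriturationDesign()
    cfg = config or GeneratorConfig()
    seed = design.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_ref, s_prof, s_shift, s_bg = ss.spawn(4)
    ref_peaks = reference_peaks(int(s_ref.generate_state(1)[0] % 2**31), config=replace(cfg, signal_scale=1.0))
    # signal_scale is applied at render time so one plan serves several dial settings
    profiles = random_profiles(design.n_matrices, int(s_prof.generate_state(1)[0] % 2**31), cfg)
    rng_bg = np.random.default_rng(s_bg)
    # shared mobile-phase / gradient background: broad humps present in every run,
    # shifting with the run — part of the anchor real chromatograms give the aligner
    background = tuple(
        (float(rng_bg.uniform(cfg.run_start, cfg.run_end)),
         float(rng_bg.uniform(*cfg.background_width_range)),
         float(rng_bg.uniform(0.5, 1.0)))
        for _ in range(cfg.background_n_humps)
    )
    # shared system peaks: a solvent front early in the run plus column/injection
    # artifacts at fixed retention times, present in every sample of the sequence
    sys_peaks = []
    for k in range(cfg.n_system_peaks):
        rt = (float(rng_bg.uniform(cfg.run_start + 0.4, cfg.run_start + 1.0)) if k == 0
              else float(rng_bg.uniform(cfg.run_start + 1.0, cfg.run_end - 0.3)))
        sys_peaks.append(PeakSpec(
            retention_time=rt,
            width=float(rng_bg.uniform(*cfg.system_width)),
            height=float(rng_bg.uniform(*cfg.system_height)),
            mz=float(rng_bg.uniform(*cfg.analyte_mz_range)),
        ))
    rng_shift = np.random.default_rng(s_shift)
    band = cfg.shift_band * cfg.run_length
    order: list[dict] = [
        {"sample_id": "reference", "role": "reference", "matrix_id": "", "ratio": 1.0, "class": 1}
    ]
    shifts = {"reference": 0.0}
    for p in profiles:
        sid = f"blank_{p.matrix_id}"
        order.append({"sample_id": sid, "role": "blank", "matrix_id": p.matrix_id, "ratio": np.nan, "class": 2})
        shifts[sid] = float(rng_shift.uniform(-band, band))
    for p in profiles:
        for k, ratio in enumerate(design.ratios):
            sid = f"trit_{p.matrix_id}_r{k}"
            order.append(
                {"sample_id": sid, "role": "trituration", "matrix_id": p.matrix_id,
                 "ratio": float(ratio), "class": 1}
            )
            shifts[sid] = float(rng_shift.uniform(-band, band))
    return StudyPlan(design=design, ref_peaks=ref_peaks, profiles=profiles, shifts=shifts,
                     order=order, background=background, system_peaks=tuple(sys_peaks))


def render_study(plan: StudyPlan, config: GeneratorConfig, noise_seed: int) -> Dataset:
    """Render a plan under one instrument config (grid + noise) into a Dataset."""
    cfg = config
    grid = cfg.time_grid()
    bg = np.zeros(grid.size)
    for rt, width, rel in plan.background:
        bg += rel * cfg.background_amplitude * np.exp(-0.5 * ((grid - rt) / width) ** 2)
    scaled = tuple(replace(p, height=p.height * cfg.signal_scale) for p in plan.ref_peaks)
    # the shared system peaks belong to every component, reference and blanks alike.
    # Component mass traces are rendered without a detection limit; the limit is
    # applied to the mixture each sample actually presents to the peak picker.
    ref_int, ref_mass = render_peaks(scaled + plan.system_peaks, cfg.reference_baseline, grid,
                                     mass_detect_threshold=0.0)
    ref_int = ref_int + bg
    # peak-only traces drive the base-peak m/z dominance decision: background ions
    # are excluded from peak picking, so they never claim the mass channel
    ref_peak_part = ref_int - bg - cfg.reference_baseline
    clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    peak_part: dict[str, np.ndarray] = {}
    for p in plan.profiles:
        bi, bm = render_peaks(p.peaks + plan.system_peaks, p.baseline_level, grid,
                              mass_detect_threshold=0.0)
        peak_part[p.matrix_id] = bi - p.baseline_level
        clean[p.matrix_id] = (bi + bg, bm)
    noise_rng = {
        row["sample_id"]: np.random.default_rng(child)
        for row, child in zip(plan.order, np.random.SeedSequence(noise_seed).spawn(len(plan.order)))
    }
    fps: list[Fingerprint] = []
    for row in plan.order:
        sid = row["sample_id"]
        shift = plan.shifts[sid]
        thr = cfg.mass_detect_threshold
        if row["role"] == "reference":
            intensity = ref_int.copy()
            mass = np.where(ref_peak_part >= thr, ref_mass, 0.0)
        elif row["role"] == "blank":
            bi, bm = clean[row["matrix_id"]]
            mass = np.where(peak_part[row["matrix_id"]] >= thr, bm, 0.0)
            intensity, mass = _shift(grid, bi, shift), _shift(grid, mass, shift)
        else:
            bi, bm = clean[row["matrix_id"]]
            r = row["ratio"]
            ref_mix = r * ref_peak_part
            blank_mix = (1 - r) * peak_part[row["matrix_id"]]
            intensity = _shift(grid, r * ref_int + (1 - r) * bi, shift)
            mass = np.where(ref_mix >= blank_mix, ref_mass, bm)
            mass[np.maximum(ref_mix, blank_mix) < thr] = 0.0  # below the peak picker's limit
            mass = _shift(grid, mass, shift)
        rng_s = noise_rng[sid]
        if cfg.loading_rsd > 0:
            # sample weighing / injection volume variability scales the whole trace
            intensity = intensity * float(np.exp(rng_s.normal(0.0, cfg.loading_rsd)))
        intensity = _add_noise(intensity, rng_s, cfg)
        fps.append(
            Fingerprint(
                sample_id=sid, times=grid, intensities=intensity, masses=mass,
                metadata={k: row[k] for k in ("role", "matrix_id", "ratio", "class")},
            )
        )
    manifest = pd.DataFrame(plan.order)
    return Dataset(fingerprints=fps, manifest=manifest)


def generate_study(
    design: TriturationDesign | None = None,
    seed: int | None = None,
    config: GeneratorConfig | None = None,
) -> Dataset:
    """Generate the full study: triturations + blanks + 1 reference.

    With the default design that is 55 + 11 + 1 = 67 fingerprints; the
    reference and all triturations carry class 1, the blanks class 2.
    """
    design = design or TriturationDesign()
    cfg = config or GeneratorConfig()
    seed = design.seed if seed is None else seed
    plan = plan_study(design, seed, cfg)
    return render_study(plan, cfg, noise_seed=_mix_seed(seed, 1))


def generate_paired_blocks(
    design: TriturationDesign | None = None,
    seed: int | None = None,
    config_a: GeneratorConfig | None = None,
    config_b: GeneratorConfig | None = None,
) -> tuple[Dataset, Dataset]:
    """Two detector blocks over identical samples (MS-like and DAD-like).

    Both blocks share the composition and retention-time shifts; they differ in
    grid density and noise level, so feature dimensions differ while class
    structure and sample order are identical.
    """
    design = design or TriturationDesign()
    seed = design.seed if seed is None else seed
    cfg_a = config_a or GeneratorConfig()
    cfg_b = config_b or replace(cfg_a, points_per_min=60, noise_scale=0.04, noise_floor=0.8)
    plan = plan_study(design, seed, cfg_a)
    block_a = render_study(plan, cfg_a, noise_seed=_mix_seed(seed, 1))
    block_b = render_study(plan, cfg_b, noise_seed=_mix_seed(seed, 2))
    return block_a, block_b


def _mix_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % 2**31)
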