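"""Synthetic cohort generator.

Builds complete per-animal raw datasets — broadband NIRS attenuation
time series with a terminal anoxia pulse, single-slice ASL stacks with
a variable-TR T1 series, pulse-oximeter style arterial saturation, and
daily disease-score trajectories — whose group-level statistics match
the study conditions: three groups (naive, CFA/PTX adjuvant controls,
EAE) with preset means and SDs for cerebral blood flow, tissue oxygen
saturation, total cytochrome-c-oxidase and its oxidized fraction.

The simulators share the forward models of :mod:`oxymet.optics` and the
CASL equation inverted by :mod:`oxymet.asl`, so that pipeline recovery
tests are exact in the noise-free limit.  All randomness flows from one
cohort seed through per-animal ``numpy.random.SeedSequence`` spawns.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .asl import DEFAULT_TR_LIST_S, AslGeometry, AslModelParams, AslStack
from .nirs import NirsProtocol
from .optics import ExtinctionTable, TissueState, attenuation_forward

__all__ = [
    "TruncatedNormal",
    "DiseaseParams",
    "CohortPreset",
    "AnimalPhysiology",
    "DiseaseCourse",
    "NirsRecording",
    "SimulatedAsl",
    "builtin_presets",
    "sample_animal",
    "simulate_nirs_timeseries",
    "simulate_asl_stack",
    "simulate_disease_course",
    "generate_cohort",
]

MAX_SCORE_ALIVE = 14  # tail (0-2) + four limbs (0-3 each); 15 is reserved for death


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal distribution truncated to physical bounds, moment-matched.

    ``mean`` and ``sd`` are the *observed* (post-truncation) moments —
    the group statistics a study reports.  The generator solves for the
    parent normal parameters whose truncation to ``(lower, upper)``
    reproduces those moments exactly, so sampled populations carry both
    the preset mean and the preset SD even when a physical bound (e.g.
    saturation ≤ 100 %) clips the parent distribution.  For bounds
    several SDs away the parent parameters coincide with the presets.
    """

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not self.lower < self.upper:
            raise ValueError("lower must be below upper")
        if not self.lower <= self.mean <= self.upper:
            raise ValueError("mean must lie within the physical bounds")

    @property
    def parent_params(self) -> tuple[float, float]:
        """(mu, sigma) of the untruncated parent normal."""
        return _solve_parent(self.mean, self.sd, self.lower, self.upper)

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    def sample(self, rng: np.random.Generator, size=None, max_retries: int = 10000):
        if self.sd == 0:
            return self.mean if size is None else np.full(size, self.mean)
        mu, sigma = self.parent_params
        n = 1 if size is None else int(np.prod(size))
        out = np.empty(n)
        filled = 0
        for _ in range(max_retries):
            draw = rng.normal(mu, sigma, size=max(n - filled, 16))
            ok = draw[(draw >= self.lower) & (draw <= self.upper)]
            take = min(ok.size, n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
            if filled == n:
                break
        else:
            raise RuntimeError("truncation rejection exceeded the retry cap")
        if size is None:
            return float(out[0])
        return out.reshape(size)


@lru_cache(maxsize=256)
def _solve_parent(mean: float, sd: float, lower: float, upper: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose (lower, upper)-truncation has the given moments."""
    from scipy import optimize
    from scipy import stats as sps

    # quick exit when the bounds are irrelevant (> 5 sigma away)
    if (mean - lower) > 5 * sd and (upper - mean) > 5 * sd:
        return (mean, sd)

    def moments(params):
        mu, sigma = params
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m = sps.truncnorm.mean(a, b, loc=mu, scale=sigma)
        s = sps.truncnorm.std(a, b, loc=mu, scale=sigma)
        return [m - mean, s - sd]

    sol, info, ier, msg = optimize.fsolve(
        moments, x0=[mean, sd], full_output=True, xtol=1e-12
    )
    if ier != 1 or sol[1] <= 0:
        raise RuntimeError(f"truncated-normal moment matching failed: {msg}")
    return (float(sol[0]), float(sol[1]))


@dataclass(frozen=True)
class DiseaseParams:
    """EAE disease-course shape: onset, sigmoidal rise, plateau at peak."""

    onset_day_range: tuple[int, int] = (10, 12)
    plateau_mean: float = 7.9
    plateau_sd: float = 0.7
    plateau_days: tuple[int, int] = (15, 17)
    n_days: int = 17


@dataclass(frozen=True)
class CohortPreset:
    """Group-level distributional preset for one experimental arm."""

    name: str
    n: int
    cbf: TruncatedNormal  # ml·100g^-1·min^-1
    sto2: TruncatedNormal  # %
    tot_cco: TruncatedNormal  # µM
    oxidized_fraction: TruncatedNormal  # dimensionless
    thb: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(100.0, 10.0, lower=30.0)
    )
    sao2: float = 98.0  # %
    rho_cbf_sto2: float = 0.0
    pathlength: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(1.8, 0.15, lower=0.5)
    )
    disease: DiseaseParams | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 < self.sao2 <= 100:
            raise ValueError("sao2 must lie in (0, 100]")
        if not -1 < self.rho_cbf_sto2 < 1:
            raise ValueError("rho_cbf_sto2 must lie in (-1, 1)")
        if not (self.sto2.lower >= 0 and self.sto2.upper <= 100):
            raise ValueError("sto2 truncation bounds must keep values within [0, 100]")
        if self.tot_cco.lower < 0 or self.oxidized_fraction.lower < 0 or self.oxidized_fraction.upper > 1:
            raise ValueError("tot_cco must stay positive and oxidized_fraction within (0, 1)")


def builtin_presets() -> dict[str, CohortPreset]:
    """The three study arms with their reported group means and SDs.

    CBF, StO₂, totCCO and oxidized-fraction parameters are the printed
    group statistics; arterial saturation (98 %) and total hemoglobin
    (100 ± 10 µM) are free presets of the simulator at the scale
    expected for anesthetized rodent cortex.  The CBF–StO₂ correlation
    is 0 in naive animals and +0.5 in the inflamed groups, encoding low
    flow co-occurring with low oxygenation.
    """
    return {
        "naive": CohortPreset(
            name="naive",
            n=15,
            cbf=TruncatedNormal(252.6, 24.6, lower=0.0),
            sto2=TruncatedNormal(82.7, 4.1, lower=0.0, upper=100.0),
            tot_cco=TruncatedNormal(4.6, 0.3, lower=0.0),
            oxidized_fraction=TruncatedNormal(0.74, 0.01, lower=0.0, upper=1.0),
            rho_cbf_sto2=0.0,
            disease=None,
        ),
        "cfa_ptx": CohortPreset(
            name="cfa_ptx",
            n=14,
            cbf=TruncatedNormal(207.7, 35.5, lower=0.0),
            sto2=TruncatedNormal(74.5, 7.8, lower=0.0, upper=100.0),
            tot_cco=TruncatedNormal(4.4, 0.6, lower=0.0),
            oxidized_fraction=TruncatedNormal(0.84, 0.01, lower=0.0, upper=1.0),
            rho_cbf_sto2=0.5,
            disease=None,
        ),
        "eae": CohortPreset(
            name="eae",
            n=13,
            cbf=TruncatedNormal(166.4, 63.3, lower=0.0),
            sto2=TruncatedNormal(63.8, 14.8, lower=0.0, upper=100.0),
            tot_cco=TruncatedNormal(3.9, 0.5, lower=0.0),
            oxidized_fraction=TruncatedNormal(0.85, 0.01, lower=0.0, upper=1.0),
            rho_cbf_sto2=0.5,
            disease=DiseaseParams(),
        ),
    }


@dataclass(frozen=True)
class AnimalPhysiology:
    """Ground-truth physiology of one simulated animal."""

    animal_id: str
    group: str
    cbf: float
    sto2: float
    thb: float
    tot_cco: float
    oxidized_fraction: float
    sao2: float
    pathlength_L: float
    baseline: tuple[float, float]
    seed: int

    def __post_init__(self):
        if not 0 <= self.sto2 <= 100:
            raise ValueError("sto2 must lie in [0, 100]")
        for name in ("cbf", "thb", "tot_cco", "pathlength_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def dhb(self) -> float:
        return self.thb * (1.0 - self.sto2 / 100.0)

    @property
    def hbo2(self) -> float:
        return self.thb - self.dhb

    @property
    def ox_cco(self) -> float:
        return self.tot_cco * self.oxidized_fraction

    @property
    def re_cco(self) -> float:
        return self.tot_cco - self.ox_cco

    def tissue_state(self, water_fraction: float = 0.80) -> TissueState:
        return TissueState(
            concentrations={
                "dHb": self.dhb,
                "HbO2": self.hbo2,
                "oxCCO": self.ox_cco,
                "reCCO": self.re_cco,
                "water": water_fraction,
            },
            pathlength_L=self.pathlength_L,
            baseline=self.baseline,
        )


def _rng_from(seed) -> tuple[np.random.Generator, int]:
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(int(seed))
    entropy = int(ss.generate_state(1, dtype=np.uint32)[0])
    return np.random.Generator(np.random.PCG64(ss)), entropy


def sample_animal(
    preset: CohortPreset, seed, animal_id: str | None = None, max_retries: int = 10000
) -> AnimalPhysiology:
    """Draw one animal's ground truth from a preset, deterministically per seed.

    (CBF, StO₂) come from a bivariate normal with the preset correlation,
    rejected until both marginals fall inside their truncation bounds;
    the remaining quantities are independent truncated-normal draws.
    """
    rng, entropy = _rng_from(seed)
    rho = preset.rho_cbf_sto2
    cbf_mu, cbf_sigma = preset.cbf.parent_params
    st_mu, st_sigma = preset.sto2.parent_params
    cbf_lo, cbf_hi = preset.cbf.bounds
    st_lo, st_hi = preset.sto2.bounds
    for _ in range(max_retries):
        z1, z2 = rng.standard_normal(2)
        cbf = cbf_mu + cbf_sigma * z1
        sto2 = st_mu + st_sigma * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        if cbf_lo <= cbf <= cbf_hi and st_lo <= sto2 <= st_hi:
            break
    else:
        raise RuntimeError("bivariate truncation rejection exceeded the retry cap")
    return AnimalPhysiology(
        animal_id=animal_id or f"{preset.name}_{entropy:08x}",
        group=preset.name,
        cbf=float(cbf),
        sto2=float(sto2),
        thb=preset.thb.sample(rng),
        tot_cco=preset.tot_cco.sample(rng),
        oxidized_fraction=preset.oxidized_fraction.sample(rng),
        sao2=preset.sao2,
        pathlength_L=preset.pathlength.sample(rng),
        baseline=(float(rng.uniform(0.2, 0.4)), float(rng.uniform(-5e-4, 5e-4))),
        seed=entropy,
    )


@dataclass(frozen=True)
class NirsRecording:
    """Frame-wise attenuation spectra of one recording session."""

    times: np.ndarray  # s
    wavelengths: np.ndarray  # nm
    attenuation: np.ndarray  # (n_frames, n_wavelengths), OD
    protocol: NirsProtocol

    def frame_slice(self, window) -> np.ndarray:
        lo, hi = window
        return (self.times >= lo) & (self.times < hi)  # half-open [start, end)


def _sto2_trajectory(times, physio, protocol, anoxia_tau_s: float = 4.0) -> np.ndarray:
    sto2 = np.full(times.shape, physio.sto2)
    if protocol.anoxia_window is not None:
        t0, t1 = protocol.anoxia_window
        inside = (times >= t0) & (times <= t1)
        sto2[inside] = physio.sto2 * np.exp(-(times[inside] - t0) / anoxia_tau_s)
        sto2[times > t1] = physio.sto2 * np.exp(-(t1 - t0) / anoxia_tau_s)
    return sto2


def simulate_nirs_timeseries(
    physio: AnimalPhysiology,
    table: ExtinctionTable,
    protocol: NirsProtocol | None = None,
    noise_sd_od: float = 1e-3,
    seed=0,
    decimation: int = 1,
    water_fraction: float = 0.80,
    anoxia_tau_s: float = 4.0,
) -> NirsRecording:
    """Frame-wise forward spectra for one animal.

    Baseline frames hold dHb = tHb·(1 − StO₂/100) constant; during the
    anoxia pulse tissue saturation decays exponentially to ~0 (time
    constant ``anoxia_tau_s``) so that dHb plateaus at tHb, the basis of
    the total-hemoglobin calibration.  CCO states, scattering and water
    stay constant.  Independent Gaussian OD noise is added per frame and
    wavelength.  ``decimation`` thins the 6 Hz frame grid uniformly (the
    estimators average within windows, so thinning adds variance but no
    bias).
    """
    if noise_sd_od < 0:
        raise ValueError("noise_sd_od must be >= 0")
    if decimation < 1:
        raise ValueError("decimation must be >= 1")
    protocol = protocol or NirsProtocol()
    rng, _ = _rng_from(seed)
    dt = decimation / protocol.sampling_rate
    times = np.arange(0.0, protocol.total_duration, dt)
    sto2_t = _sto2_trajectory(times, physio, protocol, anoxia_tau_s)
    dhb_t = physio.thb * (1.0 - sto2_t / 100.0)
    hbo2_t = physio.thb - dhb_t

    lam = table.wavelengths
    state0 = physio.tissue_state(water_fraction)
    static = dict(state0.concentrations)
    static["dHb"] = 0.0
    static["HbO2"] = 0.0
    base = attenuation_forward(
        TissueState(static, physio.pathlength_L, physio.baseline), table
    ).attenuation
    atten = (
        base[None, :]
        + physio.pathlength_L * np.outer(dhb_t, table.epsilon["dHb"])
        + physio.pathlength_L * np.outer(hbo2_t, table.epsilon["HbO2"])
    )
    if noise_sd_od > 0:
        atten = atten + rng.normal(0.0, noise_sd_od, size=atten.shape)
    return NirsRecording(times, lam, atten, protocol)


@dataclass(frozen=True)
class SimulatedAsl:
    """One animal's simulated ASL acquisition plus its ground truth."""

    stack: AslStack
    cortex_mask: np.ndarray
    brain_mask: np.ndarray
    true_cbf_map: np.ndarray
    t1_cortex: float
    m0: float


def _phantom_masks(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    r_brain = 0.41 * min(h, w)
    brain = r <= r_brain
    cortex = (r >= 0.30 * min(h, w)) & brain & (yy < cy)
    return brain, cortex


def simulate_asl_stack(
    physio: AnimalPhysiology,
    geometry: AslGeometry | None = None,
    params: AslModelParams | None = None,
    t1_cortex: float = 1.9,
    m0: float = 1000.0,
    noise_sd: float = 20.0,
    n_averages: int = 16,
    seq_tr_s: float = 3.0,
    heterogeneity: float = 0.10,
    seed=0,
) -> SimulatedAsl:
    """Digital single-slice perfusion phantom for one animal.

    A brain disc carries a dorsal cortical band at the animal's true CBF
    (plus a zero-mean smooth heterogeneity pattern) over a background at
    60 % of cortical flow.  Control images, tag images and the
    variable-TR T1 series are generated with exactly the saturation-
    recovery and CASL equations that :mod:`oxymet.asl` inverts; Gaussian
    noise is scaled by 1/sqrt(n_averages).
    """
    geometry = geometry or AslGeometry()
    params = params or AslModelParams()
    rng, _ = _rng_from(seed)
    shape = geometry.matrix
    brain, cortex = _phantom_masks(shape)
    if not np.any(cortex):
        raise ValueError("cortex mask empty under this geometry")

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    pattern = np.sin(2 * np.pi * xx / 32.0) * np.cos(2 * np.pi * yy / 32.0)
    pattern = pattern - pattern[cortex].mean()  # exactly zero-mean over the ROI
    cbf_map = np.zeros(shape)
    cbf_map[brain] = 0.6 * physio.cbf
    cbf_map[cortex] = physio.cbf * (1.0 + heterogeneity * pattern[cortex])

    t1_map = np.where(brain, t1_cortex, np.nan)
    mctrl = np.zeros(shape)
    mctrl[brain] = m0 * (1.0 - np.exp(-seq_tr_s / t1_cortex))
    dm = np.zeros(shape)
    dm[brain] = (
        cbf_map[brain]
        * 2.0
        * params.alpha_label
        * t1_cortex
        * mctrl[brain]
        / (params.unit_scale * params.lambda_partition)
    )
    sigma = noise_sd / np.sqrt(n_averages)

    def noisy(img):
        return img + rng.normal(0.0, sigma, size=img.shape) if sigma > 0 else img.copy()

    controls = np.stack([noisy(mctrl), noisy(mctrl)])
    tags = np.stack([noisy(mctrl - dm), noisy(mctrl - dm)])
    tr = np.asarray(DEFAULT_TR_LIST_S)
    series = np.stack(
        [noisy(np.where(brain, m0 * (1.0 - np.exp(-t / t1_cortex)), 0.0)) for t in tr]
    )
    stack = AslStack(controls, tags, series, tuple(tr), geometry)
    return SimulatedAsl(stack, cortex, brain, cbf_map, t1_cortex, m0)


@dataclass(frozen=True)
class DiseaseCourse:
    """Daily disease scores on the 15-point scale (tail + four limbs)."""

    days: np.ndarray  # integer days, 0..n_days
    total: np.ndarray
    tail: np.ndarray
    limbs: np.ndarray  # (n_days+1, 4)

    def __post_init__(self):
        total = np.asarray(self.total)
        tail = np.asarray(self.tail)
        limbs = np.asarray(self.limbs)
        if np.any(total != tail + limbs.sum(axis=1)):
            raise ValueError("total must equal tail + sum of limb scores")
        if np.any(tail < 0) or np.any(tail > 2) or np.any(limbs < 0) or np.any(limbs > 3):
            raise ValueError("component scores out of range")
        if np.any(total > MAX_SCORE_ALIVE):
            raise ValueError("total score above 14 is reserved for death")


def _decompose_score(total: int) -> tuple[int, list[int]]:
    tail = min(2, total)
    rest = total - tail
    limbs = []
    for _ in range(4):
        take = min(3, rest)
        limbs.append(take)
        rest -= take
    return tail, limbs


def simulate_disease_course(preset: CohortPreset, seed) -> DiseaseCourse:
    """Daily 15-point disease scores for one animal.

    Control arms (no ``disease`` parameters) score zero on every day.
    EAE animals stay at zero until a per-animal onset day, rise linearly
    to a per-animal plateau drawn from the preset plateau distribution,
    and hold that plateau over the peak-disease days.  Integer totals
    are decomposed into a valid tail (0–2) + four-limb (0–3) breakdown.
    """
    n_days = preset.disease.n_days if preset.disease else 17
    days = np.arange(0, n_days + 1)
    totals = np.zeros(days.size, dtype=int)
    if preset.disease is not None:
        p = preset.disease
        rng, _ = _rng_from(seed)
        onset = int(rng.integers(p.onset_day_range[0], p.onset_day_range[1] + 1))
        plateau_dist = TruncatedNormal(
            p.plateau_mean, p.plateau_sd, lower=0.0, upper=float(MAX_SCORE_ALIVE)
        )
        plateau = plateau_dist.sample(rng)
        peak_start = p.plateau_days[0]
        for i, d in enumerate(days):
            if d < onset:
                continue
            if d >= peak_start:
                totals[i] = int(round(plateau))
            else:
                frac = (d - onset + 1) / (peak_start - onset + 1)
                totals[i] = int(round(plateau * frac))
    tails = np.zeros(days.size, dtype=int)
    limbs = np.zeros((days.size, 4), dtype=int)
    for i, tot in enumerate(totals):
        tails[i], limb = _decompose_score(int(tot))
        limbs[i] = limb
    return DiseaseCourse(days, totals, tails, limbs)


def write_spectra_csv(recording: NirsRecording, path) -> None:
    """Spectra time series as CSV: a `time_s` column plus one OD column per nm."""
    cols = {"time_s": recording.times}
    for j, lam in enumerate(recording.wavelengths):
        cols[f"od_{lam:.0f}nm"] = recording.attenuation[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def read_spectra_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`write_spectra_csv`: (times, wavelengths, attenuation)."""
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy(dtype=float)
    lam_cols = [c for c in df.columns if c.startswith("od_")]
    wavelengths = np.array([float(c[3:-2]) for c in lam_cols])
    return times, wavelengths, df[lam_cols].to_numpy(dtype=float)


def generate_cohort(
    presets: Mapping[str, CohortPreset],
    out_dir,
    seed: int,
    table: ExtinctionTable,
    protocol: NirsProtocol | None = None,
    noise_sd_od: float = 1e-3,
    asl_noise_sd: float = 20.0,
    decimation: int = 10,
) -> pd.DataFrame:
    """Write a full on-disk synthetic dataset and return its manifest.

    Layout::

        out_dir/
          manifest.csv  presets.json
          <group>/<animal_id>/
            spectra.csv  scores.csv  sidecar.json
            asl/{controls,tags,tr_series,cortex_mask}.nii.gz

    Fully reproducible from (presets, seed); the manifest records every
    ground-truth value for recovery testing and is never read by the
    analysis pipeline.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = protocol or NirsProtocol()
    root_ss = np.random.SeedSequence(int(seed))
    rows = []
    for preset in presets.values():
        key = zlib.crc32(preset.name.encode()) & 0x7FFFFFFF  # stable across processes
        animal_seeds = np.random.SeedSequence(
            entropy=root_ss.entropy, spawn_key=(key,)
        ).spawn(preset.n)
        for i, a_ss in enumerate(animal_seeds):
            animal_id = f"{preset.name}_{i + 1:02d}"
            phys_ss, nirs_ss, asl_ss, score_ss = a_ss.spawn(4)
            physio = sample_animal(preset, phys_ss, animal_id=animal_id)
            adir = out / preset.name / animal_id
            (adir / "asl").mkdir(parents=True, exist_ok=True)

            rec = simulate_nirs_timeseries(
                physio, table, protocol, noise_sd_od, seed=nirs_ss, decimation=decimation
            )
            write_spectra_csv(rec, adir / "spectra.csv")

            sim = simulate_asl_stack(physio, noise_sd=asl_noise_sd, seed=asl_ss)
            affine = sim.stack.geometry.affine
            for name, img in (
                ("controls", np.moveaxis(sim.stack.controls, 0, -1)),
                ("tags", np.moveaxis(sim.stack.tags, 0, -1)),
                ("tr_series", np.moveaxis(sim.stack.tr_series, 0, -1)),
                ("cortex_mask", sim.cortex_mask.astype(np.uint8)),
            ):
                nib.save(nib.Nifti1Image(np.asarray(img, dtype=np.float32), affine),
                         str(adir / "asl" / f"{name}.nii.gz"))

            course = simulate_disease_course(preset, score_ss)
            pd.DataFrame(
                {
                    "day": course.days,
                    "total": course.total,
                    "tail": course.tail,
                    **{f"limb{k + 1}": course.limbs[:, k] for k in range(4)},
                }
            ).to_csv(adir / "scores.csv", index=False)

            sidecar = {
                "animal_id": animal_id,
                "group": preset.name,
                "tr_list_ms": [t * 1000.0 for t in sim.stack.tr_list],
                "fov_mm": list(sim.stack.geometry.fov_mm),
                "matrix": list(sim.stack.geometry.matrix),
                "slice_thickness_mm": sim.stack.geometry.slice_thickness_mm,
                "sampling_rate_hz": protocol.sampling_rate / decimation,
                "anoxia_window_s": list(protocol.anoxia_window or ()),
                "averaging_window_s": list(protocol.averaging_window),
                "sao2_pct": physio.sao2,
            }
            (adir / "sidecar.json").write_text(json.dumps(sidecar, indent=1))

            rows.append(
                {
                    "animal_id": animal_id,
                    "group": preset.name,
                    "seed": physio.seed,
                    "cbf": physio.cbf,
                    "sto2": physio.sto2,
                    "thb": physio.thb,
                    "dhb": physio.dhb,
                    "ox_cco": physio.ox_cco,
                    "re_cco": physio.re_cco,
                    "tot_cco": physio.tot_cco,
                    "oxidized_fraction": physio.oxidized_fraction,
                    "sao2": physio.sao2,
                    "pathlength_cm": physio.pathlength_L,
                    "baseline_a": physio.baseline[0],
                    "baseline_b": physio.baseline[1],
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "presets.json").write_text(
        json.dumps({k: asdict(v) for k, v in presets.items()}, indent=1, default=str)
    )
    return manifest
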