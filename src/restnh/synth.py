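"""Synthetic resting-state cohorts with known, parameterized group effects.

The generator emulates the acquisition and effect structure this pipeline is
designed to analyze: two groups (40 patients, 38 controls), TR 2 s, 240
volumes on a 3 mm grid, a multi-region network mask, a regional low-frequency
amplitude effect (drives fALFF), regional shared-signal effects of both signs
(drive network homogeneity up in one region and down in another), and clinical
scores negatively correlated with the implanted coupling perturbation.

Per voxel the signal is

    x(t) = baseline + noise_sd * AR1(t) + a * [ sqrt(f) * C_r(t) + sqrt(1-f) * U(t) ]

with AR1 a unit-variance AR(1) noise process, C_r a band-limited (0.01-0.08 Hz)
signal common to region r, U a band-limited voxel-specific signal, f the
region's shared-variance fraction, and a the low-frequency amplitude (times
``falff_amplitude_ratio`` for patients in the amplitude-effect region).
Effects live in variance components, never in added means, because fALFF and
NH are both mean-invariant.  Voxels outside the network mask carry baseline
noise only: the mask defines where structured signal lives.

Note one deliberate piece of coupled physics: a region's shared-signal
fraction also controls how much of its low-frequency variance survives
spatial smoothing (coherent signal averages up, idiosyncratic signal averages
down), so coupling effects leave a secondary imprint on smoothed-amplitude
maps.  Recovery tests therefore check each implanted effect in its own map
and tail rather than assuming the maps are independent.

Everything is deterministic given (config, subject_id).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import optimize, signal

from .io import (
    CONTROL,
    PATIENT,
    BoldSeries,
    MotionParams,
    NetworkMask,
    SubjectRecord,
    write_bold,
    write_json,
    write_manifest,
    write_mask,
    write_motion,
)

__all__ = [
    "RegionSpec",
    "NhEffect",
    "SyntheticConfig",
    "SubjectData",
    "Cohort",
    "generate_mask",
    "generate_bold",
    "generate_cohort",
]

# Clinical score distributions mirroring a typical medicine-free OCD cohort
# (patient vs control mean, SD); scores are clipped at 0.
_SCORE_DISTS = {
    "ybocs_obsessive": ((12.85, 4.25), (0.37, 0.49)),
    "ybocs_compulsive": ((12.05, 4.62), (0.74, 0.72)),
    "hamd": ((8.05, 4.40), (1.45, 0.95)),
    "hama": ((10.83, 6.55), (1.16, 1.00)),
}
_AGE_MEAN_SD = (27.2, 8.2)
_EDU_MEAN_SD = (13.6, 2.9)
_DURATION_MEAN_SD = (66.7, 75.5)
_P_MALE = {PATIENT: 27 / 40, CONTROL: 25 / 38}


@dataclass(frozen=True)
class RegionSpec:
    """A discrete sphere: name, 0-based center voxel, radius in voxels."""

    name: str
    center: tuple[int, int, int]
    radius: float


@dataclass(frozen=True)
class NhEffect:
    """Shared-variance fractions for one region, per group."""

    region: str
    patient_fraction: float
    control_fraction: float


def _default_regions() -> tuple[RegionSpec, ...]:
    return (
        RegionSpec("right_frontal", (11, 4, 6), 3.0),
        RegionSpec("left_frontal", (4, 4, 6), 3.0),
        RegionSpec("right_striatum", (11, 11, 6), 3.0),
        RegionSpec("limbic", (4, 11, 6), 3.0),
    )


def _default_nh_effects() -> tuple[NhEffect, ...]:
    return (
        NhEffect("left_frontal", 0.5, 0.3),
        NhEffect("right_striatum", 0.1, 0.3),
    )


@dataclass
class SyntheticConfig:
    """Generation conditions for one synthetic cohort."""

    n_patients: int = 40
    n_controls: int = 38
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    voxel_size_mm: float = 3.0
    tr_seconds: float = 2.0
    n_volumes: int = 240
    region_specs: tuple[RegionSpec, ...] = field(default_factory=_default_regions)
    falff_effect_region: str = "right_frontal"
    falff_amplitude_ratio: float = 1.5
    nh_effects: tuple[NhEffect, ...] = field(default_factory=_default_nh_effects)
    baseline_shared_fraction: float = 0.3
    clinical_link_region: str = "right_striatum"
    clinical_nh_correlation: float = -0.33
    latent_fraction_scale: float = 0.08
    low_freq_amplitude: float = 1.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    ar_coef: float = 0.3
    noise_sd: float = 1.0
    baseline_level: float = 100.0
    motion_scale_mm: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("need at least one subject per group")
        if self.n_volumes < 64:
            raise ValueError(
                "n_volumes must be >= 64 for adequate spectral resolution in the "
                "0.01-0.08 Hz band"
            )
        names = [r.name for r in self.region_specs]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        for eff in self.nh_effects:
            for f in (eff.patient_fraction, eff.control_fraction):
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"shared fraction out of [0,1]: {f}")
            if eff.region not in names:
                raise ValueError(f"nh effect region {eff.region!r} not in region_specs")
        if not 0.0 <= self.baseline_shared_fraction <= 1.0:
            raise ValueError("baseline_shared_fraction out of [0,1]")
        if not -1.0 < self.clinical_nh_correlation < 1.0:
            raise ValueError("clinical_nh_correlation must be in (-1, 1)")
        if self.falff_amplitude_ratio <= 0:
            raise ValueError("falff_amplitude_ratio must be positive")
        if self.motion_scale_mm < 0:
            raise ValueError("motion_scale_mm must be nonnegative")
        if self.falff_effect_region not in names:
            raise ValueError(f"falff_effect_region {self.falff_effect_region!r} not in region_specs")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def region_labels(self) -> dict[str, int]:
        return {r.name: i + 1 for i, r in enumerate(self.region_specs)}


# ---------------------------------------------------------------------------
# Seeding: one top-level seed, stable named substreams per subject
# ---------------------------------------------------------------------------


def _rng(config: SyntheticConfig, *keys: str) -> np.random.Generator:
    parts = [int(config.seed) & 0x7FFFFFFF]
    parts.extend(zlib.crc32(k.encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(parts))


def latent_effect(config: SyntheticConfig, subject_id: str) -> float:
    """Subject-level standard-normal latent driving both the NH perturbation in
    the clinically linked region and the symptom scores."""
    return float(_rng(config, subject_id, "latent").standard_normal())


# ---------------------------------------------------------------------------
# Mask
# ---------------------------------------------------------------------------


def generate_mask(config: SyntheticConfig) -> NetworkMask:
    """Build the toy multi-region network mask: one discrete sphere per region,
    labels 1..K in spec order.  Overlapping regions are an error."""
    shape = tuple(config.grid_shape)
    labels = np.zeros(shape, dtype=np.int32)
    grids = np.indices(shape)
    owner: dict[str, np.ndarray] = {}
    for k, region in enumerate(config.region_specs, start=1):
        c = np.asarray(region.center, dtype=float).reshape(3, 1, 1, 1)
        dist2 = ((grids - c) ** 2).sum(axis=0)
        sphere = dist2 <= region.radius**2 + 1e-9
        if not np.any(sphere):
            raise ValueError(f"region {region.name!r} contains no voxels")
        clash = sphere & (labels > 0)
        if np.any(clash):
            other_label = int(labels[clash][0])
            other = config.region_specs[other_label - 1].name
            raise ValueError(f"overlapping regions: {other!r} and {region.name!r}")
        labels[sphere] = k
        owner[region.name] = sphere
    # center the grid on the origin so MNI coordinates are symmetric
    v = config.voxel_size_mm
    affine = np.diag([v, v, v, 1.0])
    affine[:3, 3] = -v * (np.asarray(shape) - 1) / 2.0
    names = {k: r.name for k, r in enumerate(config.region_specs, start=1)}
    return NetworkMask(label_data=labels, affine=affine, region_names=names)


# ---------------------------------------------------------------------------
# Per-subject signal generation
# ---------------------------------------------------------------------------


def _band_limited(rng: np.random.Generator, n_series: int, config: SyntheticConfig) -> np.ndarray:
    """Unit-variance signals with all spectral content in the passband."""
    T = config.n_volumes
    freqs = np.fft.rfftfreq(T, d=config.tr_seconds)
    in_band = (freqs >= config.band_hz[0] - 1e-12) & (freqs <= config.band_hz[1] + 1e-12)
    in_band[0] = False
    coeffs = np.zeros((n_series, freqs.size), dtype=complex)
    nb = int(in_band.sum())
    coeffs[:, in_band] = rng.standard_normal((n_series, nb)) + 1j * rng.standard_normal((n_series, nb))
    x = np.fft.irfft(coeffs, n=T, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _ar1_noise(rng: np.random.Generator, n_series: int, config: SyntheticConfig) -> np.ndarray:
    """Unit marginal-variance AR(1) noise; 20-sample burn-in discarded."""
    phi = config.ar_coef
    burn = 20
    innov = rng.standard_normal((n_series, config.n_volumes + burn)).astype(np.float32)
    x = signal.lfilter([np.sqrt(1.0 - phi**2)], [1.0, -phi], innov, axis=1)
    return x[:, burn:]


def _subject_fractions(config: SyntheticConfig, record: SubjectRecord) -> dict[str, float]:
    """Shared-variance fraction per region for one subject."""
    fractions = {r.name: config.baseline_shared_fraction for r in config.region_specs}
    for eff in config.nh_effects:
        fractions[eff.region] = (
            eff.patient_fraction if record.is_patient else eff.control_fraction
        )
    if record.is_patient and config.clinical_link_region in fractions:
        e = latent_effect(config, record.subject_id)
        f = fractions[config.clinical_link_region] + config.latent_fraction_scale * e
        fractions[config.clinical_link_region] = float(np.clip(f, 0.0, 1.0))
    return fractions


def generate_bold(
    config: SyntheticConfig,
    mask: NetworkMask,
    record: SubjectRecord,
) -> tuple[BoldSeries, MotionParams]:
    """Generate one subject's 4D BOLD series and motion random walk.

    Deterministic for a given (config, subject_id).
    """
    shape = tuple(config.grid_shape)
    V = int(np.prod(shape))
    rng = _rng(config, record.subject_id, "bold")

    labels_flat = mask.label_data.reshape(-1)
    inside = labels_flat > 0

    # structured (band-limited) signal lives inside the network mask; outside
    # voxels carry baseline noise only
    noise = _ar1_noise(rng, V, config)
    common = _band_limited(rng, len(config.region_specs), config)
    idio = _band_limited(rng, int(inside.sum()), config)

    fractions = _subject_fractions(config, record)
    f_by_label = np.zeros(len(config.region_specs) + 1)
    for name, lab in config.region_labels.items():
        f_by_label[lab] = fractions[name]
    f_in = f_by_label[labels_flat[inside]]

    amp_in = np.full(int(inside.sum()), config.low_freq_amplitude)
    if record.is_patient:
        lab = config.region_labels[config.falff_effect_region]
        amp_in[labels_flat[inside] == lab] *= config.falff_amplitude_ratio

    data = noise.astype(np.float64)
    data *= config.noise_sd
    data += config.baseline_level
    common_in = common[labels_flat[inside] - 1]
    low = np.sqrt(f_in)[:, None] * common_in + np.sqrt(1.0 - f_in)[:, None] * idio
    data[inside] += amp_in[:, None] * low
    bold = BoldSeries(
        voxel_data=data.reshape(shape + (config.n_volumes,)),
        affine=mask.affine,
        tr_seconds=config.tr_seconds,
        subject_id=record.subject_id,
    )

    mrng = _rng(config, record.subject_id, "motion")
    trans = np.cumsum(mrng.normal(0.0, config.motion_scale_mm, (config.n_volumes, 3)), axis=0)
    rot = np.cumsum(mrng.normal(0.0, config.motion_scale_mm / 50.0, (config.n_volumes, 3)), axis=0)
    if config.motion_scale_mm == 0:
        trans[:] = 0.0
        rot[:] = 0.0
    return bold, MotionParams(translations_mm=trans, rotations_rad=rot)


def generate_nuisance(config: SyntheticConfig, subject_id: str) -> tuple[np.ndarray, np.ndarray]:
    """White-matter and CSF mean time series (AR(1), unit variance)."""
    rng = _rng(config, subject_id, "nuisance")
    wm, csf = _ar1_noise(rng, 2, config)
    return wm, csf


# ---------------------------------------------------------------------------
# Cohort: manifest + lazy per-subject data
# ---------------------------------------------------------------------------


def _subscale_latent_coef(config: SyntheticConfig) -> float:
    """Per-subscale loading on the latent so that the *total* score's
    correlation with the latent hits ``clinical_nh_correlation``.

    The total is the sum of the obsessive and compulsive subscales, each drawn
    with the same latent loading rho:

        corr(total, e) = rho (so + sc) / sqrt(so^2 + sc^2 + 2 rho^2 so sc)
    """
    target = abs(config.clinical_nh_correlation)
    if target == 0:
        return 0.0
    so = _SCORE_DISTS["ybocs_obsessive"][0][1]
    sc = _SCORE_DISTS["ybocs_compulsive"][0][1]

    def gap(rho: float) -> float:
        tot_sd = np.sqrt(so**2 + sc**2 + 2 * rho**2 * so * sc)
        return rho * (so + sc) / tot_sd - target

    hi = 0.999999
    if gap(hi) < 0:
        raise ValueError(
            f"clinical_nh_correlation {config.clinical_nh_correlation} not attainable "
            "from subscale sums"
        )
    rho = optimize.brentq(gap, 0.0, hi)
    return float(np.sign(config.clinical_nh_correlation) * rho)


def _draw_record(config: SyntheticConfig, subject_id: str, group: str, rho: float) -> SubjectRecord:
    rng = _rng(config, subject_id, "clinical")
    sex = "male" if rng.random() < _P_MALE[group] else "female"
    age = float(np.clip(rng.normal(*_AGE_MEAN_SD), 18.0, 50.0))
    edu = float(np.clip(rng.normal(*_EDU_MEAN_SD), 6.0, 22.0))
    e = latent_effect(config, subject_id)
    scores: dict[str, float] = {}
    for name, (pat, ctl) in _SCORE_DISTS.items():
        mu, sd = pat if group == PATIENT else ctl
        if group == PATIENT and name.startswith("ybocs"):
            z = rho * e + np.sqrt(1.0 - rho**2) * rng.standard_normal()
        else:
            z = rng.standard_normal()
        scores[name] = float(np.clip(mu + sd * z, 0.0, None))
    duration = None
    if group == PATIENT:
        duration = float(np.clip(rng.normal(*_DURATION_MEAN_SD), 1.0, None))
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        age_years=round(age, 2),
        sex=sex,
        education_years=round(edu, 2),
        illness_duration_months=None if duration is None else round(duration, 1),
        ybocs_total=round(scores["ybocs_obsessive"] + scores["ybocs_compulsive"], 2),
        ybocs_obsessive=round(scores["ybocs_obsessive"], 2),
        ybocs_compulsive=round(scores["ybocs_compulsive"], 2),
        hamd=round(scores["hamd"], 2),
        hama=round(scores["hama"], 2),
    )


@dataclass
class SubjectData:
    """One subject's generated raw inputs."""

    bold: BoldSeries
    motion: MotionParams
    wm: np.ndarray
    csf: np.ndarray


class Cohort:
    """A generated cohort: manifest records plus on-demand per-subject data.

    Per-subject 4D series are generated lazily (a materialized 78-subject
    cohort would hold ~0.5 GB) and are deterministic per subject id.
    """

    def __init__(self, config: SyntheticConfig):
        self.config = config
        self.mask = generate_mask(config)
        rho = _subscale_latent_coef(config)
        self.records: list[SubjectRecord] = []
        for i in range(config.n_patients):
            self.records.append(_draw_record(config, f"sub-p{i + 1:03d}", PATIENT, rho))
        for i in range(config.n_controls):
            self.records.append(_draw_record(config, f"sub-c{i + 1:03d}", CONTROL, rho))
        self._by_id = {r.subject_id: r for r in self.records}

    def subject_data(self, subject_id: str) -> SubjectData:
        record = self._by_id[subject_id]
        bold, motion = generate_bold(self.config, self.mask, record)
        wm, csf = generate_nuisance(self.config, subject_id)
        return SubjectData(bold=bold, motion=motion, wm=wm, csf=csf)

    def nh_perturbation(self, subject_id: str) -> float:
        """The implanted shared-fraction perturbation in the clinically linked
        region (0 for controls); used by recovery tests."""
        record = self._by_id[subject_id]
        if not record.is_patient:
            return 0.0
        return self.config.latent_fraction_scale * latent_effect(self.config, subject_id)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def write(self, outdir: str | Path, compress: bool = True) -> Path:
        """Write the full cohort to disk: NIfTI BOLD + motion text + manifest
        TSV + mask + the generating config as JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = ".nii.gz" if compress else ".nii"
        records = []
        for record in self.records:
            data = self.subject_data(record.subject_id)
            bold_path = outdir / f"{record.subject_id}_bold{ext}"
            motion_path = outdir / f"{record.subject_id}_motion.txt"
            nuis_path = outdir / f"{record.subject_id}_nuisance.txt"
            write_bold(data.bold, bold_path)
            write_motion(data.motion, motion_path)
            np.savetxt(nuis_path, np.column_stack([data.wm, data.csf]), fmt="%.10g")
            from dataclasses import replace

            records.append(
                replace(record, bold_path=bold_path.name, motion_path=motion_path.name)
            )
        write_mask(self.mask, outdir / f"mask{ext}")
        write_manifest(records, outdir / "manifest.tsv")
        write_json(self.config.to_dict(), outdir / "config.json")
        return outdir


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a cohort: manifest records with clinical scores linked to the
    implanted coupling perturbation, plus lazy per-subject images."""
    return Cohort(config)
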