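"""Synthetic serum-like free induction decays (FIDs) and FID file I/O.

The time-domain model is the standard sum of damped complex sinusoids
(Lorentzian lines):

    x(n) = sum_p A_p * exp(i*(2*pi*nu_p*n*dt + phi_p)) * exp(-n*dt / T2_p)
           + water term + complex Gaussian noise,

with dwell time ``dt = 1/spectral_width``.  Residual water is a resonance
at 0 Hz offset whose amplitude is multiplied by an attenuation factor in
[0, 1]; this emulates the net effect of DANTE presaturation during
acquisition without simulating the pulse train itself.  Noise is i.i.d.
circular complex Gaussian (quadrature thermal noise): each channel has
standard deviation ``noise_sd`` per point.

Cohorts carry a controlled two-or-more-group structure: a named subset of
resonances receives per-group multiplicative amplitude and T2 modifiers,
and every sample additionally receives small seeded multiplicative
amplitude jitter, so downstream multivariate models see realistic
within-group spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AliasingError, ConfigurationError, InvalidParameterError, ParseError

__all__ = [
    "ResonanceSpec",
    "WaterResidual",
    "GroupEffect",
    "CohortDesign",
    "FIDRecord",
    "simulate_fid",
    "simulate_cohort",
    "write_fid",
    "read_fid",
    "write_manifest",
    "read_manifest",
    "read_jdf",
    "serum_resonances",
    "default_water",
    "two_state_design",
]

DEFAULT_N_POINTS = 16_384
DEFAULT_SPECTRAL_WIDTH_HZ = 10_016.0


@dataclass(frozen=True)
class ResonanceSpec:
    """One Lorentzian resonance line.

    Parameters
    ----------
    amplitude : float
        Signal amplitude in arbitrary units, >= 0.
    frequency_hz : float
        Offset from the carrier; must satisfy ``|f| < spectral_width/2``.
    phase_rad : float
        Initial phase in radians.
    t2_s : float
        Transverse (T2) decay constant in seconds, > 0.  ``math.inf``
        disables decay.
    name : str
        Optional label used to address this resonance in group effects.
    """

    amplitude: float
    frequency_hz: float
    phase_rad: float = 0.0
    t2_s: float = math.inf
    name: str = ""

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidParameterError(f"amplitude must be >= 0, got {self.amplitude}")
        if not self.t2_s > 0:
            raise InvalidParameterError(f"t2_s must be > 0, got {self.t2_s}")


@dataclass(frozen=True)
class WaterResidual:
    """Residual water line at 0 Hz with a suppression attenuation factor."""

    resonance: ResonanceSpec
    attenuation: float = 1.0

    def __post_init__(self) -> None:
        if self.resonance.frequency_hz != 0.0:
            raise InvalidParameterError(
                f"water residual must sit at 0 Hz, got {self.resonance.frequency_hz} Hz"
            )
        if not 0.0 <= self.attenuation <= 1.0:
            raise InvalidParameterError(
                f"attenuation must lie in [0, 1], got {self.attenuation}"
            )

    def effective(self) -> ResonanceSpec:
        """Water resonance with the attenuation folded into its amplitude."""
        return replace(
            self.resonance, amplitude=self.resonance.amplitude * self.attenuation
        )


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative modifiers applied to named resonances in one group."""

    amplitude_scale: Mapping[str, float] = field(default_factory=dict)
    t2_scale: Mapping[str, float] = field(default_factory=dict)

    def touched(self) -> set[str]:
        return set(self.amplitude_scale) | set(self.t2_scale)

    def apply(self, res: ResonanceSpec) -> ResonanceSpec:
        a = self.amplitude_scale.get(res.name, 1.0)
        t = self.t2_scale.get(res.name, 1.0)
        if a == 1.0 and t == 1.0:
            return res
        t2 = res.t2_s * t if math.isfinite(res.t2_s) else res.t2_s
        return replace(res, amplitude=res.amplitude * a, t2_s=t2)


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic cohort with group-dependent resonances.

    ``group_effects`` maps group label -> :class:`GroupEffect`; its keys
    define the groups.  Identical design (including ``seed``) yields a
    bit-identical cohort.
    """

    n_per_group: int
    shared_resonances: tuple[ResonanceSpec, ...]
    group_effects: Mapping[str, GroupEffect]
    water_residual: WaterResidual | None = None
    noise_sd: float = 0.05
    amplitude_jitter: float = 0.05
    n_points: int = DEFAULT_N_POINTS
    spectral_width_hz: float = DEFAULT_SPECTRAL_WIDTH_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise InvalidParameterError("n_per_group must be >= 1")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.amplitude_jitter < 0:
            raise InvalidParameterError("amplitude_jitter must be >= 0")
        known = {r.name for r in self.shared_resonances if r.name}
        for label, effect in self.group_effects.items():
            unknown = effect.touched() - known
            if unknown:
                raise ConfigurationError(
                    f"group {label!r} modifies unknown resonance(s): {sorted(unknown)}"
                )

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(self.group_effects)


@dataclass
class FIDRecord:
    """One sample's complex time-domain signal plus acquisition metadata."""

    sample_id: str
    signal: np.ndarray
    spectral_width_hz: float = DEFAULT_SPECTRAL_WIDTH_HZ
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.complex128)
        if self.signal.ndim != 1:
            raise InvalidParameterError("FID signal must be one-dimensional")
        if self.spectral_width_hz <= 0:
            raise InvalidParameterError("spectral_width_hz must be > 0")

    @property
    def n_points(self) -> int:
        return self.signal.shape[0]

    @property
    def dwell_s(self) -> float:
        """Sampling interval, the reciprocal of the spectral width."""
        return 1.0 / self.spectral_width_hz

    @property
    def acquisition_time_s(self) -> float:
        return self.n_points * self.dwell_s


def _resonance_sum(
    resonances: Sequence[ResonanceSpec],
    n_points: int,
    spectral_width_hz: float,
) -> np.ndarray:
    dt = 1.0 / spectral_width_hz
    t = np.arange(n_points) * dt
    x = np.zeros(n_points, dtype=np.complex128)
    nyquist = spectral_width_hz / 2.0
    for res in resonances:
        if abs(res.frequency_hz) >= nyquist:
            raise AliasingError(
                f"resonance {res.name or res.frequency_hz} at {res.frequency_hz} Hz "
                f"reaches the Nyquist edge +/-{nyquist} Hz"
            )
        osc = res.amplitude * np.exp(
            1j * (2.0 * np.pi * res.frequency_hz * t + res.phase_rad)
        )
        if math.isfinite(res.t2_s):
            osc *= np.exp(-t / res.t2_s)
        x += osc
    return x


def simulate_fid(
    resonances: Sequence[ResonanceSpec],
    water: WaterResidual | None = None,
    noise_sd: float = 0.0,
    n_points: int = DEFAULT_N_POINTS,
    spectral_width_hz: float = DEFAULT_SPECTRAL_WIDTH_HZ,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sim",
    group_label: str | None = None,
) -> FIDRecord:
    """Simulate one FID from the damped-complex-sinusoid model.

    Deterministic for a fixed ``seed``.  With no resonances, no water and
    ``noise_sd == 0`` the signal is identically zero.
    """
    if n_points < 2:
        raise InvalidParameterError("n_points must be >= 2")
    if spectral_width_hz <= 0:
        raise InvalidParameterError("spectral_width_hz must be > 0")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")

    all_res = list(resonances)
    if water is not None:
        all_res.append(water.effective())
    x = _resonance_sum(all_res, n_points, spectral_width_hz)
    if noise_sd > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        x = x + noise_sd * (
            rng.standard_normal(n_points) + 1j * rng.standard_normal(n_points)
        )
    return FIDRecord(
        sample_id=sample_id,
        signal=x,
        spectral_width_hz=spectral_width_hz,
        group_label=group_label,
    )


def simulate_cohort(design: CohortDesign) -> list[FIDRecord]:
    """Simulate ``n_groups * n_per_group`` FIDs with group structure.

    Records within a group share resonance parameters and differ only by
    per-sample multiplicative amplitude jitter and noise.  Sample seeds are
    spawned from ``design.seed`` in a fixed order, so the cohort is
    reproducible byte-for-byte.
    """
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(len(design.group_effects) * design.n_per_group)
    records: list[FIDRecord] = []
    idx = 0
    for label in design.group_labels:
        effect = design.group_effects[label]
        group_res = [effect.apply(r) for r in design.shared_resonances]
        for j in range(design.n_per_group):
            rng = np.random.default_rng(children[idx])
            jit = 1.0 + design.amplitude_jitter * rng.standard_normal(len(group_res))
            jit = np.clip(jit, 0.0, None)
            jittered = [
                replace(r, amplitude=r.amplitude * float(f))
                for r, f in zip(group_res, jit)
            ]
            rec = simulate_fid(
                jittered,
                water=design.water_residual,
                noise_sd=design.noise_sd,
                n_points=design.n_points,
                spectral_width_hz=design.spectral_width_hz,
                seed=rng,
                sample_id=f"{label}-{j + 1:02d}",
                group_label=label,
            )
            records.append(rec)
            idx += 1
    return records


# ---------------------------------------------------------------------------
# File I/O
#
# Text format: header lines "# key=value" (sample_id, group, n_points,
# spectral_width_hz) followed by two whitespace-separated numeric columns
# (real, imaginary), one row per time index.  Binary format: NumPy ``.npz``
# archive, bit-exact round trip.
# ---------------------------------------------------------------------------

_TEXT_SUFFIXES = {".txt", ".tsv", ".dat", ".fid"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in {"text", "npz"}:
            raise InvalidParameterError(f"unknown FID format {fmt!r}")
        return fmt
    if path.suffix == ".npz":
        return "npz"
    if path.suffix in _TEXT_SUFFIXES:
        return "text"
    raise InvalidParameterError(f"cannot infer FID format from suffix {path.suffix!r}")


def write_fid(record: FIDRecord, path: str | Path, fmt: str | None = None) -> Path:
    """Write one FID to ``path`` as delimited text or an ``.npz`` archive."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "npz":
        np.savez(
            path,
            signal=record.signal,
            spectral_width_hz=np.float64(record.spectral_width_hz),
            sample_id=np.str_(record.sample_id),
            group_label=np.str_(record.group_label or ""),
        )
        return path
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"# sample_id={record.sample_id}\n")
        if record.group_label is not None:
            fh.write(f"# group={record.group_label}\n")
        fh.write(f"# n_points={record.n_points}\n")
        fh.write(f"# spectral_width_hz={record.spectral_width_hz!r}\n")
        for v in record.signal:
            fh.write(f"{v.real:.17g} {v.imag:.17g}\n")
    return path


def read_fid(path: str | Path, fmt: str | None = None) -> FIDRecord:
    """Read an FID written by :func:`write_fid`.

    Raises :class:`ParseError` (naming the offending line where possible)
    on empty files, malformed headers, wrong column counts, or a length
    mismatch against the declared ``n_points``.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "npz":
        try:
            with np.load(path) as z:
                sig = z["signal"]
                sw = float(z["spectral_width_hz"])
                sid = str(z["sample_id"])
                grp = str(z["group_label"]) or None
        except Exception as exc:  # zipfile/KeyError → uniform parse error
            raise ParseError(f"{path}: not a valid FID npz archive ({exc})") from exc
        return FIDRecord(sample_id=sid, signal=sig, spectral_width_hz=sw, group_label=grp)

    meta: dict[str, str] = {}
    real: list[float] = []
    imag: list[float] = []
    with open(path, encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise ParseError(f"{path}:{lineno}: malformed header {line!r}")
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns (real, imaginary), "
                    f"got {len(parts)}"
                )
            try:
                real.append(float(parts[0]))
                imag.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
    if not real:
        raise ParseError(f"{path}: no data rows found")
    if "n_points" in meta and int(meta["n_points"]) != len(real):
        raise ParseError(
            f"{path}: header declares n_points={meta['n_points']} "
            f"but {len(real)} rows were read"
        )
    signal = np.asarray(real) + 1j * np.asarray(imag)
    return FIDRecord(
        sample_id=meta.get("sample_id", path.stem),
        signal=signal,
        spectral_width_hz=float(meta.get("spectral_width_hz", DEFAULT_SPECTRAL_WIDTH_HZ)),
        group_label=meta.get("group") or None,
    )


def write_manifest(records: Sequence[FIDRecord], paths: Sequence[str | Path], manifest_path: str | Path) -> Path:
    """Write a cohort manifest table: sample_id, group_label, path."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group_label": [r.group_label or "" for r in records],
            "path": [str(p) for p in paths],
        }
    )
    manifest_path = Path(manifest_path)
    df.to_csv(manifest_path, index=False)
    return manifest_path


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path, dtype=str).fillna("")
    missing = {"sample_id", "group_label", "path"} - set(df.columns)
    if missing:
        raise ParseError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Serum-like default cohort
# ---------------------------------------------------------------------------


def serum_resonances() -> tuple[ResonanceSpec, ...]:
    """A serum-like resonance set at a 400 MHz field, carrier on water.

    Frequencies are chemical-shift offsets from water (4.70 ppm) at
    400 Hz/ppm.  Broad lipoprotein lipid lines get short T2; small
    mobile metabolites (lactate, alanine, acetate) get long T2.
    Amplitudes are relative signal units on the scale of a protein-rich
    biofluid: lipid and glucose envelopes dominate.
    """
    return (
        ResonanceSpec(6.0, -1520.0, 0.0, 0.035, name="lipid_ch3"),
        ResonanceSpec(10.0, -1360.0, 0.3, 0.030, name="lipid_ch2"),
        ResonanceSpec(5.0, -1348.0, 0.0, 0.20, name="lactate_ch3"),
        ResonanceSpec(1.5, -1288.0, 0.5, 0.18, name="alanine_ch3"),
        ResonanceSpec(0.8, -1112.0, 0.0, 0.25, name="acetate"),
        ResonanceSpec(2.0, -1064.0, 0.2, 0.08, name="nac_glycoprotein"),
        ResonanceSpec(8.0, -480.0, 0.0, 0.09, name="glucose_ring"),
        ResonanceSpec(1.5, 212.0, 0.0, 0.12, name="glucose_anomeric"),
        ResonanceSpec(2.0, 256.0, 0.4, 0.040, name="lipid_unsat"),
    )


def default_water() -> WaterResidual:
    """Residual water line after presaturation (strongly attenuated)."""
    return WaterResidual(
        ResonanceSpec(150.0, 0.0, 0.0, 0.12, name="water"), attenuation=0.02
    )


def two_state_design(
    n_per_group: int = 6,
    seed: int = 0,
    labels: tuple[str, str] = ("precursor", "progressed"),
    noise_sd: float = 0.05,
    amplitude_jitter: float = 0.05,
) -> CohortDesign:
    """Two latent serum states differing in lipid and glucose signals.

    The progressed state doubles the main lipid CH2 envelope (with a
    20% T2 shortening, i.e. line broadening) and raises the glucose
    ring envelope by 50% — dyslipidemia plus hyperglycemia, the serum
    phenotype such cohorts are built to emulate.  Both effects are large
    against the 5% per-sample amplitude jitter.
    """
    effects = {
        labels[0]: GroupEffect(),
        labels[1]: GroupEffect(
            amplitude_scale={"lipid_ch2": 2.0, "glucose_ring": 1.5},
            t2_scale={"lipid_ch2": 0.8},
        ),
    }
    return CohortDesign(
        n_per_group=n_per_group,
        shared_resonances=serum_resonances(),
        group_effects=effects,
        water_residual=default_water(),
        noise_sd=noise_sd,
        amplitude_jitter=amplitude_jitter,
        seed=seed,
    )


def read_jdf(path: str | Path) -> FIDRecord:
    """Vendor-format adapter stub for JEOL Delta (JDF) files."""
    raise NotImplementedError(
        "JEOL Delta (JDF) parsing is not implemented; export the FID as "
        "delimited text or npz and use read_fid instead"
    )
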