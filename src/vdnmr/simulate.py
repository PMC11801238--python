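"""Synthetic aromatic 13C-1H time-domain spectrum generator.

Produces training triples for the virtual-decoupling network: two input
planes recorded with coupling-evolution delays tau_coup = 0 and 2.3 ms,
plus a target plane that is free of 13C-13C splittings and has its 13C
transverse relaxation halved (R2,tar = 0.5 R2,inp).

Physics emulated per cross-peak:

* 13C multiplets from two active one-bond couplings J1C, J2C ~ N(63, 10) Hz,
  each zeroed with probability 0.2, giving 64% triplets / 32% doublets /
  4% singlets;
* roofing (strong-coupling intensity tilt) via complex modulation factors
  {cos(pi J t) + rho i sin(pi J t)} with rho ~ N(0, 0.08), in both dims;
* 1H passive couplings J1H ~ N(8, 2) Hz (10% zeroed) and J2H ~ N(4, 2) Hz
  (50% zeroed), present identically in inputs and target;
* 13C shifts uniform over the sweep width; 1H shifts drawn N(0, SW/4) and
  squeezed toward the centre through a tanh placement map that also keeps
  peaks off the spectrum edge;
* a residual-solvent tail built in the 1H frequency domain and added
  (t1-independently) to the input planes, mirrored for half of the sets;
* complex Gaussian noise and small zero-/first-order phase errors on the
  input planes only.

Time-domain planes are stored hypercomplex: shape (2, n_h, n_c) complex,
where axis 0 holds the cosine- and sine-modulated t1 interferograms
(States quadrature) and the complex dtype carries the 1H quadrature.
``analytic(plane)`` collapses this to the (n_h, n_c) analytic signal whose
2D FFT is the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "AcquisitionScheme",
    "AromaticSpinSystem",
    "SolventArtifact",
    "SyntheticSpectrumSet",
    "GeneratorConfig",
    "sample_carbon_couplings",
    "sample_proton_couplings",
    "place_proton_shift",
    "multiplet_modulation",
    "solvent_profile",
    "synthesize_fid",
    "generate_training_set",
    "analytic",
]

TAU_COUP = 2.3e-3  # s; total 13C-13C coupling evolution 4*Delta


@dataclass
class AcquisitionScheme:
    """Sweep widths, complex point counts and the coupling-evolution delay."""

    sw_h: float = 10000.0  # Hz
    sw_c: float = 5000.0  # Hz
    n_c: int = 200  # complex 13C points, 96..200
    n_h: int = 256  # complex 1H points, 128..256
    tau_coup: float = 0.0  # s
    zf_c: int = 200
    zf_h: int = 256

    def __post_init__(self):
        if not (96 <= self.n_c <= self.zf_c == 200):
            raise ValueError(f"n_c must satisfy 96 <= n_c <= zf_c = 200, got {self.n_c}")
        if not (128 <= self.n_h <= self.zf_h == 256):
            raise ValueError(f"n_h must satisfy 128 <= n_h <= zf_h = 256, got {self.n_h}")
        if self.tau_coup < 0:
            raise ValueError("tau_coup must be >= 0")
        if self.sw_h <= 0 or self.sw_c <= 0:
            raise ValueError("sweep widths must be positive")

    @property
    def t1(self):
        """13C evolution time grid (s)."""
        return np.arange(self.n_c) / self.sw_c

    @property
    def t2(self):
        """1H acquisition time grid (s)."""
        return np.arange(self.n_h) / self.sw_h


@dataclass
class AromaticSpinSystem:
    """One cross-peak: shifts, intensity, relaxation, couplings, roofing."""

    delta_c: float  # 13C offset, Hz
    delta_h0: float  # initial 1H offset, Hz
    delta_h: float  # placed 1H offset, Hz
    intensity: float
    r2c_in: float  # 13C R2 of the inputs, s^-1
    r2c_tar: float  # 13C R2 of the target (= r2c_in / 2), s^-1
    r2h: float  # 1H R2, s^-1
    j1c: float = 0.0
    j2c: float = 0.0
    rho1c: float = 0.0
    rho2c: float = 0.0
    j1h: float = 0.0
    j2h: float = 0.0
    rho1h: float = 0.0
    rho2h: float = 0.0

    @property
    def multiplet_class(self):
        """'singlet', 'doublet' or 'triplet' from the active 13C couplings."""
        nz = (self.j1c != 0.0) + (self.j2c != 0.0)
        return ("singlet", "doublet", "triplet")[nz]


@dataclass
class SolventArtifact:
    """Residual-solvent tail: amplitude, shape parameter, 1H mirror flag."""

    amp: float
    slp: float
    inverted: bool


@dataclass
class SyntheticSpectrumSet:
    """One training triple plus everything that generated it."""

    input_nocoup: np.ndarray  # complex (2, n_h, n_c)
    input_coup: np.ndarray
    target: np.ndarray
    systems: list
    solvent: SolventArtifact
    acq: AcquisitionScheme
    seed: int
    noise_sd: float = 0.0
    phase_errors: dict = field(default_factory=dict)

    @property
    def planes(self):
        return (self.input_nocoup, self.input_coup, self.target)


@dataclass
class GeneratorConfig:
    """Every distribution parameter of the synthetic generator.

    Defaults are the training conditions: J_C ~ N(63, 10) Hz with 20%
    zeroing, R2,inp ~ N(50, 20) s^-1 (13C, clipped to >= 1), roofing
    N(0, 0.08), 40-200 cross-peaks, acquisition sizes uniform over the
    stated ranges.  Intensity |N(1, 0.3)|, noise 1e-3 of the max input
    amplitude, phase errors within +/-5 degrees.
    """

    sw_h: float = 10000.0
    sw_c: float = 5000.0
    n_peaks_min: int = 40
    n_peaks_max: int = 200
    n_c_min: int = 96
    n_c_max: int = 200
    n_h_min: int = 128
    n_h_max: int = 256
    jc_mean: float = 63.0
    jc_sd: float = 10.0
    jc_p_zero: float = 0.2
    j1h_mean: float = 8.0
    j1h_sd: float = 2.0
    j1h_p_zero: float = 0.1
    j2h_mean: float = 4.0
    j2h_sd: float = 2.0
    j2h_p_zero: float = 0.5
    roofing_sd: float = 0.08
    r2c_mean: float = 50.0
    r2c_sd: float = 20.0
    r2h_mean: float = 50.0
    r2h_sd: float = 20.0
    r2_floor: float = 1.0
    intensity_mean: float = 1.0
    intensity_sd: float = 0.3
    noise_sd_rel: float = 1e-3
    phase_max_deg: float = 5.0
    solvent: bool = True
    tau_coup: float = TAU_COUP

    def validate(self):
        if not (0 <= self.jc_p_zero <= 1 and 0 <= self.j1h_p_zero <= 1 and 0 <= self.j2h_p_zero <= 1):
            raise ValueError("zeroing probabilities must lie in [0, 1]")
        if min(self.jc_sd, self.j1h_sd, self.j2h_sd, self.roofing_sd) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not (1 <= self.n_peaks_min <= self.n_peaks_max):
            raise ValueError("invalid peak-count range")
        if self.noise_sd_rel < 0 or self.phase_max_deg < 0:
            raise ValueError("noise/phase parameters must be nonnegative")
        return self

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data).validate()

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def sample_carbon_couplings(rng, mean=63.0, sd=10.0, p_zero=0.2):
    """Draw the two active 13C-13C couplings for one cross-peak.

    Each is N(mean, sd) then independently set to zero with probability
    ``p_zero``; the defaults give 64% triplets, 32% doublets, 4% singlets.
    """
    if not 0 <= p_zero <= 1:
        raise ValueError("p_zero must lie in [0, 1]")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    j = rng.normal(mean, sd, size=2)
    j[rng.random(2) < p_zero] = 0.0
    return float(j[0]), float(j[1])


def sample_proton_couplings(rng, cfg=None):
    """Draw the passive 1H-1H couplings (J1H, J2H) for one cross-peak."""
    cfg = cfg or GeneratorConfig()
    j1 = rng.normal(cfg.j1h_mean, cfg.j1h_sd)
    if rng.random() < cfg.j1h_p_zero:
        j1 = 0.0
    j2 = rng.normal(cfg.j2h_mean, cfg.j2h_sd)
    if rng.random() < cfg.j2h_p_zero:
        j2 = 0.0
    return float(j1), float(j2)


def place_proton_shift(delta_h0, sw_h):
    """Squeeze an initial 1H offset toward centre, keeping it off the edge.

    delta_h = 0.2 SW tanh(6 d0/SW) + 0.3 SW tanh(2 d0/SW); odd in d0 and
    bounded by 0.5 SW in magnitude, so no cross-peak sits on the 1H edge.
    """
    if sw_h <= 0:
        raise ValueError("sw_h must be positive")
    d0 = np.asarray(delta_h0, dtype=float)
    out = 0.2 * sw_h * np.tanh(6.0 * d0 / sw_h) + 0.3 * sw_h * np.tanh(2.0 * d0 / sw_h)
    # keep strictly inside the sweep width even when tanh saturates to 1.0
    bound = 0.5 * sw_h * (1.0 - 1e-12)
    out = np.clip(out, -bound, bound)
    return float(out) if out.ndim == 0 else out


def multiplet_modulation(j1, j2, rho1, rho2, t, tau_coup=0.0):
    """Complex coupling-evolution factor for one dimension.

    {cos(pi J1 te) + rho1 i sin(pi J1 te)} x {cos(pi J2 te) + rho2 i
    sin(pi J2 te)} at effective time te = t + tau_coup.  rho = 0 gives the
    weak-coupling cosine modulation; nonzero rho adds roofing.  No
    amplitude decay is applied during tau_coup (phase evolution only).
    """
    te = np.asarray(t, dtype=float) + tau_coup
    f1 = np.cos(np.pi * j1 * te) + rho1 * 1j * np.sin(np.pi * j1 * te)
    f2 = np.cos(np.pi * j2 * te) + rho2 * 1j * np.sin(np.pi * j2 * te)
    out = f1 * f2
    return complex(out) if out.ndim == 0 else out


def solvent_profile(amp, slp, n, inverted=False):
    """Residual-solvent 1H frequency-domain profile.

    profile(x) = 10 amp [slp (1/(x+0.1) - 0.9) - (1-slp) x] at x_i = i/n,
    a sharp tail decaying from the x = 0 edge; mirrored when ``inverted``.
    """
    if not 0 <= slp <= 1:
        raise ValueError("slp must lie in [0, 1]")
    if n < 2:
        raise ValueError("n must be >= 2")
    x = np.arange(n) / n
    prof = 10.0 * amp * (slp * (1.0 / (x + 0.1) - 0.9) - (1.0 - slp) * x)
    if inverted:
        prof = prof[::-1].copy()
    return prof


def _carbon_signal(sys: AromaticSpinSystem, acq: AcquisitionScheme, mode: str):
    t1 = acq.t1
    if mode == "target":
        r2 = sys.r2c_tar
        mod = 1.0
    else:
        r2 = sys.r2c_in
        tau = acq.tau_coup if mode == "input_coup" else 0.0
        mod = multiplet_modulation(sys.j1c, sys.j2c, sys.rho1c, sys.rho2c, t1, tau)
    return np.exp((2j * np.pi * sys.delta_c - r2) * t1) * mod


def _proton_signal(sys: AromaticSpinSystem, acq: AcquisitionScheme):
    t2 = acq.t2
    mod = multiplet_modulation(sys.j1h, sys.j2h, sys.rho1h, sys.rho2h, t2, 0.0)
    return np.exp((2j * np.pi * sys.delta_h - sys.r2h) * t2) * mod


def synthesize_fid(systems, acq: AcquisitionScheme, mode):
    """Sum the hypercomplex time-domain plane for one mode.

    ``mode`` is 'input_nocoup', 'input_coup' or 'target'.  Returns a
    complex array of shape (2, n_h, n_c): cos-/sin-modulated t1
    interferograms, complex in t2.  Noise, phase errors and solvent are
    added separately by the generator.
    """
    if mode not in ("input_nocoup", "input_coup", "target"):
        raise ValueError(f"unknown mode {mode!r}")
    plane = np.zeros((2, acq.n_h, acq.n_c), dtype=complex)
    for sys in systems:
        c = _carbon_signal(sys, acq, mode)
        p = sys.intensity * _proton_signal(sys, acq)
        plane[0] += np.outer(p, c.real)
        plane[1] += np.outer(p, c.imag)
    return plane


def analytic(plane):
    """Collapse a hypercomplex (2, n_h, n_c) plane to its analytic signal."""
    return plane[0] + 1j * plane[1]


def _solvent_time_signal(solv: SolventArtifact, n_h: int):
    prof = solvent_profile(solv.amp, solv.slp, n_h, solv.inverted)
    # frequency-domain profile -> 1H time-domain signal
    return np.fft.ifft(np.fft.ifftshift(prof)) * n_h


def _apply_phase_error(plane, p0_deg, p1_deg, axis):
    """Zero-/first-order phase error along one axis of the analytic plane."""
    n = plane.shape[axis]
    k = np.arange(n) / n - 0.5
    ph = np.exp(1j * np.deg2rad(p0_deg + p1_deg * k))
    shape = [1, 1]
    shape[axis] = n
    f = np.fft.fft(plane, axis=axis)
    f *= np.fft.ifftshift(ph).reshape(shape)
    return np.fft.ifft(f, axis=axis)


def generate_training_set(config: GeneratorConfig, rng) -> SyntheticSpectrumSet:
    """Generate one (input_nocoup, input_coup, target) triple.

    ``rng`` is either an integer seed or a numpy Generator; an integer
    makes the set byte-reproducible.
    """
    config.validate()
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = -1

    acq_kw = dict(sw_h=config.sw_h, sw_c=config.sw_c)
    n_c = int(rng.integers(config.n_c_min, config.n_c_max + 1))
    n_h = int(rng.integers(config.n_h_min, config.n_h_max + 1))
    n_peaks = int(rng.integers(config.n_peaks_min, config.n_peaks_max + 1))

    systems = []
    for _ in range(n_peaks):
        delta_c = float(rng.uniform(-0.5 * config.sw_c, 0.5 * config.sw_c))
        delta_h0 = float(rng.normal(0.0, config.sw_h / 4.0))
        j1c, j2c = sample_carbon_couplings(rng, config.jc_mean, config.jc_sd, config.jc_p_zero)
        rho1c, rho2c = rng.normal(0.0, config.roofing_sd, size=2)
        j1h, j2h = sample_proton_couplings(rng, config)
        rho1h, rho2h = rng.normal(0.0, config.roofing_sd, size=2)
        r2c = max(config.r2_floor, float(rng.normal(config.r2c_mean, config.r2c_sd)))
        r2h = max(config.r2_floor, float(rng.normal(config.r2h_mean, config.r2h_sd)))
        intensity = abs(float(rng.normal(config.intensity_mean, config.intensity_sd)))
        systems.append(
            AromaticSpinSystem(
                delta_c=delta_c,
                delta_h0=delta_h0,
                delta_h=place_proton_shift(delta_h0, config.sw_h),
                intensity=intensity,
                r2c_in=r2c,
                r2c_tar=0.5 * r2c,
                r2h=r2h,
                j1c=j1c,
                j2c=j2c,
                rho1c=float(rho1c),
                rho2c=float(rho2c),
                j1h=j1h,
                j2h=j2h,
                rho1h=float(rho1h),
                rho2h=float(rho2h),
            )
        )

    acq0 = AcquisitionScheme(n_c=n_c, n_h=n_h, tau_coup=0.0, **acq_kw)
    acqc = AcquisitionScheme(n_c=n_c, n_h=n_h, tau_coup=config.tau_coup, **acq_kw)
    input_nocoup = synthesize_fid(systems, acq0, "input_nocoup")
    input_coup = synthesize_fid(systems, acqc, "input_coup")
    target = synthesize_fid(systems, acq0, "target")

    solvent = SolventArtifact(
        amp=abs(float(rng.normal(config.intensity_mean, config.intensity_sd))),
        slp=float(rng.uniform(0.0, 1.0)),
        inverted=bool(rng.random() < 0.5),
    )
    if config.solvent:
        solv_t2 = _solvent_time_signal(solvent, n_h)
        for plane in (input_nocoup, input_coup):
            plane[0] += solv_t2[:, None]

    phase_errors = {}
    pm = config.phase_max_deg
    for name, plane in (("input_nocoup", input_nocoup), ("input_coup", input_coup)):
        p = rng.uniform(-pm, pm, size=4)  # p0/p1 per dimension
        phase_errors[name] = p.tolist()
        for comp in range(2):
            z = plane[comp]
            z = _apply_phase_error(z, p[0], p[1], axis=0)  # 1H
            z = _apply_phase_error(z, p[2], p[3], axis=1)  # 13C
            plane[comp] = z

    scale = max(np.abs(input_nocoup).max(), np.abs(input_coup).max())
    noise_sd = config.noise_sd_rel * scale
    if noise_sd > 0:
        for plane in (input_nocoup, input_coup):
            plane += noise_sd * (
                rng.standard_normal(plane.shape) + 1j * rng.standard_normal(plane.shape)
            )

    return SyntheticSpectrumSet(
        input_nocoup=input_nocoup,
        input_coup=input_coup,
        target=target,
        systems=systems,
        solvent=solvent,
        acq=acqc,
        seed=seed,
        noise_sd=float(noise_sd),
        phase_errors=phase_errors,
    )
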