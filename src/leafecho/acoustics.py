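"""Monostatic foliage-echo synthesis from leaf-disc reflectors.

Each leaf disc inside the sonar mainlobe contributes one reflected component
per frequency bin.  At frequency f_k the complex echo spectrum is

    y*_k = Σ_{i=1..m} A_ki cos(φ_ki) + j Σ_{i=1..m} A_ki sin(φ_ki),

with amplitude

    A_ki = S(az_i, el_i, A0) · L_i(β_i, a_i, f_k) · λ_k / (2π r_i²),

where S is the Gaussian mainlobe beampattern of the sonar, L the fitted
cosine beampattern of a circular-disc reflector, λ_k = v/f_k the wavelength,
and r_i the range.  The phase is the monostatic round-trip propagation phase
φ_ki = 2π f_k (2 r_i)/v, so the inverse FFT places each reflector's arrival
at delay 2r/v.  Components are nonzero only inside the emission band
(60–80 kHz by default, the terminal-FM band of greater horseshoe bats).
Shading between leaves and Doppler shifts are deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import LeafDisc

#: σ normalisation constant: σ = (θ/2)/√((3/10)·ln 10) for −3 dB full width θ
#: under the 20·log10 amplitude-dB convention.
_SIGMA_Q = 0.3 * math.log(10.0)
#: value of az²/(2σ²) + el²/(2σ²) on the −3 dB amplitude contour
#: (gain 10^(−3/20) = exp(−(3/20)·ln 10)).
_CONTOUR_Q = 0.15 * math.log(10.0)


def beamwidth_to_sigma(beamwidth: float) -> float:
    """Gaussian spread σ from a full −3 dB beamwidth (radians).

    −3 dB is read on the amplitude gain, 20·log10(S/A0) = −3, so the gain at
    the half-beamwidth is 10^(−3/20) and σ = (θ/2)/√((3/10)·ln 10).
    """
    if beamwidth <= 0:
        raise ValueError("beamwidth must be positive")
    return (beamwidth / 2.0) / math.sqrt(_SIGMA_Q)


@dataclass
class SonarBeam:
    """Monostatic sonar pose and Gaussian mainlobe beampattern.

    The beam frame is right-handed: boresight forward, ``up_reference``
    projected out of the boresight gives beam-up; azimuth is measured in the
    horizontal (right/forward) plane, elevation towards beam-up.
    """

    position: np.ndarray
    boresight: np.ndarray
    beamwidth_az: float = math.radians(40.0)
    beamwidth_el: float = math.radians(40.0)
    A0: float = 1.0
    up_reference: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        b = np.asarray(self.boresight, dtype=float)
        nb = np.linalg.norm(b)
        if nb == 0:
            raise ValueError("boresight must be nonzero")
        self.boresight = b / nb
        up = np.asarray(self.up_reference, dtype=float)
        up = up - np.dot(up, self.boresight) * self.boresight
        if np.linalg.norm(up) < 1e-12:  # boresight parallel to up: pick any
            up = np.array([1.0, 0.0, 0.0])
            up = up - np.dot(up, self.boresight) * self.boresight
        self.up_reference = up / np.linalg.norm(up)
        self.sigma_az = beamwidth_to_sigma(self.beamwidth_az)
        self.sigma_el = beamwidth_to_sigma(self.beamwidth_el)

    @property
    def right(self) -> np.ndarray:
        return np.cross(self.boresight, self.up_reference)

    def frame_angles(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(range, azimuth, elevation) of points in the beam frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.position
        r = np.linalg.norm(pts, axis=1)
        if np.any(r == 0):
            raise ValueError("reflector coincides with the sonar position")
        u = pts / r[:, None]
        fwd = u @ self.boresight
        rgt = u @ self.right
        upc = np.clip(u @ self.up_reference, -1.0, 1.0)
        az = np.arctan2(rgt, fwd)
        el = np.arcsin(upc)
        return r, az, el


@dataclass(frozen=True)
class ReflectorView:
    """Per-leaf geometry as seen from the sonar."""

    r: float
    az: float
    el: float
    beta: float
    a: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("range must be positive")
        if self.a <= 0:
            raise ValueError("disc radius must be positive")


@dataclass(frozen=True)
class FrequencyBand:
    """Emission band, sampling grid and propagation speed."""

    f_lo: float = 60e3
    f_hi: float = 80e3
    fs: float = 400e3
    n_fft: int = 4096
    sound_speed: float = 343.0
    taper: str = "rectangular"  # or "raised-cosine"
    taper_fraction: float = 0.1  # of the band, each edge, for raised-cosine

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError("f_lo must be below f_hi")
        if self.fs <= 2 * self.f_hi:
            raise ValueError("sampling rate must exceed twice f_hi")
        if self.n_fft & (self.n_fft - 1):
            raise ValueError("n_fft must be a power of two")
        if self.taper not in ("rectangular", "raised-cosine"):
            raise ValueError(f"unknown taper {self.taper!r}")

    def frequencies(self) -> np.ndarray:
        """The nonnegative FFT bin frequencies, 0 … fs/2."""
        return np.fft.rfftfreq(self.n_fft, d=1.0 / self.fs)

    def in_band(self) -> np.ndarray:
        f = self.frequencies()
        return (f >= self.f_lo) & (f <= self.f_hi)

    def taper_weights(self) -> np.ndarray:
        """Unit weights in-band; optional raised-cosine roll-off at the edges."""
        f = self.frequencies()
        w = self.in_band().astype(float)
        if self.taper == "raised-cosine":
            edge = self.taper_fraction * (self.f_hi - self.f_lo)
            lo_ramp = (f >= self.f_lo) & (f < self.f_lo + edge)
            hi_ramp = (f > self.f_hi - edge) & (f <= self.f_hi)
            w[lo_ramp] = 0.5 * (1 - np.cos(np.pi * (f[lo_ramp] - self.f_lo) / edge))
            w[hi_ramp] = 0.5 * (1 - np.cos(np.pi * (self.f_hi - f[hi_ramp]) / edge))
        return w


@dataclass
class EchoSpectrum:
    """One-sided complex spectrum on the band's rfft grid."""

    frequencies: np.ndarray
    values: np.ndarray
    band: FrequencyBand
    m: int = 0  # number of in-mainlobe reflectors that contributed


@dataclass
class ImpulseResponse:
    """Real time-domain echo; sample 0 is the emission instant."""

    samples: np.ndarray
    fs: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def envelope(self) -> np.ndarray:
        from scipy.signal import hilbert

        return np.abs(hilbert(self.samples))

    def to_wav(self, path) -> None:
        from scipy.io import wavfile

        wavfile.write(path, int(self.fs), self.samples.astype(np.float32))

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.samples]),
            delimiter=",",
            header="time_s,amplitude",
            comments="",
        )


# ---------------------------------------------------------------------------
# Elementary gains
# ---------------------------------------------------------------------------


def reflector_view(beam: SonarBeam, disc: LeafDisc) -> ReflectorView:
    """Range, beam-frame angles, incident angle and radius of one disc."""
    r, az, el = beam.frame_angles(disc.center[None, :])
    to_sonar = beam.position - disc.center
    to_sonar = to_sonar / np.linalg.norm(to_sonar)
    # discs are two-sided: fold the incidence angle to [0, pi/2]
    beta = math.acos(min(1.0, abs(float(np.dot(disc.normal, to_sonar)))))
    return ReflectorView(r=float(r[0]), az=float(az[0]), el=float(el[0]), beta=beta, a=disc.radius)


def beam_gain(beam: SonarBeam, az, el):
    """Gaussian mainlobe amplitude gain S(az, el) with peak A0 on boresight."""
    az = np.asarray(az, dtype=float)
    el = np.asarray(el, dtype=float)
    q = az**2 / (2 * beam.sigma_az**2) + el**2 / (2 * beam.sigma_el**2)
    return beam.A0 * np.exp(-q)


def in_mainlobe(beam: SonarBeam, az, el):
    """True inside (or on) the −3 dB ellipse and in the forward hemisphere."""
    az = np.asarray(az, dtype=float)
    el = np.asarray(el, dtype=float)
    q = az**2 / (2 * beam.sigma_az**2) + el**2 / (2 * beam.sigma_el**2)
    forward = np.abs(az) <= math.pi / 2
    return (q <= _CONTOUR_Q + 1e-12) & forward


def _p1(c):
    return 0.5003 * c**2 + 0.6867


def _p2(c):
    return 0.3999 * c**-0.9065 + 0.9979


def leaf_gain(beta, a: float, f, v: float = 343.0, clamp: bool = True):
    """Backscatter gain of a circular disc of radius ``a`` at incidence ``beta``.

    The numerically computed scattered field of a disc is approximated by
    L = P1(c)·cos(P2(c)·β) with c = 2πaf/v and the fitted polynomials
    P1(c) = 0.5003 c² + 0.6867, P2(c) = 0.3999 c^(−0.9065) + 0.9979.
    Negative values (beyond the first cosine zero, where the fit is an
    extrapolation) are clamped to 0 unless ``clamp`` is False.
    """
    if a <= 0:
        raise ValueError("disc radius must be positive")
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    c = 2.0 * math.pi * a * f / v
    out = _p1(c) * np.cos(_p2(c) * np.asarray(beta, dtype=float))
    if clamp:
        out = np.maximum(out, 0.0)
    return out


def facet_amplitude(view: ReflectorView, beam: SonarBeam, f, band: FrequencyBand) -> np.ndarray:
    """A = S(az, el) · L(β, a, f) · λ_f / (2π r²) at frequency f (may be an array)."""
    f = np.asarray(f, dtype=float)
    s = beam_gain(beam, view.az, view.el)
    L = leaf_gain(view.beta, view.a, f, band.sound_speed)
    lam = band.sound_speed / f
    return s * L * lam / (2.0 * math.pi * view.r**2)


def facet_phase(view: ReflectorView, f, v: float = 343.0) -> np.ndarray:
    """Monostatic round-trip propagation phase φ = 2π f (2r)/v."""
    return 2.0 * math.pi * np.asarray(f, dtype=float) * (2.0 * view.r) / v


# ---------------------------------------------------------------------------
# Spectrum synthesis and inversion
# ---------------------------------------------------------------------------


def synthesize_spectrum(
    beam: SonarBeam,
    discs: list[LeafDisc],
    band: FrequencyBand | None = None,
    clamp_leaf_gain: bool = True,
) -> EchoSpectrum:
    """Superpose the reflected components of all in-mainlobe discs.

    Discs outside the −3 dB contour (or behind the sonar) are culled before
    any amplitude is evaluated.  Linearity is exact: the spectrum of a union
    of disjoint disc sets is the sum of the individual spectra.
    """
    if band is None:
        band = FrequencyBand()
    f_all = band.frequencies()
    mask = band.in_band()
    weights = band.taper_weights()[mask]
    values = np.zeros(len(f_all), dtype=complex)
    m = 0
    if discs:
        centers = np.array([d.center for d in discs])
        r, az, el = beam.frame_angles(centers)
        keep = in_mainlobe(beam, az, el)
        m = int(keep.sum())
        if m:
            f = f_all[mask]
            lam = band.sound_speed / f
            normals = np.array([d.normal for d in discs])[keep]
            radii = np.array([d.radius for d in discs])[keep]
            r, az, el = r[keep], az[keep], el[keep]
            u = (beam.position - centers[keep]) / r[:, None]
            cosb = np.clip(np.abs(np.einsum("ij,ij->i", normals, u)), 0.0, 1.0)
            beta = np.arccos(cosb)

            s = beam_gain(beam, az, el)  # (m,)
            c = 2.0 * math.pi * radii[:, None] * f[None, :] / band.sound_speed
            L = _p1(c) * np.cos(_p2(c) * beta[:, None])
            if clamp_leaf_gain:
                L = np.maximum(L, 0.0)
            A = s[:, None] * L * lam[None, :] / (2.0 * math.pi * r[:, None] ** 2)
            phi = 2.0 * math.pi * f[None, :] * (2.0 * r[:, None]) / band.sound_speed
            # The spectrum carries e^{-j phi}: under the e^{+j2pi f t} inverse-
            # transform convention a positive round-trip delay 2r/v needs a
            # negative phase ramp, so each arrival lands at sample fs*2r/v.
            values[mask] = (A * np.exp(-1j * phi)).sum(axis=0) * weights
    return EchoSpectrum(frequencies=f_all, values=values, band=band, m=m)


def impulse_response(spectrum: EchoSpectrum, band: FrequencyBand | None = None) -> ImpulseResponse:
    """Inverse FFT of the one-sided spectrum with conjugate symmetry enforced.

    The returned signal is real; the imaginary residue of the full inverse
    transform is checked to be below 1e-10 of the peak magnitude.
    """
    band = band or spectrum.band
    n = band.n_fft
    if len(spectrum.frequencies) != n // 2 + 1 or not np.allclose(
        spectrum.frequencies, band.frequencies()
    ):
        raise ValueError("spectrum frequency grid does not match the band")
    full = np.zeros(n, dtype=complex)
    half = spectrum.values.copy()
    full[: n // 2 + 1] = half
    full[n // 2 + 1 :] = np.conj(half[1 : n // 2][::-1])
    y = np.fft.ifft(full)
    peak = np.max(np.abs(y)) if np.max(np.abs(y)) > 0 else 1.0
    resid = np.max(np.abs(y.imag)) / peak
    if resid > 1e-10:
        raise ValueError(f"imaginary residue {resid:.2e} exceeds 1e-10 of peak")
    return ImpulseResponse(samples=y.real.copy(), fs=band.fs)


def echo(
    beam: SonarBeam,
    discs: list[LeafDisc],
    band: FrequencyBand | None = None,
) -> tuple[ImpulseResponse, EchoSpectrum]:
    """Convenience wrapper: spectrum synthesis followed by inverse FFT."""
    band = band or FrequencyBand()
    spec = synthesize_spectrum(beam, discs, band)
    return impulse_response(spec, band), spec
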