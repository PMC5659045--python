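"""Log-Gabor filter bank and the 2-D phase-congruency map.

Phase congruency (PC) marks points where the Fourier components of the
image are maximally in phase — edges, lines and dots — independently of
local brightness and contrast, which is what makes it suitable for low
contrast vasculature and microaneurysms. The map is

    PC(m,n) = sum_o sum_s W_o . max(E_so - T_o, 0)
              -----------------------------------------
              sum_o sum_s A_so(m,n) + eps

with A_so the amplitude of the quadrature log-Gabor response at scale s
and orientation o, E_so that scale's contribution to the local energy,
T_o a per-orientation noise floor (Rayleigh estimate from the smallest
scale) and W_o a sigmoid weight on filter-response spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ChannelImage, PipelineConfig


@dataclass
class PCParams:
    n_orient: int = 8
    n_scale: int = 3
    wavelength_min: float = 3.0
    scale_factor: float = 1.6
    epsilon: float = 1e-5
    noise_k: float = 2.0
    sigma_onf: float = 0.55     # log-Gabor bandwidth: sigma / center frequency
    cut_off: float = 0.15       # frequency-spread weighting sigmoid midpoint;
                                # low because with 3 scales a wide vessel
                                # legitimately concentrates in one band
    gain: float = 10.0          # and its steepness

    def __post_init__(self) -> None:
        if self.n_orient < 1 or self.n_scale < 1:
            raise ValueError("need at least one orientation and scale")
        if self.scale_factor <= 1:
            raise ValueError("scale_factor must exceed 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @classmethod
    def from_config(cls, cfg: PipelineConfig,
                    wavelength_min: float | None = None) -> "PCParams":
        return cls(n_orient=cfg.pc_orientations, n_scale=cfg.pc_scales,
                   wavelength_min=wavelength_min or cfg.pc_wavelength_min,
                   scale_factor=cfg.pc_scale_factor, epsilon=cfg.pc_epsilon,
                   noise_k=cfg.pc_noise_k, sigma_onf=cfg.pc_sigma_onf)


@dataclass
class FilterResponse:
    """Raw per-orientation machinery behind a PC map (mainly for tests)."""
    amplitude: list            # [orient][scale] H x W amplitude A_so
    energy: list               # [orient] H x W local energy
    noise_floor: list          # [orient] scalar T_o
    weight: list               # [orient] H x W weight W_o in [0, 1]
    pc: np.ndarray = field(default=None)


def _radial_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.sqrt(fx * fx + fy * fy)
    radius[0, 0] = 1.0          # avoid log(0) at DC; the filter is zeroed there
    theta = np.arctan2(-fy, fx)
    return radius, np.sin(theta), np.cos(theta)


def _lowpass(shape: tuple[int, int], cutoff: float = 0.45, order: int = 15) -> np.ndarray:
    radius, _, _ = _radial_grid(shape)
    radius = radius.copy()
    radius[0, 0] = 0.0
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * order))


def loggabor_bank(shape: tuple[int, int], params: PCParams | None = None) -> list:
    """Frequency-domain filters, indexed [orientation][scale].

    Radial centers follow wavelength_min * scale_factor**(j-1); angular
    lobes are Gaussian in angle with spacing pi / n_orient. Every filter
    has exactly zero DC response.
    """
    params = params or PCParams()
    h, w = shape
    if h < 16 or w < 16:
        raise ValueError("image must be at least 16 x 16")
    if params.wavelength_min < 2:
        raise ValueError("wavelength_min below 2 px is sub-Nyquist")
    radius, sintheta, costheta = _radial_grid(shape)
    lp = _lowpass(shape)
    log_sig = np.log(params.sigma_onf) ** 2

    radials = []
    for s in range(params.n_scale):
        wavelength = params.wavelength_min * params.scale_factor ** s
        f0 = 1.0 / wavelength
        rad = np.exp(-(np.log(radius / f0) ** 2) / (2 * log_sig)) * lp
        rad[0, 0] = 0.0
        radials.append(rad)

    theta_sigma = np.pi / params.n_orient / 1.5
    bank = []
    for o in range(params.n_orient):
        angle = o * np.pi / params.n_orient
        ds = sintheta * np.cos(angle) - costheta * np.sin(angle)
        dc = costheta * np.cos(angle) + sintheta * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta ** 2) / (2 * theta_sigma ** 2))
        bank.append([rad * spread for rad in radials])
    return bank


def filter_responses(ch: ChannelImage | np.ndarray,
                     params: PCParams | None = None) -> FilterResponse:
    """Quadrature responses, per-orientation energy, noise floors, weights."""
    params = params or PCParams()
    img = ch.data if isinstance(ch, ChannelImage) else np.asarray(ch, dtype=np.float64)
    F = np.fft.fft2(img)
    bank = loggabor_bank(img.shape, params)

    amplitude, energy, noise_floor, weight = [], [], [], []
    for filters in bank:
        evens, odds, amps = [], [], []
        sum_e = np.zeros_like(img)
        sum_o = np.zeros_like(img)
        sum_a = np.zeros_like(img)
        for filt in filters:
            # the angular lobe covers a single half-plane, so the complex
            # inverse transform is the analytic signal: real part = even
            # (symmetric) response, imaginary part = odd (Hilbert) response
            eo = np.fft.ifft2(F * filt)
            e, od = np.real(eo), np.imag(eo)
            a = np.sqrt(e * e + od * od)
            evens.append(e)
            odds.append(od)
            amps.append(a)
            sum_e += e
            sum_o += od
            sum_a += a

        # mean phase direction
        norm = np.sqrt(sum_e ** 2 + sum_o ** 2) + 1e-12
        me, mo = sum_e / norm, sum_o / norm
        # PC2 energy: projection onto mean phase minus orthogonal deviation
        en_raw = np.zeros_like(img)
        for e, od in zip(evens, odds):
            en_raw += e * me + od * mo - np.abs(e * mo - od * me)
        en = np.maximum(en_raw, 0.0)

        # Rayleigh noise floor calibrated on the energy image itself: the
        # median of E over a mostly-background image estimates the Rayleigh
        # median 1.177 sigma_R, from which mean and spread follow
        sigma_r = np.median(en_raw) / np.sqrt(np.log(4))
        noise_mean = sigma_r * np.sqrt(np.pi / 2)
        noise_sigma = sigma_r * np.sqrt((4 - np.pi) / 2)
        T = noise_mean + params.noise_k * noise_sigma

        # frequency-spread weighting
        amax = np.max(amps, axis=0) + 1e-12
        spread = (sum_a / amax - 1.0) / max(params.n_scale - 1, 1)
        W = 1.0 / (1.0 + np.exp(params.gain * (params.cut_off - spread)))

        amplitude.append(amps)
        energy.append(en)
        noise_floor.append(float(T))
        weight.append(W)

    return FilterResponse(amplitude=amplitude, energy=energy,
                          noise_floor=noise_floor, weight=weight)


def phase_congruency(ch: ChannelImage | np.ndarray,
                     params: PCParams | None = None,
                     return_responses: bool = False):
    """The PC map in [0, 1]."""
    params = params or PCParams()
    resp = filter_responses(ch, params)
    img_shape = resp.energy[0].shape
    num = np.zeros(img_shape)
    den = np.full(img_shape, params.epsilon)
    for o in range(len(resp.energy)):
        num += resp.weight[o] * np.maximum(resp.energy[o] - resp.noise_floor[o], 0.0)
        for a in resp.amplitude[o]:
            den += a
    pc = np.clip(num / den, 0.0, 1.0)
    resp.pc = pc
    return (pc, resp) if return_responses else pc
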