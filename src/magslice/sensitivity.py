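"""NV-magnetometer sensitivity algebra.

Converts between the three noise figures used to characterize a wide-field
NV imaging system:

* volume-normalized sensitivity ``eta_V`` (nT.um^{3/2}.Hz^{-1/2}) -- the
  intrinsic figure of merit of the diamond/readout combination,
* area-normalized noise ``eta = eta_V sqrt(f_s / h)`` (nT.um) -- fixed once
  the NV-layer height ``h`` and sampling rate ``f_s`` are chosen,
* pixel noise ``eta_pixel = eta / Delta`` (nT) -- what a single pixel of
  size ``Delta`` sees per sample.

Trial averaging reduces noise as ``1/sqrt(N)``, giving the number of
stimulus repetitions needed to reach a target noise level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GYROMAGNETIC_HZ_PER_NT",
    "CARBON_DENSITY_PER_UM3_PPM",
    "NVSensorSpec",
    "volume_sensitivity",
    "area_noise",
    "pixel_noise",
    "trials_to_reach",
]

#: NV gyromagnetic ratio g.muB/h, Hz per nT
GYROMAGNETIC_HZ_PER_NT = 28.0

#: carbon atoms per um^3 per ppm in diamond (1.76e5 atoms/um^3/ppm)
CARBON_DENSITY_PER_UM3_PPM = 1.76e5


@dataclass(frozen=True)
class NVSensorSpec:
    """Physical parameters of an NV ensemble magnetometer.

    ``contrast`` is the on-resonance fluorescence contrast C,
    ``collection_efficiency`` the photon collection efficiency epsilon,
    ``nv_density_ppm`` the NV concentration, ``t2_star_us`` the ensemble
    dephasing time, ``layer_height_um`` the NV-layer thickness and
    ``sampling_rate_hz`` the acquisition rate.
    """

    contrast: float
    collection_efficiency: float = 1.0e-2
    nv_density_ppm: float = 1.0
    t2_star_us: float = 0.5
    layer_height_um: float = 5.0
    sampling_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        for name in (
            "contrast",
            "collection_efficiency",
            "nv_density_ppm",
            "t2_star_us",
            "layer_height_um",
            "sampling_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.contrast > 1 or self.collection_efficiency > 1:
            raise ValueError("contrast and collection efficiency are fractions <= 1")

    @property
    def nv_density_per_um3(self) -> float:
        return self.nv_density_ppm * CARBON_DENSITY_PER_UM3_PPM


def volume_sensitivity(spec: NVSensorSpec) -> float:
    """Volume- and bandwidth-normalized sensitivity limit (nT.um^{3/2}.Hz^{-1/2}).

    ``eta_V = (h / g muB) / (C sqrt(eps n_NV T2*))`` with the gyromagnetic
    constant fixed at 28 Hz/nT, the NV density in um^-3 and T2* in seconds.
    """
    t2_s = spec.t2_star_us * 1e-6
    return 1.0 / (
        GYROMAGNETIC_HZ_PER_NT
        * spec.contrast
        * math.sqrt(spec.collection_efficiency * spec.nv_density_per_um3 * t2_s)
    )


def contrast_for_sensitivity(
    eta_v: float,
    collection_efficiency: float = 1.0e-2,
    nv_density_ppm: float = 1.0,
    t2_star_us: float = 0.5,
) -> float:
    """Invert the sensitivity expression for the fluorescence contrast C."""
    if eta_v <= 0:
        raise ValueError("eta_v must be > 0")
    t2_s = t2_star_us * 1e-6
    n = nv_density_ppm * CARBON_DENSITY_PER_UM3_PPM
    return 1.0 / (
        GYROMAGNETIC_HZ_PER_NT * eta_v * math.sqrt(collection_efficiency * n * t2_s)
    )


def area_noise(eta_v: float, layer_height_um: float, sampling_rate_hz: float) -> float:
    """Area-normalized noise ``eta = eta_V sqrt(f_s / h)`` in nT.um."""
    if layer_height_um <= 0 or sampling_rate_hz <= 0:
        raise ValueError("layer height and sampling rate must be > 0")
    return eta_v * math.sqrt(sampling_rate_hz / layer_height_um)


def pixel_noise(eta: float, delta_um: float) -> float:
    """Per-pixel noise ``eta_pixel = eta / Delta`` in nT."""
    if delta_um <= 0:
        raise ValueError("pixel size must be > 0")
    return eta / delta_um


def trials_to_reach(eta_current: float, eta_target: float) -> int:
    """Number of averaged trials to reduce ``eta_current`` to ``eta_target``.

    Averaging N trials reduces white noise by ``sqrt(N)``, so
    ``N = ceil((eta_current / eta_target)^2)``; already-sufficient noise
    levels need a single trial.
    """
    if eta_current <= 0 or eta_target <= 0:
        raise ValueError("noise levels must be > 0")
    if eta_target >= eta_current:
        return 1
    # tiny deduction guards against float noise pushing an exact square up
    return math.ceil((eta_current / eta_target) ** 2 * (1.0 - 1e-12))
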