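"""Template-based compartmental activity: membrane potentials, membrane
currents, axial currents and equivalent current dipoles.

Instead of integrating conductance-based channel dynamics, this module uses
parametric spatiotemporal templates for the membrane potential of the two
activity regimes of an evoked slice response:

* ``non_spiking`` -- each synaptic event produces a double-exponential EPSP
  depolarization that ramps up with distance from the soma within the
  driven dendritic regions (apical/S.R. and basal/S.O., split per the
  schedule's region weights), emulating distally weighted excitatory input.
* ``spiking`` -- additionally, a stereotyped biphasic action-potential
  depolarization peaks at the soma a fixed latency after each synaptic
  event and decays electrotonically into the dendrites, with a longer
  space constant on the apical than on the basal side (the spike
  back-propagates preferentially into the apical trunk).

Axial currents follow from the potential differences along the compartment
tree, ``I_axial^n = (V_m^n - V_m^parent) / (Delta_s^n r_i^n)``, and the
membrane currents follow from current conservation at each node, so the
membrane currents of an isolated cell sum to zero at every instant exactly.
The equivalent current dipole (ECD) is the length-weighted sum of axial
currents; template amplitudes are calibrated against the per-cell ECD
anchor of 0.2 pA.m at an action potential.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .geometry import REGION_APICAL, REGION_BASAL, CellMorphology

__all__ = [
    "WaveformParams",
    "ActivityTrace",
    "ECDSeries",
    "generate_cell_activity",
    "compute_axial_currents",
    "compute_ecd",
    "calibrate_waveforms",
    "STRENGTH_SCALES",
]

# Synaptic-strength conditions are labels mapped onto EPSP amplitude
# factors relative to the sub-threshold (0.3 nS) reference condition.
STRENGTH_SCALES = {"non_spiking": 1.0, "spiking": 2.0, "strong": 4.0}


@dataclass(frozen=True)
class WaveformParams:
    """Spatiotemporal template parameters.

    Times are in ms, potentials in mV.  ``ap_width`` is the full width at
    half maximum of the depolarizing lobe of the action-potential template
    at the 35 degC slice scenario; ``temperature_scale`` multiplies all
    time constants to emulate slower kinetics at lower bath temperatures.
    The spatial spread of the back-propagating spike is set by the apical
    and basal space constants (um).
    """

    dt: float = 0.025
    duration: float = 60.0
    epsp_tau_rise: float = 0.5
    epsp_tau_decay: float = 5.0
    epsp_amplitude: float = 5.0  # mV at the distal apical dendrite per event
    ap_amplitude: float = 80.0  # mV somatic spike amplitude
    ap_width: float = 1.5
    ap_latency: float = 2.0
    case: str = "spiking"
    membrane_tau: float = 1.0  # ms, compartmental low-pass for Vm
    ap_lambda_apical: float = 300.0  # um, back-propagation space constant (apical)
    ap_lambda_basal: float = 100.0  # um, back-propagation space constant (basal)
    v_rest: float = -65.0  # mV
    temperature_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")
        if self.case not in ("non_spiking", "spiking"):
            raise ValueError("case must be 'non_spiking' or 'spiking'")
        if self.case == "spiking" and self.ap_width <= 0:
            raise ValueError("ap_width must be > 0 in the spiking case")
        if min(self.epsp_tau_rise, self.epsp_tau_decay, self.membrane_tau) <= 0:
            raise ValueError("time constants must be > 0")
        if self.temperature_scale <= 0:
            raise ValueError("temperature_scale must be > 0")
        if min(self.ap_lambda_apical, self.ap_lambda_basal) <= 0:
            raise ValueError("space constants must be > 0")

    @property
    def time_base(self) -> np.ndarray:
        return np.arange(0.0, self.duration, self.dt)


@dataclass
class ActivityTrace:
    """Per-compartment time courses of one cell.

    ``Vm`` are membrane potentials (mV, compartments x time), ``Im``
    transmembrane currents (nA; inward negative) and ``I_axial`` the
    derived axial currents (nA, parent-difference convention with zero at
    the root).
    """

    time_base: np.ndarray
    Vm: np.ndarray
    Im: np.ndarray
    I_axial: np.ndarray

    def __post_init__(self) -> None:
        nt = self.time_base.size
        for name in ("Vm", "Im", "I_axial"):
            arr = getattr(self, name)
            if arr.ndim != 2 or arr.shape[1] != nt:
                raise ValueError(f"{name} must be (compartments, time)")


@dataclass
class ECDSeries:
    """Equivalent current dipole time series in pA.m."""

    time_base: np.ndarray
    Q: np.ndarray  # (time, 3) pA.m

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.Q, axis=1)

    @property
    def peak_magnitude(self) -> float:
        return float(self.magnitude.max())


def _double_exponential(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak double-exponential synaptic time course."""
    tt = np.maximum(t, 0.0)
    g = np.where(t >= 0, np.exp(-tt / tau_decay) - np.exp(-tt / tau_rise), 0.0)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return g / peak


def _ap_biphasic(t: np.ndarray, width: float) -> np.ndarray:
    """Unit-peak biphasic action-potential template.

    Difference of two Gaussians with matched areas (zero time integral): a
    fast depolarizing lobe of FWHM ``width`` followed by a shallow
    after-hyperpolarization twice as wide.
    """
    s1 = width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    s2 = 2.0 * s1
    g = np.exp(-0.5 * (t / s1) ** 2) - (s1 / s2) * np.exp(-0.5 * (t / s2) ** 2)
    return g / g.max()


def _branch_arclength_from_soma(cell: CellMorphology) -> np.ndarray:
    """Arc-length distance of each compartment midpoint from the soma."""
    mids = 0.5 * (cell.starts + cell.ends)
    return np.linalg.norm(mids - cell.soma_position, axis=1)


def _epsp_profile(cell: CellMorphology, region_weights: dict[str, float]) -> np.ndarray:
    """Spatial EPSP depolarization profile (1 at the reference distal site).

    Within each driven region the depolarization ramps linearly with
    distance from the soma -- synaptic drive is distally weighted, and the
    normalization is common to both regions, so a longer branch reaches a
    proportionally larger distal depolarization.
    """
    dist = _branch_arclength_from_soma(cell)
    ref = dist.max()
    u = np.zeros(cell.n_compartments)
    for region, frac in region_weights.items():
        idx = cell.region_indices(region)
        if idx.size:
            u[idx] = frac * dist[idx] / ref
    if not np.any(u > 0):
        raise ValueError("no driven compartments for the given region weights")
    return u / u.max()


def _ap_profile(cell: CellMorphology, params: WaveformParams) -> np.ndarray:
    """Spatial profile of the back-propagating somatic spike (1 at soma)."""
    dist = _branch_arclength_from_soma(cell)
    u = np.exp(-dist / params.ap_lambda_apical)
    basal = cell.region_indices(REGION_BASAL)
    u[basal] = np.exp(-dist[basal] / params.ap_lambda_basal)
    u[cell.soma_index] = 1.0
    return u


def generate_cell_activity(
    cell: CellMorphology,
    event_times,
    params: WaveformParams,
    region_weights: dict[str, float] | None = None,
) -> ActivityTrace:
    """Generate membrane potentials and currents for one cell.

    The membrane potential is a low-pass filtered (time constant
    ``membrane_tau``) superposition of the EPSP and action-potential
    templates; membrane currents are derived from the axial currents by
    current conservation at every node, so they sum to zero exactly.
    """
    t = params.time_base
    events = np.atleast_1d(np.asarray(event_times, dtype=float))
    if events.size and (events.min() < 0 or events.max() > params.duration):
        raise ValueError("event time outside the activity time base")
    if region_weights is None:
        region_weights = {REGION_APICAL: 0.5, REGION_BASAL: 0.5}

    scale_t = params.temperature_scale
    g_epsp = np.zeros_like(t)
    g_ap = np.zeros_like(t)
    for t0 in events:
        g_epsp += _double_exponential(
            t - t0, params.epsp_tau_rise * scale_t, params.epsp_tau_decay * scale_t
        )
        if params.case == "spiking":
            g_ap += _ap_biphasic(
                t - (t0 + params.ap_latency * scale_t), params.ap_width * scale_t
            )

    # compartmental low-pass response (one-pole filter)
    alpha = params.dt / (params.membrane_tau * scale_t + params.dt)
    g_epsp = lfilter([alpha], [1.0, alpha - 1.0], g_epsp)
    g_ap = lfilter([alpha], [1.0, alpha - 1.0], g_ap)

    Vm = np.full((cell.n_compartments, t.size), params.v_rest)
    if events.size:
        u_epsp = _epsp_profile(cell, region_weights)
        Vm = Vm + params.epsp_amplitude * np.outer(u_epsp, g_epsp)
        if params.case == "spiking":
            u_ap = _ap_profile(cell, params)
            Vm = Vm + params.ap_amplitude * np.outer(u_ap, g_ap)

    I_axial = compute_axial_currents(cell, Vm)
    Im = _membrane_currents_from_axial(cell, I_axial)
    return ActivityTrace(time_base=t, Vm=Vm, Im=Im, I_axial=I_axial)


def _membrane_currents_from_axial(cell: CellMorphology, I_axial: np.ndarray) -> np.ndarray:
    """Membrane currents by Kirchhoff's law at each compartment node.

    ``I_axial^n`` is the current flowing from compartment ``n`` into its
    parent; the outward membrane current is the inflow from the children
    minus the outflow to the parent.  Summing over the tree telescopes to
    the root's (zero) axial current, so conservation is exact.
    """
    Im = -I_axial.copy()
    has_parent = cell.parent >= 0
    idx = np.flatnonzero(has_parent)
    np.add.at(Im, cell.parent[idx], I_axial[idx])
    return Im


def compute_axial_currents(cell: CellMorphology, Vm: np.ndarray) -> np.ndarray:
    """Axial current of each compartment from the membrane potentials.

    ``I_axial[n] = (Vm[n] - Vm[parent(n)]) / (Delta_s[n] * r_i[n])`` in nA;
    the root compartment carries no axial current.
    """
    Vm = np.asarray(Vm, dtype=float)
    if Vm.shape[0] != cell.n_compartments:
        raise ValueError("Vm must have one row per compartment")
    I = np.zeros_like(Vm)
    idx = np.flatnonzero(cell.parent >= 0)
    parents = cell.parent[idx]
    denom = (cell.lengths[idx] * cell.r_i[idx])[:, None]  # um * MOhm/um = MOhm
    I[idx] = (Vm[idx] - Vm[parents]) / denom  # mV / MOhm = nA
    return I


def compute_ecd(cell: CellMorphology, I_axial: np.ndarray) -> ECDSeries:
    """Equivalent current dipole ``Q(t) = sum_k I_axial^k(t) L^k`` in pA.m.

    ``L^k`` is the compartment's vector length (end - start); 1 nA.um =
    1e-3 pA.m.
    """
    I_axial = np.asarray(I_axial, dtype=float)
    if I_axial.shape[0] != cell.n_compartments:
        raise ValueError("I_axial must have one row per compartment")
    L = cell.ends - cell.starts  # um
    Q_nAum = I_axial.T @ L  # (time, 3) nA.um
    nt = I_axial.shape[1]
    return ECDSeries(time_base=np.arange(nt, dtype=float), Q=Q_nAum * 1e-3)


def _single_event_peak_ecd(params: WaveformParams, cell: CellMorphology) -> float:
    spiking = replace(params, case="spiking")
    trace = generate_cell_activity(cell, [spiking.duration / 2.0], spiking)
    return compute_ecd(cell, trace.I_axial).peak_magnitude


def calibrate_waveforms(
    params: WaveformParams,
    target_peak_ecd: float = 0.2,
    cell: CellMorphology | None = None,
) -> WaveformParams:
    """Scale template amplitudes so a single spiking event peaks at the
    target ECD magnitude (pA.m).

    Both EPSP and AP amplitudes are scaled by the same factor, preserving
    their ratio; by linearity the calibration is exact and idempotent.
    """
    if target_peak_ecd <= 0:
        raise ValueError("target_peak_ecd must be > 0")
    if cell is None:
        from .geometry import build_template_cell

        cell = build_template_cell()
    peak = _single_event_peak_ecd(params, cell)
    if peak <= 0:
        raise ValueError("template produces zero ECD; cannot calibrate")
    factor = target_peak_ecd / peak
    return replace(
        params,
        epsp_amplitude=params.epsp_amplitude * factor,
        ap_amplitude=params.ap_amplitude * factor,
    )
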