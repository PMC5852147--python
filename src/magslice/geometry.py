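"""Simplified pyramidal-cell geometries and randomized population layouts.

The coordinate convention follows the imaging geometry: the diamond sensor
surface is the plane ``z = 0``, the slice occupies ``z > 0``, ``x`` spans the
slice width and ``y`` is the dendritic (somato-dendritic) axis of the
pyramidal cells.  All positions and lengths are in micrometres.

A cell is represented as a tree of straight cylindrical compartments.  The
template builder produces a three-branch "ball-and-stick" stand-in for a CA1
pyramidal cell: a basal chain (stratum oriens), a soma compartment, and an
apical chain (stratum radiatum), all aligned with +Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Compartment",
    "CellMorphology",
    "PopulationLayout",
    "SynapticSchedule",
    "build_template_cell",
    "place_population",
    "sample_event_times",
    "REGION_SOMA",
    "REGION_APICAL",
    "REGION_BASAL",
]

REGION_SOMA = "soma"
REGION_APICAL = "apical"  # stratum radiatum (S.R.)
REGION_BASAL = "basal"  # stratum oriens (S.O.)

_VALID_REGIONS = (REGION_SOMA, REGION_APICAL, REGION_BASAL)


@dataclass(frozen=True)
class Compartment:
    """One straight cylindrical compartment of a cell.

    ``axial_resistance_per_length`` is the intracellular (axial) resistance
    per unit length in MOhm/um, so that a 1 mV potential difference across a
    compartment of total axial resistance 1 MOhm drives 1 nA.
    """

    start_point: np.ndarray  # um, shape (3,)
    end_point: np.ndarray  # um, shape (3,)
    axial_resistance_per_length: float  # MOhm/um
    parent_index: int | None  # None for the root
    region: str = REGION_SOMA

    @property
    def length(self) -> float:
        """Euclidean length Delta-s in um."""
        return float(np.linalg.norm(self.end_point - self.start_point))

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("compartment length must be > 0")
        if self.axial_resistance_per_length <= 0:
            raise ValueError("axial resistance per length must be > 0")
        if self.region not in _VALID_REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class CellMorphology:
    """A connected tree of compartments with one root (the soma).

    Array attributes are the primary representation (``starts``, ``ends``:
    (N, 3) um; ``r_i``: (N,) MOhm/um; ``parent``: (N,) int, -1 at the root);
    :class:`Compartment` records are views for convenience.
    """

    starts: np.ndarray
    ends: np.ndarray
    r_i: np.ndarray
    parent: np.ndarray
    regions: list[str]
    soma_index: int
    main_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.r_i = np.asarray(self.r_i, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        n = self.n_compartments
        if not (self.ends.shape == (n, 3) and self.r_i.shape == (n,) and self.parent.shape == (n,)):
            raise ValueError("inconsistent morphology array shapes")
        if len(self.regions) != n:
            raise ValueError("one region label per compartment required")
        if not np.isclose(np.linalg.norm(self.main_axis), 1.0):
            raise ValueError("main_axis must have unit norm")
        if np.any(self.lengths <= 0):
            raise ValueError("all compartment lengths must be > 0")
        if np.any(self.r_i <= 0):
            raise ValueError("all axial resistances must be > 0")
        if np.sum(self.parent < 0) != 1:
            raise ValueError("compartments must form a tree with exactly one root")
        self._check_connected()

    def _check_connected(self) -> None:
        n = self.n_compartments
        root = int(np.flatnonzero(self.parent < 0)[0])
        seen = np.zeros(n, dtype=bool)
        seen[root] = True
        frontier = [root]
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)
        while frontier:
            node = frontier.pop()
            for c in children.get(node, ()):
                seen[c] = True
                frontier.append(c)
        if not seen.all():
            raise ValueError("compartment tree is not connected")

    @property
    def n_compartments(self) -> int:
        return self.starts.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        """Per-compartment lengths Delta-s in um."""
        return np.linalg.norm(self.ends - self.starts, axis=1)

    @property
    def compartments(self) -> list[Compartment]:
        return [
            Compartment(
                start_point=self.starts[i],
                end_point=self.ends[i],
                axial_resistance_per_length=float(self.r_i[i]),
                parent_index=None if self.parent[i] < 0 else int(self.parent[i]),
                region=self.regions[i],
            )
            for i in range(self.n_compartments)
        ]

    @property
    def soma_position(self) -> np.ndarray:
        """Midpoint of the soma compartment, um."""
        i = self.soma_index
        return 0.5 * (self.starts[i] + self.ends[i])

    def region_indices(self, region: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.regions) == region)

    def translated(self, offset: np.ndarray) -> "CellMorphology":
        offset = np.asarray(offset, dtype=float)
        return replace(
            self,
            starts=self.starts + offset,
            ends=self.ends + offset,
            regions=list(self.regions),
        )

    def rotated_about_y(self, angle: float, center: np.ndarray | None = None) -> "CellMorphology":
        """Rotate the cell about a +Y axis through ``center`` (default: soma)."""
        if center is None:
            center = self.soma_position
        center = np.asarray(center, dtype=float)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        return replace(
            self,
            starts=(self.starts - center) @ rot.T + center,
            ends=(self.ends - center) @ rot.T + center,
            regions=list(self.regions),
        )


@dataclass(frozen=True)
class PopulationLayout:
    """Geometry of the active tissue patch above the sensor.

    The active volume spans ``width_x`` x ``length_y`` laterally (centred on
    the origin) and ``active_thickness_d`` in depth, starting at
    ``dead_layer_z0`` above the diamond surface.  It is divided into
    Z-layers of ``layer_thickness`` each holding ``cells_per_layer`` cells,
    with soma Y positions jittered within a ``soma_band_width_y`` wide band.
    """

    width_x: float = 500.0
    length_y: float = 500.0
    active_thickness_d: float = 300.0
    dead_layer_z0: float = 50.0
    cells_per_layer: int = 1000
    layer_thickness: float = 50.0
    soma_band_width_y: float = 50.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("width_x", "length_y", "active_thickness_d", "layer_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dead_layer_z0 < 0:
            raise ValueError("dead_layer_z0 must be >= 0")
        if self.soma_band_width_y < 0:
            raise ValueError("soma_band_width_y must be >= 0")
        if self.cells_per_layer < 1:
            raise ValueError("cells_per_layer must be >= 1")
        n = self.active_thickness_d / self.layer_thickness
        if abs(n - round(n)) > 1e-9:
            raise ValueError("active_thickness_d must be an integer multiple of layer_thickness")

    @property
    def n_layers(self) -> int:
        return int(round(self.active_thickness_d / self.layer_thickness))

    @property
    def n_cells(self) -> int:
        return self.n_layers * self.cells_per_layer


@dataclass
class SynapticSchedule:
    """Per-cell synaptic event times with Gaussian timing jitter.

    ``region_weights`` give the fraction of synaptic drive delivered to the
    apical (S.R.) and basal (S.O.) dendrites; they must sum to one.
    ``strength_label`` records the synaptic-strength condition of the
    schedule (sub-threshold / just-spiking / strong drive).
    """

    base_event_times: np.ndarray  # ms
    jitter_sigma: float  # ms
    per_cell_event_times: np.ndarray  # (cells, events) ms
    region_weights: dict[str, float] = field(
        default_factory=lambda: {REGION_APICAL: 0.5, REGION_BASAL: 0.5}
    )
    strength_label: str = "spiking"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.base_event_times = np.atleast_1d(np.asarray(self.base_event_times, dtype=float))
        self.per_cell_event_times = np.atleast_2d(
            np.asarray(self.per_cell_event_times, dtype=float)
        )
        if self.per_cell_event_times.shape[1] != self.base_event_times.size:
            raise ValueError("per_cell_event_times columns must match base_event_times")
        total = sum(self.region_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError("region_weights must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.per_cell_event_times.shape[0]


def build_template_cell(
    apical_length: float = 300.0,
    basal_length: float = 200.0,
    n_compartments_per_branch: int = 10,
    r_i: float = 0.12,
    soma_length: float = 20.0,
) -> CellMorphology:
    """Build the three-branch stand-in cell aligned with +Y.

    The cell spans ``[-basal_length, +apical_length]`` along Y with the soma
    compartment (length ``soma_length``) centred on the origin; the apical
    and basal chains fill the remaining span with
    ``n_compartments_per_branch`` compartments each.  Total compartment
    count is ``2 * n_compartments_per_branch + 1``.
    """
    if apical_length <= soma_length / 2 or basal_length <= soma_length / 2:
        raise ValueError("branch lengths must exceed half the soma length")
    if n_compartments_per_branch < 1:
        raise ValueError("n_compartments_per_branch must be >= 1")
    if r_i <= 0:
        raise ValueError("r_i must be > 0")
    if soma_length <= 0:
        raise ValueError("soma_length must be > 0")

    half = soma_length / 2.0
    nb = n_compartments_per_branch

    starts: list[list[float]] = []
    ends: list[list[float]] = []
    parents: list[int] = []
    regions: list[str] = []

    # soma: index 0, root
    starts.append([0.0, -half, 0.0])
    ends.append([0.0, half, 0.0])
    parents.append(-1)
    regions.append(REGION_SOMA)

    # apical chain: from soma top towards +Y (stratum radiatum)
    apical_nodes = np.linspace(half, apical_length, nb + 1)
    prev = 0
    for i in range(nb):
        starts.append([0.0, apical_nodes[i], 0.0])
        ends.append([0.0, apical_nodes[i + 1], 0.0])
        parents.append(prev)
        regions.append(REGION_APICAL)
        prev = len(parents) - 1

    # basal chain: from soma bottom towards -Y (stratum oriens)
    basal_nodes = np.linspace(-half, -basal_length, nb + 1)
    prev = 0
    for i in range(nb):
        starts.append([0.0, basal_nodes[i], 0.0])
        ends.append([0.0, basal_nodes[i + 1], 0.0])
        parents.append(prev)
        regions.append(REGION_BASAL)
        prev = len(parents) - 1

    n = len(parents)
    return CellMorphology(
        starts=np.asarray(starts),
        ends=np.asarray(ends),
        r_i=np.full(n, float(r_i)),
        parent=np.asarray(parents),
        regions=regions,
        soma_index=0,
    )


def place_population(
    layout: PopulationLayout, template: CellMorphology
) -> list[CellMorphology]:
    """Place randomized copies of ``template`` according to ``layout``.

    Soma X and Z are uniform within each Z-layer footprint, soma Y is uniform
    within the soma band, and each cell is rotated by a uniform angle about
    the +Y axis through its soma.  Placement is deterministic given
    ``layout.rng_seed``.
    """
    if not np.allclose(template.main_axis, [0.0, 1.0, 0.0]):
        raise ValueError("template main_axis must be +Y")
    rng = np.random.default_rng(layout.rng_seed)
    cells: list[CellMorphology] = []
    for layer in range(layout.n_layers):
        z_lo = layout.dead_layer_z0 + layer * layout.layer_thickness
        for _ in range(layout.cells_per_layer):
            x = rng.uniform(-layout.width_x / 2.0, layout.width_x / 2.0)
            y = rng.uniform(-layout.soma_band_width_y / 2.0, layout.soma_band_width_y / 2.0)
            z = z_lo + rng.uniform(0.0, layout.layer_thickness)
            angle = rng.uniform(0.0, 2.0 * np.pi)
            cell = template.translated(np.array([x, y, z]) - template.soma_position)
            cell = cell.rotated_about_y(angle)
            cells.append(cell)
    return cells


def sample_event_times(
    base_times,
    sigma: float,
    n_cells: int,
    rng_seed: int = 0,
    region_weights: dict[str, float] | None = None,
    strength_label: str = "spiking",
) -> SynapticSchedule:
    """Draw per-cell event times ``base + N(0, sigma^2)``, one row per cell."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    base = np.atleast_1d(np.asarray(base_times, dtype=float))
    rng = np.random.default_rng(rng_seed)
    jitter = rng.normal(0.0, sigma, size=(n_cells, base.size)) if sigma > 0 else np.zeros(
        (n_cells, base.size)
    )
    kwargs = {} if region_weights is None else {"region_weights": dict(region_weights)}
    return SynapticSchedule(
        base_event_times=base,
        jitter_sigma=float(sigma),
        per_cell_event_times=base[None, :] + jitter,
        strength_label=strength_label,
        rng_seed=rng_seed,
        **kwargs,
    )
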