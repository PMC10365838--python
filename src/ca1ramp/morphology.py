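"""Reduced CA1 pyramidal-cell morphology and spatial channel-density gradients.

The full reconstructed morphology of a CA1 pyramidal neuron is replaced by a
parameterized ball-and-stick: a spherical soma, a uniform apical trunk
cylinder, and an optional basal stub.  The mechanisms under study (somatic
spike-rate adaptation and its reversal by a soma/proximal TRPM4 conductance)
are local to the soma and proximal trunk, so this reduction preserves the
relevant electrotonic structure while keeping the model fully specified by a
handful of geometric parameters.

Spatial rules applied on top of uniform base densities:

* h-conductance rises linearly with path distance to 7x its somatic value at
  ``gradient_span`` (then stays constant),
* A-type K+ conductance rises to 6x over the same span,
* dendritic Na+ conductance is 75% of the somatic value everywhere outside
  the soma,
* membrane and axial resistivity fall sigmoidally with distance (logistic in
  path distance), lowering distal input resistance,
* a spine factor >= 1 multiplies the membrane area of dendritic segments.

Distances are path distances from the soma center to segment centers, in um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "GradientRules",
    "ChannelDensityMap",
    "CHANNEL_NAMES",
    "build_reduced_morphology",
    "apply_gradients",
]

#: Channels carried by every segment (conductance densities in S/cm2).
CHANNEL_NAMES = (
    "na",
    "cal",
    "car",
    "cat",
    "kv1",
    "kv2",
    "ka",
    "kir",
    "h",
    "leak",
    "trpm4",
)

#: Default reversal potentials, mV.
DEFAULT_REVERSALS = {
    "na": 55.0,
    "cal": 120.0,
    "car": 120.0,
    "cat": 120.0,
    "kv1": -90.0,
    "kv2": -90.0,
    "ka": -90.0,
    "kir": -90.0,
    "h": -30.0,
    "leak": -66.0,
    "trpm4": 0.0,
}


@dataclass
class Section:
    """A neurite section discretized into ``n_segments`` iso-potential segments.

    Parameters
    ----------
    name
        Section label (``"soma"``, ``"apical"``, ``"basal"``).
    length, diameter
        Geometry in um.  The soma is treated as a sphere of diameter
        ``diameter`` (its ``length`` is ignored for area purposes).
    n_segments
        Number of equal-length segments.
    R_m, R_a, C_m
        Base passive parameters: specific membrane resistance (Ohm cm2),
        axial resistivity (Ohm cm), specific capacitance (uF/cm2).
    spine_factor
        Multiplier (>= 1) on membrane area accounting for spines.
    """

    name: str
    length: float
    diameter: float
    n_segments: int = 1
    R_m: float = 28_000.0
    R_a: float = 150.0
    C_m: float = 1.0
    spine_factor: float = 1.0
    is_soma: bool = False
    # Path distance (um) from the soma center to this section's proximal end.
    proximal_distance: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(
                f"section {self.name!r}: length and diameter must be positive"
            )
        if self.n_segments < 1:
            raise ValueError(f"section {self.name!r}: n_segments must be >= 1")
        if self.spine_factor < 1.0:
            raise ValueError(f"section {self.name!r}: spine_factor must be >= 1")

    @property
    def segment_length(self) -> float:
        return self.length / self.n_segments

    @property
    def path_distance_of_segment_centers(self) -> np.ndarray:
        """Path distance (um) from soma center to each segment center."""
        if self.is_soma:
            return np.zeros(self.n_segments)
        dx = self.segment_length
        return self.proximal_distance + dx * (np.arange(self.n_segments) + 0.5)

    def segment_areas(self) -> np.ndarray:
        """Membrane area per segment, um2, including the spine factor."""
        if self.is_soma:
            # Sphere split evenly across segments (normally 1 segment).
            total = math.pi * self.diameter**2 * self.spine_factor
            return np.full(self.n_segments, total / self.n_segments)
        lateral = math.pi * self.diameter * self.segment_length
        return np.full(self.n_segments, lateral * self.spine_factor)


@dataclass
class Morphology:
    """Tree of sections; exactly one soma, children attach to a parent."""

    sections: list[Section]
    # parent[name] = name of parent section; soma has no entry.
    parents: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        somas = [s for s in self.sections if s.is_soma]
        if len(somas) != 1:
            raise ValueError("morphology must contain exactly one soma")
        names = {s.name for s in self.sections}
        for child, parent in self.parents.items():
            if child not in names or parent not in names:
                raise ValueError(f"connectivity refers to unknown section: {child}->{parent}")
        # tree check: every non-soma section must reach the soma
        soma = somas[0].name
        for s in self.sections:
            if s.is_soma:
                continue
            seen, cur = set(), s.name
            while cur != soma:
                if cur in seen or cur not in self.parents:
                    raise ValueError(f"section {s.name!r} is not connected to the soma")
                seen.add(cur)
                cur = self.parents[cur]

    @property
    def soma(self) -> Section:
        return next(s for s in self.sections if s.is_soma)

    @property
    def n_compartments(self) -> int:
        return sum(s.n_segments for s in self.sections)

    def flatten(self):
        """Flatten to per-compartment arrays in section order.

        Returns a dict with keys ``section`` (labels), ``distance`` (um),
        ``area`` (um2, spine-corrected), ``diameter`` (um), ``seg_length``
        (um), ``parent_index`` (int, -1 for the root/soma), and ``is_soma``.
        Compartments within a section form a chain; the first segment of a
        child section couples to the last segment of its parent.
        """
        labels: list[str] = []
        dist: list[float] = []
        area: list[float] = []
        diam: list[float] = []
        seg_len: list[float] = []
        is_soma: list[bool] = []
        parent_index: list[int] = []
        first_idx: dict[str, int] = {}
        last_idx: dict[str, int] = {}

        idx = 0
        for s in self.sections:
            first_idx[s.name] = idx
            centers = s.path_distance_of_segment_centers
            areas = s.segment_areas()
            for j in range(s.n_segments):
                labels.append(s.name)
                dist.append(float(centers[j]))
                area.append(float(areas[j]))
                diam.append(s.diameter)
                seg_len.append(s.segment_length if not s.is_soma else s.diameter)
                is_soma.append(s.is_soma)
                if j == 0:
                    if s.is_soma:
                        parent_index.append(-1)
                    else:
                        parent_index.append(last_idx[self.parents[s.name]])
                else:
                    parent_index.append(idx - 1)
                idx += 1
            last_idx[s.name] = idx - 1

        return {
            "section": labels,
            "distance": np.asarray(dist),
            "area": np.asarray(area),
            "diameter": np.asarray(diam),
            "seg_length": np.asarray(seg_len),
            "is_soma": np.asarray(is_soma),
            "parent_index": np.asarray(parent_index, dtype=np.int64),
        }

    def total_area(self) -> float:
        """Total membrane area, um2 (spine-corrected)."""
        return float(sum(s.segment_areas().sum() for s in self.sections))


@dataclass
class GradientRules:
    """Spatial rules for channel densities and passive parameters.

    ``h_fold`` and ``ka_fold`` are the fold increases reached linearly at
    ``gradient_span`` um from the soma (constant beyond).  ``na_dend_factor``
    scales every dendritic segment's Na density relative to the soma.  The
    sigmoidal fall of R_m and R_a is ``1 - depth + depth/(1+exp((d-mid)/slope))``
    so distal values approach ``(1-depth)`` of the somatic value.
    """

    h_fold: float = 7.0
    ka_fold: float = 6.0
    na_dend_factor: float = 0.75
    gradient_span: float = 350.0
    sigmoid_mid: float = 150.0
    sigmoid_slope: float = 50.0
    sigmoid_depth: float = 0.5

    def fold(self, channel: str, distance: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(distance, dtype=float) / self.gradient_span, 0.0, 1.0)
        if channel == "h":
            return 1.0 + (self.h_fold - 1.0) * x
        if channel == "ka":
            return 1.0 + (self.ka_fold - 1.0) * x
        raise KeyError(channel)

    def passive_scale(self, distance: np.ndarray) -> np.ndarray:
        d = np.asarray(distance, dtype=float)
        return 1.0 - self.sigmoid_depth + self.sigmoid_depth / (
            1.0 + np.exp((d - self.sigmoid_mid) / self.sigmoid_slope)
        )


@dataclass
class ChannelDensityMap:
    """Per-compartment conductance densities (S/cm2) and reversals (mV)."""

    density: dict[str, np.ndarray]
    reversal: dict[str, float]
    R_m: np.ndarray
    R_a: np.ndarray
    C_m: np.ndarray
    distance: np.ndarray

    def __post_init__(self) -> None:
        for name, g in self.density.items():
            if np.any(np.asarray(g) < 0):
                raise ValueError(f"negative density for channel {name!r}")

    def to_frame(self):
        """Human-readable per-segment table (pandas DataFrame)."""
        import pandas as pd

        cols = {"distance_um": self.distance}
        for name in CHANNEL_NAMES:
            cols[f"g_{name}_S_per_cm2"] = self.density[name]
        cols["R_m_ohm_cm2"] = self.R_m
        cols["R_a_ohm_cm"] = self.R_a
        return pd.DataFrame(cols)


def build_reduced_morphology(
    soma_diameter: float = 20.0,
    trunk_length: float = 400.0,
    trunk_diameter: float = 2.0,
    trunk_segments: int = 20,
    basal_length: float = 0.0,
    basal_diameter: float = 2.0,
    basal_segments: int = 1,
    spine_factor: float = 2.0,
    R_m: float = 28_000.0,
    R_a: float = 150.0,
    C_m: float = 1.0,
) -> Morphology:
    """Build the default ball-and-stick morphology.

    A spherical soma plus a uniform apical trunk; a basal stub is added when
    ``basal_length > 0``.  ``spine_factor`` applies to dendritic sections
    only (the soma has no spines).
    """
    if soma_diameter <= 0 or trunk_length <= 0 or trunk_diameter <= 0:
        raise ValueError("soma and trunk geometry must be positive")
    sections = [
        Section(
            "soma",
            length=soma_diameter,
            diameter=soma_diameter,
            n_segments=1,
            R_m=R_m,
            R_a=R_a,
            C_m=C_m,
            is_soma=True,
        ),
        Section(
            "apical",
            length=trunk_length,
            diameter=trunk_diameter,
            n_segments=trunk_segments,
            R_m=R_m,
            R_a=R_a,
            C_m=C_m,
            spine_factor=spine_factor,
            proximal_distance=soma_diameter / 2.0,
        ),
    ]
    parents = {"apical": "soma"}
    if basal_length > 0:
        sections.append(
            Section(
                "basal",
                length=basal_length,
                diameter=basal_diameter,
                n_segments=basal_segments,
                R_m=R_m,
                R_a=R_a,
                C_m=C_m,
                spine_factor=spine_factor,
                proximal_distance=soma_diameter / 2.0,
            )
        )
        parents["basal"] = "soma"
    return Morphology(sections, parents)


#: Default somatic conductance densities, S/cm2 (tuned; see docs/methods.md).
DEFAULT_BASE_DENSITIES = {
    "na": 0.032,
    "cal": 0.0006,
    "car": 0.0003,
    "cat": 0.0007,
    "kv1": 0.015,
    "kv2": 0.003,
    "ka": 0.002,
    "kir": 0.0003,
    "h": 0.00005,
    "leak": 1.0 / 28_000.0,
    "trpm4": 0.0033,
}

#: Path distance (um) out to which TRPM4 conductance is placed by default.
DEFAULT_TRPM4_EXTENT = 100.0


def apply_gradients(
    morphology: Morphology,
    base_densities: dict[str, float] | None = None,
    rules: GradientRules | None = None,
    reversals: dict[str, float] | None = None,
    trpm4_extent: float = DEFAULT_TRPM4_EXTENT,
) -> ChannelDensityMap:
    """Turn somatic base densities into a per-compartment density map.

    The soma carries the base densities unchanged; dendritic segments get the
    linear h/KA gradients, the 75% Na scaling, the sigmoidal R_m/R_a fall,
    and TRPM4 restricted to soma plus proximal apical (within
    ``trpm4_extent`` um).
    """
    base = dict(DEFAULT_BASE_DENSITIES)
    if base_densities:
        unknown = set(base_densities) - set(CHANNEL_NAMES)
        if unknown:
            raise KeyError(f"unknown channel name(s): {sorted(unknown)}")
        base.update(base_densities)
    for name, g in base.items():
        if g < 0:
            raise ValueError(f"negative base density for {name!r}")
    rules = rules or GradientRules()
    rev = dict(DEFAULT_REVERSALS)
    if reversals:
        rev.update(reversals)

    flat = morphology.flatten()
    dist = flat["distance"]
    soma_mask = flat["is_soma"]

    density: dict[str, np.ndarray] = {}
    for name in CHANNEL_NAMES:
        g = np.full(dist.shape, base[name], dtype=float)
        if name in ("h", "ka"):
            g = base[name] * rules.fold(name, dist)
            g[soma_mask] = base[name]
        elif name == "na":
            g[~soma_mask] = base[name] * rules.na_dend_factor
        elif name == "trpm4":
            g[dist > trpm4_extent] = 0.0
        density[name] = g

    scale = rules.passive_scale(dist)
    scale[soma_mask] = 1.0
    # leak conductance is 1/R_m, so the sigmoidal R_m fall raises it distally
    density["leak"] = density["leak"] / scale
    soma = morphology.soma
    return ChannelDensityMap(
        density=density,
        reversal=rev,
        R_m=soma.R_m * scale,
        R_a=soma.R_a * scale,
        C_m=np.full(dist.shape, soma.C_m),
        distance=dist,
    )
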