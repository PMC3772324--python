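"""Neuron morphologies: SWC I/O, synthetic builder, spines, cable discretization.

Geometry is stored in micrometres throughout; electrical formulas convert to
cgs (cm) internally.  A morphology is first represented as a
:class:`SegmentTree` (point/parent skeleton, as in an SWC file) and then
discretized into a :class:`CompartmentGraph` of iso-potential compartments
coupled by axial conductances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SegmentNode",
    "SegmentTree",
    "Compartment",
    "CompartmentGraph",
    "read_swc",
    "write_swc",
    "build_synthetic_morphology",
    "attach_spine",
    "coupling_conductance",
    "discretize",
    "apply_spine_correction",
    "SwcParseError",
    "MorphologyError",
]

# SWC structure codes: 1 = soma, 3/4 = dendrite, 5 = custom (spine head here)
_SWC_TO_LABEL = {1: "soma", 2: "dendrite", 3: "dendrite", 4: "dendrite", 5: "spine_head"}
_LABEL_TO_SWC = {"soma": 1, "dendrite": 3, "spine_head": 5, "spine_neck": 5}

REGION_ORDER = ("soma", "proximal", "middle", "distal", "spine")

#: Default path-distance boundaries (μm) separating proximal / middle / distal
#: dendrite.  Places a 25 μm spine in "proximal" and a 100 μm spine at the
#: distal border, matching the density tiers used for the channel tables.
DEFAULT_REGION_BOUNDARIES = (50.0, 100.0)


class SwcParseError(ValueError):
    """Malformed SWC content (reports the offending line number)."""


class MorphologyError(ValueError):
    """Structurally invalid morphology (orphan nodes, bad geometry...)."""


@dataclass(frozen=True)
class SegmentNode:
    id: int
    parent_id: int | None
    x: float
    y: float
    z: float
    radius: float  # μm
    label: str  # soma | dendrite | spine_neck | spine_head


@dataclass
class SegmentTree:
    """Point/parent skeleton of a neuron (SWC semantics)."""

    nodes: list[SegmentNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise MorphologyError("duplicate node ids")
        roots = [n for n in self.nodes if n.parent_id is None]
        if self.nodes and len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        idset = set(ids)
        for n in self.nodes:
            if n.parent_id is not None and n.parent_id not in idset:
                raise MorphologyError(
                    f"node {n.id} references missing parent {n.parent_id}"
                )
            if n.radius <= 0:
                raise MorphologyError(f"node {n.id} has non-positive radius")
        # acyclicity / connectivity: every node must reach the root
        parent = {n.id: n.parent_id for n in self.nodes}
        for n in self.nodes:
            seen: set[int] = set()
            cur: int | None = n.id
            while cur is not None:
                if cur in seen:
                    raise MorphologyError(f"cycle detected at node {cur}")
                seen.add(cur)
                cur = parent[cur]

    @property
    def root(self) -> SegmentNode:
        return next(n for n in self.nodes if n.parent_id is None)

    def node(self, node_id: int) -> SegmentNode:
        return next(n for n in self.nodes if n.id == node_id)

    def children(self, node_id: int) -> list[SegmentNode]:
        return [n for n in self.nodes if n.parent_id == node_id]

    def path_distance(self, node_id: int) -> float:
        """Path distance (μm) from the node to the root along the skeleton."""
        dist = 0.0
        n = self.node(node_id)
        while n.parent_id is not None:
            p = self.node(n.parent_id)
            dist += math.dist((n.x, n.y, n.z), (p.x, p.y, p.z))
            n = p
        return dist

    def next_id(self) -> int:
        return max((n.id for n in self.nodes), default=0) + 1


def read_swc(path) -> SegmentTree:
    """Read a standard 7-column SWC file into a :class:`SegmentTree`.

    Structure codes 1 → soma, 2/3/4 → dendrite, 5 → spine head (the code this
    package uses when writing spine attachments).
    """
    nodes: list[SegmentNode] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                code = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"line {lineno}: {exc}") from exc
            label = _SWC_TO_LABEL.get(code, "dendrite")
            nodes.append(
                SegmentNode(nid, None if pid == -1 else pid, x, y, z, r, label)
            )
    return SegmentTree(nodes)


def write_swc(tree: SegmentTree, path) -> None:
    """Write a :class:`SegmentTree` as standard 7-column SWC.

    Spine heads are written with custom structure code 5 so that a round trip
    preserves them.
    """
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in tree.nodes:
            pid = -1 if n.parent_id is None else n.parent_id
            fh.write(
                f"{n.id} {_LABEL_TO_SWC[n.label]} {n.x:.6g} {n.y:.6g} {n.z:.6g} "
                f"{n.radius:.6g} {pid}\n"
            )


def build_synthetic_morphology(
    n_primary_dendrites: int = 4,
    dendrite_length_um: float = 200.0,
    soma_diameter_um: float = 16.0,
    initial_diameter_um: float = 2.25,
    final_diameter_um: float = 0.5,
    sample_step_um: float = 5.0,
) -> SegmentTree:
    """Build a stylized medium-spiny-neuron skeleton.

    A spherical soma with ``n_primary_dendrites`` straight, linearly tapering
    dendrites radiating from it.  Defaults give an MSN-like scale on which the
    standard proximal (25 μm) and distal (100 μm) spine sites are resolvable.
    ``n_primary_dendrites = 0`` yields a soma-only tree.
    """
    if dendrite_length_um <= 0 and n_primary_dendrites > 0:
        raise MorphologyError("dendrite length must be positive")
    if soma_diameter_um <= 0:
        raise MorphologyError("soma diameter must be positive")
    nodes = [SegmentNode(1, None, 0.0, 0.0, 0.0, soma_diameter_um / 2.0, "soma")]
    nid = 2
    for k in range(n_primary_dendrites):
        theta = 2.0 * math.pi * k / max(n_primary_dendrites, 1)
        ux, uy = math.cos(theta), math.sin(theta)
        parent = 1
        n_pts = max(1, int(round(dendrite_length_um / sample_step_um)))
        for i in range(1, n_pts + 1):
            s = dendrite_length_um * i / n_pts
            frac = s / dendrite_length_um
            diam = initial_diameter_um + frac * (final_diameter_um - initial_diameter_um)
            nodes.append(
                SegmentNode(nid, parent, ux * s, uy * s, 0.0, diam / 2.0, "dendrite")
            )
            parent = nid
            nid += 1
    return SegmentTree(nodes)


def attach_spine(
    tree: SegmentTree,
    site_um: float,
    diameter_um: float = 1.0,
    length_um: float = 1.273,
    dendrite: int = 0,
) -> tuple[SegmentTree, float]:
    """Attach a single-compartment cylindrical spine head at a path distance.

    ``dendrite`` selects which primary branch (index among the root's dendrite
    children) hosts the spine.  Returns the new tree and the head volume in
    μm³ (the default 1 μm diameter × 1.273 μm length gives 1.0 μm³).
    """
    if diameter_um <= 0 or length_um <= 0:
        raise MorphologyError("spine geometry must be positive")
    root = tree.root
    branches = [n for n in tree.children(root.id) if n.label == "dendrite"]
    if not branches:
        raise MorphologyError("tree has no dendrites to host a spine")
    if not 0 <= dendrite < len(branches):
        raise MorphologyError(f"dendrite index {dendrite} out of range")
    # walk down the selected branch collecting path distances
    best_id, best_err = None, float("inf")
    n = branches[dendrite]
    dist = tree.path_distance(n.id)
    while True:
        err = abs(dist - site_um)
        if err < best_err:
            best_id, best_err = n.id, err
        kids = [c for c in tree.children(n.id) if c.label == "dendrite"]
        if not kids:
            break
        nxt = kids[0]
        dist += math.dist((n.x, n.y, n.z), (nxt.x, nxt.y, nxt.z))
        n = nxt
    if site_um > dist + 1e-9:
        raise MorphologyError(
            f"spine site {site_um} μm beyond dendrite length {dist:.1f} μm"
        )
    host = tree.node(best_id)
    # place the head off-axis (z) so the segment length encodes the cylinder
    new = SegmentNode(
        tree.next_id(), host.id, host.x, host.y, host.z + length_um,
        diameter_um / 2.0, "spine_head",
    )
    volume = math.pi * (diameter_um / 2.0) ** 2 * length_um
    return SegmentTree(tree.nodes + [new]), volume


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass
class Compartment:
    id: int
    length_um: float
    diam_um: float
    area_um2: float  # π d l membrane area (before spine-factor correction)
    region: str
    spine_factor: float
    dist_um: float  # path distance of compartment centre to soma
    volume_um3: float


@dataclass
class CompartmentGraph:
    """Discretized electrical skeleton.

    ``parent[j]`` is the index of the neighbour toward the soma (−1 for the
    root); the construction guarantees ``parent[j] < j`` so a single
    Hines-style sweep solves the implicit cable system.  ``g_axial_S[j]`` is
    the coupling conductance of the edge (j, parent[j]) in siemens, used
    identically in both directions.
    """

    compartments: list[Compartment]
    parent: np.ndarray  # int, parent[j] < j, root −1
    g_axial_S: np.ndarray  # S, per edge to parent (root entry 0)
    g_a: float  # axial conductance, S·cm
    C_uF_cm2: float = 1.0
    g_leak_S_cm2: float = 1.7e-5
    E_leak_mV: float = -70.0

    @property
    def n(self) -> int:
        return len(self.compartments)

    @property
    def regions(self) -> list[str]:
        return [c.region for c in self.compartments]

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(c, attr) for c in self.compartments], dtype=float)

    @property
    def area_cm2(self) -> np.ndarray:
        return self.array("area_um2") * 1e-8

    @property
    def C_nF(self) -> np.ndarray:
        """Per-compartment capacitance (nF), including the spine factor."""
        return self.C_uF_cm2 * self.array("spine_factor") * self.area_cm2 * 1e3

    @property
    def g_leak_uS(self) -> np.ndarray:
        """Per-compartment leak conductance (μS), including the spine factor."""
        return self.g_leak_S_cm2 * self.array("spine_factor") * self.area_cm2 * 1e6

    def spine_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.compartments) if c.region == "spine"]

    def total_corrected_area_um2(self) -> float:
        return float(sum(c.area_um2 * c.spine_factor for c in self.compartments))


def coupling_conductance(
    l1_um: float, d1_um: float, l2_um: float, d2_um: float, g_a: float
) -> float:
    """Axial coupling conductance (S) between two cylindrical compartments.

    Series half-resistances: 1/g = 2 l₁/(g_a π d₁²) + 2 l₂/(g_a π d₂²), with
    lengths and diameters converted from μm to cm and g_a in S·cm.
    """
    if d1_um <= 0 or d2_um <= 0:
        raise MorphologyError("invalid geometry: zero diameter")
    l1, l2 = l1_um * 1e-4, l2_um * 1e-4
    d1, d2 = d1_um * 1e-4, d2_um * 1e-4
    r = 2.0 * l1 / (g_a * math.pi * d1 ** 2) + 2.0 * l2 / (g_a * math.pi * d2 ** 2)
    return 1.0 / r


def _lambda_ac_um(diam_um: float, freq_hz: float, g_a: float, c_uf_cm2: float) -> float:
    """AC length constant (μm) at ``freq_hz`` for a cable of given diameter."""
    d_cm = diam_um * 1e-4
    ra_ohm_cm = 1.0 / g_a
    c_f_cm2 = c_uf_cm2 * 1e-6
    lam_cm = 0.5 * math.sqrt(d_cm / (math.pi * freq_hz * ra_ohm_cm * c_f_cm2))
    return lam_cm * 1e4


def _classify(dist_um: float, boundaries: tuple[float, float]) -> str:
    prox, mid = boundaries
    if dist_um <= prox:
        return "proximal"
    if dist_um <= mid:
        return "middle"
    return "distal"


def discretize(
    tree: SegmentTree,
    f_lambda: float = 0.1,
    freq_hz: float = 100.0,
    C_uF_cm2: float = 1.0,
    g_leak_S_cm2: float = 1.7e-5,
    g_a: float = 0.01,
    E_leak_mV: float = -70.0,
    region_boundaries: tuple[float, float] = DEFAULT_REGION_BOUNDARIES,
) -> CompartmentGraph:
    """Split the skeleton into compartments using the d_lambda rule.

    Each unbranched section is cut into the smallest odd number of
    compartments with length ≤ ``f_lambda`` × the AC length constant at
    ``freq_hz``.  The soma sphere becomes a single equivalent cylinder with
    l = d (identical membrane area); spine heads are single compartments.
    """
    if not 0 < f_lambda < 1:
        raise MorphologyError("f_lambda must be in (0, 1)")
    root = tree.root
    comps: list[Compartment] = []
    parent_idx: list[int] = []
    g_ax: list[float] = []

    soma_d = 2.0 * root.radius
    comps.append(
        Compartment(
            id=0, length_um=soma_d, diam_um=soma_d,
            area_um2=math.pi * soma_d * soma_d, region="soma", spine_factor=1.0,
            dist_um=0.0, volume_um3=math.pi / 6.0 * soma_d ** 3,
        )
    )
    parent_idx.append(-1)
    g_ax.append(0.0)

    # depth-first over sections (unbranched dendrite runs and spine heads)
    def walk(start: SegmentNode, attach_comp: int, dist0: float) -> None:
        if start.label == "spine_head":
            host = tree.node(start.parent_id)
            length = math.dist(
                (start.x, start.y, start.z), (host.x, host.y, host.z)
            )
            d = 2.0 * start.radius
            idx = len(comps)
            comps.append(
                Compartment(
                    id=idx, length_um=length, diam_um=d,
                    area_um2=math.pi * d * length, region="spine",
                    spine_factor=1.0, dist_um=dist0,
                    volume_um3=math.pi * (d / 2.0) ** 2 * length,
                )
            )
            parent_idx.append(attach_comp)
            pc = comps[attach_comp]
            g_ax.append(coupling_conductance(length, d, pc.length_um, pc.diam_um, g_a))
            return
        # collect the unbranched run starting at `start`; a run ends at a
        # branch point, a terminal, a node hosting a spine, or a region
        # boundary (so spine-factor tiers never straddle a compartment)
        run = [start]
        dists = [dist0 + math.dist(
            (start.x, start.y, start.z),
            _xyz(tree.node(start.parent_id)))]
        while True:
            kids = tree.children(run[-1].id)
            dend_kids = [k for k in kids if k.label == "dendrite"]
            if len(dend_kids) != 1 or len(kids) != 1:
                break
            if any(dists[0] < b <= dists[-1] + 1e-9 for b in region_boundaries):
                break
            nxt = dend_kids[0]
            dists.append(dists[-1] + math.dist(_xyz(run[-1]), _xyz(nxt)))
            run.append(nxt)
        sec_len = dists[-1] - dist0
        if sec_len <= 0:
            sec_len = 1e-3
        mean_d = 2.0 * sum(n.radius for n in run) / len(run)
        lam = _lambda_ac_um(mean_d, freq_hz, g_a, C_uF_cm2)
        nseg = max(1, int(math.ceil(sec_len / (f_lambda * lam))))
        if nseg % 2 == 0:
            nseg += 1
        seg_len = sec_len / nseg
        # interpolate diameter along the run by arc length
        arc = np.array(dists) - dist0
        rads = np.array([n.radius for n in run])
        prev_comp = attach_comp
        for s in range(nseg):
            mid = (s + 0.5) * seg_len
            d_here = 2.0 * float(np.interp(mid, arc, rads))
            idx = len(comps)
            comps.append(
                Compartment(
                    id=idx, length_um=seg_len, diam_um=d_here,
                    area_um2=math.pi * d_here * seg_len,
                    region=_classify(dist0 + mid, region_boundaries),
                    spine_factor=1.0, dist_um=dist0 + mid,
                    volume_um3=math.pi * (d_here / 2.0) ** 2 * seg_len,
                )
            )
            parent_idx.append(prev_comp)
            pc = comps[prev_comp]
            g_ax.append(
                coupling_conductance(seg_len, d_here, pc.length_um, pc.diam_um, g_a)
            )
            prev_comp = idx
        # children hang off the final node of the run (runs end at branch
        # points, spine hosts, or terminals)
        last_comp = len(comps) - 1
        for kid in tree.children(run[-1].id):
            walk(kid, last_comp, dists[-1])

    def _xyz(n: SegmentNode):
        return (n.x, n.y, n.z)

    for child in tree.children(root.id):
        walk(child, 0, 0.0)

    return CompartmentGraph(
        compartments=comps,
        parent=np.array(parent_idx, dtype=int),
        g_axial_S=np.array(g_ax, dtype=float),
        g_a=g_a, C_uF_cm2=C_uF_cm2, g_leak_S_cm2=g_leak_S_cm2,
        E_leak_mV=E_leak_mV,
    )


def apply_spine_correction(
    graph: CompartmentGraph, factors: dict[str, float] | None = None
) -> CompartmentGraph:
    """Scale leak conductance and capacitance for membrane area in spines.

    ``factors`` maps region → F (F = 1 + A_spine/A_dend); defaults are
    proximal 1, middle 1.3, distal 3.  Explicit spine compartments and the
    soma keep F = 1.  Returns a new graph; the input is not mutated.
    """
    if factors is None:
        factors = {"proximal": 1.0, "middle": 1.3, "distal": 3.0}
    full = {"soma": 1.0, "spine": 1.0, **factors}
    for region in full:
        if region not in REGION_ORDER:
            raise MorphologyError(f"unknown region label: {region!r}")
        if full[region] < 1.0:
            raise MorphologyError("spine factors must be ≥ 1")
    new_comps = [
        replace(c, spine_factor=full.get(c.region, 1.0)) for c in graph.compartments
    ]
    return CompartmentGraph(
        compartments=new_comps,
        parent=graph.parent.copy(),
        g_axial_S=graph.g_axial_S.copy(),
        g_a=graph.g_a, C_uF_cm2=graph.C_uF_cm2,
        g_leak_S_cm2=graph.g_leak_S_cm2, E_leak_mV=graph.E_leak_mV,
    )
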