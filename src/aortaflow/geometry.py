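"""Idealized aortic tree geometry and the virtual-aging procedure.

The arterial tree is a directed tree of tapered 1D vessel segments.  The
aortic trunk (root to aorto-iliac bifurcation) is parameterized by normalized
arc length ``s`` in [0, 1]; the iliac path extends the coordinate to
s = 1.27.  Trunk inner radii interpolate the tabulated station values at
s = 0.12 (ATA), 0.4 (DTA) and 0.88 (IAA) linearly, with constant
extrapolation proximal of 0.12 and distal of 0.88 (through the iliacs).

Virtual aging applies, per decade of aging and compounding geometrically:

* regional lengthening — 3% ascending aorta, 7% arch, 5% descending
  thoracic aorta (abdominal aorta, iliacs and branches keep their length);
* radial dilation — trunk radii are rescaled so the station radii match the
  target-age table exactly, with the scale factor interpolated linearly in
  ``s`` between stations; branch radii scale with the factor at their
  take-off point;
* height loss — the straight-line root-to-bifurcation distance shrinks
  (default 1%/decade) while the arc length is preserved, recorded as an
  increase in tortuosity (a 1D model carries no curvature, so tortuosity is
  metadata; its pressure cost is absorbed downstream by distal-resistance
  calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .tables import STATION_S, WallTable

TRUNK_REGIONS = (
    "ascending", "arch", "descending-thoracic",
    "suprarenal-abdominal", "infrarenal-abdominal", "iliac",
)

#: per-decade fractional lengthening by region
DEFAULT_LENGTHENING = {"ascending": 0.03, "arch": 0.07, "descending-thoracic": 0.05}

#: region boundaries on the baseline trunk (normalized arc length)
REGION_BOUNDS = {
    "ascending": (0.0, 0.13),
    "arch": (0.13, 0.22),
    "descending-thoracic": (0.22, 0.55),
    "suprarenal-abdominal": (0.55, 0.72),
    "infrarenal-abdominal": (0.72, 1.0),
}


class ConfigurationError(ValueError):
    """Raised for inconsistent or incomplete geometry configuration."""


@dataclass
class VesselSegment:
    """One tapered 1D vessel segment.

    Trunk (and iliac-path) segments carry the aortic ``s`` coordinate in
    ``s_range``; branches carry a local coordinate (s_range is None) and
    remember the aortic coordinate of their take-off in ``attach_s``.
    """

    name: str
    region: str
    length: float                     # arc length [m]
    radius_prox: float                # inner radius at proximal end [m]
    radius_dist: float                # inner radius at distal end [m]
    s_range: tuple[float, float] | None = None
    attach_s: float | None = None
    outlet_id: str | None = None

    def __post_init__(self):
        if self.length <= 0:
            raise ConfigurationError(f"{self.name}: length must be > 0")
        if self.radius_prox <= 0 or self.radius_dist <= 0:
            raise ConfigurationError(f"{self.name}: radii must be > 0")
        if self.s_range is not None and not self.s_range[1] > self.s_range[0]:
            raise ConfigurationError(f"{self.name}: s_range must be increasing")

    @property
    def is_aortic(self) -> bool:
        return self.s_range is not None

    def radius_at(self, xi: float) -> float:
        """Inner radius at fractional position xi in [0, 1] along the segment."""
        return self.radius_prox + (self.radius_dist - self.radius_prox) * xi


@dataclass
class AortoTree:
    """Directed tree of vessel segments; every child attaches at its
    parent's distal end."""

    segments: dict[str, VesselSegment]
    children: dict[str, list[str]]
    root: str
    age: int = 30
    tortuosity: float = 1.05   # trunk arc length / straight root-to-bifurcation distance
    # exact piecewise-linear radius knots (s, r) for the trunk (s <= 1) and
    # the iliac path (s > 1); segments' endpoint radii are samples of these
    trunk_knots: tuple[np.ndarray, np.ndarray] | None = None
    iliac_knots: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        self.validate()

    # -- topology ----------------------------------------------------------
    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.segments)
        for parent, kids in self.children.items():
            for k in kids:
                g.add_edge(parent, k)
        return g

    @property
    def terminals(self) -> list[str]:
        return [n for n in self.segments if not self.children.get(n)]

    @property
    def outlet_names(self) -> list[str]:
        return [self.segments[t].outlet_id for t in self.terminals
                if self.segments[t].outlet_id is not None]

    def parent_of(self, name: str) -> str | None:
        for p, kids in self.children.items():
            if name in kids:
                return p
        return None

    # -- aortic path -------------------------------------------------------
    @property
    def trunk_chain(self) -> list[str]:
        """Trunk segments (s <= 1) ordered by increasing s."""
        segs = [s for s in self.segments.values()
                if s.is_aortic and s.s_range[1] <= 1.0 + 1e-9]
        return [s.name for s in sorted(segs, key=lambda s: s.s_range[0])]

    @property
    def aortic_path(self) -> list[str]:
        """Trunk plus one canonical iliac side, ordered by increasing s.

        The left and right iliac paths are mirror images; the canonical
        s axis (used for property queries beyond the bifurcation) follows
        one side only.
        """
        path = list(self.trunk_chain)
        cur = path[-1]
        while True:
            nxt = sorted(c for c in self.children.get(cur, [])
                         if self.segments[c].is_aortic)
            if not nxt:
                break
            cur = nxt[0]
            path.append(cur)
        return path

    @property
    def trunk_length(self) -> float:
        """Arc length from aortic root to aorto-iliac bifurcation [m]."""
        return sum(self.segments[n].length for n in self.trunk_chain)

    @property
    def s_max(self) -> float:
        return self.segments[self.aortic_path[-1]].s_range[1]

    def arc_length_of(self, s: float) -> float:
        """Physical arc length from the root to normalized coordinate s."""
        return s * self.trunk_length

    def radius_profile(self, s) -> np.ndarray:
        """Inner radius at aortic coordinate(s) s (clamped to the tree range)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self.trunk_knots is not None:
            out = np.empty_like(s)
            trunk = s <= 1.0 + 1e-12
            out[trunk] = np.interp(s[trunk], *self.trunk_knots)
            if np.any(~trunk):
                if self.iliac_knots is not None:
                    out[~trunk] = np.interp(s[~trunk], *self.iliac_knots)
                else:
                    out[~trunk] = self.trunk_knots[1][-1]
            return out
        out = np.empty_like(s)
        path = self.aortic_path
        for i, si in enumerate(s):
            si = min(max(si, 0.0), self.s_max)
            for name in path:
                seg = self.segments[name]
                s0, s1 = seg.s_range
                if si <= s1 + 1e-12:
                    xi = (si - s0) / (s1 - s0)
                    out[i] = seg.radius_at(min(max(xi, 0.0), 1.0))
                    break
        return out

    def straight_distance(self) -> float:
        """Straight-line root-to-bifurcation distance implied by tortuosity."""
        return self.trunk_length / self.tortuosity

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        g = self.graph()
        if not nx.is_arborescence(g):
            raise ConfigurationError("vessel graph must be a rooted tree")
        if self.root not in self.segments:
            raise ConfigurationError(f"root segment {self.root!r} missing")
        path = self.aortic_path
        if not path or self.segments[path[0]].s_range[0] != 0.0:
            raise ConfigurationError("aortic path must start at s = 0")
        prev = 0.0
        for name in path:
            s0, s1 = self.segments[name].s_range
            if abs(s0 - prev) > 1e-9:
                raise ConfigurationError(
                    f"aortic path has a gap/overlap at s = {s0:.4f} ({name})")
            prev = s1


def tree_to_dict(tree: AortoTree) -> dict:
    """JSON-serializable description of a tree (lossless round trip)."""
    return {
        "root": tree.root,
        "age": tree.age,
        "tortuosity": tree.tortuosity,
        "trunk_knots": [list(map(float, a)) for a in tree.trunk_knots]
        if tree.trunk_knots is not None else None,
        "iliac_knots": [list(map(float, a)) for a in tree.iliac_knots]
        if tree.iliac_knots is not None else None,
        "children": {k: list(v) for k, v in tree.children.items() if v},
        "segments": {
            name: {
                "region": s.region, "length": s.length,
                "radius_prox": s.radius_prox, "radius_dist": s.radius_dist,
                "s_range": list(s.s_range) if s.s_range else None,
                "attach_s": s.attach_s, "outlet_id": s.outlet_id,
            } for name, s in tree.segments.items()},
    }


def tree_from_dict(d: dict) -> AortoTree:
    segments = {
        name: VesselSegment(
            name=name, region=sd["region"], length=sd["length"],
            radius_prox=sd["radius_prox"], radius_dist=sd["radius_dist"],
            s_range=tuple(sd["s_range"]) if sd["s_range"] else None,
            attach_s=sd["attach_s"], outlet_id=sd["outlet_id"])
        for name, sd in d["segments"].items()}
    knots = {}
    for key in ("trunk_knots", "iliac_knots"):
        knots[key] = tuple(np.asarray(a) for a in d[key]) if d.get(key) else None
    return AortoTree(segments=segments,
                     children={k: list(v) for k, v in d.get("children", {}).items()},
                     root=d["root"], age=int(d["age"]),
                     tortuosity=float(d["tortuosity"]),
                     trunk_knots=knots["trunk_knots"],
                     iliac_knots=knots["iliac_knots"])


@dataclass(frozen=True)
class BranchDef:
    """Configuration of one branch vessel: where it leaves the aorta and its
    baseline caliber/length."""

    name: str
    attach_s: float
    radius: float   # [m]
    length: float   # [m]
    outlet: str | None = None   # Windkessel outlet id; None for intermediate trunks
    parent: str | None = None   # None = aorta; else the named branch segment


#: baseline (30 yo) branch geometry; radii/lengths are literature-typical
#: approximations (configurable), take-off positions are fixed by s
DEFAULT_BRANCHES = (
    BranchDef("right_subclavian", 0.13, 4.2e-3, 0.040, "right_subclavian"),
    BranchDef("right_carotid", 0.16, 3.7e-3, 0.120, "right_carotid"),
    BranchDef("left_carotid", 0.19, 3.7e-3, 0.120, "left_carotid"),
    BranchDef("left_subclavian", 0.22, 4.2e-3, 0.040, "left_subclavian"),
    BranchDef("celiac_trunk", 0.58, 3.9e-3, 0.025, None),
    BranchDef("celiac", 0.58, 2.7e-3, 0.040, "celiac", parent="celiac_trunk"),
    BranchDef("gastric", 0.58, 1.8e-3, 0.030, "gastric", parent="celiac_trunk"),
    BranchDef("splenic", 0.58, 2.4e-3, 0.040, "splenic", parent="celiac_trunk"),
    BranchDef("superior_mesenteric", 0.63, 3.9e-3, 0.060, "superior_mesenteric"),
    BranchDef("right_renal", 0.70, 2.8e-3, 0.035, "right_renal"),
    BranchDef("left_renal", 0.72, 2.8e-3, 0.035, "left_renal"),
    BranchDef("inferior_mesenteric", 0.83, 2.0e-3, 0.045, "inferior_mesenteric"),
    BranchDef("right_int_iliac", 1.08, 3.0e-3, 0.045, "right_int_iliac"),
    BranchDef("left_int_iliac", 1.08, 3.0e-3, 0.045, "left_int_iliac"),
)


@dataclass
class AgingSpec:
    """Parameters of the virtual-aging transformation."""

    wall_table: WallTable = field(default_factory=WallTable)
    per_decade_lengthening: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTHENING))
    height_reduction_per_decade: float = 0.01
    target_ages: tuple[int, ...] = (40, 60, 75)

    def __post_init__(self):
        if any(f < 0 for f in self.per_decade_lengthening.values()):
            raise ConfigurationError("lengthening fractions must be >= 0")

    def length_factor(self, region: str, d_age: float) -> float:
        """Geometric compounding with fractional-decade exponents."""
        f = self.per_decade_lengthening.get(region, 0.0)
        return (1.0 + f) ** (d_age / 10.0)


@dataclass
class GeometryConfig:
    """Baseline (30 yo) tree construction parameters."""

    trunk_length: float = 0.500            # root to aorto-iliac bifurcation [m]
    baseline_tortuosity: float = 1.05
    iliac_s_end: float = 1.27
    iliac_split_s: float = 1.08            # internal iliac take-off
    # combined iliac/aortic area ratio ~0.85 at baseline: the aortic
    # bifurcation is a net positive (closed-type) reflector
    iliac_radius_prox: float = 5.2e-3
    iliac_radius_mid: float = 4.7e-3
    iliac_radius_dist: float = 4.0e-3
    branches: tuple[BranchDef, ...] = DEFAULT_BRANCHES


def _region_of(s_mid: float) -> str:
    for region, (a, b) in REGION_BOUNDS.items():
        if a - 1e-12 <= s_mid <= b + 1e-12:
            return region
    return "iliac" if s_mid > 1.0 else "infrarenal-abdominal"


def build_baseline_tree(spec: AgingSpec | None = None,
                        config: GeometryConfig | None = None) -> AortoTree:
    """Construct the idealized baseline 30 yo tree.

    The trunk is split into pieces at every branch take-off so that junctions
    coincide with segment ends; radii follow the tabulated station values.
    With ``config.branches = ()`` the tree degenerates to a single tapered
    aortic tube with one terminal.
    """
    spec = spec or AgingSpec()
    config = config or GeometryConfig()
    table = spec.wall_table
    L = config.trunk_length

    r30 = lambda s: float(table.radius(30, s))

    aortic_branches = sorted(
        {b.attach_s for b in config.branches if b.parent is None and b.attach_s <= 1.0})
    for b in config.branches:
        if b.outlet is None and b.parent is not None:
            raise ConfigurationError(f"intermediate branch {b.name} cannot nest")
    # cut the trunk at branch take-offs, region boundaries, and the three
    # property stations (so the radius profile keeps its kinks at the knots)
    cuts = sorted((set(aortic_branches) | {0.12, 0.40, 0.55, 0.72, 0.88})
                  - {0.0, 1.0})
    bounds = [0.0] + [c for c in cuts if 0.0 < c < 1.0] + [1.0]

    segments: dict[str, VesselSegment] = {}
    children: dict[str, list[str]] = {}
    order = []
    for i, (s0, s1) in enumerate(zip(bounds[:-1], bounds[1:])):
        name = f"aorta_{i:02d}"
        seg = VesselSegment(
            name=name, region=_region_of(0.5 * (s0 + s1)),
            length=(s1 - s0) * L,
            radius_prox=r30(s0), radius_dist=r30(s1),
            s_range=(s0, s1))
        segments[name] = seg
        if order:
            children.setdefault(order[-1], []).append(name)
        order.append(name)

    has_branches = bool(config.branches)
    if has_branches:
        # iliac path: common iliac then external iliac, on the extended s axis
        s_split, s_end = config.iliac_split_s, config.iliac_s_end
        for side in ("right", "left"):
            common = VesselSegment(
                name=f"{side}_common_iliac", region="iliac",
                length=(s_split - 1.0) * L,
                radius_prox=config.iliac_radius_prox,
                radius_dist=config.iliac_radius_mid,
                s_range=(1.0, s_split))
            ext = VesselSegment(
                name=f"{side}_ext_iliac", region="iliac",
                length=(s_end - s_split) * L,
                radius_prox=config.iliac_radius_mid,
                radius_dist=config.iliac_radius_dist,
                s_range=(s_split, s_end),
                outlet_id=f"{side}_ext_iliac")
            segments[common.name] = common
            segments[ext.name] = ext
            children.setdefault(order[-1], []).append(common.name)
            children.setdefault(common.name, []).append(ext.name)

        by_attach = {}
        for b in config.branches:
            by_attach.setdefault((b.parent, b.attach_s), []).append(b)
        for (parent, attach_s), defs in by_attach.items():
            if parent is None:
                if attach_s <= 1.0:
                    host = next(
                        (n for n in order
                         if abs(segments[n].s_range[1] - attach_s) < 1e-9), None)
                    if host is None:
                        raise ConfigurationError(
                            f"no trunk cut at s = {attach_s} for "
                            f"{[d.name for d in defs]}")
                else:
                    # internal iliacs attach at the common/external interface
                    hosts = {
                        "right": "right_common_iliac", "left": "left_common_iliac"}
                    for d in defs:
                        side = d.name.split("_")[0]
                        _add_branch(segments, children, hosts[side], d)
                    continue
            else:
                host = parent
                if host not in segments:
                    raise ConfigurationError(f"unknown parent branch {host!r}")
            for d in defs:
                if d.name in segments:
                    continue
                _add_branch(segments, children, host, d)

    st = np.array([0.0, STATION_S["ATA"], STATION_S["DTA"], STATION_S["IAA"], 1.0])
    trunk_knots = (st, np.array([r30(x) for x in st]))
    iliac_knots = (
        np.array([1.0, config.iliac_split_s, config.iliac_s_end]),
        np.array([config.iliac_radius_prox, config.iliac_radius_mid,
                  config.iliac_radius_dist]),
    ) if has_branches else None
    tree = AortoTree(segments=segments, children=children, root=order[0],
                     age=30, tortuosity=config.baseline_tortuosity,
                     trunk_knots=trunk_knots, iliac_knots=iliac_knots)
    if has_branches:
        missing = [b.outlet for b in config.branches if b.outlet] + \
                  ["right_ext_iliac", "left_ext_iliac"]
        have = set(tree.outlet_names)
        lost = [m for m in missing if m not in have]
        if lost:
            raise ConfigurationError(f"outlets not realized as terminals: {lost}")
    return tree


def _add_branch(segments, children, host: str, d: BranchDef) -> None:
    seg = VesselSegment(
        name=d.name, region="branch", length=d.length,
        radius_prox=d.radius, radius_dist=0.85 * d.radius,
        attach_s=d.attach_s, outlet_id=d.outlet)
    segments[d.name] = seg
    children.setdefault(host, []).append(d.name)


def age_geometry(tree: AortoTree, from_age: float, to_age: float,
                 spec: AgingSpec | None = None) -> AortoTree:
    """Apply the virtual-aging transformation and return a new tree.

    Lengths compound geometrically per decade by region; radii are rescaled
    so that trunk station radii match the target-age table exactly (linear
    interpolation of the scale factor between stations, constant outside);
    branch radii scale by the factor at their take-off coordinate; the
    straight-line root-to-bifurcation distance shrinks at the configured
    per-decade rate while arc length is preserved (tortuosity rises).
    """
    if to_age < from_age:
        raise ValueError("to_age must be >= from_age")
    spec = spec or AgingSpec()
    table = spec.wall_table
    d_age = to_age - from_age
    if d_age == 0:
        return tree

    if int(to_age) not in table.ages:
        raise KeyError(
            f"no station radii for age {to_age}; available: {table.ages}")

    # 1. lengthen regions, recompute the normalized coordinate
    segs = {n: replace(s) for n, s in tree.segments.items()}
    aortic = [n for n, s in tree.segments.items() if s.is_aortic]
    new_len = {n: segs[n].length * spec.length_factor(segs[n].region, d_age)
               for n in aortic}
    trunk_names = tree.trunk_chain
    L_new = sum(new_len[n] for n in trunk_names)
    cum = 0.0
    for name in trunk_names:
        segs[name].length = new_len[name]
        segs[name].s_range = (cum / L_new, (cum + new_len[name]) / L_new)
        cum += new_len[name]
    # iliac sides run in parallel beyond the bifurcation; walk each chain
    stack = [(c, 0.0) for c in tree.children.get(trunk_names[-1], [])
             if tree.segments[c].is_aortic]
    while stack:
        name, beyond = stack.pop()
        segs[name].length = new_len[name]
        segs[name].s_range = (1.0 + beyond / L_new,
                              1.0 + (beyond + new_len[name]) / L_new)
        stack.extend((c, beyond + new_len[name])
                     for c in tree.children.get(name, [])
                     if tree.segments[c].is_aortic)

    # 2. radial scale factor anchored at the stations, in the new coordinate
    st = np.array([STATION_S[k] for k in ("ATA", "DTA", "IAA")])
    cur = np.array([tree.radius_profile(x)[0] for x in st])
    tgt = np.array([table.radius(int(to_age), x) for x in st], dtype=float)
    factor = lambda s: np.interp(np.asarray(s, float), st, tgt / cur)

    # exact new radius knots: old profile times the station-anchored factor
    ks_t, _ = tree.trunk_knots if tree.trunk_knots is not None else (
        np.array([0.0, *st, 1.0]), None)
    kr_t = tree.radius_profile(ks_t) * factor(ks_t)
    trunk_knots = (ks_t.copy(), kr_t)
    iliac_knots = None
    if tree.iliac_knots is not None:
        # iliac knot positions follow the renormalized coordinate; radii
        # scale with the factor at the bifurcation
        old_s, old_r = tree.iliac_knots
        phys = (old_s - 1.0) * tree.trunk_length
        new_s = 1.0 + phys / L_new
        iliac_knots = (new_s, old_r * float(factor(1.0)))

    for name in aortic:
        seg = segs[name]
        s0, s1 = seg.s_range
        # iliac-path segments use the iliac knots (the radius is
        # discontinuous across the bifurcation)
        if s1 > 1.0 + 1e-12 and iliac_knots is not None:
            knots = iliac_knots
        else:
            knots = trunk_knots
        seg.radius_prox = float(np.interp(s0, *knots))
        seg.radius_dist = float(np.interp(s1, *knots))
    for name, seg in segs.items():
        if seg.region == "branch":
            f = float(factor(min(seg.attach_s, 1.0)))
            seg.radius_prox *= f
            seg.radius_dist *= f

    # 3. height loss -> tortuosity metadata (arc length preserved)
    shrink = (1.0 - spec.height_reduction_per_decade) ** (d_age / 10.0)
    straight_new = tree.straight_distance() * shrink * (L_new / tree.trunk_length)
    tortuosity = L_new / straight_new

    return AortoTree(segments=segs, children={k: list(v) for k, v in tree.children.items()},
                     root=tree.root, age=int(to_age), tortuosity=tortuosity,
                     trunk_knots=trunk_knots, iliac_knots=iliac_knots)
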