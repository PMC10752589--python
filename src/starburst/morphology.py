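"""SAC morphologies: SWC reading/writing and synthetic radial trees.

A morphology is a rooted tree of 3-D sample points with per-point radii,
the standard 7-column SWC representation.  Starburst amacrine cells are
radially symmetric, with thin (0.2 um) dendrites beyond 30 um from the
soma; ``normalize_diameters`` applies that rule to any loaded
reconstruction, and :func:`generate_synthetic_sac` builds a deterministic
stand-in tree with the same gross architecture (radial primaries that
bifurcate toward terminal tips near a target radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SWCError(ValueError):
    pass


@dataclass
class Morphology:
    """Point-tree morphology (SWC semantics).

    ids are contiguous 0..n-1 after loading; ``parent[i] < i`` except for
    the root, whose parent is -1.  ``path_dist`` is the arc length to the
    soma along the tree, in um.
    """

    xyz: np.ndarray        # (n, 3) um
    radius: np.ndarray     # (n,) um
    parent: np.ndarray     # (n,) int, -1 for root
    ntype: np.ndarray      # (n,) SWC type (1 soma, 3 dendrite, ...)
    path_dist: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.path_dist is None:
            self.path_dist = self._compute_path_dist()

    def _compute_path_dist(self) -> np.ndarray:
        n = len(self.parent)
        d = np.zeros(n)
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                d[i] = d[p] + np.linalg.norm(self.xyz[i] - self.xyz[p])
        return d

    @property
    def n_points(self) -> int:
        return len(self.parent)

    @property
    def soma_xyz(self) -> np.ndarray:
        return self.xyz[0]

    def children(self):
        ch = [[] for _ in range(self.n_points)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def tips(self) -> np.ndarray:
        """Indices of terminal points (no children, non-soma)."""
        has_child = np.zeros(self.n_points, dtype=bool)
        for p in self.parent:
            if p >= 0:
                has_child[p] = True
        return np.flatnonzero(~has_child & (self.ntype != 1))

    def total_length(self) -> float:
        seg = self.xyz[1:] - self.xyz[self.parent[1:]]
        return float(np.linalg.norm(seg, axis=1).sum())

    def subtree(self, root_idx: int) -> np.ndarray:
        """Indices of all points at or below ``root_idx``."""
        ch = self.children()
        out, stack = [], [root_idx]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(ch[i])
        return np.array(sorted(out))

    def normalize_diameters(self, thin_radius: float = 0.1,
                            dist_threshold: float = 30.0) -> "Morphology":
        """Set dendrites beyond ``dist_threshold`` um from the soma to
        0.2 um diameter (0.1 um radius), the standard SAC correction."""
        r = self.radius.copy()
        far = (self.path_dist > dist_threshold) & (self.ntype != 1)
        r[far] = thin_radius
        return Morphology(self.xyz.copy(), r, self.parent.copy(),
                          self.ntype.copy(), self.path_dist.copy())


def read_swc(path) -> Morphology:
    """Parse a 7-column SWC file into a :class:`Morphology`.

    Accepts child-before-parent ordering and arbitrary (unique) sample
    ids; raises :class:`SWCError` with the offending line number on
    malformed records, orphans or cycles.
    """
    ids, rows = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 7:
                raise SWCError(f"line {ln}: expected 7 columns, got {len(parts)}")
            try:
                i = int(parts[0]); t = int(parts[1])
                x, y, z, r = map(float, parts[2:6])
                p = int(parts[6])
            except ValueError as e:
                raise SWCError(f"line {ln}: {e}") from None
            if r <= 0:
                raise SWCError(f"line {ln}: non-positive radius")
            ids.append(i)
            rows.append((i, t, x, y, z, r, p, ln))
    if not rows:
        raise SWCError("empty SWC file")
    id_set = set(ids)
    if len(id_set) != len(ids):
        raise SWCError("duplicate sample ids")
    roots = [r for r in rows if r[6] == -1]
    if len(roots) != 1:
        raise SWCError(f"expected exactly one root, found {len(roots)}")
    for r in rows:
        if r[6] != -1 and r[6] not in id_set:
            raise SWCError(f"line {r[7]}: orphan node (parent {r[6]} missing)")
    # topological order from root; also detects cycles
    by_parent = {}
    by_id = {r[0]: r for r in rows}
    for r in rows:
        by_parent.setdefault(r[6], []).append(r[0])
    order, stack = [], [roots[0][0]]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(sorted(by_parent.get(i, []), reverse=True))
    if len(order) != len(rows):
        raise SWCError("cycle or disconnected component detected")
    remap = {old: new for new, old in enumerate(order)}
    n = len(order)
    xyz = np.empty((n, 3)); rad = np.empty(n)
    par = np.empty(n, dtype=int); typ = np.empty(n, dtype=int)
    for old in order:
        i, t, x, y, z, r, p, _ = by_id[old]
        new = remap[old]
        xyz[new] = (x, y, z); rad[new] = r; typ[new] = t
        par[new] = -1 if p == -1 else remap[p]
    return Morphology(xyz, rad, par, typ)


def write_swc(morph: Morphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# generated by starburst\n")
        for i in range(morph.n_points):
            x, y, z = morph.xyz[i]
            p = morph.parent[i]
            fh.write(f"{i + 1} {morph.ntype[i]} {x:.4f} {y:.4f} {z:.4f} "
                     f"{morph.radius[i]:.4f} {p + 1 if p >= 0 else -1}\n")


def generate_synthetic_sac(seed: int = 0, n_primary: int = 8,
                           radius: float = 120.0, branch_orders: int = 4,
                           point_spacing: float = 6.0,
                           soma_radius: float = 5.0,
                           angle_jitter: float = 0.06) -> Morphology:
    """Deterministic radially symmetric SAC-like tree.

    ``n_primary`` primary dendrites leave the soma at evenly spaced angles
    (with a small seeded jitter) and bifurcate ``branch_orders - 1`` times
    at evenly spaced radial shells, yielding ``n_primary * 2**(orders-1)``
    terminal dendrites whose tips lie near ``radius`` um.  Diameters taper
    from 1 um at the soma to 0.2 um beyond 30 um (the SAC thin-dendrite
    rule).  The defaults (8 primaries, 4 branch orders) give 64 terminal
    dendrites and ~4.3 mm of total dendritic length, in the range of real
    mouse SAC reconstructions.  Output is byte-stable for a fixed seed.
    """
    if n_primary < 4:
        raise ValueError("n_primary must be >= 4")
    rng = np.random.default_rng(seed)
    pts = [(0.0, 0.0, 0.0)]
    rads = [soma_radius]
    parents = [-1]
    types = [1]
    shells = np.linspace(0.0, radius, branch_orders + 1)

    def grow(parent_idx, r0, r1, angle, order):
        """Straight segment from shell r0 to r1 at the given angle."""
        length = r1 - r0
        n_seg = max(2, int(round(length / point_spacing)))
        last = parent_idx
        for k in range(1, n_seg + 1):
            r = r0 + length * k / n_seg
            x, y = r * np.cos(angle), r * np.sin(angle)
            dia = 1.0 if r < 15.0 else (0.5 if r < 30.0 else 0.2)
            pts.append((x, y, 0.0))
            rads.append(dia / 2.0)
            parents.append(last)
            types.append(3)
            last = len(pts) - 1
        if order + 1 < branch_orders:
            spread = np.pi / n_primary / (2 ** order)
            for sgn in (-1.0, 1.0):
                jit = rng.normal(0.0, angle_jitter * spread)
                grow(last, r1, shells[order + 2], angle + sgn * spread + jit,
                     order + 1)

    base = rng.uniform(0.0, 2 * np.pi / n_primary)
    for i in range(n_primary):
        ang = base + 2 * np.pi * i / n_primary + rng.normal(0.0, angle_jitter)
        grow(0, 0.0, shells[1], ang, 0)

    return Morphology(np.array(pts), np.array(rads),
                      np.array(parents, dtype=int), np.array(types, dtype=int))
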