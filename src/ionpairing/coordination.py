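"""Coordination-matrix classification of labeled 3-D structure frames.

Post-processes simulation frames of a ureido-amide calix[4]arene host (and
its Na+/Cl- complexes) into discrete coordination signatures:

* ``Na (total, ether, amide)`` - oxygens coordinating the sodium ion,
  criteria ``d(O-Na+) < 3 A`` and ``0 deg < angle(C-O-Na+) < 180 deg``
  (the angle window only excludes exactly collinear/degenerate geometries
  and is applied literally);
* ``Cl (total, urea1, urea2)`` - NH groups coordinating chloride,
  ``d(NH-Cl-) < 2.9 A`` and ``90 deg < angle(N-H-Cl-) < 180 deg``;
* ``HB (total, amide-O, urea-O)`` - intramolecular hydrogen bonds,
  ``d(NH-O) < 3.2 A`` and ``90 deg < angle(N-H-O) < 180 deg``;
* a solvent-inclusion class (``none`` / ``methyl-in`` / ``nitrile-in``)
  from which end of an acetonitrile molecule sits inside the cavity.

All distance cutoffs are strict inequalities.  Frames are grouped by their
discrete signature; cluster populations are simulation-time fractions and a
representative frame per cluster is chosen by principal component analysis
on an internal-coordinate feature vector (closest frame to the cluster
centroid in the first three PCs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "LabeledFrame",
    "CoordinationState",
    "BasketSpec",
    "ClusterReport",
    "na_coordination",
    "cl_coordination",
    "hb_detect",
    "solvent_inclusion",
    "classify_frame",
    "feature_vector",
    "cluster_frames",
    "read_xyz_frames",
    "write_xyz_frame",
    "load_role_map",
]

NA_DIST = 3.0
CL_DIST = 2.9
HB_DIST = 3.2


@dataclass
class LabeledFrame:
    """Atom positions (A) with role labels, group ids and bonds.

    ``roles`` uses the vocabulary ``Na``, ``Cl``, ``O_ether``, ``O_amide``,
    ``O_urea``, ``N_urea``, ``H_ureaNH``, ``C_carbonyl``,
    ``solvent_C_methyl``, ``solvent_N`` plus free-form carbon/scaffold
    roles; ``groups`` distinguishes e.g. ``urea1``/``urea2`` and
    ``amide1``/``amide2``.  N-H (and C-O) connectivity comes from ``bonds``,
    never from distances.
    """

    positions: np.ndarray
    roles: list[str]
    groups: list[str | None] = None
    bonds: list[tuple[int, int]] = field(default_factory=list)
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_atoms, 3)")
        n = len(self.positions)
        if len(self.roles) != n:
            raise ValueError("roles must match atom count")
        if self.groups is None:
            self.groups = [None] * n
        if len(self.groups) != n:
            raise ValueError("groups must match atom count")
        self._neighbors: dict[int, list[int]] = {i: [] for i in range(n)}
        for i, j in self.bonds:
            self._neighbors[i].append(j)
            self._neighbors[j].append(i)
        for h in self.by_role("H_ureaNH"):
            if not any(self.roles[j] == "N_urea" for j in self._neighbors[h]):
                raise ValueError(f"urea H atom {h} is not bonded to a labeled N_urea")

    def by_role(self, *roles: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r in roles]

    def bonded(self, i: int, role_prefix: str | None = None) -> list[int]:
        nb = self._neighbors[i]
        if role_prefix is None:
            return nb
        return [j for j in nb if self.roles[j].startswith(role_prefix)]

    def donor_nitrogen(self, h: int) -> int:
        for j in self._neighbors[h]:
            if self.roles[j] == "N_urea":
                return j
        raise ValueError(f"atom {h} has no bonded N_urea")


@dataclass(frozen=True)
class CoordinationState:
    """Discrete signature of one frame.

    ``na`` / ``cl`` are ``None`` when the ion is absent.  Totals are the
    sums of the listed parts except that the Na total also counts any
    coordinating urea oxygens (none in the canonical structures, but they
    are screened).
    """

    na: tuple[int, int, int] | None
    cl: tuple[int, int, int] | None
    hb: tuple[int, int, int]
    solvent: str = "none"

    def __post_init__(self):
        for mat in (self.na, self.cl, self.hb):
            if mat is not None and (len(mat) != 3 or any(v < 0 for v in mat)):
                raise ValueError("coordination matrices are 3 non-negative integers")
        if self.solvent not in ("none", "methyl-in", "nitrile-in"):
            raise ValueError("unknown solvent-inclusion class")

    def label(self) -> str:
        parts = []
        if self.na is not None:
            parts.append("Na " + str(tuple(self.na)))
        if self.cl is not None:
            parts.append("Cl " + str(tuple(self.cl)))
        parts.append("HB " + str(tuple(self.hb)))
        if self.solvent != "none":
            parts.append(self.solvent)
        return ", ".join(parts)


@dataclass
class BasketSpec:
    """Cavity geometry: narrow-rim reference atoms, wide-rim atoms, radius.

    The cavity is the cylinder of the given radius about the axis from the
    centroid of ``ref_indices`` (the four phenolic-scaffold atoms) toward
    the centroid of ``rim_indices``; a solvent end atom is *inside* when it
    lies within the cylinder between the two rim planes.
    """

    ref_indices: list[int]
    rim_indices: list[int]
    radius: float = 2.5


@dataclass
class ClusterReport:
    signature: CoordinationState
    population_pct: float
    representative: int  # frame index
    n_frames: int

    def to_dict(self) -> dict:
        return {
            "signature": self.signature.label(),
            "population_pct": self.population_pct,
            "representative_frame": self.representative,
            "n_frames": self.n_frames,
        }


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees; NaN for degenerate (zero-length) arms."""
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def na_coordination(frame: LabeledFrame) -> tuple[int, int, int]:
    """Na coordination matrix (total O, ether O, amide O).

    Strict cutoff ``d < 3.0 A``; the ``0 < angle(C-O-Na) < 180`` window is
    applied literally and only rejects exactly collinear or degenerate
    geometries.  Urea oxygens are screened and enter the total only.
    """
    na_idx = frame.by_role("Na")
    if not na_idx:
        raise ValueError("frame contains no Na")
    na = frame.positions[na_idx[0]]
    counts = {"O_ether": 0, "O_amide": 0, "O_urea": 0}
    for o in frame.by_role("O_ether", "O_amide", "O_urea"):
        if np.linalg.norm(frame.positions[o] - na) >= NA_DIST:
            continue
        carbons = frame.bonded(o, "C")
        if not carbons:
            continue
        ang = _angle_deg(frame.positions[carbons[0]], frame.positions[o], na)
        if math.isnan(ang) or not (0.0 < ang < 180.0):
            continue
        counts[frame.roles[o]] += 1
    return (sum(counts.values()), counts["O_ether"], counts["O_amide"])


def cl_coordination(frame: LabeledFrame) -> tuple[int, int, int]:
    """Cl coordination matrix (total NH, NH from urea 1, NH from urea 2)."""
    cl_idx = frame.by_role("Cl")
    if not cl_idx:
        raise ValueError("frame contains no Cl")
    cl = frame.positions[cl_idx[0]]
    per_group: dict[str, int] = {}
    for h in frame.by_role("H_ureaNH"):
        if np.linalg.norm(frame.positions[h] - cl) >= CL_DIST:
            continue
        n = frame.donor_nitrogen(h)
        ang = _angle_deg(frame.positions[n], frame.positions[h], cl)
        if not 90.0 < ang < 180.0:
            continue
        g = frame.groups[n] or frame.groups[h] or "urea1"
        per_group[g] = per_group.get(g, 0) + 1
    u1 = per_group.get("urea1", 0)
    u2 = per_group.get("urea2", 0)
    return (u1 + u2, u1, u2)


def hb_detect(frame: LabeledFrame) -> tuple[int, int, int]:
    """Intramolecular H-bond matrix (total, to amide O, to urea O)."""
    n_amide = n_urea = 0
    for h in frame.by_role("H_ureaNH"):
        n = frame.donor_nitrogen(h)
        hpos = frame.positions[h]
        for o in frame.by_role("O_amide", "O_urea"):
            if np.linalg.norm(frame.positions[o] - hpos) >= HB_DIST:
                continue
            ang = _angle_deg(frame.positions[n], hpos, frame.positions[o])
            if not 90.0 < ang < 180.0:
                continue
            if frame.roles[o] == "O_amide":
                n_amide += 1
            else:
                n_urea += 1
    return (n_amide + n_urea, n_amide, n_urea)


def solvent_inclusion(frame: LabeledFrame, basket: BasketSpec) -> str:
    """Solvent-inclusion class from which acetonitrile end sits in the cavity."""
    for idx in basket.ref_indices + basket.rim_indices:
        if idx >= len(frame.positions):
            raise ValueError("basket reference atom missing from frame")
    base = frame.positions[basket.ref_indices].mean(axis=0)
    top = frame.positions[basket.rim_indices].mean(axis=0)
    axis = top - base
    height = np.linalg.norm(axis)
    if height == 0:
        raise ValueError("degenerate basket axis")
    u = axis / height

    def inside(p) -> float | None:
        rel = p - base
        proj = float(rel @ u)
        if not 0.0 <= proj <= height:
            return None
        radial = np.linalg.norm(rel - proj * u)
        return proj if radial < basket.radius else None

    candidates = []
    for i in frame.by_role("solvent_C_methyl"):
        d = inside(frame.positions[i])
        if d is not None:
            candidates.append((d, "methyl-in"))
    for i in frame.by_role("solvent_N"):
        d = inside(frame.positions[i])
        if d is not None:
            candidates.append((d, "nitrile-in"))
    if not candidates:
        return "none"
    return min(candidates)[1]  # the deeper-lying end defines the class


def classify_frame(
    frame: LabeledFrame, basket: BasketSpec | None = None
) -> CoordinationState:
    na = na_coordination(frame) if frame.by_role("Na") else None
    cl = cl_coordination(frame) if frame.by_role("Cl") else None
    hb = hb_detect(frame)
    solv = solvent_inclusion(frame, basket) if basket is not None else "none"
    return CoordinationState(na, cl, hb, solv)


def feature_vector(frame: LabeledFrame) -> np.ndarray:
    """Internal-coordinate descriptor of one frame.

    Blocks, in order: NH...amide-O distances, NH...urea-O distances,
    Cl...NH distances (if Cl present), Na...O distances by role (ether,
    amide, urea; if Na present), followed by the matching angles
    (N-H-O, N-H-Cl, C-O-Na).  Within each block the (distance, angle)
    pairs are sorted by distance, which makes the vector invariant to both
    rigid-body motion and atom input order; frames of the same composition
    yield equal-length vectors.
    """
    hs = frame.by_role("H_ureaNH")
    dist_blocks: list[list[tuple[float, float]]] = []

    def nh_o_block(role):
        pairs = []
        for h in hs:
            n = frame.donor_nitrogen(h)
            for o in frame.by_role(role):
                d = float(np.linalg.norm(frame.positions[o] - frame.positions[h]))
                a = _angle_deg(frame.positions[n], frame.positions[h], frame.positions[o])
                pairs.append((d, a))
        return pairs

    dist_blocks.append(nh_o_block("O_amide"))
    dist_blocks.append(nh_o_block("O_urea"))
    cl_idx = frame.by_role("Cl")
    if cl_idx:
        cl = frame.positions[cl_idx[0]]
        pairs = []
        for h in hs:
            n = frame.donor_nitrogen(h)
            d = float(np.linalg.norm(cl - frame.positions[h]))
            a = _angle_deg(frame.positions[n], frame.positions[h], cl)
            pairs.append((d, a))
        dist_blocks.append(pairs)
    na_idx = frame.by_role("Na")
    if na_idx:
        na = frame.positions[na_idx[0]]
        for role in ("O_ether", "O_amide", "O_urea"):
            pairs = []
            for o in frame.by_role(role):
                d = float(np.linalg.norm(na - frame.positions[o]))
                carbons = frame.bonded(o, "C")
                a = (
                    _angle_deg(frame.positions[carbons[0]], frame.positions[o], na)
                    if carbons
                    else float("nan")
                )
                pairs.append((d, a))
            dist_blocks.append(pairs)

    out: list[float] = []
    angle_tail: list[float] = []
    for block in dist_blocks:
        block = sorted(block, key=lambda p: p[0])
        out.extend(d for d, _ in block)
        angle_tail.extend(a for _, a in block)
    return np.array(out + angle_tail)


def cluster_frames(
    frames: list[LabeledFrame],
    basket: BasketSpec | None = None,
    n_components: int = 3,
) -> list[ClusterReport]:
    """Group frames by discrete signature; pick PCA-centroid representatives.

    Signatures (coordination matrices + solvent class) define cluster
    identity; populations are frame-count fractions of the ensemble.  A PCA
    over the feature vectors of the *whole* ensemble defines the low-
    dimensional space in which each cluster's representative is the member
    frame closest to the cluster centroid (PC1-3 by default).
    """
    if not frames:
        raise ValueError("empty frame ensemble")
    sigs = [classify_frame(f, basket) for f in frames]
    feats = np.array([feature_vector(f) for f in frames])
    if np.isnan(feats).any():
        feats = np.nan_to_num(feats, nan=0.0)
    if len(frames) > 1:
        from sklearn.decomposition import PCA

        ncomp = min(n_components, feats.shape[1], len(frames))
        scores = PCA(n_components=ncomp).fit_transform(feats)
    else:
        scores = np.zeros((1, 1))

    groups: dict[CoordinationState, list[int]] = {}
    for i, s in enumerate(sigs):
        groups.setdefault(s, []).append(i)
    reports = []
    for sig, idx in groups.items():
        centroid = scores[idx].mean(axis=0)
        rep = idx[int(np.argmin(np.linalg.norm(scores[idx] - centroid, axis=1)))]
        reports.append(
            ClusterReport(sig, 100.0 * len(idx) / len(frames), rep, len(idx))
        )
    reports.sort(key=lambda r: -r.population_pct)
    return reports


# ----------------------------------------------------------------------
# frame I/O
# ----------------------------------------------------------------------


def load_role_map(path) -> dict:
    """Sidecar role map: per-atom roles/groups, bonds, optional basket spec."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "roles" not in cfg:
        raise ValueError("role map must define 'roles'")
    return cfg


def read_xyz_frames(path, role_map: dict) -> list[LabeledFrame]:
    """Read a (multi-frame) XYZ file and attach roles from the sidecar map."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        coords = []
        for k in range(n):
            parts = lines[i + 2 + k].split()
            coords.append([float(x) for x in parts[1:4]])
        try:
            t = float(comment.split("t=")[1].split()[0])
        except (IndexError, ValueError):
            t = float(len(frames))
        frames.append(
            LabeledFrame(
                np.array(coords),
                list(role_map["roles"]),
                list(role_map.get("groups") or [None] * n),
                [tuple(b) for b in role_map.get("bonds", [])],
                time=t,
            )
        )
        i += 2 + n
    return frames


def write_xyz_frame(frame: LabeledFrame, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(frame.positions)}\n{comment}\n")
        for role, pos in zip(frame.roles, frame.positions):
            elem = {"Na": "Na", "Cl": "Cl"}.get(role, role.split("_")[0][0].upper())
            fh.write(f"{elem} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}\n")


def read_pdb_frames(path, role_map_by_atom_name: dict, bonds=(), basket=None):
    """Read PDB frames with roles assigned from atom names via a mapping.

    Requires MDAnalysis; atoms whose names are missing from the mapping get
    role ``other``.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    roles = [role_map_by_atom_name.get(nm, "other") for nm in u.atoms.names]
    frames = []
    for ts in u.trajectory:
        frames.append(
            LabeledFrame(
                ts.positions.copy(), roles, None, [tuple(b) for b in bonds], time=ts.time
            )
        )
    return frames
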