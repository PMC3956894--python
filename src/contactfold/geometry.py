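"""Backbone geometry: torsion -> coordinate construction and structural metrics.

The chain model is coarse-grained: five centres per residue (N, CA, C, O, CB)
built from ideal bond lengths/angles and per-residue (phi, psi, omega)
torsions.  CB is an ideal tetrahedral pseudo-side-chain (a virtual CB is also
placed on glycine so contact distances are uniformly defined); there are no
further side-chain atoms.  Structural similarity is measured by TM-score
(length-normalised, reference = second argument), RMSD after optimal
superposition, and the superposition-free distance-matrix error (DME).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.distance import pdist

# atom slots in the (L, 5, 3) coordinate array
ATOM_N, ATOM_CA, ATOM_C, ATOM_O, ATOM_CB = 0, 1, 2, 3, 4
ATOM_NAMES = ("N", "CA", "C", "O", "CB")

# ideal backbone geometry (Engh-Huber-like averages), Angstrom / degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# default torsions for the extended (initial) chain
EXTENDED_PHI = -139.0
EXTENDED_PSI = 135.0
TRANS_OMEGA = 180.0


@dataclass
class Conformation:
    """One protein chain: sequence, torsions and derived coordinates.

    ``coords`` has shape (L, 5, 3) with atom order N, CA, C, O, CB.
    ``phi[0]`` and ``omega[-1]`` do not influence coordinates; they are kept
    so that torsion arrays stay aligned with residues.  ``segments`` lists
    (start, end) half-open runs of residues with intact backbone connectivity
    (a single run for chains built from torsions).
    """

    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    coords: np.ndarray
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        L = len(self.sequence)
        for name in ("phi", "psi", "omega"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (L,):
                raise ValueError(f"{name} must have length {L}")
            setattr(self, name, arr)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (L, 5, 3):
            raise ValueError("coords must have shape (L, 5, 3)")
        if not self.segments:
            self.segments = [(0, L)]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, ATOM_CA, :]

    @property
    def cb(self) -> np.ndarray:
        """Contact centres: CB, except CA for glycine."""
        out = self.coords[:, ATOM_CB, :].copy()
        gly = np.array([aa == "G" for aa in self.sequence])
        out[gly] = self.coords[gly, ATOM_CA, :]
        return out

    def copy(self) -> "Conformation":
        return Conformation(
            self.sequence,
            self.phi.copy(),
            self.psi.copy(),
            self.omega.copy(),
            self.coords.copy(),
            list(self.segments),
        )


@dataclass(frozen=True)
class Superposition:
    """Proper rigid transform b ~ a @ rotation.T + translation with its RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# torsion -> coordinates (NeRF chain extension)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d given three predecessors, bond |cd|, angle b-c-d, torsion a-b-c-d."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.sqrt(bc[0] ** 2 + bc[1] ** 2 + bc[2] ** 2)
    ab = b - a
    n = np.empty(3)
    n[0] = ab[1] * bc[2] - ab[2] * bc[1]
    n[1] = ab[2] * bc[0] - ab[0] * bc[2]
    n[2] = ab[0] * bc[1] - ab[1] * bc[0]
    nn = np.sqrt(n[0] ** 2 + n[1] ** 2 + n[2] ** 2)
    n /= nn
    m = np.empty(3)
    m[0] = n[1] * bc[2] - n[2] * bc[1]
    m[1] = n[2] * bc[0] - n[0] * bc[2]
    m[2] = n[0] * bc[1] - n[1] * bc[0]
    d2 = np.empty(3)
    d2[0] = -bond * np.cos(ang)
    d2[1] = bond * np.sin(ang) * np.cos(tor)
    d2[2] = bond * np.sin(ang) * np.sin(tor)
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


@njit(cache=True, fastmath=True)
def _build_coords(phi, psi, omega, is_gly):
    L = phi.shape[0]
    coords = np.zeros((L, 5, 3))
    # first residue in a canonical frame
    coords[0, 0] = np.array([0.0, 0.0, 0.0])                       # N
    coords[0, 1] = np.array([BOND_N_CA, 0.0, 0.0])                 # CA
    ang = np.radians(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0]
    )                                                               # C
    for i in range(L - 1):
        n_next = _place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2],
            BOND_C_N, ANGLE_CA_C_N, psi[i],
        )
        ca_next = _place_atom(
            coords[i, 1], coords[i, 2], n_next,
            BOND_N_CA, ANGLE_C_N_CA, omega[i],
        )
        c_next = _place_atom(
            coords[i, 2], n_next, ca_next,
            BOND_CA_C, ANGLE_N_CA_C, phi[i + 1],
        )
        coords[i + 1, 0] = n_next
        coords[i + 1, 1] = ca_next
        coords[i + 1, 2] = c_next
    # carbonyl O: anti to psi direction
    for i in range(L):
        coords[i, 3] = _place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2],
            BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0,
        )
    # ideal tetrahedral CB from local N/CA/C frame (virtual CB on glycine too)
    for i in range(L):
        b = coords[i, 1] - coords[i, 0]
        c = coords[i, 2] - coords[i, 1]
        a = np.empty(3)
        a[0] = b[1] * c[2] - b[2] * c[1]
        a[1] = b[2] * c[0] - b[0] * c[2]
        a[2] = b[0] * c[1] - b[1] * c[0]
        coords[i, 4] = (
            -0.58273431 * a + 0.56802827 * b - 0.54067466 * c + coords[i, 1]
        )
    return coords


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral CB position from backbone N, CA, C."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def build_chain(sequence: str, torsions) -> Conformation:
    """Realise a chain from per-residue (phi, psi, omega), degrees.

    ``torsions`` is an (L, 3) array-like.  Angles wrap mod 360; coordinates
    are a deterministic function of the input.
    """
    tor = np.asarray(torsions, dtype=float)
    if tor.shape != (len(sequence), 3):
        raise ValueError("torsions must be (L, 3) matching the sequence")
    phi = ((tor[:, 0] + 180.0) % 360.0) - 180.0
    psi = ((tor[:, 1] + 180.0) % 360.0) - 180.0
    omega = ((tor[:, 2] + 180.0) % 360.0) - 180.0
    is_gly = np.array([aa == "G" for aa in sequence])
    coords = _build_coords(phi, psi, omega, is_gly)
    return Conformation(sequence, phi, psi, omega, coords)


def extended_chain(sequence: str) -> Conformation:
    L = len(sequence)
    tor = np.column_stack(
        [
            np.full(L, EXTENDED_PHI),
            np.full(L, EXTENDED_PSI),
            np.full(L, TRANS_OMEGA),
        ]
    )
    return build_chain(sequence, tor)


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def extract_torsions(conf_or_coords) -> np.ndarray:
    """Recover (phi, psi, omega) in degrees from backbone coordinates.

    phi[0] and omega[-1] are undefined by the geometry; they are filled with
    the extended-chain defaults.  psi of the last residue is taken from the
    carbonyl O (psi = torsion(N, CA, C, O) - 180).
    """
    coords = (
        conf_or_coords.coords
        if isinstance(conf_or_coords, Conformation)
        else np.asarray(conf_or_coords)
    )
    L = coords.shape[0]
    phi = np.full(L, EXTENDED_PHI)
    psi = np.empty(L)
    omega = np.full(L, TRANS_OMEGA)
    for i in range(L):
        if i > 0:
            phi[i] = dihedral(
                coords[i - 1, ATOM_C], coords[i, ATOM_N],
                coords[i, ATOM_CA], coords[i, ATOM_C],
            )
        if i < L - 1:
            psi[i] = dihedral(
                coords[i, ATOM_N], coords[i, ATOM_CA],
                coords[i, ATOM_C], coords[i + 1, ATOM_N],
            )
            omega[i] = dihedral(
                coords[i, ATOM_CA], coords[i, ATOM_C],
                coords[i + 1, ATOM_N], coords[i + 1, ATOM_CA],
            )
        else:
            ang = dihedral(
                coords[i, ATOM_N], coords[i, ATOM_CA],
                coords[i, ATOM_C], coords[i, ATOM_O],
            ) - 180.0
            psi[i] = ang + 360.0 if ang <= -180.0 else ang
    return np.column_stack([phi, psi, omega])


# ---------------------------------------------------------------------------
# superposition (Kabsch), TM-score, DME
# ---------------------------------------------------------------------------

def superpose(a: np.ndarray, b: np.ndarray, weights=None) -> Superposition:
    """Least-squares proper rigid transform mapping point set ``a`` onto ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("point sets must be equal (n, 3) arrays with n >= 3")
    if weights is None:
        w = np.ones(len(a))
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    ca_ = (w[:, None] * a).sum(0) / wsum
    cb_ = (w[:, None] * b).sum(0) / wsum
    am = a - ca_
    bm = b - cb_
    h = (w[:, None] * am).T @ bm
    u, s, vt = np.linalg.svd(h)
    if weights is None and s[1] < 1e-8 * max(1.0, s[0]):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    moved = am @ rot.T
    rmsd = float(np.sqrt((w[:, None] * (moved - bm) ** 2).sum() / wsum))
    trans = cb_ - ca_ @ rot.T
    return Superposition(rot, trans, rmsd)


def tm_d0(l_ref: int) -> float:
    """TM-score distance scale d0 = 1.24 (L-15)^(1/3) - 1.8, clamped >= 0.5 A."""
    return max(0.5, 1.24 * np.cbrt(l_ref - 15.0) - 1.8)


def _tm_value(model_t: np.ndarray, ref: np.ndarray, d0: float) -> float:
    d2 = ((model_t - ref) ** 2).sum(1)
    return float((1.0 / (1.0 + d2 / d0 ** 2)).sum() / len(ref))


def _seed_windows(L: int) -> list[tuple[int, int]]:
    wins = []
    for wl in {L, max(3, L // 2), max(3, L // 4), min(4, L)}:
        wl = max(3, min(wl, L))
        step = max(1, wl // 2)
        starts = list(range(0, L - wl + 1, step))
        if starts and starts[-1] != L - wl:
            starts.append(L - wl)
        wins.extend((s, s + wl) for s in starts)
    return sorted(set(wins))


# below this length the TM search additionally seeds from every 3-residue
# subset (exhaustive); affordable only for short chains, where the TM
# landscape is spikiest (d0 is clamped near its floor)
TM_EXHAUSTIVE_MAX_L = 24


def _seed_subsets(L: int):
    from itertools import combinations

    return [list(s) for s in combinations(range(L), 3)]


def tm_score(model, reference, return_superposition: bool = False):
    """TM-score of ``model`` against ``reference`` (equal-length CA traces).

    TM = (1/L_ref) sum_i 1 / (1 + (d_i/d0)^2), maximised over rigid
    superpositions.  The search seeds a superposition from every contiguous
    window of a few lengths and refines each by iteratively reweighted
    superposition (weights 1/(1 + (d/d0)^2)^2, the stationarity weights of
    the TM objective); the best converged value is returned.  Deterministic.
    """
    a = model.ca if isinstance(model, Conformation) else np.asarray(model, float)
    b = (
        reference.ca
        if isinstance(reference, Conformation)
        else np.asarray(reference, float)
    )
    if a.shape != b.shape:
        raise ValueError("model and reference must have equal lengths")
    L = len(b)
    if L < 3:
        raise ValueError("reference too short for TM-score (need >= 3 residues)")
    d0 = tm_d0(L)
    seeds = [list(range(s, e)) for s, e in _seed_windows(L)]
    n_refine = len(seeds)
    if L <= TM_EXHAUSTIVE_MAX_L:
        seeds.extend(_seed_subsets(L))
        n_refine = max(n_refine, 60)
    # phase 1: score every seed superposition
    scored = []
    for idx in seeds:
        try:
            sup = superpose(a[idx], b[idx])
        except ValueError:
            continue
        scored.append((_tm_value(sup.apply(a), b, d0), sup))
    scored.sort(key=lambda t: -t[0])
    # phase 2: refine the most promising seeds to convergence
    best = -1.0
    best_sup = None
    for tm, sup in scored[:n_refine]:
        for _ in range(60):
            d2 = ((sup.apply(a) - b) ** 2).sum(1)
            w = 1.0 / (1.0 + d2 / d0 ** 2) ** 2
            sup = superpose(a, b, weights=w)
            tm_new = _tm_value(sup.apply(a), b, d0)
            if abs(tm_new - tm) < 1e-9:
                tm = tm_new
                break
            tm = tm_new
        if tm > best:
            best = tm
            best_sup = sup
    if return_superposition:
        return best, best_sup
    return best


def dme(a, b) -> float:
    """Root-mean-square difference of the two CA distance matrices (i < j)."""
    ca_a = a.ca if isinstance(a, Conformation) else np.asarray(a, float)
    ca_b = b.ca if isinstance(b, Conformation) else np.asarray(b, float)
    if ca_a.shape != ca_b.shape:
        raise ValueError("conformations must have equal lengths")
    da = pdist(ca_a)
    db = pdist(ca_b)
    return float(np.sqrt(np.mean((da - db) ** 2)))


# ---------------------------------------------------------------------------
# torsion-based secondary-structure classification (shared with fragments/HB)
# ---------------------------------------------------------------------------

HELIX_PHI = (-120.0, -20.0)
HELIX_PSI = (-100.0, 10.0)
STRAND_PHI = (-180.0, -80.0)
STRAND_PSI_LO = 90.0     # psi in [90, 180] or [-180, -170] counts as strand
STRAND_PSI_WRAP = -170.0


def classify_ss(phi: float, psi: float) -> str:
    """Assign H/E/C from backbone torsions (degrees)."""
    if HELIX_PHI[0] <= phi <= HELIX_PHI[1] and HELIX_PSI[0] <= psi <= HELIX_PSI[1]:
        return "H"
    if STRAND_PHI[0] <= phi <= STRAND_PHI[1] and (
        psi >= STRAND_PSI_LO or psi <= STRAND_PSI_WRAP
    ):
        return "E"
    return "C"


def ss_string(conf: Conformation) -> str:
    """Geometric secondary-structure string of a conformation."""
    return "".join(
        classify_ss(conf.phi[i], conf.psi[i]) for i in range(len(conf))
    )
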