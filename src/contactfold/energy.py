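"""The seven-term folding objective and its standard-deviation weight scheme.

E_total = sum_k W_k * E_k over terms

    SR      pairwise statistical potential, sequence separation 5-10
    LR      pairwise statistical potential, separation > 10
    SOLV    solvation/burial preference
    HB      secondary-structure (hydrogen-bonding proxy) reward
    COMPACT radius-of-gyration restraint
    STERIC  clash repulsion
    RR      predicted-contact pseudo-energy (rrcon)

The pairwise SR/LR tables are trained from reference structures by the
inverse-Boltzmann rule over a reduced 7-class residue alphabet.  SOLV, HB,
COMPACT and STERIC are fixed-form desk-scale potentials (the classic
fragment-assembly statistical potentials are not published in a portable
form); each sits behind this module's interface so a faithful port can
replace it.  Weights W_k equalise the spread of every term against the SR
term over an ensemble of random-torsion conformations of the target, then
multiply in the user factors (1 for all terms except STERIC x3 and RR x5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .contacts import ContactList, D_CON, DECAY
from .geometry import Conformation, build_chain

logger = logging.getLogger("contactfold")

TERM_NAMES = ("SR", "LR", "SOLV", "HB", "COMPACT", "STERIC", "RR")
TERM_SR, TERM_LR, TERM_SOLV, TERM_HB, TERM_COMPACT, TERM_STERIC, TERM_RR = range(7)
DEFAULT_FACTORS = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 3.0, 5.0])

# reduced residue alphabet: hydrophobic, aromatic, polar, positive, negative,
# glycine, proline
N_CLASSES = 7
_CLASS_OF = {}
for _aa in "AVLIMC":
    _CLASS_OF[_aa] = 0
for _aa in "FWYH":
    _CLASS_OF[_aa] = 1
for _aa in "STNQX":
    _CLASS_OF[_aa] = 2
for _aa in "KR":
    _CLASS_OF[_aa] = 3
for _aa in "DE":
    _CLASS_OF[_aa] = 4
_CLASS_OF["G"] = 5
_CLASS_OF["P"] = 6

# Kyte-Doolittle hydropathy, scaled to [-1, 1]
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

# distance binning of the pair potential
BIN_WIDTH = 0.5
MAX_DIST = 15.0
N_BINS = int(MAX_DIST / BIN_WIDTH)
SR_SEP_MIN, SR_SEP_MAX = 5, 10           # SR class; LR is separation > 10
PSEUDO_FREQ = 1e-4   # frequency pseudocount ~ one count at desk-scale n

# fixed-form term constants
BURIAL_RADIUS = 10.0                     # A; CB-neighbour sphere for burial
BURIAL_CAP = 12                          # neighbours at/above this = fully buried
RG_COEFF = 2.2                           # target Rg = 2.2 * L^0.38 A
RG_EXP = 0.38
CLASH_CA = 4.0                           # A; CA-CA clash threshold
CLASH_CB = 3.7                           # A; CB-CB clash threshold
# torsion windows of the H/E geometry classifier (degrees); keep in sync with
# geometry.classify_ss
_H_PHI_LO, _H_PHI_HI, _H_PSI_LO, _H_PSI_HI = -120.0, -20.0, -100.0, 10.0
_E_PHI_LO, _E_PHI_HI, _E_PSI_LO, _E_PSI_WRAP = -180.0, -80.0, 90.0, -170.0


def residue_classes(sequence: str) -> np.ndarray:
    return np.array([_CLASS_OF[aa] for aa in sequence], dtype=np.int64)


def hydropathy(sequence: str) -> np.ndarray:
    return np.array([_KD[aa] / 4.5 for aa in sequence])


@dataclass
class EnergyModel:
    """Calibrated weights plus the trained tables and per-target inputs."""

    pair_table: np.ndarray                       # (7, 7, N_BINS, 2)
    ss_states: np.ndarray | None = None          # (L,) 0=C 1=H 2=E predicted
    ss_conf: np.ndarray | None = None            # (L,) confidence of the call
    factors: np.ndarray = None
    weights: np.ndarray | None = None            # set by calibrate_weights
    d_con: float = D_CON
    decay: float = DECAY

    def __post_init__(self):
        if self.factors is None:
            self.factors = DEFAULT_FACTORS.copy()
        self.pair_table = np.ascontiguousarray(self.pair_table, dtype=np.float64)
        if self.pair_table.shape != (N_CLASSES, N_CLASSES, N_BINS, 2):
            raise ValueError("pair_table has wrong shape")

    @property
    def calibrated(self) -> bool:
        return self.weights is not None

    @classmethod
    def from_ss_prediction(cls, pair_table, ss_pred, **kw) -> "EnergyModel":
        states = np.array(["CHE".index(s) for s in ss_pred.states], dtype=np.int64)
        conf = np.array(
            [ss_pred.confidences[i, states[i]] for i in range(len(ss_pred))]
        )
        return cls(pair_table, ss_states=states, ss_conf=conf, **kw)


# ---------------------------------------------------------------------------
# pair-potential training (inverse Boltzmann)
# ---------------------------------------------------------------------------

def train_pair_potential(reference_structures, pseudo: float = PSEUDO_FREQ):
    """Inverse-Boltzmann pairwise table from reference conformations.

    E(a, b, bin, sep_class) = -ln[(f_obs + pseudo) / (f_exp + pseudo)] with
    f_exp the product of the type-pair and distance-bin marginals within the
    separation class.  The pseudocount acts on frequencies, so the table is
    invariant under rescaling all counts.  Symmetric in (a, b).
    """
    refs = list(reference_structures)
    if not refs:
        raise ValueError("empty reference set")
    counts = np.zeros((N_CLASSES, N_CLASSES, N_BINS, 2))
    for conf in refs:
        cls = residue_classes(conf.sequence)
        cb = conf.cb
        L = len(conf)
        for i in range(L):
            for j in range(i + SR_SEP_MIN, L):
                sc = 0 if j - i <= SR_SEP_MAX else 1
                d = np.linalg.norm(cb[i] - cb[j])
                if d >= MAX_DIST:
                    continue
                b = int(d / BIN_WIDTH)
                a, c = cls[i], cls[j]
                counts[a, c, b, sc] += 1
                if a != c:
                    counts[c, a, b, sc] += 1
    return pair_table_from_counts(counts, pseudo)


def pair_table_from_counts(counts: np.ndarray, pseudo: float = PSEUDO_FREQ):
    table = np.zeros_like(counts)
    for sc in range(2):
        n = counts[:, :, :, sc].sum()
        if n == 0:
            continue
        f_obs = counts[:, :, :, sc] / n
        pair_marg = counts[:, :, :, sc].sum(axis=2) / n      # (7, 7)
        bin_marg = counts[:, :, :, sc].sum(axis=(0, 1)) / n  # (N_BINS,)
        f_exp = pair_marg[:, :, None] * bin_marg[None, None, :]
        table[:, :, :, sc] = -np.log((f_obs + pseudo) / (f_exp + pseudo))
    return table


def write_pair_table(table: np.ndarray, path) -> None:
    """Serialise the trained table as TSV."""
    with open(path, "w") as fh:
        fh.write("type_a\ttype_b\tsep_class\tbin_low\tbin_high\tenergy\n")
        for a in range(N_CLASSES):
            for b in range(N_CLASSES):
                for sc, name in enumerate(("SR", "LR")):
                    for k in range(N_BINS):
                        fh.write(
                            f"{a}\t{b}\t{name}\t{k * BIN_WIDTH:.1f}\t"
                            f"{(k + 1) * BIN_WIDTH:.1f}\t{table[a, b, k, sc]:.6f}\n"
                        )


def read_pair_table(path) -> np.ndarray:
    table = np.zeros((N_CLASSES, N_CLASSES, N_BINS, 2))
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            a, b, sc, lo, hi, e = line.split("\t")
            table[int(a), int(b), int(float(lo) / BIN_WIDTH),
                  0 if sc == "SR" else 1] = float(e)
    return table


# ---------------------------------------------------------------------------
# term evaluation (numba kernel shared with the sampler)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def compute_terms(
    ca, cbc, types, kd, ss_states, ss_conf, phi, psi,
    pair_table, ci, cj, cp, max_sep, d_con, decay,
):
    """Raw values of the 7 energy terms for one conformation.

    ``cbc`` are contact centres (CB, CA for glycine); ``max_sep`` < 0 means
    all contacts active.  Returns a length-7 array in TERM_NAMES order.
    """
    L = ca.shape[0]
    terms = np.zeros(7)
    # SR / LR pair terms + SOLV burial counts in one pass
    burial = np.zeros(L)
    for i in range(L):
        for j in range(i + 1, L):
            dx = cbc[i, 0] - cbc[j, 0]
            dy = cbc[i, 1] - cbc[j, 1]
            dz = cbc[i, 2] - cbc[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d <= 10.0:
                burial[i] += 1.0
                burial[j] += 1.0
            sep = j - i
            if sep >= 5 and d < 15.0:
                b = int(d / 0.5)
                if sep <= 10:
                    terms[0] += pair_table[types[i], types[j], b, 0]
                else:
                    terms[1] += pair_table[types[i], types[j], b, 1]
    # SOLV: hydrophobic burial reward / polar burial penalty
    for i in range(L):
        frac = burial[i] / 12.0
        if frac > 1.0:
            frac = 1.0
        terms[2] += -kd[i] * frac
    # HB: reward residues whose backbone geometry matches the predicted state
    for i in range(L):
        s = ss_states[i]
        if s == 0:
            continue
        match = False
        if s == 1:
            match = (-120.0 <= phi[i] <= -20.0) and (-100.0 <= psi[i] <= 10.0)
        elif s == 2:
            match = (-180.0 <= phi[i] <= -80.0) and (
                psi[i] >= 90.0 or psi[i] <= -170.0
            )
        if match:
            terms[3] -= ss_conf[i]
    # COMPACT: (Rg - 2.2 L^0.38)^2 over CA
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(L):
        cx += ca[i, 0]
        cy += ca[i, 1]
        cz += ca[i, 2]
    cx /= L
    cy /= L
    cz /= L
    rg2 = 0.0
    for i in range(L):
        rg2 += (
            (ca[i, 0] - cx) ** 2 + (ca[i, 1] - cy) ** 2 + (ca[i, 2] - cz) ** 2
        )
    rg = np.sqrt(rg2 / L)
    rg_target = 2.2 * L ** 0.38
    terms[4] = (rg - rg_target) ** 2
    # STERIC: quadratic clash repulsion over CA and CB centres, |i-j| >= 2
    for i in range(L):
        for j in range(i + 2, L):
            dx = ca[i, 0] - ca[j, 0]
            dy = ca[i, 1] - ca[j, 1]
            dz = ca[i, 2] - ca[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 4.0:
                terms[5] += (4.0 - d) ** 2
            dx = cbc[i, 0] - cbc[j, 0]
            dy = cbc[i, 1] - cbc[j, 1]
            dz = cbc[i, 2] - cbc[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 3.7:
                terms[5] += (3.7 - d) ** 2
            dx = ca[i, 0] - cbc[j, 0]
            dy = ca[i, 1] - cbc[j, 1]
            dz = ca[i, 2] - cbc[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 3.85:
                terms[5] += (3.85 - d) ** 2
            dx = cbc[i, 0] - ca[j, 0]
            dy = cbc[i, 1] - ca[j, 1]
            dz = cbc[i, 2] - ca[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 3.85:
                terms[5] += (3.85 - d) ** 2
    # RR: contact pseudo-energy over the active schedule
    for k in range(ci.shape[0]):
        i = ci[k]
        j = cj[k]
        if max_sep >= 0 and j - i > max_sep:
            continue
        dx = cbc[i, 0] - cbc[j, 0]
        dy = cbc[i, 1] - cbc[j, 1]
        dz = cbc[i, 2] - cbc[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d <= d_con:
            terms[6] += -cp[k]
        else:
            terms[6] += cp[k] * (1.0 - 2.0 * np.exp(-(d - d_con) / decay))
    return terms


def _contact_centres(conf: Conformation) -> np.ndarray:
    return np.ascontiguousarray(conf.cb)


def evaluate_terms(
    model: Conformation,
    em: EnergyModel,
    contacts: ContactList | None = None,
    max_separation: int | None = None,
) -> np.ndarray:
    """The 7 raw term values (TERM_NAMES order) for one conformation."""
    L = len(model)
    if em.ss_states is None:
        ss_states = np.zeros(L, dtype=np.int64)
        ss_conf = np.zeros(L)
    else:
        ss_states, ss_conf = em.ss_states, em.ss_conf
    if len(ss_states) != L:
        raise ValueError("secondary-structure prediction length mismatch")
    if contacts is None:
        ci = np.empty(0, dtype=np.int64)
        cj = np.empty(0, dtype=np.int64)
        cp = np.empty(0, dtype=np.float64)
    else:
        ci, cj, cp = contacts.arrays()
        if len(cj) and cj.max() >= L:
            raise IndexError("contact index out of range for model length")
    return compute_terms(
        np.ascontiguousarray(model.ca),
        _contact_centres(model),
        residue_classes(model.sequence),
        hydropathy(model.sequence),
        np.ascontiguousarray(ss_states),
        np.ascontiguousarray(ss_conf, dtype=np.float64),
        model.phi,
        model.psi,
        em.pair_table,
        ci, cj, cp,
        -1 if max_separation is None else int(max_separation),
        em.d_con, em.decay,
    )


def total_energy(
    model: Conformation,
    em: EnergyModel,
    contacts: ContactList | None = None,
    max_separation: int | None = None,
) -> float:
    """Weighted total energy; requires a calibrated model."""
    if not em.calibrated:
        raise ValueError("EnergyModel is not calibrated (run calibrate_weights)")
    terms = evaluate_terms(model, em, contacts, max_separation)
    return float(np.dot(em.weights, terms))


# ---------------------------------------------------------------------------
# weight calibration
# ---------------------------------------------------------------------------

def random_conformations(sequence: str, n: int, seed: int):
    """Random-torsion conformations (phi, psi uniform, omega trans)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        L = len(sequence)
        tor = np.column_stack(
            [
                rng.uniform(-180.0, 180.0, L),
                rng.uniform(-180.0, 180.0, L),
                np.full(L, 180.0),
            ]
        )
        out.append(build_chain(sequence, tor))
    return out


def calibrate_weights(
    em: EnergyModel,
    sequence: str,
    contacts: ContactList | None = None,
    n_random: int = 200,
    seed: int = 0,
) -> EnergyModel:
    """Set W_k = factor_k * sigma(SR) / sigma(term_k) over a random ensemble.

    Spreads are measured across ``n_random`` random-torsion conformations of
    the target, so every weighted term fluctuates on the scale of the SR
    term before the user factors (STERIC x3, RR x5) are applied.
    """
    if n_random < 50:
        raise ValueError("n_random must be >= 50 for stable spread estimates")
    ens = random_conformations(sequence, n_random, seed)
    values = np.array([evaluate_terms(c, em, contacts) for c in ens])
    sig = values.std(axis=0, ddof=1)
    weights = np.empty(7)
    for k in range(7):
        if sig[k] == 0.0:
            logger.warning(
                "term %s has zero spread over the random ensemble; weight "
                "set from factor alone", TERM_NAMES[k],
            )
            weights[k] = em.factors[k]
        else:
            weights[k] = em.factors[k] * sig[TERM_SR] / sig[k]
    return replace(em, weights=weights)
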