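"""Synthetic fixture generator: toy targets, native structures, noisy
contact predictions and labelled decoy ensembles.

Toy proteins are ideal-torsion secondary-structure elements joined by short
loops whose base torsions were optimised once so the elements pack (helices
~9 A apart, paired strands ~5 A); generation adds seeded jitter (sigma = 5
degrees) to the loop torsions and resamples until the chain is clash-free.
Predicted-contact lists are sampled from the native contact map at a
controlled precision, emulating the PPV-scored output of a covariance-based
contact predictor.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactList, ContactRecord, D_CON
from .formats_io import SecondaryStructurePrediction, SequenceRecord
from .geometry import Conformation, build_chain, ss_string, tm_score

TOPOLOGIES = ("helix_hairpin", "three_helix_bundle", "beta_hairpin", "mixed")

HELIX = (-57.0, -47.0)
STRAND = (-139.0, 135.0)

# base loop torsions (phi, psi per residue), optimised once so the flanking
# elements pack against each other without clashes
LOOP_HELIX_HAIRPIN = np.array(
    [[35.8, -53.8], [-159.1, -161.2], [-53.2, 207.6], [86.7, 113.5]]
)
TURN_BETA = np.array([[-53.1, 52.4], [154.8, -28.0]])
LOOP_BUNDLE = np.array(
    [[40.2, -13.1], [144.8, 97.2], [119.3, 168.5], [86.3, 63.6]]
)
LOOP_MIXED = np.array(
    [[158.6, -45.5], [-148.5, -80.8], [-122.8, -127.2], [108.1, 7.9]]
)
# the middle helix of the bundle must keep its found phase: the packing of
# helix 3 against helices 1-2 depends on helix 2's length modulo ~5 turns
BUNDLE_MID_BASE = 12
BUNDLE_MID_PERIOD = 18

LOOP_JITTER_SIGMA = 5.0    # degrees
MAX_RESAMPLE = 100
FALSE_CONTACT_MIN_DIST = 12.0  # A; native distance floor for "false" pairs

_HYDROPHOBIC = "LIVMF"
_POLAR = "STNQEKRD"
_LOOP_RES = "GSDNA"


@dataclass(frozen=True)
class ToySpec:
    topology: str
    length: int
    seed: int = 0

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 30 <= self.length <= 120:
            raise ValueError("toy length must be in [30, 120]")


@dataclass(frozen=True)
class PredictionNoiseSpec:
    n_contacts: int
    target_precision: float
    ppv_assignment: str = "independent"   # or "correlated"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.target_precision <= 1.0:
            raise ValueError("target_precision must be in [0, 1]")
        if self.ppv_assignment not in ("independent", "correlated"):
            raise ValueError("ppv_assignment must be independent|correlated")


def _layout(topology: str, L: int):
    """Element plan: list of ('H'|'E', n) and ('loop', base_torsion_array)."""
    if topology == "helix_hairpin":
        loop = LOOP_HELIX_HAIRPIN
        rest = L - len(loop)
        n1 = rest // 2
        return [("H", n1), ("loop", loop), ("H", rest - n1)]
    if topology == "three_helix_bundle":
        rest = L - len(LOOP_HELIX_HAIRPIN) - len(LOOP_BUNDLE)
        n2 = BUNDLE_MID_BASE
        while n2 + BUNDLE_MID_PERIOD <= rest - 2 * BUNDLE_MID_PERIOD:
            n2 += BUNDLE_MID_PERIOD
        n1 = (rest - n2) // 2
        return [
            ("H", n1), ("loop", LOOP_HELIX_HAIRPIN),
            ("H", n2), ("loop", LOOP_BUNDLE),
            ("H", rest - n1 - n2),
        ]
    if topology == "beta_hairpin":
        loop = TURN_BETA
        rest = L - len(loop)
        n1 = rest // 2
        return [("E", n1), ("loop", loop), ("E", rest - n1)]
    # mixed: beta hairpin packed under a helix; even strand lengths keep the
    # alternating-sidechain register of the optimised connector
    rest = L - len(TURN_BETA) - len(LOOP_MIXED)
    n_e = max(4, (rest // 4) // 2 * 2)
    n_h = rest - 2 * n_e
    return [
        ("E", n_e), ("loop", TURN_BETA), ("E", n_e),
        ("loop", LOOP_MIXED), ("H", n_h),
    ]


def _plan_torsions(plan, rng, jitter: float):
    rows = []
    ss = []
    for kind, payload in plan:
        if kind == "loop":
            base = payload
            jit = rng.normal(0.0, jitter, size=base.shape)
            for (ph, ps) in base + jit:
                rows.append((ph, ps, 180.0))
                ss.append("C")
        else:
            ph, ps = HELIX if kind == "H" else STRAND
            for _ in range(payload):
                rows.append((ph, ps, 180.0))
                ss.append(kind)
    return np.array(rows), "".join(ss)


def _plan_sequence(ss: str, rng) -> str:
    """Hydrophobic-patterned sequence consistent with the topology."""
    seq = []
    helix_phase = 0
    strand_phase = 0
    for state in ss:
        if state == "H":
            # heptad: hydrophobic at positions a/d
            core = helix_phase % 7 in (0, 3)
            helix_phase += 1
            strand_phase = 0
            pool = _HYDROPHOBIC if core else _POLAR
        elif state == "E":
            core = strand_phase % 2 == 0
            strand_phase += 1
            helix_phase = 0
            pool = _HYDROPHOBIC if core else _POLAR
        else:
            helix_phase = 0
            strand_phase = 0
            pool = _LOOP_RES
        seq.append(pool[rng.integers(0, len(pool))])
    return "".join(seq)


def _is_clash_free(conf: Conformation, tol: float = 0.5) -> bool:
    """Steric penalty of the chain below ``tol`` (CA/CB quadratic clashes)."""
    ca = conf.ca
    cb = conf.cb
    L = len(conf)
    pen = 0.0
    for i in range(L):
        d_ca = np.linalg.norm(ca[i + 2:] - ca[i], axis=1)
        d_cb = np.linalg.norm(cb[i + 2:] - cb[i], axis=1)
        d_ab = np.linalg.norm(cb[i + 2:] - ca[i], axis=1)
        d_ba = np.linalg.norm(ca[i + 2:] - cb[i], axis=1)
        pen += (np.clip(4.0 - d_ca, 0, None) ** 2).sum()
        pen += (np.clip(3.7 - d_cb, 0, None) ** 2).sum()
        pen += (np.clip(3.85 - d_ab, 0, None) ** 2).sum()
        pen += (np.clip(3.85 - d_ba, 0, None) ** 2).sum()
        if pen >= tol:
            return False
    return True


def make_toy(spec: ToySpec):
    """Native conformation, sequence record and true secondary structure.

    Returns (native, SequenceRecord, SecondaryStructurePrediction); the
    "prediction" is the construction truth with 0.9 confidence on the true
    state.
    """
    rng = np.random.default_rng(spec.seed)
    plan = _layout(spec.topology, spec.length)
    # jitter-free base chain anchors what "packed" means for this layout
    base_tor, base_ss = _plan_torsions(plan, rng, 0.0)
    base_n = len(native_contacts(build_chain("A" * spec.length, base_tor)))
    ss = None
    for attempt in range(MAX_RESAMPLE):
        tor, ss = _plan_torsions(plan, rng, LOOP_JITTER_SIGMA)
        seq = _plan_sequence(ss, rng)
        conf = build_chain(seq, tor)
        if _is_clash_free(conf) and len(native_contacts(conf)) >= 0.5 * base_n:
            break
    else:
        raise RuntimeError(
            f"no clash-free chain after {MAX_RESAMPLE} loop resamples "
            f"({spec.topology}, L={spec.length}, seed={spec.seed})"
        )
    conf_mat = np.full((len(ss), 3), 0.05)
    for i, state in enumerate(ss):
        conf_mat[i, "CHE".index(state)] = 0.90
    record = SequenceRecord(
        f"{spec.topology}_L{spec.length}_s{spec.seed}", conf.sequence
    )
    return conf, record, SecondaryStructurePrediction(ss, conf_mat)


# ---------------------------------------------------------------------------
# contact predictions at controlled precision
# ---------------------------------------------------------------------------

def native_contacts(native: Conformation, d_con: float = D_CON):
    """All (i, j) with CB-CB <= d_con and separation >= 5, i < j."""
    cb = native.cb
    L = len(native)
    out = []
    for i in range(L):
        for j in range(i + 5, L):
            if np.linalg.norm(cb[i] - cb[j]) <= d_con:
                out.append((i, j))
    return out


def simulate_predictions(
    native: Conformation, noise: PredictionNoiseSpec
) -> ContactList:
    """Sample a PPV-scored contact list with a controlled precision.

    round(n * p) entries are true native contacts; the rest are false pairs
    whose native distance exceeds 12 A (so jittered decoys cannot blur the
    truth labels).  In the default truth-independent mode PPVs are drawn iid
    from one distribution, so the expected precision of any top-k prefix is
    p; the correlated mode draws true PPVs from Beta(4, 2) and false from
    Beta(2, 4), mimicking an informative but imperfect ranking.
    """
    if noise.n_contacts <= 0:
        raise ValueError("n_contacts must be positive")
    rng = np.random.default_rng(noise.seed)
    cb = native.cb
    L = len(native)
    trues = native_contacts(native)
    n_true = int(round(noise.n_contacts * noise.target_precision))
    n_false = noise.n_contacts - n_true
    if n_true > len(trues):
        raise ValueError(
            f"native has only {len(trues)} true contacts; {n_true} requested"
        )
    idx = rng.choice(len(trues), size=n_true, replace=False)
    chosen = [trues[k] for k in sorted(idx)]
    false_pool = [
        (i, j)
        for i in range(L)
        for j in range(i + 5, L)
        if np.linalg.norm(cb[i] - cb[j]) > FALSE_CONTACT_MIN_DIST
    ]
    if n_false > len(false_pool):
        raise ValueError("not enough well-separated false pairs")
    fidx = rng.choice(len(false_pool), size=n_false, replace=False)
    falses = [false_pool[k] for k in sorted(fidx)]
    records = []
    for (i, j), is_true in [(c, True) for c in chosen] + [
        (c, False) for c in falses
    ]:
        if noise.ppv_assignment == "independent":
            ppv = rng.uniform(0.05, 1.0)
        else:
            a, b = (4.0, 2.0) if is_true else (2.0, 4.0)
            ppv = float(np.clip(rng.beta(a, b), 1e-6, 1.0))
        records.append(ContactRecord(i, j, ppv))
    return ContactList(records, L=L)


def true_contact_list(native: Conformation, ppv: float = 1.0) -> ContactList:
    """The full native contact map as a prediction with uniform PPV."""
    records = [ContactRecord(i, j, ppv) for i, j in native_contacts(native)]
    return ContactList(records, L=len(native))


# ---------------------------------------------------------------------------
# labelled decoy sets
# ---------------------------------------------------------------------------

def make_decoy_set(
    native: Conformation,
    n_near: int,
    n_far: int,
    seed: int = 0,
    em=None,
    near_sigma: float = 8.0,
    shuffle_block: int = 9,
):
    """Labelled ensemble of near-native and fold-destroyed decoys.

    Near decoys jitter the native's loop torsions (sigma in degrees,
    loop-only); far decoys shuffle ``shuffle_block``-residue torsion blocks,
    destroying the topology while keeping local structure.  Each decoy's
    TM-score to the native is stored in ``stats['tm_to_native']``; energies
    are computed when an :class:`~.energy.EnergyModel` is supplied (NaN
    otherwise).
    """
    from .sampler import Decoy, Ensemble

    rng = np.random.default_rng(seed)
    ss = ss_string(native)
    loop_idx = np.array([i for i, s in enumerate(ss) if s == "C"], dtype=int)
    base = np.column_stack([native.phi, native.psi, native.omega])
    decoys = []
    for k in range(n_near):
        tor = base.copy()
        if loop_idx.size:
            tor[loop_idx, 0] += rng.normal(0.0, near_sigma, loop_idx.size)
            tor[loop_idx, 1] += rng.normal(0.0, near_sigma, loop_idx.size)
        conf = build_chain(native.sequence, tor)
        decoys.append(_make_decoy(conf, native, em, "near", seed + k))
    L = len(native)
    for k in range(n_far):
        blocks = [
            base[s:s + shuffle_block] for s in range(0, L, shuffle_block)
        ]
        order = rng.permutation(len(blocks))
        tor = np.vstack([blocks[o] for o in order])
        tor = tor + rng.normal(0.0, 4.0, tor.shape)
        # re-draw the junction torsions: local structure survives inside the
        # blocks while the global topology is scrambled (pure block
        # permutation would leave periodic elements nearly unchanged)
        for b in range(1, len(blocks)):
            j = b * shuffle_block
            if j < L:
                tor[j, 0] = rng.uniform(-180.0, 180.0)
                tor[j, 1] = rng.uniform(-180.0, 180.0)
        tor[:, 2] = 180.0
        conf = build_chain(native.sequence, tor[:L])
        decoys.append(_make_decoy(conf, native, em, "far", seed + n_near + k))
    return Ensemble(decoys)


def _make_decoy(conf, native, em, mode, seed):
    from .energy import total_energy
    from .sampler import Decoy

    energy = float("nan")
    if em is not None and em.calibrated:
        energy = total_energy(conf, em)
    d = Decoy(conformation=conf, energy=energy, terms=None, mode=mode, seed=seed)
    d.stats["tm_to_native"] = tm_score(conf, native)
    return d
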