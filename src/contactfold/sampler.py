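"""Replica-exchange simulated-annealing fragment assembly.

Monte Carlo moves are fragment replacements (a random position's shortlist
fragment overwrites the local torsions, p = 0.8) and single-residue torsion
perturbations (sigma = 10 degrees, p = 0.2), accepted by the Metropolis
rule.  Replicas sit on a geometric temperature ladder annealed linearly over
the run; neighbouring replicas attempt a standard Metropolis exchange every
``exchange_interval`` steps.  One exchange block is one "cycle": in
sequential mode the maximum active contact separation grows linearly with
each cycle from the short-range bound to the full chain.  The decoy returned
is the lowest-total-energy conformation visited by the coldest replica.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .contacts import ContactList, SHORT_MAX, schedule_max_separation
from .energy import (
    EnergyModel,
    TERM_RR,
    compute_terms,
    evaluate_terms,
    hydropathy,
    residue_classes,
)
from .formats_io import SecondaryStructurePrediction, SequenceRecord
from .geometry import Conformation, _build_coords, extended_chain
from .fragments import FragmentLibrary, build_shortlists

logger = logging.getLogger("contactfold")

MODES = ("all", "sequential", "no_contacts", "contacts_only")

P_FRAGMENT_MOVE = 0.8
PERTURB_SIGMA = 10.0  # degrees


@dataclass
class AnnealConfig:
    """Sampler settings.  ``steps`` counts Monte Carlo moves summed over all
    replicas; the paper-scale defaults (5-10 million by target size) are
    reached via ``steps_for_length`` scaled by ``steps_scale``."""

    steps: int = 50_000
    n_replicas: int = 8
    t_high: float = 10.0
    t_low: float = 0.5
    exchange_interval: int = 500
    mode: str = "all"
    seed: int = 0

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if not self.t_high > self.t_low > 0:
            raise ValueError("need T_high > T_low > 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def steps_for_length(L: int, steps_scale: float = 1.0) -> int:
    """Paper-scale step counts: 10M for targets >= 120 residues, else 5M,
    multiplied by a single desk-scale factor."""
    base = 10_000_000 if L >= 120 else 5_000_000
    return max(1, int(base * steps_scale))


@dataclass
class Decoy:
    conformation: Conformation
    energy: float
    terms: np.ndarray | None
    mode: str
    seed: int
    stats: dict = field(default_factory=dict)


@dataclass
class Ensemble:
    decoys: list[Decoy]

    def __len__(self) -> int:
        return len(self.decoys)

    def __iter__(self):
        return iter(self.decoys)

    def __getitem__(self, idx) -> Decoy:
        return self.decoys[idx]

    @property
    def energies(self) -> np.ndarray:
        return np.array([d.energy for d in self.decoys])


# ---------------------------------------------------------------------------
# numba Monte Carlo block
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _energy_of(torsions, weights, is_gly, types, kd, ss_states, ss_conf,
               pair_table, ci, cj, cp, max_sep, d_con, decay):
    coords = _build_coords(torsions[:, 0], torsions[:, 1], torsions[:, 2], is_gly)
    L = coords.shape[0]
    ca = coords[:, 1, :].copy()
    cbc = coords[:, 4, :].copy()
    for i in range(L):
        if is_gly[i]:
            cbc[i] = ca[i]
    terms = compute_terms(
        ca, cbc, types, kd, ss_states, ss_conf,
        torsions[:, 0], torsions[:, 1],
        pair_table, ci, cj, cp, max_sep, d_con, decay,
    )
    e = 0.0
    for k in range(7):
        e += weights[k] * terms[k]
    return e


@njit(cache=True, fastmath=True)
def _mc_block(
    torsions, energy, weights, temperature, nsteps, max_sep,
    frag_tor, frag_len, pos_ptr, pos_flat, valid_pos,
    is_gly, types, kd, ss_states, ss_conf, pair_table,
    ci, cj, cp, d_con, decay, seed,
    best_energy, best_torsions, track_best,
):
    """Run ``nsteps`` Metropolis moves on one replica, in place.

    Returns (energy, n_accepted).  ``best_*`` updated when ``track_best``.
    """
    np.random.seed(seed)
    L = torsions.shape[0]
    n_accept = 0
    old_window = np.empty((frag_tor.shape[1], 3))
    for _ in range(nsteps):
        use_frag = valid_pos.shape[0] > 0 and np.random.random() < P_FRAGMENT_MOVE
        if use_frag:
            pos = valid_pos[np.random.randint(0, valid_pos.shape[0])]
            row_start = pos_ptr[pos]
            row_end = pos_ptr[pos + 1]
            fidx = pos_flat[row_start + np.random.randint(0, row_end - row_start)]
            flen = frag_len[fidx]
            for k in range(flen):
                for c in range(3):
                    old_window[k, c] = torsions[pos + k, c]
                    torsions[pos + k, c] = frag_tor[fidx, k, c]
            move_pos = pos
            move_len = flen
            old_val = 0.0
            move_res = -1
            move_ang = -1
        else:
            move_res = np.random.randint(0, L)
            move_ang = np.random.randint(0, 2)
            old_val = torsions[move_res, move_ang]
            new_val = old_val + np.random.normal(0.0, PERTURB_SIGMA)
            new_val = ((new_val + 180.0) % 360.0) - 180.0
            torsions[move_res, move_ang] = new_val
            move_pos = -1
            move_len = 0
        e_new = _energy_of(
            torsions, weights, is_gly, types, kd, ss_states, ss_conf,
            pair_table, ci, cj, cp, max_sep, d_con, decay,
        )
        accept = e_new <= energy
        if not accept:
            accept = np.random.random() < np.exp(-(e_new - energy) / temperature)
        if accept:
            energy = e_new
            n_accept += 1
            # <= so equal-energy plateaus keep the latest state visited
            if track_best and energy <= best_energy:
                best_energy = energy
                for k in range(L):
                    for c in range(3):
                        best_torsions[k, c] = torsions[k, c]
        else:
            if move_pos >= 0:
                for k in range(move_len):
                    for c in range(3):
                        torsions[move_pos + k, c] = old_window[k, c]
            else:
                torsions[move_res, move_ang] = old_val
    return energy, n_accept, best_energy


def _pack_shortlists(shortlists):
    """Flatten per-position shortlists into CSR arrays for the kernel."""
    frags = []
    index = {}
    rows = []
    for pos, lst in enumerate(shortlists):
        row = []
        for f in lst:
            key = id(f)
            if key not in index:
                index[key] = len(frags)
                frags.append(f)
            row.append(index[key])
        rows.append(row)
    if frags:
        maxlen = max(len(f) for f in frags)
        frag_tor = np.zeros((len(frags), maxlen, 3))
        frag_len = np.zeros(len(frags), dtype=np.int64)
        for k, f in enumerate(frags):
            frag_tor[k, : len(f)] = f.torsions
            frag_len[k] = len(f)
    else:
        frag_tor = np.zeros((0, 1, 3))
        frag_len = np.zeros(0, dtype=np.int64)
    pos_ptr = np.zeros(len(rows) + 1, dtype=np.int64)
    flat = []
    for pos, row in enumerate(rows):
        flat.extend(row)
        pos_ptr[pos + 1] = len(flat)
    pos_flat = np.array(flat, dtype=np.int64) if flat else np.zeros(0, np.int64)
    valid = np.array(
        [p for p, row in enumerate(rows) if row], dtype=np.int64
    )
    return frag_tor, frag_len, pos_ptr, pos_flat, valid


def _effective_weights(em: EnergyModel, mode: str) -> np.ndarray:
    w = em.weights.copy()
    if mode == "no_contacts":
        w[TERM_RR] = 0.0
    elif mode == "contacts_only":
        mask = np.zeros(7)
        mask[TERM_RR] = 1.0
        w = w * mask
    return w


def anneal(
    target: SequenceRecord,
    ss_pred: SecondaryStructurePrediction,
    shortlists,
    em: EnergyModel,
    contacts: ContactList | None,
    cfg: AnnealConfig,
) -> Decoy:
    """One folding run; returns the best decoy of the coldest replica.

    ``shortlists`` is the per-position fragment shortlist list (see
    :func:`~.fragments.build_shortlists`) or a FragmentLibrary, in which
    case shortlists are built here.
    """
    if not em.calibrated:
        raise ValueError("EnergyModel must be calibrated before sampling")
    if isinstance(shortlists, FragmentLibrary):
        shortlists = build_shortlists(shortlists, target, ss_pred, em.pair_table)
    n_nonempty = sum(1 for s in shortlists if s)
    if n_nonempty == 0:
        raise ValueError("all fragment shortlists are empty")
    insertable = sum(1 for s in shortlists if s is not None)
    if n_nonempty < 0.8 * len(shortlists):
        logger.warning(
            "only %d/%d positions have a non-empty shortlist",
            n_nonempty, len(shortlists),
        )
    L = len(target.sequence)
    seq = target.sequence
    is_gly = np.array([aa == "G" for aa in seq])
    types = residue_classes(seq)
    kd = hydropathy(seq)
    ss_states = em.ss_states if em.ss_states is not None else np.zeros(L, np.int64)
    ss_conf = em.ss_conf if em.ss_conf is not None else np.zeros(L)
    if contacts is not None and cfg.mode not in ("no_contacts",):
        ci, cj, cp = contacts.arrays()
    else:
        ci = np.empty(0, np.int64)
        cj = np.empty(0, np.int64)
        cp = np.empty(0, np.float64)
    weights = _effective_weights(em, cfg.mode)
    frag_tor, frag_len, pos_ptr, pos_flat, valid = _pack_shortlists(shortlists)

    start = extended_chain(seq)
    tors = [
        np.column_stack([start.phi, start.psi, start.omega]).copy()
        for _ in range(cfg.n_replicas)
    ]
    # geometric ladder, replica 0 coldest
    if cfg.n_replicas > 1:
        ratio = (cfg.t_high / cfg.t_low) ** (1.0 / (cfg.n_replicas - 1))
        ladder = np.array(
            [cfg.t_low * ratio ** r for r in range(cfg.n_replicas)]
        )
    else:
        ladder = np.array([cfg.t_low])

    steps_per_replica = cfg.steps // cfg.n_replicas
    n_blocks = max(1, math.ceil(steps_per_replica / cfg.exchange_interval)) \
        if steps_per_replica > 0 else 0
    rng = np.random.default_rng(cfg.seed)
    block_seeds = rng.integers(0, 2 ** 31 - 1,
                               size=(max(n_blocks, 1), cfg.n_replicas))

    max_sep0 = (
        schedule_max_separation(0, n_blocks, L, SHORT_MAX)
        if cfg.mode == "sequential"
        else -1
    )
    energies = np.array(
        [
            _energy_of(
                t, weights, is_gly, types, kd, ss_states, ss_conf,
                em.pair_table, ci, cj, cp, max_sep0, em.d_con, em.decay,
            )
            for t in tors
        ]
    )
    best_energy = energies[0]
    best_tor = tors[0].copy()
    n_accept_total = 0
    n_moves_total = 0
    n_swap_accept = 0
    n_swap_tries = 0

    anneal_end = cfg.t_low / cfg.t_high
    for block in range(n_blocks):
        cycle_frac = block / max(1, n_blocks - 1) if n_blocks > 1 else 1.0
        scale = 1.0 + (anneal_end - 1.0) * cycle_frac
        max_sep = (
            schedule_max_separation(block, max(1, n_blocks - 1), L, SHORT_MAX)
            if cfg.mode == "sequential"
            else -1
        )
        remaining = steps_per_replica - block * cfg.exchange_interval
        nsteps = min(cfg.exchange_interval, remaining)
        if nsteps <= 0:
            break
        for r in range(cfg.n_replicas):
            track = r == 0
            e, acc, be = _mc_block(
                tors[r], energies[r], weights, ladder[r] * scale, nsteps,
                max_sep, frag_tor, frag_len, pos_ptr, pos_flat, valid,
                is_gly, types, kd, ss_states, ss_conf, em.pair_table,
                ci, cj, cp, em.d_con, em.decay,
                int(block_seeds[block, r]),
                best_energy, best_tor, track,
            )
            energies[r] = e
            if track:
                best_energy = be
            n_accept_total += acc
            n_moves_total += nsteps
        # neighbour exchanges (alternating parity)
        for r in range(block % 2, cfg.n_replicas - 1, 2):
            t1 = ladder[r] * scale
            t2 = ladder[r + 1] * scale
            delta = (1.0 / t1 - 1.0 / t2) * (energies[r + 1] - energies[r])
            n_swap_tries += 1
            if delta >= 0 or rng.random() < math.exp(delta):
                tors[r], tors[r + 1] = tors[r + 1], tors[r]
                energies[r], energies[r + 1] = energies[r + 1], energies[r]
                n_swap_accept += 1
                if r == 0 and energies[0] < best_energy:
                    best_energy = energies[0]
                    best_tor = tors[0].copy()

    conf = _conformation_from_torsions(seq, best_tor)
    final_terms = evaluate_terms(
        conf, em, contacts if cfg.mode != "no_contacts" else None
    )
    final_energy = float(np.dot(weights, final_terms))
    return Decoy(
        conformation=conf,
        energy=final_energy,
        terms=final_terms,
        mode=cfg.mode,
        seed=cfg.seed,
        stats={
            "acceptance_rate": (
                n_accept_total / n_moves_total if n_moves_total else 0.0
            ),
            "exchange_rate": (
                n_swap_accept / n_swap_tries if n_swap_tries else 0.0
            ),
            "n_blocks": n_blocks,
        },
    )


def _conformation_from_torsions(seq: str, tor: np.ndarray) -> Conformation:
    from .geometry import build_chain

    return build_chain(seq, tor)


def generate_ensemble(
    target: SequenceRecord,
    ss_pred: SecondaryStructurePrediction,
    shortlists,
    em: EnergyModel,
    contacts: ContactList | None,
    cfg: AnnealConfig,
    n_decoys: int = 200,
    combined: bool = False,
) -> Ensemble:
    """``n_decoys`` independent annealing runs with seeds seed+0..seed+n-1.

    With ``combined`` the pool mixes the all-contacts and sequential modes
    half and half (all-contacts first), the two-schedule pool from which
    best-top-5 selection draws.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    if isinstance(shortlists, FragmentLibrary):
        shortlists = build_shortlists(shortlists, target, ss_pred, em.pair_table)
    decoys = []
    for k in range(n_decoys):
        mode = cfg.mode
        if combined:
            mode = "all" if k < (n_decoys + 1) // 2 else "sequential"
        run_cfg = AnnealConfig(
            steps=cfg.steps,
            n_replicas=cfg.n_replicas,
            t_high=cfg.t_high,
            t_low=cfg.t_low,
            exchange_interval=cfg.exchange_interval,
            mode=mode,
            seed=cfg.seed + k,
        )
        decoys.append(anneal(target, ss_pred, shortlists, em, contacts, run_cfg))
    return Ensemble(decoys)
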