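"""Predicted-contact machinery: the contact pseudo-energy (RRCON), the
sequential-introduction schedule, contact order and satisfaction statistics.

A contact is a residue pair (i, j), j - i >= 5, carrying a confidence P
(positive predictive value of the upstream predictor, in (0, 1]).  Distances
are measured between CB atoms (CA for glycine).  Contacts are classed by
sequence separation s = j - i: short (5-9), mid (10-23), long (>23).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

D_CON = 8.0          # maximum contact distance, Angstrom
DECAY = 4.0          # decay length of the unsatisfied-contact penalty, Angstrom
SHORT_MAX = 9        # end of the short-range separation class
MID_MAX = 23         # end of the mid-range class; s = 23 is mid, > 23 long

RANGE_CLASSES = ("short", "mid", "long")


def range_class(separation: int) -> str:
    """Class of a sequence separation: short 5-9, mid 10-23, long > 23."""
    if separation < 5:
        raise ValueError(f"separation {separation} below the contact minimum 5")
    if separation <= SHORT_MAX:
        return "short"
    if separation <= MID_MAX:
        return "mid"
    return "long"


@dataclass(frozen=True)
class ContactRecord:
    """One predicted contact; indices 0-based, i < j, separation >= 5."""

    i: int
    j: int
    ppv: float

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError(f"contact indices must satisfy i < j: ({self.i},{self.j})")
        if self.j - self.i < 5:
            raise ValueError(f"contact separation {self.j - self.i} < 5")
        if not 0.0 < self.ppv <= 1.0:
            raise ValueError(f"ppv must be in (0, 1]: {self.ppv}")

    @property
    def separation(self) -> int:
        return self.j - self.i

    @property
    def range_class(self) -> str:
        return range_class(self.separation)


class ContactList:
    """Contacts ordered by descending ppv (ties by (i, j) lexicographic).

    ``L`` is the target length; ``top_l(k)`` returns the first
    min(round(k*L), n) records — the paper-style top-L prefix for k = 1.
    """

    def __init__(self, records, L: int):
        self.records: list[ContactRecord] = sorted(
            records, key=lambda r: (-r.ppv, r.i, r.j)
        )
        self.L = int(L)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, idx):
        return self.records[idx]

    def top_l(self, k: float = 1.0) -> "ContactList":
        n = min(int(round(k * self.L)), len(self.records))
        out = ContactList.__new__(ContactList)
        out.records = self.records[:n]
        out.L = self.L
        return out

    def arrays(self):
        """(i, j, ppv) as numpy arrays, in list order."""
        if not self.records:
            return (
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.float64),
            )
        i = np.array([r.i for r in self.records], dtype=np.int64)
        j = np.array([r.j for r in self.records], dtype=np.int64)
        p = np.array([r.ppv for r in self.records], dtype=np.float64)
        return i, j, p


# ---------------------------------------------------------------------------
# RRCON pseudo-energy
# ---------------------------------------------------------------------------

def rrcon_energy(
    ppv: float, d: float, d_con: float = D_CON, decay: float = DECAY
) -> float:
    """Contact pseudo-energy for one predicted contact.

    A square well of depth -P out to ``d_con``; beyond it the attraction
    decays exponentially and the term approaches the unsatisfied-contact
    penalty +P, so violated contacts are penalised proportionally to P:

        E(d) = -P                                   for d <= d_con
        E(d) = P * (1 - 2 exp(-(d - d_con)/decay))   for d >  d_con

    Continuous at d_con, strictly increasing beyond it, linear in P.
    """
    if ppv <= 0:
        raise ValueError("ppv must be positive (non-positive contacts are filtered)")
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d <= d_con:
        return -ppv
    return ppv * (1.0 - 2.0 * math.exp(-(d - d_con) / decay))


def rrcon_total(
    model,
    contacts: ContactList,
    max_separation: int | None = None,
    d_con: float = D_CON,
    decay: float = DECAY,
) -> float:
    """Sum of :func:`rrcon_energy` over active contacts of a conformation.

    ``max_separation`` restricts the active set to contacts with
    j - i <= max_separation (the sequential-introduction schedule); ``None``
    activates all contacts.  Distances are CB-CB (CA for glycine).
    """
    cb = model.cb
    L = cb.shape[0]
    total = 0.0
    for rec in contacts:
        if rec.j >= L:
            raise IndexError(
                f"contact ({rec.i},{rec.j}) out of range for length {L}"
            )
        if max_separation is not None and rec.separation > max_separation:
            continue
        d = float(np.linalg.norm(cb[rec.i] - cb[rec.j]))
        total += rrcon_energy(rec.ppv, d, d_con, decay)
    return total


# ---------------------------------------------------------------------------
# sequential contact-introduction schedule
# ---------------------------------------------------------------------------

def schedule_max_separation(t: int, T: int, L: int, s0: int = SHORT_MAX) -> int:
    """Maximum active contact separation at cycle ``t`` of ``T``.

    Linear ramp from ``s0`` (only short-range contacts at the start of the
    run) to L - 1 (all contacts) with round-half-up; T = 0 means all
    contacts are active throughout.
    """
    if T == 0:
        return L - 1
    if not 0 <= t <= T:
        raise ValueError(f"cycle {t} outside [0, {T}]")
    x = s0 + (L - 1 - s0) * t / T
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# contact order & satisfaction statistics
# ---------------------------------------------------------------------------

def contact_order(contacts: ContactList, k: float = 1.0) -> float:
    """Predicted contact order, percent: 100 * mean separation / L, over top-k*L."""
    top = contacts.top_l(k)
    if len(top) == 0:
        raise ValueError("no contacts in the top-k*L prefix")
    mean_sep = float(np.mean([r.separation for r in top]))
    return 100.0 * mean_sep / contacts.L


def satisfaction_stats(
    model,
    contacts: ContactList,
    native=None,
    k: float = 1.0,
    d_con: float = D_CON,
) -> dict:
    """Per-range contact-satisfaction report for a model.

    A predicted contact is satisfied when the model's CB-CB distance is
    <= d_con.  With a native structure, predictions are split into true
    (native distance <= d_con) and false, and satisfied fractions are
    reported separately for each.  Returns a dict keyed by range class
    ('short'/'mid'/'long') plus 'overall'.
    """
    top = contacts.top_l(k)
    cb = model.cb
    native_cb = native.cb if native is not None else None
    if native is not None and len(native.sequence) != cb.shape[0]:
        raise ValueError("native and model lengths differ")
    keys = list(RANGE_CLASSES) + ["overall"]
    stats = {
        key: {
            "n_predicted": 0, "n_satisfied": 0,
            "n_true": 0, "n_true_satisfied": 0,
            "n_false": 0, "n_false_satisfied": 0,
        }
        for key in keys
    }
    for rec in top:
        d = float(np.linalg.norm(cb[rec.i] - cb[rec.j]))
        sat = d <= d_con
        for key in (rec.range_class, "overall"):
            s = stats[key]
            s["n_predicted"] += 1
            s["n_satisfied"] += sat
            if native_cb is not None:
                dn = float(np.linalg.norm(native_cb[rec.i] - native_cb[rec.j]))
                if dn <= d_con:
                    s["n_true"] += 1
                    s["n_true_satisfied"] += sat
                else:
                    s["n_false"] += 1
                    s["n_false_satisfied"] += sat
    for s in stats.values():
        s["fraction"] = (
            s["n_satisfied"] / s["n_predicted"] if s["n_predicted"] else float("nan")
        )
    return stats


def satisfaction_tsv(stats: dict) -> str:
    cols = (
        "range", "n_predicted", "n_satisfied", "fraction",
        "n_true", "n_true_satisfied", "n_false", "n_false_satisfied",
    )
    lines = ["\t".join(cols)]
    for key in list(RANGE_CLASSES) + ["overall"]:
        s = stats[key]
        lines.append(
            "\t".join(
                [key]
                + [str(s[c]) if c != "fraction" else f"{s[c]:.4f}" for c in cols[1:]]
            )
        )
    return "\n".join(lines) + "\n"
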