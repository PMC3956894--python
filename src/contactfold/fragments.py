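"""Fragment library construction and per-position shortlist selection.

Fragments are torsion snippets cut from source structures: every contiguous
fixed-length window (default 9 residues) plus supersecondary fragments
spanning two secondary-structure elements (helix/strand runs of >= 4
residues) and their connecting loop (<= 8 residues).  Secondary structure of
library material is assigned geometrically from backbone torsions, so no
external assignment program is needed.  Library decontamination drops any
window whose local sequence identity to the excluded target reaches the
threshold, emulating a blind-prediction setting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .formats_io import SecondaryStructurePrediction, SequenceRecord
from .geometry import Conformation, build_chain, classify_ss

logger = logging.getLogger("contactfold")

FIXED_LEN = 9
MIN_ELEMENT = 4      # residues in a supersecondary helix/strand element
MAX_LOOP = 8         # residues in the connecting loop
MAX_IDENTITY = 0.35  # decontamination threshold over a window


@dataclass(frozen=True)
class Fragment:
    kind: str                 # "fixed" or "supersecondary"
    torsions: np.ndarray      # (length, 3) phi/psi/omega, degrees
    ss: str                   # geometric H/E/C string
    sequence: str             # source sequence of the window
    source: str               # source structure id
    offset: int               # 0-based start in the source

    def __post_init__(self):
        object.__setattr__(
            self, "torsions", np.asarray(self.torsions, dtype=float)
        )
        if len(self.ss) != self.torsions.shape[0] or self.torsions.shape[1] != 3:
            raise ValueError("fragment torsions/ss length mismatch")
        if len(self) < 3:
            raise ValueError("fragment shorter than 3 residues")

    def __len__(self) -> int:
        return self.torsions.shape[0]

    @property
    def pattern(self) -> str:
        """Supersecondary pattern label, e.g. 'H-loop-H' ('' for fixed)."""
        if self.kind != "supersecondary":
            return ""
        return f"{self.ss[0]}-loop-{self.ss[-1]}"


@dataclass
class FragmentLibrary:
    fragments: list[Fragment] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fragments)

    def of_kind(self, kind: str) -> list[Fragment]:
        return [f for f in self.fragments if f.kind == kind]


def _ss_runs(ss: str):
    """Maximal runs of identical states as (state, start, end) half-open."""
    runs = []
    start = 0
    for i in range(1, len(ss) + 1):
        if i == len(ss) or ss[i] != ss[start]:
            runs.append((ss[start], start, i))
            start = i
    return runs


def _window_identity(window_seq: str, target: str) -> float:
    """Best ungapped local identity of the window against the target."""
    w = len(window_seq)
    if w > len(target):
        return 0.0
    best = 0
    for off in range(len(target) - w + 1):
        m = sum(a == b for a, b in zip(window_seq, target[off:off + w]))
        if m > best:
            best = m
    return best / w


def build_library(
    sources,
    fixed_len: int = FIXED_LEN,
    exclude_target: SequenceRecord | None = None,
    max_identity: float = MAX_IDENTITY,
    source_ids=None,
) -> FragmentLibrary:
    """Cut fixed-length and supersecondary fragments from source structures.

    ``sources`` is an iterable of Conformations (their ``segments`` limit the
    extractable windows).  Windows whose local sequence identity to
    ``exclude_target`` reaches ``max_identity`` are dropped.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("no source structures")
    if source_ids is None:
        source_ids = [f"src{k}" for k in range(len(sources))]
    target_seq = exclude_target.sequence if exclude_target is not None else None
    frags: list[Fragment] = []
    for sid, conf in zip(source_ids, sources):
        tor = np.column_stack([conf.phi, conf.psi, conf.omega])
        ss = "".join(
            classify_ss(conf.phi[i], conf.psi[i]) for i in range(len(conf))
        )
        for seg_start, seg_end in conf.segments:
            seg_len = seg_end - seg_start
            # fixed-length windows
            for off in range(seg_start, seg_end - fixed_len + 1):
                frags.append(
                    Fragment(
                        "fixed",
                        tor[off:off + fixed_len].copy(),
                        ss[off:off + fixed_len],
                        conf.sequence[off:off + fixed_len],
                        sid,
                        off,
                    )
                )
            # supersecondary: element-loop-element spans
            runs = [
                r for r in _ss_runs(ss[seg_start:seg_end])
            ]
            elems = [
                (state, seg_start + s, seg_start + e)
                for state, s, e in runs
                if state in "HE" and e - s >= MIN_ELEMENT
            ]
            for (s1, a1, b1), (s2, a2, b2) in zip(elems, elems[1:]):
                loop = a2 - b1
                if 0 <= loop <= MAX_LOOP:
                    frags.append(
                        Fragment(
                            "supersecondary",
                            tor[a1:b2].copy(),
                            ss[a1:b2],
                            conf.sequence[a1:b2],
                            sid,
                            a1,
                        )
                    )
    if target_seq is not None:
        frags = [
            f
            for f in frags
            if _window_identity(f.sequence, target_seq) < max_identity
        ]
    if not frags:
        raise ValueError("fragment library empty after decontamination")
    return FragmentLibrary(
        frags,
        {"n_sources": len(sources), "fixed_len": fixed_len,
         "max_identity": max_identity},
    )


# ---------------------------------------------------------------------------
# shortlists
# ---------------------------------------------------------------------------

SS_MATCH_MIN = 0.70   # confidence-weighted agreement threshold
SHORTLIST_K = 25


def _ss_agreement(
    frag: Fragment, position: int, ss_pred: SecondaryStructurePrediction
) -> float:
    """Confidence-weighted fraction of window positions whose predicted state
    matches the fragment's geometric state."""
    num = 0.0
    den = 0.0
    for k in range(len(frag)):
        i = position + k
        conf = ss_pred.confidences[i, "CHE".index(ss_pred.states[i])]
        den += conf
        if frag.ss[k] == ss_pred.states[i]:
            num += conf
    return num / den if den > 0 else 0.0


def threading_score(frag: Fragment, window_seq: str, pair_table) -> float:
    """Pairwise-potential energy of the target residues mounted on the
    fragment's local geometry (the shortlist ranking score)."""
    from .energy import N_BINS, residue_classes

    conf = build_chain(window_seq, frag.torsions)
    cb = conf.cb
    cls = residue_classes(window_seq)
    w = len(window_seq)
    e = 0.0
    for i in range(w):
        for j in range(i + 5, w):
            d = float(np.linalg.norm(cb[i] - cb[j]))
            if d >= 15.0:
                continue
            b = int(d / 0.5)
            sc = 0 if j - i <= 10 else 1
            e += pair_table[cls[i], cls[j], b, sc]
    return e


def shortlist(
    lib: FragmentLibrary,
    position: int,
    ss_pred: SecondaryStructurePrediction,
    target: SequenceRecord,
    pair_table,
    K: int = SHORTLIST_K,
) -> list[Fragment]:
    """Ranked fragments insertable at ``position``.

    Filters to fragments whose geometric secondary structure agrees with the
    prediction (confidence-weighted agreement >= 70%), then ranks by
    threading score, ascending.  Ties break by (source, offset).  When the
    filter is empty, falls back to the K best-agreeing fragments.
    """
    L = len(target.sequence)
    fitting = [f for f in lib.fragments if position + len(f) <= L]
    scored = []
    for f in fitting:
        agree = _ss_agreement(f, position, ss_pred)
        if agree >= SS_MATCH_MIN:
            scored.append((f, agree))
    if not scored:
        logger.warning(
            "no fragment passes the ss filter at position %d; falling back "
            "to best ss agreement", position,
        )
        by_agree = sorted(
            ((f, _ss_agreement(f, position, ss_pred)) for f in fitting),
            key=lambda t: (-t[1], t[0].source, t[0].offset),
        )
        return [f for f, _ in by_agree[:K]]
    window = target.sequence
    ranked = sorted(
        scored,
        key=lambda t: (
            threading_score(
                t[0], window[position:position + len(t[0])], pair_table
            ),
            t[0].source,
            t[0].offset,
        ),
    )
    return [f for f, _ in ranked[:K]]


def build_shortlists(
    lib: FragmentLibrary,
    target: SequenceRecord,
    ss_pred: SecondaryStructurePrediction,
    pair_table,
    K: int = SHORTLIST_K,
) -> list[list[Fragment]]:
    """Shortlists for every target position (empty where nothing fits)."""
    L = len(target.sequence)
    min_len = min(len(f) for f in lib.fragments)
    out = []
    for pos in range(L):
        if pos + min_len > L:
            out.append([])
        else:
            out.append(shortlist(lib, pos, ss_pred, target, pair_table, K))
    return out


# ---------------------------------------------------------------------------
# serialization (JSON lines)
# ---------------------------------------------------------------------------

def write_library(lib: FragmentLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write(json.dumps({"meta": lib.meta}) + "\n")
        for f in lib.fragments:
            fh.write(
                json.dumps(
                    {
                        "kind": f.kind,
                        "source": f.source,
                        "offset": f.offset,
                        "ss": f.ss,
                        "sequence": f.sequence,
                        "torsions": [[round(x, 4) for x in row]
                                     for row in f.torsions.tolist()],
                    }
                )
                + "\n"
            )


def read_library(path) -> FragmentLibrary:
    frags = []
    meta = {}
    with open(path) as fh:
        for k, line in enumerate(fh):
            obj = json.loads(line)
            if k == 0 and "meta" in obj:
                meta = obj["meta"]
                continue
            frags.append(
                Fragment(
                    obj["kind"],
                    np.array(obj["torsions"]),
                    obj["ss"],
                    obj["sequence"],
                    obj["source"],
                    obj["offset"],
                )
            )
    if not frags:
        raise ValueError(f"{path}: empty fragment library")
    return FragmentLibrary(frags, meta)
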