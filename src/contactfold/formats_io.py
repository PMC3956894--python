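"""Readers/writers for the tool's external formats plus MSA preprocessing.

Formats: FASTA (sequences and alignments), PSIPRED ``.ss2`` secondary
structure, CASP RR predicted-contact lists, and PDB backbone structures
(single models and multi-MODEL decoy ensembles with per-model energy
REMARKs).  Residue indices are 1-based in every file format and 0-based in
memory; the conversion happens here and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .geometry import (
    ATOM_NAMES,
    Conformation,
    extract_torsions,
    virtual_cb,
)

logger = logging.getLogger("contactfold")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
AA_1TO3["X"] = "UNK"

MIN_SEPARATION = 5          # smallest sequence separation a contact may have
CHAIN_BREAK_CA_CA = 4.5     # Angstrom; larger gaps split fragment segments


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SecondaryStructurePrediction:
    """Per-residue 3-state prediction with (pC, pH, pE) confidences."""

    states: str                  # characters in {H, E, C}
    confidences: np.ndarray      # (L, 3) columns (pC, pH, pE), rows sum to 1

    def __post_init__(self):
        self.confidences = np.asarray(self.confidences, dtype=float)
        if self.confidences.shape != (len(self.states), 3):
            raise ValueError("confidences must be (L, 3)")
        if set(self.states) - set("HEC"):
            raise ValueError("states must be H/E/C")

    def __len__(self) -> int:
        return len(self.states)

    def state_probability(self, i: int, state: str) -> float:
        return float(self.confidences[i, "CHE".index(state)])


@dataclass
class Alignment:
    """Aligned rows; the first row is the query."""

    rows: list[SequenceRecord]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("empty alignment")
        n = len(self.rows[0].sequence)
        if any(len(r.sequence) != n for r in self.rows):
            raise ValueError("alignment rows differ in length")

    @property
    def query(self) -> SequenceRecord:
        return self.rows[0]

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> SequenceRecord:
    """First record of a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        return SequenceRecord(rec.id, str(rec.seq).upper())
    raise ParseError(f"no FASTA records in {path}")


def write_fasta(records, path) -> None:
    if isinstance(records, SequenceRecord):
        records = [records]
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


_GAP_ALPHABET = AA_ALPHABET | {"-"}


def read_alignment(path) -> Alignment:
    """Aligned FASTA; gaps '-' (or '.') allowed, first record is the query."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(".", "-")
        bad = set(seq) - _GAP_ALPHABET
        if bad:
            raise ParseError(f"bad characters in alignment row {rec.id}: {sorted(bad)}")
        rows.append((rec.id, seq))
    if not rows:
        raise ParseError(f"no alignment rows in {path}")
    return Alignment([_aligned_record(i, s) for i, s in rows])


def _aligned_record(rid: str, seq: str) -> SequenceRecord:
    # bypass the residue-alphabet invariant for gapped rows
    rec = object.__new__(SequenceRecord)
    object.__setattr__(rec, "id", rid)
    object.__setattr__(rec, "sequence", seq)
    return rec


def filter_msa(
    aln: Alignment, target: SequenceRecord, min_identity: float = 0.30
) -> Alignment:
    """Apply the folding-input alignment filters.

    Duplicate rows are removed first; then columns gapped in the query are
    deleted; then rows with sequence identity to the target below
    ``min_identity`` are removed.  Identity = matches / non-gap query columns.
    """
    seen = set()
    rows = []
    for r in aln.rows:
        if r.sequence not in seen:
            seen.add(r.sequence)
            rows.append(r)
    query = rows[0].sequence
    keep = [i for i, c in enumerate(query) if c != "-"]
    rows = [
        _aligned_record(r.id, "".join(r.sequence[i] for i in keep)) for r in rows
    ]
    if rows[0].sequence != target.sequence:
        logger.warning(
            "alignment query differs from target sequence; identity computed "
            "against the target"
        )
    n_cols = len(rows[0].sequence)
    out = [rows[0]]
    for r in rows[1:]:
        matches = sum(a == b for a, b in zip(r.sequence, target.sequence))
        if matches / n_cols >= min_identity:
            out.append(r)
    if not out:
        raise ValueError("alignment empty after filtering")
    return Alignment(out)


# ---------------------------------------------------------------------------
# PSIPRED ss2
# ---------------------------------------------------------------------------

def read_ss2(path, sequence: str | None = None) -> SecondaryStructurePrediction:
    """Parse a PSIPRED ``.ss2`` file (index, residue, state, pC pH pE)."""
    states = []
    confs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: malformed ss2 line: {s!r}")
            state = parts[2]
            if state not in "HEC":
                raise ParseError(f"{path}:{lineno}: unknown state {state!r}")
            try:
                triplet = np.array([float(p) for p in parts[3:6]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad confidence values") from exc
            total = triplet.sum()
            if abs(total - 1.0) > 0.01:
                logger.warning(
                    "%s:%d: confidence triplet sums to %.3f; renormalizing",
                    path, lineno, total,
                )
                if total <= 0:
                    raise ParseError(f"{path}:{lineno}: non-positive confidences")
                triplet = triplet / total
            states.append(state)
            confs.append(triplet)
    if not states:
        raise ParseError(f"{path}: empty ss2 file")
    if sequence is not None and len(states) != len(sequence):
        raise ParseError(
            f"{path}: ss2 length {len(states)} != sequence length {len(sequence)}"
        )
    return SecondaryStructurePrediction("".join(states), np.array(confs))


def write_ss2(pred: SecondaryStructurePrediction, sequence: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT\n\n")
        for i, (aa, st) in enumerate(zip(sequence, pred.states)):
            pc, ph, pe = pred.confidences[i]
            fh.write(f"{i + 1:4d} {aa} {st}  {pc:6.3f} {ph:6.3f} {pe:6.3f}\n")


# ---------------------------------------------------------------------------
# CASP RR contact lists
# ---------------------------------------------------------------------------

_RR_HEADER_PREFIXES = ("PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "REMARK", "END")


def read_contacts(path, min_ppv: float = 0.0, L: int | None = None):
    """Read a CASP-RR-dialect contact list into a :class:`~.contacts.ContactList`.

    Accepts "i j d_low d_high prob" (the distance-bound columns are ignored;
    the contact well bound is the model's d_con) and bare "i j [prob]" lines.
    Records with ppv <= ``min_ppv`` (strict: only contacts with positive
    predictive value above the floor are used), separation < 5 or i == j are
    dropped; duplicate pairs keep the highest ppv; output is sorted by
    descending ppv.
    """
    from .contacts import ContactList, ContactRecord  # local import, no cycle

    best: dict[tuple[int, int], float] = {}
    max_index = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(_RR_HEADER_PREFIXES):
                continue
            parts = s.split()
            # a bare sequence line (some RR files carry the target sequence)
            if len(parts) == 1 and not parts[0][0].isdigit():
                continue
            try:
                i = int(parts[0])
                j = int(parts[1])
                if len(parts) >= 5:
                    ppv = float(parts[4])
                elif len(parts) >= 3:
                    ppv = float(parts[2])
                else:
                    ppv = 1.0
            except (ValueError, IndexError) as exc:
                raise ParseError(
                    f"{path}:{lineno}: malformed contact line: {s!r}"
                ) from exc
            if i > j:
                i, j = j, i
            if i == j:
                logger.warning("%s:%d: self-contact (%d,%d) rejected", path, lineno, i, j)
                continue
            if j - i < MIN_SEPARATION:
                continue
            if not ppv > min_ppv:
                continue
            if ppv > 1.0:
                raise ParseError(f"{path}:{lineno}: ppv {ppv} > 1")
            key = (i - 1, j - 1)  # to 0-based
            if ppv > best.get(key, -1.0):
                best[key] = ppv
            max_index = max(max_index, j)
    records = [ContactRecord(i, j, p) for (i, j), p in best.items()]
    return ContactList(records, L=L if L is not None else max_index)


def write_contacts(clist, path, target_id: str = "target") -> None:
    """Write a ContactList in CASP RR dialect (1-based indices, d 0-8)."""
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        fh.write(f"TARGET {target_id}\n")
        fh.write("MODEL 1\n")
        for rec in clist.records:
            fh.write(f"{rec.i + 1} {rec.j + 1} 0 8 {rec.ppv:.6f}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def read_structure(path, chain: str | None = None, model: int = 1) -> Conformation:
    """Read backbone (+CB) coordinates of one chain from a PDB file.

    Keeps altloc 'A'/blank records; insertion codes collapse into sequential
    numbering.  Missing CB is synthesised at the ideal tetrahedral position
    (glycine included).  A residue missing any of N/CA/C/O terminates the
    current fragment-extractable segment, as does a CA-CA gap > 4.5 A;
    segment boundaries are recorded on the returned conformation.
    """
    with open(path) as fh:
        residues = _parse_pdb_residues(fh, chain, model)
    if not residues:
        raise ParseError(f"{path}: no parseable residues" +
                         (f" in chain {chain!r}" if chain else ""))
    return _residues_to_conformation(residues)


def _residues_to_conformation(residues) -> Conformation:
    seq = []
    coords = []
    complete = []
    for resname, atoms in residues:
        seq.append(AA_3TO1.get(resname, "X"))
        ok = all(a in atoms for a in ("N", "CA", "C"))
        row = np.full((5, 3), np.nan)
        if ok:
            for k, name in enumerate(ATOM_NAMES):
                if name in atoms:
                    row[k] = atoms[name]
            if np.isnan(row[3]).any():       # O missing: treat as incomplete
                ok = "O" in atoms
            if np.isnan(row[4]).any():
                row[4] = virtual_cb(row[0], row[1], row[2])
        complete.append(ok and not np.isnan(row[:3]).any() and "O" in atoms)
        coords.append(row)
    coords = np.array(coords)
    L = len(seq)
    segments = []
    start = None
    for i in range(L):
        if not complete[i]:
            if start is not None:
                segments.append((start, i))
                start = None
            continue
        if start is None:
            start = i
        elif np.linalg.norm(coords[i, 1] - coords[i - 1, 1]) > CHAIN_BREAK_CA_CA:
            segments.append((start, i))
            start = i
    if start is not None:
        segments.append((start, L))
    # incomplete residues keep NaN-free coords by falling back to CA everywhere
    for i in range(L):
        if np.isnan(coords[i]).any():
            fallback = coords[i, 1] if not np.isnan(coords[i, 1]).any() else np.zeros(3)
            for k in range(5):
                if np.isnan(coords[i, k]).any():
                    coords[i, k] = fallback
    tor = extract_torsions(coords)
    conf = Conformation("".join(seq), tor[:, 0], tor[:, 1], tor[:, 2], coords)
    conf.segments = segments if segments else [(0, 0)]
    return conf


def _parse_pdb_residues(lines, chain, model):
    """Parse ATOM records via biotite, keeping the first altloc per atom;
    insertion codes collapse into sequential numbering.

    Returns a list of (residue_name, {atom_name: xyz}) in file order.
    """
    import io as _io

    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    text = lines if isinstance(lines, str) else "".join(lines)
    pdbf = PDBFile.read(_io.StringIO(text))
    try:
        arr = pdbf.get_structure(model=model, altloc="first")
    except (ValueError, IndexError):
        return []
    arr = arr[~arr.hetero]
    if chain is not None:
        arr = arr[arr.chain_id == chain]
    if arr.array_length() == 0:
        return []
    residues = []
    for res in struc.residue_iter(arr):
        atoms = {}
        for at in res:
            atoms.setdefault(at.atom_name, np.asarray(at.coord, dtype=float))
        residues.append((res.res_name[0], atoms))
    return residues


def _pdb_atom_lines(conf: Conformation, serial_start: int = 1, chain: str = "A"):
    lines = []
    serial = serial_start
    for i, aa in enumerate(conf.sequence):
        res3 = AA_1TO3.get(aa, "UNK")
        for k, name in enumerate(ATOM_NAMES):
            if name == "CB" and aa == "G":
                continue
            x, y, z = conf.coords[i, k]
            element = name[0]
            lines.append(
                f"ATOM  {serial:5d} {name:^4s}{res3:>4s} {chain}{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{element:>2s}"
            )
            serial += 1
    return lines, serial


def write_structure(conf: Conformation, path, chain: str = "A") -> None:
    lines, _ = _pdb_atom_lines(conf, chain=chain)
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
        fh.write("\nTER\nEND\n")


def write_ensemble(ensemble, path) -> None:
    """Write decoys as a multi-MODEL PDB with per-model energy REMARKs."""
    with open(path, "w") as fh:
        for m, decoy in enumerate(ensemble.decoys, 1):
            fh.write(f"MODEL     {m:4d}\n")
            fh.write(f"REMARK ENERGY {decoy.energy:.6f}\n")
            fh.write(f"REMARK MODE {decoy.mode}\n")
            fh.write(f"REMARK SEED {decoy.seed}\n")
            lines, _ = _pdb_atom_lines(decoy.conformation)
            fh.write("\n".join(lines))
            fh.write("\nTER\nENDMDL\n")
        fh.write("END\n")


def read_ensemble(path):
    """Read a multi-MODEL ensemble PDB written by :func:`write_ensemble`."""
    from .sampler import Decoy, Ensemble

    decoys = []
    meta = {}
    block = []
    in_model = False
    for line in open(path):
        if line.startswith("MODEL"):
            in_model = True
            meta = {"energy": np.nan, "mode": "unknown", "seed": -1}
            block = []
        elif line.startswith("REMARK ENERGY"):
            meta["energy"] = float(line.split()[2])
        elif line.startswith("REMARK MODE"):
            meta["mode"] = line.split()[2]
        elif line.startswith("REMARK SEED"):
            meta["seed"] = int(line.split()[2])
        elif line.startswith("ATOM") and in_model:
            block.append(line)
        elif line.startswith("ENDMDL"):
            conf = _residues_to_conformation(_parse_pdb_residues(block, None, 1))
            decoys.append(
                Decoy(
                    conformation=conf,
                    energy=meta["energy"],
                    terms=None,
                    mode=meta["mode"],
                    seed=meta["seed"],
                )
            )
            in_model = False
    if not decoys:
        raise ParseError(f"{path}: no MODEL blocks")
    return Ensemble(decoys)
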